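"""Exception hierarchy shared across the toolkit."""


class CycleClassError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CycleClassError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class ParameterError(CycleClassError, ValueError):
    """An operation was called with out-of-range parameters."""


class ValidationError(CycleClassError, ValueError):
    """Input data violate a structural invariant (duplicates, negatives...)."""


class FormatError(CycleClassError, ValueError):
    """An on-disk file does not parse under its declared dialect."""


class ContractError(CycleClassError, ValueError):
    """Two objects that must agree (e.g. model features vs. query genes) do not."""
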