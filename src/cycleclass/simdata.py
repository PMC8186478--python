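"""Synthetic cell-cycle scRNA-seq and survival-cohort generators.

The count simulator emulates a cycling neural stem/progenitor
population resolved into seven cell-cycle states -- Neural G0, G1,
Late G1, S, S/G2, G2/M, M/Early G1 -- plus a low-RNA outgroup class
("G1/other").  Each phase carries a block of marker genes whose mean is
up-shifted by a configurable log2 fold-change; a fraction of each
phase's markers are also elevated (at half effect) in the cyclically
adjacent phase so that neighbouring phases are genuinely confusable,
as they are in real data.  Counts are negative-binomial with per-cell
log-normal library sizes; the outgroup is simply a class with reduced
library size.  Ground-truth labels and the planted marker sets are
returned so every downstream stage can be scored.

The survival simulator produces an expression table whose signature
genes share a latent per-sample factor, and exponential survival times
whose log-hazard is linear in that factor plus covariates, so the
eigengene/Cox/Kaplan-Meier stack can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classifier import PhaseLabeling
from .errors import ConfigurationError
from .matrixio import CountMatrix

__all__ = [
    "DEFAULT_PHASES",
    "DEFAULT_PROPORTIONS",
    "SimulationConfig",
    "SimulatedDataset",
    "SurvivalSimConfig",
    "simulate_cycle_counts",
    "simulate_survival_cohort",
]

# Seven cycling states in cycle order, then the low-RNA outgroup.
DEFAULT_PHASES = (
    "Neural G0",
    "G1",
    "Late G1",
    "S",
    "S/G2",
    "G2/M",
    "M/Early G1",
    "G1/other",
)
# Observed state frequencies in the training population; the outgroup
# proportion is never reported and 0.025 (the remainder) is our choice.
DEFAULT_PROPORTIONS = (0.173, 0.367, 0.064, 0.072, 0.109, 0.106, 0.084, 0.025)


@dataclass
class SimulationConfig:
    """Parameters of the cyclic count simulator.

    Attributes
    ----------
    phase_names, phase_proportions :
        Ordered states and their sampling probabilities (must sum to 1).
        The outgroup (``outgroup_name``) takes no part in cyclic marker
        sharing and has its library size scaled down.
    markers_per_phase :
        Number of marker genes planted per state.
    effect_log2fc :
        log2 fold-change applied to a state's markers in that state.
    neighbor_share :
        Fraction of each state's markers also elevated, at half effect,
        in the next state around the cycle.
    libsize_mean, libsize_cv :
        Mean and coefficient of variation of the log-normal per-cell
        library size (expected total UMI per cell).
    nb_dispersion :
        Negative-binomial dispersion alpha, var = mu + alpha * mu^2.
    outgroup_libsize_factor :
        Multiplier (0, 1] applied to outgroup cells' library sizes.
    """

    phase_names: tuple[str, ...] = DEFAULT_PHASES
    phase_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_cells: int = 3000
    n_genes: int = 5000
    markers_per_phase: int = 100
    effect_log2fc: float = 1.5
    neighbor_share: float = 0.25
    libsize_mean: float = 5000.0
    libsize_cv: float = 0.3
    nb_dispersion: float = 0.5
    outgroup_libsize_factor: float = 0.3
    outgroup_name: str = "G1/other"
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.phase_proportions, dtype=float)
        if len(props) != len(self.phase_names):
            raise ConfigurationError(
                f"{len(props)} proportions for {len(self.phase_names)} phases"
            )
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phase_proportions must be nonnegative and sum to 1 "
                f"(sum = {props.sum()!r})"
            )
        if self.markers_per_phase * len(self.phase_names) > self.n_genes:
            raise ConfigurationError(
                f"{self.markers_per_phase} markers x {len(self.phase_names)} phases "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells and n_genes must be positive")
        if not 0 <= self.neighbor_share <= 1:
            raise ConfigurationError("neighbor_share must lie in [0, 1]")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0 < self.outgroup_libsize_factor <= 1:
            raise ConfigurationError("outgroup_libsize_factor must lie in (0, 1]")
        if self.libsize_mean <= 0 or self.libsize_cv < 0:
            raise ConfigurationError("library-size parameters out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_names"] = list(d["phase_names"])
        d["phase_proportions"] = list(d["phase_proportions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "phase_names" in d:
            d["phase_names"] = tuple(d["phase_names"])
        if "phase_proportions" in d:
            d["phase_proportions"] = tuple(d["phase_proportions"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    """Counts with ground-truth labels and planted marker sets."""

    counts: CountMatrix
    true_labels: PhaseLabeling
    marker_truth: dict[str, set[str]]
    config: SimulationConfig

    def __post_init__(self):
        if len(self.true_labels.labels) != self.counts.n_cells:
            raise ConfigurationError("label vector length != number of cells")
        genes = set(self.counts.gene_ids)
        for phase, markers in self.marker_truth.items():
            if not markers <= genes:
                raise ConfigurationError(f"marker genes for {phase!r} not in matrix")


def simulate_cycle_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw a cyclic phase-structured UMI count matrix.

    Cells get phases multinomially; each phase's expression profile is a
    shared log-normal baseline with its marker block multiplied by
    ``2**effect_log2fc`` (and the shared fraction of the neighbouring
    phase's markers by ``2**(effect_log2fc/2)``); per-cell expected
    counts are the profile times a log-normal library size, scaled down
    for the outgroup; observed counts are negative-binomial.  The same
    config (including seed) reproduces the dataset bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.phase_names)
    n_phases = len(names)
    props = np.asarray(cfg.phase_proportions, dtype=float)
    props = props / props.sum()

    phase_idx = rng.choice(n_phases, size=cfg.n_cells, p=props)

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)

    # the outgroup is purely a low-library-size class and carries no
    # markers of its own; only cycling states get marker blocks
    cycle = [p for p, name in enumerate(names) if name != cfg.outgroup_name]

    # markers are planted on adequately expressed genes (upper half of the
    # baseline), mirroring the fact that discovered cluster markers are by
    # construction expressed; near-silent genes cannot carry a detectable
    # fold-change after log1p normalization
    n_markers_total = cfg.markers_per_phase * len(cycle)
    pool_size = max(cfg.n_genes // 2, n_markers_total)
    pool = np.argsort(-baseline, kind="stable")[:pool_size]
    perm = pool[rng.permutation(pool_size)]
    marker_idx = {
        names[p]: perm[i * cfg.markers_per_phase : (i + 1) * cfg.markers_per_phase]
        for i, p in enumerate(cycle)
    }

    effect = np.ones((n_phases, cfg.n_genes))
    for p in cycle:
        effect[p, marker_idx[names[p]]] *= 2.0**cfg.effect_log2fc
    n_shared = int(round(cfg.neighbor_share * cfg.markers_per_phase))
    if len(cycle) >= 2 and n_shared > 0 and cfg.effect_log2fc > 0:
        for pos, p in enumerate(cycle):
            nxt = cycle[(pos + 1) % len(cycle)]
            shared = marker_idx[names[p]][:n_shared]
            effect[nxt, shared] *= 2.0 ** (cfg.effect_log2fc / 2.0)

    profiles = baseline[None, :] * effect
    profiles /= profiles.sum(axis=1, keepdims=True)

    sigma2 = np.log1p(cfg.libsize_cv**2)
    mu = np.log(cfg.libsize_mean) - sigma2 / 2.0
    libsize = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=cfg.n_cells)
    if cfg.outgroup_name in names:
        out_p = names.index(cfg.outgroup_name)
        libsize[phase_idx == out_p] *= cfg.outgroup_libsize_factor

    mean_counts = profiles[phase_idx, :].T * libsize[None, :]  # genes x cells
    r = 1.0 / cfg.nb_dispersion
    p_nb = r / (r + mean_counts)
    counts = rng.negative_binomial(r, p_nb)

    cell_ids = [f"C{i + 1:05d}" for i in range(cfg.n_cells)]
    labels = np.array([names[p] for p in phase_idx], dtype=object)
    marker_truth = {
        name: {gene_ids[i] for i in idx} for name, idx in marker_idx.items()
    }
    return SimulatedDataset(
        counts=CountMatrix(values=counts, gene_ids=gene_ids, cell_ids=cell_ids),
        true_labels=PhaseLabeling(labels=labels, cell_ids=cell_ids),
        marker_truth=marker_truth,
        config=cfg,
    )


@dataclass
class SurvivalSimConfig:
    """Parameters of the survival-cohort simulator.

    A latent per-sample factor g ~ N(0, 1) drives both the signature
    genes (g plus N(0, noise_sd) noise) and the hazard
    exp(beta_score * g + covariate effects) / baseline_scale.  Grade is
    drawn uniformly from {2, 3, 4} and idh_mut Bernoulli(1/2); any other
    covariate named in ``covariate_effects`` is standard normal.
    """

    n_samples: int = 500
    n_signature_genes: int = 22
    n_noise_genes: int = 200
    beta_score: float = -0.5
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"grade": 0.4, "idh_mut": -0.5}
    )
    baseline_scale: float = 1000.0  # days
    censor_fraction: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.baseline_scale <= 0:
            raise ConfigurationError("baseline_scale must be positive")
        if not 0 <= self.censor_fraction <= 1:
            raise ConfigurationError("censor_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")


def simulate_survival_cohort(
    config: SurvivalSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate (expression table, survival table, latent factor).

    Returns a samples x genes expression DataFrame (signature genes named
    ``SIG_...``, noise genes ``NOISE_...``), a survival DataFrame with
    columns ``sample_id, time_days, event, grade, idh_mut`` (+ extras),
    and the latent factor as a Series.  Censoring is independent uniform
    on [0, c] with c solved numerically so the realized censored
    fraction approximates ``censor_fraction``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    g = rng.standard_normal(n)
    sig = g[:, None] + cfg.noise_sd * rng.standard_normal((n, cfg.n_signature_genes))
    noise = rng.standard_normal((n, cfg.n_noise_genes))
    expr = pd.DataFrame(
        np.hstack([sig, noise]),
        index=sample_ids,
        columns=[f"SIG_{j + 1:04d}" for j in range(cfg.n_signature_genes)]
        + [f"NOISE_{j + 1:04d}" for j in range(cfg.n_noise_genes)],
    )

    covariates: dict[str, np.ndarray] = {}
    lin = cfg.beta_score * g
    for name, beta in cfg.covariate_effects.items():
        if name == "grade":
            values = rng.integers(2, 5, size=n).astype(float)
            lin = lin + beta * (values - 3.0)  # centered at grade III
        elif name == "idh_mut":
            values = rng.integers(0, 2, size=n).astype(float)
            lin = lin + beta * (values - 0.5)
        else:
            values = rng.standard_normal(n)
            lin = lin + beta * values
        covariates[name] = values

    # T ~ Exponential(rate = exp(lin)/baseline_scale)
    event_times = rng.exponential(scale=1.0, size=n) * cfg.baseline_scale / np.exp(lin)

    if cfg.censor_fraction > 0:
        u = rng.uniform(size=n)

        def censored_frac(c: float) -> float:
            return float(np.mean(c * u < event_times)) - cfg.censor_fraction

        lo, hi = 1e-9, float(event_times.max()) * 1e3
        if censored_frac(hi) > 0:  # even huge c leaves too much censoring
            c_max = hi
        else:
            c_max = brentq(censored_frac, lo, hi, xtol=1e-6 * cfg.baseline_scale)
        censor_times = c_max * u
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time = event_times
        event = np.ones(n, dtype=int)

    survival = pd.DataFrame({"sample_id": sample_ids, "time_days": time, "event": event})
    for name, values in covariates.items():
        survival[name] = values
    survival = survival.set_index("sample_id", drop=False)
    return expr, survival, pd.Series(g, index=sample_ids, name="latent_factor")
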