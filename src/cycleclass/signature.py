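"""Signature eigengenes and their association with patient survival.

An eigengene summarizes a gene set's expression across samples as the
first principal component of the z-scored signature submatrix, with the
sign fixed so that the score correlates positively with the per-sample
mean of the signature z-scores ("high score = high signature
expression") and rescaled to unit variance.  Association with outcome
is assessed two ways: a Cox proportional-hazards model with clinical
covariates (Efron tie handling, via lifelines), and a contrast of the
top versus bottom score quartiles by Kaplan-Meier curves with a
Fleming-Harrington G-rho weighted log-rank test (weights S(t-)^rho;
rho = 0 recovers the standard log-rank test, rho = 1, the default,
emphasizes late differences).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import chi2

from .errors import ParameterError, ValidationError

logger = logging.getLogger("cycleclass")

__all__ = [
    "SignatureScore",
    "compute_eigengene",
    "cox_association",
    "km_quartile_contrast",
    "fleming_harrington_test",
    "KMContrast",
]


@dataclass
class SignatureScore:
    """Per-sample eigengene of a gene set.

    ``values`` has zero mean and unit variance; ``explained_variance``
    is the fraction of the signature submatrix's variance captured by
    the first principal component; ``sign_anchor_corr`` is the
    (nonnegative, after correction) correlation between the eigengene
    and the per-sample mean z-score of the signature genes.
    """

    values: pd.Series
    explained_variance: float
    sign_anchor_corr: float
    genes_used: list[str]

    def __len__(self) -> int:
        return len(self.values)


def compute_eigengene(expr: pd.DataFrame, signature) -> SignatureScore:
    """Sign-corrected first-principal-component score of a gene set.

    ``expr`` is samples x genes.  The signature genes present in the
    table are z-scored across samples (zero-variance genes dropped with
    a warning), the first right singular direction gives per-sample
    scores, the sign is flipped if the scores anticorrelate with the
    per-sample mean z-score, and the result is rescaled to unit
    variance.
    """
    signature = [str(g) for g in signature]
    present = [g for g in signature if g in expr.columns]
    if not present:
        raise ValidationError("no signature genes present in the expression table")
    if expr.shape[0] < 3:
        raise ParameterError("need at least 3 samples")

    X = expr[present].to_numpy(dtype=float)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [g for g, k in zip(present, keep) if not k]
        warnings.warn(f"dropped {len(dropped)} zero-variance signature genes")
        present = [g for g, k in zip(present, keep) if k]
        X = X[:, keep]
        sds = sds[keep]
    if X.shape[1] == 0:
        raise ValidationError("all signature genes have zero variance")

    Z = (X - X.mean(axis=0)) / sds
    # PC1 via SVD of the centered (z-scored) matrix
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    explained = float(S[0] ** 2 / np.sum(S**2))

    anchor = Z.mean(axis=1)
    if anchor.std() > 0 and scores.std() > 0:
        corr = float(np.corrcoef(scores, anchor)[0, 1])
    else:
        corr = 0.0
    if corr < 0:
        scores = -scores
        corr = -corr

    sd = scores.std()
    if sd > 0:
        scores = (scores - scores.mean()) / sd
    return SignatureScore(
        values=pd.Series(scores, index=expr.index, name="eigengene"),
        explained_variance=explained,
        sign_anchor_corr=corr,
        genes_used=present,
    )


def cox_association(
    cohort: pd.DataFrame,
    terms: list[str],
    duration_col: str = "time_days",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards coefficients for the given terms.

    Maximizes the partial likelihood with Efron tie handling; returns a
    table (term, coef, se, p) on the log-hazard scale.  Constant or
    collinear covariates are rejected up front.
    """
    missing = [t for t in terms if t not in cohort.columns]
    if missing:
        raise ParameterError(f"term {missing[0]!r} absent from the cohort table")
    if cohort[event_col].sum() < 1:
        raise ValidationError("no observed events in the cohort")
    if (cohort[duration_col] <= 0).any():
        raise ValidationError("survival times must be positive")
    X = cohort[terms].to_numpy(dtype=float)
    if any(X[:, j].std() == 0 for j in range(X.shape[1])):
        bad = terms[[j for j in range(X.shape[1]) if X[:, j].std() == 0][0]]
        raise ValidationError(f"covariate {bad!r} is constant")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < len(terms):
        raise ValidationError("covariates are collinear")

    df = cohort[[duration_col, event_col] + terms].copy()
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col=duration_col, event_col=event_col)
    out = fitter.summary.loc[terms, ["coef", "se(coef)", "p"]].reset_index()
    out.columns = ["term", "coef", "se", "p"]
    return out


def fleming_harrington_test(
    time, event, group, rho: float = 1.0
) -> tuple[float, float]:
    """Fleming-Harrington G-rho weighted log-rank test for two groups.

    At each distinct event time the (observed - expected) events in
    group 1 are weighted by S(t-)^rho, where S is the left-continuous
    pooled Kaplan-Meier estimate.  Returns (chi_square, p) with 1 df;
    rho = 0 is the standard log-rank test.  If no events are observed
    the test is undefined and (nan, nan) is returned with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ParameterError(f"need exactly 2 groups, got {len(levels)}")
    if event.sum() == 0:
        warnings.warn("no observed events in either group; test undefined")
        return float("nan"), float("nan")
    in1 = group == levels[0]

    event_times = np.unique(time[event == 1])
    s_pooled = 1.0  # S(t-) of the pooled sample, updated as we walk times
    score = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & in1).sum())
        w = s_pooled**rho
        score += w * (d1 - d * n1 / n)
        if n > 1:
            variance += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        s_pooled *= 1 - d / n
    if variance == 0:
        warnings.warn("zero variance in the weighted log-rank test")
        return float("nan"), float("nan")
    stat = score**2 / variance
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class KMContrast:
    """Top-vs-bottom quartile Kaplan-Meier contrast."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival)
    medians: dict[str, float]  # median survival; inf if never reached
    chi_square: float
    p_value: float
    rho: float
    group_size: int


def km_quartile_contrast(
    cohort: pd.DataFrame,
    score,
    q: float = 0.25,
    rho: float = 1.0,
    duration_col: str = "time_days",
    event_col: str = "event",
) -> KMContrast:
    """Contrast survival of the top vs bottom score quantile groups.

    Samples are ranked by the signature score; the top group is the
    highest ``floor(q*n)`` samples and the bottom group the lowest
    ``floor(q*n)`` (ties broken by stable input order so group sizes
    are exact).  Each group gets a Kaplan-Meier estimate and its median
    survival (inf when the curve never drops to 0.5), and the groups
    are compared with the Fleming-Harrington G-rho test.
    """
    values = score.values if isinstance(score, SignatureScore) else score
    values = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    n = len(cohort)
    if len(values) != n:
        raise ParameterError("score length does not match the cohort")
    k = int(np.floor(q * n))
    if k < 1:
        raise ParameterError(f"quantile group would be empty (n={n}, q={q})")

    order = np.argsort(values, kind="stable")
    bottom_idx = order[:k]
    top_idx = order[-k:]

    curves, medians = {}, {}
    frames = []
    for name, idx in (("top", top_idx), ("bottom", bottom_idx)):
        sub = cohort.iloc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
        medians[name] = float(kmf.median_survival_time_)
        frames.append(
            pd.DataFrame(
                {
                    "time": sub[duration_col].to_numpy(),
                    "event": sub[event_col].to_numpy(),
                    "group": name,
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    stat, p = fleming_harrington_test(
        pooled["time"], pooled["event"], pooled["group"], rho=rho
    )
    return KMContrast(
        curves=curves,
        medians=medians,
        chi_square=stat,
        p_value=p,
        rho=rho,
        group_size=k,
    )
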