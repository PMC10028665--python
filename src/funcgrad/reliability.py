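"""Within-subject inference and test-retest reliability.

Two-condition repeated-measures ANOVA (equivalent to the squared paired t
when no covariate is given; ANCOVA on paired differences with a centred
covariate otherwise), Bonferroni correction, and one-way random-effects
intraclass correlation in two flavours: the ANOVA moment estimator
ICC = (BMS - EMS) / (BMS + (K - 1) EMS), which may be negative, and the
balanced-design ReML estimator, which truncates the between-subject
variance component at zero and therefore never goes below 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RmAnovaResult",
    "IccResult",
    "IccSimulationReport",
    "rm_anova_two_condition",
    "bonferroni_threshold",
    "format_threshold",
    "anova_icc",
    "reml_icc",
    "compare_icc_sets",
    "icc_simulation_study",
]


@dataclass
class RmAnovaResult:
    """Repeated-measures ANOVA outcome for a two-condition contrast."""

    f: float
    df1: int
    df2: int
    p: float
    covariate_adjusted: bool
    mean_a: float
    mean_b: float

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("F statistic cannot be negative")
        if not 0 <= self.p <= 1:
            raise ValueError("p value must lie in [0, 1]")


@dataclass
class IccResult:
    """One-way random-effects reliability coefficient with its components."""

    icc: float
    bms: float
    ems: float
    k: int
    method: str
    sigma2_between: float | None = None
    sigma2_error: float | None = None


@dataclass
class IccSimulationReport:
    """Monte-Carlo summary of ICC estimator behaviour at a planted value."""

    planted_icc: float
    n_subjects: int
    k: int
    reps: int
    mean_anova: float
    sd_anova: float
    mean_reml: float
    sd_reml: float


def _paired(values_a, values_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired condition vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    return a, b


def rm_anova_two_condition(values_a, values_b, covariate=None) -> RmAnovaResult:
    """Two-condition repeated-measures ANOVA on paired values.

    Without a covariate the F statistic on (1, n-1) degrees of freedom is
    exactly the squared paired t statistic. With a covariate (e.g. the
    per-subject EC-EO difference in frame-wise displacement) the paired
    differences are regressed on an intercept plus the centred covariate
    and the intercept is tested on (1, n-2) degrees of freedom.
    """
    a, b = _paired(values_a, values_b)
    n = a.size
    d = a - b
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != a.shape:
            raise ValueError("covariate must match the paired vectors in length")
        c = cov - cov.mean()
        if np.allclose(c, 0):
            raise ValueError("covariate is constant; refusing a degenerate adjustment")
        x = np.column_stack([np.ones(n), c])
        beta, *_ = np.linalg.lstsq(x, d, rcond=None)
        resid = d - x @ beta
        df2 = n - 2
        s2 = float(resid @ resid) / df2
        # centred covariate is orthogonal to the intercept, so
        # var(intercept-hat) = s2 / n
        if s2 == 0:
            warnings.warn("zero residual variance; reporting F = inf")
            f = np.inf if beta[0] != 0 else 0.0
        else:
            f = float(beta[0] ** 2 / (s2 / n))
        adjusted = True
    else:
        df2 = n - 1
        var_d = d.var(ddof=1)
        if var_d == 0:
            if np.allclose(d, 0):
                f = 0.0
            else:
                warnings.warn("zero variance of paired differences; reporting F = inf")
                f = np.inf
        else:
            f = float(d.mean() ** 2 / (var_d / n))
        adjusted = False
    p = float(stats.f.sf(f, 1, df2)) if np.isfinite(f) else (1.0 if f == 0 else 0.0)
    if f == 0.0:
        p = 1.0
    return RmAnovaResult(
        f=f, df1=1, df2=df2, p=p, covariate_adjusted=adjusted,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("the number of comparisons must be at least 1")
    return alpha / m


def format_threshold(threshold: float, decimals: int = 4) -> str:
    """Display helper: threshold rounded to 4 decimals, leading zero dropped
    (0.05 / 14 renders as '.0036')."""
    s = f"{round(threshold, decimals):.{decimals}f}"
    return s[1:] if s.startswith("0.") else s


def _mean_squares(session_matrix: np.ndarray) -> tuple[float, float, int, int]:
    y = np.asarray(session_matrix, dtype=float)
    if y.ndim != 2:
        raise ValueError("session matrix must be n_subjects x K")
    if np.any(~np.isfinite(y)):
        raise ValueError("session matrix has missing or non-finite cells; "
                         "the one-way ICC requires complete balanced data")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    subject_means = y.mean(axis=1)
    grand = y.mean()
    bms = k * ((subject_means - grand) ** 2).sum() / (n - 1)
    ems = ((y - subject_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float(bms), float(ems), n, k


def anova_icc(session_matrix) -> IccResult:
    """One-way random-effects ANOVA intraclass correlation.

    ICC = (BMS - EMS) / (BMS + (K - 1) EMS), where BMS is the
    between-subject mean square, EMS the within-subject (error) mean
    square, and K the number of repeated sessions. Negative estimates are
    returned as computed.
    """
    bms, ems, n, k = _mean_squares(session_matrix)
    denom = bms + (k - 1) * ems
    icc = 1.0 if denom == 0 else (bms - ems) / denom
    return IccResult(icc=float(icc), bms=bms, ems=ems, k=k, method="anova")


def reml_icc(session_matrix) -> IccResult:
    """Balanced one-way ReML intraclass correlation.

    For a complete balanced design the restricted-maximum-likelihood
    variance components have the closed form sigma_e^2 = EMS and
    sigma_b^2 = max(0, (BMS - EMS) / K), giving
    ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2). This equals the ANOVA ICC
    whenever BMS >= EMS and is 0 otherwise, so negative ANOVA values
    surface as (near-)zero ReML values.
    """
    bms, ems, n, k = _mean_squares(session_matrix)
    sigma_e2 = ems
    sigma_b2 = max(0.0, (bms - ems) / k)
    total = sigma_b2 + sigma_e2
    icc = 1.0 if total == 0 else sigma_b2 / total
    return IccResult(
        icc=float(icc), bms=bms, ems=ems, k=k, method="reml",
        sigma2_between=float(sigma_b2), sigma2_error=float(sigma_e2),
    )


def compare_icc_sets(icc_condition_a, icc_condition_b) -> RmAnovaResult:
    """Compare two per-network ICC vectors with a repeated-measures ANOVA
    treating the networks as units (df = (1, m - 1) for m networks)."""
    return rm_anova_two_condition(icc_condition_a, icc_condition_b)


def icc_simulation_study(
    planted_icc: float, n: int, k: int, reps: int, seed: int | None = None
) -> IccSimulationReport:
    """Monte-Carlo study of both ICC estimators at a planted reliability.

    Data are generated from the one-way random-effects model
    y_ij = b_i + e_ij with sigma_b^2 = planted_icc and
    sigma_e^2 = 1 - planted_icc (total variance 1).
    """
    if not 0 <= planted_icc < 1:
        raise ValueError("planted_icc must lie in [0, 1)")
    if reps < 100:
        raise ValueError("need at least 100 replications for a stable report")
    rng = np.random.default_rng(seed)
    sigma_b = np.sqrt(planted_icc)
    sigma_e = np.sqrt(1.0 - planted_icc)
    b = rng.normal(0.0, sigma_b, size=(reps, n, 1))
    e = rng.normal(0.0, sigma_e, size=(reps, n, k))
    y = b + e
    subject_means = y.mean(axis=2)
    grand = y.mean(axis=(1, 2), keepdims=True)
    bms = k * ((subject_means - grand[:, :, 0]) ** 2).sum(axis=1) / (n - 1)
    ems = ((y - subject_means[:, :, None]) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
    anova = (bms - ems) / (bms + (k - 1) * ems)
    sigma_b2 = np.clip((bms - ems) / k, 0.0, None)
    reml = sigma_b2 / (sigma_b2 + ems)
    return IccSimulationReport(
        planted_icc=planted_icc,
        n_subjects=n,
        k=k,
        reps=reps,
        mean_anova=float(anova.mean()),
        sd_anova=float(anova.std(ddof=1)),
        mean_reml=float(reml.mean()),
        sd_reml=float(reml.std(ddof=1)),
    )
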