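"""Inferential statistics for group contrasts and brain-behavior relations.

Paired and Welch two-sample t-tests with Cohen's d, Bonferroni correction
with explicit family sizes, Pearson brain-behavior correlation tables, the
standardized CPT composite score, and the OLS model predicting treatment
response from placebo-condition connectivity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class GroupComparison:
    """One contrast: t statistic, df, p values and effect size.

    ``d`` follows the paired-differences convention for paired contrasts
    (mean difference / SD of differences = t / sqrt(n)) and the pooled-SD
    convention for two-sample contrasts; two-sample results also carry
    ``d_unpooled`` (mean difference / RMS of the two SDs) since Welch's
    test does not pool variances.
    """

    name: str
    t: float
    df: float
    p_raw: float
    d: float
    n1: int
    n2: int
    p_bonferroni: float | None = None
    d_unpooled: float | None = None


@dataclass
class PredictionModel:
    """OLS fit of an outcome on connectivity metrics plus covariates."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n: int


def cohen_d_paired(t: float, n: int) -> float:
    """Paired-design effect size from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(t / np.sqrt(n))


def paired_t(a, b, name: str = "") -> GroupComparison:
    """Two-tailed paired t-test on matched arrays ``a`` and ``b``.

    d = mean(a - b) / SD(a - b), identically t / sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return GroupComparison(
        name=name,
        t=float(t),
        df=float(n - 1),
        p_raw=float(p),
        d=cohen_d_paired(t, n),
        n1=n,
        n2=n,
    )


def welch_t(x, y, name: str = "") -> GroupComparison:
    """Two-tailed Welch t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups")
    nx, ny = x.size, y.size
    res = stats.ttest_ind(x, y, equal_var=False)
    pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    delta = x.mean() - y.mean()
    return GroupComparison(
        name=name,
        t=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        d=float(delta / pooled) if pooled > 0 else float("inf"),
        d_unpooled=float(delta / np.sqrt((vx + vy) / 2)),
        n1=nx,
        n2=ny,
    )


def bonferroni(p_raw, m: int) -> np.ndarray:
    """Elementwise ``min(1, m * p)`` for an explicit family size ``m``."""
    p_raw = np.atleast_1d(np.asarray(p_raw, dtype=float))
    if m < p_raw.size:
        raise ValueError(
            f"family size m={m} smaller than the {p_raw.size} tests declared"
        )
    return np.minimum(1.0, m * p_raw)


def correct_family(comparisons: list[GroupComparison], m: int | None = None) -> None:
    """Fill ``p_bonferroni`` in-place for a family of comparisons."""
    if m is None:
        m = len(comparisons)
    corrected = bonferroni([c.p_raw for c in comparisons], m)
    for c, p in zip(comparisons, corrected):
        c.p_bonferroni = float(p)


def composite_cpt(table: pd.DataFrame, columns: tuple[str, ...]) -> pd.Series:
    """Composite performance score: mean of z-scored measures (lower = better).

    Each column is standardized (sample SD) across the rows of ``table``
    before averaging; the standardization population is therefore the
    analysis sample itself.
    """
    missing = set(columns) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    z = (table[list(columns)] - table[list(columns)].mean()) / table[
        list(columns)
    ].std(ddof=1)
    return z.mean(axis=1)


def brain_behavior_correlations(
    table: pd.DataFrame,
    metric_columns: tuple[str, ...],
    clinical_columns: tuple[str, ...],
    family: int | None = None,
) -> pd.DataFrame:
    """Pearson r for each (connectivity metric, clinical measure) pair.

    Rows with missing values in a pair are dropped per pair; the Bonferroni
    family defaults to the number of clinical measures (applied per
    metric). Requires n >= 10 complete cases per pair.
    """
    if family is None:
        family = len(clinical_columns)
    rows = []
    for metric in metric_columns:
        for clinical in clinical_columns:
            sub = table[[metric, clinical]].dropna()
            if len(sub) < 10:
                raise ValueError(
                    f"need >= 10 complete cases for ({metric}, {clinical}), "
                    f"got {len(sub)}"
                )
            r, p = stats.pearsonr(sub[metric], sub[clinical])
            rows.append(
                {
                    "metric": metric,
                    "clinical": clinical,
                    "n": len(sub),
                    "r": float(r),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, family * p)),
                }
            )
    return pd.DataFrame(rows)


DEFAULT_PREDICTORS = ("nii_mean", "nii_sd", "age", "fsiq", "mean_fd")


def predict_treatment_response(
    table: pd.DataFrame,
    outcome: str = "composite_change",
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> PredictionModel:
    """OLS of an outcome on connectivity metrics plus covariates.

    Raises on rank deficiency, naming the collinear columns.
    """
    cols = [outcome, *predictors]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = table[cols].dropna()
    n = len(data)
    if n <= len(predictors) + 2:
        raise ValueError(
            f"need n > {len(predictors) + 2} complete cases, got {n}"
        )
    design = sm.add_constant(data[list(predictors)], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    fit = sm.OLS(data[outcome], design).fit()
    terms = list(design.columns)
    return PredictionModel(
        terms=terms,
        coef={t: float(fit.params[t]) for t in terms},
        se={t: float(fit.bse[t]) for t in terms},
        tvalues={t: float(fit.tvalues[t]) for t in terms},
        pvalues={t: float(fit.pvalues[t]) for t in terms},
        r_squared=float(fit.rsquared),
        n=n,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence (via QR pivoting)."""
    a = design.to_numpy()
    _, r = np.linalg.qr(a)
    small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return [c for c, s in zip(design.columns, small) if s]
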