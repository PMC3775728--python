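"""Cohort inference chain: normality gate, group comparisons, screening,
and standardized multiple regression.

The analysis asks which of three candidate predictors — MCA occlusion
duration, AChA patency (occluded or not), and body weight — independently
predict 24 h infarct volume:

1. D'Agostino & Pearson omnibus normality tests gate the t-tests
   (retrospective design).
2. Two-tailed t-tests compare infarct volume between MCAo and MCAo + AChAo
   animals within each occlusion group and pooled; a group whose smaller
   cell has fewer than 3 animals is reported "not analyzed".
3. Each candidate predictor is screened by marginal Pearson correlation
   (point-biserial for the binary AChAo indicator); predictors with p < 0.10
   enter the model.
4. Ordinary least squares with standardized coefficients (z-scored response
   and predictors, sample SD with n-1 denominator) and adjusted r^2.

Permanent occlusion has no stated duration; it is coded 24 h by default
(time from occlusion to euthanasia), with an ordinal 1/2/3 coding available.
No multiple-testing correction is applied, mirroring the source analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic import GROUP_ORDER, AnimalRecord

__all__ = [
    "StatsInputError",
    "cohort_table",
    "dagostino_pearson",
    "two_sample_t",
    "two_sample_t_from_stats",
    "pearson_r",
    "ScreenEntry",
    "screen_predictors",
    "RegressionResult",
    "multiple_linear_regression",
    "GroupComparison",
    "run_group_comparisons",
    "DEFAULT_PREDICTORS",
    "DURATION_CODINGS",
]

DEFAULT_RESPONSE = "infarct_volume_mm3"
DEFAULT_PREDICTORS = ("duration_h", "acha_occluded", "weight_g")

DURATION_CODINGS = {
    "hours24": {"1h": 1.0, "2h": 2.0, "permanent": 24.0},
    "ordinal": {"1h": 1.0, "2h": 2.0, "permanent": 3.0},
}

MIN_NORMALITY_N = 8


class StatsInputError(ValueError):
    """Invalid sample or table for a statistical routine."""


def cohort_table(
    records: list[AnimalRecord],
    acha_calls: dict[str, bool] | None = None,
    volumes: dict[str, float] | None = None,
    duration_coding: str = "hours24",
) -> pd.DataFrame:
    """Assemble the analysis table, one row per animal.

    ``acha_calls`` (e.g. the blinded CBV classification) and ``volumes``
    (e.g. edema-corrected histology volumes) override the records' ground
    truth when given, reproducing the study's measurement chain.
    """
    if duration_coding not in DURATION_CODINGS:
        raise StatsInputError(f"unknown duration coding {duration_coding!r}")
    coding = DURATION_CODINGS[duration_coding]
    rows = []
    for rec in records:
        acha = (
            acha_calls[rec.animal_id] if acha_calls is not None else rec.acha_occluded
        )
        vol = (
            volumes[rec.animal_id]
            if volumes is not None
            else rec.infarct_volume_total
        )
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.occlusion_group,
                "duration_h": coding[rec.occlusion_group],
                "acha_occluded": int(bool(acha)),
                "weight_g": rec.weight_g,
                DEFAULT_RESPONSE: vol,
            }
        )
    return pd.DataFrame(rows)


def _as_sample(x, min_n: int, name: str = "sample") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise StatsInputError(f"{name} must be 1D with at least {min_n} values")
    if np.any(~np.isfinite(x)):
        raise StatsInputError(f"{name} contains non-finite values")
    return x


def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino & Pearson omnibus K^2 normality test.

    K^2 is the sum of the squared normalizing transforms of sample skewness
    and kurtosis, referred to chi-square with 2 df. Requires n >= 8 and a
    non-degenerate sample.
    """
    x = _as_sample(sample, MIN_NORMALITY_N)
    if np.std(x) == 0:
        raise StatsInputError("normality test undefined for a constant sample")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)


def two_sample_t(a, b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``variant`` selects Student's pooled-variance test (default, the
    convention of the software used in the source analysis) or Welch's.
    """
    a = _as_sample(a, 2, "a")
    b = _as_sample(b, 2, "b")
    if variant not in ("pooled", "welch"):
        raise StatsInputError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from group summaries; returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise StatsInputError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise StatsInputError("SDs must be non-negative")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise StatsInputError("variant must be 'pooled' or 'welch'")
    if se == 0:
        raise StatsInputError("zero standard error: degenerate summaries")
    t = (mean1 - mean2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    On a binary variable this is the point-biserial correlation; p comes
    from the exact t transform with n-2 df.
    """
    x = _as_sample(x, 3, "x")
    y = _as_sample(y, 3, "y")
    if len(x) != len(y):
        raise StatsInputError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsInputError("correlation undefined for a constant variable")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ScreenEntry:
    """Marginal screening outcome for one candidate predictor."""

    name: str
    r: float | None
    p: float | None
    included: bool
    note: str = ""


def screen_predictors(
    table: pd.DataFrame,
    response: str = DEFAULT_RESPONSE,
    candidates: tuple[str, ...] = DEFAULT_PREDICTORS,
    alpha: float = 0.10,
) -> list[ScreenEntry]:
    """Marginal Pearson screening: candidates with p < alpha are included.

    Candidate order is preserved. A constant candidate (e.g. an AChAo column
    with no occlusions) is excluded with an explanatory note rather than
    raising, so degenerate cohorts produce a warning, not a crash.
    """
    for col in (response, *candidates):
        if col not in table.columns:
            raise StatsInputError(f"unknown column {col!r}")
        if table[col].isna().any():
            raise StatsInputError(f"column {col!r} contains missing values")
    y = table[response].to_numpy(dtype=float)
    out: list[ScreenEntry] = []
    for name in candidates:
        x = table[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            out.append(
                ScreenEntry(name, None, None, False, "constant predictor: excluded")
            )
            continue
        r, p = pearson_r(x, y)
        out.append(ScreenEntry(name, r, p, bool(p < alpha)))
    return out


@dataclass
class RegressionResult:
    """OLS fit with standardized coefficients.

    ``beta`` are coefficients after z-scoring response and predictors with
    the sample SD (n-1 denominator); for a single predictor |beta| equals
    |Pearson r|. p-values are the coefficient t-tests of the unstandardized
    fit (identical t statistics).
    """

    predictors: tuple[str, ...]
    beta: dict[str, float]
    coef: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    n: int
    warnings: list[str] = field(default_factory=list)


def multiple_linear_regression(
    table: pd.DataFrame,
    response: str = DEFAULT_RESPONSE,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> RegressionResult:
    """Ordinary least squares of ``response`` on ``predictors``.

    Constant predictors are dropped with a warning; a rank-deficient design
    among the remaining predictors raises :class:`StatsInputError`.
    """
    for col in (response, *predictors):
        if col not in table.columns:
            raise StatsInputError(f"unknown column {col!r}")
    warnings: list[str] = []
    keep = []
    for name in predictors:
        if table[name].std(ddof=1) == 0:
            warnings.append(f"constant predictor {name!r} dropped")
        else:
            keep.append(name)
    if not keep:
        raise StatsInputError("no non-constant predictors remain")
    n = len(table)
    if n <= len(keep) + 1:
        raise StatsInputError("need n > number of predictors + 1")
    y = table[response].to_numpy(dtype=float)
    X = table[list(keep)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(keep) + 1:
        raise StatsInputError("rank-deficient design (collinear predictors)")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    sy = np.std(y, ddof=1)
    beta = {}
    coef = {}
    pvals = {}
    for j, name in enumerate(keep):
        b = float(model.params[j + 1])
        coef[name] = b
        beta[name] = b * float(np.std(X[:, j], ddof=1)) / sy
        pvals[name] = float(model.pvalues[j + 1])
    return RegressionResult(
        predictors=tuple(keep),
        beta=beta,
        coef=coef,
        pvalues=pvals,
        r_squared=float(model.rsquared),
        adjusted_r_squared=float(model.rsquared_adj),
        n=n,
        warnings=warnings,
    )


@dataclass
class GroupComparison:
    """AChAo-vs-not infarct volume comparison within one stratum."""

    name: str
    n_no_achao: int
    n_achao: int
    mean_no_achao: float | None
    sd_no_achao: float | None
    mean_achao: float | None
    sd_achao: float | None
    analyzed: bool
    reason: str = ""
    normality: dict[str, float] = field(default_factory=dict)
    t: float | None = None
    df: float | None = None
    p: float | None = None
    warnings: list[str] = field(default_factory=list)


def _cell_summary(x: np.ndarray) -> tuple[float | None, float | None]:
    if len(x) == 0:
        return None, None
    if len(x) == 1:
        return float(x[0]), None
    return float(np.mean(x)), float(np.std(x, ddof=1))


def _normality_gate(
    cells: tuple[np.ndarray, np.ndarray], scope: str
) -> tuple[dict[str, float], list[str]]:
    """Run the normality test at the widest feasible scope.

    'auto' tests per cell when both cells have n >= 8, else on the pooled
    group when it has n >= 8, else flags the test as untestable. A failed
    test flags the comparison; it does not suppress the t statistic (no
    rank-based fallback is substituted).
    """
    a, b = cells
    pvalues: dict[str, float] = {}
    warnings: list[str] = []
    use_cells = scope == "cell" or (
        scope == "auto" and len(a) >= MIN_NORMALITY_N and len(b) >= MIN_NORMALITY_N
    )
    if use_cells:
        for label, x in (("no_achao", a), ("achao", b)):
            if len(x) < MIN_NORMALITY_N or np.std(x) == 0:
                warnings.append(f"normality untestable in cell {label} (n<8)")
                continue
            _, p = dagostino_pearson(x)
            pvalues[label] = p
            if p <= 0.05:
                warnings.append(f"non-normal cell {label} (p={p:.3g})")
    else:
        pooled = np.concatenate([a, b])
        if len(pooled) >= MIN_NORMALITY_N and np.std(pooled) > 0:
            _, p = dagostino_pearson(pooled)
            pvalues["group"] = p
            if p <= 0.05:
                warnings.append(f"non-normal group distribution (p={p:.3g})")
        else:
            warnings.append("normality untestable (n<8)")
    return pvalues, warnings


def run_group_comparisons(
    table: pd.DataFrame,
    response: str = DEFAULT_RESPONSE,
    group_col: str = "group",
    indicator: str = "acha_occluded",
    min_cell: int = 3,
    variant: str = "pooled",
    normality_scope: str = "auto",
) -> list[GroupComparison]:
    """Within-group and pooled AChAo-vs-not comparisons.

    Groups appear in the order 1 h, 2 h, permanent (those present), followed
    by a 'pooled' row over all animals. A comparison whose smaller cell has
    fewer than ``min_cell`` animals is reported "not analyzed", matching the
    small-cell rule of the source analysis.
    """
    for col in (response, group_col, indicator):
        if col not in table.columns:
            raise StatsInputError(f"unknown column {col!r}")
    groups = [g for g in GROUP_ORDER if g in set(table[group_col])]
    groups += [g for g in table[group_col].unique() if g not in GROUP_ORDER]
    out: list[GroupComparison] = []
    for name in [*groups, "pooled"]:
        sub = table if name == "pooled" else table[table[group_col] == name]
        a = sub.loc[sub[indicator] == 0, response].to_numpy(dtype=float)
        b = sub.loc[sub[indicator] == 1, response].to_numpy(dtype=float)
        mean_a, sd_a = _cell_summary(a)
        mean_b, sd_b = _cell_summary(b)
        comp = GroupComparison(
            name=name,
            n_no_achao=len(a),
            n_achao=len(b),
            mean_no_achao=mean_a,
            sd_no_achao=sd_a,
            mean_achao=mean_b,
            sd_achao=sd_b,
            analyzed=False,
        )
        if min(len(a), len(b)) < min_cell:
            comp.reason = (
                f"not analyzed: smaller cell has n={min(len(a), len(b))} < {min_cell}"
            )
            out.append(comp)
            continue
        comp.normality, comp.warnings = _normality_gate((a, b), normality_scope)
        t, df, p = two_sample_t(a, b, variant=variant)
        comp.analyzed = True
        comp.t, comp.df, comp.p = t, df, p
        out.append(comp)
    return out
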