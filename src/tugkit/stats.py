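"""The validity-analysis statistics layer.

Reusable operations mirroring the study's analysis plan: normality-gated
two-group comparisons (pooled-variance t or Mann-Whitney U), effect sizes r
with the published interpretation thresholds (0.12 small / 0.20 medium /
0.32 large), Pearson/Spearman correlations with magnitude labels, the
mRS / FACHS clinical dichotomizations, the two-means sample-size formula,
and a cohort-level report builder.

Compatibility notes
-------------------
* The Mann-Whitney normal approximation uses NO tie correction and NO
  continuity correction, which reproduces the published r values exactly
  (e.g. U = 549 with n = 36/33 gives r = 0.065); both corrections are
  available as switches.
* The t test pools variances (the published tables use a fixed
  df = n1 + n2 - 2); Welch is available as a switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from ._errors import DataError, ParameterError

EFFECT_THRESHOLDS = (0.12, 0.20, 0.32)  # small / medium / large


def effect_label(r: float) -> str:
    if r >= EFFECT_THRESHOLDS[2]:
        return "large"
    if r >= EFFECT_THRESHOLDS[1]:
        return "medium"
    if r >= EFFECT_THRESHOLDS[0]:
        return "small"
    return "below_small"


def correlation_magnitude(coefficient: float) -> str:
    """Magnitude label of a correlation coefficient.

    The source bands (0.1-0.3 small, 0.4-0.6 medium, >= 0.7 large) leave
    gaps; contiguous bands are used: < 0.1 negligible, [0.1, 0.4) small,
    [0.4, 0.7) medium, >= 0.7 large.
    """
    a = abs(coefficient)
    if a >= 0.7:
        return "large"
    if a >= 0.4:
        return "medium"
    if a >= 0.1:
        return "small"
    return "negligible"


@dataclass
class ComparisonResult:
    test_used: str  # {"t_pooled", "t_welch", "mann_whitney"}
    statistic: float  # t or U (U of the first sample)
    df: Optional[float]  # t only
    p: float
    effect_r: float
    effect_label: str


@dataclass
class CorrelationResult:
    method: str  # {"pearson", "spearman"}
    coefficient: float
    p: float
    magnitude: str


@dataclass(frozen=True)
class SampleSizeSpec:
    alpha: float = 0.05  # two-sided type-I rate
    beta: float = 0.05  # type-II rate
    sd: float = 10.11  # common standard deviation, s
    delta: float = 9.57  # detectable between-group difference, s

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ParameterError("alpha and beta must lie in (0, 1)")
        if self.sd <= 0:
            raise ParameterError("sd must be positive")
        if self.delta <= 0:
            raise ParameterError("delta must be positive")


# ---------------------------------------------------------------------------
# Effect-size converters
# ---------------------------------------------------------------------------

def effect_size_from_u(U: float, n1: int, n2: int) -> float:
    """r = |Z| / sqrt(N) with Z from the plain normal approximation of U.

    Z = (U - n1 n2 / 2) / sqrt(n1 n2 (n1 + n2 + 1) / 12), no tie or
    continuity correction.
    """
    if not 0 <= U <= n1 * n2:
        raise ParameterError(f"U = {U} outside [0, n1*n2] = [0, {n1 * n2}]")
    z = (U - n1 * n2 / 2.0) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return abs(z) / math.sqrt(n1 + n2)


def effect_size_from_t(t: float, df: float) -> float:
    """r = sqrt(t^2 / (t^2 + df)); monotone in |t|, -> 1 as |t| -> inf."""
    if df < 1:
        raise ParameterError(f"df must be >= 1, got {df}")
    return math.sqrt(t * t / (t * t + df))


# ---------------------------------------------------------------------------
# Two-group comparison
# ---------------------------------------------------------------------------

def _mwu_u1(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of the first sample, with midranks for ties."""
    ranks = sst.rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    normality_alpha: float = 0.05,
    method: str = "auto",
    welch: bool = False,
    tie_correction: bool = False,
    continuity: bool = False,
) -> ComparisonResult:
    """Normality-gated two-group comparison with effect size r.

    With ``method='auto'``: both groups pass Shapiro-Wilk at
    ``normality_alpha`` -> pooled-variance t (df = n1 + n2 - 2; Welch
    optional); otherwise Mann-Whitney U with a normal-approximation two-sided
    p (corrections off by default, see module notes).  ``method='t'`` or
    ``'mwu'`` forces a branch.  r comes from the matching converter.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise DataError(f"each group needs n >= 3, got {n1} and {n2}")
    if method not in ("auto", "t", "mwu"):
        raise ParameterError(f"unknown method {method!r}")

    a_const = np.ptp(a) == 0
    b_const = np.ptp(b) == 0
    if method == "auto":
        normal = False
        if not (a_const or b_const):
            normal = (
                sst.shapiro(a).pvalue > normality_alpha
                and sst.shapiro(b).pvalue > normality_alpha
            )
    else:
        normal = method == "t"

    if normal:
        if np.ptp(np.concatenate([a, b])) == 0:
            raise DataError("both groups constant and equal; t test degenerate")
        res = sst.ttest_ind(a, b, equal_var=not welch)
        t = float(res.statistic)
        df = float(res.df)
        r = effect_size_from_t(t, df)
        return ComparisonResult(
            test_used="t_welch" if welch else "t_pooled",
            statistic=t,
            df=df,
            p=float(res.pvalue),
            effect_r=r,
            effect_label=effect_label(r),
        )

    u1 = _mwu_u1(a, b)
    mean_u = n1 * n2 / 2.0
    if tie_correction:
        combined = np.concatenate([a, b])
        nn = n1 + n2
        _, counts = np.unique(combined, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (nn * (nn - 1))
        var_u = n1 * n2 / 12.0 * (nn + 1 - tie_term)
    else:
        var_u = n1 * n2 * (n1 + n2 + 1) / 12.0
    if var_u == 0:
        raise DataError("degenerate rank variance (all values tied)")
    num = u1 - mean_u
    if continuity:
        num = num - 0.5 * np.sign(num)
    z = num / math.sqrt(var_u)
    p = 2.0 * sst.norm.sf(abs(z))
    r = abs(z) / math.sqrt(n1 + n2)
    return ComparisonResult(
        test_used="mann_whitney",
        statistic=u1,
        df=None,
        p=float(min(p, 1.0)),
        effect_r=r,
        effect_label=effect_label(r),
    )


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t and df from summary statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return (mean2 - mean1) / se, float(df)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson or Spearman correlation with a magnitude label.

    ``auto`` picks Pearson when both marginals pass Shapiro-Wilk, else
    Spearman.  No multiple-testing adjustment is applied anywhere in this
    module (matching the analysis plan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise DataError(f"correlation needs n >= 4, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance in one of the vectors; correlation undefined")
    if method == "auto":
        both_normal = (
            sst.shapiro(x).pvalue > normality_alpha
            and sst.shapiro(y).pvalue > normality_alpha
        )
        method = "pearson" if both_normal else "spearman"
    if method == "pearson":
        res = sst.pearsonr(x, y)
    elif method == "spearman":
        res = sst.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    coef = float(res.statistic)
    return CorrelationResult(
        method=method,
        coefficient=coef,
        p=float(res.pvalue),
        magnitude=correlation_magnitude(coef),
    )


# ---------------------------------------------------------------------------
# Clinical dichotomizations
# ---------------------------------------------------------------------------

_DICHOTOMIES = {
    "mrs": {
        "column": "mrs",
        "low": (0, 1),
        "high": (2, 3),
        "low_label": "no_significant_disability",
        "high_label": "slight_moderate_disability",
        "valid": range(0, 4),
    },
    "fachs": {
        "column": "fachs",
        "low": (2, 3),
        "high": (4, 5),
        "low_label": "limited_community_ambulation",
        "high_label": "independent_community_ambulation",
        "valid": range(2, 6),
    },
}


def dichotomize(subjects: pd.DataFrame, by: str = "mrs") -> dict[str, pd.DataFrame]:
    """Split the stroke subjects by the clinical cutpoints.

    mRS: 0-1 (no significant disability) vs 2-3 (slight/moderate);
    FACHS: 4-5 (independent community ambulation) vs 2-3 (limited).
    Raises on scores violating the study's inclusion criteria (mRS > 3 or
    FACHS < 2 within the stroke group).
    """
    if by not in _DICHOTOMIES:
        raise ParameterError(f"unknown dichotomization {by!r}; use 'mrs' or 'fachs'")
    spec = _DICHOTOMIES[by]
    stroke = subjects[subjects["group"] == "stroke"] if "group" in subjects else subjects
    scores = stroke[spec["column"]]
    bad = ~scores.isin(spec["valid"])
    if bad.any():
        first = stroke.loc[bad].iloc[0]
        raise DataError(
            f"stroke subject {first.get('subject_id', '?')} has {by} = "
            f"{first[spec['column']]}, violating the inclusion criteria"
        )
    return {
        spec["low_label"]: stroke[scores.isin(spec["low"])],
        spec["high_label"]: stroke[scores.isin(spec["high"])],
    }


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

def sample_size_two_means(spec: SampleSizeSpec = SampleSizeSpec()) -> int:
    """Per-group n for a two-sided two-means design:
    n = ceil(2 sd^2 (z_{1-alpha/2} + z_{1-beta})^2 / delta^2)."""
    z_a = sst.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sst.norm.ppf(1.0 - spec.beta)
    n = 2.0 * spec.sd**2 * (z_a + z_b) ** 2 / spec.delta**2
    return int(math.ceil(n))


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

_PARAMETER_COLUMNS = (
    "MLDisp", "APDisp", "CCrange", "MLrange", "PturnSit", "Pstand",
    "RangeJerkSit", "RangeJerkStand", "total_time", "reaction_time",
)
_CLINICAL_COLUMNS = ("tug_s", "walk_speed_mps", "fivests_s")


@dataclass
class AnalysisReport:
    group_comparison: pd.DataFrame
    correlations: pd.DataFrame
    dichotomized: dict[str, pd.DataFrame]

    def summary_markdown(self) -> str:
        parts = [
            "# Mobility-test validity report",
            "\n## Stroke vs control\n",
            self.group_comparison.to_string(index=False),
            "\n## Correlations with clinical scores (stroke group)\n",
            self.correlations.to_string(index=False),
        ]
        for by, table in self.dichotomized.items():
            parts.append(f"\n## Stroke subgroups by {by}\n")
            parts.append(table.to_string(index=False))
        return "\n".join(parts)


def _describe(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"
    q1, md, q3 = np.percentile(x, [25, 50, 75])
    return f"{md:.2f} ({q1:.2f}-{q3:.2f})"


def _comparison_table(
    frame: pd.DataFrame, label_col: str, labels: tuple[str, str],
    parameters: Sequence[str], normality_alpha: float,
) -> pd.DataFrame:
    rows = []
    for param in parameters:
        a = frame.loc[frame[label_col] == labels[0], param].to_numpy(float)
        b = frame.loc[frame[label_col] == labels[1], param].to_numpy(float)
        res = compare_groups(a, b, normality_alpha=normality_alpha)
        normal = res.test_used.startswith("t")
        rows.append(
            {
                "parameter": param,
                labels[0]: _describe(a, normal),
                labels[1]: _describe(b, normal),
                "test": res.test_used,
                "statistic": round(res.statistic, 3),
                "df": res.df,
                "p": round(res.p, 3),
                "effect_r": round(res.effect_r, 3),
                "effect": res.effect_label,
            }
        )
    return pd.DataFrame(rows)


def analysis_report(
    cohort: pd.DataFrame,
    parameters: Sequence[str] = _PARAMETER_COLUMNS,
    clinical: Sequence[str] = _CLINICAL_COLUMNS,
    normality_alpha: float = 0.05,
) -> AnalysisReport:
    """Build the full validity report from a tidy cohort table.

    One comparison row per kinematic parameter (stroke vs control), a
    correlation table of parameters against the clinical scores within the
    stroke group, and the mRS / FACHS dichotomized contrasts.  Statistics and
    r are rounded to 3 decimals in the tables.
    """
    groups = cohort["group"].unique()
    if not {"stroke", "control"} <= set(groups):
        raise DataError("cohort must contain both a 'stroke' and a 'control' group")
    counts = cohort["group"].value_counts()
    if (counts < 3).any():
        raise DataError(f"every group needs >= 3 subjects, got {counts.to_dict()}")

    comparison = _comparison_table(
        cohort, "group", ("stroke", "control"), parameters, normality_alpha
    )

    stroke = cohort[cohort["group"] == "stroke"]
    corr_rows = []
    for clin in clinical:
        if clin not in stroke.columns:
            continue
        for param in parameters:
            res = correlate(stroke[clin], stroke[param])
            corr_rows.append(
                {
                    "clinical": clin,
                    "parameter": param,
                    "method": res.method,
                    "coefficient": round(res.coefficient, 3),
                    "p": round(res.p, 3),
                    "magnitude": res.magnitude,
                }
            )
    correlations = pd.DataFrame(corr_rows)

    dichotomized = {}
    for by in ("mrs", "fachs"):
        if by not in cohort.columns:
            continue
        halves = dichotomize(cohort, by=by)
        (lab_a, grp_a), (lab_b, grp_b) = halves.items()
        if len(grp_a) >= 3 and len(grp_b) >= 3:
            merged = pd.concat([grp_a.assign(_half=lab_a), grp_b.assign(_half=lab_b)])
            dichotomized[by] = _comparison_table(
                merged, "_half", (lab_a, lab_b), parameters, normality_alpha
            )
    return AnalysisReport(
        group_comparison=comparison,
        correlations=correlations,
        dichotomized=dichotomized,
    )
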