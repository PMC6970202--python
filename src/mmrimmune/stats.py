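"""The cohort statistics battery.

Omnibus and post-hoc tests for comparing immune cell counts across the
molecular groups, with multiplicity correction, plus heteroscedasticity
screens and inter-rater reliability:

* Kruskal-Wallis (tie-corrected) with Dunn's post-hoc z tests and
  Benjamini-Hochberg step-up false-discovery-rate adjustment;
* one-way ANOVA with Tukey's HSD, and Games-Howell pairwise comparisons
  (per-pair Welch-Satterthwaite degrees of freedom, studentized-range
  reference distribution) for heteroscedastic / unbalanced designs;
* Levene (median-centered, i.e. Brown-Forsythe), Bartlett and
  Fligner-Killeen variance screens;
* Cronbach's alpha for inter-observer agreement.

All p values are two-sided. Routing between parametric and non-parametric
paths is an explicit caller choice, never an automatic normality decision.
Omnibus and screen tests delegate to scipy; Dunn and Games-Howell are
implemented here from their standard formulas (no post-hoc library in the
dependency set), and Benjamini-Hochberg delegates to statsmodels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .records import Cohort, CohortLabel, Compartment, Marker, overall_sum, sum_compartment


class DegenerateDataError(ValueError):
    """The input admits no meaningful test (e.g. zero variance everywhere)."""


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: object  # float or (df1, df2)
    p_value: float
    adjusted_p: Optional[float] = None
    group_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    return arrays


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square reference (k-1 df)."""
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 observations in total")
    k = len(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, k - 1, 1.0)
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), k - 1, float(p))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted p values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _rank_means_and_tie_term(arrays: list[np.ndarray]):
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    rank_means = []
    start = 0
    for a in arrays:
        rank_means.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    return np.array(rank_means), tie_term, n_total


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: str = "BH",
    labels: Optional[Sequence[object]] = None,
) -> list[TestResult]:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)] with
    tie term T = sum(t^3 - t) / (12 (N-1)); two-sided normal p values,
    optionally Benjamini-Hochberg adjusted across the pair family.
    """
    arrays = _check_groups(groups)
    if adjust not in ("BH", "NONE"):
        raise ValueError("adjust must be 'BH' or 'NONE'")
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    rank_means, tie_term, n_total = _rank_means_and_tie_term(arrays)
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    results = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        denom2 = base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if denom2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (rank_means[i] - rank_means[j]) / math.sqrt(denom2)
            p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            TestResult("dunn", float(z), np.inf, float(min(p, 1.0)),
                       group_labels=(labels[i], labels[j]))
        )
    if adjust == "BH":
        adjusted = benjamini_hochberg([r.p_value for r in results])
        for r, ap in zip(results, adjusted):
            r.adjusted_p = float(ap)
    return results


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    f, p = sps.f_oneway(*arrays)
    return TestResult("one_way_anova", float(f), (k - 1, n_total - k), float(p))


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[object]] = None
) -> list[TestResult]:
    """Tukey's honestly-significant-difference pairwise comparisons."""
    arrays = _check_groups(groups)
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    res = sps.tukey_hsd(*arrays)
    n_total = sum(a.size for a in arrays)
    df = n_total - len(arrays)
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        out.append(
            TestResult(
                "tukey_hsd",
                float(res.statistic[i, j]),
                df,
                float(res.pvalue[i, j]),
                group_labels=(labels[i], labels[j]),
            )
        )
    return out


def games_howell(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[object]] = None
) -> list[TestResult]:
    """Games-Howell pairwise comparisons for unequal variances and sizes.

    t_ij = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j), per-pair
    Welch-Satterthwaite df, and p from the studentized range distribution
    with k groups via q = t * sqrt(2).
    """
    arrays = _check_groups(groups)
    for idx, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"Games-Howell needs n >= 2 per group (group {idx})")
        if np.var(a, ddof=1) == 0:
            raise DegenerateDataError(f"group {idx} has zero within-group variance")
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    k = len(arrays)
    means = [a.mean() for a in arrays]
    variances = [a.var(ddof=1) for a in arrays]
    sizes = [a.size for a in arrays]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = variances[i] / sizes[i], variances[j] / sizes[j]
        se = math.sqrt(vi + vj)
        t = (means[i] - means[j]) / se
        df = (vi + vj) ** 2 / (vi**2 / (sizes[i] - 1) + vj**2 / (sizes[j] - 1))
        p = sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df)
        out.append(
            TestResult("games_howell", float(t), float(df), float(min(p, 1.0)),
                       group_labels=(labels[i], labels[j]))
        )
    return out


def variance_screens(groups: Sequence[Sequence[float]]) -> list[TestResult]:
    """Levene (median-centered), Bartlett and Fligner-Killeen screens."""
    arrays = _check_groups(groups)
    if all(np.var(a) == 0 for a in arrays):
        raise DegenerateDataError("all groups are constant; variance screens undefined")
    k = len(arrays)
    lev_s, lev_p = sps.levene(*arrays, center="median")
    bar_s, bar_p = sps.bartlett(*arrays)
    fli_s, fli_p = sps.fligner(*arrays)
    return [
        TestResult("levene_brown_forsythe", float(lev_s), (k - 1, sum(a.size for a in arrays) - k), float(lev_p)),
        TestResult("bartlett", float(bar_s), k - 1, float(bar_p)),
        TestResult("fligner_killeen", float(fli_s), k - 1, float(fli_p)),
    ]


def cronbach_alpha(ratings: np.ndarray) -> float:
    """Cronbach's alpha over an items x raters matrix.

    alpha = k/(k-1) * (1 - sum of per-rater variances / variance of totals),
    the standard internal-consistency coefficient, here used for
    inter-observer agreement on repeat-scored slides.
    """
    matrix = np.asarray(ratings, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    k = matrix.shape[1]
    item_vars = matrix.var(axis=0, ddof=1)
    total_var = matrix.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Study-table driver: omnibus + pairwise comparisons per marker x location
# ---------------------------------------------------------------------------

_LOCATIONS = ("OVERALL", "CT", "IM")


def _location_values(cohort: Cohort, marker: Marker, location: str):
    by_group: dict[CohortLabel, list[float]] = {}
    for record in cohort:
        if location == "OVERALL":
            value = overall_sum(record, marker)
        else:
            comp = Compartment(location)
            if not record.has_compartment(comp):
                continue
            value = sum_compartment(record, marker, comp)
        by_group.setdefault(record.cohort, []).append(float(value))
    return by_group


def run_table3(
    cohort: Cohort,
    route: str = "nonparametric",
    endometrioid_only: bool = False,
) -> pd.DataFrame:
    """Omnibus + pairwise group comparisons per marker and tumor location.

    For every marker and location (overall / tumor center / invasive
    margin): a 3-group omnibus test followed by the three pairwise
    comparisons, Benjamini-Hochberg-adjusted within each marker x location
    family. ``route`` selects Kruskal-Wallis + Dunn (default) or ANOVA +
    Games-Howell. ``endometrioid_only`` restricts to endometrioid tumors,
    the study's histology-sensitivity re-run.
    """
    if route not in ("nonparametric", "parametric"):
        raise ValueError("route must be 'nonparametric' or 'parametric'")
    if endometrioid_only:
        cohort = cohort.subset(lambda r: r.histology == "ENDOMETRIOID")
    rows = []
    for marker in Marker:
        for location in _LOCATIONS:
            by_group = _location_values(cohort, marker, location)
            if len(by_group) < 2:
                raise ValueError(
                    f"fewer than 2 groups remain for {marker.value}/{location} after filtering"
                )
            labels = [l for l in CohortLabel if l in by_group]
            groups = [by_group[l] for l in labels]
            if route == "nonparametric":
                omnibus = kruskal_wallis(groups)
                pairwise = dunn_posthoc(groups, adjust="BH", labels=[l.value for l in labels])
            else:
                omnibus = one_way_anova(groups)
                pairwise = games_howell(groups, labels=[l.value for l in labels])
                adj = benjamini_hochberg([r.p_value for r in pairwise])
                for r, ap in zip(pairwise, adj):
                    r.adjusted_p = float(ap)
            rows.append(
                {
                    "marker": marker.value,
                    "location": location,
                    "comparison": "omnibus",
                    "test": omnibus.test_name,
                    "statistic": omnibus.statistic,
                    "p": omnibus.p_value,
                    "adjusted_p": np.nan,
                }
            )
            for r in pairwise:
                rows.append(
                    {
                        "marker": marker.value,
                        "location": location,
                        "comparison": f"{r.group_labels[0]} vs {r.group_labels[1]}",
                        "test": r.test_name,
                        "statistic": r.statistic,
                        "p": r.p_value,
                        "adjusted_p": r.adjusted_p if r.adjusted_p is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def run_score_stats(score_frame: pd.DataFrame, cohorts: Sequence[CohortLabel] = tuple(CohortLabel)) -> pd.DataFrame:
    """Per-score group comparisons: 3-class Dunn pairwise (BH within score)
    plus the pooled 2-class (MMR-deficient vs proficient) Kruskal-Wallis.

    ``score_frame`` is a score matrix with a leading ``cohort`` column (as
    produced by :func:`mmrimmune.scores.export_heatmap_matrix`).
    """
    rows = []
    score_cols = [c for c in score_frame.columns if c != "cohort"]
    for score_id in score_cols:
        sub = score_frame[["cohort", score_id]].dropna()
        labels = [l for l in cohorts if l.value in set(sub["cohort"])]
        groups = [sub.loc[sub["cohort"] == l.value, score_id].to_numpy() for l in labels]
        pairwise = dunn_posthoc(groups, adjust="BH", labels=[l.value for l in labels])
        for r in pairwise:
            rows.append(
                {
                    "score": score_id,
                    "comparison": f"{r.group_labels[0]} vs {r.group_labels[1]}",
                    "test": "dunn",
                    "p": r.p_value,
                    "adjusted_p": r.adjusted_p,
                }
            )
        deficient = sub.loc[sub["cohort"] != CohortLabel.MMRP.value, score_id].to_numpy()
        proficient = sub.loc[sub["cohort"] == CohortLabel.MMRP.value, score_id].to_numpy()
        if deficient.size and proficient.size:
            kw = kruskal_wallis([deficient, proficient])
            rows.append(
                {
                    "score": score_id,
                    "comparison": "MMRD vs MMRP",
                    "test": kw.test_name,
                    "p": kw.p_value,
                    "adjusted_p": np.nan,
                }
            )
    return pd.DataFrame(rows)
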