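"""Assumption-gated omnibus group comparisons and confounder screening.

Each measure is compared across groups with a one-way ANOVA when both
normality (Shapiro–Wilk per group) and variance homogeneity (Levene) hold at
alpha = 0.05, and with a Kruskal–Wallis test otherwise.  Effect sizes are
eta-squared (ANOVA: SS_between / SS_total; KW: the rank-based
eta^2_H = (H - k + 1) / (n - k)).  Bonferroni correction multiplies the raw
p by the family size.  Post-hoc pairwise tests (Tukey HSD on the ANOVA path,
Dunn with Bonferroni on the KW path) are reported only when the corrected
omnibus p is below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_ASSUMPTIONS = 0.05
ALPHA_POSTHOC = 0.05


@dataclass
class TestResult:
    measure_name: str
    test_used: str                      # "ANOVA" or "Kruskal-Wallis"
    statistic_label: str                # "F" or "H"
    statistic_value: float
    p_raw: float
    p_bonferroni: float
    effect_size_eta2: float
    group_means: Dict[str, float] = field(default_factory=dict)
    group_sds: Dict[str, float] = field(default_factory=dict)
    pairwise: Dict[Tuple[str, str], Tuple[float, str]] = field(default_factory=dict)


def _eta_squared_anova(groups: Sequence[np.ndarray]) -> float:
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((allv - grand) ** 2).sum())
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> Dict[Tuple[str, str], Tuple[float, str]]:
    """Dunn's rank-based z tests with Bonferroni adjustment over all pairs."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: Dict[str, float] = {}
    start = 0
    for k in labels:
        size = len(groups[k])
        mean_rank[k] = float(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    out: Dict[Tuple[str, str], Tuple[float, str]] = {}
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        direction = f"{a}>{b}" if np.mean(groups[a]) > np.mean(groups[b]) else f"{a}<{b}"
        out[(a, b)] = (float(p), direction)
    return out


def _tukey_pairwise(groups: Mapping[str, np.ndarray]) -> Dict[Tuple[str, str], Tuple[float, str]]:
    labels = list(groups)
    res = stats.tukey_hsd(*[groups[k] for k in labels])
    out: Dict[Tuple[str, str], Tuple[float, str]] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                direction = f"{a}>{b}" if groups[a].mean() > groups[b].mean() else f"{a}<{b}"
                out[(a, b)] = (float(res.pvalue[i, j]), direction)
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    family_size: int = 1,
    measure_name: str = "measure",
) -> TestResult:
    """Omnibus comparison of one measure across >= 2 groups.

    The parametric path is taken only when every group passes Shapiro–Wilk
    and Levene's test does not reject homogeneity, both at alpha = 0.05.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 observations")
        if np.isnan(g).any():
            raise ValueError(f"group {k!r} contains missing values; drop or impute upstream")
    if all(np.ptp(g) == 0 for g in groups.values()):
        raise ValueError("all groups are constant; no comparison possible")

    arrays = list(groups.values())
    normal = True
    for g in arrays:
        if np.ptp(g) == 0:  # constant group cannot be normal
            normal = False
            break
        if stats.shapiro(g).pvalue < ALPHA_ASSUMPTIONS:
            normal = False
            break
    homogeneous = stats.levene(*arrays).pvalue >= ALPHA_ASSUMPTIONS if normal else False

    if normal and homogeneous:
        stat, p = stats.f_oneway(*arrays)
        eta2 = _eta_squared_anova(arrays)
        test_used, label = "ANOVA", "F"
    else:
        stat, p = stats.kruskal(*arrays)
        k, n = len(arrays), sum(len(g) for g in arrays)
        eta2 = float(np.clip((stat - k + 1) / (n - k), 0.0, 1.0))
        test_used, label = "Kruskal-Wallis", "H"

    result = TestResult(
        measure_name=measure_name,
        test_used=test_used,
        statistic_label=label,
        statistic_value=float(stat),
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p * family_size)),
        effect_size_eta2=eta2,
        group_means={k: float(g.mean()) for k, g in groups.items()},
        group_sds={k: float(g.std(ddof=1)) for k, g in groups.items()},
    )
    if result.p_bonferroni < ALPHA_POSTHOC:
        result.pairwise = (
            _tukey_pairwise(groups) if test_used == "ANOVA" else _dunn_pairwise(groups)
        )
    return result


def compare_measures_table(
    frame: pd.DataFrame,
    measures: Sequence[str],
    group_col: str = "group",
    family_size: Optional[int] = None,
) -> Tuple[pd.DataFrame, List[TestResult]]:
    """Group-comparison table over several measures (one row per measure).

    The Bonferroni family defaults to the number of rows emitted.
    """
    family = family_size if family_size is not None else len(measures)
    results = []
    rows = []
    group_labels = list(dict.fromkeys(frame[group_col]))
    for m in measures:
        by_group = {
            g: frame.loc[(frame[group_col] == g) & frame[m].notna(), m].to_numpy()
            for g in group_labels
        }
        res = compare_groups(by_group, family_size=family, measure_name=m)
        results.append(res)
        row: Dict[str, object] = {"measure": m}
        for g in group_labels:
            row[f"{g}_mean"] = res.group_means[g]
            row[f"{g}_sd"] = res.group_sds[g]
        row.update(
            test=res.test_used,
            statistic=res.statistic_value,
            p_raw=res.p_raw,
            p_bonferroni=res.p_bonferroni,
            eta2=res.effect_size_eta2,
            pairwise="; ".join(
                f"{d} (p={p:.4g})" for (_, _), (p, d) in sorted(res.pairwise.items())
            ),
        )
        rows.append(row)
    return pd.DataFrame(rows), results


def confounder_correlations(
    measures: pd.DataFrame, confounders: pd.DataFrame
) -> pd.DataFrame:
    """Pearson (point-biserial for binary) correlation grid measure x confounder.

    Constant columns yield a missing ``r`` plus a ``warning`` note instead of
    an exception.
    """
    if len(measures) != len(confounders):
        raise ValueError("measures and confounders must have the same rows")
    if len(measures) < 10:
        raise ValueError("need at least 10 paired observations")
    rows = []
    for m in measures.columns:
        x = measures[m].to_numpy(dtype=float)
        for c in confounders.columns:
            y = confounders[c].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            warning = ""
            if ok.sum() < 10:
                r = p = np.nan
                warning = "fewer than 10 complete pairs"
            elif np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                r = p = np.nan
                warning = "constant column"
                logger.warning("constant column in correlation of %s vs %s", m, c)
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {"measure": m, "confounder": c, "r": r, "p": p, "n": int(ok.sum()),
                 "warning": warning}
            )
    return pd.DataFrame(rows)


def contingency_test(labels_a: Sequence, labels_b: Sequence) -> Dict[str, float]:
    """Chi-squared test with Cramer's V (convenience wrapper for demographics)."""
    table = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b)).to_numpy()
    chi2, p, dof, _ = stats.chi2_contingency(table)
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof), "cramers_v": v}
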