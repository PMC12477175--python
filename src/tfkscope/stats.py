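"""Nonparametric group comparisons with the study's star convention.

Two-group comparisons use Mann–Whitney U: the p-value is exact (full
enumeration of group assignments, midranks for ties) when the combined
sample size is at most 12, else a normal approximation with tie and
continuity correction.  Three-group comparisons use Kruskal–Wallis
one-way ANOVA on ranks.  Significance stars follow the convention
* p<0.05, ** p<0.005, *** p<0.001, **** p<0.0001 (note the 0.005, not
0.01, second tier).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 12  # full enumeration below/at this combined n

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.005, "**"),
                   (0.05, "*"))


def stars_from_p(p: float) -> str:
    """Map a p-value to the star annotation (most significant applicable)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, star in STAR_THRESHOLDS:
        if p < threshold:
            return star
    return "ns"


@dataclass
class GroupComparison:
    test: str  # mann_whitney | kruskal_wallis | t_test
    groups: dict[str, list[float]]
    statistic: float
    p_value: float
    stars: str = ""
    method_detail: str = ""
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = stars_from_p(self.p_value)

    @property
    def n_per_group(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: #{a>b} + ½·#{a=b} over all cross pairs (midranks)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b, alternative: str = "two-sided") -> GroupComparison:
    """Mann–Whitney U test of two independent samples.

    Exact two-sided p by full enumeration of the C(n, n₁) assignments of
    the pooled values when n₁+n₂ ≤ 12 (ties handled by the midrank U, so
    the enumeration stays valid with ties); otherwise the normal
    approximation with tie and continuity correction via scipy.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    if n1 + n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        idx = range(n1 + n2)
        count = total = 0
        for combo in combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / total
        detail = f"exact enumeration ({total} assignments)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        detail = "normal approximation, tie + continuity correction"
    return GroupComparison(
        test="mann_whitney",
        groups={"a": a.tolist(), "b": b.tolist()},
        statistic=u_obs,
        p_value=min(1.0, p),
        method_detail=detail,
    )


def kruskal_wallis(groups: dict[str, list[float]]) -> GroupComparison:
    """Kruskal–Wallis H with tie correction, chi-square p (df = k−1).

    All-tied input is degenerate (no rank variation): returns H=0, p=1
    with a warning instead of failing.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {k!r} is empty")
    total_n = sum(arr.size for arr in arrays.values())
    if total_n < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        logger.warning("all values identical; Kruskal-Wallis degenerate")
        warnings.warn("all values identical; H=0, p=1", RuntimeWarning,
                      stacklevel=2)
        return GroupComparison(
            test="kruskal_wallis",
            groups={k: v.tolist() for k, v in arrays.items()},
            statistic=0.0, p_value=1.0,
            method_detail="degenerate all-tied input",
        )
    h, p = sps.kruskal(*arrays.values())
    return GroupComparison(
        test="kruskal_wallis",
        groups={k: v.tolist() for k, v in arrays.items()},
        statistic=float(h),
        p_value=float(p),
        method_detail=f"chi-square approximation, df={len(groups) - 1}",
    )


def t_test(a, b) -> GroupComparison:
    """Welch two-sample t-test (non-default parity option)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        test="t_test",
        groups={"a": a.tolist(), "b": b.tolist()},
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method_detail="Welch t-test",
    )


def compare_groups(
    summaries,
    metric: str,
    design: str = "k_group",
    group_order: list[str] | None = None,
    parametric: bool = False,
) -> GroupComparison:
    """Compare a per-sample metric across cohorts.

    Samples whose metric is undefined (None) are excluded and reported in
    the result; each compared group must keep at least 2 samples.  Two
    groups dispatch to Mann–Whitney (or Welch's t with ``parametric``),
    three or more to Kruskal–Wallis.
    """
    grouped: dict[str, list[float]] = {}
    excluded: dict[str, int] = {}
    for s in summaries:
        if not hasattr(s, metric):
            raise ValueError(f"metric {metric!r} not in SampleSummary schema")
        value = getattr(s, metric)
        if value is None:
            excluded[s.group_label] = excluded.get(s.group_label, 0) + 1
            continue
        grouped.setdefault(s.group_label, []).append(float(value))
    if group_order is not None:
        grouped = {g: grouped.get(g, []) for g in group_order}
    for g, vals in grouped.items():
        if len(vals) < 2:
            raise ValueError(
                f"group {g!r} has {len(vals)} usable samples after "
                f"exclusions; need >= 2")
    if design == "two_group":
        if len(grouped) != 2:
            raise ValueError(f"two_group design needs 2 groups, got "
                             f"{len(grouped)}")
        (na, va), (nb, vb) = grouped.items()
        cmp = t_test(va, vb) if parametric else mann_whitney(va, vb)
        cmp.groups = {na: va, nb: vb}
    elif design == "k_group":
        cmp = kruskal_wallis(grouped)
    else:
        raise ValueError(f"unknown design {design!r}")
    cmp.excluded = excluded
    return cmp


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted q-values (optional; the default workflow applies none)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()
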