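"""Group-comparison statistics.

The decision tree mirrors common practice for imaging readouts:

* two groups — Welch's t-test when both groups pass a Shapiro-Wilk
  normality check (alpha = 0.05), otherwise a two-sided Mann-Whitney U test
  (exact for small tie-free samples, normal approximation with tie
  correction otherwise);
* three or more groups — one-way ANOVA followed by Tukey's HSD when every
  group is normal *and* Bartlett's test does not reject homogeneous
  variances, otherwise Kruskal-Wallis followed by Dunn's post-hoc test with
  Bonferroni family correction.

Significance stars follow the usual thresholds: * p < 0.05, ** p < 0.01,
*** p < 0.001 (strict inequalities).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InvalidParameterError

ALPHA = 0.05


class InsufficientDataError(ValueError):
    """A group has fewer observations than the test requires."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class NormalityDecision:
    normal: bool
    p_value: float
    method: str = "shapiro-wilk"
    note: str = ""


def normality_check(x: "np.ndarray | list[float]") -> NormalityDecision:
    """Shapiro-Wilk normality decision at alpha = 0.05.

    Degenerate (constant) samples are reported non-normal with a note
    rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: normality undefined, reported non-normal")
        return NormalityDecision(normal=False, p_value=0.0,
                                 note="degenerate-constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    return NormalityDecision(normal=bool(p > ALPHA), p_value=float(p))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a (pairs won + half the ties)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


@lru_cache(maxsize=None)
def _u_count(n: int, m: int, u: int) -> int:
    """Number of rank assignments of n-vs-m tie-free samples with U == u
    (classical recursion)."""
    if u < 0 or u > n * m:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(n - 1, m, u - m) + _u_count(n, m - 1, u)


def _exact_p_no_ties(n: int, m: int, u_obs: float) -> float:
    """Two-sided exact p: P(|U - nm/2| >= |u_obs - nm/2|) under the null."""
    center = n * m / 2.0
    dev = abs(u_obs - center)
    total = 0
    for u in range(n * m + 1):
        if abs(u - center) >= dev - 1e-12:
            total += _u_count(n, m, u)
    from math import comb

    return total / comb(n + m, n)


def _exact_p_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating every split of the pooled sample,
    handling ties through midrank (0.5) pair scores."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    center = n * m / 2.0
    u_obs = mann_whitney_u(a, b)
    dev = abs(u_obs - center)
    idx = np.arange(n + m)
    hits = total = 0
    for combo in itertools.combinations(idx, n):
        sel = np.zeros(n + m, dtype=bool)
        sel[list(combo)] = True
        u = mann_whitney_u(pooled[sel], pooled[~sel])
        if abs(u - center) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_test(
    a: "np.ndarray | list[float]", b: "np.ndarray | list[float]"
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have n <= 8 (recursion for
    tie-free data, full enumeration when ties are present); otherwise the
    normal approximation with tie correction and continuity correction.
    Returns (U, p, method_detail).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = mann_whitney_u(a, b)
    n, m = len(a), len(b)
    small = n <= 8 and m <= 8
    has_ties = len(np.unique(np.concatenate([a, b]))) < n + m
    if small and not has_ties:
        return u, _exact_p_no_ties(n, m, u), "exact"
    if small and has_ties:
        return u, _exact_p_enumeration(a, b), "exact-enumeration"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue), "normal-approximation"


# ---------------------------------------------------------------------------
# Dunn's post-hoc test

def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled mean ranks after Kruskal-Wallis.

    Pooled midranks; the z denominator carries the tie correction
    sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values are Bonferroni
    multiplied by the number of pairs (capped at 1).
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([groups[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in names:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    sigma2_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(sigma2_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * n_pairs) if adjust == "bonferroni" else p
        rows.append({"group1": g1, "group2": g2, "statistic": z,
                     "p_unadjusted": p, "p_adjusted": p_adj,
                     "stars": significance_stars(p_adj)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Public comparisons

@dataclass
class GroupComparison:
    """Outcome of a two-group or multi-group comparison."""

    groups: dict[str, np.ndarray]
    test_used: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    normality: dict[str, NormalityDecision] = field(default_factory=dict)

    @property
    def significance_stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def summary(self) -> str:
        lines = [
            f"test: {self.test_used}",
            f"statistic = {self.statistic:.6g}, p = {self.p_value:.4g} "
            f"[{self.significance_stars}]",
        ]
        for name, vals in self.groups.items():
            vals = np.asarray(vals, dtype=float)
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            norm = self.normality.get(name)
            norm_txt = (
                f", normal={norm.normal} (p={norm.p_value:.3g})" if norm else ""
            )
            lines.append(
                f"  {name}: n={len(vals)}, mean={vals.mean():.6g} "
                f"+/- {sem:.3g} SEM{norm_txt}"
            )
        if self.posthoc is not None and len(self.posthoc):
            lines.append("post-hoc:")
            for _, row in self.posthoc.iterrows():
                lines.append(
                    f"  {row['group1']} vs {row['group2']}: "
                    f"p_adj={row['p_adjusted']:.4g} [{row['stars']}]"
                )
        return "\n".join(lines)


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise InsufficientDataError(
                f"insufficient-n: group {name!r} has n={vals.size} < 3"
            )
        clean[name] = vals
    return clean


def compare_two(
    a: "np.ndarray | list[float]",
    b: "np.ndarray | list[float]",
    names: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-condition comparison: Welch's t-test when both groups are normal
    (Shapiro-Wilk), two-sided Mann-Whitney U otherwise."""
    groups = _validate_groups({names[0]: a, names[1]: b})
    a, b = groups[names[0]], groups[names[1]]
    normality = {k: normality_check(v) for k, v in groups.items()}
    if all(d.normal for d in normality.values()):
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison(groups, "welch-t", float(stat), float(p),
                               normality=normality)
    u, p, detail = mann_whitney_test(a, b)
    return GroupComparison(groups, f"mann-whitney({detail})", u, p,
                           normality=normality)


def compare_many(groups: "dict[str, np.ndarray]") -> GroupComparison:
    """Multi-condition comparison.

    All groups normal and Bartlett's test not rejecting equal variances ->
    one-way ANOVA with Tukey HSD post-hoc; otherwise Kruskal-Wallis with
    Dunn's (Bonferroni) post-hoc.
    """
    if len(groups) < 3:
        raise InvalidParameterError("compare_many needs >= 3 groups")
    groups = _validate_groups(groups)
    names = list(groups)
    arrays = [groups[k] for k in names]
    normality = {k: normality_check(v) for k, v in groups.items()}
    parametric = all(d.normal for d in normality.values())
    if parametric:
        _, bartlett_p = sps.bartlett(*arrays)
        parametric = bartlett_p > ALPHA
    if parametric:
        stat, p = sps.f_oneway(*arrays)
        tk = sps.tukey_hsd(*arrays)
        rows = []
        for i, j in itertools.combinations(range(len(names)), 2):
            p_adj = float(tk.pvalue[i, j])
            rows.append({"group1": names[i], "group2": names[j],
                         "statistic": float(tk.statistic[i, j]),
                         "p_unadjusted": p_adj, "p_adjusted": p_adj,
                         "stars": significance_stars(p_adj)})
        posthoc = pd.DataFrame(rows)
        return GroupComparison(groups, "anova+tukey", float(stat), float(p),
                               posthoc=posthoc, normality=normality)
    stat, p = sps.kruskal(*arrays)
    posthoc = dunn_posthoc(groups, adjust="bonferroni")
    return GroupComparison(groups, "kruskal-wallis+dunn", float(stat), float(p),
                           posthoc=posthoc, normality=normality)


def partial_inhibition_flag(
    vs_stimulated: GroupComparison | None,
    vs_control: GroupComparison | None,
) -> bool:
    """True when a treatment differs significantly (p < 0.05, strict) from
    BOTH the stimulated condition and the corresponding control."""
    if vs_stimulated is None or vs_control is None:
        raise InvalidParameterError(
            "partial_inhibition_flag requires both comparisons"
        )
    return bool(vs_stimulated.significant and vs_control.significant)
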