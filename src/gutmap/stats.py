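"""Phenotype scoring and the statistical test suite.

Neuron-count phenotyping counts HuC/D+ neurons within a fixed somite-length
window of the anal pore and scores the position of the k-th most distal
neuron.  The exact small-sample tests (permutation Spearman, Fisher 2x2) are
implemented from first principles; the classical tests (ANOVA variants,
Shapiro-Wilk, Brown-Forsythe) wrap the standard numerical implementations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n: int | tuple | None = None
    note: str = ""
    pairwise: list = field(default_factory=list)   # post-hoc TestResults

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {"method": self.method, "statistic": self.statistic,
             "p_value": self.p_value, "df": self.df, "n": self.n}
        if self.note:
            d["note"] = self.note
        if self.pairwise:
            d["pairwise"] = [p.to_dict() for p in self.pairwise]
        return d


def significance_stars(p: float) -> str:
    """Graded significance symbols: ns, *, **, ***, ****."""
    if p < 0.0001:
        return "****"
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# neuron-count phenotyping


def count_distal(positions, window_somites: float) -> int:
    """Count neurons within ``window_somites`` of the anal pore (inclusive).

    Positions are somite-lengths from the anal pore; the convention is 5
    somites for 4 dpf larvae and 10 for 3 dpf.
    """
    if window_somites <= 0:
        raise ValueError("window_somites must be > 0")
    positions = np.asarray(list(positions), dtype=float)
    return int(np.sum(positions <= window_somites))


def kth_distal_position(positions, k: int) -> float:
    """Position of the k-th most distal neuron (k-th smallest distance from
    the anal pore), or NaN with a warning when fewer than k neurons exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    positions = np.sort(np.asarray(list(positions), dtype=float))
    if len(positions) < k:
        warnings.warn(f"only {len(positions)} neurons, need {k}; "
                      "returning missing", stacklevel=2)
        return math.nan
    return float(positions[k - 1])


def classify_phenotype(most_distal_pos: float, distal_count: int,
                       np_margin_somites: float = 1.0,
                       severe_threshold: int = 24) -> tuple[str, str]:
    """Phenotype call: (NP|P, severe|not_severe).

    Non-phenotypic (NP) larvae have their most distal neuron within
    ``np_margin_somites`` of the anal pore; severity is a strict count
    threshold (severe = fewer than ``severe_threshold`` distal neurons).
    A larva with no neurons at all (position NaN) is P and severe.
    """
    np_call = "NP" if (not math.isnan(most_distal_pos)
                       and most_distal_pos <= np_margin_somites) else "P"
    severity = "severe" if distal_count < severe_threshold else "not_severe"
    return np_call, severity


# ---------------------------------------------------------------------------
# exact tests (first-principles)


def _spearman_rs_from_d2(d2: float, n: int) -> float:
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_exact(x, y, exact_max_n: int = 8) -> TestResult:
    """Spearman rank correlation with an exact permutation p for small n.

    For untied samples with n <= ``exact_max_n`` the two-sided p-value is
    obtained by full enumeration of rank permutations: the one-sided tail of
    the observed sum of squared rank differences is doubled and capped at 1.
    Larger n (or ties, with a warning) fall back to the asymptotic
    t-approximation on midranks.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if ties or n > exact_max_n:
        if ties:
            warnings.warn("ties present: midrank rs with asymptotic p",
                          stacklevel=2)
        rs = float(np.corrcoef(rx, ry)[0, 1])
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            tstat = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
            p = 2.0 * sps.t.sf(abs(tstat), n - 2)
        return TestResult("spearman_asymptotic", rs, min(p, 1.0), df=n - 2, n=n)

    d2_obs = float(np.sum((rx - ry) ** 2))
    rs = _spearman_rs_from_d2(d2_obs, n)
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(base):
        d2 = float(np.sum((base - np.asarray(perm)) ** 2))
        if rs >= 0:
            count += d2 <= d2_obs       # at least as concordant
        else:
            count += d2 >= d2_obs       # at least as discordant
    p = min(1.0, 2.0 * count / total)
    return TestResult("spearman_exact", rs, p, n=n)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    Margins fixed; the p-value sums the hypergeometric probabilities of all
    tables at most as probable as the observed one.  Degenerate margins give
    p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    if min(r1, r2, c1, n - c1) == 0:
        warnings.warn("degenerate margin: p = 1", stacklevel=2)
        return TestResult("fisher_exact", odds, 1.0, n=n)
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    probs = rv.pmf(support)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return TestResult("fisher_exact", odds, min(p, 1.0), n=n)


# ---------------------------------------------------------------------------
# classical tests (contract: match the reference implementations)


def _check_groups(groups: list[np.ndarray], labels: list[str],
                  min_size: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for lab, g in zip(labels, groups):
        if len(g) < min_size:
            raise ValueError(f"group {lab!r} has fewer than {min_size} values")


def _split(values, labels) -> tuple[list[np.ndarray], list[str]]:
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    uniq = list(dict.fromkeys(labels))          # preserve first-seen order
    return [values[labels == u] for u in uniq], [str(u) for u in uniq]


def welch_anova_f(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA (F*, df1, df2)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(vars_ == 0):
        raise ValueError("Welch ANOVA requires positive within-group variance")
    w = ns / vars_
    mw = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    den = 1 + 2 * (k - 2) / (k * k - 1) * lam
    df2 = (k * k - 1) / (3 * lam)
    return num / den, k - 1.0, df2


def _bonferroni_pairs(groups, labels) -> list[TestResult]:
    """All-pairs t tests on the pooled ANOVA error term, Bonferroni-adjusted."""
    k = len(groups)
    ns = [len(g) for g in groups]
    n_tot = sum(ns)
    mse = sum(np.sum((g - np.mean(g)) ** 2) for g in groups) / (n_tot - k)
    m = k * (k - 1) // 2
    out = []
    for (i, j) in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
        tstat = (np.mean(groups[i]) - np.mean(groups[j])) / se
        p_raw = 2 * sps.t.sf(abs(tstat), n_tot - k)
        out.append(TestResult(f"t_bonferroni[{labels[i]} vs {labels[j]}]",
                              float(tstat), min(1.0, m * p_raw),
                              df=n_tot - k, n=(ns[i], ns[j]),
                              note=f"raw_p={p_raw:.6g}"))
    return out


def _tukey_pairs(groups, labels) -> list[TestResult]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(groups)
    labs = np.concatenate([[labels[i]] * len(g) for i, g in enumerate(groups)])
    res = pairwise_tukeyhsd(values, labs)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
        out.append(TestResult(f"tukey[{g1} vs {g2}]", float(meandiff),
                              float(p_adj)))
    return out


def compare_groups(values, labels, method: str = "anova",
                   posthoc: str = "none") -> TestResult:
    """Omnibus group comparison with optional post-hoc pairwise tests.

    ``method``: "anova" (classical one-way) or "welch_anova" (recommended for
    unequal variances).  ``posthoc``: "bonferroni" (pooled-variance pairwise t
    with Bonferroni adjustment), "tukey" (Tukey HSD) or "none".  Adjusted
    pairwise p-values are attached to the returned result.
    """
    groups, labs = _split(values, labels)
    _check_groups(groups, labs)
    if method == "anova":
        f, p = sps.f_oneway(*groups)
        k, n_tot = len(groups), sum(len(g) for g in groups)
        result = TestResult("anova", float(f), float(p),
                            df=(k - 1, n_tot - k), n=tuple(len(g) for g in groups))
    elif method == "welch_anova":
        f, df1, df2 = welch_anova_f(groups)
        p = float(sps.f.sf(f, df1, df2))
        result = TestResult("welch_anova", float(f), p, df=(df1, df2),
                            n=tuple(len(g) for g in groups))
    else:
        raise ValueError(f"unknown method {method!r}")

    if posthoc == "bonferroni":
        result.pairwise = _bonferroni_pairs(groups, labs)
    elif posthoc == "tukey":
        result.pairwise = _tukey_pairs(groups, labs)
    elif posthoc != "none":
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return result


def test_normality(values) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(list(values), dtype=float)
    if not (3 <= len(values) <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant input: W undefined")
    w, p = sps.shapiro(values)
    return TestResult("shapiro_wilk", float(w), float(p), n=len(values))


def test_variance_homogeneity(values, labels) -> TestResult:
    """Brown-Forsythe test: one-way ANOVA on absolute deviations from group
    medians (robust variance-homogeneity test)."""
    groups, labs = _split(values, labels)
    _check_groups(groups, labs)
    stat, p = sps.levene(*groups, center="median")
    return TestResult("brown_forsythe", float(stat), float(p),
                      n=tuple(len(g) for g in groups))
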