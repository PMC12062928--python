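"""Nonparametric and exact tests used throughout the play-face analyses.

The toolbox mirrors what behavioural studies with small, dependent samples
typically need: a Yates-corrected 2x2 chi-square, an exact Wilcoxon
signed-rank test (full enumeration of sign assignments for small samples),
a Kruskal-Wallis test whose p-value comes from Monte Carlo randomization of
group labels, Dunn's post hoc comparisons with Bonferroni correction, a
paired t-test, an exact binomial test, Cohen's kappa for inter-observer
agreement, and the duration-per-occurrence IOA score.

Every routine returns a :class:`TestResult`, which carries the statistic,
sample-size information, the tie count where relevant, and — for
randomization tests — the permutation count and seed so a run can be
reproduced bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "yates_chi2",
    "wilcoxon_exact",
    "kruskal_wallis_mc",
    "dunn_bonferroni",
    "paired_t",
    "binomial_exact",
    "cohens_kappa",
    "duration_ioa",
]

# above this many nonzero differences the signed-rank null is effectively
# normal and full enumeration buys nothing
_EXACT_WILCOXON_LIMIT = 25


@dataclass
class TestResult:
    """One test outcome, serializable as a single TSV record."""

    test: str
    statistic_name: str
    statistic: float
    df_or_n: Optional[float] = None
    ties: Optional[int] = None
    p_value: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None
    correction: Optional[str] = None
    extra: dict = field(default_factory=dict)

    @property
    def available(self) -> bool:
        """False when the test was degenerate (e.g. all differences zero)."""
        return self.p_value is not None and not math.isnan(self.statistic)

    def to_tsv(self) -> str:
        def fmt(v):
            return "" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))

        fields = [
            self.test,
            self.statistic_name,
            fmt(self.statistic),
            fmt(self.df_or_n),
            fmt(self.ties),
            fmt(self.p_value),
            fmt(self.n_perm),
            fmt(self.seed),
            self.correction or "",
        ]
        return "\t".join(fields)


def _na_result(test: str, stat_name: str, n=None, ties=None, **extra) -> TestResult:
    return TestResult(test, stat_name, float("nan"), df_or_n=n, ties=ties,
                      p_value=None, extra=extra)


# ---------------------------------------------------------------------------
# 2x2 chi-square with continuity correction
# ---------------------------------------------------------------------------

def yates_chi2(table) -> TestResult:
    """Yates-corrected chi-square on a 2x2 contingency table.

    ``table`` is (a, b, c, d) row-wise, anything with an ``as_array`` method,
    or a 2x2 array. The correction term |ad - bc| - N/2 is clamped at zero so
    that weak associations cannot be inflated by the correction.
    """
    if hasattr(table, "as_array"):
        arr = np.asarray(table.as_array(), dtype=float)
    else:
        arr = np.asarray(table, dtype=float).reshape(2, 2)
    if (arr < 0).any():
        raise ValueError("contingency counts must be non-negative")
    a, b, c, d = arr.ravel()
    n = arr.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        return _na_result("yates_chi2", "chi2", n=n)
    diff = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * diff ** 2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult("yates_chi2", "chi2", float(chi2), df_or_n=1, p_value=p,
                      correction="yates")


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the doubled positive-rank sum over all sign assignments.

    Ranks are mid-ranks; doubling makes them integers so the distribution can
    be built by the classic dynamic-programming convolution.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else counts * 2
    return counts


def wilcoxon_exact(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> TestResult:
    """Exact Wilcoxon signed-rank test for two dependent samples.

    Zero differences are dropped and reported as the ``ties`` count, matching
    the common reporting style of observational studies (T, ties, p). The
    statistic T is the smaller of the positive and negative rank sums. For up
    to 25 nonzero differences the p-value is exact over all 2^m sign
    assignments (mid-ranks handled by the doubled-rank convolution);
    larger samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("paired samples of equal, nonzero length required")
    d = x - y
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return _na_result("wilcoxon_exact", "T", n=len(x), ties=n_zero)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    t_stat = min(w_plus, w_minus)
    total = w_plus + w_minus

    if m <= _EXACT_WILCOXON_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        denom = 2.0 ** m
        sums = np.arange(len(counts)) / 2.0  # back to the rank-sum scale
        if alternative == "two-sided":
            lo = counts[sums <= t_stat + 1e-9].sum()
            hi = counts[sums >= total - t_stat - 1e-9].sum()
            p = min(1.0, (lo + hi) / denom)
        elif alternative == "greater":  # x tends to exceed y
            p = counts[sums >= w_plus - 1e-9].sum() / denom
        elif alternative == "less":
            p = counts[sums <= w_plus + 1e-9].sum() / denom
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        method = "exact"
    else:
        mu = m * (m + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_sizes ** 3 - tie_sizes) / 48.0
        if var <= 0:
            return _na_result("wilcoxon_exact", "T", n=len(x), ties=n_zero)
        if alternative == "two-sided":
            z = (t_stat - mu + 0.5) / math.sqrt(var)
            p = min(1.0, 2 * float(sps.norm.cdf(z)))
        elif alternative == "greater":
            z = (w_plus - mu - 0.5) / math.sqrt(var)
            p = float(sps.norm.sf(z))
        else:
            z = (w_plus - mu + 0.5) / math.sqrt(var)
            p = float(sps.norm.cdf(z))
        method = "normal-approx"
    return TestResult("wilcoxon_exact", "T", t_stat, df_or_n=len(x), ties=n_zero,
                      p_value=float(p), correction=method,
                      extra={"w_plus": w_plus, "w_minus": w_minus, "m": m})


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Monte Carlo randomization
# ---------------------------------------------------------------------------

def _kw_h_from_ranksums(ranksums, sizes, n, tie_factor) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * np.sum(ranksums ** 2 / sizes, axis=-1) - 3 * (n + 1)
    return h / tie_factor if tie_factor > 0 else h


def kruskal_wallis_mc(groups: Sequence[Sequence[float]], n_perm: int = 10000,
                      seed: Optional[int] = None) -> TestResult:
    """Kruskal-Wallis H with a Monte Carlo randomization p-value.

    Group labels are reshuffled over the pooled observations ``n_perm`` times
    (group sizes preserved); the p-value uses the add-one estimator
    (1 + #{H* >= H}) / (1 + B), so it can never be exactly zero. H carries
    the usual tie correction on pooled mid-ranks. Because pooled ranks are
    invariant under relabeling, the randomization only permutes the rank
    vector, which keeps the whole test vectorizable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    pooled = np.concatenate(groups)
    n = len(pooled)
    sizes = np.array([len(g) for g in groups])
    k = len(groups)
    ranks = sps.rankdata(pooled)
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_factor = 1.0 - np.sum(tie_sizes ** 3 - tie_sizes) / (n ** 3 - n)
    if tie_factor <= 0:  # all observations identical
        return TestResult("kruskal_wallis_mc", "H", 0.0, df_or_n=k - 1,
                          ties=int(n - len(tie_sizes)), p_value=1.0,
                          n_perm=n_perm, seed=seed)
    bounds = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    obs_sums = np.add.reduceat(ranks, bounds)
    h_obs = float(_kw_h_from_ranksums(obs_sums, sizes, n, tie_factor))

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        permed = ranks[idx]
        sums = np.add.reduceat(permed, bounds, axis=1)
        h_perm = _kw_h_from_ranksums(sums, sizes, n, tie_factor)
        exceed += int(np.sum(h_perm >= h_obs - 1e-12))
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TestResult("kruskal_wallis_mc", "H", h_obs, df_or_n=k - 1,
                      ties=int(n - len(tie_sizes)), p_value=float(p),
                      n_perm=n_perm, seed=seed)


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Optional[Sequence[str]] = None) -> list[TestResult]:
    """Dunn's pairwise post hoc comparisons with Bonferroni correction.

    Uses the pooled mid-ranks of the Kruskal-Wallis context. Each result
    reports both the raw mean-rank difference (``statistic``) and the
    standardized z (``extra['z']``); the p-value is the two-sided normal
    tail multiplied by the number of pairwise comparisons, capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_term = np.sum(tie_sizes ** 3 - tie_sizes) / (12.0 * (n - 1)) if n > 1 else 0.0
    sizes = [len(g) for g in groups]
    bounds = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    mean_ranks = np.add.reduceat(ranks, bounds) / np.array(sizes)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        diff = float(mean_ranks[i] - mean_ranks[j])
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = diff / math.sqrt(var)
            p = min(1.0, 2 * float(sps.norm.sf(abs(z))) * n_pairs)
        out.append(TestResult("dunn_bonferroni", "mean_rank_diff", diff,
                              df_or_n=n, p_value=p, correction="bonferroni",
                              extra={"pair": (labels[i], labels[j]), "z": z,
                                     "n_comparisons": n_pairs}))
    return out


# ---------------------------------------------------------------------------
# parametric / exact helpers
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test for dependent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        return _na_result("paired_t", "t", n=len(x))
    t, p = sps.ttest_rel(x, y)
    return TestResult("paired_t", "t", float(t), df_or_n=len(x) - 1,
                      p_value=float(p))


def binomial_exact(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test (sum of outcomes no more probable
    than the observed one)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n > 0")
    res = sps.binomtest(k, n, p0)
    return TestResult("binomial_exact", "k", float(k), df_or_n=n,
                      p_value=float(res.pvalue), extra={"p0": p0})


def cohens_kappa(codes1: Sequence, codes2: Sequence) -> TestResult:
    """Cohen's kappa: chance-corrected agreement of two categorical codings."""
    c1 = np.asarray(codes1)
    c2 = np.asarray(codes2)
    if c1.shape != c2.shape or c1.ndim != 1 or len(c1) == 0:
        raise ValueError("two equal-length codings required")
    cats = np.unique(np.concatenate([c1, c2]))
    n = len(c1)
    p_o = float(np.mean(c1 == c2))
    p_e = 0.0
    for cat in cats:
        p_e += np.mean(c1 == cat) * np.mean(c2 == cat)
    if p_e >= 1.0 - 1e-12:
        return _na_result("cohens_kappa", "kappa", n=n)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return TestResult("cohens_kappa", "kappa", float(kappa), df_or_n=n,
                      p_value=None, extra={"p_o": p_o, "p_e": float(p_e)})


def duration_ioa(d1: Sequence[float], d2: Sequence[float],
                 percent: bool = False) -> float:
    """Mean duration-per-occurrence inter-observer agreement.

    For each timing trial the smaller of the two observers' durations is
    divided by the larger; the per-trial ratios are averaged. With
    ``percent=True`` the mean is scaled to a percentage, the form usually
    quoted for a whole reliability assessment.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or len(d1) == 0:
        raise ValueError("paired duration trials required")
    if (d1 <= 0).any() or (d2 <= 0).any():
        raise ValueError("durations must be positive")
    ratios = np.minimum(d1, d2) / np.maximum(d1, d2)
    return float(ratios.mean() * (100.0 if percent else 1.0))
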