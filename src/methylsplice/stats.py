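"""Shared statistical primitives for the methylation/splicing pipeline.

Every hypothesis test used anywhere in the pipeline lives here, so each one
is a single audited implementation: the binomial upper tail behind k-mer
enrichment, the hypergeometric tail behind region/gene-set enrichment,
Benjamini-Hochberg and Bonferroni corrections, the Welch t-test used for
probe-level methylation and exon-level inclusion differences, a balanced
label-permutation FDR estimate, and a two-proportion z-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is test-specific (t, z, or the observed count for exact
    tests); ``n`` records the problem size the test was computed on.
    """

    statistic: float
    p_value: float
    n: int
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass
class BinomialModel:
    """Occurrence model for one k-mer: M hits among N windows at background f."""

    M: int
    N: int
    f: float

    def __post_init__(self) -> None:
        if not 0 <= self.M <= self.N:
            raise ValueError(f"need 0 <= M <= N, got M={self.M}, N={self.N}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"background frequency outside [0, 1]: {self.f}")


def binomial_uppertail(model: BinomialModel) -> float:
    """Upper-tail probability P(X >= M) for X ~ Binomial(N, f).

    Uses the survival function in the regularized-incomplete-beta
    formulation, which is numerically stable for N up to millions of
    windows.  ``M = 0`` covers the whole support and returns exactly 1.
    """
    if model.M == 0:
        return 1.0
    return float(sps.binom.sf(model.M - 1, model.N, model.f))


def binomial_uppertail_many(M: np.ndarray, N: int, f: np.ndarray) -> np.ndarray:
    """Vectorized ``binomial_uppertail`` over arrays of counts/frequencies."""
    M = np.asarray(M)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("background frequency outside [0, 1]")
    if np.any((M < 0) | (M > N)):
        raise ValueError("need 0 <= M <= N")
    p = sps.binom.sf(M - 1, N, f)
    return np.where(M == 0, 1.0, p)


def hypergeom_enrichment(
    observed_in_category: int, category_size: int, universe: int, draws: int
) -> TestResult:
    """Upper-tail hypergeometric enrichment P(X >= observed).

    ``draws`` items are sampled without replacement from a ``universe`` that
    contains ``category_size`` items of the category of interest.
    """
    if draws > universe or category_size > universe:
        raise ValueError("category_size and draws must not exceed universe")
    if observed_in_category > min(category_size, draws):
        raise ValueError("observed exceeds min(category_size, draws)")
    if observed_in_category < 0:
        raise ValueError("negative observed count")
    if observed_in_category == 0:
        p = 1.0
    else:
        p = float(sps.hypergeom.sf(observed_in_category - 1, universe, category_size, draws))
    return TestResult(statistic=float(observed_in_category), p_value=min(p, 1.0), n=universe)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return np.minimum(p * p.size, 1.0)


def probe_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test between two replicate groups.

    The statistic's sign follows mean(A) - mean(B).  Two degenerate groups
    with zero variance and equal means return p = 1 by convention (no
    evidence of difference, rather than NaN).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    t, p = welch_t_rows(a[None, :], b[None, :])
    return TestResult(statistic=float(t[0]), p_value=float(p[0]), n=a.size + b.size)


def welch_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test for matrices of shape (n_rows, n_replicates).

    Degenerate rows (both groups zero-variance) get t = 0, p = 1 when the
    means agree and p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        equal = degenerate & np.isclose(diff, 0.0)
        unequal = degenerate & ~np.isclose(diff, 0.0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        with np.errstate(invalid="ignore"):
            t = np.where(unequal, np.sign(diff) * np.inf, t)
        p = np.where(unequal, 0.0, p)
    return t, p


def moderated_welch_rows(
    a: np.ndarray, b: np.ndarray, prior_df: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test with empirical-Bayes variance moderation.

    The per-row squared standard error is shrunk toward the median across
    rows with ``prior_df`` pseudo-observations (limma-style), and the
    statistic is referred to a t distribution with the correspondingly
    augmented degrees of freedom.  With few replicates this rescues the
    power that a 4-df per-row variance estimate throws away.
    ``prior_df = 0`` reduces to the plain Welch test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if prior_df <= 0:
        return welch_t_rows(a, b)
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = a.var(axis=1, ddof=1) / n1 + b.var(axis=1, ddof=1) / n2
    resid_df = n1 + n2 - 2
    prior = float(np.median(se2))
    se2_mod = (resid_df * se2 + prior_df * prior) / (resid_df + prior_df)
    t = np.full(diff.shape, 0.0)
    p = np.ones_like(t)
    ok = se2_mod > 0
    t[ok] = diff[ok] / np.sqrt(se2_mod[ok])
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), resid_df + prior_df)
    degenerate = ~ok & ~np.isclose(diff, 0.0)
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p[degenerate] = 0.0
    return t, p


def _balanced_splits(labels: Sequence[str]) -> list[np.ndarray]:
    """All relabelings that keep group sizes, excluding the observed one
    and its mirror (those reproduce the true split and would pin the
    estimated FDR at >= 2/n_perm even for arbitrarily strong signal)."""
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("permutation FDR requires exactly two groups")
    idx_a = frozenset(np.flatnonzero(labels == uniq[0]).tolist())
    n = labels.size
    k = len(idx_a)
    out = []
    for combo in itertools.combinations(range(n), k):
        s = frozenset(combo)
        if s == idx_a or s == frozenset(range(n)) - idx_a:
            continue
        perm = np.full(n, uniq[1], dtype=object)
        perm[list(combo)] = uniq[0]
        out.append(perm)
    return out


def permutation_fdr(
    matrix: np.ndarray,
    labels: Sequence[str],
    threshold: float = 0.005,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Estimate the probe-level FDR at a p-value cutoff by label permutation.

    For each balanced relabeling of the samples the per-row Welch test is
    recomputed; the FDR estimate is the mean, over permutations, of the
    number of rows passing ``threshold`` under permuted labels divided by
    the number passing under the true labels (floored at 1).  All balanced
    splits are enumerated when there are at most ``n_perm`` of them,
    otherwise ``n_perm`` are drawn with ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    matrix = np.asarray(matrix, dtype=float)
    uniq = sorted(set(labels.tolist()))
    mask_a = labels == uniq[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("need at least 2 samples per label")
    _, p_true = welch_t_rows(matrix[:, mask_a], matrix[:, ~mask_a])
    n_true = max(1, int(np.sum(p_true < threshold)))

    splits = _balanced_splits(labels)
    if len(splits) > n_perm:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(splits), size=n_perm, replace=False)
        splits = [splits[i] for i in chosen]
    ratios = []
    for perm in splits:
        m = perm == uniq[0]
        _, p_perm = welch_t_rows(matrix[:, m], matrix[:, ~m])
        ratios.append(np.sum(p_perm < threshold) / n_true)
    return float(np.mean(ratios))


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided z-test for H0: p1 = p2 (pooled variance, no continuity
    correction).  Identical observed proportions return z = 0, p = 1 even
    when the pooled proportion is degenerate (0 or 1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        z = 0.0 if p1 == p2 else math.copysign(math.inf, p1 - p2)
    else:
        z = (p1 - p2) / se
    p = 1.0 if z == 0.0 else float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=z, p_value=min(p, 1.0), n=n1 + n2)
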