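"""Clustering and resampling statistics used across the pipeline.

This module self-contains the statistics the analyses are built on:

* pair-count Rand index and chance-adjusted Rand index (:func:`rand_index`,
  :func:`adjusted_rand_index`),
* the silhouette index s(i) = (b(i) - a(i)) / max{a(i), b(i)},
* seeded best-of-restarts k-means (delegating the Lloyd iterations to
  scikit-learn),
* Hartigan & Hartigan's dip statistic of unimodality with a bootstrap
  p-value under the uniform null,
* a pooled-null bootstrap t-test,
* Benjamini-Hochberg FDR control (via statsmodels).

Dip computation
---------------
For a sorted sample the dip is the smallest ``d`` such that some unimodal
CDF G stays within ``d`` of the empirical CDF everywhere. Writing the
per-value band constraints (upper bound = left limit of the empirical CDF
plus d, lower bound = its right value minus d), a convex-then-concave G
exists inside the band if and only if, on the rising side, the greatest
convex minorant of the upper bounds clears the lower bounds, and
symmetrically on the falling side with the least concave majorant. The dip
is therefore half the minimum, over all mode placements (at each data value
or in each gap), of the worst band violation. This is an exact O(n^2)
evaluation of the definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "Partition",
    "PairCounts",
    "pair_counts",
    "rand_index",
    "adjusted_rand_index",
    "silhouette_index",
    "kmeans",
    "dip_statistic",
    "dip_pvalue",
    "bootstrap_ttest",
    "bh_fdr",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of items to clusters; ``labels[i]`` is the cluster of ``items[i]``."""

    items: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.items) != len(self.labels):
            raise ValidationError("items and labels must have equal length")
        if len(set(self.items)) != len(self.items):
            raise ValidationError("items must be unique")

    @classmethod
    def from_labels(cls, labels, items=None) -> "Partition":
        labels = list(labels)
        if items is None:
            items = list(range(len(labels)))
        return cls(tuple(items), tuple(labels))

    @classmethod
    def from_groups(cls, groups: dict) -> "Partition":
        """Build from {cluster_name: iterable of items}."""
        items, labels = [], []
        for name, members in groups.items():
            for m in members:
                items.append(m)
                labels.append(name)
        return cls(tuple(items), tuple(labels))

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def aligned_labels(self, items) -> np.ndarray:
        """Integer labels in the order of ``items``."""
        lookup = dict(zip(self.items, self.labels))
        try:
            raw = [lookup[i] for i in items]
        except KeyError as e:
            raise ValidationError(f"item {e.args[0]} not in partition") from e
        codes = {lab: j for j, lab in enumerate(dict.fromkeys(raw))}
        return np.array([codes[lab] for lab in raw], dtype=int)


@dataclass(frozen=True)
class PairCounts:
    """Exhaustive classification of the n(n-1)/2 item pairs.

    a: same cluster in both partitions; b: same in U only; c: same in V
    only; d: different in both.
    """

    a: int
    b: int
    c: int
    d: int
    n: int

    def __post_init__(self):
        if self.a + self.b + self.c + self.d != self.n * (self.n - 1) // 2:
            raise ValidationError("pair counts do not sum to n(n-1)/2")


def pair_counts(U: Partition, V: Partition) -> PairCounts:
    if set(U.items) != set(V.items):
        raise ValidationError("partitions must cover the same item set")
    items = list(U.items)
    lu = U.aligned_labels(items)
    lv = V.aligned_labels(items)
    n = len(items)
    iu, ju = np.triu_indices(n, k=1)
    same_u = lu[iu] == lu[ju]
    same_v = lv[iu] == lv[ju]
    a = int(np.sum(same_u & same_v))
    b = int(np.sum(same_u & ~same_v))
    c = int(np.sum(~same_u & same_v))
    d = int(np.sum(~same_u & ~same_v))
    return PairCounts(a, b, c, d, n)


def rand_index(pc: PairCounts) -> float:
    """RI = (a + d) / (a + b + c + d)."""
    total = pc.a + pc.b + pc.c + pc.d
    if total == 0:
        raise ParameterError("Rand index undefined for n < 2")
    return (pc.a + pc.d) / total


def adjusted_rand_index(U: Partition, V: Partition) -> float:
    """Chance-corrected Rand index from pair counts.

    RI_adj = [C(n,2)(a+d) - ((a+b)(a+c) + (c+d)(b+d))]
             / [C(n,2)^2 - ((a+b)(a+c) + (c+d)(b+d))]

    Equals 1 iff the partitions coincide up to label renaming and has
    expected value 0 for independent clusterings.
    """
    pc = pair_counts(U, V)
    if pc.n < 2:
        raise ParameterError("adjusted Rand index undefined for n < 2")
    total = pc.n * (pc.n - 1) / 2
    chance = (pc.a + pc.b) * (pc.a + pc.c) + (pc.c + pc.d) * (pc.b + pc.d)
    denom = total * total - chance
    if denom == 0:
        # both partitions put all items together or all apart
        return 1.0
    return (total * (pc.a + pc.d) - chance) / denom


def _ari_from_label_arrays(lu: np.ndarray, lv: np.ndarray) -> float:
    """Adjusted Rand index on integer label arrays (hot path helper)."""
    return adjusted_rand_index(Partition.from_labels(lu), Partition.from_labels(lv))


def silhouette_index(distances: np.ndarray, labels) -> tuple[np.ndarray, float]:
    """Per-item silhouette s(i) and its mean.

    ``distances`` is a square symmetric matrix; items in singleton clusters
    score 0 by convention.
    """
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValidationError("distances must be square and symmetric")
    if labels.shape[0] != n:
        raise ValidationError("labels length must match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ParameterError("silhouette undefined for a single cluster")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def kmeans(X: np.ndarray, k: int, n_restarts: int = 50, seed: int | None = 0):
    """Best-of-restarts k-means. Returns (Partition, inertia).

    Uses k-means++ initialization with ``n_restarts`` seeded restarts and
    keeps the lowest within-cluster sum of squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > X.shape[0]:
        raise ParameterError(f"k={k} exceeds number of items {X.shape[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trip ConvergenceWarning
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return Partition.from_labels(km.labels_.tolist()), float(km.inertia_)


# ---------------------------------------------------------------------------
# Hartigan dip
# ---------------------------------------------------------------------------


def _band_violations(v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Left and right worst band violations for every mode placement.

    ``hi``/``lo`` are the upper/lower band values at the unique sample
    points ``v`` (empirical CDF left limits and right values). Returns
    (L, R): L[i] is the worst amount by which the greatest convex minorant
    of hi[0..i] undercuts lo[k] for k < i; R[i] mirrors it from the right
    with the least concave majorant of lo[i..m-1] against hi[k], k > i.
    """
    m = v.size
    L = np.zeros(m)
    hull: list[int] = []  # lower convex hull of (v, hi)
    for i in range(m):
        while len(hull) >= 2:
            p, q = hull[-2], hull[-1]
            if (hi[q] - hi[p]) * (v[i] - v[q]) > (hi[i] - hi[q]) * (v[q] - v[p]):
                hull.pop()
            else:
                break
        hull.append(i)
        if i:
            fit = np.interp(v[:i], v[hull], hi[hull])
            L[i] = max(0.0, float(np.max(lo[:i] - fit)))
    R = np.zeros(m)
    hull = []  # upper concave hull of (v, lo), built right to left
    for i in range(m - 1, -1, -1):
        while len(hull) >= 2:
            p, q = hull[-2], hull[-1]
            # pop q if it falls on/below the chord from i to p (concavity violated)
            if (lo[q] - lo[i]) * (v[p] - v[q]) <= (lo[p] - lo[q]) * (v[q] - v[i]):
                hull.pop()
            else:
                break
        hull.append(i)
        if i < m - 1:
            knots = hull[::-1]
            fit = np.interp(v[i + 1:], v[knots], lo[knots])
            R[i] = max(0.0, float(np.max(fit - hi[i + 1:])))
    return L, R


def dip_statistic(sample) -> float:
    """Hartigan & Hartigan's dip: sup-norm distance of the empirical CDF
    from the nearest unimodal CDF.

    Exact for finite samples; invariant under affine rescaling of the
    sample. Minimum possible value is 0 (all values equal) and 1/(2n) for
    samples with distinct values.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"dip requires at least 4 observations, got {n}")
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    cum = np.cumsum(counts)
    lo = cum / n  # empirical CDF right values
    hi = (cum - counts) / n  # left limits
    w = counts / n
    L, R = _band_violations(v, lo, hi)
    # mode at a data value: that value's lower bound moves to the concave side
    best = float(np.min(np.maximum(L, R)))
    # mode strictly inside a gap (both bounds active on their sides)
    if m > 1:
        gap = np.maximum.reduce([L[:-1], R[1:], w[:-1], w[1:]])
        best = min(best, float(np.min(gap)))
    # mode below or above all data
    best = min(best, max(R[0], w[0]), max(L[-1], w[-1]))
    return best / 2.0


_DIP_NULL_CACHE: dict = {}


def dip_null_distribution(n: int, n_boot: int = 2000, seed: int | None = 0) -> np.ndarray:
    """Bootstrap null dips from uniform samples of size ``n`` (cached)."""
    key = (int(n), int(n_boot), seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        _DIP_NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)]
        )
    return _DIP_NULL_CACHE[key]


def dip_pvalue(sample, n_boot: int = 2000, seed: int | None = 0) -> float:
    """Bootstrap p-value of the dip under a uniform null with matched n."""
    x = np.asarray(sample, dtype=float)
    d = dip_statistic(x)
    null = dip_null_distribution(x.size, n_boot=n_boot, seed=seed)
    return float((1 + np.sum(null >= d)) / (n_boot + 1))


# ---------------------------------------------------------------------------
# Resampling tests
# ---------------------------------------------------------------------------


def bootstrap_ttest(
    x,
    y,
    n_boot: int = 2000,
    seed: int | None = 0,
    alternative: str = "greater",
) -> float:
    """Bootstrap t-test of mean(x) vs mean(y) under the pooled null.

    The null distribution is formed by resampling both groups with
    replacement from the mean-centered pooled sample and recomputing the
    Welch t statistic ``n_boot`` times. ``alternative='greater'`` tests
    mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise InsufficientDataError("bootstrap t-test needs >= 5 samples per group")
    pooled = np.concatenate([x, y])
    if np.var(pooled) == 0:
        raise DegenerateInputError("pooled sample has zero variance")
    pooled = pooled - pooled.mean()

    def welch_t(a, b, axis=-1):
        na, nb = a.shape[axis], b.shape[axis]
        va = a.var(axis=axis, ddof=1) / na
        vb = b.var(axis=axis, ddof=1) / nb
        se = np.sqrt(va + vb)
        se = np.where(se == 0, np.finfo(float).tiny, se)
        return (a.mean(axis=axis) - b.mean(axis=axis)) / se

    t_obs = welch_t(x, y)
    rng = np.random.default_rng(seed)
    bx = rng.choice(pooled, size=(n_boot, x.size), replace=True)
    by = rng.choice(pooled, size=(n_boot, y.size), replace=True)
    t_null = welch_t(bx, by)
    if alternative == "greater":
        exceed = np.sum(t_null >= t_obs)
    elif alternative == "less":
        exceed = np.sum(t_null <= t_obs)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(t_null) >= abs(t_obs))
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return float((1 + exceed) / (n_boot + 1))


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns a boolean mask."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]
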