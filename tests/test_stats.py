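import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from amecog.errors import InsufficientDataError, ParameterError
from amecog.stats import (
    Partition,
    adjusted_rand_index,
    bh_fdr,
    bootstrap_ttest,
    dip_pvalue,
    dip_statistic,
    kmeans,
    pair_counts,
    rand_index,
    silhouette_index,
)
from oracles import dip_bruteforce


# ---------------------------------------------------------------------------
# pair counts / Rand indices
# ---------------------------------------------------------------------------

U4 = Partition.from_groups({"A": [1, 2], "B": [3, 4]})
V4 = Partition.from_groups({"A": [1, 3], "B": [2, 4]})


@pytest.mark.parametrize(
    "U,V,expected",
    [
        (U4, U4, (2, 0, 0, 4)),
        (U4, V4, (0, 2, 2, 2)),
        (
            Partition.from_labels(range(4)),
            Partition.from_labels(range(4)),
            (0, 0, 0, 6),
        ),
    ],
)
def test_pair_counts_classifies_all_pairs(U, V, expected):
    pc = pair_counts(U, V)
    assert (pc.a, pc.b, pc.c, pc.d) == expected


def test_rand_index_values():
    assert rand_index(pair_counts(U4, U4)) == 1.0
    assert rand_index(pair_counts(U4, V4)) == pytest.approx(1 / 3)


def test_adjusted_rand_identical_and_crossed():
    P8 = Partition.from_groups({"a": [0, 1, 2], "b": [3, 4, 5], "c": [6, 7]})
    assert adjusted_rand_index(P8, P8) == 1.0
    assert adjusted_rand_index(U4, V4) == pytest.approx(-0.5)


def test_adjusted_rand_matches_contingency_form():
    """Pair-count formula vs the contingency-table implementation (sklearn)."""
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(1000):
        n = int(rng.integers(5, 30))
        lu = rng.integers(0, rng.integers(2, 5), size=n)
        lv = rng.integers(0, rng.integers(2, 5), size=n)
        ours = adjusted_rand_index(Partition.from_labels(lu), Partition.from_labels(lv))
        worst = max(worst, abs(ours - adjusted_rand_score(lu, lv)))
    assert worst < 1e-12


def test_adjusted_rand_mean_zero_for_independent_partitions():
    rng = np.random.default_rng(1)
    vals = [
        adjusted_rand_index(
            Partition.from_labels(rng.integers(0, 3, 24)),
            Partition.from_labels(rng.integers(0, 3, 24)),
        )
        for _ in range(2000)
    ]
    assert abs(np.mean(vals)) < 0.01


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def _distances(X):
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.atleast_2d(X).T if np.ndim(X) == 1 else X))


def test_silhouette_coincident_groups_score_one():
    X = np.array([[0.0, 0.0]] * 4 + [[10.0, 0.0]] * 4)
    s, mean = silhouette_index(_distances(X), [0] * 4 + [1] * 4)
    assert np.allclose(s, 1.0)
    assert mean == 1.0


def test_silhouette_hand_value_and_misassignment():
    X = np.array([0.0, 1.0, 10.0, 11.0])
    D = _distances(X)
    s, _ = silhouette_index(D, [0, 0, 1, 1])
    assert s[0] == pytest.approx((10.5 - 1.0) / 10.5)
    _, mean_swapped = silhouette_index(D, [0, 1, 0, 1])
    assert mean_swapped < 0


def test_silhouette_matches_sklearn_and_is_order_invariant(rng):
    X = rng.normal(size=(20, 2))
    labels = rng.integers(0, 3, 20)
    D = _distances(X)
    _, mean = silhouette_index(D, labels)
    assert mean == pytest.approx(silhouette_score(D, labels, metric="precomputed"))
    perm = rng.permutation(20)
    _, mean_p = silhouette_index(D[np.ix_(perm, perm)], labels[perm])
    assert mean_p == pytest.approx(mean)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def test_kmeans_recovers_separated_clouds(rng):
    centers = np.array([[0, 0], [20, 0], [0, 20]])
    truth = np.repeat([0, 1, 2], 15)
    X = centers[truth] + rng.normal(0, 1, size=(45, 2))
    part, _ = kmeans(X, 3, seed=0)
    assert adjusted_rand_index(part, Partition.from_labels(truth)) == 1.0


def test_kmeans_degenerate_cases(rng):
    X = rng.normal(size=(10, 2))
    part, inertia = kmeans(X, 1, seed=0)
    assert part.k == 1
    assert inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())
    dup = np.zeros((6, 2))
    _, inertia0 = kmeans(dup, 2, seed=0)
    assert inertia0 == 0.0
    with pytest.raises(ParameterError):
        kmeans(X, 11)


# ---------------------------------------------------------------------------
# dip
# ---------------------------------------------------------------------------

def test_dip_analytic_anchors():
    # equally spaced points: best unimodal CDF is the straight line -> 1/(2n)
    assert dip_statistic([0.0, 1.0, 2.0, 3.0]) == pytest.approx(1 / 8)
    # half mass at each of two points -> 1/4
    assert dip_statistic([0.0, 0.0, 10.0, 10.0]) == pytest.approx(0.25)
    with pytest.raises(InsufficientDataError):
        dip_statistic([1.0, 2.0, 3.0])


def test_dip_affine_invariance(rng):
    x = rng.normal(size=40)
    assert dip_statistic(3.7 * x - 11.0) == pytest.approx(dip_statistic(x))


def test_dip_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for trial in range(25):
        n = int(rng.integers(4, 13))
        if trial % 3 == 0:
            x = rng.normal(size=n)
        elif trial % 3 == 1:
            x = np.concatenate(
                [rng.normal(size=n // 2), rng.normal(8, 0.5, size=n - n // 2)]
            )
        else:
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        assert dip_statistic(x) == pytest.approx(dip_bruteforce(x), abs=1e-6)


def test_dip_pvalue_detects_bimodality_not_unimodality():
    rng = np.random.default_rng(4)
    bimodal = np.r_[np.zeros(50), np.full(50, 10.0)] + rng.normal(0, 0.01, 100)
    assert dip_pvalue(bimodal, n_boot=500, seed=0) < 0.01
    calm = 0
    for s in range(20):
        x = np.random.default_rng(100 + s).normal(size=100)
        calm += dip_pvalue(x, n_boot=500, seed=0) > 0.05
    assert calm >= 18  # >= 90% of unimodal samples not flagged


# ---------------------------------------------------------------------------
# bootstrap t-test / FDR
# ---------------------------------------------------------------------------

def test_bootstrap_ttest_separation_and_symmetry(rng):
    y = rng.normal(0, 1, 50)
    assert bootstrap_ttest(y + 10, y, seed=0) < 0.001
    x = rng.normal(size=50)
    assert bootstrap_ttest(x, x.copy(), seed=1) == pytest.approx(0.5, abs=0.05)
    with pytest.raises(InsufficientDataError):
        bootstrap_ttest([1.0] * 3, y)


def test_bh_fdr_step_up():
    mask = bh_fdr(np.array([0.001, 0.02, 0.9]), q=0.05)
    assert mask.tolist() == [True, True, False]
    assert not bh_fdr(np.full(10, 0.9), q=0.05).any()
    with pytest.raises(Exception):
        bh_fdr(np.array([0.5, 1.5]))
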