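"""Representational geometry of token-evoked responses.

The mean evoked pattern to each CV syllable (electrodes x time,
concatenated) is compared across tokens with correlation distances
(1 - Pearson r), visualized with metric MDS, and clustered with k-means
into k = 3 groups. Agreement between the neural clustering and the
linguistic gold standards (place vs manner of articulation) is measured
with the adjusted Rand index; Delta RI_adj = RI_adj(manner/acoustic) -
RI_adj(place) localizes which organization dominates, with a label-
permutation null and Benjamini-Hochberg correction across time windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import smacof

from .core import EvokedDataset, get_logger
from .errors import ParameterError, ValidationError
from .features import scheme_partition
from .stats import Partition, adjusted_rand_index, bh_fdr, kmeans

log = get_logger("amecog.geometry")

__all__ = [
    "TokenResponseMatrix",
    "token_means",
    "distance_matrix",
    "mds_embed",
    "cluster_agreement",
    "cluster_agreement_bootstrap",
    "delta_ri",
    "delta_ri_trajectory",
]


@dataclass
class TokenResponseMatrix:
    """Tokens x features (electrode x time means within a window)."""

    values: np.ndarray
    tokens: list[str]
    window: tuple[float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape[0] != len(self.tokens):
            raise ValidationError("one row per token required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in token response matrix")


def token_means(
    evoked: EvokedDataset,
    electrode_subset=None,
    window: tuple[float, float] = (0.0, 0.5),
) -> TokenResponseMatrix:
    """Trial-mean responses per token, concatenated across electrodes."""
    ds = evoked if electrode_subset is None else evoked.subset_electrodes(electrode_subset)
    if ds.responses.shape[0] == 0:
        raise ParameterError("electrode subset is empty")
    sl = ds.window_slice(window)
    means = ds.responses[..., sl].mean(axis=2)  # electrode x token x time
    mat = means.transpose(1, 0, 2).reshape(len(ds.tokens), -1)
    return TokenResponseMatrix(values=mat, tokens=list(ds.tokens), window=window)


def distance_matrix(trm: TokenResponseMatrix) -> np.ndarray:
    """1 - Pearson r between token rows; symmetric, zero diagonal."""
    X = trm.values
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 features per token")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [trm.tokens[i] for i in np.flatnonzero(sd == 0)]
        raise ParameterError(f"zero-variance response rows for tokens: {bad}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def mds_embed(D: np.ndarray, dims: int = 2, seed: int | None = 0):
    """Metric MDS (SMACOF) of a distance matrix, classically initialized.

    Correlation distances are generally non-Euclidean, so stress
    minimization is iterative; the classical-scaling solution seeds it.
    Returns (coords, stress); orientation is arbitrary.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be square and symmetric")
    # classical scaling init: double-centered squared distances
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    init = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    coords, stress = smacof(
        D, n_components=dims, init=init, n_init=1, metric=True,
        random_state=seed, eps=1e-12, max_iter=1000, normalized_stress=False,
    )
    return coords, float(stress)


def cluster_agreement(
    trm: TokenResponseMatrix,
    scheme: str | Partition,
    k: int = 3,
    n_restarts: int = 50,
    seed: int | None = 0,
) -> float:
    """Adjusted Rand index between k-means on token rows and a gold standard."""
    if k > len(trm.tokens):
        raise ParameterError(f"k={k} exceeds token count")
    gold = scheme if isinstance(scheme, Partition) else scheme_partition(trm.tokens, scheme)
    part, _ = kmeans(trm.values, k, n_restarts=n_restarts, seed=seed)
    neural = Partition(tuple(trm.tokens), part.labels)
    return adjusted_rand_index(neural, gold)


def cluster_agreement_bootstrap(
    evoked: EvokedDataset,
    scheme: str,
    electrode_subset=None,
    window: tuple[float, float] = (0.0, 0.5),
    k: int = 3,
    n_boot: int = 100,
    n_restarts: int = 10,
    seed: int | None = 0,
) -> tuple[float, float, np.ndarray]:
    """RI_adj distribution over trial-bootstrap resamples x k-means restarts.

    Returns (mean, SD, samples).
    """
    ds = evoked if electrode_subset is None else evoked.subset_electrodes(electrode_subset)
    sl = ds.window_slice(window)
    rng = np.random.default_rng(seed)
    gold = scheme_partition(ds.tokens, scheme)
    n_trials = ds.responses.shape[2]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_trials, size=n_trials)
        means = ds.responses[:, :, pick, sl].mean(axis=2)
        mat = means.transpose(1, 0, 2).reshape(len(ds.tokens), -1)
        part, _ = kmeans(mat, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        vals[b] = adjusted_rand_index(Partition(tuple(ds.tokens), part.labels), gold)
    return float(vals.mean()), float(vals.std()), vals


def delta_ri(
    trm: TokenResponseMatrix,
    k: int = 3,
    n_restarts: int = 50,
    seed: int | None = 0,
) -> float:
    """RI_adj against the acoustic (manner) scheme minus the place scheme.

    +1 indicates pure acoustic-feature organization, -1 pure place
    organization.
    """
    part, _ = kmeans(trm.values, k, n_restarts=n_restarts, seed=seed)
    neural = Partition(tuple(trm.tokens), part.labels)
    return adjusted_rand_index(neural, scheme_partition(trm.tokens, "manner")) - (
        adjusted_rand_index(neural, scheme_partition(trm.tokens, "place"))
    )


def _delta_ri_of_labels(labels: np.ndarray, manner: np.ndarray, place: np.ndarray) -> float:
    a = adjusted_rand_index(Partition.from_labels(labels), Partition.from_labels(manner))
    b = adjusted_rand_index(Partition.from_labels(labels), Partition.from_labels(place))
    return a - b


def delta_ri_trajectory(
    evoked: EvokedDataset,
    window_len: float = 0.1,
    step: float = 0.01,
    k: int = 3,
    n_perm: int = 1000,
    q: float = 0.05,
    n_restarts: int = 10,
    seed: int | None = 0,
    electrode_subset=None,
):
    """Sliding-window Delta RI_adj with a permutation null and FDR mask.

    In each window the token means are clustered and Delta RI_adj computed;
    the null randomizes the token labeling of the clustering
    ``n_perm`` times. One-sided p-values (toward acoustic organization) are
    Benjamini-Hochberg corrected at level ``q`` across windows.

    Returns a dict with window centers, delta values, p-values and the
    significance mask.
    """
    if n_perm < 10:
        raise ParameterError("n_perm must be at least 10")
    if n_perm < 100:
        log.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    ds = evoked if electrode_subset is None else evoked.subset_electrodes(electrode_subset)
    t0, t1 = ds.time_axis[0], ds.time_axis[-1]
    if window_len > t1 - t0:
        raise ParameterError("window_len exceeds the response duration")
    rng = np.random.default_rng(seed)
    manner = scheme_partition(ds.tokens, "manner").aligned_labels(ds.tokens)
    place = scheme_partition(ds.tokens, "place").aligned_labels(ds.tokens)
    starts = np.arange(t0, t1 - window_len + 1e-9, step)
    centers, deltas, pvals = [], [], []
    n_tok = len(ds.tokens)
    for s in starts:
        trm = token_means(ds, window=(s, s + window_len))
        part, _ = kmeans(trm.values, k, n_restarts=n_restarts,
                         seed=int(rng.integers(2**31)))
        labels = np.asarray(part.aligned_labels(part.items))
        obs = _delta_ri_of_labels(labels, manner, place)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _delta_ri_of_labels(labels[rng.permutation(n_tok)], manner, place)
        pvals.append(float((1 + np.sum(null >= obs)) / (n_perm + 1)))
        deltas.append(obs)
        centers.append(s + window_len / 2)
    mask = bh_fdr(np.array(pvals), q=q)
    return {
        "window_centers_s": np.array(centers),
        "delta_ri": np.array(deltas),
        "p": np.array(pvals),
        "significant": mask,
    }
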