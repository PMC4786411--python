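"""Spatial clustering of electrode positions.

Are the responsive electrodes spatially clustered at all? Following the
dip-means idea, each electrode in turn acts as a 'viewer': if the
distribution of its distances to all other electrodes significantly
deviates from unimodality (Hartigan dip test), the configuration is
considered clustered. Only then is k chosen, by running k-means for
k = 2..6 and keeping the k with the best mean silhouette.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ElectrodeTable
from .errors import InsufficientDataError, ParameterError
from .stats import Partition, dip_pvalue, kmeans, silhouette_index

__all__ = ["dip_means_is_clustered", "select_k"]


def dip_means_is_clustered(
    electrodes: ElectrodeTable,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = 0,
    bonferroni: bool = False,
) -> tuple[bool, np.ndarray]:
    """Viewer-wise dip tests on pairwise distances.

    Returns (clustered, per-viewer p-values); clustered is True when at
    least one viewer's distance distribution is significantly non-unimodal
    at ``alpha`` (optionally Bonferroni-corrected across viewers).
    """
    n = len(electrodes)
    if n < 5:
        raise InsufficientDataError("need at least 5 electrodes")
    D = squareform(pdist(electrodes.positions))
    level = alpha / n if bonferroni else alpha
    pvals = np.empty(n)
    for i in range(n):
        d = np.delete(D[i], i)
        if np.allclose(d, d[0]):
            pvals[i] = 1.0  # degenerate: all distances equal, trivially unimodal
            continue
        pvals[i] = dip_pvalue(d, n_boot=n_boot, seed=seed)
    return bool(np.any(pvals < level)), pvals


def select_k(
    electrodes: ElectrodeTable,
    k_range=range(2, 7),
    n_restarts: int = 50,
    seed: int | None = 0,
) -> tuple[int, dict, Partition]:
    """Choose k by mean silhouette over k-means solutions for k = 2..6."""
    X = electrodes.positions
    k_range = list(k_range)
    if len(X) < max(k_range):
        raise ParameterError(
            f"{len(X)} electrodes cannot support k up to {max(k_range)}"
        )
    D = squareform(pdist(X))
    silhouettes = {}
    partitions = {}
    for k in k_range:
        part, _ = kmeans(X, k, n_restarts=n_restarts, seed=seed)
        labels = part.aligned_labels(part.items)
        _, mean_s = silhouette_index(D, labels)
        silhouettes[k] = mean_s
        partitions[k] = part
    best_k = max(silhouettes, key=silhouettes.get)
    best = partitions[best_k]
    # re-key the partition by electrode ids
    best = Partition(tuple(electrodes.ids), best.labels)
    return best_k, silhouettes, best
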