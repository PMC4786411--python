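"""Phoneme selectivity index (PSI).

For one electrode, responses aligned to phoneme onsets are reduced to one
scalar per occurrence (mean z-scored high gamma in a short post-onset
window). The PSI of phoneme p is the number of *other* phonemes whose
response distribution differs significantly from p's (two-sample Wilcoxon
rank-sum, p < 0.01, corrected for the n(n-1)/2 pairwise comparisons). With
33 phonemes the PSI ranges 0..32: 0 = not selective, 32 = responds
differently to every other phoneme.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import EventTable, HighGammaSeries, get_logger
from .errors import InsufficientDataError, ParameterError, WindowingError
from .stats import bh_fdr

log = get_logger("amecog.psi")

__all__ = ["PSIVector", "align_to_phonemes", "psi_vector"]


@dataclass
class PSIVector:
    """Integer PSI per phoneme for one electrode."""

    phonemes: list[str]
    psi: np.ndarray
    alpha: float
    correction: str
    electrode_id: str | None = None

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=int)
        n = len(self.phonemes)
        if self.psi.shape != (n,):
            raise ParameterError("one PSI per phoneme required")
        if np.any(self.psi < 0) or np.any(self.psi > n - 1):
            raise ParameterError("PSI values must lie in [0, n_phonemes - 1]")

    def as_dict(self) -> dict:
        return dict(zip(self.phonemes, self.psi.tolist()))


def align_to_phonemes(
    hg: HighGammaSeries,
    events: EventTable,
    window: tuple[float, float] = (0.0, 0.15),
    min_occurrences: int = 31,
    channel: int = 0,
) -> dict:
    """Scalar response per phoneme occurrence for one channel.

    Each occurrence contributes the mean z within ``window`` after its
    onset; phonemes with fewer than ``min_occurrences`` occurrences are
    excluded (logged), mirroring the "more than 30 occurrences" rule.
    """
    if window[1] <= window[0]:
        raise WindowingError("phoneme window must have positive length")
    fs = hg.fs_out
    a_off = int(round(window[0] * fs))
    b_off = int(round(window[1] * fs))
    if b_off <= a_off:
        raise WindowingError("phoneme window shorter than one sample")
    n = hg.values.shape[1]
    out: dict[str, np.ndarray] = {}
    for ph, rows in events.df.groupby("label"):
        if len(rows) < min_occurrences:
            log.info("phoneme %s excluded (%d < %d occurrences)",
                     ph, len(rows), min_occurrences)
            continue
        vals = []
        for onset in rows["onset_s"]:
            a = int(round(onset * fs)) + a_off
            b = int(round(onset * fs)) + b_off
            if a < 0 or b > n:
                raise WindowingError(f"phoneme at {onset} s outside the series")
            vals.append(hg.values[channel, a:b].mean())
        out[str(ph)] = np.asarray(vals)
    return out


def psi_vector(
    per_phoneme_trials: dict,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    electrode_id: str | None = None,
) -> PSIVector:
    """PSI per phoneme from pairwise rank-sum tests.

    All n(n-1)/2 phoneme pairs are tested (two-sided Wilcoxon rank-sum) and
    corrected for multiple comparisons ('bonferroni' default, 'fdr' for
    Benjamini-Hochberg); PSI(p) counts the phonemes significantly
    different from p. Phonemes with fewer than 5 trials are excluded with
    a warning.
    """
    from scipy.stats import ranksums

    if correction not in ("bonferroni", "fdr"):
        raise ParameterError(f"unknown correction {correction!r}")
    kept = {}
    for ph, vals in per_phoneme_trials.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 5:
            log.warning("phoneme %s excluded (%d < 5 trials)", ph, vals.size)
            continue
        kept[ph] = vals
    if len(kept) < 2:
        raise InsufficientDataError("need at least 2 phonemes with >= 5 trials")
    phonemes = sorted(kept)
    pairs = list(combinations(range(len(phonemes)), 2))
    # one vectorized rank-sum call across all pairs (trial counts equal),
    # falling back to a loop otherwise
    sizes = {kept[ph].size for ph in phonemes}
    if len(sizes) == 1:
        A = np.stack([kept[phonemes[i]] for i, _ in pairs])
        B = np.stack([kept[phonemes[j]] for _, j in pairs])
        _, pvals = ranksums(A, B, axis=1)
    else:
        pvals = np.array(
            [ranksums(kept[phonemes[i]], kept[phonemes[j]])[1] for i, j in pairs]
        )
    if correction == "bonferroni":
        sig = pvals < alpha / len(pairs)
    else:
        sig = bh_fdr(pvals, q=alpha)
    psi = np.zeros(len(phonemes), dtype=int)
    for (i, j), s in zip(pairs, sig):
        if s:
            psi[i] += 1
            psi[j] += 1
    return PSIVector(phonemes=phonemes, psi=psi, alpha=alpha,
                     correction=correction, electrode_id=electrode_id)
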