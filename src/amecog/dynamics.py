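"""Response latencies and cross-correlation lead-lag analysis.

Onset latency is the first post-onset time at which across-trial activity
significantly exceeds the pooled 500 ms pre-stimulus baseline (one-tailed
Wilcoxon rank-sum, p < 0.001); peak latency is the argmax of the
trial-mean response. Timing between electrode pairs comes from per-trial
cross-correlograms, normalized by 1/(M - |tau|) for an unbiased estimate
at each lag and averaged over trials.

Sign convention: a *negative* peak lag means the first argument (e.g. an
STG electrode) leads the second (e.g. a vSMC electrode). The asymmetry
index (Ppos - Pneg)/(Ppos + Pneg) sums only the positive correlogram
values on each side of lag zero; -1 means all mass at negative lags (first
electrode leads), +1 all mass at positive lags (second electrode leads).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import ranksums

from .core import get_logger
from .errors import ParameterError, WindowingError

log = get_logger("amecog.dynamics")

__all__ = [
    "CrossCorrelogram",
    "onset_latency",
    "peak_latency",
    "compare_latencies",
    "cross_correlogram",
    "asymmetry_index",
    "classify_lead_lag",
]


@dataclass
class CrossCorrelogram:
    """Lag-indexed, trial-averaged normalized correlation of two electrodes."""

    lags: np.ndarray    # seconds, symmetric about 0
    values: np.ndarray
    M: int              # response length in samples (normalization constant)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.lags.shape != self.values.shape:
            raise ParameterError("lags and values must align")

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.values))])


def onset_latency(
    trials: np.ndarray,
    time_axis: np.ndarray,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    alpha: float = 0.001,
) -> float | None:
    """First post-onset time (ms) significantly above baseline, or None.

    ``trials`` is (n_trials, n_time). At each post-onset sample the
    across-trial values are compared with the pooled baseline samples by a
    one-tailed rank-sum test.
    """
    trials = np.asarray(trials, float)
    time_axis = np.asarray(time_axis, float)
    base_mask = (time_axis >= baseline_window[0]) & (time_axis < baseline_window[1])
    if not base_mask.any():
        raise WindowingError(f"empty baseline window {baseline_window}")
    baseline = trials[:, base_mask].ravel()
    post = np.flatnonzero(time_axis >= 0)
    # vectorized rank-sum over time points
    stat, p = ranksums(
        trials[:, post], baseline[:, None], alternative="greater", axis=0
    )
    sig = np.flatnonzero(p < alpha)
    if sig.size == 0:
        return None
    return float(time_axis[post[sig[0]]] * 1000.0)


def peak_latency(
    mean_response: np.ndarray,
    time_axis: np.ndarray,
    window: tuple[float, float] | None = None,
) -> tuple[float, bool]:
    """Time (ms) of the maximum of the trial-mean response.

    Exact ties resolve to the earliest sample and set the tie flag.
    """
    r = np.asarray(mean_response, float)
    t = np.asarray(time_axis, float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        if not m.any():
            raise WindowingError(f"empty peak window {window}")
        r, t = r[m], t[m]
    peak = int(np.argmax(r))
    tie = bool(np.sum(r == r[peak]) > 1)
    return float(t[peak] * 1000.0), tie


def compare_latencies(latencies: pd.DataFrame, min_per_region: int = 3) -> pd.DataFrame:
    """Pairwise two-tailed rank-sum tests of latency between regions.

    ``latencies`` needs columns ``region`` and ``latency_ms`` (NaN/None
    rows dropped). Returns one row per region pair with the Z statistic.
    """
    df = latencies.dropna(subset=["latency_ms"])
    groups = {
        r: sub["latency_ms"].to_numpy(float)
        for r, sub in df.groupby("region")
        if len(sub) >= min_per_region
    }
    skipped = set(df["region"].unique()) - set(groups)
    if skipped:
        log.warning("regions skipped (fewer than %d sites): %s",
                    min_per_region, sorted(skipped))
    rows = []
    for r1, r2 in combinations(sorted(groups), 2):
        z, p = ranksums(groups[r1], groups[r2])
        rows.append({"region_a": r1, "region_b": r2, "z": float(z), "p": float(p),
                     "median_a_ms": float(np.median(groups[r1])),
                     "median_b_ms": float(np.median(groups[r2]))})
    return pd.DataFrame(rows, columns=["region_a", "region_b", "z", "p",
                                       "median_a_ms", "median_b_ms"])


def cross_correlogram(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    fs: float,
    max_lag: float = 0.75,
    time_axis: np.ndarray | None = None,
    window: tuple[float, float] = (-0.5, 1.0),
    demean: bool = True,
) -> CrossCorrelogram:
    """Trial-averaged normalized cross-correlogram of two electrodes.

    Trials are mean-subtracted within the analysis window (``demean=False``
    keeps raw products, e.g. for analytic constructions on nonnegative
    pulses); each trial's lagged products are scaled by 1/(M - |tau|) (an
    unbiased estimate at every lag) and the per-trial correlograms are
    averaged. Lags run over [-max_lag, +max_lag]; a negative peak lag
    means x leads y.
    """
    x = np.atleast_2d(np.asarray(x_trials, float))
    y = np.atleast_2d(np.asarray(y_trials, float))
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal trial counts and lengths")
    if time_axis is not None:
        m = (np.asarray(time_axis) >= window[0]) & (np.asarray(time_axis) <= window[1])
        x, y = x[:, m], y[:, m]
    M = x.shape[1]
    max_lag_samp = int(round(max_lag * fs))
    if max_lag_samp >= M:
        raise ParameterError("max_lag must be shorter than the response window")
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
    # per-trial scale so values are correlation-like
    denom = x.std(axis=1) * y.std(axis=1)
    denom[denom == 0] = np.inf
    lags_full = sp_signal.correlation_lags(M, M)
    keep = np.abs(lags_full) <= max_lag_samp
    lag_samples = lags_full[keep]
    acc = np.zeros(lag_samples.size)
    for i in range(x.shape[0]):
        cc = sp_signal.correlate(x[i], y[i], mode="full")[keep]
        acc += cc / (M - np.abs(lag_samples)) / denom[i]
    values = acc / x.shape[0]
    return CrossCorrelogram(lags=lag_samples / fs, values=values, M=M)


def asymmetry_index(xc: CrossCorrelogram) -> float | None:
    """(Ppos - Pneg)/(Ppos + Pneg) over positive correlogram values.

    Lag 0 belongs to neither side. Returns None when there is no positive
    correlogram mass at all.
    """
    pos_side = xc.values[(xc.lags > 0) & (xc.values > 0)].sum()
    neg_side = xc.values[(xc.lags < 0) & (xc.values > 0)].sum()
    total = pos_side + neg_side
    if total == 0:
        return None
    return float((pos_side - neg_side) / total)


def classify_lead_lag(indices, band: float = 0.25) -> dict:
    """Percentages of pairs with x leading, coactive, or y leading.

    Thresholds the asymmetry index at +-``band``: index < -band means the
    first electrode (x) leads, index > +band the second (y) leads.
    """
    idx = np.asarray([i for i in indices if i is not None], float)
    if idx.size == 0:
        raise ParameterError("need at least one asymmetry index")
    x_leads = float(np.mean(idx < -band) * 100.0)
    y_leads = float(np.mean(idx > band) * 100.0)
    coactive = 100.0 - x_leads - y_leads
    return {"x_leads": x_leads, "coactive": coactive, "y_leads": y_leads}
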