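"""Raw voltage to z-scored high-gamma.

The chain follows standard intracranial practice: notch out line noise
(60 Hz and harmonics), drop channels whose periodogram deviates more than
two SDs from the average of the other channels, common-average reference
within contiguous amplifier banks, extract the 70-150 Hz analytic
amplitude with a bank of eight Gaussian bandpass filters and the Hilbert
transform, average the eight amplitudes, downsample to 100 Hz, and z-score
each channel against baseline rest data.

Every filter stage is zero-phase (frequency-domain Gaussians, filtfilt
notches, polyphase resampling), so envelope peak times are not biased.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import fft, ifft, next_fast_len

from .core import EventTable, EvokedDataset, HighGammaSeries, Recording, get_logger
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
    ReferenceError_,
    WindowingError,
)

log = get_logger("amecog.preprocess")

__all__ = [
    "notch_filter",
    "detect_bad_channels",
    "common_average_reference",
    "extract_high_gamma",
    "zscore_to_baseline",
    "preprocess_recording",
    "epoch_high_gamma",
]


def notch_filter(rec: Recording, freqs=(60.0, 120.0, 180.0), q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at each frequency (forward-backward, Q=30)."""
    for f0 in freqs:
        if f0 >= rec.fs / 2:
            raise ParameterError(f"notch frequency {f0} at or above Nyquist")
    signal = np.asarray(rec.signal, dtype=float)
    for f0 in freqs:
        b, a = sp_signal.iirnotch(f0, q, fs=rec.fs)
        signal = sp_signal.filtfilt(b, a, signal, axis=1)
    return Recording(signal, rec.fs, list(rec.channel_ids), rec.bank_size)


def detect_bad_channels(rec: Recording, threshold_sd: float = 2.0) -> set[str]:
    """Channels whose log-periodogram deviates from the others'.

    Welch periodograms (1 s windows); each channel's deviation is the
    Euclidean distance between its log-periodogram and the mean
    log-periodogram of the *other* channels. A channel is flagged when its
    deviation exceeds the cross-channel mean deviation by more than
    ``threshold_sd`` cross-channel standard deviations. (Distances are
    positive even for perfectly typical channels, so the threshold applies
    to the centered deviation, not the raw distance.)
    """
    if rec.n_channels < 3:
        raise InsufficientDataError("bad-channel detection needs >= 3 channels")
    nperseg = min(int(rec.fs), rec.n_samples)
    _, pxx = sp_signal.welch(rec.signal, fs=rec.fs, nperseg=nperseg, axis=1)
    logp = np.log10(np.maximum(pxx, np.finfo(float).tiny))
    total = logp.sum(axis=0)
    n = rec.n_channels
    dist = np.array(
        [np.linalg.norm(logp[c] - (total - logp[c]) / (n - 1)) for c in range(n)]
    )
    sd = dist.std()
    flagged = np.flatnonzero(dist - dist.mean() > threshold_sd * sd)
    return {rec.channel_ids[c] for c in flagged}


def common_average_reference(
    rec: Recording, bank_size: int | None = None, exclude=()
) -> Recording:
    """Subtract each bank's mean over non-excluded channels from all its channels.

    Banks are contiguous blocks of ``bank_size`` channels in channel order
    (the wiring of one amplifier); the final bank may be short. Excluded
    channels do not contribute to the mean but are still referenced.
    """
    bank_size = bank_size or rec.bank_size
    exclude = set(exclude)
    unknown = exclude - set(rec.channel_ids)
    if unknown:
        raise ParameterError(f"excluded ids not in recording: {sorted(unknown)}")
    signal = np.array(rec.signal, dtype=float)
    keep = np.array([cid not in exclude for cid in rec.channel_ids])
    for b, idx in enumerate(
        Recording(signal, rec.fs, list(rec.channel_ids), bank_size).banks()
    ):
        good = idx[keep[idx]]
        if good.size == 0:
            raise ReferenceError_(f"bank {b} has no non-excluded channels")
        signal[idx] -= signal[good].mean(axis=0)
    return Recording(signal, rec.fs, list(rec.channel_ids), bank_size)


def _gaussian_filter_bank(band: tuple[float, float], n_filters: int):
    """Log-spaced centers with bandwidths growing as sqrt(f).

    The sigmas are scaled so the filters' full widths at half maximum tile
    the band end to end.
    """
    lo, hi = band
    centers = np.geomspace(lo, hi, n_filters)
    root = np.sqrt(centers)
    fwhm_per_sigma = 2.0 * np.sqrt(2.0 * np.log(2.0))
    c = (hi - lo) / (fwhm_per_sigma * root.sum())
    sigmas = c * root
    return centers, sigmas


def extract_high_gamma(
    rec: Recording,
    band: tuple[float, float] = (70.0, 150.0),
    n_filters: int = 8,
    fs_out: float = 100.0,
) -> HighGammaSeries:
    """Average analytic amplitude over Gaussian bandpass filters, resampled.

    Each filter is a Gaussian in the frequency domain; its analytic signal
    comes from zeroing the negative frequencies (Hilbert transform), and
    its amplitude is the complex magnitude. The ``n_filters`` amplitudes
    are averaged and the result polyphase-resampled to ``fs_out``. The
    output is *not* yet z-scored.
    """
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ParameterError(f"band {band} not inside (0, Nyquist)")
    if fs_out > rec.fs:
        raise ParameterError("fs_out cannot exceed the recording rate")
    n = rec.n_samples
    nfft = next_fast_len(n)
    freqs = np.fft.fftfreq(nfft, d=1.0 / rec.fs)
    centers, sigmas = _gaussian_filter_bank(band, n_filters)

    spectra = fft(np.asarray(rec.signal, dtype=float), n=nfft, axis=1)
    analytic_weight = np.zeros(nfft)
    analytic_weight[freqs > 0] = 2.0
    analytic_weight[freqs == 0] = 1.0

    amplitude = np.zeros((rec.n_channels, n))
    for fc, sg in zip(centers, sigmas):
        w = np.exp(-0.5 * ((freqs - fc) / sg) ** 2) * analytic_weight
        analytic = ifft(spectra * w, axis=1)[:, :n]
        amplitude += np.abs(analytic)
    amplitude /= n_filters

    if fs_out != rec.fs:
        frac = Fraction(fs_out / rec.fs).limit_denominator(100000)
        amplitude = sp_signal.resample_poly(amplitude, frac.numerator,
                                            frac.denominator, axis=1)
    return HighGammaSeries(values=amplitude, fs_out=float(fs_out),
                           channel_ids=list(rec.channel_ids))


def zscore_to_baseline(hg: HighGammaSeries, baseline_intervals) -> HighGammaSeries:
    """Per-channel z-score against the pooled baseline rest intervals."""
    if not baseline_intervals:
        raise WindowingError("no baseline intervals given")
    n = hg.values.shape[1]
    mask = np.zeros(n, dtype=bool)
    for start, end in baseline_intervals:
        a = max(0, int(round(start * hg.fs_out)))
        b = min(n, int(round(end * hg.fs_out)))
        mask[a:b] = True
    if mask.sum() < hg.fs_out:
        raise WindowingError("baseline intervals must total at least 1 s")
    mu = hg.values[:, mask].mean(axis=1)
    sd = hg.values[:, mask].std(axis=1)
    if np.any(sd == 0):
        raise DegenerateInputError("zero-variance baseline on some channel")
    values = (hg.values - mu[:, None]) / sd[:, None]
    return HighGammaSeries(values=values, fs_out=hg.fs_out,
                           channel_ids=list(hg.channel_ids),
                           baseline_mean=mu, baseline_sd=sd)


def baseline_intervals_from_events(events: EventTable, pre_s: float = 0.5) -> list:
    """Pre-stimulus silent windows, one per event."""
    return [
        (row["onset_s"] - pre_s, row["onset_s"]) for _, row in events.df.iterrows()
    ]


def preprocess_recording(
    rec: Recording,
    baseline_intervals=None,
    events: EventTable | None = None,
    notch_freqs=(60.0, 120.0, 180.0),
    bad_threshold_sd: float = 2.0,
    band: tuple[float, float] = (70.0, 150.0),
    n_filters: int = 8,
    fs_out: float = 100.0,
) -> tuple[HighGammaSeries, set[str]]:
    """Full chain: notch -> reject -> banked CAR -> high gamma -> z-score.

    Baseline rest intervals default to the 500 ms pre-stimulus windows of
    ``events``. Returns the z-scored series and the rejected channel ids
    (their rows are kept, NaN-filled, to preserve channel indexing).
    """
    rec = notch_filter(rec, notch_freqs)
    bad = detect_bad_channels(rec, bad_threshold_sd)
    if bad:
        log.info("rejecting channels: %s", sorted(bad))
    rec = common_average_reference(rec, exclude=bad)
    hg = extract_high_gamma(rec, band=band, n_filters=n_filters, fs_out=fs_out)
    if baseline_intervals is None:
        if events is None:
            raise WindowingError("need baseline_intervals or events")
        baseline_intervals = baseline_intervals_from_events(events)
    hg = zscore_to_baseline(hg, baseline_intervals)
    bad_idx = [i for i, cid in enumerate(hg.channel_ids) if cid in bad]
    hg.values[bad_idx] = np.nan
    return hg, bad


def epoch_high_gamma(
    hg: HighGammaSeries,
    events: EventTable,
    t_range: tuple[float, float] = (-0.5, 1.0),
) -> EvokedDataset:
    """Cut event-aligned trials into an electrode x token x trial x time array.

    Tokens with unequal trial counts are truncated to the common minimum.
    """
    fs = hg.fs_out
    offs = np.arange(round(t_range[0] * fs), round(t_range[1] * fs) + 1)
    time_axis = offs / fs
    tokens = sorted(events.df["label"].unique())
    per_token = {}
    for tok in tokens:
        rows = events.df[events.df["label"] == tok]
        trials = []
        for _, row in rows.iterrows():
            center = int(round(row["onset_s"] * fs))
            idx = center + offs
            if idx[0] < 0 or idx[-1] >= hg.values.shape[1]:
                raise WindowingError(
                    f"event at {row['onset_s']} s does not fit the epoch window"
                )
            trials.append(hg.values[:, idx])
        per_token[tok] = np.stack(trials)  # (trial, channel, time)
    n_trials = min(v.shape[0] for v in per_token.values())
    if any(v.shape[0] != n_trials for v in per_token.values()):
        log.info("truncating tokens to %d trials each", n_trials)
    responses = np.stack([per_token[t][:n_trials] for t in tokens], axis=0)
    responses = responses.transpose(2, 0, 1, 3)  # -> electrode, token, trial, time
    task = events.df["task"].iloc[0]
    return EvokedDataset(responses=responses, time_axis=time_axis, tokens=tokens,
                         electrode_ids=list(hg.channel_ids), task=str(task))
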