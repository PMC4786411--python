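"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and emits
a :class:`GroundTruth` that suffices to compute the ideal noise-free output
of every downstream stage. The generators emulate the statistical
structure the analyses assume -- 1/f background with line noise and shared
bank noise, event-locked high-gamma bursts, feature-organized evoked
responses with region-dependent latencies, linear STRF responses to
modulation-limited spectrograms, and phoneme trials with controllable
selectivity -- without attempting acoustic or articulatory realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter

from .core import ElectrodeTable, EventTable, EvokedDataset, Recording
from .errors import ParameterError
from .features import SCHEMES, TOKENS, token_group
from .strf import Spectrogram, STRFModel, predict_response

__all__ = [
    "GroundTruth",
    "PHONEMES_33",
    "generate_raw_recording",
    "generate_evoked_dataset",
    "generate_strf_dataset",
    "generate_phoneme_dataset",
    "generate_electrode_positions",
    "make_true_strf",
    "make_syllable_events",
    "raised_cosine",
    "true_burst_envelope",
]

#: 33-label phoneme inventory (ARPAbet-style) for selectivity analyses.
PHONEMES_33 = (
    "aa", "ae", "ah", "ao", "aw", "ay", "b", "ch", "d", "dh", "eh",
    "er", "ey", "f", "g", "hh", "ih", "iy", "jh", "k", "l", "m", "n",
    "ng", "ow", "p", "r", "s", "sh", "t", "th", "uh", "uw",
)

#: Default region onset latencies (s): auditory cortex precedes motor.
DEFAULT_LATENCY_MAP = {"STG": 0.10, "vSMC_inf": 0.15, "vSMC_sup": 0.15, "other": 0.12}

_REGION_CENTERS = {
    "vSMC_sup": (5.0, 18.0),
    "vSMC_inf": (5.0, 6.0),
    "STG": (12.0, -8.0),
    "other": (-18.0, 0.0),
}


def _np_to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _np_to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_np_to_plain(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Planted structure behind a generated dataset.

    ``electrodes`` maps electrode/channel id to its planted properties
    (region, per-token gain, onset latency, lead/lag offset, ...);
    ``extra`` holds generator-specific structure such as burst windows.
    """

    seed: int
    mode: str | None = None
    noise_sd: float | None = None
    electrodes: dict = field(default_factory=dict)
    strf: list | None = None
    selectivity: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(_np_to_plain(asdict(self)), f, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            return cls(**json.load(f))


def raised_cosine(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Smooth unit-peak bump rising at ``onset`` and lasting ``duration``."""
    phase = (np.asarray(t, float) - onset) / duration
    out = np.zeros_like(phase)
    inside = (phase >= 0) & (phase <= 1)
    out[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * phase[inside]))
    return out


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f ("pink") noise with the requested standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n)
    return x * (sd / x.std())


def make_syllable_events(
    tokens=TOKENS,
    n_trials: int = 10,
    task: str = "listen",
    start_s: float = 2.0,
    iti_s: float = 1.5,
    duration_s: float = 0.3,
    seed: int | None = 0,
) -> EventTable:
    """Randomly ordered token presentations with fixed inter-trial spacing."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(tokens), n_trials)
    rng.shuffle(labels)
    onsets = start_s + iti_s * np.arange(labels.size)
    return EventTable(
        pd.DataFrame(
            {
                "onset_s": onsets,
                "offset_s": onsets + duration_s,
                "label": labels,
                "task": task,
            }
        )
    )


def true_burst_envelope(events: EventTable, n_samples: int, fs: float) -> np.ndarray:
    """Noise-free burst envelope time series on a clock at ``fs``."""
    t = np.arange(n_samples) / fs
    env = np.zeros(n_samples)
    for _, row in events.df.iterrows():
        env += raised_cosine(t, row["onset_s"], row["offset_s"] - row["onset_s"])
    return env


def generate_raw_recording(
    n_channels: int,
    duration_s: float,
    fs: float,
    events: EventTable,
    line_amp: float = 5.0,
    bank_noise_sd: float = 1.0,
    burst_snr: float = 5.0,
    seed: int | None = 0,
    noise_sd: float = 10.0,
    bank_size: int = 16,
    burst_band: tuple[float, float] = (70.0, 150.0),
    responsive_channels=None,
    bad_channel: int | None = None,
    bad_channel_factor: float = 10.0,
) -> tuple[Recording, GroundTruth]:
    """Raw multichannel voltage with planted structure.

    Per channel: pink background noise (``noise_sd``), shared 60/120/180 Hz
    sinusoids (``line_amp`` each), Gaussian noise shared within each
    ``bank_size``-channel bank (``bank_noise_sd``), and, on the designated
    responsive channels, event-locked 70-150 Hz bursts whose envelope peak
    is ``burst_snr`` times the channel's in-band background SD. One channel
    may get ``bad_channel_factor`` x inflated background to exercise the
    periodogram rejection rule.
    """
    if fs < 1000:
        raise ParameterError("fs must be >= 1000 Hz")
    if burst_band[1] >= fs / 2:
        raise ParameterError("burst band exceeds Nyquist")
    n = int(round(duration_s * fs))
    if np.any(events.df["offset_s"] > duration_s):
        raise ParameterError("events extend past the recording")
    rng = np.random.default_rng(seed)
    if responsive_channels is None:
        responsive_channels = list(range(n_channels // 2))
    responsive_channels = sorted(int(c) for c in responsive_channels)

    t = np.arange(n) / fs
    signal = np.empty((n_channels, n), dtype=float)
    for c in range(n_channels):
        sd = noise_sd * (bad_channel_factor if c == bad_channel else 1.0)
        signal[c] = _pink_noise(rng, n, sd)

    line = sum(
        line_amp * np.sin(2 * np.pi * f0 * t + ph)
        for f0, ph in zip((60.0, 120.0, 180.0), rng.uniform(0, 2 * np.pi, 3))
    )
    signal += line

    n_banks = int(np.ceil(n_channels / bank_size))
    for b in range(n_banks):
        shared = rng.standard_normal(n) * bank_noise_sd
        signal[b * bank_size:(b + 1) * bank_size] += shared

    # in-band background SD sets the burst scale per channel
    sos = sp_signal.butter(4, burst_band, btype="bandpass", fs=fs, output="sos")
    amps = {}
    envelope = true_burst_envelope(events, n, fs)
    for c in responsive_channels:
        band_sd = sp_signal.sosfiltfilt(sos, signal[c]).std()
        amp = burst_snr * band_sd
        # broadband in-band noise carrier: spectrally realistic (no sharp
        # periodogram spike) and its analytic amplitude tracks the envelope
        carrier = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        signal[c] += amp * envelope * carrier
        amps[c] = float(amp)

    rec = Recording(
        signal=signal.astype(np.float32),
        fs=float(fs),
        channel_ids=[f"ch{c:03d}" for c in range(n_channels)],
        bank_size=bank_size,
    )
    gt = GroundTruth(
        seed=seed,
        noise_sd=noise_sd,
        electrodes={
            f"ch{c:03d}": {"responsive": c in responsive_channels,
                           "burst_amp": amps.get(c, 0.0),
                           "bad": c == bad_channel}
            for c in range(n_channels)
        },
        extra={
            "line_amp": line_amp,
            "bank_noise_sd": bank_noise_sd,
            "burst_snr": burst_snr,
            "burst_band": list(burst_band),
            "bad_channel": bad_channel,
            "responsive_channels": responsive_channels,
        },
    )
    return rec, gt


def _electrode_positions_for_regions(counts: dict, rng) -> pd.DataFrame:
    rows = []
    i = 0
    for region, n_el in counts.items():
        cx, cy = _REGION_CENTERS[region]
        for _ in range(n_el):
            x = cx + rng.normal(0, 2.0)
            y = cy + rng.normal(0, 2.0)
            rows.append(
                {"id": f"e{i:03d}", "x_mm": x, "y_mm": y,
                 "dist_cs_mm": x, "dist_sf_mm": y, "region": region}
            )
            i += 1
    return pd.DataFrame(rows, columns=["id", "x_mm", "y_mm", "dist_cs_mm",
                                       "dist_sf_mm", "region"])


def generate_evoked_dataset(
    n_electrodes_per_region: dict,
    tokens=TOKENS,
    n_trials: int = 20,
    mode: str = "manner",
    latency_map: dict | None = None,
    noise_sd: float = 0.5,
    seed: int | None = 0,
    fs: float = 100.0,
    t_range: tuple[float, float] = (-0.5, 1.0),
    response_duration: float = 0.4,
    gain_levels: tuple[float, float, float] = (1.0, 0.55, 0.2),
    gain_jitter: float = 0.2,
    onset_jitter_sd: float = 0.0,
    peak_gain: float = 4.0,
    task: str | None = None,
) -> tuple[EvokedDataset, ElectrodeTable, GroundTruth]:
    """Trial-aligned evoked responses with planted feature organization.

    Each electrode is assigned one of the three feature groups of ``mode``
    ('place' or 'manner'); its response gain to a token depends only on the
    token's group relative to its own (``gain_levels``), so token-mean
    response patterns cluster exactly by feature group in the noise-free
    limit. ``mode='none'`` makes gains token-independent. Response onsets
    come from ``latency_map`` per region (seconds after acoustic onset).
    """
    if mode not in ("place", "manner", "none"):
        raise ParameterError(f"unknown mode {mode!r}")
    unknown = [t for t in tokens if t not in TOKENS]
    if unknown:
        raise ParameterError(f"unknown tokens: {unknown}")
    latency_map = {**DEFAULT_LATENCY_MAP, **(latency_map or {})}
    rng = np.random.default_rng(seed)
    meta = _electrode_positions_for_regions(n_electrodes_per_region, rng)
    electrodes = ElectrodeTable(meta)
    n_el = len(meta)

    group_names = list(SCHEMES[mode]) if mode != "none" else [None]
    token_groups = (
        [group_names.index(token_group(t, mode)) for t in tokens]
        if mode != "none"
        else [0] * len(tokens)
    )

    time_axis = np.arange(round(t_range[0] * fs), round(t_range[1] * fs) + 1) / fs
    n_t = time_axis.size
    responses = np.empty((n_el, len(tokens), n_trials, n_t))
    gt_electrodes = {}
    for e in range(n_el):
        region = meta["region"][e]
        group = e % 3 if mode != "none" else -1
        gain = 1.0 + gain_jitter * rng.uniform(-1, 1)
        onset = latency_map[region] + (
            rng.normal(0, onset_jitter_sd) if onset_jitter_sd else 0.0
        )
        kernel = raised_cosine(time_axis, onset, response_duration)
        token_gains = {}
        for k, tok in enumerate(tokens):
            if mode == "none":
                w = 1.0
            else:
                w = gain_levels[(token_groups[k] - group) % 3]
            amp = peak_gain * gain * w
            token_gains[tok] = float(amp)
            responses[e, k] = amp * kernel + rng.normal(
                0, noise_sd, size=(n_trials, n_t)
            )
        gt_electrodes[meta["id"][e]] = {
            "region": region,
            "group": group_names[group] if mode != "none" else None,
            "gain": float(gain),
            "onset_s": float(onset),
            "lead_lag_s": float(latency_map[region] - min(latency_map.values())),
            "token_gains": token_gains,
        }

    if task is None:
        task = "speak" if mode == "place" else "listen"
    ds = EvokedDataset(
        responses=responses,
        time_axis=time_axis,
        tokens=list(tokens),
        electrode_ids=list(meta["id"]),
        task=task,
    )
    gt = GroundTruth(
        seed=seed,
        mode=mode,
        noise_sd=noise_sd,
        electrodes=gt_electrodes,
        extra={"latency_map": latency_map, "response_duration": response_duration},
    )
    return ds, electrodes, gt


def make_true_strf(
    n_delays: int = 20,
    n_freqs: int = 16,
    seed: int | None = 0,
    sparse_frac: float | None = None,
) -> np.ndarray:
    """Smooth localized ground-truth STRF (excitatory lobe + inhibitory tail).

    With ``sparse_frac`` only that fraction of weights (largest magnitude)
    is kept nonzero.
    """
    tau = np.arange(n_delays)[:, None]
    f = np.arange(n_freqs)[None, :]
    rng = np.random.default_rng(seed)
    t0 = n_delays * 0.3 + rng.uniform(-1, 1)
    f0 = n_freqs * 0.5 + rng.uniform(-1, 1)
    exc = np.exp(-((tau - t0) ** 2) / 8.0 - ((f - f0) ** 2) / 6.0)
    inh = -0.6 * np.exp(-((tau - t0 - 4) ** 2) / 10.0 - ((f - f0) ** 2) / 6.0)
    H = exc + inh
    if sparse_frac is not None:
        k = int(round((1 - sparse_frac) * H.size))
        thresh = np.sort(np.abs(H).ravel())[k - 1] if k > 0 else -np.inf
        H = np.where(np.abs(H) > thresh, H, 0.0)
    return H


def generate_strf_dataset(
    true_strf: np.ndarray,
    n_samples: int,
    fs_resp: float = 100.0,
    noise_sd: float = 0.5,
    seed: int | None = 0,
    center_freqs: np.ndarray | None = None,
    time_smooth: float = 2.0,
    freq_smooth: float = 1.0,
) -> tuple[Spectrogram, np.ndarray]:
    """Spectrogram-response pair generated by a known linear STRF.

    The stimulus is Gaussian noise lowpass-filtered along time and
    frequency (a modulation-limited, non-white spectrogram, so reverse
    correlation must normalize by the stimulus autocorrelation); the
    response is its causal convolution with ``true_strf`` plus Gaussian
    noise of SD ``noise_sd``.
    """
    H = np.asarray(true_strf, dtype=float)
    n_delays, n_freqs = H.shape
    if n_samples <= n_delays:
        raise ParameterError("n_samples must exceed the number of delays")
    rng = np.random.default_rng(seed)
    S = gaussian_filter(
        rng.standard_normal((n_samples, n_freqs)),
        sigma=(time_smooth, freq_smooth),
        mode="wrap",
    )
    S /= S.std()
    if center_freqs is None:
        center_freqs = np.geomspace(180.0, 7000.0, n_freqs)
    spec = Spectrogram(S=S, dt=1.0 / fs_resp, center_freqs=center_freqs)
    model = STRFModel(H=H, dt=1.0 / fs_resp, ridge=0.0, sparseness=0.0)
    response = predict_response(model, spec) + rng.normal(0, noise_sd, n_samples)
    return spec, response


def generate_phoneme_dataset(
    selectivity_profile: dict,
    n_trials: int = 30,
    seed: int | None = 0,
) -> tuple[dict, GroundTruth]:
    """Per-phoneme trial responses drawn Normal(mean, 1).

    ``selectivity_profile`` maps each phoneme label to its response mean.
    """
    if len(selectivity_profile) < 2:
        raise ParameterError("need at least 2 phonemes")
    if n_trials < 5:
        raise ParameterError("need at least 5 trials per phoneme")
    rng = np.random.default_rng(seed)
    trials = {
        ph: rng.normal(mean, 1.0, size=n_trials)
        for ph, mean in selectivity_profile.items()
    }
    gt = GroundTruth(seed=seed, selectivity=dict(selectivity_profile))
    return trials, gt


def generate_electrode_positions(
    n: int,
    centers,
    spread_mm: float,
    seed: int | None = 0,
    region: str = "vSMC_inf",
) -> ElectrodeTable:
    """Isotropic Gaussian scatter of ``n`` electrodes around ``centers``."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 1 or centers.shape[1] != 2:
        raise ParameterError("centers must be a list of 2-D points")
    if spread_mm <= 0:
        raise ParameterError("spread_mm must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cx, cy = centers[i % centers.shape[0]]
        x = cx + rng.normal(0, spread_mm)
        y = cy + rng.normal(0, spread_mm)
        rows.append(
            {"id": f"s{i:03d}", "x_mm": x, "y_mm": y,
             "dist_cs_mm": x, "dist_sf_mm": y, "region": region}
        )
    df = pd.DataFrame(rows, columns=["id", "x_mm", "y_mm", "dist_cs_mm",
                                     "dist_sf_mm", "region"])
    return ElectrodeTable(df)
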