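"""Spectrotemporal receptive field (STRF) estimation.

A cochlear-model front end turns audio into a time x frequency
"auditory spectrogram"; the STRF is the linear filter H(tau, f) that best
predicts an electrode's high-gamma response from that spectrogram,

    r_hat(t) = sum_f sum_tau H(tau, f) S(t - tau, f),

fit by regularized reverse correlation (ridge-penalized least squares on
the lagged stimulus design, i.e. normalization by the stimulus
autocorrelation) with an optional sparseness stage that prunes the
smallest-magnitude weights and refits the survivors. Hyperparameters are
chosen by grid search over contiguous-block cross-validation folds, and
model quality is the mean held-out Pearson correlation; significance comes
from a circular-shift permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.linalg import cho_factor, cho_solve

from .errors import DegenerateInputError, ParameterError, ValidationError

__all__ = [
    "Spectrogram",
    "STRFModel",
    "cochlear_spectrogram",
    "predict_response",
    "fit_strf",
    "fit_strf_cv",
    "strf_significance",
    "strf_summary_map",
]


@dataclass
class Spectrogram:
    """Time x frequency stimulus representation at a uniform frame rate."""

    S: np.ndarray               # (n_frames, n_channels)
    dt: float                   # frame step, seconds
    center_freqs: np.ndarray    # (n_channels,) Hz, strictly increasing

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.S.ndim != 2:
            raise ValidationError("spectrogram must be 2-D (time x frequency)")
        if self.S.shape[1] != self.center_freqs.size:
            raise ValidationError("channel count mismatch")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValidationError("center frequencies must be strictly increasing")
        if not self.dt > 0:
            raise ValidationError("frame step must be positive")

    @property
    def n_frames(self) -> int:
        return self.S.shape[0]

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]


@dataclass
class STRFModel:
    """Fitted STRF: weights H (delays x frequencies) plus fit metadata."""

    H: np.ndarray
    dt: float
    ridge: float
    sparseness: float
    cv_correlation: float = np.nan
    p_value: float = np.nan
    fold_correlations: np.ndarray | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2:
            raise ValidationError("H must be 2-D (delays x frequencies)")

    @property
    def n_delays(self) -> int:
        return self.H.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.H.shape[1]


def cochlear_spectrogram(
    waveform,
    fs: float,
    n_channels: int = 60,
    f_range: tuple[float, float] = (180.0, 7000.0),
    frame_rate: float = 100.0,
    compression: float = 1.0 / 3.0,
) -> Spectrogram:
    """Cochlear-model auditory spectrogram.

    Stages: constant-Q gammatone filterbank on log-spaced center
    frequencies -> power-law compression -> first difference across the
    spectral axis (lateral inhibition), half-wave rectified -> lowpass
    envelope -> frames at ``frame_rate``.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ParameterError("waveform must be 1-D")
    f_lo, f_hi = f_range
    if f_hi >= fs / 2:
        raise ParameterError(f"f_max {f_hi} must be below Nyquist {fs / 2}")
    if not 0 < f_lo < f_hi:
        raise ParameterError("invalid frequency range")
    centers = np.geomspace(f_lo, f_hi, n_channels)
    out = np.empty((x.size, n_channels))
    for j, fc in enumerate(centers):
        b, a = sp_signal.gammatone(fc, "fir", fs=fs)
        y = sp_signal.fftconvolve(x, b, mode="same")
        out[:, j] = np.sign(y) * np.abs(y) ** compression
    # lateral inhibition: derivative along the spectral axis, rectified
    lin = np.diff(out, axis=1, prepend=out[:, :1])
    lin = np.maximum(lin, 0.0)
    # envelope: lowpass below the frame Nyquist, then downsample
    sos = sp_signal.butter(4, min(frame_rate / 2 * 0.8, fs / 2 * 0.9), fs=fs, output="sos")
    env = sp_signal.sosfiltfilt(sos, lin, axis=0)
    step = fs / frame_rate
    idx = np.round(np.arange(0, x.size, step)).astype(int)
    idx = idx[idx < x.size]
    frames = np.maximum(env[idx], 0.0)
    return Spectrogram(S=frames, dt=1.0 / frame_rate, center_freqs=centers)


def predict_response(model: STRFModel, spec: Spectrogram) -> np.ndarray:
    """Causal convolution of the spectrogram with the STRF weights."""
    if spec.n_channels != model.n_freqs:
        raise ValidationError(
            f"spectrogram has {spec.n_channels} channels, model expects {model.n_freqs}"
        )
    if abs(spec.dt - model.dt) > 1e-9:
        raise ValidationError("frame step mismatch between model and spectrogram")
    T = spec.n_frames
    r = np.zeros(T)
    for f in range(model.n_freqs):
        r += np.convolve(spec.S[:, f], model.H[:, f])[:T]
    return r


def _lagged_design(S: np.ndarray, n_delays: int) -> np.ndarray:
    """(T, n_delays * M) design with column (tau, f) = S[t - tau, f]."""
    T, M = S.shape
    X = np.zeros((T, n_delays * M))
    for tau in range(n_delays):
        X[tau:, tau * M:(tau + 1) * M] = S[: T - tau]
    return X


def _solve_ridge(XtX, Xty, lam: float) -> np.ndarray:
    A = XtX + lam * np.eye(XtX.shape[0])
    try:
        return cho_solve(cho_factor(A), Xty)
    except np.linalg.LinAlgError as e:
        raise DegenerateInputError("singular stimulus autocorrelation") from e


def fit_strf(
    spec: Spectrogram,
    response,
    n_delays: int,
    ridge: float = 0.0,
    sparseness: float = 0.0,
) -> STRFModel:
    """Fit H by L2-penalized reverse correlation at fixed hyperparameters.

    ``sparseness`` in [0, 1) zeroes that fraction of weights (smallest in
    magnitude) and refits the surviving support once.
    """
    r = np.asarray(response, dtype=float)
    if r.size != spec.n_frames:
        raise ValidationError("response length must match spectrogram frames")
    if ridge < 0:
        raise ParameterError("ridge must be >= 0")
    if not 0 <= sparseness < 1:
        raise ParameterError("sparseness must lie in [0, 1)")
    if not np.any(spec.S):
        raise DegenerateInputError("all-zero stimulus")
    X = _lagged_design(spec.S, n_delays)
    h = _fit_flat(X, r, ridge, sparseness)
    H = h.reshape(n_delays, spec.n_channels)
    return STRFModel(H=H, dt=spec.dt, ridge=ridge, sparseness=sparseness)


def _fit_flat(X: np.ndarray, r: np.ndarray, ridge: float, sparseness: float) -> np.ndarray:
    # center design and response: the lagged design carries no intercept,
    # and reverse correlation operates on deviations from the mean
    X = X - X.mean(axis=0)
    r = r - r.mean()
    if ridge == 0:
        h, *_ = np.linalg.lstsq(X, r, rcond=None)
    else:
        h = _solve_ridge(X.T @ X, X.T @ r, ridge)
    if sparseness > 0:
        k = int(np.floor(sparseness * h.size))
        if k > 0:
            keep = np.argsort(np.abs(h))[k:]
            h2 = np.zeros_like(h)
            Xk = X[:, keep]
            if ridge == 0:
                hk, *_ = np.linalg.lstsq(Xk, r, rcond=None)
            else:
                hk = _solve_ridge(Xk.T @ Xk, Xk.T @ r, ridge)
            h2[keep] = hk
            h = h2
    return h


def _fold_slices(T: int, n_folds: int) -> list[slice]:
    edges = np.linspace(0, T, n_folds + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mutual_information(pred: np.ndarray, resp: np.ndarray, n_bins: int = 16,
                        rate: float = 100.0) -> float:
    """Binned MI (bits/s) between prediction and response.

    Equal-occupancy bins on each variable; first-order (Miller-Madow) bias
    correction.
    """
    n = pred.size
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    pb = np.searchsorted(np.quantile(pred, qs), pred)
    rb = np.searchsorted(np.quantile(resp, qs), resp)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (pb, rb), 1.0)
    joint /= n
    pi = joint.sum(axis=1, keepdims=True)
    pj = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pi @ pj)[nz])))
    mi -= (n_bins - 1) ** 2 / (2 * n * np.log(2))
    return max(mi, 0.0) * rate


def fit_strf_cv(
    spec: Spectrogram,
    response,
    n_delays: int = 30,
    ridge_grid=None,
    sparseness_grid=(0.0, 0.25, 0.5, 0.75),
    n_folds: int = 10,
    criterion: str = "correlation",
    seed: int | None = 0,
) -> STRFModel:
    """Grid-search hyperparameters by cross-validation and fit the final STRF.

    Folds are contiguous time blocks (temporal autocorrelation would leak
    across shuffled folds). For each (ridge, sparseness) pair the criterion
    is averaged over held-out folds; at the winning pair the final H and
    the reported correlation are the means over the ``n_folds`` per-fold
    fits, mirroring a 10-fold estimation-and-average procedure.
    """
    r = np.asarray(response, dtype=float)
    if r.size != spec.n_frames:
        raise ValidationError("response length must match spectrogram frames")
    if r.size < 10 * n_delays:
        raise ParameterError("need at least 10 * n_delays frames")
    if ridge_grid is None:
        base = float(np.trace(spec.S.T @ spec.S) / spec.n_channels)
        ridge_grid = base * np.logspace(-5, 1, 6)
    ridge_grid = list(ridge_grid)
    sparseness_grid = list(sparseness_grid)
    if not ridge_grid or not sparseness_grid:
        raise ParameterError("hyperparameter grids must be non-empty")
    if criterion not in ("correlation", "mi"):
        raise ParameterError(f"unknown criterion {criterion!r}")

    X = _lagged_design(spec.S, n_delays)
    folds = _fold_slices(r.size, n_folds)
    masks = []
    for sl in folds:
        m = np.ones(r.size, dtype=bool)
        m[sl] = False
        masks.append(m)

    def held_out_scores(lam, s):
        scores = np.empty(n_folds)
        for i, (sl, m) in enumerate(zip(folds, masks)):
            h = _fit_flat(X[m], r[m], lam, s)
            pred = X[sl] @ h
            if criterion == "correlation":
                scores[i] = _pearson(pred, r[sl])
            else:
                scores[i] = _mutual_information(pred, r[sl], rate=1.0 / spec.dt)
        return scores

    best = (None, -np.inf)
    for lam in ridge_grid:
        for s in sparseness_grid:
            score = float(held_out_scores(lam, s).mean())
            if score > best[1]:
                best = ((lam, s), score)
    lam, s = best[0]

    Hs, rs = [], []
    for sl, m in zip(folds, masks):
        h = _fit_flat(X[m], r[m], lam, s)
        Hs.append(h)
        rs.append(_pearson(X[sl] @ h, r[sl]))
    H = np.mean(Hs, axis=0).reshape(n_delays, spec.n_channels)
    return STRFModel(
        H=H,
        dt=spec.dt,
        ridge=lam,
        sparseness=s,
        cv_correlation=float(np.mean(rs)),
        fold_correlations=np.array(rs),
    )


def strf_significance(
    model: STRFModel,
    spec: Spectrogram,
    response,
    n_perm: int = 200,
    seed: int | None = 0,
) -> float:
    """Permutation p-value for the model's prediction correlation.

    Null correlations come from circularly shifting the response relative
    to the stimulus by random offsets of at least ``n_delays`` frames; the
    p-value is the fraction of null correlations >= the observed one.
    """
    r = np.asarray(response, dtype=float)
    T = r.size
    if T <= 2 * model.n_delays + 2:
        raise ParameterError("series too short for circular-shift permutation")
    pred = predict_response(model, spec)
    observed = (
        model.cv_correlation if np.isfinite(model.cv_correlation) else _pearson(pred, r)
    )
    rng = np.random.default_rng(seed)
    shifts = rng.integers(model.n_delays, T - model.n_delays, size=n_perm)
    null = np.array([_pearson(pred, np.roll(r, int(k))) for k in shifts])
    return float(np.mean(null >= observed))


def strf_summary_map(models: dict, electrodes, r_min: float = 0.10, p_max: float = 0.01):
    """Join model performance with electrode coordinates.

    Returns a DataFrame (electrode, dist_cs_mm, dist_sf_mm, r, p,
    significant) where ``significant`` flags r >= r_min and p < p_max.
    Electrodes without coordinates are dropped with a warning.
    """
    import pandas as pd

    from .core import get_logger

    log = get_logger("amecog.strf")
    meta = electrodes.df.set_index("id")
    rows = []
    for eid, model in models.items():
        if eid not in meta.index:
            log.warning("electrode %s missing from electrode table; dropped", eid)
            continue
        rows.append(
            {
                "electrode": eid,
                "dist_cs_mm": float(meta.loc[eid, "dist_cs_mm"]),
                "dist_sf_mm": float(meta.loc[eid, "dist_sf_mm"]),
                "r": float(model.cv_correlation),
                "p": float(model.p_value),
                "significant": bool(
                    model.cv_correlation >= r_min and model.p_value < p_max
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["electrode", "dist_cs_mm", "dist_sf_mm", "r", "p", "significant"]
    )
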