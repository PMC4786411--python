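import numpy as np
import pandas as pd
import pytest

from amecog import dynamics as dyn, synth
from amecog.errors import ParameterError, WindowingError

FS = 100.0
T = np.arange(-50, 101) / FS  # [-0.5, 1.0]


def _trials(onset, n_trials=50, amp=5.0, noise=1.0, seed=0, duration=0.15):
    rng = np.random.default_rng(seed)
    kernel = amp * synth.raised_cosine(T, onset, duration)
    return kernel + rng.normal(0, noise, size=(n_trials, T.size))


# ---------------------------------------------------------------------------
# latencies
# ---------------------------------------------------------------------------

def test_onset_latency_recovers_planted_onset():
    got = dyn.onset_latency(_trials(0.1, seed=1), T)
    assert 80.0 <= got <= 120.0


def test_onset_latency_null_rarely_fires():
    """Uncorrected per-sample testing at alpha=0.001: with ~150 post-onset
    samples the chance of any false onset per run is ~0.14, so most null
    runs must return None."""
    none_count = 0
    for seed in range(30):
        rng = np.random.default_rng(1000 + seed)
        trials = rng.normal(size=(20, T.size))
        none_count += dyn.onset_latency(trials, T) is None
    assert none_count >= 21


def test_onset_latency_step_at_zero():
    trials = np.where(T >= 0, 10.0, 0.0) + np.random.default_rng(2).normal(
        0, 0.1, size=(20, T.size)
    )
    assert dyn.onset_latency(trials, T) == pytest.approx(0.0)
    with pytest.raises(WindowingError):
        dyn.onset_latency(trials, T, baseline_window=(-2.0, -1.5))


def test_peak_latency_cases():
    bump = synth.raised_cosine(T, 0.05, 0.4)  # full bump: peaks at 250 ms
    ms, tie = dyn.peak_latency(bump, T)
    assert ms == pytest.approx(250.0, abs=10.0 + 1e-9)
    assert not tie
    ramp = np.linspace(0, 1, T.size)
    assert dyn.peak_latency(ramp, T)[0] == pytest.approx(T[-1] * 1000)
    ms_c, tie_c = dyn.peak_latency(np.ones(T.size), T)
    assert ms_c == pytest.approx(T[0] * 1000)
    assert tie_c


def test_compare_latencies_detects_separation():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "region": ["STG"] * 30 + ["vSMC_inf"] * 30,
            "latency_ms": np.r_[rng.normal(100, 10, 30), rng.normal(160, 10, 30)],
        }
    )
    out = dyn.compare_latencies(df)
    row = out.iloc[0]
    assert row["p"] < 0.001
    assert row["median_a_ms"] < row["median_b_ms"]
    assert row["z"] < 0


def test_compare_latencies_null_and_single_region():
    rng = np.random.default_rng(4)
    fp = 0
    for s in range(20):
        df = pd.DataFrame(
            {
                "region": ["STG"] * 15 + ["vSMC_inf"] * 15,
                "latency_ms": rng.normal(120, 10, 30),
            }
        )
        fp += dyn.compare_latencies(df).iloc[0]["p"] < 0.05
    assert fp <= 3
    single = pd.DataFrame({"region": ["STG"] * 5, "latency_ms": np.arange(5.0)})
    assert len(dyn.compare_latencies(single)) == 0


# ---------------------------------------------------------------------------
# cross-correlogram
# ---------------------------------------------------------------------------

def test_autocorrelation_peaks_at_zero(rng):
    x = rng.normal(size=(10, T.size))
    xc = dyn.cross_correlogram(x, x, fs=FS)
    assert xc.peak_lag == 0.0


def test_pulse_offset_gives_negative_lag_when_x_leads():
    x = synth.raised_cosine(T, 0.15, 0.1)[None, :]
    y = synth.raised_cosine(T, 0.35, 0.1)[None, :]
    xc = dyn.cross_correlogram(x, y, fs=FS, demean=False)
    assert xc.peak_lag == pytest.approx(-0.2, abs=1e-9)
    assert dyn.asymmetry_index(xc) == -1.0


def test_white_noise_correlogram_is_small_and_flat(rng):
    x = rng.normal(size=(100, T.size))
    y = rng.normal(size=(100, T.size))
    xc = dyn.cross_correlogram(x, y, fs=FS)
    assert np.abs(xc.values).max() < 0.1
    # unbiased normalization: variance should not blow up at extreme lags
    inner = np.abs(xc.values[np.abs(xc.lags) < 0.25]).mean()
    outer = np.abs(xc.values[np.abs(xc.lags) > 0.5]).mean()
    assert outer < 5 * inner


def test_swapping_electrodes_mirrors_and_negates(rng):
    x = _trials(0.1, n_trials=8, seed=5)
    y = _trials(0.3, n_trials=8, seed=6)
    a = dyn.cross_correlogram(x, y, fs=FS)
    b = dyn.cross_correlogram(y, x, fs=FS)
    assert np.allclose(a.values, b.values[::-1], atol=1e-12)
    ia, ib = dyn.asymmetry_index(a), dyn.asymmetry_index(b)
    assert ia == pytest.approx(-ib, abs=1e-9)


def test_max_lag_guard():
    x = np.zeros((1, 50))
    with pytest.raises(ParameterError):
        dyn.cross_correlogram(x, x, fs=FS, max_lag=0.75)


# ---------------------------------------------------------------------------
# asymmetry index and classification
# ---------------------------------------------------------------------------

def test_asymmetry_index_hand_values():
    lags = np.array([-0.1, 0.0, 0.1])
    xc = dyn.CrossCorrelogram(lags, np.array([0.3, 0.5, 0.1]), M=100)
    assert dyn.asymmetry_index(xc) == pytest.approx((0.1 - 0.3) / 0.4)
    sym = dyn.CrossCorrelogram(lags, np.array([0.2, 0.9, 0.2]), M=100)
    assert dyn.asymmetry_index(sym) == 0.0
    negative_only = dyn.CrossCorrelogram(lags, np.array([-0.2, -0.1, -0.3]), M=100)
    assert dyn.asymmetry_index(negative_only) is None


def test_classify_lead_lag():
    out = dyn.classify_lead_lag([-1.0, 0.0, 1.0], band=0.25)
    assert out["x_leads"] == pytest.approx(100 / 3)
    assert out["coactive"] == pytest.approx(100 / 3)
    assert out["y_leads"] == pytest.approx(100 / 3)
    assert dyn.classify_lead_lag([0.0, 0.1, -0.2])["coactive"] == 100.0
    with pytest.raises(ParameterError):
        dyn.classify_lead_lag([])


def test_planted_lead_lag_proportions_recovered():
    rng = np.random.default_rng(7)
    indices = []
    for s in range(30):
        lead = s < 20  # 2/3 of pairs: x leads by 100 ms
        x = _trials(0.1 if lead else 0.2, n_trials=10, noise=0.8, seed=s)
        y = _trials(0.2 if lead else 0.1, n_trials=10, noise=0.8, seed=1000 + s)
        xc = dyn.cross_correlogram(x, y, fs=FS)
        indices.append(dyn.asymmetry_index(xc))
    out = dyn.classify_lead_lag(indices, band=0.25)
    assert out["x_leads"] > 50.0
    assert out["y_leads"] < 50.0
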