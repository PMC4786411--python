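import numpy as np
import pytest

from amecog import strf as st, synth
from amecog.errors import DegenerateInputError, ParameterError, ValidationError
from oracles import ols_strf


@pytest.fixture(scope="module")
def snr3_dataset():
    H = synth.make_true_strf(20, 16, seed=0)
    clean_spec, clean = synth.generate_strf_dataset(H, 10000, noise_sd=0.0, seed=1)
    noise_sd = float(clean.std()) / 3.0
    spec, resp = synth.generate_strf_dataset(H, 10000, noise_sd=noise_sd, seed=1)
    return H, spec, resp


# ---------------------------------------------------------------------------
# cochlear front end
# ---------------------------------------------------------------------------

def test_cochlear_tone_peaks_near_its_frequency():
    fs = 16000
    t = np.arange(int(0.5 * fs)) / fs
    tone = np.sin(2 * np.pi * 1000.0 * t)
    spec = st.cochlear_spectrogram(tone, fs, n_channels=48)
    energy = spec.S.sum(axis=0)
    fpeak = spec.center_freqs[int(np.argmax(energy))]
    assert 850.0 <= fpeak <= 1150.0


def test_cochlear_silence_and_guards():
    spec = st.cochlear_spectrogram(np.zeros(8000), 16000)
    assert np.allclose(spec.S, 0.0)
    with pytest.raises(ParameterError):
        st.cochlear_spectrogram(np.zeros(8000), 8000, f_range=(180, 7000))


def test_cochlear_noise_has_flatter_profile_than_tone():
    fs = 16000
    rng = np.random.default_rng(0)
    t = np.arange(int(0.5 * fs)) / fs
    tone = st.cochlear_spectrogram(np.sin(2 * np.pi * 1000 * t), fs)
    noise = st.cochlear_spectrogram(rng.normal(size=t.size), fs)
    from scipy.stats import kurtosis

    assert kurtosis(tone.S.sum(axis=0)) > kurtosis(noise.S.sum(axis=0))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _toy_spec(T=200, M=6, seed=0):
    rng = np.random.default_rng(seed)
    return st.Spectrogram(rng.normal(size=(T, M)), 0.01, np.geomspace(200, 4000, M))


def test_predict_response_identity_shift_and_zero():
    spec = _toy_spec()
    H = np.zeros((5, 6))
    model = st.STRFModel(H, 0.01, 0.0, 0.0)
    assert np.allclose(st.predict_response(model, spec), 0.0)
    H2 = np.zeros((5, 6))
    H2[0, 2] = 1.0
    pred = st.predict_response(st.STRFModel(H2, 0.01, 0.0, 0.0), spec)
    assert np.allclose(pred, spec.S[:, 2])
    H3 = np.zeros((5, 6))
    H3[3, 2] = 1.0
    pred3 = st.predict_response(st.STRFModel(H3, 0.01, 0.0, 0.0), spec)
    assert np.allclose(pred3[3:], spec.S[:-3, 2])
    assert np.allclose(pred3[:3], 0.0)
    with pytest.raises(ValidationError):
        st.predict_response(st.STRFModel(np.zeros((5, 4)), 0.01, 0.0, 0.0), spec)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_strf_matches_ols_on_noiseless_data():
    H = synth.make_true_strf(10, 8, seed=2)
    spec, resp = synth.generate_strf_dataset(H, 2000, noise_sd=0.0, seed=2)
    model = st.fit_strf(spec, resp, 10, ridge=0.0)
    assert np.abs(model.H - H).max() < 1e-6
    assert np.abs(model.H - ols_strf(spec.S, resp, 10)).max() < 1e-9


def test_infinite_shrinkage_zeroes_weights():
    H = synth.make_true_strf(10, 8, seed=3)
    spec, resp = synth.generate_strf_dataset(H, 2000, noise_sd=0.1, seed=3)
    model = st.fit_strf(spec, resp, 10, ridge=1e12)
    assert np.abs(model.H).max() < 1e-4
    with pytest.raises(DegenerateInputError):
        st.fit_strf(
            st.Spectrogram(np.zeros((500, 8)), 0.01, np.geomspace(200, 4000, 8)),
            np.zeros(500), 10,
        )


def test_sparseness_recovers_sparse_support():
    H = synth.make_true_strf(10, 8, seed=4, sparse_frac=0.1)
    spec, resp = synth.generate_strf_dataset(H, 3000, noise_sd=0.0, seed=4)
    model = st.fit_strf(spec, resp, 10, ridge=0.0, sparseness=0.9)
    assert np.array_equal(model.H != 0, H != 0)


def test_cv_fit_recovers_truth_at_snr3(snr3_dataset):
    H, spec, resp = snr3_dataset
    model = st.fit_strf_cv(spec, resp, n_delays=20, seed=0)
    assert model.cv_correlation > 0.5
    assert np.corrcoef(model.H.ravel(), H.ravel())[0, 1] > 0.8
    # determinism
    again = st.fit_strf_cv(spec, resp, n_delays=20, seed=0)
    assert np.array_equal(model.H, again.H)
    assert model.cv_correlation == again.cv_correlation


def test_cv_r_invariant_to_response_rescaling(snr3_dataset):
    _, spec, resp = snr3_dataset
    a = st.fit_strf_cv(spec, resp, n_delays=20, seed=0)
    b = st.fit_strf_cv(spec, 3.0 * resp + 5.0, n_delays=20, seed=0)
    assert a.cv_correlation == pytest.approx(b.cv_correlation, abs=1e-9)


def test_cv_null_response_near_zero():
    rng = np.random.default_rng(5)
    spec = _toy_spec(T=10000, M=8, seed=5)
    model = st.fit_strf_cv(spec, rng.normal(size=10000), n_delays=10, seed=0)
    assert abs(model.cv_correlation) < 0.1


def test_recovery_degrades_monotonically_with_noise():
    H = synth.make_true_strf(10, 8, seed=6)
    cors = []
    for noise in (0.2, 1.0, 4.0):
        spec, resp = synth.generate_strf_dataset(H, 4000, noise_sd=noise, seed=6)
        m = st.fit_strf_cv(spec, resp, n_delays=10,
                           sparseness_grid=(0.0,), seed=0)
        cors.append(np.corrcoef(m.H.ravel(), H.ravel())[0, 1])
    assert cors[0] > cors[1] > cors[2]


# ---------------------------------------------------------------------------
# significance and summary
# ---------------------------------------------------------------------------

def test_significance_planted_vs_noise(snr3_dataset):
    H, spec, resp = snr3_dataset
    model = st.fit_strf_cv(spec, resp, n_delays=20, seed=0)
    p = st.strf_significance(model, spec, resp, n_perm=100, seed=0)
    assert p < 0.01
    # p-value resolution follows n_perm
    p10 = st.strf_significance(model, spec, resp, n_perm=10, seed=0)
    assert round(p10 * 10, 9) == int(round(p10 * 10))


def test_summary_map_flags_and_drops():
    el = synth.generate_electrode_positions(3, [[0, 0]], 1.0, seed=0)
    mk = lambda r, p: st.STRFModel(np.zeros((2, 2)), 0.01, 0.0, 0.0,
                                   cv_correlation=r, p_value=p)
    models = {"s000": mk(0.4, 0.001), "s001": mk(0.05, 0.001),
              "missing": mk(0.9, 0.0)}
    table = st.strf_summary_map(models, el)
    assert len(table) == 2
    assert table.set_index("electrode").loc["s000", "significant"]
    assert not table.set_index("electrode").loc["s001", "significant"]
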