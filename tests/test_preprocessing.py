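"""Preprocessing chain: oracles, planted-truth recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vibromap.core import HyperspectralImage, SpectralAxis, Spectrum, ValidationError
from vibromap.preprocessing import (
    AslsBaseline,
    Despike,
    PCANoiseFilter,
    PreprocessConfig,
    SavitzkyGolay,
    StageError,
    TotalAreaNormalizer,
    _whittaker_solve,
    asls_baseline,
    normalize_total_area,
    preprocess,
    savgol,
    trim,
)
from vibromap.simulate import islet_scene, generate


def brute_force_savgol(y, frame, order):
    """Independent oracle: per-window least-squares polynomial fit,
    truncated windows at the edges."""
    n = len(y)
    half = frame // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        offsets = np.arange(lo, hi) - i
        k = min(order, hi - lo - 1)
        A = np.vander(offsets, k + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(A, y[lo:hi], rcond=None)
        out[i] = beta[0]
    return out


class TestSavitzkyGolay:
    def test_interior_equals_moving_average_and_impulse(self):
        y = np.array([0.0, 0, 5, 0, 0, 0, 0, 0])
        out = SavitzkyGolay(frame=5, order=1).transform(y[None, :])[0]
        assert out[2] == pytest.approx(1.0)  # 5-point mean of the impulse
        x = np.arange(20.0) ** 1.7
        sm = SavitzkyGolay(frame=5, order=1).transform(x[None, :])[0]
        conv = np.convolve(x, np.ones(5) / 5, mode="valid")
        assert np.allclose(sm[2:-2], conv)

    def test_linear_ramp_preserved(self):
        ramp = np.linspace(1, 5, 9)
        out = SavitzkyGolay(frame=5, order=1).transform(ramp[None, :])[0]
        assert np.allclose(out, ramp, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for frame, order in [(5, 1), (5, 2), (7, 3), (9, 0)]:
            y = rng.normal(size=80)
            out = SavitzkyGolay(frame=frame, order=order).transform(y[None, :])[0]
            assert np.max(np.abs(out - brute_force_savgol(y, frame, order))) <= 1e-10

    def test_frame_larger_than_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            SavitzkyGolay(frame=11, order=1).transform(np.zeros((1, 9)))


class TestAslsBaseline:
    def test_constant_spectrum_fit_exactly(self):
        y = np.full(60, 4.2)
        z = AslsBaseline(lam=1e4, p=0.01).baseline(y[None, :])[0]
        assert np.max(np.abs(z - 4.2)) < 1e-8
        corrected = AslsBaseline(lam=1e4, p=0.01).transform(y[None, :])[0]
        assert np.max(np.abs(corrected)) < 1e-8

    @pytest.mark.parametrize("lam", [5_000.0, 10_000.0])
    def test_planted_line_recovered_under_peak(self, lam, rng):
        v = np.arange(950.0, 2001.0, 4.0)
        for _ in range(5):
            a, b = rng.uniform(0.1, 1.0), rng.uniform(-4e-4, 8e-4)
            line = a + b * (v - v[0])
            amp = rng.uniform(0.5, 2.0)
            peak = amp * np.exp(-4 * np.log(2) * ((v - rng.uniform(1200, 1700)) / 40.0) ** 2)
            z = AslsBaseline(lam=lam, p=0.01).baseline((line + peak)[None, :])[0]
            rmse = np.sqrt(np.mean((z - line) ** 2))
            assert rmse < 0.01 * amp

    def test_symmetric_case_equals_one_shot_whittaker(self, rng):
        y = rng.normal(size=100) + np.linspace(0, 3, 100)
        z = AslsBaseline(lam=1e4, p=0.5).baseline(y[None, :])[0]
        oracle = _whittaker_solve(y, np.full(100, 0.5), 1e4)
        assert np.max(np.abs(z - oracle)) < 1e-8

    def test_baseline_hugs_lower_envelope(self, rng):
        # noisy peak-bearing spectrum: with p = 0.01 the baseline tracks the
        # lower envelope, staying below the signal at >= 90% of channels
        v = np.arange(630.0, 1891.0, 2.0)
        y = 0.3 + 1e-4 * v + np.exp(-4 * np.log(2) * ((v - 1004) / 15) ** 2)
        y += np.exp(-4 * np.log(2) * ((v - 1445) / 25) ** 2)
        y += rng.normal(0, 0.02, len(v))
        z = AslsBaseline(lam=1e4, p=0.01).baseline(y[None, :])[0]
        assert np.mean(z <= y) >= 0.90

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError):
            AslsBaseline().baseline(np.array([[1.0, np.nan] + [0.0] * 10]))


class TestNormalize:
    def test_unit_sum_and_idempotence(self):
        y = np.array([2.0, 2, 2, 2])
        t = TotalAreaNormalizer()
        out = t.transform(y[None, :])[0]
        assert np.allclose(out, 0.25, atol=1e-12)
        again = t.transform(out[None, :])[0]
        assert np.max(np.abs(again - out)) < 1e-12

    def test_zero_spectrum_flagged_not_normalized(self):
        t = TotalAreaNormalizer()
        out = t.transform(np.zeros((1, 6)))
        assert t.unnormalizable_[0]
        assert np.array_equal(out, np.zeros((1, 6)))


class TestDespike:
    def test_spike_free_image_untouched(self, rng):
        X = rng.normal(1.0, 0.05, size=(30, 100))
        out = Despike(window=5, z=10.0).transform(X)
        assert np.array_equal(out, X)

    def test_planted_spikes_removed(self, rng):
        X = rng.normal(1.0, 0.05, size=(200, 150))
        planted = []
        for i in range(200):
            if rng.random() < 0.5:
                j = int(rng.integers(2, 148))
                X[i, j] += 50.0
                planted.append((i, j))
        d = Despike(window=5, z=10.0)
        out = d.transform(X)
        removed = sum(abs(out[i, j] - X[i, j]) > 10 for i, j in planted)
        assert removed / len(planted) >= 0.99

    def test_broad_band_not_flagged(self, rng):
        v = np.arange(200.0)
        clean = 2.0 * np.exp(-4 * np.log(2) * ((v - 100) / 50.0) ** 2)
        X = clean[None, :] + rng.normal(0, 0.02, size=(20, 200))
        out = Despike(window=5, z=10.0).transform(X)
        assert np.array_equal(out, X)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValidationError):
            Despike(window=11).transform(np.zeros((2, 9)))


class TestPCANoiseFilter:
    def test_full_rank_is_identity(self, rng):
        X = rng.normal(size=(15, 10))
        f = PCANoiseFilter(rank=10).fit(X)
        assert np.max(np.abs(f.transform(X) - X)) < 1e-10

    def test_exact_low_rank_data_reconstructed(self, rng):
        C = rng.normal(size=(40, 2))
        S = rng.normal(size=(2, 25))
        X = C @ S
        f = PCANoiseFilter(rank=2).fit(X)
        assert np.max(np.abs(f.transform(X) - X)) < 1e-10

    @pytest.mark.parametrize("sigma", [0.05, 0.2, 0.5])
    def test_denoising_improves_over_input(self, sigma, rng):
        C = np.abs(rng.normal(size=(60, 2)))
        S = np.abs(rng.normal(size=(2, 40)))
        truth = C @ S
        noisy = truth + rng.normal(0, sigma, truth.shape)
        f = PCANoiseFilter(rank=2).fit(noisy)
        filtered = f.transform(noisy)
        assert np.linalg.norm(filtered - truth) < np.linalg.norm(noisy - truth)

    def test_rank_out_of_range(self, rng):
        with pytest.raises(ValidationError):
            PCANoiseFilter(rank=20).fit(rng.normal(size=(5, 10)))


class TestTrim:
    def test_fingerprint_trim(self, rng):
        axis = SpectralAxis(values=np.arange(900.0, 4000.0, 4.0))
        img = HyperspectralImage(axis=axis, cube=rng.normal(size=(2, 2, len(axis))))
        out = trim(img, 950.0, 2000.0)
        assert out.axis.values.min() >= 950.0 and out.axis.values.max() <= 2000.0

    def test_full_range_identity_and_idempotence(self, small_image):
        lo, hi = small_image.axis.values[0], small_image.axis.values[-1]
        out = trim(small_image, lo, hi)
        assert np.array_equal(out.cube, small_image.cube)
        again = trim(out, lo, hi)
        assert np.array_equal(again.cube, out.cube)

    def test_raman_top_channels_removed(self, rng):
        axis = SpectralAxis(values=np.arange(630.0, 1901.0, 2.0))
        img = HyperspectralImage(axis=axis, cube=rng.normal(size=(1, 2, len(axis))))
        out = trim(img, 630.0, 1890.0)
        assert out.axis.values.max() <= 1890.0
        assert out.n_bands < img.n_bands

    def test_disjoint_range_rejected(self, small_image):
        with pytest.raises(ValidationError):
            trim(small_image, 4000.0, 5000.0)


class TestFunctionalWrappers:
    def test_spectrum_level_chain(self, small_axis, rng):
        y = np.abs(rng.normal(1, 0.1, len(small_axis)))
        sp = Spectrum(axis=small_axis, intensities=y)
        base, corr = asls_baseline(sp, lam=5000.0)
        assert np.allclose(base.intensities + corr.intensities, y, atol=1e-12)
        sm = savgol(sp)
        assert sm.intensities.shape == y.shape
        norm = normalize_total_area(sp)
        assert norm.intensities.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    arrays(
        np.float64,
        st.tuples(st.integers(1, 4), st.integers(8, 30)),
        elements=st.floats(0.0, 1e6, allow_nan=False),
    )
)
def test_normalization_idempotent_on_any_nonnegative_input(X):
    """Property: normalizing twice equals normalizing once; flagged rows
    pass through unchanged."""
    t1 = TotalAreaNormalizer()
    once = t1.transform(X)
    twice = TotalAreaNormalizer().transform(once)
    assert np.max(np.abs(twice - once)) <= 1e-12
    assert np.array_equal(once[t1.unnormalizable_], X[t1.unnormalizable_])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.1, 5.0),
)
def test_savgol_is_linear_operator(seed, scale):
    """Property: smoothing commutes with scaling and addition."""
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(2, 40))
    sg = SavitzkyGolay(frame=5, order=1)
    lhs = sg.transform((scale * a + b)[None, :])[0]
    rhs = scale * sg.transform(a[None, :])[0] + sg.transform(b[None, :])[0]
    assert np.max(np.abs(lhs - rhs)) <= 1e-9 * max(1.0, np.max(np.abs(lhs)))


class TestPreprocessChain:
    def test_identity_settings_produce_identity(self, small_image):
        cfg = PreprocessConfig(
            run_despike=False, noise_rank=None, run_trim=False,
            run_baseline=False, run_savgol=False, run_normalize=False,
        )
        out = preprocess(small_image, cfg)
        assert np.array_equal(out.cube, small_image.cube)

    def test_deterministic(self, small_image):
        cfg = PreprocessConfig(lam=5000.0, run_despike=False)
        a = preprocess(small_image, cfg)
        b = preprocess(small_image, cfg)
        assert np.array_equal(a.cube, b.cube)

    def test_history_records_stages(self, small_image):
        cfg = PreprocessConfig.preset("ftir")
        out = preprocess(small_image, cfg.replace(trim_lo=950.0, trim_hi=1010.0))
        stages = [h["stage"] for h in out.metadata["history"]]
        assert stages == ["trim", "asls_baseline", "savgol", "normalize_total_area"]

    def test_recovers_planted_clean_profiles(self):
        scene = islet_scene(seed=3, spike_rate=0.01)
        img, truth = generate(scene)
        pre = preprocess(img, PreprocessConfig.preset("raman-dry"))
        flat_clean = truth.clean.reshape(-1, truth.clean.shape[-1])
        flat_out = pre.as_matrix()
        tissue = truth.mask.labels.ravel() > 0
        cors = []
        for i in np.flatnonzero(tissue):
            c = np.corrcoef(flat_out[i], flat_clean[i])[0, 1]
            cors.append(c)
        assert np.min(cors) >= 0.98

    def test_trim_error_names_stage(self, small_image):
        cfg = PreprocessConfig.preset("ftir")  # axis of fixture is 950-1010
        cfg = cfg.replace(trim_lo=3000.0, trim_hi=4000.0)
        with pytest.raises(StageError, match="trim"):
            preprocess(small_image, cfg)

    def test_presets_carry_published_parameters(self):
        ftir = PreprocessConfig.preset("ftir")
        assert (ftir.lam, ftir.trim_lo, ftir.trim_hi) == (5000.0, 950.0, 2000.0)
        dry = PreprocessConfig.preset("raman-dry")
        assert (dry.lam, dry.trim_lo, dry.trim_hi) == (10000.0, 630.0, 1890.0)
        intact = PreprocessConfig.preset("raman-intact")
        assert intact.lam == 1_000_000.0
        for cfg in (ftir, dry, intact):
            assert cfg.p_asym == 0.01 and cfg.sg_frame == 5 and cfg.sg_order == 1
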