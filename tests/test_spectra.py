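"""Spectral preprocessing: SNV algebra, Savitzky–Golay filter properties,
region cropping, replicate averaging and the artifact-removal contract of
the fixed SNV → smooth → crop chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import savgol_coeffs
from sklearn.pipeline import make_pipeline

from flyage.containers import Spectrum, SpectraSet
from flyage.spectra import (RegionCropper, SavitzkyGolaySmoother, SNVScaler,
                            average_replicates, crop_region,
                            preprocess_spectrum, read_jcamp, read_spectra_wide,
                            savgol_smooth, snv, write_jcamp)
from flyage.synthetic import (make_measurement_design, simulate_dataset,
                              write_spectra_wide)


def _spec(absorbance, wn=None, **meta):
    absorbance = np.asarray(absorbance, dtype=float)
    if wn is None:
        wn = np.linspace(2000, 1000, absorbance.size)
    return Spectrum(wn, absorbance, meta=meta)


class TestSNV:
    def test_simple_example(self):
        out = snv(_spec([1.0, 2.0, 3.0]))
        assert np.allclose(out.absorbance, [-1.0, 0.0, 1.0])

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant spectrum"):
            snv(_spec([5.0, 5.0, 5.0]))

    def test_output_moments(self, rng):
        out = snv(_spec(rng.normal(size=200)))
        assert abs(out.absorbance.mean()) < 1e-12
        assert abs(out.absorbance.std(ddof=1) - 1.0) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(0.1, 10), seed=st.integers(0, 100))
    def test_affine_invariance(self, a, b, seed):
        """SNV removes exactly multiplicative gain and additive offset."""
        x = np.random.default_rng(seed).normal(size=64)
        base = snv(_spec(x)).absorbance
        shifted = snv(_spec(a + b * x)).absorbance
        assert np.allclose(shifted, base, atol=1e-9)


class TestSavitzkyGolay:
    def test_cubic_reproduced_on_interior(self):
        t = np.linspace(-1, 1, 101)
        s = _spec(t ** 3, wn=np.linspace(2000, 1000, 101))
        out = savgol_smooth(s, window=15, polyorder=3)
        assert np.abs(out.absorbance[7:-7] - s.absorbance[7:-7]).max() < 1e-9

    def test_constant_unchanged(self):
        s = _spec(np.full(50, 2.5))
        out = savgol_smooth(s)
        assert np.allclose(out.absorbance, 2.5)

    def test_white_noise_variance_ratio(self, rng):
        """Linear filtering shrinks white-noise variance by the sum of
        squared central coefficients."""
        h = savgol_coeffs(15, 3)
        expected = (h ** 2).sum()
        x = rng.normal(size=10_000)
        out = savgol_smooth(_spec(x, wn=np.linspace(4000, 900, x.size)))
        ratio = out.absorbance[7:-7].var() / x.var()
        assert abs(ratio - expected) / expected < 0.10

    @pytest.mark.parametrize("window, polyorder", [(14, 3), (5, 5), (3, 4)])
    def test_invalid_filter_parameters(self, window, polyorder):
        with pytest.raises(ValueError):
            savgol_smooth(_spec(np.arange(30.0)), window=window,
                          polyorder=polyorder)


class TestCrop:
    def test_simple_example(self):
        s = Spectrum(np.array([2000.0, 1500.0, 1000.0, 800.0]),
                     np.array([1.0, 2.0, 3.0, 4.0]))
        out = crop_region(s, high=1800, low=900)
        assert list(out.wavenumbers) == [1500.0, 1000.0]
        assert list(out.absorbance) == [2.0, 3.0]

    def test_idempotent(self, default_params):
        s = _spec(np.sin(np.linspace(0, 5, 1608)), wn=default_params.grid)
        once = crop_region(s)
        twice = crop_region(once)
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.absorbance, twice.absorbance)

    def test_no_interpolation_and_bounds(self, default_params):
        s = _spec(np.ones(1608), wn=default_params.grid)
        out = crop_region(s)
        assert out.wavenumbers.min() >= 900.0
        assert out.wavenumbers.max() <= 1800.0
        assert set(out.wavenumbers) <= set(s.wavenumbers)
        expected = ((default_params.grid >= 900) & (default_params.grid <= 1800)).sum()
        assert out.wavenumbers.size == expected

    def test_empty_overlap_rejected(self):
        s = _spec([1.0, 2.0], wn=np.array([3000.0, 2900.0]))
        with pytest.raises(ValueError, match="overlap"):
            crop_region(s, high=1800, low=900)


class TestAveraging:
    def test_identical_spectra_average_to_themselves(self):
        members = [_spec([1.0, 2.0, 3.0], temperature_C=25, age_days=1,
                         sample_id=f"s{i}") for i in range(9)]
        out = average_replicates(SpectraSet(members))
        assert len(out) == 1
        assert np.allclose(out[0].absorbance, [1.0, 2.0, 3.0])
        assert out[0].meta["n_averaged"] == 9

    def test_pointwise_mean(self):
        a = _spec([0.0, 0.0, 0.0], temperature_C=25, age_days=1, sample_id="a")
        b = _spec([2.0, 4.0, 6.0], temperature_C=25, age_days=1, sample_id="b")
        out = average_replicates(SpectraSet([a, b]))
        assert np.allclose(out[0].absorbance, [1.0, 2.0, 3.0])

    def test_one_average_per_age_on_default_25C_set(self, default_params):
        design = make_measurement_design(25)
        spectra, _ = simulate_dataset(design, default_params)
        out = average_replicates(spectra)  # group by (temperature, age)
        assert len(out) == 10

    def test_mismatched_grids_rejected_naming_samples(self):
        a = _spec([1.0, 2.0], wn=np.array([2000.0, 1000.0]), sample_id="a")
        b = _spec([1.0, 2.0], wn=np.array([1900.0, 1000.0]), sample_id="b")
        with pytest.raises(ValueError, match="b"):
            SpectraSet([a, b])


class TestChain:
    def test_artifact_removal(self, noise_free_params, rng):
        """Multiplicative gain + offset on a clean spectrum preprocesses to
        the same result as the clean spectrum itself."""
        from flyage.synthetic import simulate_spectrum
        clean = simulate_spectrum(5, 25, noise_free_params, seed=1)
        distorted = clean.replace(absorbance=1.7 * clean.absorbance + 0.3)
        a = preprocess_spectrum(clean)
        b = preprocess_spectrum(distorted)
        assert np.abs(a.absorbance - b.absorbance).max() < 1e-9

    def test_deterministic(self, default_params):
        from flyage.synthetic import simulate_spectrum
        s = simulate_spectrum(2, 30, default_params, seed=5)
        a = preprocess_spectrum(s)
        b = preprocess_spectrum(s)
        assert np.array_equal(a.absorbance, b.absorbance)


class TestTransformers:
    def test_pipeline_matches_functions(self, default_params):
        from flyage.synthetic import simulate_spectrum
        spectra = [simulate_spectrum(a, 30, default_params, seed=a)
                   for a in range(1, 9)]
        X = np.vstack([s.absorbance for s in spectra])
        pipe = make_pipeline(SNVScaler(), SavitzkyGolaySmoother(),
                             RegionCropper(default_params.grid))
        Xt = pipe.fit_transform(X)
        ref = np.vstack([preprocess_spectrum(s).absorbance for s in spectra])
        assert np.allclose(Xt, ref)

    def test_get_params_round_trip(self):
        sm = SavitzkyGolaySmoother(window=11, polyorder=2)
        assert SavitzkyGolaySmoother(**sm.get_params()).get_params() == sm.get_params()


class TestIO:
    def test_wide_csv_round_trip(self, tmp_path, default_params):
        design = make_measurement_design(30, n_replicates=1)
        spectra, _ = simulate_dataset(design, default_params)
        path = tmp_path / "wide.csv"
        write_spectra_wide(spectra, path)
        loaded = read_spectra_wide(path, meta=design)
        assert len(loaded) == len(spectra)
        assert np.allclose(loaded[0].absorbance, spectra[0].absorbance)
        assert loaded[0].meta["age_days"] == spectra[0].meta["age_days"]

    def test_jcamp_round_trip(self, tmp_path, default_params):
        from flyage.synthetic import simulate_spectrum
        s = simulate_spectrum(1, 25, default_params, seed=7)
        path = tmp_path / "s.jdx"
        write_jcamp(s, path, title="test")
        loaded = read_jcamp(path)
        assert np.allclose(loaded.wavenumbers, s.wavenumbers, atol=1e-3)
        assert np.allclose(loaded.absorbance, s.absorbance, atol=1e-7)
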