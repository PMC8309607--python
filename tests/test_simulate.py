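import numpy as np
import pytest

from ramandenoise import (
    LorentzianPeak,
    SimConfig,
    Spectrum,
    add_shot_noise,
    default_axis,
    generate_dataset,
    locate_peak_region,
    lorentzian_lineshape,
    scale_to_max,
)


class TestLorentzianLineshape:
    def test_value_at_resonance_is_amplitude_over_linewidth(self, axis600):
        center = axis600.values[250]
        s = lorentzian_lineshape(
            [LorentzianPeak(amplitude=2.0, center=center, linewidth=1.0)], axis600)
        assert s.intensity[250] == pytest.approx(2.0)

    def test_half_maximum_at_center_plus_minus_linewidth(self, axis600):
        # linewidth of exactly 5 axis steps: ω = Ω ± Γ lands on-grid
        step = axis600.step
        center = axis600.values[300]
        gamma = 5 * step
        s = lorentzian_lineshape(
            [LorentzianPeak(amplitude=gamma, center=center, linewidth=gamma)],
            axis600)
        assert s.intensity[300] == pytest.approx(1.0)
        assert s.intensity[295] == pytest.approx(0.5)
        assert s.intensity[305] == pytest.approx(0.5)

    def test_matches_complex_susceptibility_oracle(self, axis600, rng):
        # oracle: evaluate A/(Ω-ω-iΓ) in complex arithmetic, take Im part
        peaks = [LorentzianPeak(amplitude=float(rng.uniform(0.5, 5)),
                                center=float(rng.uniform(500, 1900)),
                                linewidth=float(rng.uniform(1, 50)))
                 for _ in range(7)]
        s = lorentzian_lineshape(peaks, axis600)
        w = axis600.values
        oracle = np.zeros_like(w)
        for p in peaks:
            chi = p.amplitude / (p.center - w - 1j * p.linewidth)
            oracle += chi.imag
        np.testing.assert_allclose(s.intensity, oracle, rtol=1e-12)
        assert np.all(s.intensity > 0)

    def test_empty_peak_list_rejected(self, axis600):
        with pytest.raises(ValueError):
            lorentzian_lineshape([], axis600)


class TestScaleToMax:
    def test_linear_scaling(self, axis600):
        s = Spectrum(axis600, np.linspace(0.1, 2.0, 600))
        out = scale_to_max(s, 4000.0)
        assert out.intensity.max() == pytest.approx(4000.0)
        np.testing.assert_allclose(out.intensity, s.intensity * 2000.0)
        assert np.argmax(out.intensity) == np.argmax(s.intensity)

    def test_identity_when_target_equals_max(self, single_peak_spectrum):
        out = scale_to_max(single_peak_spectrum,
                           float(single_peak_spectrum.intensity.max()))
        np.testing.assert_allclose(out.intensity, single_peak_spectrum.intensity)

    def test_zero_spectrum_rejected(self, axis600):
        with pytest.raises(ValueError):
            scale_to_max(Spectrum(axis600, np.zeros(600)), 10.0)


class TestShotNoise:
    def test_zero_intensity_stays_zero(self, axis600):
        out = add_shot_noise(Spectrum(axis600, np.zeros(600)), seed=1)
        assert np.all(out.intensity == 0)

    def test_poisson_moments_at_high_intensity(self):
        # Poisson: mean = variance = λ; check both within 5 standard errors
        lam, n = 4000.0, 100_000
        ax = default_axis(n, 0, n - 1)
        noisy = add_shot_noise(Spectrum(ax, np.full(n, lam)), seed=7)
        x = noisy.intensity
        se_mean = np.sqrt(lam / n)
        assert abs(x.mean() - lam) < 5 * se_mean
        # Var[sample variance] ≈ (μ4 - σ⁴)/n with μ4 = λ(1+3λ) for Poisson
        se_var = np.sqrt((lam * (1 + 3 * lam) - lam ** 2) / n)
        assert abs(x.var(ddof=1) - lam) < 5 * se_var

    def test_reproducible_for_fixed_seed(self, single_peak_spectrum):
        big = scale_to_max(single_peak_spectrum, 1000.0)
        a = add_shot_noise(big, seed=3)
        b = add_shot_noise(big, seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_negative_intensity_rejected(self, axis600):
        with pytest.raises(ValueError):
            add_shot_noise(Spectrum(axis600, np.full(600, -1.0)), seed=0)


class TestLocatePeakRegion:
    def test_fwhm_of_single_lorentzian(self, single_peak_spectrum):
        # linewidth = 3 samples -> FWHM = 6 samples -> half-width n = 3
        region = locate_peak_region(single_peak_spectrum)
        assert region.center_index == 300
        assert region.half_width == 3

    def test_argmax_picks_higher_of_two_peaks(self, axis600):
        step = axis600.step
        peaks = [
            LorentzianPeak(amplitude=4 * step, center=axis600.values[150],
                           linewidth=4 * step),       # height 1.0
            LorentzianPeak(amplitude=8 * step, center=axis600.values[450],
                           linewidth=4 * step),       # height 2.0
        ]
        region = locate_peak_region(lorentzian_lineshape(peaks, axis600))
        assert region.center_index == 450

    def test_window_shrinks_near_edge(self, axis600):
        step = axis600.step
        peak = LorentzianPeak(amplitude=10 * step, center=axis600.values[2],
                              linewidth=10 * step)
        region = locate_peak_region(lorentzian_lineshape([peak], axis600))
        assert region.center_index == 2
        assert region.half_width <= 2  # clamped so the window fits

    def test_flat_spectrum_rejected(self, axis600):
        with pytest.raises(ValueError, match="no peak"):
            locate_peak_region(Spectrum(axis600, np.ones(600)))


class TestGenerateDataset:
    def test_reproducible_from_seed(self):
        cfg = SimConfig(seed=9)
        a = generate_dataset(cfg, 5)
        b = generate_dataset(cfg, 5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.reference.intensity,
                                          pb.reference.intensity)
            np.testing.assert_array_equal(pa.noisy.intensity,
                                          pb.noisy.intensity)
            assert pa.peak_region == pb.peak_region
            assert pa.snr == pb.snr

    def test_snr_annotations_match_definition(self, small_dataset):
        from ramandenoise import global_snr
        for p in small_dataset[:10]:
            assert p.snr == pytest.approx(global_snr(p.noisy, p.reference))

    def test_snr_band_and_intensity_range(self, small_dataset):
        snrs = np.array([p.snr for p in small_dataset])
        assert snrs.min() >= 15.0 and snrs.max() <= 145.0
        maxima = np.array([p.reference.intensity.max() for p in small_dataset])
        assert maxima.max() <= 4000.0
        assert np.all(maxima > 0)

    def test_profile_diversity_spans_sharp_and_broad(self):
        # FWHM of the dominant peak should range from sharp (chemical-like)
        # to broad (biological-like) profiles
        pairs = generate_dataset(SimConfig(seed=5), 200)
        widths = np.array([p.peak_region.half_width for p in pairs])
        assert widths.min() <= 4
        assert widths.max() >= 15

    def test_clean_spectra_strictly_positive(self, small_dataset):
        for p in small_dataset[:10]:
            assert np.all(p.reference.intensity > 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_peaks_range=(5, 2))
        with pytest.raises(ValueError):
            SimConfig(linewidth_range=(0.0, 10.0))
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(), 0)
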