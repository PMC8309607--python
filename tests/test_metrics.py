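import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramandenoise import (
    PeakRegion,
    global_snr,
    peak_snr,
    rmse,
    snr_product,
    snr_report,
)
from ramandenoise.metrics import write_report_table


class TestRmse:
    def test_identity_is_zero(self, rng):
        a = rng.uniform(0, 100, 600)
        assert rmse(a, a) == 0.0

    def test_constant_offset_returns_offset(self, rng):
        a = rng.uniform(0, 100, 600)
        assert rmse(a + 2.0, a) == pytest.approx(2.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        a = rng.uniform(0, 4000, 600)
        b = rng.uniform(0, 4000, 600)
        acc = 0.0
        for x, y in zip(a, b):  # brute-force definition
            acc += (x - y) ** 2
        assert rmse(a, b) == pytest.approx(math.sqrt(acc / 600), rel=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        assert rmse(a, b) == rmse(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.ones(5), np.ones(6))


class TestGlobalSnr:
    def test_offset_case(self):
        ref = np.zeros(100)
        ref[10] = 100.0
        assert global_snr(ref + 2.0, ref) == pytest.approx(50.0)

    def test_perfect_reconstruction_is_infinite(self, rng):
        ref = rng.uniform(1, 10, 60)
        assert math.isinf(global_snr(ref, ref))

    def test_not_symmetric_reference_supplies_max(self):
        ref = np.zeros(100)
        ref[0] = 100.0
        other = ref + 1.0
        # rmse is shared but the numerator comes from the reference argument
        assert global_snr(other, ref) != global_snr(ref, other)

    def test_simulated_pair_matches_composition(self, noisy_pair):
        expected = (noisy_pair.reference.intensity.max()
                    / rmse(noisy_pair.noisy, noisy_pair.reference))
        assert global_snr(noisy_pair.noisy, noisy_pair.reference) == \
            pytest.approx(expected, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            global_snr(np.ones(10), np.zeros(10))


class TestPeakSnr:
    def test_full_window_equals_global(self, rng):
        # odd length so a symmetric window can cover the whole support
        ref = rng.uniform(1, 100, 601)
        noisy = rng.poisson(ref).astype(float)
        region = PeakRegion(center_index=300, half_width=300)
        assert region.size == 601
        assert peak_snr(noisy, ref, region) == pytest.approx(
            global_snr(noisy, ref), rel=1e-12)

    def test_numerator_is_global_max_not_window_max(self, axis600):
        ref = np.ones(600)
        ref[100] = 50.0   # global max far from the scored window
        den = ref.copy()
        den[400] = 2.0    # error inside the window around 400
        region = PeakRegion(center_index=400, half_width=6)
        expected = 50.0 / rmse(den[394:407], ref[394:407])
        assert peak_snr(den, ref, region) == pytest.approx(expected, rel=1e-12)

    def test_localized_error_outside_window_gives_infinity(self, axis600):
        ref = np.ones(600)
        ref[300] = 10.0
        den = ref.copy()
        den[10] += 5.0  # error far from the peak window
        region = PeakRegion(center_index=300, half_width=6)
        assert math.isinf(peak_snr(den, ref, region))
        assert not math.isinf(global_snr(den, ref))

    def test_thirteen_sample_window_matches_slice_oracle(self, noisy_pair):
        pk = noisy_pair.peak_region.center_index
        region = PeakRegion(center_index=pk, half_width=6)
        ref = noisy_pair.reference.intensity
        den = noisy_pair.noisy.intensity
        w = slice(pk - 6, pk + 7)
        assert region.size == 13
        expected = ref.max() / rmse(den[w], ref[w])
        assert peak_snr(den, ref, region) == pytest.approx(expected, rel=1e-12)


class TestSnrProduct:
    def test_identity_denoiser_is_exactly_one(self, noisy_pair):
        x = noisy_pair.noisy.intensity
        assert snr_product(x, x, noisy_pair.reference.intensity,
                           noisy_pair.peak_region) == 1.0

    def test_oracle_denoiser_is_infinite(self, noisy_pair):
        assert math.isinf(snr_product(noisy_pair.reference.intensity,
                                      noisy_pair.noisy.intensity,
                                      noisy_pair.reference.intensity,
                                      noisy_pair.peak_region))

    def test_degrading_denoiser_below_one(self, noisy_pair, rng):
        worse = noisy_pair.noisy.intensity + rng.normal(0, 30, 600)
        value = snr_product(worse, noisy_pair.noisy.intensity,
                            noisy_pair.reference.intensity,
                            noisy_pair.peak_region)
        assert value < 1.0

    def test_noise_free_raw_rejected(self, noisy_pair):
        ref = noisy_pair.reference.intensity
        with pytest.raises(ValueError, match="raw"):
            snr_product(ref, ref, ref, noisy_pair.peak_region)

    def test_scale_invariance_of_all_metrics(self, noisy_pair):
        den = noisy_pair.noisy.intensity * 0.9 + 1.0
        raw = noisy_pair.noisy.intensity
        ref = noisy_pair.reference.intensity
        r = noisy_pair.peak_region
        c = 37.5
        assert global_snr(c * den, c * ref) == pytest.approx(
            global_snr(den, ref), rel=1e-12)
        assert peak_snr(c * den, c * ref, r) == pytest.approx(
            peak_snr(den, ref, r), rel=1e-12)
        assert snr_product(c * den, c * raw, c * ref, r) == pytest.approx(
            snr_product(den, raw, ref, r), rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_snr_product_of_identity_is_one_for_any_noise(seed):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(0.5, 100, 64)
    noisy = rng.poisson(ref).astype(float)
    region = PeakRegion(center_index=32, half_width=5)
    if np.array_equal(noisy, ref):  # pathological draw; contract excludes it
        return
    assert snr_product(noisy, noisy, ref, region) == 1.0


def test_report_table_contains_summary_row(tmp_path, noisy_pair):
    rep = snr_report(noisy_pair.noisy.intensity * 0.99,
                     noisy_pair.noisy.intensity,
                     noisy_pair.reference.intensity,
                     noisy_pair.peak_region)
    table = write_report_table([rep, rep], tmp_path / "report.tsv")
    assert len(table) == 3
    assert (tmp_path / "report.tsv").exists()
    assert table.iloc[-1]["spectrum"] == "mean"
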