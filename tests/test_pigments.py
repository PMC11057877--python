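import numpy as np
import pytest

from anemonevision.pigments import (
    LensProfile,
    PigmentError,
    PigmentFit,
    PigmentScan,
    apply_lens,
    bin_scans,
    estimate_lambda_max,
    lens_t50,
    pigment_template,
)
from anemonevision.spectra import DEFAULT_GRID, Spectrum
from anemonevision.synth import gen_msp_scans


def _fwhm(spec):
    wl, v = spec.wavelengths, spec.values
    above = wl[v >= 0.5 * v.max()]
    return above[-1] - above[0]


class TestTemplate:
    def test_peak_location_and_height(self):
        t = pigment_template(500.0, "A1")
        assert abs(t.wavelengths[np.argmax(t.values)] - 500.0) <= 1.0
        assert t.values.max() == pytest.approx(1.0)
        # the beta band never tops the alpha peak
        assert t.value_at(500.0) == pytest.approx(1.0, abs=1e-3)

    def test_a2_broader_than_a1(self):
        assert _fwhm(pigment_template(500, "A2")) > _fwhm(pigment_template(500, "A1"))

    def test_validity_range_enforced(self):
        with pytest.raises(PigmentError):
            pigment_template(320.0)


class TestEstimateLambdaMax:
    @pytest.mark.parametrize("lmax", range(360, 561, 20))
    @pytest.mark.parametrize("chrom", ["A1", "A2"])
    def test_noiseless_self_consistency(self, lmax, chrom):
        fit = estimate_lambda_max(pigment_template(float(lmax), chrom), chrom)
        assert fit.lambda_max == pytest.approx(lmax, abs=0.5)
        assert fit.lambda_max < fit.lambda_50

    def test_auto_identifies_chromophore_noiseless(self):
        for chrom in ("A1", "A2"):
            fit = estimate_lambda_max(pigment_template(500.0, chrom), "auto")
            assert fit.chromophore == chrom

    def test_noisy_recovery_uv_cone(self):
        # 30 noisy scans around the UV cone template: small bias
        scans = gen_msp_scans(386.0, n=30, noise_sd=0.05, seed=9)
        ests = [estimate_lambda_max(s, "A1").lambda_max for s in scans]
        assert abs(np.mean(ests) - 386.0) < 3.0

    def test_auto_prefers_a2_for_a2_scans(self):
        scans = gen_msp_scans(500.0, n=40, noise_sd=0.05, seed=4, chromophore="A2")
        chosen = [estimate_lambda_max(s, "auto").chromophore for s in scans]
        assert np.mean([c == "A2" for c in chosen]) >= 0.95

    def test_ascending_limb_rejected(self):
        wl = DEFAULT_GRID.wavelengths
        rising = Spectrum(wl, np.linspace(0.01, 1.0, wl.size), "absorbance")
        with pytest.raises(PigmentError):
            estimate_lambda_max(rising)


class TestBinScans:
    @staticmethod
    def _fake(lmax):
        scan = PigmentScan(pigment_template(lmax, "A1"), f"c{lmax}", "f1")
        fit = estimate_lambda_max(scan, "A1")
        return scan, fit

    def test_groups_within_10nm(self):
        fits = [self._fake(l) for l in (497.0, 499.0, 515.0)]
        out = bin_scans(fits)
        assert len(out) == 2

    def test_single_scan_identity(self):
        fits = [self._fake(500.0)]
        out = bin_scans(fits)
        assert out[0].lambda_max == fits[0][1].lambda_max

    def test_chain_merges_under_single_linkage(self):
        fits = [self._fake(l) for l in (500.0, 509.0, 518.0)]
        assert len(bin_scans(fits)) == 1

    def test_never_merges_far_scans_without_chain(self):
        fits = [self._fake(l) for l in (450.0, 480.0, 530.0)]
        assert len(bin_scans(fits)) == 3

    def test_empty_errors(self):
        with pytest.raises(PigmentError):
            bin_scans([])


class TestLensT50:
    def test_step_function(self):
        wl = DEFAULT_GRID.wavelengths
        vals = np.where(wl >= 400.0, 1.0, 0.0)
        prof = lens_t50(Spectrum(wl, vals, "transmittance"))
        assert prof.t50 == pytest.approx(400.0, abs=0.5)

    def test_logistic_midpoint(self):
        wl = DEFAULT_GRID.wavelengths
        vals = 1.0 / (1.0 + np.exp(-0.1 * (wl - 334.0)))
        assert lens_t50(Spectrum(wl, vals, "transmittance")).t50 == pytest.approx(334.0, abs=0.5)

    def test_mean_of_three_measured_profiles(self):
        # per-fish half-transmission points 322, 340 and 341 nm average to 334
        wl = DEFAULT_GRID.wavelengths
        t50s = []
        for mid in (322.0, 340.0, 341.0):
            vals = 1.0 / (1.0 + np.exp(-0.1 * (wl - mid)))
            t50s.append(lens_t50(Spectrum(wl, vals, "transmittance")).t50)
        assert round(float(np.mean(t50s))) == 334

    def test_never_crossing_errors(self):
        wl = DEFAULT_GRID.wavelengths
        with pytest.raises(PigmentError):
            lens_t50(Spectrum(wl, np.full(wl.size, 0.9), "transmittance"))


class TestApplyLens:
    def test_identity_lens(self):
        rec = pigment_template(500.0)
        lens = Spectrum(rec.wavelengths, np.ones(len(rec)), "transmittance")
        out = apply_lens(rec, lens)
        np.testing.assert_allclose(out.values, rec.values, atol=1e-12)

    def test_uv_filtering_shifts_peak_longward(self):
        rec = pigment_template(386.0)
        wl = rec.wavelengths
        lens = Spectrum(wl, 1.0 / (1.0 + np.exp(-0.05 * (wl - 370.0))), "transmittance")
        out = apply_lens(rec, lens)
        assert out.wavelengths[np.argmax(out.values)] >= 386.0

    def test_all_zero_product_errors(self):
        rec = pigment_template(386.0)
        wl = rec.wavelengths
        lens = Spectrum(wl, np.where(wl >= 650.0, 1.0, 0.0), "transmittance")
        rec_short = Spectrum(wl, np.where(wl < 600.0, rec.values, 0.0), "absorbance")
        with pytest.raises(PigmentError):
            apply_lens(rec_short, lens)
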