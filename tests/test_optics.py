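"""Calibration, forward model, LUT, artifact screening and inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorperf import optics
from tumorperf.extinction import synthetic_extinction
from tumorperf.optics import (
    ArtifactThresholds,
    LUTGridSpec,
    OpticalModelParams,
    Spectrum,
    SurrogateModel,
    build_lut,
    calibrate,
    derive_perfusion,
    fold_change,
    forward_reflectance,
    invert_spectrum,
    reject_artifacts,
)


def _spec(wl, vals, **meta):
    return Spectrum(wl, vals, meta)


class TestCalibrate:
    wl = np.arange(450.0, 651.0, 5.0)

    def test_reference_standard_fixed_point(self):
        """Sample identical to the 5% standard calibrates to R = 0.05."""
        ref = _spec(self.wl, np.full_like(self.wl, 1000.0))
        dark = _spec(self.wl, np.zeros_like(self.wl))
        out = calibrate(ref, dark, ref)
        assert np.allclose(out.intensities, 0.05)

    def test_dark_sample_calibrates_to_zero(self):
        dark = _spec(self.wl, np.full_like(self.wl, 40.0))
        ref = _spec(self.wl, np.full_like(self.wl, 900.0))
        out = calibrate(_spec(self.wl, np.full_like(self.wl, 40.0)), dark, ref)
        assert np.allclose(out.intensities, 0.0)

    def test_linearity_in_dark_subtracted_signal(self):
        rng = np.random.default_rng(0)
        dark = _spec(self.wl, np.full_like(self.wl, 30.0))
        ref = _spec(self.wl, 1000.0 + 100.0 * rng.random(self.wl.size))
        base = 30.0 + 200.0 * rng.random(self.wl.size)
        r1 = calibrate(_spec(self.wl, base), dark, ref).intensities
        r2 = calibrate(_spec(self.wl, 30.0 + 2 * (base - 30.0)), dark, ref).intensities
        assert np.allclose(r2, 2 * r1)

    def test_nonpositive_denominator_names_wavelength(self):
        dark = _spec(self.wl, np.full_like(self.wl, 100.0))
        bad_ref = np.full_like(self.wl, 900.0)
        bad_ref[self.wl == 500.0] = 50.0  # below dark
        with pytest.raises(ValueError, match="500"):
            calibrate(_spec(self.wl, bad_ref), dark, _spec(self.wl, bad_ref))


class TestForwardModel:
    def test_sto2_one_uses_only_oxyhemoglobin(self, ext, wavelengths, surrogate):
        p1 = OpticalModelParams(thb=10, sto2=1.0, a=20, b=1.0)
        mua = optics.mu_a(p1, wavelengths, ext)
        eps_hbo2, _ = ext.interp(wavelengths)
        expected = np.log(10) * (10 / 64500.0) * eps_hbo2
        assert np.allclose(mua, expected)

    def test_isosbestic_identity(self, surrogate):
        """Where both extinction spectra agree, mu_a is StO2-independent."""
        from tumorperf.extinction import ExtinctionTable

        wl = np.array([500.0, 510.0])
        eq = ExtinctionTable(wl, np.array([2.0e4, 3.0e4]), np.array([2.0e4, 3.0e4]))
        for sto2 in (0.0, 0.37, 1.0):
            p = OpticalModelParams(thb=12, sto2=sto2, a=20, b=1.0)
            ref = optics.mu_a(OpticalModelParams(12, 0.5, 20, 1.0), wl, eq)
            assert np.allclose(optics.mu_a(p, wl, eq), ref)

    def test_zero_hemoglobin_gives_scattering_only_reflectance(
            self, ext, wavelengths, surrogate):
        p = OpticalModelParams(thb=0.0, sto2=0.5, a=20, b=1.2)
        assert np.allclose(optics.mu_a(p, wavelengths, ext), 0.0)
        r = forward_reflectance(p, wavelengths, ext, surrogate)
        assert np.allclose(r, surrogate(0.0, optics.mu_s_prime(p, wavelengths)))

    def test_wavelength_outside_support_raises(self, ext, surrogate):
        p = OpticalModelParams(thb=10, sto2=0.5, a=20, b=1.0)
        with pytest.raises(ValueError, match="support"):
            forward_reflectance(p, np.array([300.0, 500.0]), ext, surrogate)


class TestLUT:
    def test_nodes_match_surrogate_exactly(self, surrogate):
        lut = build_lut(LUTGridSpec(n_mua=16, n_musp=12), surrogate)
        i, j = 5, 7
        assert lut.values[i, j] == pytest.approx(
            float(surrogate(lut.mua_grid[i], lut.musp_grid[j])), abs=0.0)
        assert lut(np.array([lut.mua_grid[i]]), np.array([lut.musp_grid[j]]))[0] \
            == pytest.approx(lut.values[i, j], rel=1e-12)

    def test_midpoint_lies_between_node_values(self, surrogate):
        lut = build_lut(LUTGridSpec(n_mua=16, n_musp=12), surrogate)
        mua_mid = np.sqrt(lut.mua_grid[3] * lut.mua_grid[4])  # log midpoint
        v = float(lut(np.array([mua_mid]), np.array([lut.musp_grid[5]]))[0])
        lo = min(lut.values[3, 5], lut.values[4, 5])
        hi = max(lut.values[3, 5], lut.values[4, 5])
        assert lo <= v <= hi

    def test_dense_offgrid_agreement_with_surrogate(self, surrogate):
        """Interpolation error on a dense off-grid probe set stays small."""
        lut = build_lut(LUTGridSpec(), surrogate)
        rng = np.random.default_rng(1)
        mua = 10 ** rng.uniform(np.log10(0.02), np.log10(40), 400)
        musp = rng.uniform(2, 45, 400)
        err = np.abs(lut(mua, musp) - surrogate(mua, musp))
        assert err.max() < 5e-3

    def test_monotonicity_enforced_at_build(self):
        with pytest.raises(ValueError, match="strictly"):
            build_lut(LUTGridSpec(n_mua=8, n_musp=8),
                      lambda mua, musp: np.ones(np.broadcast(mua, musp).shape))

    def test_monotone_in_both_arguments_on_nodes(self, surrogate):
        lut = build_lut(LUTGridSpec(), surrogate)
        assert np.all(np.diff(lut.values, axis=0) < 0)
        assert np.all(np.diff(lut.values, axis=1) > 0)


class TestArtifactRejection:
    wl = np.arange(450.0, 651.0, 5.0)

    def test_saturated_low_and_clean(self):
        clean = _spec(self.wl, np.full_like(self.wl, 0.03), raw_max=30000.0)
        saturated = _spec(self.wl, np.full_like(self.wl, 0.03),
                          raw_max=optics.SATURATION_LEVEL)
        dark = _spec(self.wl, np.full_like(self.wl, 1e-4), raw_max=100.0)
        kept, rejected = reject_artifacts([clean, saturated, dark])
        assert kept == [clean]
        assert {r for _, r in rejected} == {"saturation", "low signal"}

    def test_clean_noise_free_cohort_fully_retained(self, ext, surrogate):
        from tumorperf import synthetic

        cfg = synthetic.CohortConfig(
            n_per_group={"CG": 2, "MET": 2, "MTD": 2}, seed=3,
            missing_rate=0.0, artifact_rate=0.0, noise_sd_reflectance=0.0,
            spectra_per_visit=1, subject_sd=0.0)
        traj = synthetic.simulate_trajectories(cfg)
        samples, dark, ref, _ = synthetic.simulate_spectra(traj, cfg)
        calibrated = [calibrate(s, dark, ref) for s in samples]
        kept, rejected = reject_artifacts(calibrated)
        assert len(rejected) == 0 and len(kept) == len(samples)


class TestInversion:
    def test_noise_free_round_trip(self, clean_spectrum):
        theta, spectrum = clean_spectrum
        est = invert_spectrum(spectrum)
        assert est.converged
        assert abs(est.params.sto2 - theta.sto2) <= 0.01
        assert abs(est.params.thb - theta.thb) / theta.thb <= 0.02

    def test_round_trip_small_grid(self, ext, surrogate, wavelengths):
        for thb in (5.0, 25.0):
            for sto2 in (0.2, 0.9):
                theta = OpticalModelParams(thb, sto2, 25.0, 1.5)
                r = forward_reflectance(theta, wavelengths, ext, surrogate)
                est = invert_spectrum(Spectrum(wavelengths, r, {}))
                assert abs(est.params.sto2 - sto2) <= 0.01
                assert abs(est.params.thb - thb) / thb <= 0.02

    def test_noisy_inversion_median_error(self, clean_spectrum):
        """1% multiplicative noise: median StO2 error over 50 replicates <= 0.05."""
        theta, spectrum = clean_spectrum
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(50):
            noisy = Spectrum(
                spectrum.wavelengths,
                spectrum.intensities * (1 + rng.normal(0, 0.01,
                                                       spectrum.wavelengths.size)),
                {})
            est = invert_spectrum(noisy)
            errs.append(abs(est.params.sto2 - theta.sto2))
        assert np.median(errs) <= 0.05

    def test_pure_oxyhemoglobin_hits_upper_bound(self, ext, surrogate, wavelengths):
        theta = OpticalModelParams(thb=15, sto2=1.0, a=20, b=1.2)
        r = forward_reflectance(theta, wavelengths, ext, surrogate)
        est = invert_spectrum(Spectrum(wavelengths, r, {}))
        assert est.params.sto2 >= 0.99

    def test_high_residual_flagged_after_fit(self, clean_spectrum):
        _, spectrum = clean_spectrum
        garbled = Spectrum(spectrum.wavelengths,
                           spectrum.intensities[::-1].copy(), {})
        est = invert_spectrum(garbled, rmse_max=1e-6)
        assert est.rejected and est.reason == "high residual"
        assert est.params is None


class TestDerived:
    def test_hand_values(self):
        d = derive_perfusion(OpticalModelParams(thb=10, sto2=0.6, a=20, b=1))
        assert d["HbO2"] == pytest.approx(6.0)
        assert d["HbO"] == pytest.approx(4.0)
        d = derive_perfusion(OpticalModelParams(thb=7, sto2=1.0, a=20, b=1))
        assert d["HbO"] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(thb=st.floats(0.1, 100), sto2=st.floats(0, 1),
           a=st.floats(1, 60), b=st.floats(0, 3))
    def test_hemoglobin_conservation(self, thb, sto2, a, b):
        d = derive_perfusion(OpticalModelParams(thb, sto2, a, b))
        assert d["HbO2"] + d["HbO"] == pytest.approx(d["tHb"], rel=1e-12)


class TestFoldChange:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["tumor_id", "group", "week",
                                           "StO2", "tHb", "HbO2", "HbO"])

    def test_simple_series(self):
        rows = [("t1", "CG", w, v, 1, 1, 1)
                for w, v in zip([1, 2, 3], [10.0, 11.0, 12.0])]
        out = fold_change(self._frame(rows), metrics=("StO2",))
        assert out["value"].tolist() == pytest.approx([1.0, 1.1, 1.2])

    def test_constant_series_is_unity(self):
        rows = [("t1", "CG", w, 5.0, 1, 1, 1) for w in range(1, 7)]
        out = fold_change(self._frame(rows), metrics=("StO2",))
        assert np.allclose(out["value"], 1.0)

    def test_missing_baseline_excludes_tumor(self):
        rows = [("t1", "CG", 2, 5.0, 1, 1, 1), ("t1", "CG", 3, 6.0, 1, 1, 1),
                ("t2", "CG", 1, 5.0, 1, 1, 1), ("t2", "CG", 2, 6.0, 1, 1, 1)]
        out = fold_change(self._frame(rows), metrics=("StO2",))
        assert set(out["tumor_id"]) == {"t2"}
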