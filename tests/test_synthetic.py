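"""Ground-truth fidelity and determinism of the synthetic cohort generator."""

import numpy as np
import pytest

from tumorperf import optics, synthetic
from tumorperf.synthetic import (
    CohortConfig,
    simulate_qpcr,
    simulate_scores_and_masks,
    simulate_spectra,
    simulate_trajectories,
)


def _cfg(**kw):
    base = dict(n_per_group={"CG": 4, "MET": 4, "MTD": 4}, seed=7,
                missing_rate=0.0, artifact_rate=0.0, subject_sd=0.0,
                noise_sd_reflectance=0.0, spectra_per_visit=1, ct_noise_sd=0.0)
    base.update(kw)
    return CohortConfig(**base)


class TestTrajectories:
    def test_null_effects_are_flat_at_baseline(self):
        flat = {m: {g: ((1, 1.0), (6, 1.0)) for g in synthetic.GROUPS}
                for m in ("StO2", "tHb", "Vegf", "Hif1a")}
        trajs = simulate_trajectories(_cfg(), effects=flat)
        for t in trajs:
            assert np.allclose(list(t.sto2.values()), synthetic.STO2_BASELINE)
            assert np.allclose(list(t.thb.values()), synthetic.THB_BASELINE)
            assert np.allclose(list(t.expression["Vegf"].values()), 1.0)

    def test_met_sto2_template_peaks_at_week_four(self):
        """Noise-free MET StO2 fold change hits its 1.08 maximum at week 4."""
        trajs = simulate_trajectories(_cfg())
        met = [t for t in trajs if t.group == "MET"]
        folds = np.mean([[t.sto2[w] / t.sto2[1] for w in range(1, 7)]
                         for t in met], axis=0)
        assert folds[3] == pytest.approx(1.08, abs=1e-12)
        assert np.argmax(folds) == 3

    def test_mtd_vegf_template_halved_at_week_one(self):
        trajs = simulate_trajectories(_cfg())
        mtd = [t for t in trajs if t.group == "MTD"]
        week1 = np.mean([t.expression["Vegf"][1] for t in mtd])
        assert week1 == pytest.approx(0.5, abs=1e-12)

    def test_seeded_reproducibility(self):
        cfg = _cfg(subject_sd=0.05)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        for ta, tb in zip(a, b):
            assert ta.sto2 == tb.sto2 and ta.expression == tb.expression

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_trajectories(_cfg(), effects={"StO2": {"XX": ((1, 1),)}})
        with pytest.raises(ValueError, match="unknown group"):
            CohortConfig(n_per_group={"XX": 3})

    def test_default_cohort_sizes(self):
        trajs = simulate_trajectories(CohortConfig(seed=0))
        counts = {g: sum(t.group == g for t in trajs) for g in synthetic.GROUPS}
        assert counts == {"MTD": 27, "MET": 20, "CG": 14}


class TestSpectra:
    def test_roundtrip_recovers_truth(self, ext, surrogate):
        """Noise-free, artifact-free spectra invert back to the ground truth."""
        cfg = _cfg(n_per_group={"MET": 2})
        trajs = simulate_trajectories(cfg)
        samples, dark, ref, truth = simulate_spectra(trajs, cfg)
        sp = samples[0]
        cal = optics.calibrate(sp, dark, ref)
        est = optics.invert_spectrum(cal)
        key = f"{sp.meta['tumor_id']}|w{sp.meta['week']}"
        assert abs(est.params.sto2 - truth[key]["StO2"]) <= 0.01
        assert abs(est.params.thb - truth[key]["tHb"]) / truth[key]["tHb"] <= 0.02

    def test_every_spectrum_flagged_when_artifact_rate_is_one(self):
        cfg = _cfg(artifact_rate=1.0, n_per_group={"CG": 2})
        trajs = simulate_trajectories(cfg)
        samples, _, _, truth = simulate_spectra(trajs, cfg)
        for sp in samples:
            assert sp.meta["artifact"] in synthetic.ARTIFACT_TYPES
        for rec in truth.values():
            assert all(a is not None for a in rec["artifacts"])

    def test_missing_visits_recorded(self):
        cfg = _cfg(missing_rate=1.0, n_per_group={"CG": 2})
        trajs = simulate_trajectories(cfg)
        samples, _, _, truth = simulate_spectra(trajs, cfg)
        assert samples == []
        assert all(rec["missing"] for rec in truth.values())

    def test_raw_proportional_to_reflectance_under_flat_reference(
            self, ext, surrogate, monkeypatch):
        """With zero dark and a flat lamp, raw counts track model reflectance."""
        wl = np.arange(450.0, 651.0, 2.0)
        monkeypatch.setattr(
            synthetic, "_reference_spectra",
            lambda w: (np.full_like(w, 1000.0), np.zeros_like(w)))
        cfg = _cfg(n_per_group={"CG": 1}, wavelengths=wl)
        trajs = simulate_trajectories(cfg)
        samples, _, _, _ = simulate_spectra(trajs, cfg)
        t = trajs[0]
        week = samples[0].meta["week"]
        params = optics.OpticalModelParams(t.thb[week], t.sto2[week],
                                           t.scatter_a, t.scatter_b)
        refl = optics.forward_reflectance(params, wl, ext, surrogate)
        ratio = samples[0].intensities / refl
        assert np.allclose(ratio, ratio[0])


class TestQpcr:
    def test_standard_curve_slope_closed_form(self):
        cfg = _cfg(n_per_group={"CG": 1})
        trajs = simulate_trajectories(cfg)
        _, curves = simulate_qpcr(trajs, cfg, efficiencies={"Aldoa": 2.0},
                                  curve_noise_sd=0.0)
        sub = curves[curves["gene"] == "Aldoa"]
        slope = np.polyfit(sub["log10_dilution"], sub["ct"], 1)[0]
        assert slope == pytest.approx(-3.3219, abs=1e-3)

    def test_unit_expression_gives_base_ct(self):
        cfg = _cfg(n_per_group={"CG": 2})
        flat = {g: {grp: ((1, 1.0), (6, 1.0)) for grp in synthetic.GROUPS}
                for g in ("Vegf", "Hif1a")}
        trajs = simulate_trajectories(cfg, effects=flat)
        ct, _ = simulate_qpcr(trajs, cfg)
        vegf = ct[ct["gene"] == "Vegf"]
        assert np.allclose(vegf[["ct1", "ct2", "ct3"]], 24.0)

    def test_doubling_shifts_ct_by_one_cycle_at_e2(self):
        cfg = _cfg(n_per_group={"CG": 1})
        double = {"Vegf": {"CG": ((1, 2.0), (6, 2.0))}}
        trajs = simulate_trajectories(cfg, effects=double)
        ct, _ = simulate_qpcr(trajs, cfg, efficiencies={"Vegf": 2.0})
        vegf = ct[ct["gene"] == "Vegf"]
        assert np.allclose(vegf["ct1"], 23.0)  # one cycle earlier

    def test_out_of_range_efficiency_rejected(self):
        cfg = _cfg(n_per_group={"CG": 1})
        trajs = simulate_trajectories(cfg)
        with pytest.raises(ValueError, match="efficiency"):
            simulate_qpcr(trajs, cfg, efficiencies={"Vegf": 1.2})


class TestScoresAndMasks:
    def test_no_missing_scores_when_rate_zero(self):
        cfg = _cfg(n_per_group={"CG": 5})
        trajs = simulate_trajectories(cfg)
        scores, _, _ = simulate_scores_and_masks(trajs, cfg)
        assert scores["score"].notna().all()
        assert (scores.groupby("tumor_id").size() == 6).all()

    def test_degenerate_score_template(self):
        cfg = _cfg(n_per_group={"CG": 4})
        trajs = simulate_trajectories(cfg)
        tpl = {("CG", w): [0, 0, 0, 0, 0, 1, 0, 0, 0] for w in range(1, 7)}
        scores, _, _ = simulate_scores_and_masks(trajs, cfg, score_templates=tpl)
        assert (scores["score"] == 3.5).all()

    def test_mask_positive_fraction_is_controlled(self):
        from tumorperf.cohort import compute_mvd

        cfg = _cfg(n_per_group={"CG": 1})
        trajs = simulate_trajectories(cfg)
        _, table, masks = simulate_scores_and_masks(
            trajs, cfg, positive_fractions={"CG": 0.25, "MET": 0.24, "MTD": 0.08})
        for rec in table.itertuples():
            mvd = compute_mvd(masks[(rec.sample_id, rec.roi_id)])
            assert mvd == pytest.approx(100 * rec.true_positive_fraction, abs=0.5)

    def test_score_values_come_from_nine_categories(self):
        cfg = _cfg(n_per_group={"CG": 5, "MET": 5, "MTD": 5})
        trajs = simulate_trajectories(cfg)
        scores, _, _ = simulate_scores_and_masks(trajs, cfg)
        assert scores["score"].isin(synthetic.SCORE_CATEGORIES).all()


def test_write_cohort_emits_ground_truth(tmp_path, small_config):
    cohort = synthetic.simulate_cohort(small_config)
    synthetic.write_cohort(cohort, tmp_path)
    assert (tmp_path / "ground_truth.json").exists()
    assert (tmp_path / "spectra" / "dark.csv").exists()
    assert (tmp_path / "qpcr_ct.csv").exists()
    assert any((tmp_path / "masks").glob("*.png"))
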