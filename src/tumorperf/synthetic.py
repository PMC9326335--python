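"""Synthetic longitudinal cohort generator with known ground truth.

Emulates the raw data of a three-arm preclinical chemotherapy study —
control (CG), metronomic (MET) and maximum-tolerated-dose (MTD) — followed
over six weekly endoscopy visits: reflectance spectra (plus dark and 5%
reference standard measurements), triplicate qPCR Ct tables with standard
curves, endoscopic tumor-score tables, and 3-class vessel label masks.
Every output is paired with its generating ground truth so each downstream
stage (calibration, inversion, Pfaffl quantification, GAM inference) can be
tested against known values.

Group trend templates are piecewise-cubic (PCHIP) interpolants through
(week, level) anchors on the fold-change scale: CG flat; MET StO2 rising to
1.08 at week 4; MTD to 1.05 at week 3; MTD *Vegf* suppressed to 0.5 at week
1 and recovering.  Per-tumor heterogeneity is an additive Gaussian offset on
the fold-change scale, constant across weeks; visits go missing completely
at random; spectra are corrupted with one of three acquisition-artifact
archetypes (saturation, low signal, baseline shift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import optics
from .extinction import synthetic_extinction

GROUPS = ("CG", "MET", "MTD")

#: Cohort sizes per arm.
DEFAULT_N = {"MTD": 27, "MET": 20, "CG": 14}

#: Baseline (week-1) tissue values the fold templates multiply.
STO2_BASELINE = 0.60  # fraction
THB_BASELINE = 15.0  # g/L
SCATTER_A_BASELINE = 20.0  # 1/cm at 630 nm
SCATTER_B_BASELINE = 1.2

GENE_PANEL = ("Vegf", "Hif1a", "Dek", "Stat3", "Raptor", "Aldoa", "Pgk1", "Gapdh")
REFERENCE_GENE = "Gapdh"

SCORE_CATEGORIES = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

_FLAT = ((1, 1.0), (6, 1.0))

#: Fold-change anchors per metric per group.  HbO2/HbO trends follow from
#: StO2 x tHb, matching the reported maxima (~15% MET / ~10% MTD for HbO2).
PERFUSION_TEMPLATES = {
    "StO2": {
        "CG": _FLAT,
        "MET": ((1, 1.0), (2, 1.02), (4, 1.08), (6, 1.03)),
        "MTD": ((1, 1.0), (3, 1.05), (5, 1.01), (6, 1.0)),
    },
    "tHb": {
        "CG": _FLAT,
        "MET": ((1, 1.0), (4, 1.08), (6, 1.13)),
        "MTD": ((1, 1.0), (3, 1.06), (6, 1.11)),
    },
}

EXPRESSION_TEMPLATES = {
    "Vegf": {
        "CG": ((1, 1.0), (6, 0.85)),
        "MET": ((1, 1.0), (6, 0.80)),
        "MTD": ((1, 0.5), (4, 0.80), (6, 0.95)),
    },
    "Hif1a": {
        "CG": ((1, 1.0), (4, 0.80), (6, 1.0)),
        "MET": ((1, 1.0), (4, 1.20), (6, 1.0)),
        "MTD": ((1, 0.5), (6, 1.10)),
    },
}

#: Mean Nestin-positive tissue fraction per group (MVD ground truth).
MASK_POSITIVE_FRACTION = {"CG": 0.25, "MET": 0.24, "MTD": 0.08}


def trend_template(anchors) -> PchipInterpolator:
    """Piecewise-cubic monotone-segment interpolant through (week, level) anchors."""
    anchors = sorted(anchors)
    weeks = [w for w, _ in anchors]
    levels = [v for _, v in anchors]
    if len(anchors) == 1:
        weeks, levels = [weeks[0], weeks[0] + 1], [levels[0], levels[0]]
    return PchipInterpolator(weeks, levels, extrapolate=True)


@dataclass
class CohortConfig:
    """Study-design and noise configuration of the simulated cohort."""

    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_N))
    weeks: tuple = (1, 2, 3, 4, 5, 6)
    groups: tuple = GROUPS
    seed: int = 0
    missing_rate: float = 0.05
    artifact_rate: float = 0.05
    noise_sd_reflectance: float = 0.01  # relative, multiplicative
    subject_sd: float = 0.02  # between-tumor SD of fold-change offsets
    spectra_per_visit: int = 3
    ct_noise_sd: float = 0.15  # cycles, triplicate noise
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(430.0, 691.0, 2.0)
    )

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in self.groups:
                raise ValueError(f"unknown group label {g!r}")
            if n < 1:
                raise ValueError("n_per_group must be >= 1")
        for name in ("missing_rate", "artifact_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "weeks" in d:
            d["weeks"] = tuple(d["weeks"])
        if "wavelengths" in d:
            d["wavelengths"] = np.asarray(d["wavelengths"], float)
        return cls(**d)


@dataclass
class TrueTrajectory:
    """Ground-truth per-week tissue state of one tumor."""

    tumor_id: str
    group: str
    weeks: tuple
    sto2: dict  # week -> fraction in [0, 1]
    thb: dict  # week -> g/L, > 0
    expression: dict  # gene -> {week -> positive fold level}
    scatter_a: float = SCATTER_A_BASELINE
    scatter_b: float = SCATTER_B_BASELINE

    def __post_init__(self):
        for w, v in self.sto2.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"StO2 out of [0,1] at week {w}")
        if any(v <= 0 for v in self.thb.values()):
            raise ValueError("tHb must be positive")
        for gene, series in self.expression.items():
            if any(v <= 0 for v in series.values()):
                raise ValueError(f"expression of {gene} must be positive")


def _normalize_effects(effects):
    """Merge user anchor overrides into the default template dictionaries."""
    perf = {m: {g: v for g, v in gs.items()} for m, gs in PERFUSION_TEMPLATES.items()}
    expr = {m: {g: v for g, v in gs.items()} for m, gs in EXPRESSION_TEMPLATES.items()}
    if effects:
        for metric, per_group in effects.items():
            target = perf if metric in perf else expr
            if metric not in target:
                target[metric] = {}
            for g, anchors in per_group.items():
                if g not in GROUPS:
                    raise ValueError(f"unknown group label {g!r}")
                target[metric][g] = anchors
    return perf, expr


def simulate_trajectories(config: CohortConfig, effects=None) -> list[TrueTrajectory]:
    """Draw per-tumor ground-truth trajectories: group template + subject offset.

    `effects` optionally overrides the default (week, level) anchors,
    e.g. ``{"StO2": {"MET": [(1, 1), (4, 1.08), (6, 1)]}}``.
    """
    perf, expr = _normalize_effects(effects)
    rng = np.random.default_rng(config.seed)
    weeks = np.asarray(config.weeks, float)

    sto2_tpl = {g: trend_template(perf["StO2"].get(g, _FLAT)) for g in config.groups}
    thb_tpl = {g: trend_template(perf["tHb"].get(g, _FLAT)) for g in config.groups}
    expr_tpl = {
        gene: {g: trend_template(expr.get(gene, {}).get(g, _FLAT)) for g in config.groups}
        for gene in GENE_PANEL
    }

    out = []
    for group in config.groups:
        for i in range(config.n_per_group.get(group, 0)):
            tid = f"{group}-{i + 1:02d}"
            off_sto2 = rng.normal(0.0, config.subject_sd)
            off_thb = rng.normal(0.0, config.subject_sd)
            sto2_fold = sto2_tpl[group](weeks) + off_sto2
            thb_fold = thb_tpl[group](weeks) + off_thb
            sto2 = {int(w): float(np.clip(STO2_BASELINE * f, 0.0, 1.0))
                    for w, f in zip(weeks, sto2_fold)}
            thb = {int(w): float(max(THB_BASELINE * f, 1e-3))
                   for w, f in zip(weeks, thb_fold)}
            expression = {}
            for gene in GENE_PANEL:
                # Housekeeping expression does not respond to treatment.
                off = 0.0 if gene == REFERENCE_GENE else rng.normal(0.0, config.subject_sd)
                tpl = (trend_template(_FLAT) if gene == REFERENCE_GENE
                       else expr_tpl[gene][group])
                vals = tpl(weeks) + off
                expression[gene] = {int(w): float(max(v, 1e-3))
                                    for w, v in zip(weeks, vals)}
            out.append(TrueTrajectory(tid, group, tuple(int(w) for w in weeks),
                                      sto2, thb, expression,
                                      scatter_a=SCATTER_A_BASELINE,
                                      scatter_b=SCATTER_B_BASELINE))
    return out


# ---------------------------------------------------------------------------
# Spectra

ARTIFACT_TYPES = ("saturation", "low_signal", "baseline_shift")


def _reference_spectra(wavelengths):
    """Smooth lamp-shaped reference standard measurement and a dark frame.

    The lamp level is set so that tissue reflectance up to ~0.9 (18x the 5%
    standard) stays below the 16-bit detector ceiling.
    """
    lamp = 300.0 + 2800.0 * np.exp(-0.5 * ((wavelengths - 560.0) / 120.0) ** 2)
    dark = np.full_like(wavelengths, 50.0)
    return lamp, dark


def simulate_spectra(trajectories, config: CohortConfig, forward_model=None,
                     ext=None):
    """Render raw spectra for every tumor-visit.

    Returns (samples, dark, reference, truth) where `samples` is a list of
    raw `optics.Spectrum` (one per replicate per visit, minus missing
    visits), `dark`/`reference` are the shared calibration measurements and
    `truth` maps (tumor_id, week) to the generating state including
    artifact/missing flags.
    """
    forward_model = forward_model or optics.SurrogateModel()
    ext = ext or synthetic_extinction()
    rng = np.random.default_rng(config.seed + 1)
    wl = np.asarray(config.wavelengths, float)
    lamp, dark_counts = _reference_spectra(wl)

    dark = optics.Spectrum(wl, dark_counts, {"role": "dark"})
    reference = optics.Spectrum(wl, lamp + dark_counts, {"role": "reference"})

    samples, truth = [], {}
    for traj in trajectories:
        for week in traj.weeks:
            if week not in [int(w) for w in config.weeks]:
                raise ValueError(f"trajectory week {week} outside config weeks")
            key = f"{traj.tumor_id}|w{week}"
            if rng.random() < config.missing_rate:
                truth[key] = {"missing": True}
                continue
            params = optics.OpticalModelParams(
                thb=traj.thb[week], sto2=traj.sto2[week],
                a=traj.scatter_a, b=traj.scatter_b,
            )
            refl = optics.forward_reflectance(params, wl, ext, forward_model)
            rec = {"missing": False, "StO2": params.sto2, "tHb": params.thb,
                   "a": params.a, "b": params.b, "artifacts": []}
            for rep in range(config.spectra_per_visit):
                noise = rng.normal(0.0, config.noise_sd_reflectance, wl.size)
                raw = lamp * (refl / 0.05) * (1.0 + noise) + dark_counts
                artifact = None
                if rng.random() < config.artifact_rate:
                    artifact = ARTIFACT_TYPES[rng.integers(len(ARTIFACT_TYPES))]
                    if artifact == "saturation":
                        raw = np.minimum(raw * 50.0, optics.SATURATION_LEVEL)
                    elif artifact == "low_signal":
                        raw = dark_counts + 0.002 * (raw - dark_counts)
                    else:  # baseline_shift
                        raw = raw + 0.5 * np.max(raw - dark_counts)
                rec["artifacts"].append(artifact)
                samples.append(optics.Spectrum(wl, raw, {
                    "tumor_id": traj.tumor_id, "group": traj.group,
                    "week": week, "replicate": rep, "role": "sample",
                    "artifact": artifact,
                }))
            truth[key] = rec
    return samples, dark, reference, truth


# ---------------------------------------------------------------------------
# qPCR

DEFAULT_EFFICIENCIES = {
    "Vegf": 1.95, "Hif1a": 1.92, "Dek": 1.98, "Stat3": 1.90,
    "Raptor": 1.88, "Aldoa": 2.0, "Pgk1": 1.96, "Gapdh": 2.0,
}

#: Calibrator-level Ct per gene (abundant housekeeping amplifies earlier).
_BASE_CT = {g: (18.0 if g == REFERENCE_GENE else 24.0) for g in GENE_PANEL}


def simulate_qpcr(trajectories, config: CohortConfig, efficiencies=None,
                  curve_noise_sd: float = 0.05):
    """Generate triplicate Ct tables and per-gene standard-curve dilution series.

    Ct model: Ct = Ct_base - log_E(expression level) + N(0, ct_noise_sd) per
    replicate well; the housekeeping gene has flat expression so its Ct is
    independent of group.  Standard curves follow
    Ct = Ct_base - log10(dilution)/log10(E) + noise, i.e. slope
    -1/log10(E) versus log10(dilution).
    """
    efficiencies = dict(DEFAULT_EFFICIENCIES, **(efficiencies or {}))
    missing = [g for g in (REFERENCE_GENE,) if g not in efficiencies]
    if missing:
        raise ValueError(f"missing reference gene efficiency: {missing}")
    for g, e in efficiencies.items():
        if not 1.6 <= e <= 2.1:
            raise ValueError(f"efficiency of {g} outside [1.6, 2.1]: {e}")
    rng = np.random.default_rng(config.seed + 2)

    rows = []
    for traj in trajectories:
        for week in traj.weeks:
            ratio = float(np.clip(rng.normal(1.9, 0.05), 1.6, 2.2))
            for gene in GENE_PANEL:
                e = efficiencies[gene]
                level = traj.expression[gene][week]
                ct_true = _BASE_CT[gene] - np.log(level) / np.log(e)
                cts = ct_true + rng.normal(0.0, config.ct_noise_sd, 3)
                rows.append({
                    "sample_id": f"{traj.tumor_id}|w{week}",
                    "tumor_id": traj.tumor_id, "group": traj.group,
                    "week": week, "gene": gene,
                    "ct1": cts[0], "ct2": cts[1], "ct3": cts[2],
                    "ratio_260_280": ratio,
                })
    ct_table = pd.DataFrame(rows)

    curve_rows = []
    dilutions = 10.0 ** -np.arange(0, 5)
    for gene in GENE_PANEL:
        e = efficiencies[gene]
        for dil in dilutions:
            ct = (_BASE_CT[gene] - np.log10(dil) / np.log10(e)
                  + rng.normal(0.0, curve_noise_sd))
            curve_rows.append({"gene": gene, "dilution": dil,
                               "log10_dilution": np.log10(dil), "ct": ct})
    curves = pd.DataFrame(curve_rows)
    return ct_table, curves


# ---------------------------------------------------------------------------
# Scores and masks

#: Mean endoscopic score drift per group (week-1 -> week-6); CG and MET
#: tumors keep growing under no/metronomic therapy, MTD tumors regress.
_SCORE_MEAN = {"CG": (2.0, 3.8), "MET": (2.0, 3.6), "MTD": (2.2, 1.4)}
_SCORE_SD = 0.6


def score_distribution(group: str, week: int, weeks=(1, 6)) -> np.ndarray:
    """Probability over the nine score categories for one group-week."""
    lo, hi = _SCORE_MEAN[group]
    frac = (week - weeks[0]) / (weeks[-1] - weeks[0])
    mean = lo + (hi - lo) * frac
    cats = np.asarray(SCORE_CATEGORIES)
    w = np.exp(-0.5 * ((cats - mean) / _SCORE_SD) ** 2)
    return w / w.sum()


def simulate_scores_and_masks(trajectories, config: CohortConfig,
                              score_templates=None, mask_shape=(96, 96),
                              positive_fractions=None):
    """Draw weekly tumor scores and 3-class vessel label masks.

    Masks use labels {0: background, 1: tissue, 2: positive}; each sample
    gets 1-3 ROIs whose positive-pixel fraction is drawn around the group
    mean (defaults near CG 25%, MET 24%, MTD 8%).
    Returns (score table, mask table, masks dict keyed by (sample_id, roi)).
    """
    rng = np.random.default_rng(config.seed + 3)
    positive_fractions = positive_fractions or MASK_POSITIVE_FRACTION
    rows = []
    for traj in trajectories:
        for week in traj.weeks:
            if rng.random() < config.missing_rate:
                score = np.nan
            elif score_templates is not None:
                p = np.asarray(score_templates[(traj.group, week)], float)
                score = rng.choice(SCORE_CATEGORIES, p=p / p.sum())
            else:
                p = score_distribution(traj.group, week, config.weeks)
                score = rng.choice(SCORE_CATEGORIES, p=p)
            rows.append({"tumor_id": traj.tumor_id, "group": traj.group,
                         "week": week, "score": score})
    scores = pd.DataFrame(rows)

    masks, mask_rows = {}, []
    h, w = mask_shape
    border = max(2, h // 12)
    for traj in trajectories:
        n_roi = int(rng.integers(1, 4))
        for roi in range(1, n_roi + 1):
            frac = float(np.clip(
                rng.normal(positive_fractions[traj.group], 0.03), 0.005, 0.9))
            mask = np.zeros((h, w), dtype=np.uint8)
            mask[border:-border, border:-border] = 1
            tissue_idx = np.flatnonzero(mask == 1)
            n_pos = int(round(frac * tissue_idx.size))
            pos = rng.choice(tissue_idx, size=n_pos, replace=False)
            mask.flat[pos] = 2
            masks[(traj.tumor_id, roi)] = mask
            mask_rows.append({"sample_id": traj.tumor_id, "group": traj.group,
                              "roi_id": roi, "true_positive_fraction": frac})
    return scores, pd.DataFrame(mask_rows), masks


# ---------------------------------------------------------------------------
# Full cohort + file output


def simulate_cohort(config: CohortConfig, effects=None):
    """Generate the complete cohort (all modalities) in one call."""
    trajectories = simulate_trajectories(config, effects)
    spectra, dark, reference, spec_truth = simulate_spectra(trajectories, config)
    ct_table, curves = simulate_qpcr(trajectories, config)
    scores, mask_table, masks = simulate_scores_and_masks(trajectories, config)
    return {
        "trajectories": trajectories,
        "spectra": spectra, "dark": dark, "reference": reference,
        "spectra_truth": spec_truth,
        "ct_table": ct_table, "standard_curves": curves,
        "scores": scores, "mask_table": mask_table, "masks": masks,
    }


def _truth_json(cohort) -> dict:
    traj_records = [
        {"tumor_id": t.tumor_id, "group": t.group, "weeks": list(t.weeks),
         "StO2": t.sto2, "tHb": t.thb, "expression": t.expression,
         "scatter_a": t.scatter_a, "scatter_b": t.scatter_b}
        for t in cohort["trajectories"]
    ]
    return {"trajectories": traj_records, "spectra": cohort["spectra_truth"]}


def write_cohort(cohort, outdir) -> None:
    """Write the simulated cohort to disk in plain-text/PNG formats.

    Layout: spectra/<tumor>_w<week>_r<rep>.csv plus dark.csv/reference.csv,
    qpcr_ct.csv, standard_curves.csv, scores.csv, masks/<sample>_roi<k>.png
    (palette 0=background, 1=tissue, 2=positive) and ground_truth.json.
    """
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    cohort["dark"].to_frame().to_csv(outdir / "spectra" / "dark.csv", index=False)
    cohort["reference"].to_frame().to_csv(outdir / "spectra" / "reference.csv",
                                          index=False)
    for sp in cohort["spectra"]:
        name = (f"{sp.meta['tumor_id']}_w{sp.meta['week']}"
                f"_r{sp.meta['replicate']}.csv")
        sp.to_frame().to_csv(outdir / "spectra" / name, index=False)
    cohort["ct_table"].to_csv(outdir / "qpcr_ct.csv", index=False)
    cohort["standard_curves"].to_csv(outdir / "standard_curves.csv", index=False)
    cohort["scores"].to_csv(outdir / "scores.csv", index=False)
    cohort["mask_table"].to_csv(outdir / "mask_table.csv", index=False)
    for (sample, roi), mask in cohort["masks"].items():
        img = Image.fromarray(mask, mode="P")
        img.putpalette([0, 0, 0, 60, 90, 200, 160, 80, 40] + [0] * (768 - 9))
        img.save(outdir / "masks" / f"{sample}_roi{roi}.png")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(_truth_json(cohort), fh, indent=1)
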