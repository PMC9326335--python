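"""End-to-end pipeline: simulate -> calibrate/invert -> quantify -> fit -> compare.

`run_pipeline` executes the enabled stages in order on one shared seed,
writing each stage's tables under the output directory and a manifest JSON
recording stage outcomes, per-stage seeds and SHA-256 hashes of every file
written — reruns with the same configuration and seed are hash-identical.
`make_report` renders the summary figures (fitted trends with intervals,
difference bands with shaded significant windows, score-proportion bars and
an MVD violin) from a completed results bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from . import inference, optics, qpcr, synthetic
from .gam import BasisSpec, GroupSmoothModel

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "invert", "qpcr", "fit", "compare", "cohort", "report")
PERFUSION_METRICS = ("StO2", "tHb", "HbO2", "HbO")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results"
    seed: int = 0
    stages: tuple = ALL_STAGES
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    metrics: tuple = PERFUSION_METRICS
    genes: tuple = tuple(g for g in synthetic.GENE_PANEL
                         if g != synthetic.REFERENCE_GENE)
    basis: dict = field(default_factory=dict)  # BasisSpec overrides
    n_draws: int = 10000
    grid_size: int = 200
    perfusion_csv: str | None = None  # skip optics: load estimates instead
    expression_csv: str | None = None  # skip qPCR: load expression instead

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("stages", "metrics", "genes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the in-memory results bundle.

    On stage failure the run aborts with the stage name in the exception and
    any partially written manifest is suffixed ``.partial``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "files": {}}
    bundle: dict = {"config": config}
    written: list[Path] = []

    def record(stage, status, t0):
        manifest["stages"][stage] = {
            "status": status, "seed": stage_seed(config.seed, stage),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            runner = _STAGE_RUNNERS[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None
        try:
            runner(config, bundle, outdir, written)
        except Exception as exc:
            record(stage, "failed", t0)
            partial = outdir / "manifest.json.partial"
            partial.write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        record(stage, "ok", t0)

    for path in written:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# Stage implementations


def _write(df: pd.DataFrame, path: Path, written: list) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    written.append(path)


def _stage_simulate(config, bundle, outdir, written):
    cc = synthetic.CohortConfig.from_dict(
        {"seed": stage_seed(config.seed, "simulate"), **config.cohort})
    cohort = synthetic.simulate_cohort(cc)
    bundle["cohort_config"] = cc
    bundle["cohort"] = cohort
    datadir = outdir / "data"
    synthetic.write_cohort(cohort, datadir)
    for p in sorted(datadir.rglob("*")):
        if p.is_file() and p.suffix in {".csv", ".json"}:
            written.append(p)


def _stage_invert(config, bundle, outdir, written):
    cohort = bundle["cohort"]
    thresholds = optics.ArtifactThresholds()
    retained, rejected = optics.reject_artifacts(
        [optics.calibrate(sp, cohort["dark"], cohort["reference"])
         for sp in cohort["spectra"]], thresholds)
    by_visit: dict = {}
    for sp in retained:
        by_visit.setdefault((sp.meta["tumor_id"], sp.meta["week"]), []).append(sp)
    rows = []
    for (tumor, week), group_spectra in sorted(by_visit.items()):
        avg = optics.average_spectra(group_spectra)
        est = optics.invert_spectrum(avg, rmse_max=thresholds.rmse_max)
        rows.append(est.as_row())
    perfusion = pd.DataFrame(rows)
    bundle["perfusion"] = perfusion
    bundle["rejected_spectra"] = [(sp.meta, reason) for sp, reason in rejected]
    _write(perfusion, outdir / "perfusion.csv", written)
    ok = perfusion[~perfusion["rejected"]]
    folds = optics.fold_change(ok, metrics=config.metrics)
    bundle["fold_changes"] = folds
    _write(folds, outdir / "fold_changes.csv", written)


def _stage_qpcr(config, bundle, outdir, written):
    cohort = bundle["cohort"]
    records = qpcr.qc_filter(cohort["ct_table"])
    effs = qpcr.efficiencies_from_curves(cohort["standard_curves"])
    expression = qpcr.normalize_expression(records, effs)
    bundle["efficiencies"] = effs
    bundle["expression"] = expression
    _write(expression, outdir / "expression.csv", written)


def _iter_fit_frames(config, bundle):
    folds = bundle.get("fold_changes")
    if folds is None and config.perfusion_csv:
        perfusion = pd.read_csv(config.perfusion_csv)
        ok = perfusion[~perfusion["rejected"].astype(bool)]
        folds = optics.fold_change(ok, metrics=config.metrics)
    if folds is not None:
        for metric in config.metrics:
            sub = folds[folds["metric"] == metric]
            if not sub.empty:
                yield f"perfusion:{metric}", sub
    expr = bundle.get("expression")
    if expr is None and config.expression_csv:
        expr = pd.read_csv(config.expression_csv)
    if expr is not None:
        for gene in config.genes:
            sub = expr[expr["gene"] == gene].rename(
                columns={"relative_expression": "value"})
            if not sub.empty:
                yield f"expression:{gene}", sub


def _stage_fit(config, bundle, outdir, written):
    spec = BasisSpec(**config.basis)
    fits, summaries, curve_rows = {}, {}, []
    for name, frame in _iter_fit_frames(config, bundle):
        res = GroupSmoothModel.from_dataframe(frame, spec=spec).fit()
        fits[name] = res
        summaries[name] = {
            "lambda": dict(zip(map(str, res.groups), res.lam_.tolist())),
            "edf": {str(g): res.edf_[g] for g in res.groups},
            "scale": res.scale, "n_obs": int(res.model.endog.size),
        }
        for g in res.groups:
            curve = res.predict_curve(g, res.default_grid(config.grid_size))
            cf = curve.to_frame()
            cf.insert(0, "group", g)
            cf.insert(0, "series", name)
            curve_rows.append(cf)
    bundle["fits"] = fits
    (outdir / "fit_summaries.json").write_text(json.dumps(summaries, indent=1))
    written.append(outdir / "fit_summaries.json")
    if curve_rows:
        _write(pd.concat(curve_rows, ignore_index=True),
               outdir / "fitted_curves.csv", written)


def _stage_compare(config, bundle, outdir, written):
    seed = stage_seed(config.seed, "compare")
    band_rows, window_summary = [], {}
    for name, res in bundle.get("fits", {}).items():
        pairs = inference.pairwise_differences(
            res, res.default_grid(config.grid_size),
            n_draws=config.n_draws, seed=seed)
        for (ga, gb), (band, windows) in pairs.items():
            bf = band.to_frame()
            bf.insert(0, "pair", f"{ga}-{gb}")
            bf.insert(0, "series", name)
            band_rows.append(bf)
            window_summary.setdefault(name, {})[f"{ga}-{gb}"] = {
                "m_star": band.m_star, "windows": windows.to_records()}
    bundle["comparisons"] = window_summary
    if band_rows:
        _write(pd.concat(band_rows, ignore_index=True),
               outdir / "difference_bands.csv", written)
    (outdir / "significant_windows.json").write_text(
        json.dumps(window_summary, indent=1))
    written.append(outdir / "significant_windows.json")


def _stage_cohort(config, bundle, outdir, written):
    cohort = bundle["cohort"]
    props = cohort_stats.score_proportions(cohort["scores"])
    traj = cohort_stats.score_trajectories(cohort["scores"])
    groups = dict(zip(cohort["mask_table"]["sample_id"],
                      cohort["mask_table"]["group"]))
    mvd = cohort_stats.mvd_table(cohort["masks"], groups)
    test = cohort_stats.compare_mvd(mvd)
    bundle.update({"score_proportions": props, "score_trajectories": traj,
                   "mvd": mvd, "mvd_test": test})
    _write(props, outdir / "score_proportions.csv", written)
    _write(traj, outdir / "score_trajectories.csv", written)
    _write(mvd, outdir / "mvd.csv", written)
    (outdir / "mvd_test.json").write_text(json.dumps(test, indent=1))
    written.append(outdir / "mvd_test.json")


def _stage_report(config, bundle, outdir, written):
    make_report(bundle, outdir / "report")


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "invert": _stage_invert,
    "qpcr": _stage_qpcr,
    "fit": _stage_fit,
    "compare": _stage_compare,
    "cohort": _stage_cohort,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# Reporting


def make_report(bundle: dict, outdir) -> list:
    """Render summary figures from a results bundle; returns written paths.

    Figures with missing inputs are skipped with a log entry; regeneration
    is idempotent.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fits = bundle.get("fits", {})
    for name, res in fits.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for g in res.groups:
            curve = res.predict_curve(g)
            axes[0].plot(curve.grid, curve.mean, label=str(g))
            axes[0].fill_between(curve.grid, curve.lower, curve.upper, alpha=0.2)
        axes[0].set(xlabel="week", ylabel=name, title=f"Fitted trends: {name}")
        axes[0].legend()
        comps = bundle.get("comparisons", {}).get(name, {})
        groups = res.groups
        if len(groups) >= 2:
            ga, gb = groups[0], groups[1]
            band = res.difference(ga, gb)
            axes[1].plot(band.grid, band.diff, color="k")
            axes[1].fill_between(band.grid, band.lower, band.upper,
                                 color="gold", alpha=0.4)
            axes[1].axhline(0.0, color="red", ls=":")
            for s, e, _, _ in inference.significant_windows(band):
                axes[1].axvspan(s, e, color="purple", alpha=0.25)
            axes[1].set(xlabel="week", ylabel=f"{ga} - {gb}",
                        title="Difference with simultaneous 95% band")
        fig.tight_layout()
        path = outdir / f"trend_{name.replace(':', '_')}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
        _ = comps  # windows already drawn from the band itself

    props = bundle.get("score_proportions")
    if props is not None and not props.empty:
        groups = sorted(props["group"].unique())
        fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                                 sharey=True)
        axes = np.atleast_1d(axes)
        for ax, g in zip(axes, groups):
            sub = props[props["group"] == g].pivot(index="week", columns="score",
                                                   values="proportion")
            bottom = np.zeros(len(sub))
            for score in sub.columns:
                ax.bar(sub.index, sub[score].fillna(0), bottom=bottom,
                       label=f"{score:g}")
                bottom += sub[score].fillna(0).to_numpy()
            ax.set(title=str(g), xlabel="week")
        axes[0].set_ylabel("proportion of scores")
        fig.tight_layout()
        path = outdir / "score_proportions.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    else:
        log.info("report: score proportions unavailable; figure skipped")

    mvd = bundle.get("mvd")
    if mvd is not None and not mvd.empty:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        groups = sorted(mvd["group"].dropna().unique())
        ax.violinplot([mvd.loc[mvd["group"] == g, "mvd"] for g in groups],
                      showmedians=True)
        ax.set_xticks(range(1, len(groups) + 1), groups)
        ax.set_ylabel("MVD (% positive of tissue area)")
        test = bundle.get("mvd_test")
        if test:
            ax.set_title(f"Kruskal-Wallis p = {test['pvalue']:.2e}")
        fig.tight_layout()
        path = outdir / "mvd_violin.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    else:
        log.info("report: MVD table unavailable; figure skipped")
    return paths
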