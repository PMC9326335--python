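"""Relative qPCR quantification with efficiency correction (Pfaffl method).

Workflow: quality-filter samples on the 260/280 absorbance ratio, collapse
triplicate wells to a mean Ct (dropping one dispersed well when the
triplicate range exceeds half a cycle), estimate per-primer amplification
efficiency E from standard-curve dilution series (E = 10^(-1/slope)), and
compute the relative expression ratio of each target gene against the
housekeeping gene,

    ratio = E_target^dCt_target / E_ref^dCt_ref,   dCt = Ct_cal - Ct_sample,

with the mean Ct of the control group at week 1 as the calibrator.  When
every efficiency equals 2 this reduces exactly to the classical 2^(-ddCt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENE = "Gapdh"
TRIPLICATE_RANGE_MAX = 0.5  # cycles


def qc_filter(records: pd.DataFrame, lo: float = 1.8, hi: float = 2.0) -> pd.DataFrame:
    """Keep samples whose 260/280 absorbance ratio lies in [lo, hi] (inclusive).

    The 260/280 ratio measures nucleic-acid purity; values outside ~1.8-2.0
    indicate protein or solvent contamination.  Excluded sample ids are
    logged.
    """
    if records.empty:
        return records.copy()
    keep = (records["ratio_260_280"] >= lo) & (records["ratio_260_280"] <= hi)
    dropped = records.loc[~keep, "sample_id"].unique()
    for sid in dropped:
        log.info("qc_filter excluded sample %s (260/280 outside [%g, %g])",
                 sid, lo, hi)
    return records.loc[keep].copy()


def aggregate_triplicates(cts) -> tuple[float, bool]:
    """Collapse 1-3 replicate Cts to a mean.

    If the range exceeds 0.5 cycles, the single value farthest from the
    median is dropped before averaging and the result is flagged.
    Returns (mean Ct, outlier-dropped flag).
    """
    vals = np.asarray([c for c in np.atleast_1d(cts) if np.isfinite(c)], float)
    if vals.size == 0:
        raise ValueError("no finite Ct values in triplicate")
    flagged = False
    if vals.size > 1 and np.ptp(vals) > TRIPLICATE_RANGE_MAX:
        med = np.median(vals)
        vals = np.delete(vals, np.argmax(np.abs(vals - med)))
        flagged = True
    return float(np.mean(vals)), flagged


@dataclass(frozen=True)
class Efficiency:
    """Primer amplification efficiency estimated from a standard curve."""

    gene: str
    e: float  # fold amplification per cycle, > 1
    slope: float
    r_squared: float

    def __post_init__(self):
        if self.e <= 1.0:
            raise ValueError(f"efficiency of {self.gene} must exceed 1")


def efficiency_from_standard_curve(log10_dilutions, cts, gene: str = "") -> Efficiency:
    """Fit Ct versus log10(dilution); E = 10^(-1/slope).

    A serial dilution of template should shift Ct by -1/log10(E) per decade;
    slope >= 0 means the curve did not amplify and is rejected.
    """
    x = np.asarray(log10_dilutions, float)
    y = np.asarray(cts, float)
    if x.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError(f"non-amplifying standard curve for {gene or 'gene'} "
                         f"(slope {slope:.3f} >= 0)")
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return Efficiency(gene=gene, e=float(10.0 ** (-1.0 / slope)),
                      slope=float(slope), r_squared=float(r2))


def efficiencies_from_curves(curves: pd.DataFrame) -> dict[str, Efficiency]:
    """Per-gene efficiencies from a tidy standard-curve table."""
    out = {}
    for gene, sub in curves.groupby("gene"):
        x = (sub["log10_dilution"] if "log10_dilution" in sub
             else np.log10(sub["dilution"]))
        out[gene] = efficiency_from_standard_curve(x, sub["ct"], gene=gene)
    return out


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^dCt_t / E_ref^dCt_ref."""
    if e_target <= 1.0 or e_ref <= 1.0:
        raise ValueError("amplification efficiencies must exceed 1")
    return float(e_target**dct_target / e_ref**dct_ref)


def normalize_expression(
    records: pd.DataFrame,
    efficiencies: dict,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator_group: str = "CG",
    calibrator_week: int = 1,
    calibrator_stat=np.mean,
) -> pd.DataFrame:
    """Pfaffl relative expression of every target gene in every sample.

    `records` is the tidy Ct table (sample_id, tumor_id, group, week, gene,
    ct1..ct3); `efficiencies` maps gene to an `Efficiency` or plain E value.
    The calibrator Ct per gene is the chosen statistic (default: arithmetic
    mean) over the control-group week-1 samples, so the geometric mean of
    the calibrator group-week ratios equals 1 by construction.
    """
    def _e(gene):
        eff = efficiencies[gene]
        return eff.e if isinstance(eff, Efficiency) else float(eff)

    ct_cols = [c for c in ("ct1", "ct2", "ct3") if c in records.columns]
    work = records.copy()
    agg = work.apply(
        lambda r: aggregate_triplicates([r[c] for c in ct_cols]), axis=1)
    work["ct_mean"] = [a[0] for a in agg]
    work["triplicate_flagged"] = [a[1] for a in agg]

    cal = work[(work["group"] == calibrator_group) & (work["week"] == calibrator_week)]
    cal_ct = cal.groupby("gene")["ct_mean"].apply(calibrator_stat).to_dict()
    genes = [g for g in work["gene"].unique() if g != reference_gene]
    missing = [g for g in genes + [reference_gene] if g not in cal_ct]
    if missing:
        raise ValueError(f"no calibrator ({calibrator_group} week {calibrator_week}) "
                         f"samples for gene(s): {missing}")

    ref = work[work["gene"] == reference_gene].set_index("sample_id")["ct_mean"]
    e_ref = _e(reference_gene)
    rows = []
    for _, rec in work[work["gene"] != reference_gene].iterrows():
        sid = rec["sample_id"]
        if sid not in ref.index:
            log.info("sample %s lacks reference-gene Ct; skipped", sid)
            continue
        dct_t = cal_ct[rec["gene"]] - rec["ct_mean"]
        dct_r = cal_ct[reference_gene] - ref.loc[sid]
        rows.append({
            "sample_id": sid, "tumor_id": rec.get("tumor_id"),
            "group": rec["group"], "week": rec["week"], "gene": rec["gene"],
            "relative_expression": pfaffl_ratio(_e(rec["gene"]), dct_t, e_ref, dct_r),
            "dct_target": dct_t, "dct_ref": float(dct_r),
            "triplicate_flagged": bool(rec["triplicate_flagged"]),
        })
    return pd.DataFrame(rows)
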