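"""Tumor-score tallies and microvessel-density (MVD) comparisons.

Endoscopic tumor size is scored on a nine-category ordinal scale
{1, 1.5, ..., 5}; weekly per-group score proportions exclude missing
observations from the denominator.  MVD is the percentage of tissue area
positive for the vessel marker in a 3-class label mask (background /
tissue / positive) and is compared across treatment groups with a
Kruskal-Wallis rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SCORE_CATEGORIES = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

LABEL_BACKGROUND, LABEL_TISSUE, LABEL_POSITIVE = 0, 1, 2


def score_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per group-week proportion of each score among non-missing observations.

    Missing scores are excluded from the denominator; a group-week with no
    valid observations is still emitted, with denominator 0 and null
    proportions.  Within each non-empty group-week the proportions sum to 1.
    """
    bad = records["score"].dropna()[~records["score"].dropna().isin(SCORE_CATEGORIES)]
    if not bad.empty:
        raise ValueError(f"invalid score values: {sorted(bad.unique())}")
    rows = []
    for (group, week), sub in records.groupby(["group", "week"], sort=True):
        present = sub["score"].dropna()
        denom = int(present.size)
        counts = present.value_counts()
        for cat in SCORE_CATEGORIES:
            rows.append({
                "group": group, "week": week, "score": cat,
                "proportion": (counts.get(cat, 0) / denom) if denom else np.nan,
                "denominator": denom,
            })
    return pd.DataFrame(rows)


def score_trajectories(records: pd.DataFrame) -> pd.DataFrame:
    """Week-ordered per-tumor score series with missing weeks marked.

    Raises on duplicate (tumor, week) rows.
    """
    if records.empty:
        return pd.DataFrame(columns=["tumor_id", "group", "week", "score", "missing"])
    dup = records.duplicated(subset=["tumor_id", "week"], keep=False)
    if dup.any():
        first = records.loc[dup, ["tumor_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicate score for tumor {first['tumor_id']} week {first['week']}")
    out = records.sort_values(["tumor_id", "week"]).copy()
    out["missing"] = out["score"].isna()
    return out.reset_index(drop=True)


def compute_mvd(mask: np.ndarray) -> float:
    """MVD percent: 100 * positive / (positive + tissue); background excluded."""
    mask = np.asarray(mask)
    extra = set(np.unique(mask)) - {LABEL_BACKGROUND, LABEL_TISSUE, LABEL_POSITIVE}
    if extra:
        raise ValueError(f"mask contains labels outside {{0,1,2}}: {sorted(extra)}")
    n_pos = int(np.count_nonzero(mask == LABEL_POSITIVE))
    n_tis = int(np.count_nonzero(mask == LABEL_TISSUE))
    if n_pos + n_tis == 0:
        raise ValueError("mask has no tissue pixels; MVD undefined")
    return 100.0 * n_pos / (n_pos + n_tis)


def mvd_table(masks: dict, groups: dict | pd.DataFrame | None = None) -> pd.DataFrame:
    """MVD per (sample, ROI) from a dict of label masks.

    `groups` maps sample_id to group (dict, or a frame with sample_id/group).
    """
    if isinstance(groups, pd.DataFrame):
        groups = dict(zip(groups["sample_id"], groups["group"]))
    rows = []
    for key, mask in masks.items():
        sample, roi = key if isinstance(key, tuple) else (key, 1)
        rows.append({"sample_id": sample, "roi_id": roi,
                     "group": (groups or {}).get(sample),
                     "mvd": compute_mvd(mask)})
    return pd.DataFrame(rows)


def compare_mvd(table: pd.DataFrame, alpha: float = 0.05,
                aggregate_rois: bool = False) -> dict:
    """Kruskal-Wallis comparison of MVD across groups.

    ROI-level values are treated as independent observations by default;
    with ``aggregate_rois=True`` each sample contributes its ROI mean.
    All-tied data short-circuits to H = 0, p = 1.
    """
    work = table.dropna(subset=["mvd", "group"])
    if aggregate_rois:
        work = work.groupby(["sample_id", "group"], as_index=False)["mvd"].mean()
    samples = [sub["mvd"].to_numpy(float) for _, sub in work.groupby("group")]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    medians = work.groupby("group")["mvd"].median().to_dict()
    return {"statistic": float(h), "pvalue": float(p),
            "significant": bool(p < alpha), "alpha": alpha,
            "n_per_group": work.groupby("group")["mvd"].size().to_dict(),
            "medians": medians}
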