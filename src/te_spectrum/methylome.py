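"""Weighted 5-mC methylation levels from shallow-coverage CpG reports.

All levels are weighted (read-pooled): sum of methylated calls over sum of
total calls across the CpGs considered.  Pooling is robust at the shallow
per-CpG depths of skim bisulfite sequencing, where per-CpG fractions are
nearly meaningless.  A level is reported missing (NaN) rather than zero
whenever the summed depth falls below ``min_depth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import RegionSet, write_tsv

log = logging.getLogger(__name__)

DEFAULT_STATUS_THRESHOLDS = {
    "erased_below": 0.15,
    "atrophied_below": 0.35,
    "maintained_below": 0.65,
}


def read_cpg_report(path: str) -> pd.DataFrame:
    """Read a 4-column CpG report (chrom, 0-based pos, meth_count, total_count).

    Zero-total records are retained; they never contribute to levels.
    """
    frame = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "pos", "meth_count", "total_count"],
        dtype={"chrom": str, "pos": int, "meth_count": int, "total_count": int},
    )
    bad = frame["meth_count"] > frame["total_count"]
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"{path}:{line}: meth_count exceeds total_count")
    if (frame[["meth_count", "total_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return frame


def global_methylation(records: pd.DataFrame) -> float:
    """Pooled genome-wide weighted level, NaN when nothing is covered."""
    total = int(records["total_count"].sum())
    if total == 0:
        log.warning("no covered CpGs; global methylation undefined")
        return float("nan")
    return float(records["meth_count"].sum() / total)


@dataclass
class RegionMethylation:
    region_set: str
    label: str
    sample_id: str
    level: float  # NaN when depth < min_depth
    n_cpgs_covered: int
    total_depth: int


def region_methylation(
    records: pd.DataFrame,
    region_sets: list[RegionSet],
    sample_id: str = "sample",
    min_depth: int = 10,
) -> pd.DataFrame:
    """Pooled weighted level per labelled region, per region set.

    CpGs are matched to regions half-open; a region whose summed depth is
    below ``min_depth`` reports a missing level.
    """
    by_chrom = {c: g.sort_values("pos") for c, g in records.groupby("chrom")}
    rows = []
    for rs in region_sets:
        for chrom, iv, label in rs.regions:
            sub = by_chrom.get(chrom)
            if sub is None:
                meth = depth = ncov = 0
            else:
                pos = sub["pos"].to_numpy()
                lo = np.searchsorted(pos, iv.start, side="left")
                hi = np.searchsorted(pos, iv.end, side="left")
                sel = sub.iloc[lo:hi]
                meth = int(sel["meth_count"].sum())
                depth = int(sel["total_count"].sum())
                ncov = int((sel["total_count"] > 0).sum())
            level = meth / depth if depth >= min_depth and depth > 0 else float("nan")
            rows.append(
                {
                    "region_set": rs.name,
                    "label": label,
                    "sample_id": sample_id,
                    "level": level,
                    "n_cpgs_covered": ncov,
                    "total_depth": depth,
                }
            )
    return pd.DataFrame(rows)


def region_set_medians(region_table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, region set): median of per-label levels — the statistic
    shown as the boxplot median of a feature class."""
    return (
        region_table.groupby(["sample_id", "region_set"])["level"]
        .median()
        .rename("median_level")
        .reset_index()
    )


def imprint_status(level: float, thresholds: dict | None = None) -> str:
    """Classify an imprint's methylation level.

    Imprints are parent-of-origin DMRs expected near 50% methylation;
    departures are called ``erased`` (< 0.15), ``atrophied`` ([0.15,
    0.35)), ``maintained`` ([0.35, 0.65]) or ``hyper`` (> 0.65).  The
    cutoffs are package definitions, configurable.
    """
    th = {**DEFAULT_STATUS_THRESHOLDS, **(thresholds or {})}
    if np.isnan(level):
        return "missing"
    if level < th["erased_below"]:
        return "erased"
    if level < th["atrophied_below"]:
        return "atrophied"
    if level <= th["maintained_below"]:
        return "maintained"
    return "hyper"


def imprint_report(
    region_table: pd.DataFrame,
    set_name: str = "imprints",
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Per-imprint heatmap table (label x sample levels) with status calls."""
    sub = region_table.loc[region_table["region_set"] == set_name].copy()
    sub["status"] = [imprint_status(v, thresholds) for v in sub["level"]]
    return sub[["label", "sample_id", "level", "total_depth", "status"]].reset_index(drop=True)


def write_methylation_tables(
    global_levels: pd.DataFrame, region_table: pd.DataFrame, prefix: str
) -> None:
    write_tsv(global_levels, f"{prefix}.global.tsv")
    write_tsv(region_table, f"{prefix}.regions.tsv")
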