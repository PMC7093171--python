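"""Summary statistics for mined SSR loci.

Covers the standard genome-survey quantities: per-type counts and
percentages, relative abundance (loci per Mb of the sequence class
searched), GC content of the repeat spans, total repeat length, canonical
motif rankings, repeat-copy-number (RCN) histograms, and the coefficient of
variability of RCN,

    CV = S / mean(RCN) * 100%

with S the standard deviation of the RCN values of one SSR group (sample SD
by default).  Because a perfect SSR span is exactly its unit repeated rcn
times, GC statistics are computed from (motif, rcn) without re-reading the
genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regions import BASE_CLASSES, RegionClass, RegionModel

__all__ = [
    "REPEAT_TYPE_NAMES",
    "relative_abundance",
    "type_percentage",
    "gc_content",
    "CVStat",
    "cv_of_rcn",
    "rcn_distribution",
    "motif_ranking",
    "complete_count_summary",
    "region_count_totals",
    "summary_by_type",
    "summary_by_region",
    "build_summary_tables",
]

REPEAT_TYPE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def relative_abundance(n_loci: int, region_length_bp: float) -> float:
    """Loci per megabase of searched sequence."""
    if region_length_bp <= 0:
        raise ValueError(f"region length must be positive, got {region_length_bp}")
    return n_loci / (region_length_bp / 1e6)


def type_percentage(n_type: int, n_total: int) -> float:
    """Share of one repeat type among all loci, in percent."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if n_type > n_total:
        raise ValueError("type count exceeds total")
    return n_type / n_total * 100.0


def _gc_bases(motif: str) -> int:
    return sum(1 for b in motif if b in "GCgc")


def gc_content(loci_df: pd.DataFrame) -> float:
    """GC percent pooled over the repeat spans of a locus table.

    Returns NaN (missing) for an empty table rather than 0: an absent group
    has no GC content.
    """
    if len(loci_df) == 0:
        return math.nan
    gc = sum(_gc_bases(m) * r for m, r in zip(loci_df["motif"], loci_df["rcn"]))
    total = int((loci_df["unit_length"] * loci_df["rcn"]).sum())
    return gc / total * 100.0


@dataclass(frozen=True)
class CVStat:
    """Coefficient of variability of repeat copy number for one group."""

    n: int
    mean_rcn: float | None
    sd_rcn: float | None
    cv_percent: float | None
    reason: str | None = None  # why cv is missing, when it is


def cv_of_rcn(rcn_values: Iterable[float], ddof: int = 1) -> CVStat:
    """CV = SD/mean x 100 of a vector of repeat copy numbers.

    Sample SD (ddof=1) by default; pass ddof=0 for the population form.
    Undefined (missing, with a reason code) for fewer than two values or a
    non-positive mean.
    """
    vals = np.asarray(list(rcn_values), dtype=float)
    n = vals.size
    if n < 2:
        return CVStat(n=n, mean_rcn=float(vals.mean()) if n else None,
                      sd_rcn=None, cv_percent=None, reason="n<2")
    mean = float(vals.mean())
    if mean <= 0:
        return CVStat(n=n, mean_rcn=mean, sd_rcn=None, cv_percent=None, reason="mean<=0")
    sd = float(vals.std(ddof=ddof))
    return CVStat(n=n, mean_rcn=mean, sd_rcn=sd, cv_percent=sd / mean * 100.0)


def rcn_distribution(
    assigned_df: pd.DataFrame, by: tuple[str, ...] = ("unit_length",)
) -> pd.DataFrame:
    """Exact integer histogram of rcn within each group.

    Columns: grouping keys, ``rcn``, ``count``; bins are the observed rcn
    values, so counts within a group sum to the group size.
    """
    cols = list(by) + ["rcn"]
    out = assigned_df.groupby(cols, observed=True).size().reset_index(name="count")
    return out.sort_values(cols).reset_index(drop=True)


def motif_ranking(
    loci_df: pd.DataFrame, region_length_bp: float, top: int | None = None
) -> pd.DataFrame:
    """Canonical motifs ranked by relative abundance within each unit length.

    Ties break lexicographically on the motif.  Returns columns
    unit_length, canonical_motif, n_loci, relative_abundance.
    """
    if len(loci_df) == 0:
        return pd.DataFrame(
            columns=["unit_length", "canonical_motif", "n_loci", "relative_abundance"]
        )
    counts = (
        loci_df.groupby(["unit_length", "canonical_motif"], observed=True)
        .size()
        .reset_index(name="n_loci")
    )
    counts["relative_abundance"] = [
        relative_abundance(n, region_length_bp) for n in counts["n_loci"]
    ]
    counts = counts.sort_values(
        ["unit_length", "relative_abundance", "canonical_motif"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    if top is not None:
        counts = (
            counts.groupby("unit_length", observed=True)
            .head(top)
            .reset_index(drop=True)
        )
    return counts


def complete_count_summary(counts_by_type: Mapping[int, int]) -> pd.DataFrame:
    """Total and per-type percentages from per-unit-length locus counts.

    This is the arithmetic skeleton of a genome-wide per-type overview table:
    given the six counts it appends the total row and the percentage column.
    """
    rows = []
    total = int(sum(counts_by_type.values()))
    for k in sorted(counts_by_type):
        n = int(counts_by_type[k])
        rows.append(
            {
                "repeat_type": REPEAT_TYPE_NAMES.get(k, str(k)),
                "unit_length": k,
                "n_loci": n,
                "percentage": type_percentage(n, total) if total else math.nan,
            }
        )
    rows.append(
        {
            "repeat_type": "total",
            "unit_length": 0,
            "n_loci": total,
            "percentage": 100.0 if total else math.nan,
        }
    )
    return pd.DataFrame(rows)


def region_count_totals(counts: Mapping[str, Mapping[int, int]]) -> dict[str, int]:
    """Per-region totals of per-type counts (column sums of a region table)."""
    return {region: int(sum(by_type.values())) for region, by_type in counts.items()}


def summary_by_type(loci_df: pd.DataFrame, genome_length_bp: int) -> pd.DataFrame:
    """Genome-wide per-repeat-type overview.

    One row per unit length plus a total row: count, GC percent of the
    repeat spans, total repeat length, relative abundance and percentage.
    """
    rows = []
    total_n = len(loci_df)
    for k in range(1, 7):
        sub = loci_df[loci_df["unit_length"] == k]
        rows.append(
            {
                "repeat_type": REPEAT_TYPE_NAMES[k],
                "unit_length": k,
                "n_loci": len(sub),
                "gc_percent": gc_content(sub),
                "total_length_bp": int(sub["length_bp"].sum()),
                "relative_abundance": relative_abundance(len(sub), genome_length_bp),
                "percentage": type_percentage(len(sub), total_n) if total_n else math.nan,
            }
        )
    rows.append(
        {
            "repeat_type": "total",
            "unit_length": 0,
            "n_loci": total_n,
            "gc_percent": gc_content(loci_df),
            "total_length_bp": int(loci_df["length_bp"].sum()),
            "relative_abundance": relative_abundance(total_n, genome_length_bp),
            "percentage": 100.0 if total_n else math.nan,
        }
    )
    return pd.DataFrame(rows)


def _region_subset(assigned_df: pd.DataFrame, region: RegionClass) -> pd.DataFrame:
    if region is RegionClass.TE:
        return assigned_df[assigned_df["te"]]
    return assigned_df[assigned_df["region"] == region.value]


def summary_by_region(assigned_df: pd.DataFrame, model: RegionModel) -> pd.DataFrame:
    """Per-repeat-type, per-region counts and relative abundances.

    The five base classes partition the loci by their start coordinate; the
    TE column counts loci whose start lies inside the TE overlay (these also
    appear in their base class, mirroring an overlay-style tally).
    Relative abundance uses the merged total length of each class.
    """
    rows = []
    for region in list(BASE_CLASSES) + [RegionClass.TE]:
        sub = _region_subset(assigned_df, region)
        length = model.total_length_bp[region]
        for k in range(1, 7):
            n = int((sub["unit_length"] == k).sum())
            rows.append(
                {
                    "region": region.value,
                    "repeat_type": REPEAT_TYPE_NAMES[k],
                    "unit_length": k,
                    "n_loci": n,
                    "relative_abundance": relative_abundance(n, length) if length else math.nan,
                    "gc_percent": gc_content(sub[sub["unit_length"] == k]),
                }
            )
        rows.append(
            {
                "region": region.value,
                "repeat_type": "total",
                "unit_length": 0,
                "n_loci": len(sub),
                "relative_abundance": relative_abundance(len(sub), length) if length else math.nan,
                "gc_percent": gc_content(sub),
            }
        )
    return pd.DataFrame(rows)


def build_summary_tables(
    assigned_df: pd.DataFrame,
    model: RegionModel,
    top_motifs: int = 6,
) -> dict[str, pd.DataFrame]:
    """All three report tables from an assigned locus table.

    Returns ``by_type`` (genome-wide overview), ``by_motif`` (motif ranking)
    and ``by_region`` (region-resolved counts).
    """
    return {
        "by_type": summary_by_type(assigned_df, model.genome_length_bp),
        "by_motif": motif_ranking(assigned_df, model.genome_length_bp, top=top_motifs),
        "by_region": summary_by_region(assigned_df, model),
    }
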