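"""Interval annotation of core regions and between-line haplotype contrasts.

Feature files (genes, QTLs) come in as user-supplied BED (0-based
half-open) and are held internally as 1-based inclusive intervals, the
same convention as the panel and all region outputs.  Regions that
overlap no feature are reported with ``"/"`` in the feature column.

The between-line contrast reconstructs the core-haplotype count table
from two panels and applies a chi-square test of homogeneity, pooling
rare haplotypes to protect expected counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .ld import CoreRegion
from .panel import HaplotypePanel

__all__ = [
    "GenomicInterval",
    "ContrastResult",
    "read_intervals",
    "write_intervals",
    "overlap_regions",
    "haplotype_contrast",
]

NO_FEATURE = "/"


@dataclass(frozen=True)
class GenomicInterval:
    """One feature interval, stored 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.chrom}:{self.start}-{self.end}")


def read_intervals(path: str | os.PathLike, source: str = "") -> list[GenomicInterval]:
    """Read a 3+ column BED (0-based half-open) into 1-based inclusive
    intervals, sorted by (chrom, start, end).  Malformed lines raise with
    their line number; ``track``/``browser``/``#`` lines are skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln_no}: expected >= 3 BED columns, got {len(parts)}")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln_no}: non-integer coordinates") from exc
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}:{ln_no}: invalid BED interval {start0}-{end0}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start0}-{end0}"
            out.append(GenomicInterval(parts[0], start0 + 1, end0, name, source))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals back to BED (0-based half-open); round-trips
    :func:`read_intervals` exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")


def overlap_regions(
    regions: list[CoreRegion], features: list[GenomicInterval]
) -> pd.DataFrame:
    """One row per (region, feature) pair with >= 1 bp overlap on the
    same chromosome; regions with no overlapping feature get one row
    with ``"/"`` as the feature."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    rows = []
    for region in regions:
        hits = [
            iv for iv in by_chrom.get(region.chrom, [])
            if iv.start <= region.end_pos and iv.end >= region.start_pos
        ]
        if not hits:
            rows.append({
                "chrom": region.chrom, "region_start": region.start_pos,
                "region_end": region.end_pos, "feature": NO_FEATURE,
                "feature_start": pd.NA, "feature_end": pd.NA,
                "overlap_bp": 0, "source": "",
            })
            continue
        for iv in hits:
            ov = min(region.end_pos, iv.end) - max(region.start_pos, iv.start) + 1
            rows.append({
                "chrom": region.chrom, "region_start": region.start_pos,
                "region_end": region.end_pos, "feature": iv.name,
                "feature_start": iv.start, "feature_end": iv.end,
                "overlap_bp": ov, "source": iv.source,
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "region_start", "region_end", "feature",
        "feature_start", "feature_end", "overlap_bp", "source",
    ])


@dataclass
class ContrastResult:
    """Chi-square homogeneity test of core-haplotype counts between lines."""

    region: CoreRegion
    table: pd.DataFrame      # haplotype x line counts (after pooling)
    chi2_stat: float
    df: int
    p_value: float
    pooled_rare: bool
    status: str              # "ok" or "undefined"


def haplotype_contrast(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    region: CoreRegion,
    min_expected: float = 1.0,
) -> ContrastResult:
    """Compare core-haplotype frequencies between two lines at one region.

    ``region.marker_indices`` refer to ``panel_a`` (the panel the region
    was detected in); the same markers are located in ``panel_b`` by
    (chrom, pos).  The haplotype x line count table is built from allele
    strings over those markers; haplotypes are pooled
    smallest-total-first into ``"other"`` until every expected count
    reaches ``min_expected``, then a chi-square test of homogeneity (no
    continuity correction) is applied.
    """
    positions = [int(panel_a.markers["pos"].iloc[i]) for i in region.marker_indices]
    counts: dict[str, list[int]] = {}
    for k, panel in enumerate((panel_a, panel_b)):
        chrom_mask = (panel.markers["chrom"] == region.chrom).to_numpy()
        lookup = {
            int(p): int(i) for i, p in zip(
                np.flatnonzero(chrom_mask),
                panel.markers.loc[chrom_mask, "pos"],
            )
        }
        missing = [p for p in positions if p not in lookup]
        if missing:
            raise KeyError(
                f"marker position(s) {missing} of region {region.chrom}:"
                f"{region.start_pos}-{region.end_pos} missing from panel "
                f"{panel.line_label or ('a' if k == 0 else 'b')}"
            )
        sub = panel.haplotypes[:, [lookup[p] for p in positions]]
        for row in sub:
            s = "".join(map(str, row))
            counts.setdefault(s, [0, 0])[k] += 1
    table = pd.DataFrame(counts, index=["a", "b"]).T
    table.columns = [panel_a.line_label or "line_a", panel_b.line_label or "line_b"]
    table = table.sort_values(list(table.columns), ascending=False)

    pooled = False
    while len(table) > 2:
        exp = _expected(table.to_numpy())
        if exp.min() >= min_expected:
            break
        # pool the smallest-total haplotype into "other"
        totals = table.sum(axis=1)
        victim = totals.idxmin()
        if "other" not in table.index:
            table.loc["other"] = 0
        if victim == "other":  # only "other" left below threshold
            break
        table.loc["other"] += table.loc[victim]
        table = table.drop(index=victim)
        pooled = True

    arr = table.to_numpy()
    arr = arr[arr.sum(axis=1) > 0]
    if arr.shape[0] < 2:
        return ContrastResult(region, table, np.nan, 0, np.nan, pooled, "undefined")
    chi2, p, dof, _ = chi2_contingency(arr, correction=False)
    return ContrastResult(region, table, float(chi2), int(dof), float(p), pooled, "ok")


def _expected(arr: np.ndarray) -> np.ndarray:
    total = arr.sum()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
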