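"""Extended haplotype homozygosity (EHH) and relative EHH (REHH).

EHH of a core haplotype at a locus is the probability that two randomly
chosen chromosomes carrying that core haplotype are identical over the
entire interval from the core region out to the locus:

    EHH = sum_i C(e_i, 2) / C(c, 2)

where ``c`` carriers split into extension groups of sizes ``e_i``.
EHH-bar is the same quantity on all non-carrier chromosomes pooled, with
the interval including the core region itself (so chromosomes with
different core haplotypes are never counted homozygous).  REHH is
EHH_t / EHH-bar at a fixed distance (1 Mb by default) from the core
boundary, on each side; it corrects EHH for local recombination-rate
variation, making high-frequency long-haplotype outliers comparable
across the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .ld import CoreRegion
from .panel import HaplotypePanel

__all__ = [
    "CoreHaplotype",
    "EHHCurve",
    "REHHRecord",
    "UPSTREAM",
    "DOWNSTREAM",
    "core_haplotypes",
    "ehh_at",
    "ehh_bar_at",
    "ehh_decay",
    "rehh_test",
]

UPSTREAM = "upstream"      # decreasing bp
DOWNSTREAM = "downstream"  # increasing bp

STATUS_OK = "ok"
STATUS_TRUNCATED = "truncated_end"
STATUS_UNDEFINED_BAR = "undefined_bar"
STATUS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class CoreHaplotype:
    """One distinct allele string over a core region's markers."""

    region: CoreRegion
    allele_string: str
    carrier_rows: tuple[int, ...]

    @property
    def carrier_count(self) -> int:
        return len(self.carrier_rows)

    def frequency(self, n_haplotypes: int) -> float:
        return self.carrier_count / n_haplotypes


@dataclass
class EHHCurve:
    """EHH and pooled-other EHH evaluated marker by marker outward."""

    core: CoreHaplotype
    direction: str
    eval_positions: np.ndarray
    ehh_values: np.ndarray
    ehh_bar_values: np.ndarray  # NaN where EHH-bar is undefined


@dataclass
class REHHRecord:
    """One EHH test: a core haplotype in one direction at ~1 Mb."""

    chrom: str
    region_start: int
    region_end: int
    allele_string: str
    carrier_count: int
    frequency: float
    direction: str
    target_distance_bp: int
    eval_pos: int | None
    ehh_t: float
    ehh_bar: float
    rehh: float
    status: str


def core_haplotypes(panel: HaplotypePanel, region: CoreRegion) -> list[CoreHaplotype]:
    """Enumerate the distinct allele strings over a region's markers.

    Sorted by descending carrier count, ties broken lexicographically by
    allele string; carrier counts partition the panel's H chromosomes.
    """
    sub = panel.haplotypes[:, list(region.marker_indices)]
    strings = ["".join(map(str, row)) for row in sub]
    groups: dict[str, list[int]] = {}
    for row, s in enumerate(strings):
        groups.setdefault(s, []).append(row)
    out = [
        CoreHaplotype(region=region, allele_string=s, carrier_rows=tuple(rows))
        for s, rows in groups.items()
    ]
    out.sort(key=lambda ch: (-ch.carrier_count, ch.allele_string))
    return out


def _pair_homozygosity(sub: np.ndarray) -> float:
    """P(two random distinct rows of ``sub`` are identical) by pair counting."""
    n = sub.shape[0]
    if n < 2:
        raise ValueError("pair homozygosity needs >= 2 rows")
    if sub.shape[1] == 0:
        return 1.0
    groups: dict[bytes, int] = {}
    for row in np.ascontiguousarray(sub):
        key = row.tobytes()
        groups[key] = groups.get(key, 0) + 1
    return sum(comb(e, 2) for e in groups.values()) / comb(n, 2)


def _extension_columns(
    panel: HaplotypePanel, region: CoreRegion, direction: str, eval_marker: int
) -> list[int]:
    gstart, gend = region.marker_indices[0], region.marker_indices[-1]
    chrom_idx = panel.chrom_indices(region.chrom)
    if eval_marker not in chrom_idx:
        raise ValueError(f"eval marker {eval_marker} is not on chromosome {region.chrom}")
    if direction == DOWNSTREAM:
        if eval_marker <= gend:
            raise ValueError("eval marker must lie strictly beyond the region end")
        return list(range(gend + 1, eval_marker + 1))
    if direction == UPSTREAM:
        if eval_marker >= gstart:
            raise ValueError("eval marker must lie strictly before the region start")
        return list(range(eval_marker, gstart))
    raise ValueError(f"unknown direction {direction!r}")


def ehh_at(
    panel: HaplotypePanel, core: CoreHaplotype, direction: str, eval_marker: int
) -> float:
    """EHH of ``core`` at a marker strictly beyond the region boundary."""
    if core.carrier_count < 2:
        raise ValueError("EHH undefined for a singleton core haplotype")
    cols = _extension_columns(panel, core.region, direction, eval_marker)
    sub = panel.haplotypes[np.asarray(core.carrier_rows), :][:, cols]
    return _pair_homozygosity(sub)


def ehh_bar_at(
    panel: HaplotypePanel, core: CoreHaplotype, direction: str, eval_marker: int
) -> float:
    """Pooled-other EHH: all chromosomes NOT carrying ``core``, grouped by
    the allele string spanning the core region plus the extension."""
    others = np.setdiff1d(
        np.arange(panel.n_haplotypes), np.asarray(core.carrier_rows)
    )
    if len(others) < 2:
        raise ValueError("EHH-bar undefined with fewer than 2 other chromosomes")
    ext = _extension_columns(panel, core.region, direction, eval_marker)
    cols = list(core.region.marker_indices) + ext
    sub = panel.haplotypes[others, :][:, cols]
    return _pair_homozygosity(sub)


def ehh_decay(
    panel: HaplotypePanel, core: CoreHaplotype, direction: str
) -> EHHCurve:
    """EHH and EHH-bar at every marker outward until EHH hits 0 or the
    chromosome end.  Values are non-increasing with distance because each
    added marker can only refine the extension partition."""
    region = core.region
    if core.carrier_count < 2:
        raise ValueError("EHH undefined for a singleton core haplotype")
    chrom_idx = panel.chrom_indices(region.chrom)
    gstart, gend = region.marker_indices[0], region.marker_indices[-1]
    if direction == DOWNSTREAM:
        evals = chrom_idx[chrom_idx > gend]
    else:
        evals = chrom_idx[chrom_idx < gstart][::-1]
    carriers = np.asarray(core.carrier_rows)
    others = np.setdiff1d(np.arange(panel.n_haplotypes), carriers)
    bar_ok = len(others) >= 2
    # incremental partition refinement: group labels split as columns accrue
    lab_c = np.zeros(len(carriers), dtype=np.int64)
    lab_o = np.zeros(len(others), dtype=np.int64)
    if bar_ok:  # EHH-bar interval includes the core region itself
        for col in region.marker_indices:
            lab_o = _refine(lab_o, panel.haplotypes[others, col])
    positions, ehh_vals, bar_vals = [], [], []
    pos_all = panel.markers["pos"].to_numpy()
    for g in evals:
        lab_c = _refine(lab_c, panel.haplotypes[carriers, g])
        ehh = _label_homozygosity(lab_c)
        if bar_ok:
            lab_o = _refine(lab_o, panel.haplotypes[others, g])
            bar = _label_homozygosity(lab_o)
        else:
            bar = np.nan
        positions.append(int(pos_all[g]))
        ehh_vals.append(ehh)
        bar_vals.append(bar)
        if ehh == 0.0:
            break
    return EHHCurve(
        core=core,
        direction=direction,
        eval_positions=np.asarray(positions, dtype=np.int64),
        ehh_values=np.asarray(ehh_vals, dtype=float),
        ehh_bar_values=np.asarray(bar_vals, dtype=float),
    )


def _refine(labels: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    combined = labels * 2 + alleles.astype(np.int64)
    _, new = np.unique(combined, return_inverse=True)
    return new


def _label_homozygosity(labels: np.ndarray) -> float:
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    return sum(comb(int(e), 2) for e in counts) / comb(n, 2)


def rehh_test(
    panel: HaplotypePanel,
    core: CoreHaplotype,
    direction: str,
    target_distance_bp: int = 1_000_000,
    from_midpoint: bool = False,
) -> REHHRecord:
    """REHH = EHH_t / EHH-bar at the first marker >= the target distance.

    The distance is measured from the region boundary marker in the
    direction of travel (optionally from the region midpoint).  When no
    marker that far exists, the last marker on the chromosome is used
    and the record is flagged ``truncated_end``; EHH-bar = 0 yields
    ``undefined_bar``, and violated preconditions yield ``undefined`` —
    batch callers never see an exception for these.
    """
    region = core.region
    rec = REHHRecord(
        chrom=region.chrom,
        region_start=region.start_pos,
        region_end=region.end_pos,
        allele_string=core.allele_string,
        carrier_count=core.carrier_count,
        frequency=core.frequency(panel.n_haplotypes),
        direction=direction,
        target_distance_bp=target_distance_bp,
        eval_pos=None,
        ehh_t=np.nan,
        ehh_bar=np.nan,
        rehh=np.nan,
        status=STATUS_UNDEFINED,
    )
    c = core.carrier_count
    if c < 2 or panel.n_haplotypes - c < 2:
        return rec
    chrom_idx = panel.chrom_indices(region.chrom)
    pos_all = panel.markers["pos"].to_numpy()
    gstart, gend = region.marker_indices[0], region.marker_indices[-1]
    if from_midpoint:
        anchor = (region.start_pos + region.end_pos) // 2
    else:
        anchor = region.end_pos if direction == DOWNSTREAM else region.start_pos
    if direction == DOWNSTREAM:
        outside = chrom_idx[chrom_idx > gend]
        far = outside[pos_all[outside] - anchor >= target_distance_bp]
        eval_marker = int(far[0]) if len(far) else (int(outside[-1]) if len(outside) else None)
        truncated = len(far) == 0
    elif direction == UPSTREAM:
        outside = chrom_idx[chrom_idx < gstart]
        far = outside[anchor - pos_all[outside] >= target_distance_bp]
        eval_marker = int(far[-1]) if len(far) else (int(outside[0]) if len(outside) else None)
        truncated = len(far) == 0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if eval_marker is None:  # region abuts the terminal marker
        return rec
    rec.eval_pos = int(pos_all[eval_marker])
    rec.ehh_t = ehh_at(panel, core, direction, eval_marker)
    rec.ehh_bar = ehh_bar_at(panel, core, direction, eval_marker)
    if rec.ehh_bar == 0.0:
        rec.status = STATUS_UNDEFINED_BAR
        rec.rehh = np.nan
        return rec
    rec.rehh = rec.ehh_t / rec.ehh_bar
    rec.status = STATUS_TRUNCATED if truncated else STATUS_OK
    return rec
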