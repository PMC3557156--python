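"""Phased haplotype panels: containers, readers, writers, marker filters.

A panel is the substrate of every downstream stage: an H x M matrix of
0/1 alleles (rows = haplotypes, columns = markers) plus a marker map
(chromosome, 1-based position, allele codes) and per-haplotype sample
labels.  Two haplotypes of one diploid individual share a sample stem
and carry ``_1`` / ``_2`` suffixes.

Input is assumed fully phased and complete: phasing/imputation happen
upstream, so unphased or missing genotypes are hard errors here, never
silently imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "HaplotypePanel",
    "FilterReport",
    "PanelError",
    "read_phased_vcf",
    "read_hap_legend",
    "write_panel",
    "allele_frequencies",
    "filter_markers",
    "concat_panels",
]

#: chromosome label reserved for markers whose position is unknown
UNPLACED_CHROM = "un"

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class PanelError(ValueError):
    """Raised on malformed panel input (unphased, missing, inconsistent)."""


class Marker(NamedTuple):
    """One biallelic SNP: chromosome, 1-based bp position, allele codes."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str


def _is_placed(chrom: pd.Series, pos: pd.Series) -> pd.Series:
    return (pos >= 1) & (chrom != UNPLACED_CHROM) & (chrom != "")


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix with marker map and sample labels.

    Parameters
    ----------
    markers : DataFrame with columns ``chrom, pos, id, ref, alt``,
        one row per matrix column.  Chromosome blocks are contiguous
        (first-appearance order) and positions strictly increase within
        each chromosome; duplicate (chrom, pos) pairs are rejected
        because EHH distance grids require a strict marker ordering.
        Markers with unknown position (``pos < 1`` or chromosome
        ``"un"``) are tolerated until :func:`filter_markers` drops them.
    haplotypes : (H, M) array over {0, 1}; H >= 4.
    sample_ids : H labels; haplotype pairs share a sample stem.
    line_label : population tag, e.g. ``"lean"`` or ``"fat"``.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    line_label: str = ""

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D (H x M)")
        h, m = self.haplotypes.shape
        if h < 4:
            raise PanelError(f"need at least 4 haplotypes, got {h}")
        if list(self.markers.columns[: len(MARKER_COLUMNS)]) != MARKER_COLUMNS:
            raise PanelError(f"marker table must have columns {MARKER_COLUMNS}")
        if len(self.markers) != m:
            raise PanelError(
                f"marker table has {len(self.markers)} rows but matrix has {m} columns"
            )
        if not self.sample_ids:
            self.sample_ids = [f"hap_{i}" for i in range(h)]
        if len(self.sample_ids) != h:
            raise PanelError("sample_ids length must equal haplotype count")
        vals = np.unique(self.haplotypes)
        if not np.all(np.isin(vals, [0, 1])):
            raise PanelError(f"matrix entries must be 0/1, found {vals}")
        self.markers = self.markers.reset_index(drop=True)
        self._validate_markers()

    def _validate_markers(self) -> None:
        mk = self.markers
        if (mk["chrom"].astype(str) == "").any():
            raise PanelError("empty chromosome label")
        if (mk["ref"] == mk["alt"]).any():
            bad = mk.loc[mk["ref"] == mk["alt"]].iloc[0]
            raise PanelError(f"ref == alt at {bad['chrom']}:{bad['pos']}")
        placed = _is_placed(mk["chrom"], mk["pos"])
        # chromosome blocks must be contiguous
        chrom_codes = mk["chrom"].ne(mk["chrom"].shift()).cumsum()
        if mk.groupby("chrom", sort=False)["chrom"].count().size != chrom_codes.max():
            raise PanelError("chromosome blocks are not contiguous")
        for chrom, grp in mk.loc[placed].groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if (d <= 0).any():
                j = int(np.argmax(d <= 0))
                raise PanelError(
                    f"markers not strictly increasing on {chrom} near pos "
                    f"{int(grp['pos'].iloc[j + 1])} (duplicate or unsorted)"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return self.markers["pos"].to_numpy()
        return self.markers.loc[self.markers["chrom"] == chrom, "pos"].to_numpy()

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Global column indices of the markers on one chromosome."""
        cache = self.__dict__.setdefault("_chrom_idx_cache", {})
        if chrom not in cache:
            cache[chrom] = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        return cache[chrom]

    def marker(self, i: int) -> Marker:
        row = self.markers.iloc[i]
        return Marker(str(row["chrom"]), int(row["pos"]), str(row["id"]),
                      str(row["ref"]), str(row["alt"]))

    def subset(self, marker_indices: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(marker_indices, dtype=int)
        return HaplotypePanel(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[:, idx],
            sample_ids=list(self.sample_ids),
            line_label=self.line_label,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.markers.reset_index(drop=True).equals(other.markers.reset_index(drop=True))
            and np.array_equal(self.haplotypes, other.haplotypes)
            and self.sample_ids == other.sample_ids
        )


@dataclass
class FilterReport:
    """Bookkeeping for marker filtering, categories disjoint and ordered:
    unplaced markers are dropped first, then monomorphic ones, then the
    MAF cut, so ``n_input = n_retained + sum(removals)`` always holds."""

    n_input: int
    n_removed_unplaced: int
    n_removed_monomorphic: int
    n_removed_maf: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (self.n_removed_unplaced + self.n_removed_monomorphic
                 + self.n_removed_maf + self.n_retained)
        if total != self.n_input:
            raise ValueError("filter report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-marker statistics and filtering
# ---------------------------------------------------------------------------

def allele_frequencies(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-marker stats: ``maf`` (minor allele frequency, in [0, 0.5]),
    ``is_monomorphic`` and ``has_position`` flags."""
    p = panel.haplotypes.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame({
        "maf": maf,
        "is_monomorphic": maf == 0.0,
        "has_position": _is_placed(panel.markers["chrom"], panel.markers["pos"]).to_numpy(),
    })


def filter_markers(
    panel: HaplotypePanel, min_maf: float = 0.05
) -> tuple[HaplotypePanel, FilterReport]:
    """Drop unplaced, monomorphic and low-MAF markers, in that order.

    Markers with ``maf < min_maf`` are removed (strict inequality, the
    chip-QC convention).  Categories are disjoint: a monomorphic marker
    counts as monomorphic, never under the MAF cut.
    """
    stats = allele_frequencies(panel)
    unplaced = ~stats["has_position"].to_numpy()
    mono = stats["is_monomorphic"].to_numpy() & ~unplaced
    low = (stats["maf"].to_numpy() < min_maf) & ~mono & ~unplaced
    keep = ~(unplaced | mono | low)
    report = FilterReport(
        n_input=panel.n_markers,
        n_removed_unplaced=int(unplaced.sum()),
        n_removed_monomorphic=int(mono.sum()),
        n_removed_maf=int(low.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise PanelError(
            "all markers removed by filtering; review min_maf "
            f"({min_maf}) and input marker map"
        )
    return panel.subset(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | os.PathLike, line_label: str = "") -> HaplotypePanel:
    """Read a fully phased VCF of biallelic SNPs into a panel.

    Alleles are coded 0 = REF, 1 = ALT; every diploid sample contributes
    two haplotype rows.  Multiallelic sites, unphased genotypes and
    missing calls are hard errors naming the offending record.
    Out-of-order sites are re-sorted ascending within each chromosome,
    with matrix columns permuted consistently.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise PanelError(f"multiallelic site at {where} (ALT={var.ALT})")
        gts = var.genotypes  # per sample: [allele0, allele1, phased]
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for k, gt in enumerate(gts):
            if len(gt) < 3:
                raise PanelError(f"non-diploid genotype at {where}, sample {samples[k]}")
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise PanelError(f"missing genotype at {where}, sample {samples[k]}")
            if not phased:
                raise PanelError(f"unphased genotype at {where}, sample {samples[k]}")
            col[2 * k] = a0
            col[2 * k + 1] = a1
        rows.append({
            "chrom": var.CHROM, "pos": int(var.POS),
            "id": var.ID or f"{var.CHROM}:{var.POS}",
            "ref": var.REF, "alt": var.ALT[0],
        })
        cols.append(col)
    vcf.close()
    if not rows:
        raise PanelError(f"no variant records in {path}")
    markers = pd.DataFrame(rows)
    matrix = np.column_stack(cols)
    # stable sort: chromosome blocks in first-appearance order, pos ascending
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(markers["chrom"]))}
    order = np.lexsort((markers["pos"].to_numpy(),
                        markers["chrom"].map(chrom_order).to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    matrix = matrix[:, order]
    sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return HaplotypePanel(markers, matrix, sample_ids, line_label)


def read_hap_legend(
    hap_path: str | os.PathLike,
    legend_path: str | os.PathLike,
    samples_path: str | os.PathLike | None = None,
    line_label: str = "",
) -> HaplotypePanel:
    """Read an IMPUTE-style ``.hap`` / ``.legend`` pair.

    ``.hap`` holds one whitespace-separated 0/1 row per marker (columns
    are haplotypes); ``.legend`` has a header and columns
    ``id pos allele0 allele1 [chrom]``.  If a ``.samples`` file sits next
    to the ``.hap`` file (or is given explicitly) its lines become the
    haplotype labels.
    """
    legend = pd.read_csv(legend_path, sep=r"\s+")
    need = {"id", "pos", "allele0", "allele1"}
    if not need.issubset(legend.columns):
        raise PanelError(
            f"legend must have columns id pos allele0 allele1 [chrom], got {list(legend.columns)}"
        )
    raw = pd.read_csv(hap_path, sep=r"\s+", header=None, dtype=str)
    if len(raw) != len(legend):
        raise PanelError(
            f"row-count mismatch: hap has {len(raw)} rows, legend has {len(legend)}"
        )
    tokens = raw.to_numpy()
    if not np.isin(tokens, ["0", "1"]).all():
        bad = tokens[~np.isin(tokens, ["0", "1"])][0]
        raise PanelError(f"non-0/1 token in hap file: {bad!r}")
    matrix = tokens.astype(np.uint8).T  # -> H x M
    markers = pd.DataFrame({
        "chrom": legend["chrom"].astype(str) if "chrom" in legend.columns
                 else ["1"] * len(legend),
        "pos": legend["pos"].astype(int),
        "id": legend["id"].astype(str),
        "ref": legend["allele0"].astype(str),
        "alt": legend["allele1"].astype(str),
    })
    sample_ids: list[str] = []
    if samples_path is None:
        guess = os.path.splitext(str(hap_path))[0] + ".samples"
        if os.path.exists(guess):
            samples_path = guess
    if samples_path is not None:
        with open(samples_path) as fh:
            sample_ids = [ln.strip() for ln in fh if ln.strip()]
    return HaplotypePanel(markers, matrix, sample_ids, line_label)


def write_panel(panel: HaplotypePanel, prefix: str | os.PathLike) -> dict[str, str]:
    """Write ``<prefix>.hap``, ``<prefix>.legend`` and ``<prefix>.samples``.

    The pair round-trips exactly through :func:`read_hap_legend`.
    """
    if panel.n_markers == 0:
        raise PanelError("refusing to write a panel with no markers")
    prefix = str(prefix)
    paths = {
        "hap": prefix + ".hap",
        "legend": prefix + ".legend",
        "samples": prefix + ".samples",
    }
    legend = pd.DataFrame({
        "id": panel.markers["id"],
        "pos": panel.markers["pos"].astype(int),
        "allele0": panel.markers["ref"],
        "allele1": panel.markers["alt"],
        "chrom": panel.markers["chrom"],
    })
    legend.to_csv(paths["legend"], sep=" ", index=False)
    np.savetxt(paths["hap"], panel.haplotypes.T, fmt="%d", delimiter=" ")
    with open(paths["samples"], "w") as fh:
        fh.write("\n".join(panel.sample_ids) + "\n")
    return paths


def concat_panels(panels: Sequence[HaplotypePanel]) -> HaplotypePanel:
    """Concatenate panels over disjoint chromosomes (same haplotype rows)."""
    if not panels:
        raise PanelError("nothing to concatenate")
    h = panels[0].n_haplotypes
    for p in panels[1:]:
        if p.n_haplotypes != h:
            raise PanelError("panels differ in haplotype count")
    seen: set[str] = set()
    for p in panels:
        dup = seen.intersection(p.chroms)
        if dup:
            raise PanelError(f"duplicate chromosomes across panels: {sorted(dup)}")
        seen.update(p.chroms)
    return HaplotypePanel(
        markers=pd.concat([p.markers for p in panels], ignore_index=True),
        haplotypes=np.hstack([p.haplotypes for p in panels]),
        sample_ids=list(panels[0].sample_ids),
        line_label=panels[0].line_label,
    )
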