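"""Frequency-binned significance of REHH tests and the genome scan driver.

Selection signatures are high-REHH outliers *relative to haplotypes of
comparable frequency*: REHH grows mechanically with core-haplotype
frequency, so tests are ordered into frequency bins (20 equal-width bins
over (0, 1] by default) and each record's p-value is its upper-tail
rank among the same-bin records.  The default empirical p-value is

    p_i = #{j in bin : REHH_j >= REHH_i} / n_bin

(self included, so p >= 1/n_bin; ties counted inclusively).  A
log-normal tail fit is offered as an alternative.  Significance is a
raw-p threshold (alpha = 0.01 by default); a Benjamini-Hochberg column
is emitted for convenience but never drives the significant flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import ehh as ehh_mod
from .ehh import DOWNSTREAM, UPSTREAM, core_haplotypes, rehh_test
from .ld import CoreRegion, detect_core_regions, summarize_core_regions
from .panel import HaplotypePanel

__all__ = [
    "ScanConfig",
    "ScanResult",
    "bin_by_frequency",
    "empirical_p",
    "lognormal_p",
    "genome_scan",
    "scan_report",
]


@dataclass
class ScanConfig:
    """All scan thresholds in one place (defaults are the standard ones)."""

    min_core_snps: int = 2
    target_distance_bp: int = 1_000_000
    n_bins: int = 20
    alpha: float = 0.01
    min_report_frequency: float = 0.25
    p_mode: str = "empirical"          # or "lognormal"
    bin_scheme: str = "width"          # or "count" (quantile bins)
    strong_fraction: float = 0.95
    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    max_pair_span_bp: int = 2_500_000
    require_end_pair: bool = True
    from_midpoint: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.p_mode not in ("empirical", "lognormal"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")


def bin_by_frequency(
    records: pd.DataFrame, n_bins: int = 20, scheme: str = "width"
) -> pd.DataFrame:
    """Assign each record to a core-haplotype-frequency bin.

    Equal-width right-closed bins over (0, 1]: frequency f lands in bin
    ceil(f * n_bins) - 1 (0-based).  ``scheme="count"`` instead uses
    equal-count (quantile) bins.  Adds a ``bin_index`` column.
    """
    out = records.copy()
    f = out["frequency"].to_numpy()
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("frequencies must lie in (0, 1]")
    if scheme == "width":
        idx = np.ceil(f * n_bins).astype(int) - 1
    elif scheme == "count":
        idx = pd.qcut(f, q=n_bins, labels=False, duplicates="drop").astype(int)
    else:
        raise ValueError(f"unknown bin scheme {scheme!r}")
    out["bin_index"] = idx
    return out


def empirical_p(records: pd.DataFrame) -> pd.DataFrame:
    """Within-bin upper-tail empirical p-values, ties inclusive.

    Singleton bins yield p = 1 with ``singleton_bin`` flagged.
    """
    out = records.copy()
    p = np.empty(len(out), dtype=float)
    singleton = np.zeros(len(out), dtype=bool)
    for _, idx in out.groupby("bin_index").indices.items():
        r = out["rehh"].to_numpy()[idx]
        n = len(r)
        if n == 1:
            p[idx] = 1.0
            singleton[idx] = True
            continue
        # rank with method='min' gives 1 + #{< r_i}; #{>= r_i} = n - rank + 1
        ranks = sps.rankdata(r, method="min")
        p[idx] = (n - ranks + 1) / n
    out["p_value"] = p
    out["singleton_bin"] = singleton
    return out


def lognormal_p(records: pd.DataFrame) -> pd.DataFrame:
    """Upper-tail p from a log-normal fit to each bin's REHH values.

    Requires bin size >= 3 and REHH > 0; other records get p = NaN.
    """
    out = records.copy()
    p = np.full(len(out), np.nan)
    for _, idx in out.groupby("bin_index").indices.items():
        r = out["rehh"].to_numpy()[idx]
        ok = r > 0
        if ok.sum() < 3:
            continue
        logs = np.log(r[ok])
        mu, sd = logs.mean(), logs.std(ddof=1)
        if sd == 0:
            p[idx[ok]] = 0.5
        else:
            p[idx[ok]] = sps.norm.sf((logs - mu) / sd)
    out["p_value"] = p
    out["singleton_bin"] = False
    return out


@dataclass
class ScanResult:
    """Everything the genome scan produces."""

    records: pd.DataFrame
    regions: list[CoreRegion]
    region_summary: pd.DataFrame
    per_chrom: pd.DataFrame
    significant: pd.DataFrame
    config: ScanConfig
    n_tests_total: int = 0
    warnings: list[str] = field(default_factory=list)


_RECORD_COLUMNS = [
    "chrom", "region_start", "region_end", "n_core_snps", "allele_string",
    "carrier_count", "frequency", "direction", "eval_pos", "ehh_t",
    "ehh_bar", "rehh", "status",
]


def _collect_records(
    panel: HaplotypePanel, regions: list[CoreRegion], config: ScanConfig
) -> pd.DataFrame:
    rows = []
    for region in regions:
        for core in core_haplotypes(panel, region):
            if core.carrier_count < 2:
                continue
            if panel.n_haplotypes - core.carrier_count < 2:
                continue
            for direction in (UPSTREAM, DOWNSTREAM):
                rec = rehh_test(
                    panel, core, direction,
                    target_distance_bp=config.target_distance_bp,
                    from_midpoint=config.from_midpoint,
                )
                d = vars(rec).copy()
                d["n_core_snps"] = region.n_snps
                rows.append(d)
    if not rows:
        return pd.DataFrame(columns=_RECORD_COLUMNS)
    df = pd.DataFrame(rows)
    return df[_RECORD_COLUMNS]


def genome_scan(
    panel: HaplotypePanel,
    config: ScanConfig | None = None,
    regions: list[CoreRegion] | None = None,
) -> ScanResult:
    """Run the whole scan: core regions -> core haplotypes -> REHH both
    directions -> frequency bins -> p-values -> report tables.

    Records with undefined EHH-bar are dropped before binning;
    chromosome-end-truncated records are kept (flagged).  The
    per-chromosome table and the significant-region table are restricted
    to core haplotypes with frequency >= ``min_report_frequency``; the
    full record table is not.
    """
    config = config or ScanConfig()
    warnings: list[str] = []
    if regions is None:
        regions = detect_core_regions(
            panel,
            min_snps=config.min_core_snps,
            strong_fraction=config.strong_fraction,
            max_pair_span_bp=config.max_pair_span_bp,
            strong_low=config.strong_low,
            strong_high=config.strong_high,
            recomb_high=config.recomb_high,
            require_end_pair=config.require_end_pair,
        )
    region_summary = summarize_core_regions(regions, panel)
    all_records = _collect_records(panel, regions, config)
    n_tests_total = len(all_records)
    if not regions:
        warnings.append("no core regions detected; outputs are empty")
    testable = all_records[
        all_records["status"].isin((ehh_mod.STATUS_OK, ehh_mod.STATUS_TRUNCATED))
    ].reset_index(drop=True)
    if len(testable):
        testable = bin_by_frequency(testable, config.n_bins, config.bin_scheme)
        if config.p_mode == "empirical":
            testable = empirical_p(testable)
        else:
            testable = lognormal_p(testable)
        testable["neg_log10_p"] = -np.log10(testable["p_value"])
        testable["significant"] = testable["p_value"] < config.alpha
        testable["p_bh"] = _benjamini_hochberg(testable["p_value"].to_numpy())
    else:
        for col in ("bin_index", "p_value", "singleton_bin", "neg_log10_p",
                    "significant", "p_bh"):
            testable[col] = pd.Series(dtype=float)
        warnings.append("no testable EHH records")
    reported = testable[testable["frequency"] >= config.min_report_frequency]
    per_chrom = _per_chrom_counts(reported, panel.chroms, config.alpha)
    significant = (
        reported[reported["significant"] == True]  # noqa: E712
        .sort_values(["chrom", "region_start", "direction", "allele_string"])
        .reset_index(drop=True)
    )
    return ScanResult(
        records=testable,
        regions=regions,
        region_summary=region_summary,
        per_chrom=per_chrom,
        significant=significant,
        config=config,
        n_tests_total=n_tests_total,
        warnings=warnings,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


def _per_chrom_counts(
    reported: pd.DataFrame, chroms: list[str], alpha: float
) -> pd.DataFrame:
    rows = []
    for chrom in chroms:
        sub = reported[reported["chrom"] == chrom]
        rows.append({
            "chrom": chrom,
            "tests": len(sub),
            "p_lt_0.05": int((sub["p_value"] < 0.05).sum()),
            f"p_lt_{alpha:g}": int((sub["p_value"] < alpha).sum()),
        })
    df = pd.DataFrame(rows)
    total = df.drop(columns="chrom").sum()
    total["chrom"] = "total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)[df.columns]


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------

def _round_cols(df: pd.DataFrame) -> pd.DataFrame:
    """Stable rounding for diffable TSVs: EHH/REHH to 2 decimals, p to 4
    (numpy round-half-even)."""
    out = df.copy()
    for col, nd in (("ehh_t", 2), ("ehh_bar", 4), ("rehh", 2),
                    ("frequency", 2), ("p_value", 4), ("p_bh", 4),
                    ("neg_log10_p", 3)):
        if col in out.columns:
            out[col] = np.round(out[col].astype(float), nd)
    return out


def scan_report(result: ScanResult, outdir: str) -> dict[str, str]:
    """Write tests.tsv, per_chrom_counts.tsv, significant_regions.tsv,
    manhattan.tsv and region_summary.tsv under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path

    _write("tests.tsv", _round_cols(result.records))
    _write("per_chrom_counts.tsv", result.per_chrom)
    sig = _round_cols(result.significant)
    if len(sig):
        sig = sig[["chrom", "region_start", "region_end", "frequency",
                   "direction", "ehh_t", "rehh", "p_value", "p_bh"]]
    _write("significant_regions.tsv", sig)
    if len(result.records):
        man = result.records.assign(
            pos=((result.records["region_start"] + result.records["region_end"]) // 2)
        )[["chrom", "pos", "neg_log10_p"]]
    else:
        man = pd.DataFrame(columns=["chrom", "pos", "neg_log10_p"])
    _write("manhattan.tsv", _round_cols(man))
    _write("region_summary.tsv", result.region_summary.round(4))
    return paths
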