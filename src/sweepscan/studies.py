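"""Replicate studies on synthetic data: calibration and power.

These drive both the analysis scripts and the acceptance checks, so the
study designs live in one place.  Genomes are 24 independent 5 Mb
chromosomes (~5,400 chip-spaced markers, ~5,000 EHH tests) — large
enough that every frequency bin holds over a hundred tests and the
empirical p-value can actually fall below the 0.01 significance
threshold, which is how the method is used at full chip scale.

All randomness is controlled by one integer seed; per-replicate and
per-chromosome seeds are derived through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotate import haplotype_contrast
from .ld import detect_core_regions
from .significance import ScanConfig, ScanResult, genome_scan
from .simulate import (SweepSimParams, SweepSpec, make_two_line_panel,
                       simulate_genome)

__all__ = [
    "N_CHROMS",
    "SWEEP_CHROM",
    "derive_seed",
    "neutral_scan",
    "type_i_error",
    "sweep_recovery",
    "two_line_null",
    "line_divergence",
]

N_CHROMS = 24
SWEEP_CHROM = "12"
FOCAL_WINDOW_BP = 1_000_000


def derive_seed(*key: int) -> int:
    """A reproducible sub-seed (< 2^31) from an integer tuple."""
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def neutral_scan(
    seed: int,
    n_chroms: int = N_CHROMS,
    params: SweepSimParams | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Scan one neutral multi-chromosome genome."""
    params = params or SweepSimParams()
    panel, _ = simulate_genome(replace(params, sweep=None), seed, n_chroms)
    return genome_scan(panel, config)


@dataclass
class TypeIError:
    """Realized false-positive behaviour of the empirical-p scan under
    neutrality, with the attainable expectation given bin discreteness."""

    n_tests: int
    n_sig: int                # p < alpha
    rate: float
    expected_n_sig: float     # sum over bins of attainable p < alpha ranks
    n_p05: int
    expected_n_p05: float
    alpha: float


def _attainable(bin_sizes: np.ndarray, alpha: float) -> float:
    """Expected significant count under within-bin discrete-uniform p:
    a bin of n members can produce p = k/n < alpha only for
    k = 1 .. ceil(alpha*n) - 1."""
    return float(sum(max(int(np.ceil(alpha * n)) - 1, 0) for n in bin_sizes))


def type_i_error(
    seed: int, alpha: float = 0.01, n_chroms: int = N_CHROMS
) -> TypeIError:
    """Neutral-genome scan: how often does the scan call significance?

    The empirical p within a bin of size n is discrete on {1/n, ..., 1},
    so the attainable rate is a little below alpha; the expectation
    returned accounts for that exactly (ties only lower it further).
    """
    result = neutral_scan(seed, n_chroms=n_chroms,
                          config=ScanConfig(alpha=alpha))
    rec = result.records
    sizes = rec.groupby("bin_index").size().to_numpy()
    n_sig = int((rec["p_value"] < alpha).sum())
    n_p05 = int((rec["p_value"] < 0.05).sum())
    return TypeIError(
        n_tests=len(rec),
        n_sig=n_sig,
        rate=n_sig / len(rec) if len(rec) else 0.0,
        expected_n_sig=_attainable(sizes, alpha),
        n_p05=n_p05,
        expected_n_p05=_attainable(sizes, 0.05),
        alpha=alpha,
    )


@dataclass
class SweepReplicate:
    seed: int
    focal_pos: int
    focal_sample_frequency: float
    detected: bool            # significant region within 1 Mb of the focal site
    best_p_near_focal: float
    n_significant: int


def sweep_recovery(
    seed: int,
    n_replicates: int = 20,
    n_chroms: int = N_CHROMS,
    params: SweepSimParams | None = None,
) -> list[SweepReplicate]:
    """Power study: replicate sweep genomes, one selected chromosome each.

    A replicate counts as detected when the significant-region table
    (frequency >= 0.25, p < alpha) contains a region on the swept
    chromosome within 1 Mb of the realized focal position.
    """
    params = params or SweepSimParams(sweep=SweepSpec())
    if params.sweep is None:
        params = replace(params, sweep=SweepSpec())
    out = []
    for i in range(n_replicates):
        rep_seed = derive_seed(seed, 7, i)
        panel, truth = simulate_genome(params, rep_seed, n_chroms,
                                       sweep_on=SWEEP_CHROM)
        result = genome_scan(panel)
        sig = result.significant
        near_sig = sig[
            (sig["chrom"] == SWEEP_CHROM)
            & (sig["region_start"] <= truth.focal_pos + FOCAL_WINDOW_BP)
            & (sig["region_end"] >= truth.focal_pos - FOCAL_WINDOW_BP)
        ]
        rec = result.records
        near = rec[
            (rec["chrom"] == SWEEP_CHROM)
            & (rec["region_start"] <= truth.focal_pos + FOCAL_WINDOW_BP)
            & (rec["region_end"] >= truth.focal_pos - FOCAL_WINDOW_BP)
        ]
        out.append(SweepReplicate(
            seed=rep_seed,
            focal_pos=truth.focal_pos,
            focal_sample_frequency=truth.focal_sample_frequency,
            detected=len(near_sig) > 0,
            best_p_near_focal=float(near["p_value"].min()) if len(near) else np.nan,
            n_significant=len(sig),
        ))
    return out


def two_line_null(
    seed: int, params: SweepSimParams | None = None
) -> pd.DataFrame:
    """Null calibration of the between-line chi-square contrast.

    Both panels are drawn from the same population (zero scenario
    generations, s = 0), the exact null of the homogeneity test; returns
    one row per core region with the chi-square p-value.
    """
    params = params or SweepSimParams()
    params = replace(
        params, n_generations=0,
        sweep=SweepSpec(selection_coefficient=0.0, start_frequency=0.3),
    )
    pa, pb, _ = make_two_line_panel(params, seed, labels=("a", "b"))
    regions = detect_core_regions(pa)
    rows = []
    for region in regions:
        res = haplotype_contrast(pa, pb, region)
        if res.status != "ok":
            continue
        rows.append({
            "chrom": region.chrom, "start": region.start_pos,
            "end": region.end_pos, "chi2": res.chi2_stat,
            "df": res.df, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def line_divergence(
    seed: int, n_replicates: int = 20, params: SweepSimParams | None = None
) -> pd.DataFrame:
    """Divergent selection: is the focal site a per-site-difference outlier?

    For each replicate two-line pair, compares the between-line focal
    allele-frequency difference with the genome-wide 95th percentile of
    per-site differences.
    """
    params = params or SweepSimParams(sweep=SweepSpec())
    rows = []
    for i in range(n_replicates):
        rep_seed = derive_seed(seed, 13, i)
        pa, pb, truth = make_two_line_panel(params, rep_seed)
        diff = np.abs(pa.haplotypes.mean(axis=0) - pb.haplotypes.mean(axis=0))
        focal = diff[truth.focal_marker_index]
        q95 = float(np.quantile(np.delete(diff, truth.focal_marker_index), 0.95))
        rows.append({
            "seed": rep_seed,
            "focal_diff": float(focal),
            "genome_q95": q95,
            "outlier": bool(focal > q95),
        })
    return pd.DataFrame(rows)
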