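"""Published chicken 60K selection-scan summary the simulator emulates.

The reference study scanned two broiler lines divergently selected for
abdominal fat ("lean" and "fat") with a 60K SNP chip; its raw genotypes
were never deposited, but its per-chromosome bookkeeping tables were.
They are shipped here as plain TSVs and serve two purposes: they fix the
study conditions the synthetic generator targets (marker density, block
structure, test volume), and several design-level quantities are exact
functions of their rows (mean marker spacing, mean core-region length,
tests per core region, genome-wide test totals) that downstream scripts
recompute rather than hard-code.
"""

from __future__ import annotations

import importlib.resources as resources

import pandas as pd

__all__ = [
    "load_region_summary",
    "load_test_counts",
    "EHH_TEST_TOTALS",
    "design_stats",
]

#: genome-wide EHH test counts reported for the two lines
EHH_TEST_TOTALS = {"lean": 44822, "fat": 46775}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("sweepscan").joinpath("data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_region_summary() -> pd.DataFrame:
    """Per-chromosome marker and core-region summary of the reference scan."""
    return _read("chicken60k_region_summary.tsv")


def load_test_counts() -> pd.DataFrame:
    """Per-chromosome REHH test counts (frequency >= 0.25) with the
    numbers of tests below p = 0.05 and p = 0.01, per line."""
    return _read("chicken60k_test_counts.tsv")


def design_stats() -> dict[str, float]:
    """Design-level quantities recomputed from the reference tables.

    All values are plain arithmetic over the table rows:

    - ``mean_marker_spacing_kb``: genome length / SNP count
    - ``mean_cr_length_kb_<line>``: summed region coverage / region count
    - ``tests_per_cr_<line>``: genome-wide EHH tests / region count
    - ``tests_freq025_<line>``, ``sig_p05_<line>``, ``sig_p01_<line>``:
      column totals of the per-chromosome test-count table
    """
    t1 = load_region_summary()
    t2 = load_test_counts()
    out: dict[str, float] = {
        "n_snps": float(t1["snp_n"].sum()),
        "genome_length_mbp": float(t1["chr_length_mbp"].sum()),
        "mean_marker_spacing_kb": float(
            t1["chr_length_mbp"].sum() * 1000.0 / t1["snp_n"].sum()
        ),
    }
    for line in ("lean", "fat"):
        n_cr = float(t1[f"n_cr_{line}"].sum())
        out[f"n_cr_{line}"] = n_cr
        out[f"coverage_cr_kb_{line}"] = float(t1[f"coverage_cr_kb_{line}"].sum())
        out[f"mean_cr_length_kb_{line}"] = out[f"coverage_cr_kb_{line}"] / n_cr
        out[f"cr_snps_{line}"] = float(t1[f"cr_snps_{line}"].sum())
        out[f"tests_per_cr_{line}"] = EHH_TEST_TOTALS[line] / n_cr
        out[f"tests_freq025_{line}"] = float(t2[f"tests_{line}"].sum())
        out[f"sig_p05_{line}"] = float(t2[f"p05_{line}"].sum())
        out[f"sig_p01_{line}"] = float(t2[f"p01_{line}"].sum())
    return out
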