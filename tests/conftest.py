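import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from sweepscan.panel import HaplotypePanel


def make_panel(matrix, positions=None, chroms=None, line_label="") -> HaplotypePanel:
    """Hand-built panel from a 0/1 matrix (rows = haplotypes)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    m = matrix.shape[1]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(m)]
    if chroms is None:
        chroms = ["1"] * m
    markers = pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "id": [f"m{i}" for i in range(m)],
        "ref": "A",
        "alt": "G",
    })
    return HaplotypePanel(markers, matrix, line_label=line_label)


@pytest.fixture
def perfect_ld_panel():
    """Three markers in complete association across 100 haplotypes."""
    col = np.array([0] * 50 + [1] * 50, dtype=np.uint8)
    return make_panel(np.column_stack([col, col, col]),
                      positions=[10_000, 20_000, 30_000])


@pytest.fixture(scope="session")
def neutral_panel():
    """One neutral 5 Mb chip-like chromosome (session-cached)."""
    from sweepscan.simulate import SweepSimParams, simulate_neutral
    return simulate_neutral(SweepSimParams(), seed=11)


@pytest.fixture(scope="session")
def neutral_scan_result(neutral_panel):
    from sweepscan.significance import genome_scan
    return genome_scan(neutral_panel)


@pytest.fixture(scope="session")
def sweep_panel_truth():
    """One selected 5 Mb chromosome with its ground truth (session-cached)."""
    from sweepscan.simulate import SweepSimParams, SweepSpec, simulate_sweep
    return simulate_sweep(SweepSimParams(sweep=SweepSpec()), seed=21)
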