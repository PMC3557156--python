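"""Independent brute-force oracles the implementation is checked against.

Everything here is written the slow, obviously-correct way (per-row
loops, exact rational arithmetic, exhaustive enumeration) and shares no
code with the package internals it verifies.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


def pair_counts_oracle(col_a, col_b):
    """Tally the four phased allele pairs row by row."""
    counts = {"00": 0, "01": 0, "10": 0, "11": 0}
    for a, b in zip(col_a, col_b):
        counts[f"{a}{b}"] += 1
    return counts


def ld_oracle(n00, n01, n10, n11):
    """D, |D'|, r^2 from haplotype frequencies, textbook formulas."""
    n = n00 + n01 + n10 + n11
    pa = (n10 + n11) / n
    pb = (n01 + n11) / n
    d = n11 / n - pa * pb
    if pa in (0, 1) or pb in (0, 1):
        return None
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0
    dprime = abs(d) / dmax if d != 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, dprime, r2


def dprime_ci_oracle(n00, n01, n10, n11, conf=0.90, grid=101, floor=1e-10):
    """Grid-likelihood |D'| confidence bounds, scalar reimplementation."""
    n = n00 + n01 + n10 + n11
    pa = (n10 + n11) / n
    pb = (n01 + n11) / n
    if pa in (0, 1) or pb in (0, 1):
        return None
    d_obs = n11 / n - pa * pb
    sign = 1.0 if d_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    logliks = []
    values = [i / (grid - 1) for i in range(grid)]
    for v in values:
        d = sign * v * dmax
        probs = [
            (1 - pa) * (1 - pb) + d,
            (1 - pa) * pb - d,
            pa * (1 - pb) - d,
            pa * pb + d,
        ]
        ll = 0.0
        for cnt, p in zip((n00, n01, n10, n11), probs):
            ll += cnt * np.log(max(p, floor))
        logliks.append(ll)
    m = max(logliks)
    lik = np.exp(np.array(logliks) - m)
    lik = lik / lik.sum()
    cum = np.cumsum(lik)
    lo = values[int(np.argmax(cum >= (1 - conf) / 2 - 1e-12))]
    hi = values[int(np.argmax(cum >= (1 + conf) / 2 - 1e-12))]
    return lo, hi


def ehh_pairs_oracle(haplotype_rows) -> Fraction:
    """Exact EHH: fraction of all distinct row pairs that are identical."""
    rows = [tuple(r) for r in haplotype_rows]
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 rows")
    same = sum(1 for a, b in combinations(rows, 2) if a == b)
    return Fraction(same, n * (n - 1) // 2)


def blocks_oracle(pair_is_strong, pair_is_informative, positions,
                  min_snps=2, strong_fraction=0.95, require_end_pair=True,
                  max_span=None):
    """Exhaustive core-region detection on a tiny marker set.

    ``pair_is_strong`` / ``pair_is_informative``: dicts keyed by (i, j),
    i < j.  Returns the greedily selected (i, j) intervals, longest bp
    span first, leftmost on ties, non-overlapping.
    """
    m = len(positions)
    candidates = []
    for i in range(m):
        for j in range(i + min_snps - 1, m):
            if i == j:
                continue
            if max_span is not None and positions[j] - positions[i] > max_span:
                continue
            pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            informative = [p for p in pairs if pair_is_informative.get(p, False)]
            if not informative:
                continue
            strong = [p for p in informative if pair_is_strong.get(p, False)]
            if require_end_pair and not pair_is_strong.get((i, j), False):
                continue
            if len(strong) / len(informative) >= strong_fraction:
                candidates.append((positions[j] - positions[i], i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen = []
    used = set()
    for _, i, j in candidates:
        if any(k in used for k in range(i, j + 1)):
            continue
        used.update(range(i, j + 1))
        chosen.append((i, j))
    return sorted(chosen)


def overlap_oracle(regions, features):
    """All-pairs 1-bp-overlap scan; regions/features as (chrom, start, end)."""
    hits = set()
    for ri, (rc, rs, re) in enumerate(regions):
        for fi, (fc, fs, fe) in enumerate(features):
            if rc == fc and rs <= fe and fs <= re:
                hits.add((ri, fi))
    return hits
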