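"""Forward Wright-Fisher simulation of phased SNP-chip-like panels.

The generator stands in for an undeposited chicken 60K-chip data set:
one or more chromosomes, tens-to-hundreds of phased haplotypes per line,
~22 kb marker spacing, a MAF spectrum truncated at 0.05, background LD
that yields multi-SNP haplotype blocks, and optionally a selective sweep
elevating one haplotype's frequency around a focal site.

Model: a haploid Wright-Fisher population of 2N chromosomes evolves with
per-generation recombination (crossover count ~ Poisson(r*L), uniform
breakpoints) and infinite-sites mutation (ancestral allele 0; a mutation
flips 0 -> 1 once at a fresh uniformly drawn position).  Standing
variation is initialized at neutral mutation-recombination-drift
equilibrium by a seeded coalescent simulation (msprime) of the same
model — the coalescent is the stationary distribution of this
Wright-Fisher process, so no burn-in truncation bias enters — and every
scenario generation (drift, selection, the two-line split) then runs
forward and exactly.  A pure-forward burn-in from a monomorphic
population is available instead via ``burn_in_generations``.  Selection
multiplies a chromosome's chance of being chosen as a parent by 1 + s
when it carries the focal derived allele (or the ancestral one, for the
down-selected line).  Everything is driven by one integer-seeded NumPy
generator, so (params, seed) -> the same panel on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from numba import njit

from .panel import HaplotypePanel, concat_panels

__all__ = [
    "SweepSpec",
    "SweepSimParams",
    "SimTruth",
    "simulate_neutral",
    "simulate_sweep",
    "make_two_line_panel",
    "simulate_genome",
]

#: mean adjacent-marker spacing the thinning step targets (bp)
CHIP_SPACING_BP = 22_090

_MAX_RETRIES = 10


@dataclass(frozen=True)
class SweepSpec:
    """Selection scenario: a focal derived allele with fitness advantage."""

    selection_coefficient: float = 0.10
    start_frequency: float = 0.02
    focal_pos: int | None = None  # None -> chromosome midpoint

    def __post_init__(self) -> None:
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not (0 < self.start_frequency < 1):
            raise ValueError("start_frequency must be in (0, 1)")


@dataclass(frozen=True)
class SweepSimParams:
    """Generative parameters for one simulated chromosome.

    Defaults emulate a 60K-chip study design at desk scale: N = 500
    diploids, a 5 Mb chromosome, ~22 kb marker spacing after thinning,
    chip-style MAF floor of 0.05, mutation rate 1e-8 /bp/gen, and a
    recombination rate (1e-8 /bp/gen) whose population-scaled value at
    this N reproduces the block-rich LD regime of small-Ne livestock
    lines.  ``n_generations`` are the post-burn-in scenario generations
    over which any selection acts.
    """

    n_haplotypes: int = 100
    n_generations: int = 45
    pop_size: int = 500
    chrom_length_bp: int = 5_000_000
    target_n_snps: int | None = None     # None -> chrom_length_bp / 22,090
    recomb_rate_per_bp_per_gen: float = 1e-8
    mutation_rate_per_bp_per_gen: float = 1e-8
    #: None -> coalescent-equilibrium initialization; an integer runs a
    #: pure-forward burn-in of that many generations from monomorphic
    burn_in_generations: int | None = None
    sweep: SweepSpec | None = None
    maf_floor: float = 0.05
    chrom_name: str = "1"

    def __post_init__(self) -> None:
        if self.n_haplotypes % 2 or self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be even and >= 4")
        if self.n_haplotypes > 2 * self.pop_size:
            raise ValueError("cannot sample more haplotypes than 2N")
        if self.sweep is not None and self.chrom_length_bp < 2_200_000:
            raise ValueError(
                "chromosome too short for +/-1 Mb EHH tests around a sweep"
            )

    @property
    def resolved_target_n_snps(self) -> int:
        if self.target_n_snps is not None:
            return self.target_n_snps
        return max(2, round(self.chrom_length_bp / CHIP_SPACING_BP))



@dataclass
class SimTruth:
    """Ground truth as realized in the simulation (not the nominal target)."""

    focal_pos: int
    focal_start_frequency: float
    focal_final_frequency: float      # in the population(s), post-scenario
    focal_sample_frequency: float     # among the sampled haplotypes
    focal_marker_index: int | None    # panel column, None if filtered out
    line_divergence: dict[str, float] | None = None


@njit(cache=True)
def _assemble_children(matrix, positions, p1, p2, n_xo, bps_flat, offsets):
    """Build the child generation and its derived-allele counts.

    Child i copies parent p1[i]; with crossovers, sites switch to p2[i]
    wherever an odd number of breakpoints lies below the site position.
    """
    n, s = matrix.shape
    children = np.empty((n, s), dtype=np.uint8)
    freq = np.zeros(s, dtype=np.int64)
    for i in range(n):
        a = p1[i]
        k = n_xo[i]
        if k == 0:
            for j in range(s):
                v = matrix[a, j]
                children[i, j] = v
                freq[j] += v
        else:
            b = p2[i]
            lo = offsets[i]
            for j in range(s):
                c = 0
                for t in range(k):
                    if bps_flat[lo + t] <= positions[j]:
                        c += 1
                v = matrix[a, j] if c % 2 == 0 else matrix[b, j]
                children[i, j] = v
                freq[j] += v
    return children, freq


class _Population:
    """2N haplotypes as a (2N, S) uint8 matrix plus bp positions."""

    def __init__(self, size: int, length_bp: int, rng: np.random.Generator):
        self.size = size
        self.length_bp = length_bp
        self.rng = rng
        self.matrix = np.zeros((size, 0), dtype=np.uint8)
        self.positions = np.zeros(0, dtype=np.int64)
        #: positions of derived alleles that reached fixation (and were
        #: purged): distinguishes fixation from loss after the fact
        self.fixed_positions: set[int] = set()

    def copy(self) -> "_Population":
        new = _Population(self.size, self.length_bp, self.rng)
        new.matrix = self.matrix.copy()
        new.positions = self.positions.copy()
        new.fixed_positions = set(self.fixed_positions)
        return new

    def step(
        self,
        r: float,
        mu: float,
        weights: np.ndarray | None = None,
    ) -> None:
        """One non-overlapping Wright-Fisher generation.

        All randomness is drawn here from the NumPy generator (so runs
        are reproducible from the seed alone); the O(2N x S) child
        assembly runs in a compiled kernel.
        """
        rng = self.rng
        n = self.size
        if weights is None:
            p1 = rng.integers(0, n, size=n)
            p2 = rng.integers(0, n, size=n)
        else:
            probs = weights / weights.sum()
            p1 = rng.choice(n, size=n, p=probs)
            p2 = rng.choice(n, size=n, p=probs)
        n_xo = rng.poisson(r * self.length_bp, size=n)
        offsets = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(n_xo, out=offsets[1:])
        bps_flat = rng.uniform(0, self.length_bp, size=int(offsets[-1]))
        children, freq = _assemble_children(
            self.matrix, self.positions.astype(np.float64),
            p1, p2, n_xo, bps_flat, offsets,
        )
        # infinite-sites mutations: fresh de-duplicated positions
        n_mut = rng.poisson(mu * self.length_bp * n)
        new_pos = np.zeros(0, dtype=np.int64)
        mut_rows = np.zeros(0, dtype=np.int64)
        if n_mut:
            new_pos = rng.integers(1, self.length_bp + 1, size=n_mut)
            fresh = ~np.isin(new_pos, self.positions)
            new_pos = new_pos[fresh]
            new_pos = new_pos[np.sort(np.unique(new_pos, return_index=True)[1])]
            mut_rows = rng.integers(0, n, size=len(new_pos))
        # drop lost and fixed columns, append the new mutations, one alloc
        keep = (freq > 0) & (freq < n)
        for p in self.positions[freq == n]:
            self.fixed_positions.add(int(p))
        k = int(keep.sum())
        out = np.zeros((n, k + len(new_pos)), dtype=np.uint8)
        out[:, :k] = children[:, keep]
        if len(new_pos):
            out[mut_rows, k + np.arange(len(new_pos))] = 1
        self.matrix = out
        self.positions = np.concatenate([self.positions[keep], new_pos])

    def frequency_at(self, col: int) -> float:
        return float(self.matrix[:, col].mean())


def _burned_in_population(
    params: SweepSimParams, rng: np.random.Generator
) -> _Population:
    """Standing variation at neutral equilibrium.

    Default: a seeded coalescent simulation of the matching haploid
    model (population size 2N, same r and mu, binary 0/1 mutations on a
    discrete genome) provides the (2N, S) matrix exactly at
    stationarity.  With ``burn_in_generations`` set, a pure-forward
    burn-in from a monomorphic population is run instead.
    """
    pop = _Population(2 * params.pop_size, params.chrom_length_bp, rng)
    r = params.recomb_rate_per_bp_per_gen
    mu = params.mutation_rate_per_bp_per_gen
    if params.burn_in_generations is not None:
        for _ in range(params.burn_in_generations):
            pop.step(r, mu)
        return pop
    import msprime

    m = 2 * params.pop_size
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=m,
        ploidy=1,
        population_size=m,
        sequence_length=params.chrom_length_bp,
        recombination_rate=r,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(), random_seed=mut_seed
    )
    geno = ts.genotype_matrix()  # sites x samples, values in {0, 1}
    freq = geno.sum(axis=1)
    seg = (freq > 0) & (freq < m)
    pop.matrix = np.ascontiguousarray(geno[seg].T.astype(np.uint8))
    pop.positions = ts.sites_position[seg].astype(np.int64) + 1
    return pop


def _sample_panel(
    pop: _Population,
    params: SweepSimParams,
    rng: np.random.Generator,
    keep_pos: int | None = None,
    line_label: str = "",
) -> tuple[HaplotypePanel, np.ndarray]:
    """Sample H rows, apply the MAF floor and chip-density thinning.

    ``keep_pos`` (the focal site) is exempt from both the floor and the
    thinning.  Returns the panel and the sampled row indices.
    """
    rows = np.sort(rng.choice(pop.size, size=params.n_haplotypes, replace=False))
    return _panel_from_sample(pop, rows, params, rng, keep_pos, line_label), rows


def _panel_from_sample(
    pop: _Population,
    rows: np.ndarray,
    params: SweepSimParams,
    rng: np.random.Generator,
    keep_pos: int | None,
    line_label: str,
    extra_matrix: np.ndarray | None = None,
) -> HaplotypePanel:
    sample = pop.matrix[rows]
    judged = sample if extra_matrix is None else np.vstack([sample, extra_matrix])
    freq = judged.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= params.maf_floor
    if keep_pos is not None:
        keep |= pop.positions == keep_pos
    order = np.argsort(pop.positions[keep], kind="stable")
    pos = pop.positions[keep][order]
    mat = sample[:, keep][:, order]
    target = params.resolved_target_n_snps
    if len(pos) > target:
        pick = np.unique(np.round(np.linspace(0, len(pos) - 1, target)).astype(int))
        if keep_pos is not None and keep_pos in pos and keep_pos not in pos[pick]:
            pick = np.sort(np.append(pick, int(np.searchsorted(pos, keep_pos))))
        pos = pos[pick]
        mat = mat[:, pick]
    if len(pos) < min(50, target):
        raise RuntimeError(
            f"only {len(pos)} polymorphic sites survived sampling/filtering; "
            "increase mutation rate x chromosome length or burn-in"
        )
    markers = pd.DataFrame({
        "chrom": params.chrom_name,
        "pos": pos.astype(int),
        "id": [f"snp_{params.chrom_name}_{p}" for p in pos],
        "ref": "A",
        "alt": "G",
    })
    sample_ids = [
        f"{line_label or 'ind'}_{i // 2}_{i % 2 + 1}" for i in range(len(rows))
    ]
    return HaplotypePanel(markers, mat, sample_ids, line_label)


def simulate_neutral(
    params: SweepSimParams, seed: int, line_label: str = ""
) -> HaplotypePanel:
    """Neutral panel: burn-in + ``n_generations`` of drift, then sample."""
    if params.sweep is not None:
        raise ValueError("simulate_neutral called with a sweep scenario; "
                         "use simulate_sweep")
    rng = np.random.default_rng(seed)
    pop = _burned_in_population(params, rng)
    for _ in range(params.n_generations):
        pop.step(params.recomb_rate_per_bp_per_gen,
                 params.mutation_rate_per_bp_per_gen)
    panel, _ = _sample_panel(pop, params, rng, line_label=line_label)
    return panel


def _choose_focal(
    pop: _Population, sweep: SweepSpec, length_bp: int
) -> int | None:
    """Pick the standing variant closest in frequency to the target,
    breaking ties by distance to the nominal focal position."""
    if pop.matrix.shape[1] == 0:
        return None
    freq = pop.matrix.mean(axis=0)
    target_pos = sweep.focal_pos if sweep.focal_pos is not None else length_bp // 2
    # sites must leave >= 1 Mb flank on each side for the REHH evaluation
    flank_ok = (pop.positions > 1_100_000) & (pop.positions < length_bp - 1_100_000)
    cand = np.flatnonzero(flank_ok)
    if len(cand) == 0:
        cand = np.arange(len(freq))
    score = (
        np.abs(freq[cand] - sweep.start_frequency)
        + np.abs(pop.positions[cand] - target_pos) / (100.0 * length_bp)
    )
    return int(cand[np.argmin(score)])


def simulate_sweep(
    params: SweepSimParams, seed: int, line_label: str = ""
) -> tuple[HaplotypePanel, SimTruth]:
    """Panel with a selective sweep at a focal standing variant.

    After the neutral burn-in, the segregating site nearest the target
    start frequency (and nominal focal position) gains relative fitness
    1 + s per generation for ``n_generations``.  If the focal allele is
    lost, the whole simulation is retried with a derived sub-seed, a
    bounded number of times.
    """
    if params.sweep is None:
        raise ValueError("simulate_sweep needs params.sweep")
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng((seed, attempt) if attempt else seed)
        pop = _burned_in_population(params, rng)
        focal = _choose_focal(pop, params.sweep, params.chrom_length_bp)
        if focal is None:
            continue
        focal_pos = int(pop.positions[focal])
        start_freq = pop.frequency_at(focal)
        s = params.sweep.selection_coefficient
        lost = False
        for _ in range(params.n_generations):
            hit = np.flatnonzero(pop.positions == focal_pos)
            if len(hit):  # still segregating: select on carriers
                carriers = pop.matrix[:, int(hit[0])] == 1
                weights = np.where(carriers, 1.0 + s, 1.0)
            elif focal_pos in pop.fixed_positions:
                weights = None  # sweep complete, drift on
            else:
                lost = True
                break
            pop.step(params.recomb_rate_per_bp_per_gen,
                     params.mutation_rate_per_bp_per_gen, weights=weights)
        if lost:
            continue
        hit = np.flatnonzero(pop.positions == focal_pos)
        if len(hit):
            final_freq = pop.frequency_at(int(hit[0]))
        elif focal_pos in pop.fixed_positions:
            final_freq = 1.0
        else:
            continue  # lost in the very last generation
        panel, rows = _sample_panel(
            pop, params, rng, keep_pos=focal_pos, line_label=line_label
        )
        sample_freq = (float(pop.matrix[rows, int(hit[0])].mean())
                       if len(hit) else 1.0)
        marker_idx = np.flatnonzero(panel.markers["pos"].to_numpy() == focal_pos)
        truth = SimTruth(
            focal_pos=focal_pos,
            focal_start_frequency=start_freq,
            focal_final_frequency=final_freq,
            focal_sample_frequency=sample_freq,
            focal_marker_index=int(marker_idx[0]) if len(marker_idx) else None,
        )
        return panel, truth
    raise RuntimeError(
        f"focal allele lost in all {_MAX_RETRIES} attempts; "
        "lower s, raise start_frequency, or change the seed"
    )


def make_two_line_panel(
    params: SweepSimParams, seed: int,
    labels: tuple[str, str] = ("fat", "lean"),
) -> tuple[HaplotypePanel, HaplotypePanel, SimTruth]:
    """Two divergently selected lines from one ancestral population.

    The burned-in population is duplicated; the first line up-selects
    the focal derived allele (+s) and the second down-selects it (the
    ancestral allele gets the 1 + s weight) for ``n_generations``.  Both
    panels share one marker map: sites polymorphic (above the MAF floor)
    in the pooled sample are retained, so a site may be monomorphic
    within one line.  Retried with sub-seeds if the focal allele is lost
    from the pooled sample.
    """
    if params.sweep is None:
        raise ValueError("make_two_line_panel needs params.sweep")
    s = params.sweep.selection_coefficient
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng((seed, attempt) if attempt else seed)
        ancestral = _burned_in_population(params, rng)
        focal = _choose_focal(ancestral, params.sweep, params.chrom_length_bp)
        if focal is None:
            continue
        focal_pos = int(ancestral.positions[focal])
        start_freq = ancestral.frequency_at(focal)
        pops = [ancestral.copy(), ancestral.copy()]
        final = []
        for which, pop in enumerate(pops):
            pop.rng = rng
            for _ in range(params.n_generations):
                hit = np.flatnonzero(pop.positions == focal_pos)
                if len(hit):
                    carriers = pop.matrix[:, int(hit[0])] == 1
                    favored = carriers if which == 0 else ~carriers
                    weights = np.where(favored, 1.0 + s, 1.0)
                else:  # absorbed (lost or fixed): plain drift from here
                    weights = None
                pop.step(params.recomb_rate_per_bp_per_gen,
                         params.mutation_rate_per_bp_per_gen, weights=weights)
            hit = np.flatnonzero(pop.positions == focal_pos)
            if len(hit):
                final.append(pop.frequency_at(int(hit[0])))
            else:
                final.append(1.0 if focal_pos in pop.fixed_positions else 0.0)
        rows = [
            np.sort(rng.choice(pop.size, size=params.n_haplotypes, replace=False))
            for pop in pops
        ]
        # shared marker map: judge the MAF floor on the pooled sample
        shared_pos = _shared_positions(pops, rows, params, focal_pos)
        if shared_pos is None:
            continue
        panels = []
        for (pop, rr, label) in zip(pops, rows, labels):
            panels.append(_panel_on_positions(pop, rr, shared_pos, params, label))
        pooled = np.vstack([p.haplotypes for p in panels])
        focal_col = np.flatnonzero(shared_pos == focal_pos)
        pooled_freq = float(pooled[:, int(focal_col[0])].mean()) if len(focal_col) else 0.0
        if pooled_freq in (0.0, 1.0):
            continue
        truth = SimTruth(
            focal_pos=focal_pos,
            focal_start_frequency=start_freq,
            focal_final_frequency=float(np.mean(final)),
            focal_sample_frequency=pooled_freq,
            focal_marker_index=int(focal_col[0]),
            line_divergence={labels[0]: final[0], labels[1]: final[1]},
        )
        return panels[0], panels[1], truth
    raise RuntimeError(
        f"focal allele lost from the pooled sample in all {_MAX_RETRIES} attempts"
    )


def _shared_positions(
    pops: list[_Population],
    rows: list[np.ndarray],
    params: SweepSimParams,
    focal_pos: int,
) -> np.ndarray | None:
    all_pos = np.union1d(pops[0].positions, pops[1].positions)
    pooled_freq = np.zeros(len(all_pos))
    for pop, rr in zip(pops, rows):
        idx = np.searchsorted(all_pos, pop.positions)
        pooled_freq[idx] += pop.matrix[rr].sum(axis=0)
    pooled_freq /= 2 * params.n_haplotypes
    maf = np.minimum(pooled_freq, 1 - pooled_freq)
    keep = (maf >= params.maf_floor) | (all_pos == focal_pos)
    pos = all_pos[keep]
    target = params.resolved_target_n_snps
    if len(pos) > target:
        pick = np.unique(np.round(np.linspace(0, len(pos) - 1, target)).astype(int))
        if focal_pos in pos and focal_pos not in pos[pick]:
            pick = np.sort(np.append(pick, int(np.searchsorted(pos, focal_pos))))
        pos = pos[pick]
    if len(pos) < min(50, target):
        return None
    return pos


def _panel_on_positions(
    pop: _Population,
    rows: np.ndarray,
    positions: np.ndarray,
    params: SweepSimParams,
    line_label: str,
) -> HaplotypePanel:
    mat = np.zeros((len(rows), len(positions)), dtype=np.uint8)
    idx_in_pop = {int(p): i for i, p in enumerate(pop.positions)}
    for j, p in enumerate(positions):
        i = idx_in_pop.get(int(p))
        if i is not None:
            mat[:, j] = pop.matrix[rows, i]
        elif int(p) in pop.fixed_positions:
            mat[:, j] = 1  # fixed derived within this line
        # else lost within this line: all-ancestral column
    markers = pd.DataFrame({
        "chrom": params.chrom_name,
        "pos": positions.astype(int),
        "id": [f"snp_{params.chrom_name}_{p}" for p in positions],
        "ref": "A",
        "alt": "G",
    })
    sample_ids = [f"{line_label}_{i // 2}_{i % 2 + 1}" for i in range(len(rows))]
    return HaplotypePanel(markers, mat, sample_ids, line_label)


def simulate_genome(
    params: SweepSimParams,
    seed: int,
    n_chroms: int,
    sweep_on: str | None = None,
    line_label: str = "",
) -> tuple[HaplotypePanel, SimTruth | None]:
    """Several independent chromosomes concatenated into one panel.

    ``sweep_on`` names the chromosome (e.g. ``"3"``) that receives the
    params' sweep scenario; all others are simulated neutrally.  Seeds
    for the per-chromosome simulations are derived from (seed, chrom).
    """
    panels = []
    truth: SimTruth | None = None
    for k in range(n_chroms):
        name = str(k + 1)
        chrom_params = replace(params, chrom_name=name,
                               sweep=params.sweep if name == sweep_on else None)
        sub_seed = int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31))
        if name == sweep_on:
            panel, truth = simulate_sweep(chrom_params, sub_seed, line_label)
        else:
            panel = simulate_neutral(chrom_params, sub_seed, line_label)
        panels.append(panel)
    return concat_panels(panels), truth
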