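"""Diploid Wright-Fisher forward simulation over founder haplotypes.

Discrete, non-overlapping generations at constant census size N.  Fitness is
computed directly from the selection coefficients of the target SNPs
(genotype fitness 1 : 1 + h*s : 1 + s per locus, multiplied across loci by
default), both parents are sampled with probability proportional to fitness
(fecundity selection, with replacement), and gametes are formed by crossover
recombination along a piecewise map.  Two sexes are modelled; by default only
females recombine (Drosophila males are achiasmatic).  There is no mutation:
all variation comes from the standing variation of the founder panel, so
fixed or lost alleles stay fixed or lost.

Populations are stored as founder-mosaic breakpoint tracks (see
``_kernels``); allele frequencies decoded from the tracks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .founders import HaplotypePanel, RecombinationMap, SelectionTarget

__all__ = [
    "Population",
    "SimulationConfig",
    "Trajectory",
    "individual_fitness",
    "meiosis",
    "next_generation",
    "evolve",
    "allele_frequencies",
    "DegeneratePopulationError",
]

_INIT_CAP = 8


class DegeneratePopulationError(RuntimeError):
    """Raised when no parent can be sampled (e.g. all fitness zero)."""


@dataclass
class SimulationConfig:
    generations: int
    male_recombination: bool = False
    record_every: int | None = None
    fitness_combiner: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.fitness_combiner not in ("multiplicative", "additive"):
            raise ValueError("fitness_combiner must be 'multiplicative' or 'additive'")


@dataclass
class Trajectory:
    """Allele-frequency records: ``freqs[i]`` is the per-SNP frequency vector
    at generation ``generations[i]``."""

    generations: list[int]
    freqs: np.ndarray  # (n_records, L)


class Population:
    """A diploid population of N individuals over a founder panel.

    Haplotypes are run-length mosaics of founder haplotype rows; individual k
    owns haplotype rows 2k and 2k+1 of the track arrays.  ``is_female`` holds
    the sexes (floor(N/2) females).
    """

    def __init__(self, panel: HaplotypePanel, seg_end, seg_org, n_seg, is_female):
        self.panel = panel
        self.seg_end = seg_end
        self.seg_org = seg_org
        self.n_seg = n_seg
        self.is_female = np.asarray(is_female, dtype=bool)
        if self.seg_end.shape[0] != 2 * self.N:
            raise ValueError("track arrays must have 2N haplotype rows")

    @property
    def N(self) -> int:
        return self.is_female.shape[0]

    @property
    def cap(self) -> int:
        return self.seg_end.shape[1]

    # -- constructors -------------------------------------------------------

    @staticmethod
    def _default_sexes(n: int) -> np.ndarray:
        # alternate M, F, M, F ... -> floor(N/2) females, and contiguous
        # line blocks receive both sexes
        return np.arange(n) % 2 == 1

    @classmethod
    def from_line_indices(cls, panel: HaplotypePanel, line_indices) -> "Population":
        """Homozygous individuals: individual k carries two copies of founder
        haplotype ``line_indices[k]``."""
        line_indices = np.asarray(line_indices, dtype=np.int32)
        n = len(line_indices)
        seg_end = np.empty((2 * n, _INIT_CAP), dtype=np.int64)
        seg_org = np.empty((2 * n, _INIT_CAP), dtype=np.int32)
        seg_end[:, 0] = panel.chrom_length
        seg_org[:, 0] = np.repeat(line_indices, 2)
        n_seg = np.ones(2 * n, dtype=np.int32)
        return cls(panel, seg_end, seg_org, n_seg, cls._default_sexes(n))

    @classmethod
    def outbred(cls, panel: HaplotypePanel, n: int, rng: np.random.Generator) -> "Population":
        """Outbred individuals: each haplotype drawn uniformly with
        replacement from the founder panel."""
        hap = rng.integers(0, panel.n_hap, size=2 * n).astype(np.int32)
        seg_end = np.empty((2 * n, _INIT_CAP), dtype=np.int64)
        seg_org = np.empty((2 * n, _INIT_CAP), dtype=np.int32)
        seg_end[:, 0] = panel.chrom_length
        seg_org[:, 0] = hap
        n_seg = np.ones(2 * n, dtype=np.int32)
        return cls(panel, seg_end, seg_org, n_seg, cls._default_sexes(n))

    @classmethod
    def from_members(cls, panel: HaplotypePanel, pops_and_indices) -> "Population":
        """Assemble a population from (population, individual-indices) pairs,
        copying the selected individuals' haplotype tracks."""
        caps = [p.cap for p, _ in pops_and_indices]
        cap = max(caps)
        n = sum(len(idx) for _, idx in pops_and_indices)
        seg_end = np.zeros((2 * n, cap), dtype=np.int64)
        seg_org = np.zeros((2 * n, cap), dtype=np.int32)
        n_seg = np.empty(2 * n, dtype=np.int32)
        r = 0
        for pop, idx in pops_and_indices:
            for k in np.asarray(idx, dtype=np.int64):
                for h in (2 * k, 2 * k + 1):
                    m = pop.n_seg[h]
                    seg_end[r, :m] = pop.seg_end[h, :m]
                    seg_org[r, :m] = pop.seg_org[h, :m]
                    n_seg[r] = m
                    r += 1
        return cls(panel, seg_end, seg_org, n_seg, cls._default_sexes(n))

    # -- queries ------------------------------------------------------------

    def allele_counts(self) -> np.ndarray:
        """Per-SNP derived-allele count over the 2N haplotypes (exact)."""
        out = np.zeros(self.panel.n_snps, dtype=np.int64)
        _kernels.decode_counts_kernel(
            self.seg_end, self.seg_org, self.n_seg,
            self.panel.positions, self.panel.alleles, out,
        )
        return out

    def genotypes_at(self, targets: list[SelectionTarget]) -> np.ndarray:
        """(N, n_targets) derived-allele counts (0/1/2) per individual."""
        out = np.zeros((self.N, len(targets)), dtype=np.uint8)
        if targets:
            tsnp = np.array([t.snp_index for t in targets], dtype=np.int64)
            tpos = self.panel.positions[tsnp]
            _kernels.genotypes_at_kernel(
                self.seg_end, self.seg_org, self.n_seg,
                tpos, tsnp, self.panel.alleles, out,
            )
        return out

    def haplotype_matrix(self) -> np.ndarray:
        """Decode the full (2N, L) binary allele matrix (for inspection and
        tests; O(N*L))."""
        pos = self.panel.positions
        out = np.empty((2 * self.N, len(pos)), dtype=np.uint8)
        for r in range(2 * self.N):
            idx0 = 0
            for i in range(self.n_seg[r]):
                idx1 = np.searchsorted(pos, self.seg_end[r, i], side="right")
                out[r, idx0:idx1] = self.panel.alleles[self.seg_org[r, i], idx0:idx1]
                idx0 = idx1
        return out


def allele_frequencies(pop: Population) -> np.ndarray:
    """Per-SNP derived-allele frequency: count / 2N."""
    return pop.allele_counts() / (2.0 * pop.N)


def individual_fitness(
    genotype_at_targets,
    targets: list[SelectionTarget],
    combiner: str = "multiplicative",
) -> np.ndarray:
    """Fitness from derived-allele counts at the selected loci.

    Per-locus factor 1, 1 + h*s, or 1 + s for 0, 1, 2 derived copies,
    combined multiplicatively across loci (or additively on the selection
    differentials, floored at 0)."""
    g = np.atleast_2d(np.asarray(genotype_at_targets))
    if g.size and (g.min() < 0 or g.max() > 2):
        raise ValueError("genotype counts must be in {0, 1, 2}")
    if not targets:
        return np.ones(g.shape[0])
    s = np.array([t.s for t in targets])
    h = np.array([t.h for t in targets])
    contrib = np.where(g == 2, s, np.where(g == 1, h * s, 0.0))
    if combiner == "multiplicative":
        return np.prod(1.0 + contrib, axis=1)
    return np.maximum(1.0 + contrib.sum(axis=1), 0.0)


def _draw_crossover_cuts(recmap: RecombinationMap, n_meioses: int, rng: np.random.Generator):
    """Sample per-meiosis crossover cut positions.

    Counts are Poisson(total map length in Morgans); positions are placed
    along the genetic map (uniform in Morgans, i.e. density proportional to
    the local rate) and converted to bp.  Returns (flat sorted cuts, offsets)
    with ``cuts[off[i]:off[i+1]]`` the ascending cuts of meiosis i."""
    maplen = recmap.total_map_length
    if maplen == 0 or n_meioses == 0:
        return (np.empty(0, dtype=np.int64), np.zeros(n_meioses + 1, dtype=np.int64))
    counts = rng.poisson(maplen, size=n_meioses)
    off = np.zeros(n_meioses + 1, dtype=np.int64)
    np.cumsum(counts, out=off[1:])
    total = int(off[-1])
    g = rng.random(total) * maplen
    bp = recmap.genetic_to_physical(g)
    # sort within each meiosis: stable sort on a composite key
    owner = np.repeat(np.arange(n_meioses, dtype=np.int64), counts)
    order = np.argsort(owner * (recmap.chrom_length + 1) + bp, kind="stable")
    return bp[order], off


def meiosis(
    parent: tuple[np.ndarray, np.ndarray],
    recmap: RecombinationMap,
    positions: np.ndarray,
    recombining: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete from a parent's two explicit haplotype vectors.

    If ``recombining``, the crossover count is Poisson(map length) with
    positions placed proportionally to the local rate, and the gamete
    alternates between the parental haplotypes starting from a random one.
    Otherwise the gamete is one intact parental haplotype chosen uniformly.
    """
    h1, h2 = np.asarray(parent[0]), np.asarray(parent[1])
    if h1.shape != h2.shape:
        raise ValueError("parental haplotypes must have the same length")
    if positions[-1] > recmap.chrom_length:
        raise ValueError("SNP positions exceed the recombination map length")
    start = int(rng.integers(0, 2))
    if not recombining:
        return (h1 if start == 0 else h2).copy()
    cuts, _ = _draw_crossover_cuts(recmap, 1, rng)
    # a cut at c switches haplotype for positions > c
    hap = (start + np.searchsorted(cuts, positions, side="left")) % 2
    return np.where(hap == 0, h1, h2).astype(h1.dtype)


def next_generation(
    pop: Population,
    targets: list[SelectionTarget],
    recmap: RecombinationMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Population:
    """One Wright-Fisher generation: fitness-proportional parent sampling
    (mothers among females, fathers among males, with replacement) and
    gamete formation with female (and optionally male) recombination."""
    if recmap.chrom_length != pop.panel.chrom_length:
        raise ValueError("recombination map and panel chromosome lengths differ")
    n = pop.N
    females = np.flatnonzero(pop.is_female)
    males = np.flatnonzero(~pop.is_female)
    if len(females) == 0 or len(males) == 0:
        raise DegeneratePopulationError("need at least one female and one male")
    w = individual_fitness(pop.genotypes_at(targets), targets, config.fitness_combiner)
    wf, wm = w[females], w[males]
    if wf.sum() == 0 or wm.sum() == 0:
        raise DegeneratePopulationError("all parental fitness is zero")
    mothers = rng.choice(females, size=n, p=wf / wf.sum()).astype(np.int64)
    fathers = rng.choice(males, size=n, p=wm / wm.sum()).astype(np.int64)
    m_start = rng.integers(0, 2, size=n).astype(np.int8)
    f_start = rng.integers(0, 2, size=n).astype(np.int8)
    m_cuts, m_off = _draw_crossover_cuts(recmap, n, rng)
    if config.male_recombination:
        f_cuts, f_off = _draw_crossover_cuts(recmap, n, rng)
    else:
        f_cuts, f_off = np.empty(0, dtype=np.int64), np.zeros(n + 1, dtype=np.int64)

    cap = pop.cap
    while True:
        out_end = np.empty((2 * n, cap), dtype=np.int64)
        out_org = np.empty((2 * n, cap), dtype=np.int32)
        out_nseg = np.empty(2 * n, dtype=np.int32)
        status = _kernels.next_generation_kernel(
            pop.seg_end, pop.seg_org, pop.n_seg,
            mothers, fathers, m_start, f_start,
            m_cuts, m_off, f_cuts, f_off,
            out_end, out_org, out_nseg, pop.panel.chrom_length,
        )
        if status != _kernels.OVERFLOW:
            break
        cap *= 2  # deterministic retry: all random draws already fixed
    return Population(pop.panel, out_end, out_org, out_nseg,
                      Population._default_sexes(n))


def evolve(
    pop: Population,
    targets: list[SelectionTarget],
    recmap: RecombinationMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Population, Trajectory]:
    """Evolve for ``config.generations`` generations, recording per-SNP
    allele frequencies at generation 0, every ``record_every`` generations
    (if set) and at the final generation."""
    rec_gens = [0]
    rec_freqs = [allele_frequencies(pop)]
    for g in range(1, config.generations + 1):
        pop = next_generation(pop, targets, recmap, config, rng)
        if (config.record_every and g % config.record_every == 0
                and g != config.generations):
            rec_gens.append(g)
            rec_freqs.append(allele_frequencies(pop))
    if config.generations > 0:
        rec_gens.append(config.generations)
        rec_freqs.append(allele_frequencies(pop))
    return pop, Trajectory(rec_gens, np.vstack(rec_freqs))


def write_trajectory(traj: Trajectory, panel: HaplotypePanel, path) -> None:
    """Tab-separated trajectory: generation, snp_index, position, frequency."""
    with open(path, "w") as fh:
        fh.write("generation\tsnp_index\tposition\tfrequency\n")
        for gi, g in enumerate(traj.generations):
            for j in range(panel.n_snps):
                fh.write(f"{g}\t{j}\t{panel.positions[j]}\t{traj.freqs[gi, j]:.6g}\n")
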