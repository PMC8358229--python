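"""Synthetic founder haplotype panels, recombination maps, and selection targets.

Experimental evolution with *Drosophila*-style founder lines starts from a
panel of phased, inbred haplotypes segregating standing variation.  This
module generates such panels parametrically: derived-allele frequencies follow
a truncated power-law site-frequency spectrum (SFS), and linkage
disequilibrium is induced by building every haplotype as a block mosaic of a
small number of prototype haplotypes.  It also generates piecewise-constant
recombination maps and draws selection targets (selection coefficient ``s``,
dominance ``h``) the way an E&R power study samples them.

All generators take explicit integer seeds and are deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypePanel",
    "RecombinationMap",
    "SelectionTarget",
    "generate_recmap",
    "generate_panel",
    "sample_targets",
    "sample_dilution_focal_frequency",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_recmap",
    "write_recmap",
]


@dataclass
class SelectionTarget:
    """A positively selected SNP: panel column index, selection coefficient
    ``s`` and dominance coefficient ``h``.

    Genotype fitness contributions are 1, 1 + h*s and 1 + s for 0, 1 and 2
    derived copies.  ``h = 0.5`` is codominant (additive), ``h = 1`` dominant.
    """

    snp_index: int
    s: float
    h: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"selection coefficient must be positive, got {self.s}")


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map over one chromosome arm.

    ``starts``/``ends`` are half-open bp windows tiling [1, chrom_length + 1);
    ``rates`` are in cM/Mb.
    """

    chrom: str
    starts: np.ndarray  # int64, 1-based window start (inclusive)
    ends: np.ndarray  # int64, window end (exclusive)
    rates: np.ndarray  # float64, cM/Mb

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if np.any(self.rates < 0):
            raise ValueError("recombination rates must be non-negative")
        if self.starts[0] != 1:
            raise ValueError("map must start at position 1")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("windows must tile the chromosome without gaps")

    @property
    def chrom_length(self) -> int:
        return int(self.ends[-1] - 1)

    @property
    def total_map_length(self) -> float:
        """Total genetic length in Morgans (sum of rate x width)."""
        widths_mb = (self.ends - self.starts) / 1e6
        return float(np.sum(self.rates * widths_mb) / 100.0)

    def cumulative_morgans(self) -> np.ndarray:
        """Cumulative genetic position (Morgans) at each window boundary,
        length n_windows + 1, starting at 0."""
        widths_mb = (self.ends - self.starts) / 1e6
        return np.concatenate([[0.0], np.cumsum(self.rates * widths_mb) / 100.0])

    def genetic_to_physical(self, g: np.ndarray) -> np.ndarray:
        """Map genetic positions (Morgans in [0, total length]) to bp."""
        g = np.asarray(g, dtype=np.float64)
        cum = self.cumulative_morgans()
        # window index containing each genetic position
        idx = np.clip(np.searchsorted(cum, g, side="right") - 1, 0, len(self.rates) - 1)
        # rate could be zero inside a window only if g sits exactly on the
        # boundary; guard the division.
        per_bp = self.rates[idx] / 100.0 / 1e6
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(per_bp > 0, (g - cum[idx]) / per_bp, 0.0)
        bp = self.starts[idx] + frac
        return np.clip(bp.astype(np.int64), 1, self.chrom_length)


@dataclass
class HaplotypePanel:
    """Phased founder haplotypes over one chromosome arm.

    ``alleles`` is an (n_hap, L) binary matrix, 0 = ancestral, 1 = derived;
    ``positions`` are strictly increasing 1-based bp coordinates.  Each row is
    one founder line (an inbred line homozygous for that haplotype).
    Monomorphic columns are dropped at construction.
    """

    chrom: str
    chrom_length: int
    positions: np.ndarray
    alleles: np.ndarray
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.n_hap < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions / alleles length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions[0] < 1 or self.positions[-1] > self.chrom_length:
            raise ValueError("positions must lie in [1, chrom_length]")
        # drop monomorphic columns: only segregating biallelic SNPs are tested
        counts = self.alleles.sum(axis=0)
        keep = (counts > 0) & (counts < self.n_hap)
        if not np.all(keep):
            self.positions = self.positions[keep]
            self.alleles = np.ascontiguousarray(self.alleles[:, keep])
        if not self.line_ids:
            self.line_ids = [f"line_{i}" for i in range(self.n_hap)]
        if len(self.line_ids) != self.n_hap:
            raise ValueError("line_ids length must equal number of haplotypes")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency of each SNP across the panel."""
        return self.alleles.mean(axis=0)


def generate_recmap(
    chrom_length: int,
    n_windows: int,
    total_map_length: float,
    seed: int,
    chrom: str = "2L",
) -> RecombinationMap:
    """Generate a piecewise recombination map with the requested total
    genetic length (Morgans).

    Window rates are drawn from a Gamma(2) distribution and rescaled so the
    total map length is exact; with ``total_map_length == 0`` all rates are 0.
    """
    chrom_length = int(chrom_length)
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if total_map_length < 0:
        raise ValueError("total_map_length must be >= 0")
    rng = np.random.default_rng(seed)
    bounds = np.linspace(1, chrom_length + 1, n_windows + 1).astype(np.int64)
    starts, ends = bounds[:-1], bounds[1:]
    widths_mb = (ends - starts) / 1e6
    if total_map_length == 0:
        rates = np.zeros(n_windows)
    else:
        raw = rng.gamma(2.0, 1.0, size=n_windows)
        # rescale so sum(rate * width) = total map length in cM
        rates = raw * (total_map_length * 100.0) / np.sum(raw * widths_mb)
    return RecombinationMap(chrom=chrom, starts=starts, ends=ends, rates=rates)


def generate_panel(
    n_hap: int = 100,
    n_snps: int = 5000,
    chrom_length: int = 23_500_000,
    sfs_exponent: float = 1.0,
    n_prototypes: int = 12,
    block_length: float = 100_000.0,
    seed: int = 0,
    chrom: str = "2L",
) -> HaplotypePanel:
    """Generate a founder panel with a power-law SFS and block-mosaic LD.

    Each haplotype is a mosaic of ``n_prototypes`` prototype labels with
    geometrically distributed block lengths (mean ``block_length`` bp).  At
    every SNP a target derived-allele count is drawn with
    P(count = c) proportional to c**(-sfs_exponent), c = 1..n_hap-1, and a
    subset of prototypes is greedily assigned the derived allele so the
    realized count comes as close as possible to the target.  Columns
    therefore always segregate, and nearby SNPs share the same prototype
    partition, which is what induces LD.
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_prototypes > n_hap:
        raise ValueError("n_prototypes must not exceed n_hap")
    rng = np.random.default_rng(seed)

    positions = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=n_snps, replace=False))

    # mosaic prototype assignment per haplotype: Markov switching along the chrom
    assign = np.empty((n_hap, n_snps), dtype=np.int32)
    gaps = np.diff(positions, prepend=positions[0])
    p_switch = 1.0 - np.exp(-gaps / float(block_length))
    for i in range(n_hap):
        switch = rng.random(n_snps) < p_switch
        switch[0] = True
        labels = rng.integers(0, n_prototypes, size=int(switch.sum()))
        assign[i] = labels[np.cumsum(switch) - 1]

    # target derived counts from the truncated power-law SFS
    cvals = np.arange(1, n_hap)
    w = cvals.astype(float) ** (-float(sfs_exponent))
    target = rng.choice(cvals, size=n_snps, p=w / w.sum())

    alleles = np.zeros((n_hap, n_snps), dtype=np.uint8)
    proto_order = rng.permuted(
        np.tile(np.arange(n_prototypes), (n_snps, 1)), axis=1
    )
    for j in range(n_snps):
        # usage count of each prototype at this SNP
        u = np.bincount(assign[:, j], minlength=n_prototypes)
        # greedy subset: add prototypes (random order) while staying <= target;
        # then, if nothing selected, take the single prototype closest to target
        tot, chosen = 0, []
        for k in proto_order[j]:
            if u[k] == 0:
                continue
            if tot + u[k] <= target[j]:
                chosen.append(k)
                tot += u[k]
        if tot == 0:
            used = np.flatnonzero(u > 0)
            k = used[np.argmin(np.abs(u[used] - target[j]))]
            chosen = [k]
            tot = u[k]
        if tot == n_hap:  # keep the column segregating
            chosen.pop()
        mask = np.isin(assign[:, j], chosen)
        alleles[mask, j] = 1

    return HaplotypePanel(
        chrom=chrom,
        chrom_length=int(chrom_length),
        positions=positions,
        alleles=alleles,
    )


def sample_targets(
    panel: HaplotypePanel,
    n_targets: int,
    s_low: float = 0.07,
    s_high: float = 0.1,
    h_choices: tuple[float, ...] = (0.5, 1.0),
    freq_range: tuple[float, float] = (0.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> list[SelectionTarget]:
    """Draw selection targets: distinct SNP indices with panel frequency in
    ``freq_range``, s ~ Uniform(s_low, s_high), h uniform over ``h_choices``.
    """
    if not 0 < s_low <= s_high:
        raise ValueError("need 0 < s_low <= s_high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = panel.frequencies()
    candidates = np.flatnonzero((freqs > freq_range[0]) & (freqs < freq_range[1]))
    if len(candidates) < n_targets:
        raise ValueError(
            f"only {len(candidates)} candidate SNPs in frequency range {freq_range}, "
            f"need {n_targets}"
        )
    idx = rng.choice(candidates, size=n_targets, replace=False)
    s = rng.uniform(s_low, s_high, size=n_targets)
    h = rng.choice(np.asarray(h_choices, dtype=float), size=n_targets)
    return [SelectionTarget(int(i), float(si), float(hi)) for i, si, hi in zip(idx, s, h)]


def sample_dilution_focal_frequency(
    seed: int | np.random.Generator,
    size: int | None = None,
    a: float = 2.0,
    b: float = 18.0,
):
    """Draw focal-SNP starting frequencies for dilution schemes.

    Stand-in for the empirical starting-frequency distribution of selected
    alleles in a primary E&R (mean 0.1): Beta(2, 18) by default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.beta(a, b, size=size)
    return out


# ---------------------------------------------------------------------------
# file formats: MimicrEE2-style haplotype table and recombination-map TSV
# ---------------------------------------------------------------------------

_REF, _DERIVED = "A", "T"


def write_haplotype_table(panel: HaplotypePanel, path) -> None:
    """Tab-separated haplotype table: chrom, pos, ref, derived, then one
    haploid genotype column (A/T) per founder line."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\tderived\t" + "\t".join(panel.line_ids) + "\n")
        codes = np.array([_REF, _DERIVED])
        for j in range(panel.n_snps):
            geno = codes[panel.alleles[:, j]]
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{_REF}\t{_DERIVED}\t"
                + "\t".join(geno)
                + "\n"
            )


def read_haplotype_table(path, chrom_length: int | None = None) -> HaplotypePanel:
    """Read a haplotype table written by :func:`write_haplotype_table` (a
    header line is optional; without one, line ids are generated)."""
    line_ids: list[str] = []
    positions, rows, chrom = [], [], None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if raw.startswith("#"):
                line_ids = raw.lstrip("#").split("\t")[4:]
                continue
            parts = raw.split("\t")
            if len(parts) < 5:
                raise ValueError(f"haplotype table line {ln}: expected >=5 columns")
            chrom = parts[0]
            positions.append(int(parts[1]))
            derived = parts[3]
            rows.append([1 if g == derived else 0 for g in parts[4:]])
    alleles = np.asarray(rows, dtype=np.uint8).T
    if chrom_length is None:
        chrom_length = int(max(positions))
    return HaplotypePanel(
        chrom=chrom or "2L",
        chrom_length=chrom_length,
        positions=np.asarray(positions),
        alleles=alleles,
        line_ids=line_ids or [],
    )


def write_recmap(recmap: RecombinationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\twindow_start\twindow_end\trate_cM_per_Mb\n")
        for s, e, r in zip(recmap.starts, recmap.ends, recmap.rates):
            fh.write(f"{recmap.chrom}\t{s}\t{e}\t{float(r)!r}\n")


def read_recmap(path) -> RecombinationMap:
    starts, ends, rates, chrom = [], [], [], "2L"
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            c, s, e, r = raw.split("\t")
            chrom = c
            starts.append(int(s))
            ends.append(int(e))
            rates.append(float(r))
    return RecombinationMap(chrom=chrom, starts=np.array(starts), ends=np.array(ends), rates=np.array(rates))
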