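"""Generation-0 population construction for secondary E&R crossing schemes.

Five scheme families are supported:

* ``1:1`` (versions ``1f``, ``2f``, ``1f1nf``): the inbred focal line carrying
  the selection target is crossed at 50% to inbred nonfocal lines -- one per
  replicate (a different one in each replicate), so a focal-private SNP
  starts at frequency 0.5.
* ``1:few`` / ``1:many``: the focal line at 50% is crossed to a fixed pool of
  5 / 99 nonfocal lines, identical across replicates.
* ``dil:st`` / ``dil:mt``: a primary E&R (outbred base population of founder
  lines, N = 300, 60 generations, one replicate) is run first; 50% of the
  evolved population is then replaced by fresh ancestral genotypes and the
  diluted populations are evolved again under the same selection regime.
  Testing in the secondary E&R is restricted to a 1 Mb window around the SNP
  with the highest chi-square statistic in the primary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founders import HaplotypePanel, RecombinationMap, SelectionTarget
from .poolseq import sample_counts
from .simulate import Population, SimulationConfig, allele_frequencies, evolve
from .stats import chisq_scan

__all__ = [
    "SCHEMES",
    "ARCHITECTURES",
    "ExperimentDesign",
    "WindowSelection",
    "largest_remainder",
    "make_line_cross_population",
    "assign_replicate_partners",
    "place_targets_1to1",
    "run_primary_er",
    "PrimaryER",
    "select_window",
    "dilute",
    "pick_focal_target_dilmt",
]

SCHEMES = ("1:1_1f", "1:1_2f", "1:1_1f1nf", "1:few", "1:many", "dil:st", "dil:mt")
ARCHITECTURES = ("1f", "2f_h05", "2f_h1", "1f1nf_h05", "1f1nf_h1")

_N_FEW = 5  # nonfocal pool size of the 1:few scheme
_N_DILMT_TARGETS = 16  # selection targets of the dil:mt primary


@dataclass
class ExperimentDesign:
    """One experimental design: a crossing scheme with its population size,
    duration and replication.  ``architecture`` selects the 1:1 variant
    (where the additional target sits and its dominance)."""

    scheme: str
    N: int
    generations: int = 60
    replicates: int = 5
    architecture: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.architecture is not None and self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.scheme == "1:1_2f" and self.architecture is None:
            self.architecture = "2f_h05"
        if self.scheme == "1:1_1f1nf" and self.architecture is None:
            self.architecture = "1f1nf_h05"
        if self.scheme == "1:1_1f":
            self.architecture = "1f"


@dataclass
class WindowSelection:
    """A bp window centred on the top-scan SNP, and the SNP indices inside."""

    center_snp_index: int
    start: int
    end: int
    snp_indices: np.ndarray


def largest_remainder(proportions, n: int) -> np.ndarray:
    """Apportion n individuals to proportions exactly (largest-remainder
    rounding): floor everything, then give the leftover units to the largest
    fractional parts."""
    p = np.asarray(proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    raw = p * n
    counts = np.floor(raw).astype(np.int64)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def make_line_cross_population(
    panel: HaplotypePanel,
    focal_line: int,
    partner_lines,
    N: int,
    proportions=None,
) -> Population:
    """Generation-0 population of homozygous line individuals.

    By default the focal line takes proportion 0.5 and the partner lines
    share the other half equally; counts are apportioned with
    largest-remainder rounding so the census is exactly N."""
    partner_lines = list(partner_lines)
    if not partner_lines:
        raise ValueError("need at least one partner line")
    if proportions is None:
        proportions = [0.5] + [0.5 / len(partner_lines)] * len(partner_lines)
    if len(proportions) != 1 + len(partner_lines):
        raise ValueError("need one proportion per line (focal first)")
    counts = largest_remainder(proportions, N)
    lines = np.repeat([focal_line] + partner_lines, counts)
    return Population.from_line_indices(panel, lines)


def assign_replicate_partners(
    panel: HaplotypePanel,
    scheme: str,
    n_replicates: int,
    rng: np.random.Generator,
    focal_line: int,
    focal_snp: int,
) -> list[list[int]]:
    """Nonfocal partner lines per replicate.

    Only lines not carrying the focal derived allele qualify (a carrier
    partner would not contrast the target).  1:1 schemes use a different
    partner line in every replicate; 1:few and 1:many use the same line
    mixture in all replicates."""
    carriers = panel.alleles[:, focal_snp] == 1
    noncarriers = [i for i in range(panel.n_hap) if not carriers[i] and i != focal_line]
    if scheme.startswith("1:1"):
        if n_replicates > len(noncarriers):
            raise ValueError(
                f"{n_replicates} replicates need that many distinct noncarrier "
                f"lines, only {len(noncarriers)} available"
            )
        chosen = rng.choice(noncarriers, size=n_replicates, replace=False)
        return [[int(c)] for c in chosen]
    if scheme == "1:few":
        pool = rng.choice(noncarriers, size=_N_FEW, replace=False)
        return [[int(c) for c in pool]] * n_replicates
    if scheme == "1:many":
        return [noncarriers] * n_replicates
    raise ValueError(f"scheme {scheme!r} does not use line-cross partners")


def place_targets_1to1(
    panel: HaplotypePanel,
    architecture: str,
    rng: np.random.Generator,
    s_focal_range: tuple[float, float] = (0.07, 0.1),
    h_choices: tuple[float, ...] = (0.5, 1.0),
    min_noncarriers: int = 30,
    partner_lines: list[int] | None = None,
    focal: tuple[SelectionTarget, int] | None = None,
) -> tuple[list[SelectionTarget], int, int | None]:
    """Selection targets for the 1:1 crossing schemes.

    The focal target is a SNP with enough noncarrier lines to supply
    replicate partners; the focal line is a carrier.  For ``2f_*`` a second
    target (s ~ U(0.07, s_focal), h fixed by the architecture label) sits on
    the focal haplotype; for ``1f1nf_*`` it sits on exactly one nonfocal
    partner haplotype (pass the replicate partner lines, which are assigned
    after the focal draw -- a pre-drawn focal target can be supplied via
    ``focal``).  Returns (targets, focal_line, carrier line of the
    additional target or None)."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if s_focal_range[0] < 0.07:
        raise ValueError("s_focal below 0.07 leaves an empty range for the "
                         "additional target")
    if focal is not None:
        focal_target, focal_line = focal
        focal_snp, s_focal = focal_target.snp_index, focal_target.s
        targets = [focal_target]
    else:
        counts = panel.alleles.sum(axis=0)
        cand = np.flatnonzero((counts >= 1) & (counts <= panel.n_hap - min_noncarriers))
        if not len(cand):
            raise ValueError("no candidate focal SNP with enough noncarrier lines")
        focal_snp = int(rng.choice(cand))
        focal_line = int(rng.choice(np.flatnonzero(panel.alleles[:, focal_snp] == 1)))
        s_focal = float(rng.uniform(*s_focal_range))
        h_focal = float(rng.choice(np.asarray(h_choices, dtype=float)))
        targets = [SelectionTarget(focal_snp, s_focal, h_focal)]
    carrier: int | None = None
    if architecture == "1f":
        return targets, focal_line, carrier
    h2 = 0.5 if architecture.endswith("h05") else 1.0
    s2 = float(rng.uniform(0.07, s_focal))
    if architecture.startswith("2f"):
        carrier = focal_line
        snp_cand = np.flatnonzero(panel.alleles[focal_line] == 1)
    else:  # 1f1nf: target on one nonfocal partner haplotype
        if not partner_lines:
            raise ValueError("1f1nf architectures need the replicate partner lines")
        carrier = int(rng.choice(np.asarray(partner_lines)))
        snp_cand = np.flatnonzero(
            (panel.alleles[carrier] == 1) & (panel.alleles[focal_line] == 0)
        )
    snp_cand = snp_cand[snp_cand != focal_snp]
    if not len(snp_cand):
        raise ValueError("no candidate SNP for the additional target")
    targets.append(SelectionTarget(int(rng.choice(snp_cand)), s2, h2))
    return targets, focal_line, carrier


@dataclass
class PrimaryER:
    """Outcome of the primary E&R embedded in the dilution schemes."""

    ancestral: Population
    evolved: Population
    start_freqs: np.ndarray
    end_freqs: np.ndarray
    chi2: np.ndarray  # per-SNP statistic at depth-rescaled counts


def run_primary_er(
    panel: HaplotypePanel,
    targets: list[SelectionTarget],
    recmap: RecombinationMap,
    rng: np.random.Generator,
    N: int = 300,
    generations: int = 60,
    depth: int = 80,
) -> PrimaryER:
    """Primary E&R for dilution schemes: one outbred population of founder
    genotypes (N = 300), 60 generations, one replicate; start/end allele
    counts rescaled to uniform depth feed the chi-square scan."""
    ancestral = Population.outbred(panel, N, rng)
    cfg = SimulationConfig(generations=generations)
    evolved, traj = evolve(ancestral, targets, recmap, cfg, rng)
    f0, f1 = traj.freqs[0], traj.freqs[-1]
    d0, a0 = sample_counts(f0, depth, rng)
    d1, a1 = sample_counts(f1, depth, rng)
    chi2 = chisq_scan(d0, a0, d1, a1)
    return PrimaryER(ancestral, evolved, f0, f1, chi2)


def select_window(
    chi2_stats,
    positions,
    chrom_length: int,
    width: float = 1e6,
) -> WindowSelection:
    """The bp window of given width centred on the SNP with the highest
    statistic (ties broken by lowest position), clipped at the chromosome
    ends."""
    stats = np.asarray(chi2_stats, dtype=float)
    positions = np.asarray(positions)
    if not np.any(np.isfinite(stats)):
        raise ValueError("no testable SNP in the scan")
    smax = np.nanmax(stats)
    center = int(np.flatnonzero(stats == smax)[0])  # lowest position wins ties
    half = int(width // 2)
    start = max(1, int(positions[center]) - half)
    end = min(chrom_length, int(positions[center]) + half)
    inside = np.flatnonzero((positions >= start) & (positions <= end))
    return WindowSelection(center, start, end, inside)


def dilute(
    evolved: Population,
    panel: HaplotypePanel,
    N: int,
    rng: np.random.Generator,
    fraction: float = 0.5,
) -> Population:
    """Replace ``fraction`` of a population with fresh ancestral genotypes.

    Draws round(N * (1 - fraction)) individuals uniformly without
    replacement from the evolved population and adds round(N * fraction)
    newly constructed outbred ancestral individuals; census exactly N.
    When the diluted population is larger than the evolved one (a secondary
    experiment expanded beyond the primary census), evolved genotypes are
    drawn with replacement instead."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if evolved.N == 0:
        raise ValueError("evolved population is empty")
    n_anc = int(round(N * fraction))
    n_evo = N - n_anc
    keep = rng.choice(evolved.N, size=n_evo, replace=n_evo > evolved.N)
    ancestral = Population.outbred(panel, n_anc, rng)
    return Population.from_members(
        panel, [(evolved, keep), (ancestral, np.arange(n_anc))]
    )


def pick_focal_target_dilmt(
    targets: list[SelectionTarget],
    window: WindowSelection,
    top_snp_index: int,
    positions,
) -> SelectionTarget | None:
    """Among targets inside the window, the one closest (bp) to the SNP with
    the highest CMH statistic; ties go to the lower position.  None if no
    target lies in the window (the simulation is then scored a failure)."""
    positions = np.asarray(positions)
    inside = [t for t in targets if t.snp_index in set(window.snp_indices.tolist())]
    if not inside:
        return None
    top_pos = positions[top_snp_index]
    dists = [(abs(int(positions[t.snp_index]) - int(top_pos)),
              int(positions[t.snp_index])) for t in inside]
    best = min(range(len(inside)), key=lambda i: dists[i])
    return inside[best]
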