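"""Detection statistics for E&R scans.

SNP-wise tests of allele-frequency change between the start and the end of
an experiment: the Pearson chi-square test for a single population and the
Cochran-Mantel-Haenszel (CMH) test across replicate strata.  Each stratum is
a 2x2 table with rows = timepoint (start, end) and columns = allele
(derived, ancestral), entries = read counts.  No continuity correction is
applied, so the single-stratum CMH statistic equals (n-1)/n times the
Pearson chi-square of the same table.

SNPs are ranked by their statistic with dense ranking (ties share a rank,
no gaps), and a simulation is classified successful if the true selection
target is the top-ranked SNP (success-A) or within a fixed number of SNPs
of it (success-B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "chisq_2x2",
    "chisq_scan",
    "cmh_statistic",
    "cmh_scan",
    "dense_rank",
    "evaluate_success",
    "resolution",
    "ScanResult",
]


def chisq_scan(d0, a0, d1, a1) -> np.ndarray:
    """Vectorized Pearson chi-square (no continuity correction) per SNP.

    Arguments are per-SNP count vectors: derived/ancestral at start (d0, a0)
    and end (d1, a1).  SNPs with any zero marginal are untestable -> NaN.
    """
    d0, a0, d1, a1 = (np.asarray(x, dtype=np.float64) for x in (d0, a0, d1, a1))
    n = d0 + a0 + d1 + a1
    r0, r1 = d0 + a0, d1 + a1
    c0, c1 = d0 + d1, a0 + a1
    denom = r0 * r1 * c0 * c1
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (d0 * a1 - a0 * d1) ** 2 / denom
    return np.where(denom > 0, stat, np.nan)


def chisq_2x2(table) -> float:
    """Pearson chi-square of one 2x2 table [[a, b], [c, d]] without
    continuity correction; NaN if any marginal is zero."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    return float(chisq_scan(t[0, 0], t[0, 1], t[1, 0], t[1, 1]))


def cmh_scan(d0, a0, d1, a1, alternative: str = "two-sided") -> np.ndarray:
    """Vectorized CMH statistic per SNP across K replicate strata.

    Inputs have shape (K, L): derived/ancestral counts at start and end.
    Per stratum, a = derived count at start, E[a] = row1 * col1 / n and
    Var(a) = row1 * row2 * col1 * col2 / (n^2 (n - 1)); strata with a zero
    marginal contribute 0 to both sums.  SNPs where every stratum is
    degenerate are untestable -> NaN.

    With ``alternative="increase"`` the scan targets derived-allele
    frequency rises: SNPs whose summed deviation points the other way keep
    statistic 0, so a sweeping-out allele can never top the ranking.
    """
    if alternative not in ("two-sided", "increase"):
        raise ValueError("alternative must be 'two-sided' or 'increase'")
    d0, a0, d1, a1 = (np.atleast_2d(np.asarray(x, dtype=np.float64))
                      for x in (d0, a0, d1, a1))
    n = d0 + a0 + d1 + a1
    r0, r1 = d0 + a0, d1 + a1
    c0, c1 = d0 + d1, a0 + a1
    ok = (r0 > 0) & (r1 > 0) & (c0 > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = r0 * c0 / n
        v = r0 * r1 * c0 * c1 / (n * n * (n - 1.0))
    dev = np.where(ok, d0 - e, 0.0).sum(axis=0)
    var = np.where(ok, v, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = dev * dev / var
    if alternative == "increase":
        # dev = sum(a_start - E[a_start]); a frequency increase at the end
        # pulls the start count below expectation (dev < 0)
        stat = np.where(dev < 0, stat, 0.0)
    return np.where(var > 0, stat, np.nan)


def cmh_statistic(tables) -> float:
    """CMH statistic of one SNP: ``tables`` is (K, 2, 2) with rows =
    timepoint (start, end), columns = allele (derived, ancestral)."""
    t = np.asarray(tables, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    if t.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    return float(
        cmh_scan(t[:, 0, 0, None], t[:, 0, 1, None], t[:, 1, 0, None], t[:, 1, 1, None])[0]
    )


def dense_rank(statistics, descending: bool = True) -> np.ndarray:
    """Dense ranks starting at 1: tied values share a rank and the next
    distinct value gets the immediately following rank."""
    stats = np.asarray(statistics, dtype=np.float64)
    _, inv = np.unique(-stats if descending else stats, return_inverse=True)
    return inv + 1


@dataclass
class ScanResult:
    """Outcome of one scan: per-SNP statistics/ranks (NaN statistic = SNP
    untestable, rank 0), the focal target, and the success classification.
    ``distance`` counts SNP steps (position order, tested SNPs) between the
    focal target and the top-ranked SNP; -1 if the focal was untestable."""

    statistics: np.ndarray
    ranks: np.ndarray
    positions: np.ndarray
    focal_index: int
    success_a: bool
    success_b: bool
    distance: int
    n_top_ties: int


def evaluate_success(
    stats,
    positions,
    focal_index: int,
    threshold: int = 100,
    tie_rule: str = "nearest",
    rng: np.random.Generator | None = None,
) -> ScanResult:
    """Classify one simulation from its per-SNP scan statistics.

    The top SNP is the argmax of the statistic; ties at the maximum are
    broken by ``tie_rule``: "nearest" (tied SNP closest to the focal in
    position order, then lower position), "lowest" (lowest position) or
    "random" (uniform among ties, requires ``rng``).  The distance is the
    absolute difference of position-order indices among tested SNPs;
    success-A requires the focal to attain the maximum, success-B requires
    distance <= threshold.
    """
    stats = np.asarray(stats, dtype=np.float64)
    positions = np.asarray(positions)
    if not 0 <= focal_index < len(stats):
        raise ValueError("focal_index outside the SNP set")
    tested = np.flatnonzero(np.isfinite(stats))
    ranks = np.zeros(len(stats), dtype=np.int64)
    if len(tested):
        ranks[tested] = dense_rank(stats[tested])
    if not np.isfinite(stats[focal_index]):
        return ScanResult(stats, ranks, positions, focal_index,
                          False, False, -1, 0)
    # position-order index within the tested subset
    focal_t = int(np.searchsorted(tested, focal_index))
    smax = stats[tested].max()
    ties = np.flatnonzero(stats[tested] == smax)
    n_ties = len(ties)
    if tie_rule == "nearest":
        d = np.abs(ties - focal_t)
        top_t = int(ties[np.argmin(d)])  # argmin breaks ties by lower position
    elif tie_rule == "lowest":
        top_t = int(ties[0])
    elif tie_rule == "random":
        if rng is None:
            raise ValueError("tie_rule='random' requires an rng")
        top_t = int(rng.choice(ties))
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    distance = abs(focal_t - top_t)
    success_a = distance == 0 and stats[focal_index] == smax
    success_b = distance <= threshold
    return ScanResult(stats, ranks, positions, focal_index,
                      bool(success_a), bool(success_b), int(distance), n_ties)


def resolution(distances, threshold: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of top-SNP distances among successful simulations.

    Returns (support 0..threshold, ECDF values); the ECDF reaches 1 at the
    threshold by construction.  Raises on empty input."""
    d = np.asarray(distances)
    if d.size == 0:
        raise ValueError("no successful simulations: empty distance set")
    if np.any(d < 0) or np.any(d > threshold):
        raise ValueError("distances must lie in [0, threshold]")
    x = np.arange(threshold + 1)
    ecdf = np.searchsorted(np.sort(d), x, side="right") / d.size
    return x, ecdf


def write_scan(result: ScanResult, chrom: str, path, in_window=None) -> None:
    """Tab-separated scan output: chrom, pos, statistic, rank, is_focal,
    in_window."""
    iw = np.ones(len(result.positions), dtype=bool) if in_window is None else in_window
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstatistic\trank\tis_focal\tin_window\n")
        for j in range(len(result.positions)):
            fh.write(
                f"{chrom}\t{result.positions[j]}\t{result.statistics[j]:.6g}\t"
                f"{result.ranks[j]}\t{int(j == result.focal_index)}\t{int(iw[j])}\n"
            )
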