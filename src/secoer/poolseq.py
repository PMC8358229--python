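"""Pool-Seq emulation and PoPoolation2 sync-format I/O.

Population allele frequencies are converted to allele counts at a uniform
read depth by binomial resampling (no sequencing-error model: frequencies 0
and 1 give deterministic counts).  Count tables serialize to the sync
format: ``chrom  pos  ref  A:T:C:G:N:del`` per sample, with the derived
allele mapped to the A slot and the ancestral allele to the T slot.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountTable", "sample_counts", "write_sync", "read_sync", "SyncParseError"]


class SyncParseError(ValueError):
    pass


@dataclass
class CountTable:
    """Per-sample derived/ancestral allele counts at uniform read depth.

    ``derived``/``ancestral`` have shape (n_samples, L); a sample is one
    (replicate, timepoint) sequencing pool.  ``sample_names`` label them.
    """

    chrom: str
    positions: np.ndarray
    derived: np.ndarray
    ancestral: np.ndarray
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.derived = np.atleast_2d(np.asarray(self.derived, dtype=np.int64))
        self.ancestral = np.atleast_2d(np.asarray(self.ancestral, dtype=np.int64))
        if self.derived.shape != self.ancestral.shape:
            raise ValueError("derived / ancestral shape mismatch")
        if self.derived.shape[1] != len(self.positions):
            raise ValueError("counts / positions length mismatch")
        if np.any(self.derived < 0) or np.any(self.ancestral < 0):
            raise ValueError("counts must be non-negative")
        if not self.sample_names:
            self.sample_names = [f"sample_{i}" for i in range(self.n_samples)]

    @property
    def n_samples(self) -> int:
        return self.derived.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.derived + self.ancestral

    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency estimates, (n_samples, L)."""
        with np.errstate(invalid="ignore"):
            return self.derived / self.depth


def sample_counts(
    freqs: np.ndarray,
    depth: int = 80,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample allele counts to uniform read depth.

    Derived counts are Binomial(depth, freq) per SNP independently;
    ancestral = depth - derived.  Returns (derived, ancestral)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    derived = rng.binomial(depth, freqs)
    return derived, depth - derived


_SLOTS = 6  # A:T:C:G:N:del


def write_sync(table: CountTable, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for j in range(len(table.positions)):
            fields = [table.chrom, str(table.positions[j]), "A"]
            for i in range(table.n_samples):
                fields.append(f"{table.derived[i, j]}:{table.ancestral[i, j]}:0:0:0:0")
            fh.write("\t".join(fields) + "\n")


def read_sync(path, sample_names: list[str] | None = None) -> CountTable:
    """Read a sync file (gzip-transparent).  Derived counts are taken from
    the A slot and ancestral counts from the T slot; malformed lines raise
    :class:`SyncParseError` with the line number."""
    opener = gzip.open if str(path).endswith(".gz") else open
    chrom = None
    positions: list[int] = []
    der_rows: list[list[int]] = []
    anc_rows: list[list[int]] = []
    with opener(path, "rt") as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) < 4:
                raise SyncParseError(f"line {ln}: expected chrom, pos, ref and >=1 sample")
            chrom = parts[0]
            try:
                positions.append(int(parts[1]))
            except ValueError as e:
                raise SyncParseError(f"line {ln}: non-integer position {parts[1]!r}") from e
            der, anc = [], []
            for si, cell in enumerate(parts[3:]):
                counts = cell.split(":")
                if len(counts) != _SLOTS:
                    raise SyncParseError(
                        f"line {ln}: sample {si + 1} has {len(counts)} count fields, expected {_SLOTS}"
                    )
                try:
                    vals = [int(c) for c in counts]
                except ValueError as e:
                    raise SyncParseError(f"line {ln}: non-integer count in {cell!r}") from e
                der.append(vals[0])
                anc.append(vals[1])
            der_rows.append(der)
            anc_rows.append(anc)
    if not positions:
        raise SyncParseError("empty sync file")
    return CountTable(
        chrom=chrom or "2L",
        positions=np.asarray(positions),
        derived=np.asarray(der_rows).T,
        ancestral=np.asarray(anc_rows).T,
        sample_names=sample_names or [],
    )
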