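"""Genomic file I/O and sequence encoding.

Reads the formats the EEI pipeline touches (FASTA, BED, BEDPE) and converts
genomic intervals to the one-hot matrices the classifier consumes. All
coordinates are 0-based half-open (BED convention). Enhancers are treated as
strandless; the plus-strand sequence is always used. Windows overhanging a
chromosome end are padded with N rather than shifted, so the window midpoint
stays anchored on the region midpoint.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

# byte -> column lookup: A,C,G,T -> 0..3, N -> 4, anything else -> 5
_ENCODE_LUT = np.full(256, 5, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
_ENCODE_LUT[ord("N")] = 4


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 and self.end <= 0:
            raise ValueError(f"degenerate region {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def key(self) -> str:
        return self.id if self.id is not None else f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class LoopRecord:
    """One chromatin-interaction loop: two anchors plus an identifier."""

    anchor_left: GenomicRegion
    anchor_right: GenomicRegion
    loop_id: str


class Genome:
    """Random-access genome: out-of-range positions read as ``N``.

    Wraps either an indexed FASTA file or an in-memory ``{chrom: seq}``
    mapping (used by the synthetic fixtures and the test-suite).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
        except ValueError as exc:  # pyfaidx signals duplicate keys with ValueError
            raise FormatError(f"invalid FASTA {path}: {exc}") from exc
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        self._check(chrom)
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); positions outside the chromosome give N."""
        self._check(chrom)
        if end <= start:
            raise ValueError(f"end must exceed start ({start}, {end})")
        seq = self._seqs[chrom]
        lo, hi = max(start, 0), min(end, len(seq))
        core = seq[lo:hi] if hi > lo else ""
        return "N" * (lo - start) + core + "N" * (end - hi)

    def fetch_region(self, region: GenomicRegion) -> str:
        return self.fetch(region.chrom, region.start, region.end)

    def _check(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")


def read_fasta(path: str | os.PathLike) -> Genome:
    """Open a FASTA file as a random-access :class:`Genome`."""
    return Genome.from_fasta(path)


def _parse_coord(token: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate {token!r}") from exc


def _iter_lines(path: str | os.PathLike) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Parse a BED3+ file into regions; name column becomes the region id."""
    regions: list[GenomicRegion] = []
    for lineno, fields in _iter_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
        chrom = fields[0]
        start = _parse_coord(fields[1], str(path), lineno)
        end = _parse_coord(fields[2], str(path), lineno)
        if start >= end or start < 0:
            logger.warning("%s:%d: rejected record with start >= end (%d, %d)",
                           path, lineno, start, end)
            continue
        name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else None
        regions.append(GenomicRegion(chrom, start, end, id=name or f"{chrom}:{start}-{end}"))
    return regions


def read_bedpe(path: str | os.PathLike) -> list[LoopRecord]:
    """Parse a BEDPE file into loops; cross-chromosome records are rejected."""
    loops: list[LoopRecord] = []
    for lineno, fields in _iter_lines(path):
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: BEDPE needs >=6 columns")
        c1, s1, e1, c2, s2, e2 = fields[:6]
        s1i, e1i = (_parse_coord(t, str(path), lineno) for t in (s1, e1))
        s2i, e2i = (_parse_coord(t, str(path), lineno) for t in (s2, e2))
        if s1i >= e1i or s2i >= e2i or min(s1i, s2i) < 0:
            logger.warning("%s:%d: rejected malformed anchor coordinates", path, lineno)
            continue
        if c1 != c2:
            logger.warning("%s:%d: rejected cross-chromosome loop %s/%s", path, lineno, c1, c2)
            continue
        name = fields[6] if len(fields) >= 7 and fields[6] not in (".", "") else f"loop{lineno}"
        loops.append(LoopRecord(GenomicRegion(c1, s1i, e1i), GenomicRegion(c2, s2i, e2i), name))
    return loops


def write_bed(regions: list[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.key}\n")


def write_bedpe(loops: list[LoopRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_left, lp.anchor_right
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{lp.loop_id}\n")


def standardize_window(region: GenomicRegion, width: int = 2000) -> GenomicRegion:
    """Fixed-width window centered on the region midpoint.

    The returned start may be negative; sequence extraction pads with N so
    the midpoint stays anchored. Idempotent when the region already has the
    target width.
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be even and positive")
    mid = region.midpoint
    return GenomicRegion(region.chrom, mid - width // 2, mid + width // 2, id=region.id)


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a DNA string as an L x 4 binary matrix (columns A,C,G,T).

    N (and any unrecognized symbol, with a warning) encodes as an all-zero row.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    codes = _ENCODE_LUT[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 5):
        logger.warning("unrecognized bases treated as N")
        codes = np.where(codes == 5, 4, codes)
    mat = np.zeros((len(sequence), 5), dtype=np.float32)
    mat[np.arange(len(sequence)), codes] = 1.0
    return mat[:, :4]


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError("expected an L x 4 matrix")
    out = []
    for row in matrix:
        hits = np.flatnonzero(row)
        out.append(BASE_ORDER[hits[0]] if hits.size == 1 else "N")
    return "".join(out)


def region_to_tensor(genome: Genome, region: GenomicRegion, width: int = 2000) -> np.ndarray:
    """One-hot matrix of the width-standardized window around a region."""
    window = standardize_window(region, width)
    return one_hot_encode(genome.fetch_region(window))
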