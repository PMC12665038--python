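"""Position-weight-matrix containers and JASPAR/MEME text I/O."""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .genomio import BASE_ORDER


@dataclass
class PwmMotif:
    """A sequence motif as a position probability matrix (rows sum to 1)."""

    matrix: np.ndarray  # (width, 4), columns A,C,G,T
    name: str
    source: str = "database"  # or "attribution"
    nsites: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.name}: matrix must be w x 4")
        if np.any(self.matrix < 0):
            raise ValueError(f"motif {self.name}: negative entries")
        sums = self.matrix.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"motif {self.name}: zero row")
        self.matrix = self.matrix / sums

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, sequence: str, name: str, pseudo: float = 0.0, **kw) -> "PwmMotif":
        mat = np.full((len(sequence), 4), pseudo, dtype=float)
        for i, b in enumerate(sequence.upper()):
            mat[i, BASE_ORDER.index(b)] += 1.0
        return cls(mat, name=name, **kw)


def read_jaspar(path: str | os.PathLike) -> list[PwmMotif]:
    """Read motifs in JASPAR PFM text format.

    Accepts both the 4-row raw-count layout and the bracketed
    ``A [ 1 2 3 ]`` layout; counts are normalized per position.
    """
    motifs: list[PwmMotif] = []
    name, rows = None, []

    def flush():
        nonlocal name, rows
        if name is not None:
            if len(rows) != 4:
                raise ValueError(f"motif {name}: expected 4 base rows, got {len(rows)}")
            counts = np.array(rows, dtype=float).T  # (width, 4)
            nsites = max(1, int(round(counts[0].sum())))
            motifs.append(PwmMotif(counts, name=name, source="database", nsites=nsites))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                nums = re.findall(r"[\d.]+", line)
                if not nums:
                    continue
                rows.append([float(x) for x in nums])
    flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_jaspar(motifs: list[PwmMotif], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            counts = m.matrix * m.nsites
            for j, base in enumerate(BASE_ORDER):
                fh.write(f"{base} [ " + " ".join(f"{v:.2f}" for v in counts[:, j]) + " ]\n")


def read_meme(path: str | os.PathLike) -> list[PwmMotif]:
    """Read motifs in MEME minimal text format."""
    motifs: list[PwmMotif] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            nsites, width = 1, None
            rows: list[list[float]] = []
            i += 1
            while i < len(lines):
                sub = lines[i].strip()
                if sub.startswith("letter-probability matrix"):
                    mw = re.search(r"w=\s*(\d+)", sub)
                    mn = re.search(r"nsites=\s*(\d+)", sub)
                    width = int(mw.group(1)) if mw else None
                    nsites = int(mn.group(1)) if mn else 1
                    i += 1
                    while i < len(lines) and re.match(r"^\s*[\d.eE+-]+(\s+[\d.eE+-]+){3}\s*$", lines[i]):
                        rows.append([float(x) for x in lines[i].split()])
                        i += 1
                    break
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(f"motif {name}: expected {width} rows, got {len(rows)}")
            motifs.append(PwmMotif(np.array(rows), name=name, nsites=nsites))
        else:
            i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_meme(motifs: list[PwmMotif], path: str | os.PathLike,
               background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """Write motifs in MEME minimal format, with nsites = occurrence count."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.3f}" for b, f in zip(BASE_ORDER, background)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= {m.nsites} E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
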