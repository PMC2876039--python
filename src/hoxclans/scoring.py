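"""Substitution matrices and their text-format I/O.

A :class:`SubstitutionMatrix` couples a symmetric residue scoring table with
affine gap penalties.  A gap of length ``L`` costs ``gap_open + L *
gap_extend`` (BLAST-style: the opening surcharge is paid once, every gapped
residue pays the extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, robinson_background


@dataclass
class SubstitutionMatrix:
    """Symmetric residue scoring table plus affine gap penalties."""

    scores: np.ndarray  # (20, 20) int
    gap_open: int = 11
    gap_extend: int = 1
    name: str = "custom"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.shape != (20, 20):
            raise ValueError("scores must be a 20x20 table")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not (np.diag(self.scores) > 0).any():
            raise ValueError("matrix needs at least one positive diagonal entry")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def expected_score(self, background: np.ndarray | None = None) -> float:
        """Expected score per aligned pair under the background composition."""
        p = robinson_background() if background is None else background
        return float(p @ self.scores @ p)


def blosum62(gap_open: int = 11, gap_extend: int = 1) -> SubstitutionMatrix:
    """The canonical BLOSUM62 table with BLAST-default gap penalties."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    tab = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            tab[i, j] = int(m[a, b])
    return SubstitutionMatrix(tab, gap_open, gap_extend, name="BLOSUM62")


def write_matrix(matrix: SubstitutionMatrix, path) -> None:
    """Write a matrix in the NCBI text layout (row/column residue headers)."""
    with open(path, "w") as fh:
        fh.write(f"# {matrix.name}  gap_open={matrix.gap_open}"
                 f" gap_extend={matrix.gap_extend}\n")
        fh.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for i, a in enumerate(AMINO_ACIDS):
            row = " ".join(f"{int(s):3d}" for s in matrix.scores[i])
            fh.write(f"{a} {row}\n")


def read_matrix(path) -> SubstitutionMatrix:
    """Read a matrix written by :func:`write_matrix` (NCBI text layout)."""
    gap_open, gap_extend, name = 11, 1, "custom"
    rows: dict[str, list[int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("gap_open="):
                        gap_open = int(tok.split("=", 1)[1])
                    elif tok.startswith("gap_extend="):
                        gap_extend = int(tok.split("=", 1)[1])
                    elif "=" not in tok:
                        name = tok
                continue
            parts = line.split()
            if not parts:
                continue
            if parts[0] in AA_INDEX and len(parts) == 21:
                rows[parts[0]] = [int(x) for x in parts[1:]]
            else:
                order = parts
    if sorted(order) != sorted(AMINO_ACIDS) or len(rows) != 20:
        raise ValueError(f"malformed matrix file: {path}")
    tab = np.zeros((20, 20), dtype=np.int64)
    for a, vals in rows.items():
        for b, v in zip(order, vals):
            tab[AA_INDEX[a], AA_INDEX[b]] = v
    return SubstitutionMatrix(tab, gap_open, gap_extend, name=name)
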