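"""Shared primitives: amino-acid alphabet, background composition, records.

The residue alphabet follows the NCBI scoring-matrix order so that matrix
tables read in that layout index directly.  Background frequencies are the
Robinson & Robinson amino-acid composition, shipped as a constant so no
external file is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 20 amino acids in NCBI matrix order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Internal index used for masked positions (never a legal input residue).
MASK_INDEX = 20

# Robinson & Robinson (1991) composition, normalised to sum exactly to 1.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def robinson_background() -> np.ndarray:
    """Background residue frequencies (Robinson-Robinson), summing to 1."""
    v = np.array([_ROBINSON[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


@dataclass
class ProteinRecord:
    """A single protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header up to the first whitespace).
    seq : str
        Residue string over the 20-letter alphabet, upper case.
    description : str
        Free text after the identifier on the FASTA header line.
    """

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as int8 alphabet indices.

    Raises
    ------
    ValueError
        Naming the offending character and its 0-based position if a
        character outside the 20-letter alphabet is found.
    """
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        idx = AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"illegal residue {ch!r} at position {i}: not one of {AMINO_ACIDS}"
            )
        out[i] = idx
    return out


def decode(idx: np.ndarray) -> str:
    """Inverse of :func:`encode` (masked positions become 'x')."""
    return "".join(
        AMINO_ACIDS[i] if 0 <= i < 20 else "x" for i in np.asarray(idx, dtype=int)
    )
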