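"""Amino-acid alphabet helpers shared across the package.

The 20-letter alphabet is kept in a fixed order so that profile columns,
frequency vectors and integer encodings agree everywhere.
"""
from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_AA = 20

GAP_CHARS = "-."

# Residues treated as hydrophobic by the signal-peptide heuristic.
HYDROPHOBIC = set("AVLIMFWC")

_ENCODE_LUT = np.full(128, -1, dtype=np.int64)
for _a, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_a)] = _i


def validate_protein(seq: str) -> None:
    """Raise ValueError if *seq* contains a character outside the alphabet."""
    bad = set(seq) - set(AA)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")


def encode(seq: str) -> np.ndarray:
    """Encode a protein string into int64 codes 0..19 (-1 for unknowns)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[arr]


def decode(codes: np.ndarray) -> str:
    return "".join(AA[c] for c in codes)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability *rate* by a different residue."""
    if rate < 0 or rate > 1:
        raise ValueError("mutation rate must be in [0, 1]")
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [a for a in AA if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def shuffle_seq(seq: str, rng: np.random.Generator) -> str:
    """Residue-composition-preserving shuffle."""
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def random_protein(length: int, rng: np.random.Generator,
                   freqs: np.ndarray | None = None) -> str:
    """Sample an i.i.d. protein of *length* residues from *freqs* (uniform default)."""
    if freqs is None:
        freqs = np.full(N_AA, 1.0 / N_AA)
    codes = rng.choice(N_AA, size=length, p=freqs)
    return decode(codes)
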