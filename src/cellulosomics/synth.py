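"""Seeded synthetic proteome generator with ground truth.

Emulates the statistical structure that module detection assumes: conserved
modules (mutated copies of per-class consensus sequences) embedded between
variable linkers, plus unstructured background proteins.  Scaffoldins are
realized from architecture token strings (by default the packaged
21-scaffoldin table), dockerins carry the duplicated 22-residue repeat
layout, and SIGN tokens are realized with an N-terminus that the signal
heuristic recovers by construction.  Every planted module is recorded in a
machine-readable truth table, and identical specs (including the seed)
produce byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqs
from .arch import ROLE_OF, parse_architecture
from .dockerin import PositionFrequencyMatrix
from .references import SIGNAL_PEPTIDE, module_consensus

_TYPE_OF_TOKEN = {"Coh1": "I", "Coh2": "II", "Doc1": "I", "XDoc2": "II"}


def _default_pool() -> list[str]:
    from .arch import load_table1_fixture
    return [row.architecture for row in load_table1_fixture()]


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_background: int = 10
    n_scaffoldins: int = 10
    architecture_pool: list[str] = field(default_factory=_default_pool)
    mutation_rate: float = 0.05
    linker_length_range: tuple[int, int] = (5, 25)
    background_length_range: tuple[int, int] = (100, 400)
    residue_background_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(seqs.N_AA, 1.0 / seqs.N_AA))

    def __post_init__(self):
        if not 0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        for lo, hi in (self.linker_length_range, self.background_length_range):
            if lo > hi or lo < 0:
                raise ValueError("degenerate length range")
        f = np.asarray(self.residue_background_frequencies, float)
        if f.shape != (seqs.N_AA,) or not np.isclose(f.sum(), 1.0):
            raise ValueError("background frequencies must be a 20-vector summing to 1")
        if self.n_scaffoldins > 0 and not self.architecture_pool:
            raise ValueError("architecture_pool empty with n_scaffoldins > 0")


@dataclass
class TruthRow:
    protein_id: str
    token: str
    start0: int
    end0: int
    source_class: str
    type_label: str


def sample_dockerin(pfm: PositionFrequencyMatrix, linker_length: int,
                    mutation_rate: float, seed: int) -> tuple[str, tuple[int, int]]:
    """Sample a two-repeat dockerin from a 22-position repeat PFM.

    Both repeats are drawn independently position-wise from the PFM, then
    mutated at *mutation_rate*; the linker is uniform-random of the requested
    length.  Returns the sequence and the (repeat1_start, repeat2_start)
    truth coordinates.  Deterministic given *seed*.
    """
    if pfm.length != 22:
        raise ValueError("repeat PFM must have length 22")
    if linker_length < 0:
        raise ValueError("invalid linker length")
    rng = np.random.default_rng(seed)

    def one_repeat() -> str:
        codes = [rng.choice(seqs.N_AA, p=pfm.freqs[j]) for j in range(pfm.length)]
        return seqs.mutate(seqs.decode(np.array(codes)), mutation_rate, rng)

    r1 = one_repeat()
    r2 = one_repeat()
    linker = seqs.random_protein(linker_length, rng)
    return r1 + linker + r2, (0, 22 + linker_length)


def realize_token(token: str, mutation_rate: float,
                  rng: np.random.Generator) -> str:
    """Concrete sequence for one architecture token."""
    if token == "SIGN":
        return SIGNAL_PEPTIDE
    return seqs.mutate(module_consensus(token), mutation_rate, rng)


def generate_proteome(spec: SyntheticSpec) -> tuple[list[tuple[str, str]], list[TruthRow]]:
    """Generate FASTA records and the planted-module truth table."""
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    lo_l, hi_l = spec.linker_length_range
    for k in range(spec.n_scaffoldins):
        arch = parse_architecture(spec.architecture_pool[k % len(spec.architecture_pool)])
        pid = f"SYN_SCAF_{k:04d}"
        parts: list[str] = []
        pos = 0
        for idx, token in enumerate(arch.tokens):
            if idx > 0:
                linker = seqs.random_protein(
                    int(rng.integers(lo_l, hi_l + 1)), rng,
                    spec.residue_background_frequencies)
                parts.append(linker)
                pos += len(linker)
            mod = realize_token(token, spec.mutation_rate, rng)
            truth.append(TruthRow(pid, token, pos, pos + len(mod), token,
                                  _TYPE_OF_TOKEN.get(token, "")))
            parts.append(mod)
            pos += len(mod)
        records.append((pid, "".join(parts)))
    lo_b, hi_b = spec.background_length_range
    for k in range(spec.n_background):
        pid = f"SYN_BG_{k:04d}"
        length = int(rng.integers(lo_b, hi_b + 1))
        records.append((pid, seqs.random_protein(
            length, rng, spec.residue_background_frequencies)))
    return records, truth


def truth_to_rows(truth: list[TruthRow]) -> list[dict]:
    return [vars(r) for r in truth]
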