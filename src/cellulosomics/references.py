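"""Packaged synthetic reference sequence sets.

The detector, the type classifiers and the proteome generator all need
per-module-class reference sequences.  Curated cohesin/dockerin collections
are an external, user-supplied input; the sets generated here are SYNTHETIC:
deterministic stand-ins whose only biologically anchored content is the
dockerin repeat layout — 22 positions with D/N at the Ca2+-binding offsets
1/3/5/9/12 and the type I recognition motif S/T at 10/11 and R/R at 17/18
(type II differs at the recognition offsets).  Everything else (cohesin and
auxiliary consensus sequences) is an arbitrary fixed random consensus, which
is exactly what profile detection and identity-based typing require to be
exercised end to end.  Users analysing real proteomes should supply real
reference alignments in their place.
"""
from __future__ import annotations

import zlib

import numpy as np

from . import seqs
from .detect import ReferenceProfile, build_profile
from .dockerin import PositionFrequencyMatrix, build_pfm

#: Type I dockerin repeat consensus: Ca offsets 1/3/5/9/12 = D/N/D/N/D,
#: recognition offsets 10/11/17/18 = S/T/R/R, offset 22 variable.
REPEAT_CONSENSUS_I = "DVNGDGAINSTDLALMRRYVLA"
#: Type II repeat: same Ca scheme, divergent recognition offsets (L/I/K/Q, G).
REPEAT_CONSENSUS_II = "DIDSNGTVDLINFGIWKQEVTG"

DOC_LINKER = "GSTPTNPGTSGA"   # 12-residue inter-repeat linker

assert len(REPEAT_CONSENSUS_I) == 22 and len(REPEAT_CONSENSUS_II) == 22

DOC1_CONSENSUS = REPEAT_CONSENSUS_I + DOC_LINKER + REPEAT_CONSENSUS_I
DOC2_CONSENSUS = REPEAT_CONSENSUS_II + DOC_LINKER + REPEAT_CONSENSUS_II

#: N-terminal realization used when an architecture plants a SIGN token;
#: constructed to satisfy the signal-peptide heuristic by design.
SIGNAL_PEPTIDE = "MKR" + "L" * 9 + "ASA"

_MODULE_LENGTHS = {
    "Coh1": 120, "Coh2": 120, "CBM3": 100, "SLH": 54, "CSBM": 90,
    "UNK": 50, "Peptidase": 90, "PPC": 40, "RhsA": 70, "GalOx": 90,
    "FN3": 50, "WFA": 60,
}

N_REFS = 8
REF_MUTATION = 0.08


def _rng_for(tag: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(tag.encode()) % 2**31)


def module_consensus(token: str) -> str:
    """Deterministic synthetic consensus sequence for a module token."""
    if token == "Doc1":
        return DOC1_CONSENSUS
    if token == "XDoc2":
        x_module = seqs.random_protein(80, _rng_for("XDoc2/xmodule"))
        return x_module + DOC2_CONSENSUS
    if token == "SIGN":
        return SIGNAL_PEPTIDE
    if token in _MODULE_LENGTHS:
        return seqs.random_protein(_MODULE_LENGTHS[token], _rng_for(f"consensus/{token}"))
    raise KeyError(f"no synthetic consensus for token {token!r}")


def reference_alignment(token: str, n: int = N_REFS,
                        mutation: float = REF_MUTATION) -> list[str]:
    """n seeded mutated copies of the class consensus (trivially aligned)."""
    rng = _rng_for(f"refs/{token}")
    consensus = module_consensus(token)
    return [seqs.mutate(consensus, mutation, rng) for _ in range(n)]


def reference_profiles(tokens: list[str] | None = None, *,
                       pseudocount: float = 0.5) -> dict[str, ReferenceProfile]:
    """Detection profiles for the requested tokens (default: the classes the
    pipeline detects out of the box: Coh1, Coh2, Doc1, XDoc2, CBM3, SLH, CSBM)."""
    if tokens is None:
        tokens = ["Coh1", "Coh2", "Doc1", "XDoc2", "CBM3", "SLH", "CSBM"]
    out = {}
    for tok in tokens:
        refs = reference_alignment(tok)
        out[tok] = build_profile(refs, tok, pseudocount=pseudocount,
                                 source_ids=[f"synthetic_{tok}_{i}" for i in range(len(refs))])
    return out


def repeat_profile(type_label: str = "I", *, pseudocount: float = 0.5) -> ReferenceProfile:
    """22-position scoring profile of the dockerin repeat of the given type."""
    consensus = REPEAT_CONSENSUS_I if type_label == "I" else REPEAT_CONSENSUS_II
    rng = _rng_for(f"repeat_refs/{type_label}")
    refs = [seqs.mutate(consensus, REF_MUTATION, rng) for _ in range(N_REFS)]
    return build_profile(refs, f"DocRepeat{type_label}", pseudocount=pseudocount)


def repeat_pfm(type_label: str = "I", *, pseudocount: float = 0.5) -> PositionFrequencyMatrix:
    consensus = REPEAT_CONSENSUS_I if type_label == "I" else REPEAT_CONSENSUS_II
    rng = _rng_for(f"repeat_refs/{type_label}")
    refs = [seqs.mutate(consensus, REF_MUTATION, rng) for _ in range(N_REFS)]
    return build_pfm(refs, pseudocount=pseudocount)


def dockerin_references(type_label: str) -> list[str]:
    """Synthetic full-length dockerin reference set for type classification."""
    consensus = DOC1_CONSENSUS if type_label == "I" else DOC2_CONSENSUS
    rng = _rng_for(f"doc_refs/{type_label}")
    return [seqs.mutate(consensus, REF_MUTATION, rng) for _ in range(N_REFS)]


def cohesin_references(type_label: str) -> list[str]:
    """Synthetic cohesin reference set for type classification."""
    token = "Coh1" if type_label == "I" else "Coh2"
    rng = _rng_for(f"coh_refs/{token}")
    consensus = module_consensus(token)
    return [seqs.mutate(consensus, REF_MUTATION, rng) for _ in range(N_REFS)]
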