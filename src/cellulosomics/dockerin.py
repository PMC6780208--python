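"""Dockerin repeat conservation analysis and type classification.

A dockerin consists of two duplicated ~22-residue repeats, each a Ca2+-binding
loop followed by an alpha-helix, joined by a linker.  Within the canonical
22-position numbering, positions 1/3/5/9/12 coordinate calcium and positions
10/11/17/18/22 are the predicted cohesin-recognition residues.  This module
extracts those signatures, builds position frequency matrices and
information-content logos, quantifies repeat symmetry (similar repeats imply
a dual rather than single mode of cohesin binding), and classifies dockerins
as type I or type II by nearest-reference identity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqs
from .detect import CA_POSITIONS, RECOGNITION_POSITIONS, REPEAT_LENGTH, DockerinRepeatPair
from .pairwise import percent_identity


@dataclass
class PositionFrequencyMatrix:
    freqs: np.ndarray          # (length, 20) per-position residue probabilities
    counts_n: int
    pseudocount: float

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        return "".join(seqs.AA[i] for i in self.freqs.argmax(axis=1))

    def __post_init__(self):
        if self.counts_n < 1:
            raise ValueError("counts_n must be >= 1")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFM columns must sum to 1")


def build_pfm(segments: list[str], pseudocount: float = 0.5) -> PositionFrequencyMatrix:
    """Position frequency matrix over equal-length segments.

    frequencies = (count + pseudocount) / (n + 20 * pseudocount).
    """
    if not segments:
        raise ValueError("empty segment list")
    width = len(segments[0])
    if any(len(s) != width for s in segments):
        raise ValueError("ragged segment lengths")
    n = len(segments)
    counts = np.zeros((width, seqs.N_AA))
    for s in segments:
        for j, c in enumerate(s):
            counts[j, seqs.AA_INDEX[c]] += 1
    freqs = (counts + pseudocount) / (n + seqs.N_AA * pseudocount)
    return PositionFrequencyMatrix(freqs=freqs, counts_n=n, pseudocount=pseudocount)


def information_content(pfm: PositionFrequencyMatrix, position: int) -> float:
    """Shannon information of one PFM column in bits: log2(20) - H(column)."""
    p = pfm.freqs[position]
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(seqs.N_AA) - entropy)


@dataclass
class RecognitionSignature:
    """Literal residues at the recognition and Ca-binding repeat offsets."""

    repeat_index: int
    pos10: str
    pos11: str
    pos17: str
    pos18: str
    pos22: str
    ca: tuple[str, ...]        # residues at repeat offsets 1, 3, 5, 9, 12

    @property
    def recognition(self) -> tuple[str, ...]:
        return (self.pos10, self.pos11, self.pos17, self.pos18, self.pos22)


def extract_signature(repeat: str, repeat_index: int = 1) -> RecognitionSignature:
    """Extract recognition (10/11/17/18/22) and Ca (1/3/5/9/12) residues."""
    if len(repeat) != REPEAT_LENGTH:
        raise ValueError(
            f"expected a {REPEAT_LENGTH}-residue repeat, got {len(repeat)}")
    rec = {p: repeat[p - 1] for p in RECOGNITION_POSITIONS}
    return RecognitionSignature(
        repeat_index=repeat_index,
        pos10=rec[10], pos11=rec[11], pos17=rec[17], pos18=rec[18],
        pos22=rec[22],
        ca=tuple(repeat[p - 1] for p in CA_POSITIONS))


def repeat_identity(repeat1: str, repeat2: str) -> float:
    """Ungapped percent identity between two 22-residue repeats (symmetric)."""
    if len(repeat1) != REPEAT_LENGTH or len(repeat2) != REPEAT_LENGTH:
        raise ValueError(f"both repeats must be {REPEAT_LENGTH} residues")
    matches = sum(a == b for a, b in zip(repeat1, repeat2))
    return 100.0 * matches / REPEAT_LENGTH


def repeat_symmetry(pair: DockerinRepeatPair) -> float:
    return repeat_identity(pair.repeat1_seq, pair.repeat2_seq)


def dual_binding_mode(pair: DockerinRepeatPair, *, min_fraction: float = 0.5) -> bool:
    """Flag a dual binding mode when the side-chain recognition residues
    (offsets 10, 11, 17, 18) agree between the two repeats at >= min_fraction."""
    r1 = pair.recognition_residues(1)[:4]
    r2 = pair.recognition_residues(2)[:4]
    agree = sum(a == b for a, b in zip(r1, r2)) / 4
    return agree >= min_fraction


@dataclass
class TypeCall:
    label: str                 # "I", "II" or "unknown"
    best_identity: float       # percent
    margin: float              # percentage-point gap between the two sets


def classify_type(segment: str, type1_refs: list[str], type2_refs: list[str],
                  min_margin: float = 5.0) -> TypeCall:
    """Type a dockerin (or cohesin) segment by nearest-reference identity.

    The best global-alignment percent identity against each reference set is
    computed; the call goes to the higher-scoring set when the gap is at least
    *min_margin* percentage points, otherwise "unknown".
    """
    if not type1_refs or not type2_refs:
        raise ValueError("both reference sets must be non-empty")
    best1 = max(percent_identity(segment, r) for r in type1_refs)
    best2 = max(percent_identity(segment, r) for r in type2_refs)
    margin = abs(best1 - best2)
    if margin < min_margin:
        label = "unknown"
    else:
        label = "I" if best1 > best2 else "II"
    return TypeCall(label=label, best_identity=max(best1, best2), margin=margin)


# ---------------------------------------------------------------------------
# Sequence logo rendering (information-content letter stacks)


def plot_logo(pfm: PositionFrequencyMatrix, ax=None, path: str | None = None):
    """Render an information-content sequence logo of *pfm*.

    Letters at each position are stacked with total height equal to the
    column's information content (bits) and individual heights proportional
    to residue frequency, most frequent on top (the WebLogo convention).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, pfm.length * 0.4), 2.5))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    colors = {c: "tab:green" for c in "STYQN"}
    colors.update({c: "tab:blue" for c in "KRH"})
    colors.update({c: "tab:red" for c in "DE"})
    for j in range(pfm.length):
        ic = information_content(pfm, j)
        stack = sorted(zip(seqs.AA, pfm.freqs[j]), key=lambda t: t[1])
        y = 0.0
        for letter, f in stack:
            h = f * ic
            if h < 1e-3:
                continue
            tp = TextPath((0, 0), letter, size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D()
                  .translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height)
                  .translate(j + 0.05, y))
            ax.add_patch(PathPatch(tr.transform_path(tp),
                                   facecolor=colors.get(letter, "0.3"),
                                   edgecolor="none"))
            y += h
    ax.set_xlim(0, pfm.length)
    ax.set_ylim(0, np.log2(seqs.N_AA))
    ax.set_xticks(np.arange(pfm.length) + 0.5)
    ax.set_xticklabels(np.arange(1, pfm.length + 1), fontsize=6)
    ax.set_ylabel("bits")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
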