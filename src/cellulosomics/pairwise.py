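"""Global pairwise alignment with a fixed scoring scheme.

Percent identity from Needleman–Wunsch global alignment is the package's
yardstick both for dockerin/cohesin type assignment and for phylogenetic
p-distances.  Scoring is fixed (match 2, mismatch -1, gap open -5, extend
-0.5) so results are deterministic and comparable across runs.
"""
from __future__ import annotations

from functools import lru_cache

from Bio import Align


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global", match_score=2.0, mismatch_score=-1.0,
        open_gap_score=-5.0, extend_gap_score=-0.5)


def global_identity(a: str, b: str) -> tuple[int, int]:
    """(identities, alignment length) of the best global alignment of a vs b."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(a, b)[0]
    return int(aln.counts().identities), int(aln.length)


def percent_identity(a: str, b: str) -> float:
    ident, length = global_identity(a, b)
    return 100.0 * ident / length
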