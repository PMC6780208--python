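"""Cohesin / dockerin / auxiliary module detection on protein sequences.

The detector scores proteins against per-class position-specific scoring
matrices (log-odds profiles built from reference alignments) with local
affine-gap alignment, converts scores to an empirical E-value surrogate by
fitting an extreme-value (Gumbel) distribution to scores of residue-shuffled
copies of the query, and keeps hits below a configurable E-value threshold
(default 1e-4).  Dockerins are additionally validated by their duplicated
~22-residue Ca2+-binding repeat structure, and a coarse hydrophobic-window
heuristic flags N-terminal signal peptides.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import seqs
from ._align import sw_profile_best, sw_profile_score
from .arch import ScaffoldinArchitecture, parse_architecture

#: Uniform amino-acid background used for log-odds unless overridden.
UNIFORM_BG = np.full(seqs.N_AA, 1.0 / seqs.N_AA)

#: 1-based repeat offsets of the putative Ca2+-coordinating residues.
CA_POSITIONS = (1, 3, 5, 9, 12)
#: 1-based repeat offsets of the predicted cohesin-recognition residues.
RECOGNITION_POSITIONS = (10, 11, 17, 18, 22)

REPEAT_LENGTH = 22

_TYPE_OF_TOKEN = {"Coh1": "I", "Coh2": "II", "Doc1": "I", "XDoc2": "II"}


@dataclass
class DetectionConfig:
    evalue_threshold: float = 1e-4
    shuffle_count: int = 200
    overlap_fraction: float = 0.5
    gap_open: float = 8.0
    gap_extend: float = 1.0
    random_seed: int = 0
    linker_bounds: tuple[int, int] = (5, 25)

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.shuffle_count < 50:
            raise ValueError("shuffle_count must be >= 50")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass
class ReferenceProfile:
    """Log-odds profile over the 20 amino acids built from aligned references."""

    module_class: str
    pssm: np.ndarray                      # (length, 20) log2-odds scores
    freqs: np.ndarray                     # (length, 20) column probabilities
    source_ids: list[str] = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    @property
    def max_score(self) -> float:
        """Sum of per-position maxima — the highest ungapped score achievable."""
        return float(self.pssm.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(seqs.AA[i] for i in self.pssm.argmax(axis=1))

    def self_score(self, sequence: str) -> float:
        """Ungapped score of a sequence of exactly profile length."""
        if len(sequence) != self.length:
            raise ValueError(f"expected length {self.length}, got {len(sequence)}")
        codes = seqs.encode(sequence)
        return float(self.pssm[np.arange(self.length), codes].sum())

    def window_scores(self, protein: str) -> np.ndarray:
        """Ungapped scores of every length-L window of *protein*."""
        codes = seqs.encode(protein)
        L = self.length
        n = len(protein) - L + 1
        if n <= 0:
            return np.empty(0)
        idx = np.arange(L)
        return np.array([self.pssm[idx, codes[s:s + L]].sum() for s in range(n)])


def build_profile(aligned_refs: list[str], module_class: str, *,
                  pseudocount: float = 0.5,
                  background: np.ndarray | None = None,
                  max_gap_fraction: float = 0.5,
                  source_ids: list[str] | None = None) -> ReferenceProfile:
    """Build a log-odds profile from a gapped reference alignment.

    Columns with more than *max_gap_fraction* gap characters are dropped;
    remaining column frequencies get a pseudocount before the log-odds
    transform against *background* (uniform by default).
    """
    if not aligned_refs:
        raise ValueError("empty reference set")
    width = len(aligned_refs[0])
    if any(len(s) != width for s in aligned_refs):
        raise ValueError("ragged alignment: reference sequences differ in length")
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    cols = []
    for j in range(width):
        column = [s[j] for s in aligned_refs]
        gaps = sum(c in seqs.GAP_CHARS for c in column)
        if gaps / len(column) > max_gap_fraction:
            continue
        counts = np.zeros(seqs.N_AA)
        for c in column:
            if c in seqs.AA_INDEX:
                counts[seqs.AA_INDEX[c]] += 1
        n = counts.sum()
        cols.append((counts + pseudocount) / (n + seqs.N_AA * pseudocount))
    if not cols:
        raise ValueError("no usable alignment columns")
    freqs = np.array(cols)
    with np.errstate(divide="ignore"):
        pssm = np.log2(freqs / bg)
    return ReferenceProfile(module_class=module_class, pssm=pssm, freqs=freqs,
                            source_ids=source_ids or [], background=bg.copy())


@dataclass
class ModuleHit:
    protein_id: str
    module_class: str
    start: int                    # 0-based, half-open
    end: int
    score: float
    evalue: float
    type_label: str = "unknown"


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location, scale) fit of a score sample."""
    scores = np.asarray(scores, float)
    if scores.std() == 0:
        raise ValueError("uninformative null: zero-variance score sample")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(scale)


def null_scores(protein: str, profile: ReferenceProfile,
                config: DetectionConfig) -> np.ndarray:
    """Local-alignment scores of seeded residue shuffles of *protein*."""
    rng = np.random.default_rng(config.random_seed)
    out = np.empty(config.shuffle_count)
    for k in range(config.shuffle_count):
        shuf = seqs.shuffle_seq(protein, rng)
        out[k] = sw_profile_score(profile.pssm, seqs.encode(shuf),
                                  config.gap_open, config.gap_extend)
    return out


def estimate_evalue(score: float, protein: str, profile: ReferenceProfile,
                    config: DetectionConfig,
                    null: np.ndarray | None = None) -> float:
    """Empirical E-value surrogate for a local-alignment score.

    A Gumbel distribution is fitted to the shuffle-score null; the E-value is
    the fitted tail probability multiplied by the number of scanned positions.
    Monotonically decreasing in *score* for a fixed null.
    """
    if null is None:
        null = null_scores(protein, profile, config)
    loc, scale = fit_gumbel(null)
    positions = max(1, len(protein))
    return float(stats.gumbel_r.sf(score, loc=loc, scale=scale) * positions)


def scan_profile(protein: str, profile: ReferenceProfile,
                 config: DetectionConfig | None = None, *,
                 protein_id: str = "query",
                 null: np.ndarray | None = None,
                 max_hits: int = 64) -> list[ModuleHit]:
    """Locate all non-overlapping occurrences of *profile* in *protein*.

    Hits are extracted best-first by iterated local alignment with masking of
    already-claimed residues, so same-class hits never overlap; only hits with
    E-value below ``config.evalue_threshold`` are retained.  Returned sorted
    by start coordinate.
    """
    config = config or DetectionConfig()
    if not protein:
        return []
    codes = seqs.encode(protein)
    if null is None:
        null = null_scores(protein, profile, config)
    loc, scale = fit_gumbel(null)
    positions = max(1, len(protein))
    hits: list[ModuleHit] = []
    work = codes.copy()
    for _ in range(max_hits):
        score, qs, qe, _, _ = sw_profile_best(profile.pssm, work,
                                              config.gap_open, config.gap_extend)
        if score <= 0:
            break
        ev = float(stats.gumbel_r.sf(score, loc=loc, scale=scale) * positions)
        if ev >= config.evalue_threshold:
            break
        hits.append(ModuleHit(protein_id=protein_id,
                              module_class=profile.module_class,
                              start=qs, end=qe, score=score, evalue=ev,
                              type_label=_TYPE_OF_TOKEN.get(profile.module_class,
                                                            "unknown")))
        work[qs:qe] = -1
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Dockerin duplicated-repeat validation


@dataclass
class DockerinRepeatPair:
    """Two 22-position Ca2+-binding repeats separated by a linker."""

    repeat1_start: int
    repeat2_start: int
    linker_length: int
    pair_score: float
    repeat1_seq: str
    repeat2_seq: str
    repeat_length: int = REPEAT_LENGTH

    def ca_residues(self, repeat_index: int) -> tuple[str, ...]:
        seq = self.repeat1_seq if repeat_index == 1 else self.repeat2_seq
        return tuple(seq[p - 1] for p in CA_POSITIONS)

    def recognition_residues(self, repeat_index: int) -> tuple[str, ...]:
        seq = self.repeat1_seq if repeat_index == 1 else self.repeat2_seq
        return tuple(seq[p - 1] for p in RECOGNITION_POSITIONS)


def _ca_rule_ok(window: str, min_ca: int = 3) -> bool:
    return sum(window[p - 1] in "DNE" for p in CA_POSITIONS) >= min_ca


def find_dockerin_repeats(protein: str, repeat_profile: ReferenceProfile,
                          config: DetectionConfig | None = None, *,
                          score_fraction: float = 0.5,
                          min_ca: int = 3) -> list[DockerinRepeatPair]:
    """Find duplicated dockerin repeats in *protein*.

    Candidate 22-residue windows must score at least *score_fraction* of the
    profile maximum and carry D/N/E at >= *min_ca* of the five Ca-binding
    offsets.  Non-overlapping candidate windows are paired when the linker
    between them falls within ``config.linker_bounds``; pairs are returned
    best-first by combined score, each window used at most once.
    """
    config = config or DetectionConfig()
    if repeat_profile.length != REPEAT_LENGTH:
        raise ValueError(f"repeat profile length must be {REPEAT_LENGTH}")
    lo, hi = config.linker_bounds
    if len(protein) < 2 * REPEAT_LENGTH + lo:
        return []
    scores = repeat_profile.window_scores(protein)
    cutoff = score_fraction * repeat_profile.max_score
    cand = [(float(scores[s]), s) for s in range(len(scores))
            if scores[s] >= cutoff
            and _ca_rule_ok(protein[s:s + REPEAT_LENGTH], min_ca)]
    # best-first non-overlap selection of candidate windows
    cand.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, int]] = []
    for sc, s in cand:
        if all(abs(s - s2) >= REPEAT_LENGTH for _, s2 in kept):
            kept.append((sc, s))
    pairs: list[DockerinRepeatPair] = []
    kept_sorted = sorted(kept, key=lambda t: t[1])
    for a in range(len(kept_sorted)):
        for b in range(a + 1, len(kept_sorted)):
            s1, s2 = kept_sorted[a][1], kept_sorted[b][1]
            linker = s2 - (s1 + REPEAT_LENGTH)
            if lo <= linker <= hi:
                pairs.append(DockerinRepeatPair(
                    repeat1_start=s1, repeat2_start=s2, linker_length=linker,
                    pair_score=kept_sorted[a][0] + kept_sorted[b][0],
                    repeat1_seq=protein[s1:s1 + REPEAT_LENGTH],
                    repeat2_seq=protein[s2:s2 + REPEAT_LENGTH]))
    pairs.sort(key=lambda p: (-p.pair_score, p.repeat1_start))
    chosen: list[DockerinRepeatPair] = []
    used: set[int] = set()
    for p in pairs:
        if p.repeat1_start not in used and p.repeat2_start not in used:
            chosen.append(p)
            used.update((p.repeat1_start, p.repeat2_start))
    return chosen


# ---------------------------------------------------------------------------
# Signal-peptide heuristic


@dataclass
class SignalPrediction:
    present: bool
    region: tuple[int, int] | None = None   # predicted cleavage region, 0-based


def detect_signal_peptide(protein: str) -> SignalPrediction:
    """Coarse N-terminal signal-peptide heuristic.

    True iff within the first 35 residues there is a window of >= 8 residues
    with >= 70% hydrophobic content (AVLIMFWC), preceded by at least one K/R
    within the first 5 residues.  Deterministic; no claim of SignalP fidelity.
    """
    if not protein:
        return SignalPrediction(False)
    head = protein[:5]
    kr = [i for i, c in enumerate(head) if c in "KR"]
    if not kr:
        return SignalPrediction(False)
    first_kr = kr[0]
    limit = min(35, len(protein))
    is_h = [c in seqs.HYDROPHOBIC for c in protein[:limit]]
    best_end = None
    for i in range(first_kr + 1, limit):
        for j in range(i + 8, limit + 1):
            frac = sum(is_h[i:j]) / (j - i)
            if frac >= 0.7:
                if best_end is None or j > best_end:
                    best_end = j
    if best_end is None:
        return SignalPrediction(False)
    return SignalPrediction(True, (best_end, min(best_end + 5, len(protein))))


# ---------------------------------------------------------------------------
# Whole-protein annotation


def annotate_protein(protein: str, profiles: dict[str, ReferenceProfile],
                     config: DetectionConfig | None = None, *,
                     protein_id: str = "query",
                     name: str | None = None) -> ScaffoldinArchitecture:
    """Annotate *protein* with ordered module tokens and an optional SIGN.

    Scans every supplied profile, resolves overlaps across classes keeping the
    higher score (ties leftmost), prepends SIGN when the signal heuristic
    fires, and emits a parsed architecture.  A protein with no accepted hits
    and no signal propagates the parser's empty-architecture error.
    """
    config = config or DetectionConfig()
    all_hits: list[ModuleHit] = []
    for profile in profiles.values():
        all_hits.extend(scan_profile(protein, profile, config,
                                     protein_id=protein_id))
    accepted = resolve_overlaps(all_hits, config.overlap_fraction)
    accepted.sort(key=lambda h: h.start)
    tokens = [h.module_class for h in accepted]
    if detect_signal_peptide(protein).present:
        tokens = ["SIGN"] + tokens
    return parse_architecture(" ".join(tokens), name=name, protein_id=protein_id)


def resolve_overlaps(hits: list[ModuleHit],
                     overlap_fraction: float = 0.5) -> list[ModuleHit]:
    """Greedy cross-class overlap resolution, higher score first (tie leftmost).

    A hit is rejected when it overlaps an accepted hit by more than
    *overlap_fraction* of the shorter interval.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.start))
    accepted: list[ModuleHit] = []
    for h in order:
        ok = True
        for other in accepted:
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov <= 0:
                continue
            shorter = min(h.end - h.start, other.end - other.start)
            if ov / shorter > overlap_fraction:
                ok = False
                break
        if ok:
            accepted.append(h)
    return accepted
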