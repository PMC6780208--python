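"""Profile construction, scanning, E-values, dockerin repeats, signals."""
import numpy as np
import pytest
from scipy import stats

from cellulosomics import (
    ArchitectureError,
    DetectionConfig,
    annotate_protein,
    build_profile,
    detect_signal_peptide,
    estimate_evalue,
    find_dockerin_repeats,
    fit_gumbel,
    scan_profile,
)
from cellulosomics.detect import ModuleHit, null_scores, resolve_overlaps
from cellulosomics import seqs
from cellulosomics.references import (
    REPEAT_CONSENSUS_I,
    module_consensus,
    reference_alignment,
)
from cellulosomics.synth import SyntheticSpec, generate_proteome


class TestBuildProfile:
    def test_single_sequence_self_score_is_maximal(self):
        prof = build_profile(["ACDE"], "UNK")
        assert prof.self_score("ACDE") == pytest.approx(prof.max_score)

    def test_duplicate_references_are_idempotent(self):
        # without pseudocount smoothing, duplicated sequences change nothing
        p1 = build_profile(["ACDE"], "UNK", pseudocount=0)
        p2 = build_profile(["ACDE", "ACDE"], "UNK", pseudocount=0)
        np.testing.assert_allclose(p1.freqs, p2.freqs)
        assert p2.consensus() == p1.consensus() == "ACDE"

    def test_column_frequencies_sum_to_one(self, rng):
        refs = [seqs.random_protein(30, rng) for _ in range(5)]
        prof = build_profile(refs, "UNK")
        assert np.allclose(prof.freqs.sum(axis=1), 1.0)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["ACDE", "ACD"], "UNK")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_profile([], "UNK")

    def test_gappy_columns_dropped(self):
        prof = build_profile(["A-CD", "A-CD", "AACD"], "UNK")
        assert prof.length == 3  # the 2/3-gap column is dropped


class TestScanProfile:
    def test_exact_planted_module_recovered_with_self_score(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        module = prof.consensus()
        protein = seqs.random_protein(60, rng) + module + seqs.random_protein(80, rng)
        hits = scan_profile(protein, prof, det_config)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (60, 60 + len(module))
        assert hits[0].score == pytest.approx(prof.self_score(module))
        assert hits[0].evalue < det_config.evalue_threshold

    def test_mutated_planted_module_overlaps_truth(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        module = seqs.mutate(prof.consensus(), 0.05, rng)
        protein = seqs.random_protein(50, rng) + module + seqs.random_protein(50, rng)
        hits = scan_profile(protein, prof, det_config)
        assert len(hits) == 1
        ov = min(hits[0].end, 50 + len(module)) - max(hits[0].start, 50)
        assert ov / len(module) >= 0.8

    def test_shuffled_proteins_yield_no_hits(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        base = prof.consensus() + seqs.random_protein(60, rng)
        for _ in range(20):
            shuffled = seqs.shuffle_seq(base, rng)
            assert scan_profile(shuffled, prof, det_config) == []

    def test_empty_protein(self, profiles, det_config):
        assert scan_profile("", profiles["Coh1"], det_config) == []

    def test_hits_sorted_and_non_overlapping(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        m = prof.consensus()
        protein = m + seqs.random_protein(30, rng) + m
        hits = scan_profile(protein, prof, det_config)
        assert len(hits) == 2
        assert hits[0].start < hits[1].start
        assert hits[0].end <= hits[1].start


class TestEvalue:
    def test_score_below_null_is_insignificant(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        protein = seqs.random_protein(150, rng)
        null = null_scores(protein, prof, det_config)
        ev = estimate_evalue(float(null.min()) - 1.0, protein, prof,
                             det_config, null=null)
        assert ev > 0.5 * len(protein)

    def test_monotonically_decreasing_in_score(self, profiles, det_config, rng):
        prof = profiles["Coh1"]
        protein = seqs.random_protein(150, rng)
        null = null_scores(protein, prof, det_config)
        scores = np.linspace(null.min(), null.max() + 50, 30)
        evs = [estimate_evalue(float(s), protein, prof, det_config, null=null)
               for s in scores]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_gumbel_fit_recovers_parameters(self):
        sample = stats.gumbel_r.rvs(loc=10, scale=2, size=1000,
                                    random_state=np.random.default_rng(7))
        loc, scale = fit_gumbel(sample)
        assert abs(loc - 10) < 0.5
        assert abs(scale - 2) < 0.3

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="uninformative null"):
            fit_gumbel(np.full(100, 3.0))


class TestDockerinRepeats:
    def test_planted_consensus_pair(self, doc_repeat_profile, det_config, rng):
        rep = REPEAT_CONSENSUS_I
        linker = seqs.random_protein(12, rng)
        protein = (seqs.random_protein(20, rng) + rep + linker + rep
                   + seqs.random_protein(20, rng))
        pairs = find_dockerin_repeats(protein, doc_repeat_profile, det_config)
        assert len(pairs) == 1
        assert pairs[0].linker_length == 12
        assert pairs[0].repeat1_start == 20
        assert pairs[0].repeat2_start == 20 + 22 + 12

    def test_single_repeat_gives_no_pair(self, doc_repeat_profile, det_config, rng):
        protein = seqs.random_protein(30, rng) + REPEAT_CONSENSUS_I + seqs.random_protein(30, rng)
        assert find_dockerin_repeats(protein, doc_repeat_profile, det_config) == []

    def test_ca_position_ablation_rejected(self, doc_repeat_profile, det_config, rng):
        rep = list(REPEAT_CONSENSUS_I)
        for p in (1, 3, 5, 9, 12):
            rep[p - 1] = "A"
        broken = "".join(rep)
        protein = broken + seqs.random_protein(12, rng) + broken
        assert find_dockerin_repeats(protein, doc_repeat_profile, det_config) == []

    def test_short_protein_empty(self, doc_repeat_profile, det_config):
        assert find_dockerin_repeats("ACDEF", doc_repeat_profile, det_config) == []

    def test_wrong_profile_length_rejected(self, profiles, det_config):
        with pytest.raises(ValueError, match="22"):
            find_dockerin_repeats("A" * 100, profiles["Coh1"], det_config)


class TestSignalPeptide:
    def test_canonical_signal(self, rng):
        protein = "MKR" + "L" * 10 + "ASA" + seqs.random_protein(100, rng)
        assert detect_signal_peptide(protein).present

    def test_acidic_n_terminus(self):
        assert not detect_signal_peptide("MDDDDDDDDDD" + "G" * 50).present

    def test_empty_sequence(self):
        assert not detect_signal_peptide("").present

    def test_missing_basic_residue(self):
        assert not detect_signal_peptide("MAA" + "L" * 12 + "G" * 50).present


class TestAnnotate:
    def test_planted_scaffoldin_architecture(self, profiles, det_config):
        spec = SyntheticSpec(seed=5, n_background=0, n_scaffoldins=1,
                             architecture_pool=["SIGN Coh1 Coh1 Doc1"])
        records, _ = generate_proteome(spec)
        arch = annotate_protein(records[0][1], profiles, det_config)
        assert arch.tokens == ["SIGN", "Coh1", "Coh1", "Doc1"]

    def test_featureless_protein_raises_empty_architecture(self, profiles, det_config, rng):
        protein = seqs.random_protein(50, rng)
        with pytest.raises(ArchitectureError, match="empty architecture"):
            annotate_protein(protein, profiles, det_config)


class TestOverlapResolution:
    def test_higher_score_wins_tie_leftmost(self):
        hits = [ModuleHit("p", "Coh1", 0, 100, 50.0, 1e-9),
                ModuleHit("p", "Coh2", 10, 110, 60.0, 1e-9),
                ModuleHit("p", "Coh1", 20, 120, 60.0, 1e-9)]
        kept = resolve_overlaps(hits, 0.5)
        assert [(h.module_class, h.start) for h in kept] == [("Coh2", 10)]

    def test_disjoint_hits_all_kept(self):
        hits = [ModuleHit("p", "Coh1", 0, 100, 50.0, 1e-9),
                ModuleHit("p", "Doc1", 120, 160, 30.0, 1e-9)]
        assert len(resolve_overlaps(hits, 0.5)) == 2
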