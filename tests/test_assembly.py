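"""ELISA normalization, interaction graphs, pH profiles, complex capacity."""
import numpy as np
import pytest

from cellulosomics import (
    AssemblyClass,
    AssemblyConfig,
    BindingMatrix,
    Limits,
    binarize,
    chain_config,
    complex_capacity,
    design_matrix,
    enumerate_complexes_bruteforce,
    normalize_binding,
    ph_profile,
    type_level_rules,
)


def simple_matrix(raw, standard=1.0):
    raw = np.asarray(raw, float)
    return BindingMatrix(
        cohesin_ids=[f"c{i}" for i in range(raw.shape[0])],
        dockerin_ids=[f"d{j}" for j in range(raw.shape[1])],
        raw=raw, standard_response=standard)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [(1.0, 100.0), (0.0, 0.0), (0.5, 50.0)])
    def test_percent_of_standard(self, raw, expected):
        m = normalize_binding(simple_matrix([[raw]]))
        assert m.relative[0, 0] == pytest.approx(expected)

    def test_values_may_exceed_standard(self):
        m = normalize_binding(simple_matrix([[2.5]]))
        assert m.relative[0, 0] == pytest.approx(250.0)

    def test_invalid_standard_rejected(self):
        with pytest.raises(ValueError, match="standard_response"):
            normalize_binding(simple_matrix([[1.0]], standard=0.0))

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            simple_matrix([[-1.0]])


class TestDesign:
    @pytest.mark.parametrize("nc,nd,expected", [(21, 8, 168), (0, 5, 0), (2, 3, 6)])
    def test_pair_counts(self, nc, nd, expected):
        count, pairs = design_matrix(nc, nd)
        assert count == expected == len(pairs)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            design_matrix(-1, 2)


class TestBinarize:
    def test_strict_boundary(self):
        m = normalize_binding(simple_matrix([[0.199]], standard=1.0))
        assert binarize(m, 20.0).edge_count() == 0
        m2 = normalize_binding(simple_matrix([[0.200]], standard=1.0))
        assert binarize(m2, 20.0).edge_count() == 1

    def test_all_zero_gives_empty_graph(self):
        m = normalize_binding(simple_matrix(np.zeros((3, 3))))
        assert binarize(m, 20.0).edge_count() == 0

    def test_matches_manual_filter(self, rng):
        raw = rng.random((5, 4))
        m = normalize_binding(simple_matrix(raw, standard=1.0))
        graph_edges = {(u, v) for u, v, _ in binarize(m, 50.0).edges()}
        manual = {(f"c{i}", f"d{j}") for i in range(5) for j in range(4)
                  if 100 * raw[i, j] >= 50.0}
        manual = {tuple(sorted(e)) for e in manual}
        assert {tuple(sorted(e)) for e in graph_edges} == manual

    def test_edge_count_non_increasing_in_threshold(self, rng):
        for _ in range(10):
            m = normalize_binding(simple_matrix(rng.random((6, 5))))
            counts = [binarize(m, t).edge_count() for t in (0, 20, 40, 60, 80, 101)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            binarize(simple_matrix([[1.0]]), 20.0)


class TestPhProfile:
    def test_single_point_reference(self):
        out = ph_profile([(7.0, 1.3)], reference_ph=7.0)
        assert out["curve"] == [(7.0, 100.0)]

    def test_unimodal_retention_at_high_ph(self):
        # peak at pH 7, alkaline tail retaining 65% of the optimum
        profile = [(4.0, 0.4), (5.0, 0.7), (7.0, 1.0), (8.5, 0.9), (10.0, 0.65)]
        out = ph_profile(profile, reference_ph=7.0)
        assert out["retained_percent"] == pytest.approx(65.0)
        assert out["retained_above_cutoff"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference pH"):
            ph_profile([(4.0, 1.0)], reference_ph=7.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ph_profile([], reference_ph=7.0)


# ---------------------------------------------------------------------------
# Capacity


def three_tier_config(anchor_slots=4, adaptor_slots=5, primary_slots=8):
    """Anchoring -> adaptor -> primary -> enzymes, all type-level rules."""
    return AssemblyConfig(
        classes=[
            AssemblyClass("Anch", cohesin_slots=["II"] * anchor_slots, anchored=True),
            AssemblyClass("Adapt", cohesin_slots=["II"] * adaptor_slots, dockerin="II"),
            AssemblyClass("Prim", cohesin_slots=["I"] * primary_slots, dockerin="II"),
            AssemblyClass("Enz", dockerin="I", is_enzyme=True),
        ],
        binding_rules=type_level_rules(),
        limits=Limits(adaptor_depth=1, max_class_per_path=1))


def config_from_rows(table1, names, *, adaptor_depth, max_class_per_path=1):
    """Assembly classes derived from parsed scaffoldin-table rows."""
    classes = [AssemblyClass("Enz", dockerin="I", is_enzyme=True)]
    for name in names:
        arch = table1.by_name(name).parsed()
        slots = ["I"] * arch.count("Coh1") + ["II"] * arch.count("Coh2")
        dockerin = "II" if arch.has("XDoc2") else ("I" if arch.has("Doc1") else None)
        classes.append(AssemblyClass(name, cohesin_slots=slots, dockerin=dockerin,
                                     anchored=arch.has("SLH")))
    return AssemblyConfig(classes=classes, binding_rules=type_level_rules(),
                          limits=Limits(adaptor_depth=adaptor_depth,
                                        max_class_per_path=max_class_per_path))


def random_config(rng):
    n_scaf = int(rng.integers(1, 4))
    n_enz = int(rng.integers(1, 3))
    classes = []
    for i in range(n_scaf):
        slots = [str(rng.choice(["I", "II"])) for _ in range(rng.integers(0, 5))]
        dockerin = None if i == 0 else str(rng.choice(["I", "II"]))
        classes.append(AssemblyClass(f"S{i}", cohesin_slots=slots, dockerin=dockerin))
    for i in range(n_enz):
        classes.append(AssemblyClass(f"E{i}", dockerin=str(rng.choice(["I", "II"])),
                                     is_enzyme=True))
    rules = [r for r in type_level_rules() if rng.random() < 0.8]
    for _ in range(rng.integers(0, 3)):
        src = classes[rng.integers(len(classes))]
        dst = classes[rng.integers(len(classes))]
        if not src.is_enzyme and dst.dockerin:
            rules.append((src.name, dst.name))
    limits = Limits(adaptor_depth=int(rng.integers(0, 3)),
                    max_class_per_path=int(rng.integers(1, 3)))
    return AssemblyConfig(classes=classes, binding_rules=rules, limits=limits)


class TestCapacityWorkedExamples:
    def test_three_tier_complex_reaches_160(self):
        assert complex_capacity(three_tier_config(), "Anch").enzyme_capacity == 160

    def test_cell_free_scae_scaa_reaches_40(self, table1):
        cfg = config_from_rows(table1, ["ScaE", "ScaA"], adaptor_depth=0)
        assert complex_capacity(cfg, "ScaE").enzyme_capacity == 40

    def test_scab2_with_scan1_adaptor_layer_at_least_30(self, table1):
        cfg = config_from_rows(table1, ["ScaB2", "ScaA", "ScaN1"], adaptor_depth=1)
        result = complex_capacity(cfg, "ScaB2")
        assert result.enzyme_capacity >= 30
        assert result.enzyme_capacity == 33  # 10 ScaA slots x 3 + ScaB2's own Coh1 x 3

    def test_zero_slot_root(self):
        cfg = AssemblyConfig(
            classes=[AssemblyClass("bare"),
                     AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
            binding_rules=type_level_rules())
        assert complex_capacity(cfg, "bare").enzyme_capacity == 0

    def test_product_law_on_linear_chains(self, rng):
        for _ in range(5):
            counts = [int(rng.integers(1, 5)) for _ in range(rng.integers(1, 4))]
            cap = complex_capacity(chain_config(counts), "tier0").enzyme_capacity
            assert cap == int(np.prod(counts))

    def test_unknown_root_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            complex_capacity(three_tier_config(), "nope")

    def test_unbounded_daisy_chain_rejected(self):
        cfg = AssemblyConfig(
            classes=[AssemblyClass("ScaN", cohesin_slots=["I", "I"], dockerin="I"),
                     AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
            binding_rules=type_level_rules(),
            limits=Limits(adaptor_depth=5, max_class_per_path=None))
        with pytest.raises(ValueError, match="unbounded assembly"):
            complex_capacity(cfg, "ScaN")


class TestBruteForceOracle:
    def test_two_slot_hand_enumeration(self):
        cfg = AssemblyConfig(
            classes=[AssemblyClass("root", cohesin_slots=["I", "I"]),
                     AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
            binding_rules=type_level_rules())
        trees = enumerate_complexes_bruteforce(cfg, "root")
        assert len(trees) == 4
        assert max(c for _, c in trees) == 2
        assert max(c for _, c in trees) == complex_capacity(cfg, "root").enzyme_capacity

    def test_empty_rules_give_zero(self):
        cfg = AssemblyConfig(
            classes=[AssemblyClass("root", cohesin_slots=["I", "I"]),
                     AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
            binding_rules=[])
        trees = enumerate_complexes_bruteforce(cfg, "root")
        assert max(c for _, c in trees) == 0

    def test_bound_guard(self):
        with pytest.raises(ValueError, match="exceeds bound"):
            enumerate_complexes_bruteforce(three_tier_config(), "Anch", bound=1000)

    def test_scaled_three_tier_agrees_with_dp(self):
        cfg = three_tier_config(2, 2, 2)
        trees = enumerate_complexes_bruteforce(cfg, "Anch")
        assert max(c for _, c in trees) == 8
        assert complex_capacity(cfg, "Anch").enzyme_capacity == 8

    def test_dp_equals_bruteforce_on_random_configs(self, rng):
        checked = 0
        while checked < 30:
            cfg = random_config(rng)
            root = cfg.classes[0].name
            try:
                trees = enumerate_complexes_bruteforce(cfg, root, bound=200_000)
            except ValueError:
                continue  # combinatorially too large for the oracle
            assert (max(c for _, c in trees)
                    == complex_capacity(cfg, root).enzyme_capacity)
            checked += 1


class TestCapacityMonotonicity:
    def test_monotone_in_adaptor_depth(self, table1):
        caps = []
        for depth in range(4):
            cfg = config_from_rows(table1, ["ScaB2", "ScaA", "ScaN1"],
                                   adaptor_depth=depth)
            caps.append(complex_capacity(cfg, "ScaB2").enzyme_capacity)
        assert caps == sorted(caps)

    def test_adding_a_rule_never_decreases(self, rng):
        for _ in range(10):
            cfg = random_config(rng)
            root = cfg.classes[0].name
            before = complex_capacity(cfg, root).enzyme_capacity
            extra = AssemblyConfig(
                classes=cfg.classes,
                binding_rules=cfg.binding_rules + type_level_rules(),
                limits=cfg.limits)
            assert complex_capacity(extra, root).enzyme_capacity >= before


class TestConfigValidation:
    def test_enzyme_with_slots_rejected(self):
        with pytest.raises(ValueError, match="cohesin slots"):
            AssemblyClass("bad", cohesin_slots=["I"], dockerin="I", is_enzyme=True)

    def test_enzyme_without_dockerin_rejected(self):
        with pytest.raises(ValueError, match="dockerin"):
            AssemblyClass("bad", is_enzyme=True)

    def test_undeclared_rule_tokens_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            AssemblyConfig(
                classes=[AssemblyClass("root", cohesin_slots=["I"]),
                         AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
                binding_rules=[("Z", "I")])

    def test_json_round_trip(self):
        cfg = three_tier_config()
        text = '{"classes": [%s], "binding_rules": [["II","II"],["I","I"]], "limits": {"adaptor_depth": 1}}' % ",".join(
            '{"name":"%s","cohesin_slots":%s,"dockerin":%s,"is_enzyme":%s}' % (
                c.name, list(c.cohesin_slots),
                'null' if c.dockerin is None else f'"{c.dockerin}"',
                "true" if c.is_enzyme else "false")
            for c in cfg.classes)
        text = text.replace("'", '"')
        loaded = AssemblyConfig.from_json(text)
        assert complex_capacity(loaded, "Anch").enzyme_capacity == 160
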