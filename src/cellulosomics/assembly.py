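"""Cohesin–dockerin interaction matrices and complex-capacity computation.

ELISA raw responses (absorbance at 450 nm) are expressed as percent of a
standard's maximum response, thresholded into a bipartite cohesin–dockerin
interaction graph, and pH profiles are reduced to relative-retention
analytics.  Scaffoldin assembly configurations — classes with typed cohesin
slots and dockerins, plus admissible binding rules — feed a recursive
best-choice computation of the theoretical maximum number of enzyme subunits
a complex rooted at a given scaffoldin can integrate.  A brute-force
enumeration over all admissible assignment trees serves as an independent
oracle for the recursion on small configurations.

Two path limits make the maximization well defined: ``adaptor_depth`` bounds
the number of adaptor substitutions (a dockerin-bearing scaffoldin occupying
a cohesin slot that an enzyme could also occupy) along any root-to-leaf
path, and ``max_class_per_path`` bounds how often one class may recur along
a path — without it, adaptor scaffoldins could daisy-chain without bound,
which is reported as an error rather than looped on.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# ELISA binding matrices


@dataclass
class BindingMatrix:
    """Cohesin x dockerin assay responses; rows = cohesins, cols = dockerins."""

    cohesin_ids: list[str]
    dockerin_ids: list[str]
    raw: np.ndarray
    standard_response: float | None = None
    relative: np.ndarray | None = None
    coat_concentration_ug_ml: float = 1.0
    probe_concentration_ng_ml: float = 100.0

    def __post_init__(self):
        self.raw = np.asarray(self.raw, float)
        if self.raw.shape != (len(self.cohesin_ids), len(self.dockerin_ids)):
            raise ValueError("raw matrix shape does not match id lists")
        if (self.raw < 0).any():
            raise ValueError("raw responses must be >= 0")


def normalize_binding(matrix: BindingMatrix) -> BindingMatrix:
    """Fill ``relative`` as percent of the standard's maximum response.

    relative[i][j] = 100 * raw[i][j] / standard_response; values above 100
    are legitimate (a pair may out-respond the chosen standard).
    """
    if matrix.standard_response is None or matrix.standard_response <= 0:
        raise ValueError("standard_response must be > 0")
    rel = 100.0 * matrix.raw / matrix.standard_response
    return BindingMatrix(
        cohesin_ids=list(matrix.cohesin_ids),
        dockerin_ids=list(matrix.dockerin_ids),
        raw=matrix.raw.copy(),
        standard_response=matrix.standard_response,
        relative=rel,
        coat_concentration_ug_ml=matrix.coat_concentration_ug_ml,
        probe_concentration_ng_ml=matrix.probe_concentration_ng_ml)


def design_matrix(n_cohesins: int, n_dockerins: int) -> tuple[int, list[tuple[int, int]]]:
    """All ordered (cohesin, dockerin) test pairs; count = product."""
    if n_cohesins < 0 or n_dockerins < 0:
        raise ValueError("counts must be >= 0")
    pairs = [(i, j) for i in range(n_cohesins) for j in range(n_dockerins)]
    return len(pairs), pairs


@dataclass
class InteractionGraph:
    graph: nx.Graph
    threshold: float

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((u, v, d["relative_response"])
                      for u, v, d in self.graph.edges(data=True))

    def edge_count(self) -> int:
        return self.graph.number_of_edges()


def binarize(matrix: BindingMatrix, threshold_percent: float = 20.0) -> InteractionGraph:
    """Bipartite interaction graph: edge iff relative response >= threshold."""
    if matrix.relative is None:
        raise ValueError("matrix not normalized: call normalize_binding first")
    g = nx.Graph()
    g.add_nodes_from(matrix.cohesin_ids, bipartite="cohesin")
    g.add_nodes_from(matrix.dockerin_ids, bipartite="dockerin")
    for i, coh in enumerate(matrix.cohesin_ids):
        for j, doc in enumerate(matrix.dockerin_ids):
            rel = float(matrix.relative[i, j])
            if rel >= threshold_percent:
                g.add_edge(coh, doc, relative_response=rel)
    return InteractionGraph(graph=g, threshold=threshold_percent)


def ph_profile(profile: list[tuple[float, float]], reference_ph: float,
               retention_cutoff: float = 60.0) -> dict:
    """Express a pH/response profile relative to the reference pH.

    Returns the relative-percent curve, the percent retained at the highest
    pH measured, and whether that retention exceeds *retention_cutoff*.
    """
    if not profile:
        raise ValueError("empty pH profile")
    ref = [resp for ph, resp in profile if ph == reference_ph]
    if not ref:
        raise ValueError(f"reference pH {reference_ph} not present in profile")
    ref_resp = ref[0]
    if ref_resp <= 0:
        raise ValueError("reference response must be > 0")
    curve = [(ph, 100.0 * resp / ref_resp) for ph, resp in sorted(profile)]
    max_ph, retained = curve[-1]
    return {
        "curve": curve,
        "reference_ph": reference_ph,
        "max_ph": max_ph,
        "retained_percent": retained,
        "retention_cutoff": retention_cutoff,
        "retained_above_cutoff": retained >= retention_cutoff,
    }


# ---------------------------------------------------------------------------
# Assembly configurations and capacity


@dataclass
class AssemblyClass:
    name: str
    cohesin_slots: list[str] = field(default_factory=list)   # type labels, e.g. "I"
    dockerin: str | None = None                              # type label or None
    is_enzyme: bool = False
    anchored: bool = False

    def __post_init__(self):
        if self.is_enzyme:
            if self.cohesin_slots:
                raise ValueError(f"enzyme class {self.name!r} cannot have cohesin slots")
            if self.dockerin is None:
                raise ValueError(f"enzyme class {self.name!r} must have a dockerin")


@dataclass
class Limits:
    adaptor_depth: int = 1
    max_class_per_path: int | None = 1

    def __post_init__(self):
        if self.adaptor_depth < 0:
            raise ValueError("adaptor_depth must be >= 0")
        if self.max_class_per_path is not None and self.max_class_per_path < 1:
            raise ValueError("max_class_per_path must be >= 1")


@dataclass
class AssemblyConfig:
    classes: list[AssemblyClass]
    binding_rules: list[tuple[str, str]]    # (cohesin type|class name, dockerin type|class name)
    limits: Limits = field(default_factory=Limits)

    def __post_init__(self):
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names")
        self._by_name = {c.name: c for c in self.classes}
        canonical = {"I", "II"}
        slot_types = {t for c in self.classes for t in c.cohesin_slots}
        doc_types = {c.dockerin for c in self.classes if c.dockerin}
        vocab_lhs = slot_types | set(names) | canonical
        vocab_rhs = doc_types | set(names) | canonical
        for coh, doc in self.binding_rules:
            if coh not in vocab_lhs:
                raise ValueError(f"binding rule references undeclared cohesin {coh!r}")
            if doc not in vocab_rhs:
                raise ValueError(f"binding rule references undeclared dockerin {doc!r}")

    def get(self, name: str) -> AssemblyClass:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValueError(f"unknown class {name!r}") from None

    def admissible(self, owner: AssemblyClass, slot_type: str) -> list[AssemblyClass]:
        """Classes whose dockerin may occupy a cohesin slot of *owner*."""
        out = []
        for cand in self.classes:
            if cand.dockerin is None:
                continue
            for coh, doc in self.binding_rules:
                if coh not in (slot_type, owner.name):
                    continue
                if doc in (cand.dockerin, cand.name):
                    out.append(cand)
                    break
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyConfig":
        classes = [AssemblyClass(**c) for c in d["classes"]]
        rules = [tuple(r) for r in d["binding_rules"]]
        limits = Limits(**d.get("limits", {}))
        return cls(classes=classes, binding_rules=rules, limits=limits)

    @classmethod
    def from_json(cls, text: str) -> "AssemblyConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class SlotChoice:
    slot_index: int
    slot_type: str
    binder: str | None
    contribution: int


@dataclass
class CapacityResult:
    root: str
    enzyme_capacity: int
    per_slot: list[SlotChoice]
    depth_used: int

    def to_dict(self) -> dict:
        return {"root": self.root, "enzyme_capacity": self.enzyme_capacity,
                "depth_used": self.depth_used,
                "per_slot": [vars(s) for s in self.per_slot]}


def _check_bounded(config: AssemblyConfig, root: str) -> None:
    if config.limits.max_class_per_path is not None:
        return
    g = nx.DiGraph()
    for c in config.classes:
        if c.is_enzyme:
            continue
        for slot in c.cohesin_slots:
            for b in config.admissible(c, slot):
                if not b.is_enzyme:
                    g.add_edge(c.name, b.name)
    reachable = {root}
    if g.has_node(root):
        reachable |= nx.descendants(g, root)
    sub = g.subgraph(reachable)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("unbounded assembly: binding cycle with "
                         "max_class_per_path unbounded")


def complex_capacity(config: AssemblyConfig, root: str) -> CapacityResult:
    """Maximum number of enzyme subunits a complex rooted at *root* integrates.

    Each cohesin slot independently takes the admissible binder maximizing its
    subtree's enzyme count (an enzyme leaf contributes 1, an unbound slot 0),
    subject to the path limits described in the module docstring.  Slot
    choices tie-break deterministically: enzymes first, then lexicographic
    class name.
    """
    root_class = config.get(root)
    _check_bounded(config, root)
    limits = config.limits
    memo: dict = {}

    def best(cls: AssemblyClass, path: frozenset, adaptors_used: int):
        key = (cls.name, path, adaptors_used)
        if key in memo:
            return memo[key]
        path_counts = dict(path)
        slots: list[SlotChoice] = []
        total = 0
        depth_used = 0
        for idx, slot_type in enumerate(cls.cohesin_slots):
            cands = config.admissible(cls, slot_type)
            slot_has_enzyme = any(b.is_enzyme for b in cands)
            best_val, best_binder, best_depth = 0, None, 0
            for b in sorted(cands, key=lambda c: (not c.is_enzyme, c.name)):
                if b.is_enzyme:
                    val, d_used = 1, 0
                else:
                    occ = path_counts.get(b.name, 0)
                    if (limits.max_class_per_path is not None
                            and occ + 1 > limits.max_class_per_path):
                        continue
                    substitution = 1 if slot_has_enzyme else 0
                    if adaptors_used + substitution > limits.adaptor_depth:
                        continue
                    sub_path = frozenset((path_counts | {b.name: occ + 1}).items())
                    sub_total, _, sub_depth = best(b, sub_path,
                                                  adaptors_used + substitution)
                    val, d_used = sub_total, sub_depth + substitution
                if val > best_val:
                    best_val, best_binder, best_depth = val, b.name, d_used
            slots.append(SlotChoice(idx, slot_type, best_binder, best_val))
            total += best_val
            depth_used = max(depth_used, best_depth)
        result = (total, slots, depth_used)
        memo[key] = result
        return result

    start_path = frozenset({root: 1}.items())
    total, slots, depth_used = best(root_class, start_path, 0)
    return CapacityResult(root=root, enzyme_capacity=total, per_slot=slots,
                          depth_used=depth_used)


# ---------------------------------------------------------------------------
# Brute-force oracle


def _count_trees(config: AssemblyConfig, cls: AssemblyClass,
                 path_counts: dict, adaptors_used: int, memo: dict) -> int:
    key = (cls.name, frozenset(path_counts.items()), adaptors_used)
    if key in memo:
        return memo[key]
    total = 1
    limits = config.limits
    for slot_type in cls.cohesin_slots:
        cands = config.admissible(cls, slot_type)
        slot_has_enzyme = any(b.is_enzyme for b in cands)
        options = 1  # unbound
        for b in cands:
            if b.is_enzyme:
                options += 1
                continue
            occ = path_counts.get(b.name, 0)
            if (limits.max_class_per_path is not None
                    and occ + 1 > limits.max_class_per_path):
                continue
            substitution = 1 if slot_has_enzyme else 0
            if adaptors_used + substitution > limits.adaptor_depth:
                continue
            options += _count_trees(config, b, path_counts | {b.name: occ + 1},
                                    adaptors_used + substitution, memo)
        total *= options
    memo[key] = total
    return total


def enumerate_complexes_bruteforce(config: AssemblyConfig, root: str,
                                   bound: int = 200_000) -> list[tuple[tuple, int]]:
    """Exhaustively enumerate admissible assignment trees under the limits.

    Returns ``(tree, enzyme_count)`` pairs, where a tree is
    ``(class_name, (slot assignments...))`` and each slot assignment is
    ``None``, an enzyme class name, or a subtree.  The total number of trees
    is counted first; if it exceeds *bound* an error is raised — this oracle
    is for small configurations, the recursion in :func:`complex_capacity`
    handles the large ones.
    """
    root_class = config.get(root)
    _check_bounded(config, root)
    n = _count_trees(config, root_class, {root: 1}, 0, {})
    if n > bound:
        raise ValueError(f"search space {n} exceeds bound {bound}")
    limits = config.limits

    def expand(cls: AssemblyClass, path_counts: dict, adaptors_used: int):
        slot_option_lists = []
        for slot_type in cls.cohesin_slots:
            cands = config.admissible(cls, slot_type)
            slot_has_enzyme = any(b.is_enzyme for b in cands)
            options: list[tuple[object, int]] = [(None, 0)]
            for b in cands:
                if b.is_enzyme:
                    options.append((b.name, 1))
                    continue
                occ = path_counts.get(b.name, 0)
                if (limits.max_class_per_path is not None
                        and occ + 1 > limits.max_class_per_path):
                    continue
                substitution = 1 if slot_has_enzyme else 0
                if adaptors_used + substitution > limits.adaptor_depth:
                    continue
                for subtree, count in expand(b, path_counts | {b.name: occ + 1},
                                             adaptors_used + substitution):
                    options.append((subtree, count))
            slot_option_lists.append(options)
        trees: list[tuple[tuple, int]] = []

        def rec(i: int, chosen: list, count: int):
            if i == len(slot_option_lists):
                trees.append(((cls.name, tuple(chosen)), count))
                return
            for opt, c in slot_option_lists[i]:
                rec(i + 1, chosen + [opt], count + c)

        rec(0, [], 0)
        return trees

    return expand(root_class, {root: 1}, 0)


# ---------------------------------------------------------------------------
# Convenience builders for the worked assembly models


def type_level_rules() -> list[tuple[str, str]]:
    """Default type-level admissibility: type I cohesins take type I dockerins,
    type II cohesins take type II dockerins."""
    return [("I", "I"), ("II", "II")]


def chain_config(slot_counts: list[int]) -> AssemblyConfig:
    """Linear chain: tier i has slot_counts[i] slots all binding tier i+1's
    dockerin; the last tier is an enzyme.  Capacity is the product of counts."""
    classes = []
    rules = []
    for i, c in enumerate(slot_counts):
        classes.append(AssemblyClass(
            name=f"tier{i}", cohesin_slots=[f"T{i}"] * c,
            dockerin=None if i == 0 else f"D{i}"))
        rules.append((f"T{i}", f"D{i + 1}"))
    classes.append(AssemblyClass(name=f"tier{len(slot_counts)}",
                                 dockerin=f"D{len(slot_counts)}", is_enzyme=True))
    return AssemblyConfig(classes=classes, binding_rules=rules,
                          limits=Limits(adaptor_depth=len(slot_counts),
                                        max_class_per_path=1))
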