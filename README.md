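# cellulosomics

Tools for the in-silico characterization of **cellulosomes** — the giant
multi-enzyme complexes that anaerobic bacteria such as *Clostridium
alkalicellulosi* assemble on scaffoldin proteins to degrade plant biomass.
Cellulosome assembly is governed by high-affinity **cohesin–dockerin**
interactions: type I cohesins on a primary scaffoldin bind the type I
dockerins of enzymes, while the scaffoldin's own type II (X-)dockerin binds
type II cohesins of cell-surface anchoring or cell-free scaffoldins.

The package is aimed at researchers analysing cellulosomal gene repertoires
and binding data. It provides, as an importable library with a thin CLI:

- **Architecture grammar** (`cellulosomics.arch`) — parse/render/query
  scaffoldin domain-token strings (`SIGN Coh1 Coh1 CBM3 XDoc2` …), with the
  canonical 21-scaffoldin table of the *C. alkalicellulosi* draft genome
  packaged as a fixture (44 cohesin modules: 28 type I + 16 type II).
- **Module detection** (`cellulosomics.detect`) — position-specific scoring
  profiles from reference alignments, local Smith–Waterman profile scanning
  with affine gaps, an empirical Gumbel-tail E-value (hits kept below
  E < 10⁻⁴ by default), a duplicated 22-residue Ca²⁺-binding-repeat validator
  for dockerins, and a coarse signal-peptide heuristic.
- **Dockerin features** (`cellulosomics.dockerin`) — repeat signatures
  (Ca-binding positions 1/3/5/9/12, recognition positions 10/11/17/18/22),
  position frequency matrices, information-content logos, repeat symmetry
  (dual-binding-mode flag), and type I/II classification by
  nearest-reference identity.
- **Cohesin phylogeny** (`cellulosomics.phylo`) — p-distances from global
  alignment, deterministic neighbor joining, Newick output.
- **Scaffoldin classification** (`cellulosomics.classify`) — primary /
  anchoring / cell-free / adaptor / carrier / unconventional nomenclature by
  ordered structural rules.
- **Interaction & assembly analytics** (`cellulosomics.assembly`) — ELISA
  normalization to percent-of-standard, thresholded bipartite interaction
  graphs, pH-retention profiles, and the **complex-capacity** computation:
  the theoretical maximum number of enzyme subunits a scaffoldin assembly
  can integrate, via a recursive best-choice over admissible binders with
  explicit adaptor-depth and per-path class limits (plus an exhaustive
  brute-force oracle for verification).
- **Synthetic data** (`cellulosomics.synth`) — seeded proteome generation
  with planted modules and a ground-truth table, so every stage is testable
  without downloads.

## The capacity model

Given scaffoldin classes with typed cohesin slots and dockerins, enzyme
classes, and admissible (cohesin → dockerin) binding rules, the capacity of
a complex rooted at class *r* is

    C(r) = Σ_slots  max( 0,  max_{b admissible} c(b) ),
    c(b) = 1 if b is an enzyme, else C(b)

subject to: a non-enzyme occupying a slot that an enzyme could also occupy
("adaptor substitution") is allowed at most `adaptor_depth` times per
root-to-leaf path, and each class may recur at most `max_class_per_path`
times per path. For a linear chain of tiers with c₁, c₂, …, cₙ slots this
reduces to the product Π cᵢ — e.g. the record three-tier complex
4 × 5 × 8 = 160 enzymes.

## Worked example

```sh
python examples/complex_capacity.py
```

prints

```
three-tier anchoring->adaptor->primary: 160 enzymes
cell-free ScaE + ScaA: 40 enzymes
cell-associated ScaB2 (+ScaN1 adaptor layer): 33 enzymes
  slot breakdown: [('I', 'ScaN1', 3), ('II', 'ScaA', 30)]
```

Reading: an anchoring scaffoldin with 4 type II cohesins, each binding an
adaptor with 5 type II cohesins, each binding a primary scaffoldin carrying
8 enzymes, integrates 4·5·8 = 160 enzyme subunits. The cell-free ScaE (4
type II cohesins) loaded with ScaA molecules (10 type I cohesins each)
carries 40. Rooted at the anchoring ScaB2, its type II cohesin binds one
ScaA whose 10 slots each take a trivalent ScaN1 adaptor instead of a single
enzyme (10×3), and ScaB2's own type I cohesin takes another ScaN1 (+3) — 33
enzymes, of which the ScaA sub-assembly accounts for at least 30.

Other examples: `parse_scaffoldin_table.py` (census & classification),
`detect_modules.py` (planted-module recovery with E-values),
`dockerin_repeats.py` (signatures, logo, repeat symmetry),
`cohesin_tree.py` (NJ type clustering), `elisa_network.py` (binding-matrix
normalization and pH retention).

The same operations are available as CLI subcommands:

```sh
cellulosomics simulate --seed 1 --out-dir sim/
cellulosomics annotate --proteome sim/proteome.fasta --out-dir run/
cellulosomics capacity --config assembly.json --root ScaE
```

## Notes

The packaged reference sequence sets in `cellulosomics.references` are
synthetic (see `docs/methods.md`); for real genomes supply curated cohesin
and dockerin reference alignments via `--refs-dir` / `build_profile`.
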