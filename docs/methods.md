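# Methods

## Scope and data model

The package models the components of cellulosomal systems at the level of
protein modules: cohesins (types I and II), dockerins (type I and the type II
X-dockerin dyad), and the anchoring (SLH, CSBM), targeting (CBM3) and
auxiliary modules that co-occur with them on scaffoldins. A scaffoldin is an
ordered token string over a closed alphabet; the canonical dataset is the
packaged 21-row scaffoldin table of the *C. alkalicellulosi* draft genome
(`data/table1.tsv`), which parses to 44 cohesin tokens (28 type I, 16 type
II). Published summary figures for this genome disagree internally — 22
scaffoldins and a 31+14 cohesin type split appear in some summary statements
— and the package deliberately follows the printed per-scaffoldin table
rather than reconciling the census; the table is transcribed, not curated.
The bold markup that distinguishes "definitive" cohesins in print is
stripped: the single unbolded ScaK cohesin is counted like any other, which
is required for the 44 total.

## Module detection

Detection replaces a database BLAST search with in-repo computation:

- **Profiles.** A reference alignment per module class becomes a
  position-specific scoring matrix: columns with >50% gaps are dropped,
  column frequencies get a pseudocount (default 0.5), and scores are log₂
  odds against a uniform background. A uniform background matches the
  synthetic proteome generator's null and keeps E-value calibration honest;
  users can supply empirical backgrounds.
- **Scanning.** Smith–Waterman local alignment of profile vs protein with
  affine gaps (defaults: open 8, extend 1, in score bits). Multiple hits per
  protein are extracted best-first with masking, so same-class hits never
  overlap. Cross-class conflicts are resolved greedily by score (ties to the
  leftmost hit), rejecting hits that overlap an accepted one by more than
  half the shorter interval.
- **Significance.** The score null is obtained from residue shuffles of the
  query (default 200, seeded); a Gumbel distribution is fitted by maximum
  likelihood and E = sf(score) × scanned positions. The retention threshold
  is E < 10⁻⁴. This is an empirical surrogate, monotone in score and
  calibrated against the composition of the actual query; it makes no claim
  of reproducing BLAST's Karlin–Altschul statistics. A zero-variance null is
  an error ("uninformative null"), not a silent pass.
- **Dockerin validation.** Dockerins must show two 22-position repeats
  (windows scoring ≥50% of the repeat profile's maximum) separated by a
  5–25 residue linker, each repeat carrying D/N/E at ≥3 of the five
  Ca-binding offsets 1/3/5/9/12. The ≥3-of-5 rule is a tolerance choice:
  conservation at these positions is strong but not absolute, and logos of
  real repeats show variability. Repeat length 22 follows the canonical
  repeat numbering (positions 1–22).
- **Signal peptides.** A deliberately coarse heuristic: a K/R within the
  first 5 residues followed by a ≥8-residue window of ≥70% hydrophobic
  residues (AVLIMFWC) inside the first 35. It is a stand-in for dedicated
  predictors, used to order tokens, and is documented as such.

Coordinates are 0-based half-open internally and 1-based inclusive in
human-readable output.

## Typing and phylogeny

Dockerins and cohesins are typed I/II by best global-alignment percent
identity against type-labelled reference sets (fixed scoring: match 2,
mismatch −1, gap open −5, extend −0.5). A call requires the winning set to
lead by ≥5 percentage points (default `min_margin`), otherwise "unknown" —
with type II modules being rare relative to type I, coin-flip typing of
divergent sequences is worse than abstention. The cohesin tree uses
p-distance (1 − identity fraction) and canonical neighbor joining with
deterministic lexicographic tie-breaks; negative NJ branch lengths are
clamped to zero with the deficit moved to the sibling so pair distances are
conserved. No substitution-model correction and no bootstrap: the tree's
role is type clustering, and on additive matrices NJ is exact (tested on 50
random additive trees).

## Scaffoldin nomenclature

Classification is a fixed-order first-match rule list: (1) unconventional if
any of Peptidase/GalOx/RhsA/FN3/WFA/PPC is present — evaluated first so
auxiliary-laden scaffoldins that also carry cohesin+dockerin pairs are not
mislabeled adaptors; (2) primary (≥2 Coh1 + CBM3 + XDoc2); (3) anchoring
(SLH + cohesin); (4) carrier (CSBM + cohesin); (5) adaptor (Coh1 + Doc1);
(6) cell-free (≥2 Coh2, no anchoring/targeting/dockerin tokens); (7)
monovalent_other. ScaK (`SIGN Coh2 Doc1`) is left monovalent_other: its
printed cohesin is type II, so the adaptor rule (which requires type I
cohesins) does not apply, and the ambiguity is preserved rather than
special-cased. ScaF2 (`SIGN UNK Coh2`) likewise falls through to
monovalent_other.

## Interaction matrices and capacity

ELISA responses are normalized to percent of a standard's maximum response
(values above 100% are legitimate) and binarized at a declared threshold
(default 20% of standard, strict ≥) into a bipartite graph. The published
binding calls are qualitative; the threshold is therefore a tunable,
logged parameter, not a reconstruction. pH profiles are reduced to percent
of the response at a reference pH with a retention check at the highest pH
(default cutoff 60%).

Capacity counts **enzyme subunits only** — scaffoldins are scaffolding, and
the worked figures (160, 40, ≥30) all count enzymes. Slot choices are
independent (a theoretical maximum, with no finite enzyme pool), so the
optimum decomposes per slot; memoized recursion computes it exactly. Two
limits keep the model finite and honest:

- `adaptor_depth` (default 1): an *adaptor substitution* is counted when a
  non-enzyme binder occupies a slot that at least one enzyme class could
  also occupy under the rules. This definition is what makes the worked
  examples consistent: a primary scaffoldin docking onto a type II cohesin
  is not a substitution (no enzyme fits there), while an adaptor scaffoldin
  displacing an enzyme from a type I cohesin is.
- `max_class_per_path` (default 1): bounds recurrence of a class along a
  root-to-leaf path. Setting it unbounded with a binding cycle reachable
  from the root (e.g. an adaptor whose cohesins accept its own dockerin) is
  an explicit "unbounded assembly" error, never an infinite loop.

Default type-level rules are Coh-I→Doc-I and Coh-II→Doc-II; pair-level rules
(from a binarized ELISA graph or by class name) can extend them. The
brute-force oracle enumerates every admissible assignment tree under the
same limits and is guarded by a precomputed tree count: it exists to verify
the recursion on small configurations (the three-tier 4×5×8 model has on
the order of 10¹² distinct assignment trees, far past any enumeration
bound, so the 160 figure is instead cross-checked against the closed-form
product law for linear chains). One capacity figure circulating for this
system — "up to 105 enzymatic subunits" — has no printed derivation; under
the rules here, ScaE with one ScaN layer gives 120 and summing the named
complex types gives ≈103, neither of which is 105, so the package computes
and reports capacities but does not assert that number.

## Synthetic data

The generator emulates exactly the structure detection assumes: modules
drawn by mutating per-class consensus sequences (default per-residue
substitution rate 0.05, the divergence regime the detector is specified to
handle), joined by 5–25-residue linkers sampled from a uniform residue
background, plus uniform-random background proteins (100–400 residues).
Uniform backgrounds are a neutral null for E-value calibration; real
proteomes are not uniform. SIGN tokens are realized with the exact pattern
the signal heuristic requires — a calibration convenience making SIGN
planting perfectly recoverable, not a biological claim. All randomness
derives from a single seed; identical specs give byte-identical FASTA and
truth tables.

The packaged reference sets (`references.py`) are **synthetic**: fixed
random consensus sequences per module class, except the dockerin repeats,
which carry the field's canonical layout (D/N at Ca offsets 1/3/5/9/12;
type I recognition S/T at 10/11 and R/R at 17/18, position 22 variable;
type II divergent at the recognition offsets). Consequences for what tests
show: passing recall/precision demonstrates the detector recovers conserved
modules at 5% divergence against a uniform background — it does not
demonstrate performance on real proteomes, where background composition,
repeat families and homologous non-cellulosomal domains make the problem
harder. Real analyses should supply curated reference alignments.

## Numerical and problem-size choices

Detection tests use proteomes of ~27 proteins with ~51 planted modules and
200-shuffle nulls — sizes at which the Gumbel fit is stable and the suites
complete quickly on one core. The capacity oracle comparison uses 100
random configurations of ≤4 scaffoldin classes; NJ recovery uses 50 random
additive trees of 5–10 leaves. Ties everywhere break deterministically
(leftmost hit, lexicographic label pair, enzyme-first then name order), and
every stochastic step takes an explicit seed.

## Known limitations

- E-values are empirical surrogates; absolute values are not comparable to
  BLAST's.
- The signal-peptide heuristic has no claimed sensitivity/specificity.
- Auxiliary module classes (Peptidase, GalOx, …) are detected only when the
  user supplies profiles for them, or injected from an annotation table;
  out of the box the pipeline detects cohesins, dockerins, CBM3, SLH, CSBM.
- Bootstrap support values and likelihood phylogenetics are out of scope.
- Capacity is a theoretical maximum under slot independence; it ignores
  expression levels, enzyme pools, and steric constraints.
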