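"""Scaffoldin nomenclature classification.

Assigns each parsed architecture one functional class following the
descriptive conventions of complex cellulosome-producing clostridia:
primary scaffoldins carry many type I cohesins plus a cellulose-targeting
CBM3 and a C-terminal X-dockerin; anchoring scaffoldins attach to the cell
wall via SLH repeats; carrier scaffoldins use a CSBM; adaptor scaffoldins
carry both type I cohesins and a type I dockerin; cell-free scaffoldins are
multivalent type II cohesin backbones with no anchoring or targeting
modules; scaffoldins with peptidases / oxidases / Rhs-type auxiliary content
are grouped as unconventional.  Rule evaluation order is fixed: the
unconventional rule fires first so that auxiliary-laden scaffoldins that
also happen to carry a cohesin+dockerin combination are not mislabeled as
adaptors.
"""
from __future__ import annotations

from dataclasses import dataclass

from .arch import ScaffoldinArchitecture

UNCONVENTIONAL_TOKENS = frozenset({"Peptidase", "GalOx", "RhsA", "FN3", "WFA", "PPC"})

LABELS = ("primary", "anchoring", "cell_free", "adaptor", "carrier",
          "unconventional", "monovalent_other")


@dataclass
class NomenclatureClass:
    label: str
    rationale: str


def assign_nomenclature(arch: ScaffoldinArchitecture) -> NomenclatureClass:
    """First matching rule wins; see module docstring for the rule order."""
    ncoh = arch.count("cohesin")
    ndoc = arch.count("dockerin")
    if ncoh == 0 and ndoc == 0:
        raise ValueError("not a cellulosomal protein: no cohesin or dockerin token")
    if any(t in UNCONVENTIONAL_TOKENS for t in arch.tokens):
        return NomenclatureClass("unconventional", "auxiliary_content")
    if arch.count("Coh1") >= 2 and arch.has("CBM3") and arch.has("XDoc2"):
        return NomenclatureClass("primary", "multivalent_coh1_cbm3_xdoc")
    if arch.has("SLH") and ncoh >= 1:
        return NomenclatureClass("anchoring", "slh_with_cohesin")
    if arch.has("CSBM") and ncoh >= 1:
        return NomenclatureClass("carrier", "csbm_with_cohesin")
    if arch.count("Coh1") >= 1 and arch.count("Doc1") >= 1:
        return NomenclatureClass("adaptor", "coh1_plus_doc1")
    if (arch.count("Coh2") >= 2 and arch.count("anchoring") == 0
            and arch.count("targeting") == 0 and ndoc == 0):
        return NomenclatureClass("cell_free", "multivalent_coh2_only")
    return NomenclatureClass("monovalent_other", "fallback")
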