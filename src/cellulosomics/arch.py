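"""Scaffoldin modular-architecture notation.

Scaffoldins are non-catalytic backbone proteins of the cellulosome.  Their
domain content is written in the field as an ordered, whitespace-separated
token string, e.g. ``SIGN Coh1 Coh1 CBM3 XDoc2``: a signal peptide, two type I
cohesins, a family 3 carbohydrate-binding module and a C-terminal X-module /
type II dockerin dyad.  This module parses, renders and queries that notation
over a closed token alphabet, and packages the canonical 21-scaffoldin table
of the *Clostridium alkalicellulosi* draft genome as a fixture.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

# ---------------------------------------------------------------------------
# Token alphabet

ROLE_OF = {
    "SIGN": "signal",
    "Coh1": "cohesin",
    "Coh2": "cohesin",
    "Doc1": "dockerin",
    "XDoc2": "dockerin",
    "SLH": "anchoring",
    "CSBM": "anchoring",
    "CBM3": "targeting",
    "UNK": "auxiliary",
    "Peptidase": "auxiliary",
    "PPC": "auxiliary",
    "RhsA": "auxiliary",
    "GalOx": "auxiliary",
    "FN3": "auxiliary",
    "WFA": "auxiliary",
}

TOKENS = frozenset(ROLE_OF)
ROLES = frozenset(ROLE_OF.values())

#: Alternative spellings folded onto canonical tokens ("X" and "UNK" both
#: denote a module of unknown function).
ALIASES = {"X": "UNK", "Fn3": "FN3", "Rhs": "RhsA"}

COHESIN_TOKENS = ("Coh1", "Coh2")
DOCKERIN_TOKENS = ("Doc1", "XDoc2")


class ArchitectureError(ValueError):
    """Raised for malformed architecture strings."""


@dataclass
class ScaffoldinArchitecture:
    """An ordered scaffoldin domain-token list with optional metadata."""

    tokens: list[str]
    name: str | None = None
    protein_id: str | None = None
    nomenclature_class: str | None = None

    def render(self) -> str:
        """Canonical single-space-separated form."""
        return " ".join(self.tokens)

    def count(self, selector: str) -> int:
        return count_modules(self, selector)

    def has(self, selector: str) -> bool:
        return self.count(selector) > 0

    def to_dict(self) -> dict:
        return {"name": self.name, "protein_id": self.protein_id,
                "tokens": list(self.tokens)}


def parse_architecture(text: str, *, name: str | None = None,
                       protein_id: str | None = None) -> ScaffoldinArchitecture:
    """Parse a whitespace-separated token string.

    Markup asterisks (used in print to bold definitive cohesins) are stripped
    before tokenizing.  Unknown tokens raise :class:`ArchitectureError` naming
    the token and its 1-based position; an empty string raises
    ``"empty architecture"``.
    """
    cleaned = text.replace("*", "").strip()
    if not cleaned:
        raise ArchitectureError("empty architecture")
    fields = cleaned.split()
    tokens: list[str] = []
    for pos, raw in enumerate(fields, start=1):
        tok = ALIASES.get(raw, raw)
        if tok not in TOKENS:
            raise ArchitectureError(
                f"unrecognized token {raw!r} at position {pos}")
        tokens.append(tok)
    n_sign = tokens.count("SIGN")
    if n_sign > 1:
        raise ArchitectureError("multiple SIGN tokens")
    if n_sign == 1 and tokens[0] != "SIGN":
        raise ArchitectureError("SIGN token must be first")
    return ScaffoldinArchitecture(tokens=tokens, name=name, protein_id=protein_id)


def render_architecture(arch: ScaffoldinArchitecture) -> str:
    return arch.render()


def count_modules(arch: ScaffoldinArchitecture, selector: str) -> int:
    """Count tokens by token name (``"Coh1"``) or by role (``"cohesin"``)."""
    if selector in TOKENS:
        return sum(1 for t in arch.tokens if t == selector)
    if selector in ROLES:
        return sum(1 for t in arch.tokens if ROLE_OF[t] == selector)
    raise ValueError(f"unknown selector {selector!r} (not a token or role)")


# ---------------------------------------------------------------------------
# Packaged scaffoldin table fixture


@dataclass
class Table1Row:
    protein_id: str
    name: str
    architecture: str
    remark: str

    def parsed(self) -> ScaffoldinArchitecture:
        return parse_architecture(self.architecture, name=self.name,
                                  protein_id=self.protein_id)


@dataclass
class Table1Fixture:
    """The 21 cohesin-bearing scaffoldins of *C. alkalicellulosi*."""

    rows: list[Table1Row] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def by_name(self, name: str) -> Table1Row:
        for row in self.rows:
            if row.name == name:
                return row
        raise KeyError(name)

    def architectures(self) -> list[ScaffoldinArchitecture]:
        return [row.parsed() for row in self.rows]


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged scaffoldin table (TSV, one header line)."""
    text = resources.files("cellulosomics").joinpath("data/table1.tsv").read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != ["protein_id", "name", "architecture", "remark"]:
        raise ValueError("corrupted scaffoldin table fixture: bad header")
    rows = []
    seen_ids: set[str] = set()
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ValueError(f"corrupted scaffoldin table fixture: {ln!r}")
        pid, name, archstr, remark = parts
        if not pid.startswith("CloalDRAFT_") or pid in seen_ids:
            raise ValueError(f"corrupted scaffoldin table fixture: bad id {pid!r}")
        seen_ids.add(pid)
        rows.append(Table1Row(pid, name, archstr, remark))
    fixture = Table1Fixture(rows)
    if len(fixture) != 21:
        raise ValueError(f"corrupted scaffoldin table fixture: {len(fixture)} rows")
    for row in fixture:
        row.parsed()  # all architecture strings must parse
    return fixture


def export_architectures_json(archs: list[ScaffoldinArchitecture]) -> str:
    return json.dumps([a.to_dict() for a in archs], indent=2)
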