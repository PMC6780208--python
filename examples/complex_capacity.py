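"""Theoretical enzyme capacity of cellulosome complexes.

Three worked assemblies: the record three-tier complex (4 x 5 x 8 = 160
enzymes), the cell-free ScaE+ScaA system (4 x 10 = 40), and the
cell-associated ScaB2 complex where ScaN1 adaptors multiply ScaA's slots.
"""
from cellulosomics import (
    AssemblyClass,
    AssemblyConfig,
    Limits,
    complex_capacity,
    load_table1_fixture,
    type_level_rules,
)

table = load_table1_fixture()


def from_rows(names, adaptor_depth):
    classes = [AssemblyClass("Enz", dockerin="I", is_enzyme=True)]
    for name in names:
        arch = table.by_name(name).parsed()
        slots = ["I"] * arch.count("Coh1") + ["II"] * arch.count("Coh2")
        doc = "II" if arch.has("XDoc2") else ("I" if arch.has("Doc1") else None)
        classes.append(AssemblyClass(name, cohesin_slots=slots, dockerin=doc))
    return AssemblyConfig(classes=classes, binding_rules=type_level_rules(),
                          limits=Limits(adaptor_depth=adaptor_depth))


three_tier = AssemblyConfig(
    classes=[AssemblyClass("Anch", cohesin_slots=["II"] * 4),
             AssemblyClass("Adapt", cohesin_slots=["II"] * 5, dockerin="II"),
             AssemblyClass("Prim", cohesin_slots=["I"] * 8, dockerin="II"),
             AssemblyClass("Enz", dockerin="I", is_enzyme=True)],
    binding_rules=type_level_rules(), limits=Limits(adaptor_depth=1))
print("three-tier anchoring->adaptor->primary:",
      complex_capacity(three_tier, "Anch").enzyme_capacity, "enzymes")

cell_free = from_rows(["ScaE", "ScaA"], adaptor_depth=0)
print("cell-free ScaE + ScaA:",
      complex_capacity(cell_free, "ScaE").enzyme_capacity, "enzymes")

cell_assoc = from_rows(["ScaB2", "ScaA", "ScaN1"], adaptor_depth=1)
r = complex_capacity(cell_assoc, "ScaB2")
print("cell-associated ScaB2 (+ScaN1 adaptor layer):",
      r.enzyme_capacity, "enzymes")
print("  slot breakdown:", [(s.slot_type, s.binder, s.contribution)
                            for s in r.per_slot])
print("each capacity is the maximum over all admissible slot assignments; "
      "adaptor scaffoldins multiply a slot's yield but consume adaptor depth.")
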