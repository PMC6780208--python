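"""Census of the packaged C. alkalicellulosi scaffoldin table.

Parses the 21 scaffoldin architecture strings, counts cohesin modules and
assigns each scaffoldin its nomenclature class.
"""
from collections import Counter

from cellulosomics import assign_nomenclature, load_table1_fixture

table = load_table1_fixture()
archs = table.architectures()

print(f"scaffoldins: {len(archs)}")
print(f"total cohesins: {sum(a.count('cohesin') for a in archs)} "
      f"({sum(a.count('Coh1') for a in archs)} type I, "
      f"{sum(a.count('Coh2') for a in archs)} type II)")

labels = Counter(assign_nomenclature(a).label for a in archs)
print("nomenclature classes:", dict(sorted(labels.items())))
scaa = table.by_name("ScaA").parsed()
print(f"ScaA: {scaa.render()}")
print(f"  -> {scaa.count('Coh1')} type I cohesin slots for enzymes, plus CBM3 "
      "cellulose targeting and a C-terminal X-dockerin for cell anchoring")
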