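"""Number the cetuximab variable domains and locate their liability sites.

Assigns Kabat position labels by template alignment, tiles the domain into
framework/CDR regions, and shows that the heavy chain carries the occupied
NDT glycosylation sequon at position 85 (framework 3) and the light chain
the NGS motif at position 41 (framework 2).
"""

from humab import annotate_regions, number_sequence
from humab.datasets import cetuximab
from humab.numbering import ChainType, Region

chains = cetuximab()
vh = number_sequence(chains.vh, ChainType.VH)
vl = number_sequence(chains.vl, ChainType.VK)

for name, ns in (("VH", vh), ("VL", vl)):
    rm = annotate_regions(ns)
    print(f"{name}: {len(ns)} residues, "
          f"CDR3 = {''.join(ns.residue_at(l) for l in rm.regions[Region.CDR3])}")

print("\nVH 84-88:",
      " ".join(f"{l}{vh.residue_at(l)}" for l in ("84", "85", "86", "87", "88")))
print("VL 40-43:",
      " ".join(f"{l}{vl.residue_at(l)}" for l in ("40", "41", "42", "43")))
print("\nVH N85-D86-T87 is the NDT sequon licensing framework glycosylation;")
print("VL N41-G42 is the NG deamidation/heterogeneity motif.")
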