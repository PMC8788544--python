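"""Scan cetuximab for PTM liabilities and compute theoretical pI values.

Lists every N-glycosylation sequon and deamidation motif in the variable
domains, proposes an aglycosylating mutation for the sequon, and reproduces
the ProtParam-convention isoelectric points of the wild-type antibody and
its aglycosylated (N85E) variant.
"""

from humab import (
    design_aglyco_mutation,
    number_sequence,
    scan_deamidation,
    scan_nglyc,
    theoretical_pi,
)
from humab.datasets import cetuximab
from humab.numbering import ChainType

chains = cetuximab()
for name, seq, ct in (("VH", chains.vh, ChainType.VH),
                      ("VL", chains.vl, ChainType.VK)):
    ns = number_sequence(seq, ct)
    for hit in scan_nglyc(ns) + scan_deamidation(ns):
        print(f"{name} {hit.kind.value:14s} {hit.motif:3s} at {hit.start_label}"
              f" ({hit.region}, {hit.severity})")
    for hit in scan_nglyc(ns):
        fix = design_aglyco_mutation(ns, hit)
        print(f"  -> proposed fix: {name} "
              f"{fix.from_residue}{fix.position_label}{fix.to_residue}")

wt = theoretical_pi(chains.mab_chainset("wild_type"))
n85e = theoretical_pi(chains.mab_chainset("n85e"))
print(f"\ntheoretical pI (mature mAb, 2H+2L): wild-type {wt:.2f}, "
      f"N85E {n85e:.2f}")
print("The single Asn->Glu per heavy chain adds two negative charges and "
      "lowers the pI by ~0.2 units.")
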