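"""Run the end-to-end campaign pipeline and print the per-chain summary.

One call wires everything together: humanization, the lambda-FR4 light-chain
modification, liability comparison, humanness scoring, identity to parent,
scFv assembly and theoretical pI — the per-variant summary a humanization
campaign tabulates.
"""

import tempfile

from humab import RunConfig, run_campaign
from humab.synthetic import generate_fixtures

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_fixtures(tmp, seed=11)
    config = RunConfig(method="germline",
                       repertoire_path=str(bundle.repertoire_fasta),
                       lambda_fr4=True)
    report = run_campaign(bundle.query_vh, bundle.query_vl, config)

    for chain in (report.vh, report.vl):
        print(f"{chain.chain}: {len(chain.result.substitutions)} substitutions, "
              f"identity to parent {chain.identity_to_parent:.1f}%")
        print(f"   humanness {chain.humanness_before:.2f} -> "
              f"{chain.humanness_after:.2f}")
        print(f"   liabilities removed: "
              f"{[h.motif + '@' + h.start_label for h in chain.liabilities.removed]}"
              f", introduced: {len(chain.liabilities.introduced)}")
    print(f"VL terminus after lambda-FR4 swap: ...{report.vl.final_sequence[-4:]}")
    print(f"Fv theoretical pI {report.fv_pi_before:.2f} -> "
          f"{report.fv_pi_after:.2f}")
    print(f"scFv (VL-(G4S)4-VH) length: {len(report.scfv_sequence)}")
    print(f"toy MHCII core-peptide count {report.core_epitopes_before} -> "
          f"{report.core_epitopes_after}")
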