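# humab — antibody variable-domain humanization toolkit

`humab` is a Python library for protein engineers who humanize antibodies
discovered in non-human species. It re-creates, end to end and at the
sequence/coarse-structure level, the workflow used to humanize a mouse-derived
clinical antibody such as cetuximab: number the variable domains, pick a
humanization strategy, eliminate sequence liabilities, and quantify what
changed.

## What it computes

* **Kabat / IMGT numbering** of VH, Vκ and Vλ domains by deterministic global
  alignment against packaged human consensus templates, with canonical
  insertion codes (e.g. CDR-H3 `100A…`), region tiling (FR1…FR4), and the
  Foote–Winter Vernier-zone sets.
* **Four humanization strategies**, all of which leave Kabat-CDR and
  Vernier-zone residues untouched by construction:
  1. *CDR graft* onto a user-supplied stable human acceptor framework;
  2. *germline substitution* — every eligible framework mismatch set to the
     top-ranked human germline V gene (identity threshold 50%, tolerance 0),
     FR4 from the best-matching J gene;
  3. *consensus substitution* — positions moved to the human consensus
     residue when its germline frequency beats the query's by ≥ 20
     percentage points;
  4. *structure-guided selection* — per position, candidates are the human
     residues at ≥ 5% germline frequency plus the query residue, and a
     pluggable mutation scorer (default: a transparent CB-contact potential)
     picks the predicted most stable single mutation.
  Plus the *λ-FR4 swap*: replacing the κ C-terminus (…LEIK) with the more
  hydrophobic λ terminus LTVL.
* **Sequence liabilities** — N-glycosylation sequons `N-X-[S/T]` (X ≠ P) and
  NG/NS deamidation motifs, with region tags, aglycosylating-mutation design,
  and before/after comparison.
* **Humanness** — a T20-style score: the mean percent identity of a domain
  (framework-only by default) to its 20 closest matches in a human sequence
  database, on a 0–100 scale,
  `T20 = (1/20) · Σ_{i∈top20} %id(query, db_i)`.
* **Theoretical pI** in the Expasy ProtParam convention (Bjellqvist pKa set,
  per-chain termini, bisection on the net charge `Z(pH) = 0`).
* **scFv assembly** (`VL-(G4S)n-VH`) and a pluggable MHC-class-II
  core-peptide counting interface (15-mer windows, 9-mer cores, top-0.2%
  percentile threshold).

## Worked example

```python
from humab import number_sequence, scan_nglyc, theoretical_pi
from humab.datasets import cetuximab
from humab.numbering import ChainType

chains = cetuximab()
vh = number_sequence(chains.vh, ChainType.VH)
print([(h.motif, h.start_label, h.region) for h in scan_nglyc(vh)])
# [('NDT', '85', 'FR3')]
print(theoretical_pi(chains.mab_chainset("wild_type")))   # 7.9
print(theoretical_pi(chains.mab_chainset("n85e")))        # 7.68
```

The heavy chain carries an occupied NDT glycosylation sequon at Kabat
position 85, in framework 3 — the site whose removal is a main goal of
humanizing this antibody. Mutating that asparagine to glutamate (N85E) in
both heavy chains of the mature antibody lowers the theoretical pI from
7.90 to 7.68.

The `examples/` directory holds one short narrative script per capability
(numbering and annotation, liability scanning and pI, the four humanization
strategies side by side, and the end-to-end campaign report); each prints
the numbers it computes and a line on what they mean. A thin CLI mirrors
the library: `humab humanize|scan|pi|humanness|scfv|campaign|fixtures`.

No external databases are required: `humab.synthetic.generate_fixtures`
writes a seeded synthetic germline repertoire, a mouse-like query Fv with
the classic liability layout (NDT at H85, NG at L41), and a toy Fv
coordinate model, so every pipeline runs self-contained.

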