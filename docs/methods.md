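# Methods

This note documents the models, conventions and numerical choices behind
`humab`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what passing tests
do and do not demonstrate.

## Numbering by template alignment

Variable domains are numbered by global pairwise alignment (BLOSUM62,
affine gaps: open −11, extend −1) against packaged human consensus
templates — VH subgroup III, Vκ subgroup I, and a Vλ consensus with the
canonical one-residue FR1 deletion. Template columns carry Kabat labels;
the VH template includes the near-ubiquitous 82A–82C columns. This is a
deliberate alternative to profile-HMM numbering: it is deterministic,
dependency-light, and adequate for Fv-length inputs, at the cost of less
robustness on sequences far outside the template families.

Choices that matter:

* **Identity floor 45%** (and ≥ 50% template coverage): below this the
  Kabat labels would not be trustworthy, so the sequence is rejected with
  the best template name and identity rather than silently mis-numbered.
  Inputs must be 90–140 standard residues.
* **Insertion codes** use the alphabet A–Z. Raw alignment gap placement
  inside CDRs is not trusted; each CDR run is re-labelled canonically by its
  observed length around the standard Kabat anchors (H1: 35, H2: 52,
  H3: 100, L1: 27, L2: 54, L3: 95), so an 11-residue CDR-H3 yields
  100A–100C regardless of where the aligner opened the gap. Deletions
  shrink the run ahead of the anchor while keeping the trailing labels.
* **Terminal frameworks admit no insertions**: residues that would need
  insertion codes in FR1 or FR4 are un-numberable overhangs and rejected.
* **Kabat CDR bounds** are the standard definition (VH 31–35B / 50–65 /
  95–102; VL 24–34 / 50–56 / 89–97). The **IMGT CDR definition** is
  expressed directly in Kabat coordinates through a packaged correspondence
  (VH 26–35 / 51–57 / 93–102; VL 24–34 / 50–52 / 89–97) rather than by
  renumbering — this avoids double-numbering drift, at the cost of being
  approximate at insertion-heavy positions. IMGT-labelled output is
  likewise produced by a monotone region-wise correspondence table and is
  intended for interoperability, not for exact IMGT gap bookkeeping.
* **Vernier zone**: the Foote–Winter position sets (VH 2, 27–30, 47–49,
  67, 69, 71, 73, 78, 93, 94, 103; VL 2, 4, 35, 36, 46–49, 64, 66, 68, 69,
  71, 98), disjoint from the Kabat CDRs by construction. Which Vernier
  definition commercial humanization suites use is not public; the set in
  use is flagged in output metadata.

## Germline repertoires

Position frequencies are **unweighted per gene** — each germline counts
once. Gene- vs allele- vs expressed-repertoire weighting is genuinely open;
gene-level counting is the reproducible choice and is documented in the
frequency table itself. Percent identities use as denominator the framework
labels present in **both** sequences, so length variation at insertion
slots is not penalised. Consensus ties break by fixed residue-alphabet
order and are flagged. V records span FR1–CDR3; J records are numbered by
anchoring their C-terminus at the last template label, and FR4
humanization is always routed through J-gene ranking (V and J genes
recombine independently, so their frameworks are ranked separately).

## Humanization strategies

All strategies share one safety contract, enforced by the result type
itself: the output differs from the input exactly at the recorded
substitution positions, and every Kabat-CDR and Vernier-zone residue is
identical between input and output.

* **Exclusion sets** (all on by default): Kabat CDRs, IMGT CDRs, Vernier
  zone, and positions already matching the best germline. The proprietary
  semantics of the reference protocol's "tolerance" settings are not
  public; this package interprets *germline tolerance 0* as "substitute
  every eligible mismatch toward the top germline" and *frequent-residue
  tolerance 20* as "substitute only when the consensus frequency exceeds
  the query residue's frequency by ≥ 20 percentage points". Both are
  configurable and recorded in each substitution's rationale string.
* **CDR graft** keeps the query's CDR *and* Vernier residues on the
  acceptor framework (the conventional graft-plus-Vernier practice); a
  non-insertion framework label missing from the acceptor is an
  unresolvable gap and an error, while missing optional insertion slots
  carry the query residue through.
* **Structure-guided selection** evaluates mutations one at a time against
  the input model (no iterative remodeling or combinatorial search),
  matching best-single-mutation semantics and keeping the operation
  deterministic. Candidate sets are the ≥ 5% germline-frequency residues
  plus the query residue; ties break toward higher germline frequency,
  then alphabet order. A position absent from the structure map is skipped
  with a warning, never guessed.
* **λ-FR4 swap** replaces the last four VL residues with LTVL. On a κ
  terminus …LEIK this changes exactly three residues — which reconciles the
  two phrasings ("last four residues" vs "last three residues") found in
  descriptions of this modification. The operation is idempotent and
  rejects heavy chains.

## The contact-potential mutation scorer

Forcefield mutation energies are out of scope; the default scorer is a
transparent stand-in with the same contract (deterministic, 0 for a null
mutation, lower = predicted more stable), and the scorer registry lets a
forcefield-backed implementation plug in. Neighbors are residues with
CB–CB distance ≤ 8 Å (CB = CA for glycine), excluding the position itself
and its ±1 sequence neighbors in the same chain; positions with ≤ 2
neighbors are treated as solvent-exposed and score 0. The score is
Σ_neighbors [P(to, nb) − P(from, nb)] over a three-class
(hydrophobic / polar / charged) pair potential pinned in
`data/contact_potential.json`; antisymmetry and rigid-motion invariance
follow by construction. Author residue numbers in PDB input are never
trusted for Kabat labels — mapping is always alignment-based with a 90%
identity floor.

## Humanness and epitope counting

The T20-style score is the mean percent identity of the query
(framework-only by default) to its 20 closest database entries. The
reference score's proprietary database cannot be distributed, so absolute
published scores are treated as non-reproducible references; the packaged
tests assert the *direction* of the humanization effect (score of output ≥
score of input) against the synthetic repertoire, which is also the honest
limit of what they show about real data.

MHC-II core-peptide counting is an interface, not a model: 15-mer windows,
9-mer cores, a percentile rank per core (lower = stronger), and a count of
unique cores at or below the threshold (default top 0.2%). Deterministic
toy scorers are packaged for tests; a trained predictor can be adapted to
the same interface. Because published descriptions of the scFv used for
epitope scoring mention both (G4S)3 and (G4S)4 linkers, the linker length
is configurable with default 4, and linker-spanning cores can be reported
separately.

## Theoretical pI

The ProtParam convention, exactly: the Bjellqvist pKa set (D 4.05, E 4.45,
C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55; N-terminus by
first residue, default 7.5) pinned verbatim in `data/pka_bjellqvist.json`;
cysteines counted as ionizable; termini counted per chain copy; the pI
found by bisection on the net charge to |Z| < 1e-4 and reported to two
decimals. The result is invariant under copy-number scaling, so a 2H+2L
antibody equals its 1H+1L half-molecule.

Two conventions matter for antibody pI values. First, termini: per-chain
termini are used (computing on concatenated chains shifts a mAb-sized pI
by ≤ ~0.1; the ChainSet type makes the choice explicit). Second, the
heavy-chain C-terminal lysine: manufactured antibodies circulate
essentially des-Lys, and charge calculations for them conventionally use
the mature (clipped) heavy chain. The packaged cetuximab dataset exposes
both forms; on the mature 2H+2L antibody the package computes pI 7.90 for
wild type and 7.68 for the N85E variant, matching the published 7.92/7.66
within 0.02, while the genetically encoded (Lys-bearing) chains give
8.07/7.90.

## Synthetic fixtures: what they emulate, and what they do not

`generate_fixtures(out_dir, seed, n_germlines=12, mutation_rate=0.1)`
writes, deterministically per seed: 12 synthetic germline V genes per locus
(the consensus with 2–4 seeded framework changes each, liability-critical
columns H85–87 / L41–43 never touched), small fixed J-gene sets, a
mouse-like query (the consensus with `round(0.1 × framework length)`
seeded mutations to residues absent from the repertoire column — never
Asn, never completing an upstream sequon — three CDR mutations, and the
planted NDT at H85 / NG at L41), an acceptor framework pair, and a toy Fv
PDB (ideal-helix CA/CB trace, chains H and L). With `mutation_rate=0` the
query equals the consensus and nothing is planted.

These fixtures reproduce the *logic* of a humanization campaign — germline
divergence, planted liabilities at germline-divergent positions, frequency
structure with a dominant consensus — but not the statistics of real
repertoires (allele structure, CDR length diversity, somatic hypermutation
spectra) nor real Fv geometry. Passing tests therefore demonstrate
correctness of the algorithms and their invariants, not predictive accuracy
on real antibodies.

## Problem sizes

The test suite and the acceptance script run 13 seeded campaigns × 2
chains × 4 strategies (104 humanizations), 1000 seeded sequences for the
sequon-scanner/regex comparison, ≥ 50 positions for the structure-selection
brute-force comparison, and 100 random peptides against a 1e-4 pH-grid
charge scan — sizes chosen so the whole reproduction completes in seconds
while every rate is estimated from ≥ 100 events.

## Known limitations

* Chothia/Martin numbering, constant domains and nucleotide input are out
  of scope; IMGT output is correspondence-based, not gap-exact.
* The contact scorer is a coarse stand-in: it ranks packing plausibility,
  not energies, and no numeric equivalence with any forcefield is claimed.
* Published absolute humanness scores and MHC-II core-peptide counts
  depend on proprietary databases/models and are not reproduced — only
  trend directions are asserted.
* Homology modeling is not included; structure-guided humanization
  requires a user-supplied model (or the toy fixture).
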