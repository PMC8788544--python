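"""The four humanization strategies, exclusions, and the lambda-FR4 swap."""

import pytest

from humab.errors import HumanizationError
from humab.humanize import (
    HumanizeConfig,
    cdr_graft,
    consensus_substitute,
    excluded_positions,
    germline_substitute,
    lambda_fr4_swap,
    structure_guided_substitute,
)
from humab.humanize_types import Method
from humab.numbering import (
    ChainType,
    NumberedSequence,
    Scheme,
    annotate_regions,
    number_sequence,
    vernier_positions,
)
from humab.repertoire import (
    GermlineRecord,
    Locus,
    best_germline,
    position_frequencies,
)
from humab.structure import ContactScorer, NullScorer
from humab.templates import TEMPLATES


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def test_query_identical_to_germline_fully_excluded(vh_records):
    rec = vh_records[0]
    ns = rec.numbered
    excl = excluded_positions(ns, HumanizeConfig(), rec)
    assert set(ns.labels) <= set(excl)  # nothing left to substitute


def test_vernier_excluded_even_when_mismatching_germline(query_vh, vh_records):
    top = best_germline(query_vh, vh_records)
    excl = excluded_positions(query_vh, HumanizeConfig(), top)
    for lab in vernier_positions(ChainType.VH).positions:
        if lab in set(query_vh.labels):
            assert "vernier" in excl[lab]


def test_cdr_h2_excluded_as_kabat_cdr(query_vh):
    excl = excluded_positions(query_vh, HumanizeConfig(), None)
    assert "kabat_cdr" in excl["55"]
    assert "imgt_cdr" in excl["95"]  # IMGT CDR3 reaches 93-102


# ---------------------------------------------------------------------------
# CDR graft
# ---------------------------------------------------------------------------

def test_graft_onto_self_is_identity(query_vh):
    result = cdr_graft(query_vh, query_vh)
    assert result.substitutions == ()
    assert result.output.residues == query_vh.residues


def test_graft_carries_query_cdr3_exactly(query_vh, bundle):
    acceptor = number_sequence(bundle.acceptor_vh, ChainType.VH)
    result = cdr_graft(query_vh, acceptor)
    rm = annotate_regions(query_vh)
    for lab in rm.cdr_labels:
        assert result.output.residue_at(lab) == query_vh.residue_at(lab)


def test_graft_substitution_count_matches_direct_diff(query_vh, bundle):
    """Substitutions = framework/non-Vernier positions where the pair differ."""
    acceptor = number_sequence(bundle.acceptor_vh, ChainType.VH)
    result = cdr_graft(query_vh, acceptor)
    rm = annotate_regions(query_vh)
    protected = set(rm.cdr_labels) | vernier_positions(ChainType.VH).positions
    acc = acceptor.as_dict()
    expected = sum(
        1 for lab, res in query_vh.residues
        if lab not in protected and lab in acc and acc[lab] != res)
    assert len(result.substitutions) == expected
    assert all(s.method is Method.GRAFT for s in result.substitutions)


def test_graft_chain_type_mismatch_rejected(query_vh, query_vl):
    with pytest.raises(HumanizationError):
        cdr_graft(query_vh, query_vl)


# ---------------------------------------------------------------------------
# germline substitution
# ---------------------------------------------------------------------------

def test_germline_substitute_noop_on_matching_query(repertoire, vh_records):
    rec = vh_records[0]
    # extend the V-gene query with a J-gene FR4 so FR4 already matches too
    j = next(r for r in repertoire if r.locus is Locus.IGHJ)
    full = NumberedSequence(
        ChainType.VH, Scheme.KABAT,
        rec.numbered.residues + j.numbered.residues)
    result = germline_substitute(full, repertoire)
    assert result.substitutions == ()


def test_germline_substitute_destroys_planted_sequon(query_vh, repertoire):
    assert query_vh.residue_at("85") == "N"
    result = germline_substitute(query_vh, repertoire)
    assert result.output.residue_at("85") != "N"
    triplet = "".join(
        result.output.residue_at(lab) for lab in ("85", "86", "87"))
    assert not (triplet[0] == "N" and triplet[2] in "ST")


def test_germline_substitute_restores_g41(query_vl, repertoire):
    assert query_vl.residue_at("41") == "N"
    result = germline_substitute(query_vl, repertoire)
    assert result.output.residue_at("41") == "G"


def test_germline_substitute_below_threshold_reports_identity(query_vh,
                                                              vh_records):
    config = HumanizeConfig(identity_threshold=99.0)
    with pytest.raises(HumanizationError, match="%"):
        germline_substitute(query_vh, vh_records, config)


def test_germline_substitute_sets_fr4_from_j_gene(query_vl, repertoire):
    result = germline_substitute(query_vl, repertoire)
    fr4_labels = [lab for lab in result.output.labels
                  if annotate_regions(result.output).region_of(lab).value == "FR4"]
    j_genes = {r.gene_name: r for r in repertoire if r.locus is Locus.IGKJ}
    out = result.output.as_dict()
    vern = vernier_positions(ChainType.VK).positions
    matches_some_j = any(
        all(out[lab] == j.numbered.residue_at(lab)
            for lab in fr4_labels
            if lab not in vern and j.numbered.residue_at(lab) is not None)
        for j in j_genes.values())
    assert matches_some_j


# ---------------------------------------------------------------------------
# consensus substitution
# ---------------------------------------------------------------------------

def test_consensus_noop_when_query_is_consensus(vh_records, vh_pft):
    template_ns = number_sequence(TEMPLATES["VH"].sequence, ChainType.VH)
    v_only = NumberedSequence(
        ChainType.VH, Scheme.KABAT,
        tuple(p for p in template_ns.residues if p[0] in vh_pft.table))
    # the template is the majority residue at every column of the fixture
    result = consensus_substitute(template_ns, vh_pft)
    assert result.substitutions == ()


@pytest.mark.parametrize("query_freq,cons_freq,expect_sub", [
    (0.05, 0.80, True),   # margin 75 pp >= 20
    (0.45, 0.55, False),  # margin 10 pp < 20
])
def test_consensus_margin_rule(vh_template_ns, query_freq, cons_freq,
                               expect_sub):
    """Direct arithmetic on the 20-percentage-point substitution margin."""
    label = "77"  # plain FR3 position: not CDR, not Vernier under either def
    n = 20
    n_cons = int(round(cons_freq * n))
    n_query = int(round(query_freq * n))
    base = list(vh_template_ns.residues)
    idx = vh_template_ns.labels.index(label)
    records = []
    for i in range(n):
        pairs = list(base)
        if i < n_cons:
            pairs[idx] = (label, "K")
        elif i < n_cons + n_query:
            pairs[idx] = (label, "R")
        else:
            pairs[idx] = (label, "Q" if i % 2 else "E")
        records.append(GermlineRecord(
            f"G{i}", Locus.IGHV, "",
            NumberedSequence(ChainType.VH, Scheme.KABAT, tuple(pairs))))
    pft = position_frequencies(records)
    query = vh_template_ns.replaced({label: "R"})
    result = consensus_substitute(query, pft)
    subs_at_label = [s for s in result.substitutions
                     if s.position_label == label]
    if expect_sub:
        assert subs_at_label and subs_at_label[0].to_residue == "K"
    else:
        assert not subs_at_label


# ---------------------------------------------------------------------------
# structure-guided substitution
# ---------------------------------------------------------------------------

def test_null_scorer_selects_highest_frequency_candidate(
        query_vh, fv_model, vh_pft):
    result = structure_guided_substitute(
        query_vh, fv_model, NullScorer(), vh_pft)
    for sub in result.substitutions:
        freqs = vh_pft.frequencies(sub.position_label)
        eligible = {r: f for r, f in freqs.items() if f >= 0.05}
        assert sub.to_residue in eligible
        best = max(eligible.values())
        assert eligible[sub.to_residue] == pytest.approx(best)


def test_structure_selection_equals_bruteforce_argmin(
        query_vh, fv_model, vh_pft, vh_records):
    """Implementation agrees with exhaustive enumeration + tie rules."""
    from humab.structure import map_structure_to_numbering
    from humab.numbering import region_of_label

    scorer = ContactScorer()
    result = structure_guided_substitute(
        query_vh, fv_model, scorer, vh_pft)
    mapping = map_structure_to_numbering(fv_model, query_vh)
    excl = excluded_positions(query_vh, HumanizeConfig(), None)
    chosen = {s.position_label: s.to_residue for s in result.substitutions}
    for lab, res in query_vh.residues:
        if (region_of_label(lab, ChainType.VH).is_cdr or lab in excl
                or lab not in mapping.mapping):
            continue
        cands = {r for r, f in vh_pft.frequencies(lab).items() if f >= 0.05}
        cands.add(res)
        ranked = sorted(
            (scorer.score(mapping, lab, res, c),
             -vh_pft.frequency(lab, c), c)
            for c in cands)
        expected = ranked[0][2]
        assert chosen.get(lab, res) == expected


def test_candidates_below_floor_leave_position_unchanged(
        query_vh, fv_model, vh_records):
    """With every non-query residue under 5% there is nothing to substitute."""
    from humab.repertoire import PositionFrequencyTable
    table = {lab: {res: 0.04 for res in "ACD"} for lab in query_vh.labels}
    pft = PositionFrequencyTable(Scheme.KABAT, ChainType.VH, table)
    result = structure_guided_substitute(
        query_vh, fv_model, ContactScorer(), pft)
    assert result.substitutions == ()


# ---------------------------------------------------------------------------
# lambda FR4 swap
# ---------------------------------------------------------------------------

def test_lambda_fr4_swap_leik_to_ltvl():
    seq = TEMPLATES["VK"].sequence[:-4] + "LEIK"
    ns = number_sequence(seq, ChainType.VK)
    swapped = lambda_fr4_swap(ns)
    assert swapped.sequence.endswith("LTVL")
    assert swapped.sequence[:-4] == seq[:-4]
    changed = sum(a != b for a, b in zip(seq[-4:], "LTVL"))
    assert changed == 3  # "last four residues" touch exactly three on ...LEIK


def test_lambda_fr4_swap_idempotent():
    seq = TEMPLATES["VK"].sequence[:-4] + "LTVL"
    ns = number_sequence(seq, ChainType.VK)
    assert lambda_fr4_swap(ns).sequence == seq


def test_lambda_fr4_swap_rejects_heavy(query_vh):
    with pytest.raises(HumanizationError):
        lambda_fr4_swap(query_vh)


# ---------------------------------------------------------------------------
# cross-strategy invariant
# ---------------------------------------------------------------------------

def test_every_strategy_preserves_cdr_and_vernier(
        bundle, repertoire, vh_pft, fv_model, query_vh, query_vl):
    """The core safety contract: Kabat CDRs and Vernier residues never move."""
    acceptor = number_sequence(bundle.acceptor_vh, ChainType.VH)
    results = [
        cdr_graft(query_vh, acceptor),
        germline_substitute(query_vh, repertoire),
        consensus_substitute(query_vh, vh_pft),
        structure_guided_substitute(
            query_vh, fv_model, ContactScorer(), vh_pft),
    ]
    vern = vernier_positions(ChainType.VH).positions
    for result in results:
        rm = annotate_regions(result.input)
        for lab in set(rm.cdr_labels) | (vern & set(result.input.labels)):
            assert result.output.residue_at(lab) == \
                result.input.residue_at(lab)


def test_substitution_audit_is_exact(query_vh, repertoire):
    result = germline_substitute(query_vh, repertoire)
    diff = {lab for lab in result.input.as_dict()
            if result.input.residue_at(lab) != result.output.residue_at(lab)}
    assert diff == {s.position_label for s in result.substitutions}
    assert all(s.from_residue != s.to_residue for s in result.substitutions)
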