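"""Kabat numbering, region annotation, Vernier sets, framework extraction."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from humab.errors import NumberingError, RegionError, UnnumberableSequenceError
from humab.numbering import (
    ChainType,
    KABAT_CDR_BOUNDS,
    NumberedSequence,
    Region,
    Scheme,
    annotate_regions,
    framework_sequence,
    label_key,
    number_sequence,
    region_of_label,
    vernier_positions,
)
from humab.templates import AMINO_ACIDS, TEMPLATES


@pytest.mark.parametrize("chain_type", list(ChainType))
def test_template_self_numbering_is_identity(chain_type):
    """Numbering a packaged consensus maps each residue to its own label."""
    template = TEMPLATES[chain_type.value]
    ns = number_sequence(template.sequence, chain_type)
    assert ns.labels == template.labels
    assert ns.sequence == template.sequence


def test_cdr3_insertion_gets_insertion_coded_labels():
    """One extra CDR-H3 residue appears as 100A; all other labels unchanged.

    Oracle: hand alignment of the 117-residue query against the 116-column
    template — the single gap sits in CDR-H3, and Kabat places CDR-H3
    insertions after position 100.
    """
    template = TEMPLATES["VH"]
    seq = template.sequence
    cdr3_start = template.labels.index("95")
    inserted = seq[: cdr3_start + 6] + "W" + seq[cdr3_start + 6:]
    ns = number_sequence(inserted, ChainType.VH)
    assert "100A" in ns.labels
    others = [(lab, res) for lab, res in ns.residues if lab != "100A"]
    assert others == list(zip(template.labels, seq))


def test_random_peptide_is_unnumberable():
    rng = random.Random(0)
    peptide = "".join(rng.choice(AMINO_ACIDS) for _ in range(20))
    with pytest.raises(UnnumberableSequenceError) as info:
        number_sequence(peptide, ChainType.VH)
    assert info.value.template_name
    assert info.value.identity < 0.45


def test_unrelated_fv_length_sequence_reports_best_template():
    rng = random.Random(1)
    junk = "".join(rng.choice("AG") for _ in range(110))
    with pytest.raises(UnnumberableSequenceError) as info:
        number_sequence(junk, ChainType.VK)
    assert "identity" in str(info.value)


def test_cterminal_overhang_rejected():
    seq = TEMPLATES["VH"].sequence + "GSGSGS"
    with pytest.raises(NumberingError):
        number_sequence(seq, ChainType.VH)


@pytest.mark.parametrize("chain_type,cdr2_span", [
    (ChainType.VH, ("50", "65")),
    (ChainType.VK, ("50", "56")),
])
def test_kabat_cdr2_run_spans_definition_bounds(chain_type, cdr2_span):
    template = TEMPLATES[chain_type.value]
    ns = number_sequence(template.sequence, chain_type)
    rm = annotate_regions(ns)
    cdr2 = rm.regions[Region.CDR2]
    assert cdr2[0] == cdr2_span[0] and cdr2[-1] == cdr2_span[1]


def test_vl_position_41_is_framework(vk_template_ns):
    """L41 (the NGS-motif asparagine site) lies in FR2, not a CDR."""
    rm = annotate_regions(vk_template_ns)
    assert "41" in rm.regions[Region.FR2]


def test_vh_position_85_is_fr3(vh_template_ns):
    """H85 (the glycosylation-site asparagine) lies in framework 3."""
    rm = annotate_regions(vh_template_ns)
    assert "85" in rm.regions[Region.FR3]


def test_region_map_tiles_all_labels(query_vh, query_vl):
    for ns in (query_vh, query_vl):
        rm = annotate_regions(ns)
        tiled = [lab for reg in
                 (Region.FR1, Region.CDR1, Region.FR2, Region.CDR2,
                  Region.FR3, Region.CDR3, Region.FR4)
                 for lab in rm.regions[reg]]
        assert sorted(tiled, key=label_key) == list(ns.labels)
        assert rm.regions[Region.FR4][-1] == ns.labels[-1]


def test_missing_boundary_labels_raise():
    template = TEMPLATES["VH"]
    pairs = tuple(p for p in template.pairs if p[0] != "103")
    truncated = NumberedSequence(ChainType.VH, Scheme.KABAT, pairs)
    with pytest.raises(RegionError, match="103"):
        annotate_regions(truncated)


@pytest.mark.parametrize("chain_type", list(ChainType))
def test_vernier_disjoint_from_kabat_cdrs_and_stable(chain_type):
    vs = vernier_positions(chain_type)
    assert vs.positions
    for lab in vs.positions:
        assert not region_of_label(lab, chain_type).is_cdr
    assert vernier_positions(chain_type).positions == vs.positions


def test_framework_sequence_drops_exactly_the_cdrs(vh_template_ns):
    rm = annotate_regions(vh_template_ns)
    fw = framework_sequence(vh_template_ns, rm)
    assert len(fw) == len(vh_template_ns) - len(rm.cdr_labels)


def test_framework_independent_of_cdr3_content():
    template = TEMPLATES["VH"]
    seq = template.sequence
    i = template.labels.index("95")
    j = template.labels.index("103")
    variant = seq[:i] + "AAAAAAAA" + seq[j:]
    a = number_sequence(seq, ChainType.VH)
    b = number_sequence(variant, ChainType.VH)
    assert framework_sequence(a) == framework_sequence(b)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_numbering_roundtrip_and_purity_on_mutated_templates(rnd):
    """Mutated Fv-like sequences renumber losslessly and deterministically."""
    chain_type = rnd.choice(list(ChainType))
    seq = list(TEMPLATES[chain_type.value].sequence)
    for _ in range(rnd.randint(0, 12)):
        seq[rnd.randrange(len(seq))] = rnd.choice(AMINO_ACIDS)
    seq = "".join(seq)
    try:
        ns = number_sequence(seq, chain_type)
    except NumberingError:
        return  # heavy mutation may legitimately fall below the floor
    assert ns.sequence == seq
    again = number_sequence(seq, chain_type)
    assert again.residues == ns.residues


def test_imgt_scheme_is_monotone_and_lossless():
    template = TEMPLATES["VH"]
    ns = number_sequence(template.sequence, ChainType.VH, scheme=Scheme.IMGT)
    assert ns.sequence == template.sequence
    keys = [label_key(lab) for lab in ns.labels]
    assert keys == sorted(keys)
    assert ns.labels[0] == "1"


def test_numbered_sequence_rejects_disorder_and_bad_residues():
    with pytest.raises(NumberingError):
        NumberedSequence(ChainType.VH, Scheme.KABAT,
                         (("2", "A"), ("1", "C")))
    with pytest.raises(NumberingError):
        NumberedSequence(ChainType.VH, Scheme.KABAT, (("1", "X"),))
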