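"""T20-style scoring, identity matrices, scFv assembly, epitope counting."""

import random

import numpy as np
import pytest

from humab.errors import HumannessError
from humab.humanness import (
    FixedEpitopeScorer,
    ToyEpitopeScorer,
    build_scfv,
    count_core_epitopes,
    identity_matrix,
    linker_spanning_cores,
    t20_score,
)
from humab.numbering import ChainType, NumberedSequence, Scheme, number_sequence
from humab.templates import AMINO_ACIDS, TEMPLATES


def _db_of(ns, n, mutate_labels=()):
    """n copies of ``ns`` with optional per-entry framework mutations."""
    entries = []
    for i in range(n):
        out = ns
        for lab in mutate_labels:
            res = ns.residue_at(lab)
            out = out.replaced({lab: "A" if res != "A" else "G"})
        entries.append((f"db{i}", out))
    return entries


def test_identical_db_scores_exactly_100(vh_template_ns):
    result = t20_score(vh_template_ns, _db_of(vh_template_ns, 20))
    assert result.score == 100.0
    assert len(result.top_hits) == 20


def test_half_identity_db_scores_50(vh_template_ns):
    """A db where every entry matches exactly half the framework labels."""
    from humab.numbering import annotate_regions
    rm = annotate_regions(vh_template_ns)
    fw = list(rm.framework_labels)
    half = fw[: len(fw) // 2]
    entry = vh_template_ns
    for lab in half:
        res = entry.residue_at(lab)
        entry = entry.replaced({lab: "A" if res != "A" else "G"})
    db = [(f"e{i}", entry) for i in range(20)]
    result = t20_score(vh_template_ns, db)
    expected = 100.0 * (len(fw) - len(half)) / len(fw)
    assert result.score == pytest.approx(expected, abs=1e-9)


def test_only_top_20_of_larger_db_average(vh_template_ns):
    near = _db_of(vh_template_ns, 20)
    far = _db_of(vh_template_ns, 5, mutate_labels=("5", "70", "77"))
    result = t20_score(vh_template_ns, near + far)
    assert result.db_size == 25
    assert result.score == 100.0  # the 5 degraded entries fall outside top 20


def test_small_db_flagged(vh_template_ns):
    result = t20_score(vh_template_ns, _db_of(vh_template_ns, 7))
    assert result.db_smaller_than_20
    assert len(result.top_hits) == 7


def test_t20_invariant_to_db_order_and_monotone(query_vh, vh_records):
    rng = random.Random(5)
    shuffled = list(vh_records)
    rng.shuffle(shuffled)
    assert t20_score(query_vh, shuffled).score == \
        t20_score(query_vh, vh_records).score
    # replacing one entry by the query itself can only raise the score
    better = list(vh_records[:-1]) + [("self", query_vh)]
    assert t20_score(query_vh, better).score >= \
        t20_score(query_vh, vh_records).score


def test_empty_db_rejected(query_vh):
    with pytest.raises(HumannessError):
        t20_score(query_vh, [])


# ---------------------------------------------------------------------------
# identity matrix
# ---------------------------------------------------------------------------

def test_identity_matrix_against_bruteforce_counter(vh_records):
    subset = vh_records[:6]
    mat = identity_matrix(subset)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 100.0)
    for i, a in enumerate(subset):
        for j, b in enumerate(subset):
            if i == j:
                continue
            amap, bmap = a.numbered.as_dict(), b.numbered.as_dict()
            shared = amap.keys() & bmap.keys()
            expected = 100.0 * sum(
                amap[k] == bmap[k] for k in shared) / len(shared)
            assert mat.iloc[i, j] == pytest.approx(expected)


def test_identity_matrix_pair_with_known_differences(vh_template_ns):
    other = vh_template_ns
    labels = vh_template_ns.labels[:10]
    for lab in labels:
        res = other.residue_at(lab)
        other = other.replaced({lab: "A" if res != "A" else "G"})
    mat = identity_matrix([("a", vh_template_ns), ("b", other)])
    expected = 100.0 * (len(vh_template_ns) - 10) / len(vh_template_ns)
    assert mat.loc["a", "b"] == pytest.approx(expected)


def test_identity_matrix_rejects_mixed_chains(query_vh, query_vl):
    with pytest.raises(HumannessError):
        identity_matrix([("h", query_vh), ("l", query_vl)])


# ---------------------------------------------------------------------------
# scFv assembly
# ---------------------------------------------------------------------------

def test_scfv_length_arithmetic(query_vh, query_vl):
    construct = build_scfv(query_vl, query_vh, linker_units=4)
    assert len(construct.sequence) == \
        len(query_vl.sequence) + 20 + len(query_vh.sequence)
    assert construct.orientation == "VL-VH"


def test_scfv_g4s3_linker(query_vh, query_vl):
    construct = build_scfv(query_vl, query_vh, linker_units=3)
    assert construct.linker == "GGGGSGGGGSGGGGS"
    assert construct.sequence == (
        query_vl.sequence + "GGGGS" * 3 + query_vh.sequence)


def test_scfv_rejects_two_heavy_domains(query_vh):
    with pytest.raises(HumannessError):
        build_scfv(query_vh, query_vh)


# ---------------------------------------------------------------------------
# epitope counting
# ---------------------------------------------------------------------------

def test_uniform_rank_50_yields_zero(query_vh):
    scorer = FixedEpitopeScorer({}, default=50.0)
    assert count_core_epitopes(query_vh.sequence, scorer) == 0


def test_three_strong_cores_counted(query_vh):
    seq = query_vh.sequence
    cores = [seq[i:i + 9] for i in (0, 20, 40)]
    assert len(set(cores)) == 3
    scorer = FixedEpitopeScorer({c: 0.1 for c in cores}, default=50.0)
    assert count_core_epitopes(seq, scorer) == 3


def test_duplicate_core_counted_once():
    seq = "A" * 30  # every 9-mer is the same core
    scorer = FixedEpitopeScorer({"A" * 9: 0.1}, default=50.0)
    assert count_core_epitopes(seq, scorer) == 1


def test_count_monotone_in_threshold(query_vh):
    scorer = ToyEpitopeScorer(seed=3)
    seq = query_vh.sequence
    counts = [count_core_epitopes(seq, scorer, pct)
              for pct in (0.05, 0.2, 1.0, 5.0)]
    assert counts == sorted(counts)


def test_short_sequence_rejected():
    with pytest.raises(HumannessError):
        count_core_epitopes("ACDEFGHIK", ToyEpitopeScorer())


def test_linker_spanning_cores_subset_of_total(query_vh, query_vl):
    construct = build_scfv(query_vl, query_vh)
    scorer = ToyEpitopeScorer(seed=1)
    spanning = linker_spanning_cores(construct, scorer, top_pct=5.0)
    total = count_core_epitopes(construct, scorer, top_pct=5.0)
    assert 0 <= spanning <= total
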