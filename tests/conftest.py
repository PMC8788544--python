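"""Shared fixtures: a seeded synthetic campaign bundle and numbered queries."""

from __future__ import annotations

import pytest

from humab.numbering import ChainType, annotate_regions, number_sequence
from humab.repertoire import load_repertoire, position_frequencies
from humab.structure import read_structure
from humab.synthetic import generate_fixtures
from humab.templates import TEMPLATES

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def repertoire(bundle):
    return load_repertoire(bundle.repertoire_fasta)


@pytest.fixture(scope="session")
def vh_records(repertoire):
    return [r for r in repertoire
            if r.chain_type is ChainType.VH and not r.is_j]


@pytest.fixture(scope="session")
def vk_records(repertoire):
    return [r for r in repertoire
            if r.chain_type is ChainType.VK and not r.is_j]


@pytest.fixture(scope="session")
def vh_pft(vh_records):
    return position_frequencies(vh_records)


@pytest.fixture(scope="session")
def query_vh(bundle):
    return number_sequence(bundle.query_vh, ChainType.VH)


@pytest.fixture(scope="session")
def query_vl(bundle):
    return number_sequence(bundle.query_vl, ChainType.VK)


@pytest.fixture(scope="session")
def fv_model(bundle):
    return read_structure(bundle.structure_pdb)


@pytest.fixture(scope="session")
def vh_template_ns():
    return number_sequence(TEMPLATES["VH"].sequence, ChainType.VH)


@pytest.fixture(scope="session")
def vk_template_ns():
    return number_sequence(TEMPLATES["VK"].sequence, ChainType.VK)
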