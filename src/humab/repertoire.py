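"""Human germline repertoires: loading, position frequencies, ranking.

A repertoire is a list of :class:`GermlineRecord` (V or J genes, amino-acid
level, numbered on load).  Frequencies are unweighted per gene — each
germline counts once, the reproducible gene-level convention — and identity
denominators are the framework labels shared by both sequences, so length
variation at insertion slots is never penalised.
"""

from __future__ import annotations

import csv
import enum
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

from .errors import NumberingError, RepertoireError
from .io import read_fasta
from .numbering import (
    ChainType,
    NumberedSequence,
    Region,
    Scheme,
    number_j_segment,
    number_sequence,
    region_of_label,
)
from .templates import AMINO_ACIDS

logger = logging.getLogger(__name__)


class Locus(str, enum.Enum):
    IGHV = "IGHV"
    IGKV = "IGKV"
    IGLV = "IGLV"
    IGHJ = "IGHJ"
    IGKJ = "IGKJ"
    IGLJ = "IGLJ"

    @property
    def chain_type(self) -> ChainType:
        return {
            "IGH": ChainType.VH,
            "IGK": ChainType.VK,
            "IGL": ChainType.VL_LAMBDA,
        }[self.value[:3]]

    @property
    def is_j(self) -> bool:
        return self.value.endswith("J")


@dataclass(frozen=True)
class GermlineRecord:
    gene_name: str
    locus: Locus
    sequence: str
    numbered: NumberedSequence

    @property
    def chain_type(self) -> ChainType:
        return self.locus.chain_type

    @property
    def is_j(self) -> bool:
        return self.locus.is_j


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Per-position residue frequencies over a germline repertoire."""

    scheme: Scheme
    chain_type: ChainType
    table: Mapping[str, Mapping[str, float]]

    def frequencies(self, label: str) -> Mapping[str, float]:
        return self.table.get(label, {})

    def frequency(self, label: str, residue: str) -> float:
        return self.table.get(label, {}).get(residue, 0.0)

    def __contains__(self, label: str) -> bool:
        return label in self.table

    def to_jsonable(self) -> Dict:
        return {
            "scheme": self.scheme.value,
            "chain_type": self.chain_type.value,
            "table": {lab: dict(freqs) for lab, freqs in self.table.items()},
        }


class ConsensusCall(NamedTuple):
    residue: str
    tied: bool


def _looks_like_nucleotide(seq: str) -> bool:
    letters = set(seq.upper())
    return bool(letters) and letters <= set("ACGTUN")


def _read_metadata(metadata) -> Optional[Dict[str, str]]:
    """Sidecar locus metadata: mapping, or TSV path with gene/locus columns."""
    if metadata is None:
        return None
    if isinstance(metadata, Mapping):
        return dict(metadata)
    table: Dict[str, str] = {}
    with open(metadata, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            table[row["gene"]] = row["locus"]
    return table


def load_repertoire(fasta_path, metadata=None) -> List[GermlineRecord]:
    """Load and number an amino-acid germline repertoire from FASTA.

    Locus is taken from ``>gene|locus`` headers or from the sidecar
    ``metadata`` (mapping or TSV with ``gene``/``locus`` columns).  Records
    that fail numbering (or look like nucleotide sequences) are skipped with
    a logged warning; an empty file or a fully failed load is an error.
    """
    entries = read_fasta(fasta_path)
    if not entries:
        raise RepertoireError(f"empty repertoire FASTA: {fasta_path}")
    sidecar = _read_metadata(metadata)
    records: List[GermlineRecord] = []
    skipped = 0
    for header, seq in entries:
        name = header.split()[0]
        if "|" in name:
            gene, locus_str = name.split("|", 1)
        elif sidecar and name in sidecar:
            gene, locus_str = name, sidecar[name]
        else:
            logger.warning("no locus metadata for %r; record skipped", name)
            skipped += 1
            continue
        try:
            locus = Locus(locus_str.strip())
        except ValueError:
            logger.warning("unknown locus %r for %r; record skipped",
                           locus_str, gene)
            skipped += 1
            continue
        if _looks_like_nucleotide(seq):
            logger.warning(
                "record %r looks like a nucleotide sequence; skipped", gene)
            skipped += 1
            continue
        try:
            if locus.is_j:
                numbered = number_j_segment(seq, locus.chain_type)
            else:
                numbered = number_sequence(seq, locus.chain_type)
        except NumberingError as exc:
            logger.warning("record %r failed numbering (%s); skipped",
                           gene, exc)
            skipped += 1
            continue
        records.append(GermlineRecord(gene, locus, seq, numbered))
    if skipped:
        logger.info("repertoire load: %d record(s) skipped, %d kept",
                    skipped, len(records))
    if not records:
        raise RepertoireError(
            f"all {len(entries)} repertoire records failed to load")
    return records


def position_frequencies(
        records: Sequence[GermlineRecord]) -> PositionFrequencyTable:
    """Unweighted per-position residue frequencies over V-gene records."""
    if not records:
        raise RepertoireError("cannot build frequencies from zero records")
    chain_types = {r.chain_type for r in records}
    if len(chain_types) > 1:
        raise RepertoireError(
            f"mixed chain types in frequency input: "
            f"{sorted(c.value for c in chain_types)}")
    schemes = {r.numbered.scheme for r in records}
    if len(schemes) > 1:
        raise RepertoireError("mixed numbering schemes in frequency input")
    counts: Dict[str, Counter] = {}
    for rec in records:
        for lab, res in rec.numbered.residues:
            counts.setdefault(lab, Counter())[res] += 1
    table = {
        lab: {res: n / sum(ctr.values()) for res, n in sorted(ctr.items())}
        for lab, ctr in counts.items()
    }
    return PositionFrequencyTable(schemes.pop(), chain_types.pop(), table)


def consensus_residue(pft: PositionFrequencyTable,
                      position_label: str) -> ConsensusCall:
    """Argmax-frequency residue at a label; ties break by alphabet order."""
    freqs = pft.table.get(position_label)
    if not freqs:
        raise RepertoireError(
            f"position {position_label!r} absent from frequency table")
    best = max(freqs.values())
    winners = sorted(res for res, f in freqs.items() if f == best)
    return ConsensusCall(residue=winners[0], tied=len(winners) > 1)


def _framework_positions(ns: NumberedSequence) -> Dict[str, str]:
    return {
        lab: res for lab, res in ns.residues
        if not region_of_label(lab, ns.chain_type).is_cdr
    }


def rank_germlines(query, records: Sequence[GermlineRecord],
                   ) -> List[Tuple[str, float]]:
    """Rank V-gene records by framework percent identity to the query.

    ``query`` is a Kabat :class:`NumberedSequence` (or a raw string, numbered
    using the chain type of the records).  Identity is counted position-wise
    over framework labels present in both sequences; descending order with a
    stable alphabetical tie-break on gene name.
    """
    v_records = [r for r in records if not r.is_j]
    if not v_records:
        raise RepertoireError("no V-gene records to rank")
    if isinstance(query, str):
        query = number_sequence(query, v_records[0].chain_type)
    qfr = _framework_positions(query)
    ranked = []
    any_shared = False
    for rec in v_records:
        gfr = _framework_positions(rec.numbered)
        shared = qfr.keys() & gfr.keys()
        if not shared:
            continue
        any_shared = True
        matches = sum(1 for lab in shared if qfr[lab] == gfr[lab])
        ranked.append((rec.gene_name, 100.0 * matches / len(shared)))
    if not any_shared:
        raise RepertoireError(
            "no germline record shares a framework label with the query")
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def best_germline(query, records: Sequence[GermlineRecord]) -> GermlineRecord:
    """The top-ranked V-gene record for a query."""
    name, _ = rank_germlines(query, records)[0]
    by_name = {r.gene_name: r for r in records if not r.is_j}
    return by_name[name]
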