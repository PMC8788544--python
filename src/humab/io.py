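"""FASTA / TSV / JSON helpers shared across the toolkit."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .numbering import NumberedSequence, RegionMap


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file as ``[(full_header, sequence), ...]``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        records.append((header, str(rec.seq).upper()))
    return records


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_numbering_tsv(path, ns: NumberedSequence, rm: RegionMap) -> None:
    """Per-position numbering table: label, residue, region."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["label", "residue", "region"])
        for lab, res in ns.residues:
            writer.writerow([lab, res, rm.region_of(lab).value])
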