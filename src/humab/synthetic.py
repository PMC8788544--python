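"""Seeded synthetic fixtures: germline repertoires, mouse-like queries, toy Fv.

The generator emulates the study conditions of a humanization campaign
without any external download: a human germline V/J repertoire (perturbed
copies of the packaged consensus templates), a "mouse" query derived from
the consensus by seeded framework/CDR mutations carrying the classic
liability layout — an occupied-style NDT sequon at Kabat H85 and an NG
deamidation motif at L41, both at positions where every germline carries a
different residue — and a toy Fv coordinate model (ideal-helix CA/CB trace)
for structure-guided selection.  Identical seeds produce byte-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io import write_fasta
from .numbering import ChainType, label_key, region_of_label
from .templates import AMINO_ACIDS, TEMPLATES

# residues never used as mutation targets: no new Asn (would seed sequons),
# no Cys (unpaired thiols), no Pro (framework breakers)
_FORBIDDEN_TARGETS = set("NCP")

# liability-critical columns: never perturbed in germlines, so germline
# substitution is always able to remove the planted motifs
_PROTECTED_COLUMNS = {
    ChainType.VH: {"85", "86", "87"},
    ChainType.VK: {"41", "42", "43"},
    ChainType.VL_LAMBDA: set(),
}

_V_LOCUS = {ChainType.VH: "IGHV", ChainType.VK: "IGKV",
            ChainType.VL_LAMBDA: "IGLV"}

_J_GENES: Dict[str, List[Tuple[str, str]]] = {
    "IGHJ": [("IGHJ1-SYN", "WGQGTLVTVSS"), ("IGHJ2-SYN", "WGRGTLVTVSS"),
             ("IGHJ3-SYN", "WGQGTMVTVSS"), ("IGHJ4-SYN", "WGQGTTVTVSS")],
    "IGKJ": [("IGKJ1-SYN", "FGQGTKVEIK"), ("IGKJ2-SYN", "FGGGTKVEIK"),
             ("IGKJ3-SYN", "FGQGTRLEIK"), ("IGKJ4-SYN", "FGPGTKVDIK"),
             ("IGKJ5-SYN", "FGQGTKLEIK")],
    "IGLJ": [("IGLJ1-SYN", "FGGGTKLTVL"), ("IGLJ2-SYN", "FGTGTKVTVL"),
             ("IGLJ3-SYN", "FGGGTQLTVL")],
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class FixtureBundle:
    out_dir: Path
    repertoire_fasta: Path
    query_fasta: Path
    acceptor_fasta: Path
    structure_pdb: Path
    query_vh: str
    query_vl: str
    acceptor_vh: str
    acceptor_vl: str


def _v_gene_pairs(chain_type: ChainType) -> List[Tuple[str, str]]:
    """Template columns spanning FR1..CDR3 (V gene, FR4 excluded)."""
    template = TEMPLATES[chain_type.value]
    return [(lab, res) for lab, res in template.pairs
            if region_of_label(lab, chain_type).value != "FR4"]


def _framework_columns(chain_type: ChainType,
                       pairs: Sequence[Tuple[str, str]]) -> List[int]:
    return [i for i, (lab, _) in enumerate(pairs)
            if not region_of_label(lab, chain_type).is_cdr]


def _perturb(rng: np.random.Generator, chain_type: ChainType,
             pairs: List[Tuple[str, str]], n_sites: int) -> str:
    """A germline variant: the consensus with a few framework changes."""
    protected = _PROTECTED_COLUMNS[chain_type]
    eligible = [i for i in _framework_columns(chain_type, pairs)
                if pairs[i][0] not in protected]
    sites = rng.choice(len(eligible), size=n_sites, replace=False)
    seq = [res for _, res in pairs]
    for s in sorted(sites):
        i = eligible[s]
        current = seq[i]
        options = [a for a in AMINO_ACIDS
                   if a != current and a not in _FORBIDDEN_TARGETS]
        seq[i] = options[int(rng.integers(len(options)))]
    return "".join(seq)


def _make_repertoire(rng: np.random.Generator, chain_type: ChainType,
                     n_germlines: int) -> List[Tuple[str, str]]:
    pairs = _v_gene_pairs(chain_type)
    locus = _V_LOCUS[chain_type]
    records = []
    for g in range(n_germlines):
        n_sites = int(rng.integers(2, 5))
        seq = _perturb(rng, chain_type, pairs, n_sites)
        records.append((f"{locus}{g + 1}-SYN|{locus}", seq))
    return records


def _mutate_query(rng: np.random.Generator, chain_type: ChainType,
                  mutation_rate: float,
                  column_residues: Dict[str, set]) -> str:
    """The mouse-like query: consensus + seeded mutations + planted motifs."""
    template = TEMPLATES[chain_type.value]
    pairs = list(template.pairs)
    seq = [res for _, res in pairs]
    labels = [lab for lab, _ in pairs]
    if mutation_rate > 0:
        fr_cols = _framework_columns(chain_type, pairs)
        protected = _PROTECTED_COLUMNS[chain_type]
        eligible = [i for i in fr_cols
                    if labels[i] not in protected and i > 0]
        n_mut = int(round(mutation_rate * len(fr_cols)))
        chosen = rng.choice(len(eligible), size=min(n_mut, len(eligible)),
                            replace=False)
        for s in sorted(chosen):
            i = eligible[s]
            lab = labels[i]
            seen = column_residues.get(lab, set())
            options = [
                a for a in AMINO_ACIDS
                if a != seq[i] and a not in _FORBIDDEN_TARGETS
                and a not in seen
                and not (a in "ST" and i >= 2 and seq[i - 2] == "N")
                and not (a == "G" and i >= 1 and seq[i - 1] == "N")
            ]
            if options:
                seq[i] = options[int(rng.integers(len(options)))]
        # a couple of CDR changes so the graft actually carries mouse loops
        cdr_cols = [i for i in range(len(pairs))
                    if region_of_label(labels[i], chain_type).is_cdr]
        for s in rng.choice(len(cdr_cols), size=3, replace=False):
            i = cdr_cols[int(s)]
            options = [a for a in AMINO_ACIDS
                       if a != seq[i] and a not in _FORBIDDEN_TARGETS]
            seq[i] = options[int(rng.integers(len(options)))]
        # planted liabilities (the classic layout: NDT at H85, NG at L41)
        index_of = {lab: i for i, lab in enumerate(labels)}
        if chain_type is ChainType.VH:
            seq[index_of["85"]] = "N"   # template D86/T87 complete the sequon
        elif chain_type is ChainType.VK:
            seq[index_of["41"]] = "N"
            seq[index_of["42"]] = "G"
    return "".join(seq)


def _helix_coords(n: int, x_offset: float) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Ideal-helix CA trace with radially displaced CB pseudo-atoms."""
    coords = []
    for i in range(n):
        angle = np.deg2rad(100.0 * i)
        z = 1.5 * i
        ca = np.array([x_offset + 2.3 * np.cos(angle),
                       2.3 * np.sin(angle), z])
        cb = np.array([x_offset + 3.8 * np.cos(angle),
                       3.8 * np.sin(angle), z])
        coords.append((ca, cb))
    return coords


def _write_toy_pdb(path: Path, chains: Sequence[Tuple[str, str]]) -> None:
    """Write CA/CB-only ATOM records for each (chain_id, sequence)."""
    lines = []
    serial = 1
    for offset_idx, (chain_id, seq) in enumerate(chains):
        coords = _helix_coords(len(seq), x_offset=40.0 * offset_idx)
        for i, aa in enumerate(seq):
            resname = _ONE_TO_THREE[aa]
            ca, cb = coords[i]
            for atom_name, pos in (("CA", ca), ("CB", cb)):
                if atom_name == "CB" and aa == "G":
                    continue
                lines.append(
                    f"ATOM  {serial:5d}  {atom_name:<3s}{resname:>4s} "
                    f"{chain_id}{i + 1:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"  1.00  0.00           C")
                serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def generate_fixtures(out_dir, seed: int = 0, n_germlines: int = 12,
                      mutation_rate: float = 0.1) -> FixtureBundle:
    """Write a complete seeded fixture bundle into ``out_dir``.

    Contents: a synthetic germline repertoire (V genes FR1-CDR3, J genes
    FR4) for all three loci, a mouse-like VH/VK query pair with planted
    liabilities, a human acceptor framework pair (the consensus templates),
    and a toy Fv PDB built from the query sequences.  With
    ``mutation_rate=0`` the query equals the consensus and no liabilities
    are planted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    repertoire: List[Tuple[str, str]] = []
    column_residues: Dict[ChainType, Dict[str, set]] = {}
    for chain_type in (ChainType.VH, ChainType.VK, ChainType.VL_LAMBDA):
        v_recs = _make_repertoire(rng, chain_type, n_germlines)
        repertoire.extend(v_recs)
        cols: Dict[str, set] = {}
        labels = [lab for lab, _ in _v_gene_pairs(chain_type)]
        for _, seq in v_recs:
            for lab, res in zip(labels, seq):
                cols.setdefault(lab, set()).add(res)
        column_residues[chain_type] = cols
    for locus, genes in _J_GENES.items():
        repertoire.extend(
            (f"{name}|{locus}", seq) for name, seq in genes)
        chain_type = {"IGHJ": ChainType.VH, "IGKJ": ChainType.VK,
                      "IGLJ": ChainType.VL_LAMBDA}[locus]
        fr4_labels = TEMPLATES[chain_type.value].labels
        for _, seq in genes:
            for lab, res in zip(fr4_labels[-len(seq):], seq):
                column_residues[chain_type].setdefault(lab, set()).add(res)

    query_vh = _mutate_query(rng, ChainType.VH, mutation_rate,
                             column_residues[ChainType.VH])
    query_vl = _mutate_query(rng, ChainType.VK, mutation_rate,
                             column_residues[ChainType.VK])
    acceptor_vh = TEMPLATES["VH"].sequence
    acceptor_vl = TEMPLATES["VK"].sequence

    repertoire_fasta = out_dir / "germline_repertoire.synthetic.fasta"
    query_fasta = out_dir / "query.synthetic.fasta"
    acceptor_fasta = out_dir / "acceptor.synthetic.fasta"
    structure_pdb = out_dir / "query_fv.synthetic.pdb"

    write_fasta(repertoire_fasta, repertoire)
    write_fasta(query_fasta,
                [("query_VH", query_vh), ("query_VL", query_vl)])
    write_fasta(acceptor_fasta,
                [("acceptor_VH", acceptor_vh), ("acceptor_VL", acceptor_vl)])
    _write_toy_pdb(structure_pdb, [("H", query_vh), ("L", query_vl)])

    return FixtureBundle(
        out_dir=out_dir,
        repertoire_fasta=repertoire_fasta,
        query_fasta=query_fasta,
        acceptor_fasta=acceptor_fasta,
        structure_pdb=structure_pdb,
        query_vh=query_vh,
        query_vl=query_vl,
        acceptor_vh=acceptor_vh,
        acceptor_vl=acceptor_vl,
    )
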