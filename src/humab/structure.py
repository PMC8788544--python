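"""Minimal Fv structure handling for structure-guided humanization.

Reads CA/CB coordinates from PDB files, maps model residues onto Kabat
numbering by sequence alignment (author numbering in the file is never
trusted), and provides the default contact-based mutation scorer: a coarse
three-class (hydrophobic / polar / charged) pairwise contact potential
summed over CB-CB neighbors within 8 Angstrom.  The scorer is an explicitly
documented stand-in for forcefield mutation energies and satisfies the
:class:`MutationScorer` contract — ``score(x -> x) = 0``, lower = predicted
more stable — so a forcefield-backed scorer can be plugged in by name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Protocol, Sequence, Tuple

import gemmi
import numpy as np

from .errors import StructureError
from .numbering import NumberedSequence, label_key
from .templates import AMINO_ACIDS

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class StructureResidue:
    chain_id: str
    seq_id: str           # author residue number + insertion code
    residue_name: str     # three-letter
    one_letter: str
    ca: np.ndarray
    cb: np.ndarray        # CA for glycine / missing CB

    def __post_init__(self):
        for coords in (self.ca, self.cb):
            if not np.all(np.isfinite(coords)):
                raise StructureError(
                    f"non-finite coordinates at {self.chain_id}{self.seq_id}")


@dataclass(frozen=True)
class StructureModel:
    """Per-chain ordered residue lists with resolved CA/CB coordinates."""

    chains: Mapping[str, Tuple[StructureResidue, ...]]

    def __post_init__(self):
        if not self.chains:
            raise StructureError("structure model has no chains")

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    @property
    def residues(self) -> List[StructureResidue]:
        return [r for chain in self.chains.values() for r in chain]


def _pick_atom(residue: "gemmi.Residue", name: str):
    """First atom with the given name, altloc '' preferred, then 'A'."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if atom.altloc in ("", "\x00"):
            return atom
        if atom.altloc == "A" and best is None:
            best = atom
        best = best or atom
    return best


def read_structure(pdb_path, chain_selection: Optional[Sequence[str]] = None,
                   ) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    One entry per polymer residue with a resolved CA; CB falls back to CA
    for glycine (or when CB is missing).  Altloc A is preferred; insertion
    codes are preserved in ``seq_id``.
    """
    st = gemmi.read_structure(str(pdb_path))
    if len(st) == 0:
        raise StructureError(f"no models in {pdb_path}")
    model = st[0]
    available = [ch.name for ch in model]
    wanted = list(chain_selection) if chain_selection else available
    missing = [c for c in wanted if c not in available]
    if missing:
        raise StructureError(
            f"chain(s) {missing} not present in {pdb_path}; "
            f"available: {available}")
    chains: Dict[str, Tuple[StructureResidue, ...]] = {}
    for chain in model:
        if chain.name not in wanted:
            continue
        entries = []
        for residue in chain:
            one = THREE_TO_ONE.get(residue.name)
            if one is None:
                continue  # waters, hetero groups
            ca = _pick_atom(residue, "CA")
            if ca is None:
                continue
            cb = _pick_atom(residue, "CB")
            ca_pos = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
            cb_pos = (np.array([cb.pos.x, cb.pos.y, cb.pos.z])
                      if cb is not None and residue.name != "GLY"
                      else ca_pos)
            icode = residue.seqid.icode.strip()
            entries.append(StructureResidue(
                chain_id=chain.name,
                seq_id=f"{residue.seqid.num}{icode}",
                residue_name=residue.name,
                one_letter=one,
                ca=ca_pos,
                cb=cb_pos,
            ))
        if not entries:
            raise StructureError(
                f"chain {chain.name} has no residues with CA atoms")
        chains[chain.name] = tuple(entries)
    return StructureModel(chains)


# ---------------------------------------------------------------------------
# mapping model residues onto Kabat numbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureMapping:
    """One-to-one label -> model-residue map plus the model context."""

    model: StructureModel
    chain_id: str
    mapping: Mapping[str, StructureResidue]
    unmapped_labels: Tuple[str, ...]
    #: index of each mapped residue within its chain (for adjacency rules)
    chain_index: Mapping[str, int]


def map_structure_to_numbering(model: StructureModel, ns: NumberedSequence,
                               chain_id: Optional[str] = None,
                               min_identity: float = 0.90,
                               ) -> StructureMapping:
    """Align a model chain to a numbered sequence, label by label.

    The chain is chosen automatically (best identity) unless given.  The
    mapping is alignment-based and requires >= ``min_identity`` over aligned
    residues; labels with no model residue are reported in
    ``unmapped_labels``.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"

    candidates = [chain_id] if chain_id else sorted(model.chains)
    best = None
    for cid in candidates:
        if cid not in model.chains:
            raise StructureError(f"chain {cid!r} not in model")
        chain_seq = model.chain_sequence(cid)
        alignment = aligner.align(ns.sequence, chain_seq)[0]
        matches = aligned = 0
        pairs = []
        for (a0, a1), (b0, b1) in zip(*alignment.aligned):
            for off in range(a1 - a0):
                ai, bi = a0 + off, b0 + off
                aligned += 1
                pairs.append((ai, bi))
                if ns.sequence[ai] == chain_seq[bi]:
                    matches += 1
        identity = matches / aligned if aligned else 0.0
        if best is None or identity > best[0]:
            best = (identity, cid, pairs)
    identity, cid, pairs = best
    if identity < min_identity:
        raise StructureError(
            f"best chain {cid!r} aligns at {identity:.1%} identity, below "
            f"the {min_identity:.0%} floor; model does not match sequence")
    chain = model.chains[cid]
    mapping = {}
    chain_index = {}
    for ai, bi in pairs:
        lab = ns.residues[ai][0]
        mapping[lab] = chain[bi]
        chain_index[lab] = bi
    unmapped = tuple(lab for lab in ns.labels if lab not in mapping)
    return StructureMapping(model=model, chain_id=cid, mapping=mapping,
                            unmapped_labels=unmapped,
                            chain_index=chain_index)


# ---------------------------------------------------------------------------
# contact scorer
# ---------------------------------------------------------------------------

def _load_potential() -> Dict:
    with resources.files("humab.data").joinpath(
            "contact_potential.json").open() as handle:
        return json.load(handle)


_POTENTIAL = _load_potential()
_CLASS_OF = {aa: cls for cls, members in _POTENTIAL["classes"].items()
             for aa in members}


def residue_class(residue: str) -> str:
    try:
        return _CLASS_OF[residue]
    except KeyError as exc:
        raise StructureError(f"no contact class for residue {residue!r}") from exc


def _pair_potential(a: str, b: str) -> float:
    ca, cb = residue_class(a), residue_class(b)
    table = _POTENTIAL["pair_potential"]
    return table.get(ca + cb, table.get(cb + ca))


class MutationScorer(Protocol):
    """Scoring contract for structure-guided residue selection.

    ``score`` is dimensionless, deterministic, lower = predicted more
    stable, and must return exactly 0 for a null mutation.
    """

    def score(self, mapping: StructureMapping, position_label: str,
              from_residue: str, to_residue: str) -> float:
        ...


@dataclass(frozen=True)
class ContactScorer:
    """Default coarse contact-potential scorer (packaged constants).

    Neighbors are residues with CB-CB distance <= cutoff, excluding the
    position itself and its sequence-adjacent +-1 residues in the same
    chain; positions with too few neighbors are treated as solvent-exposed
    and score 0 for every mutation.
    """

    cutoff: float = _POTENTIAL["cb_contact_cutoff_angstrom"]
    min_neighbors: int = _POTENTIAL["min_neighbors_for_scoring"]

    def neighbors(self, mapping: StructureMapping,
                  position_label: str) -> List[StructureResidue]:
        if position_label not in mapping.mapping:
            raise StructureError(
                f"position {position_label} not mapped to the structure")
        center = mapping.mapping[position_label]
        center_idx = mapping.chain_index[position_label]
        found = []
        for cid, chain in mapping.model.chains.items():
            for idx, other in enumerate(chain):
                if cid == center.chain_id and abs(idx - center_idx) <= 1:
                    continue  # self and sequence-adjacent +-1
                if np.linalg.norm(other.cb - center.cb) <= self.cutoff:
                    found.append(other)
        return found

    def score(self, mapping: StructureMapping, position_label: str,
              from_residue: str, to_residue: str) -> float:
        if from_residue == to_residue:
            return 0.0
        nbrs = self.neighbors(mapping, position_label)
        if len(nbrs) < self.min_neighbors:
            return 0.0
        return sum(
            _pair_potential(to_residue, n.one_letter)
            - _pair_potential(from_residue, n.one_letter)
            for n in nbrs)


@dataclass(frozen=True)
class NullScorer:
    """Scores every mutation 0; selection then falls to frequency ties."""

    def score(self, mapping, position_label, from_residue, to_residue) -> float:
        return 0.0


SCORERS = {"contact": ContactScorer, "null": NullScorer}


def get_scorer(name: str, **kwargs) -> MutationScorer:
    try:
        return SCORERS[name](**kwargs)
    except KeyError as exc:
        raise StructureError(
            f"unknown scorer {name!r}; registered: {sorted(SCORERS)}") from exc


def contact_score(mapping: StructureMapping, position_label: str,
                  from_residue: str, to_residue: str,
                  cutoff: float = None, min_neighbors: int = None) -> float:
    """Functional form of :class:`ContactScorer` for one-off scoring."""
    kwargs = {}
    if cutoff is not None:
        kwargs["cutoff"] = cutoff
    if min_neighbors is not None:
        kwargs["min_neighbors"] = min_neighbors
    return ContactScorer(**kwargs).score(
        mapping, position_label, from_residue, to_residue)
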