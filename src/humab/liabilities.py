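"""Sequence-liability detection and charge calculations.

Covers the post-translational-modification motifs that matter for antibody
developability — N-glycosylation sequons (N-X-S/T, X != P) and deamidation
dipeptides (NG primary, NS secondary) — plus the design of aglycosylating
point mutations and a ProtParam-convention theoretical isoelectric point
(Bjellqvist pKa set, per-chain termini, bisection on net charge).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import LiabilityError
from .humanize_types import SubstitutionRecord
from .numbering import NumberedSequence, Region, RegionMap, annotate_regions
from .templates import AMINO_ACIDS


class LiabilityKind(str, enum.Enum):
    N_GLYC_SEQUON = "n_glyc_sequon"
    DEAMIDATION = "deamidation"


@dataclass(frozen=True)
class LiabilityHit:
    kind: LiabilityKind
    start_label: str
    motif: str
    region: str  # FR/CDR tag, e.g. "FR3"
    severity: str = "primary"

    @property
    def key(self) -> Tuple[str, str]:
        """Identity of the site for before/after comparison."""
        return (self.kind.value, self.start_label)


def scan_nglyc(ns: NumberedSequence,
               rm: Optional[RegionMap] = None) -> List[LiabilityHit]:
    """Every N-X-[S/T] sequon with X != P (standard sequon rule)."""
    if rm is None:
        rm = annotate_regions(ns)
    hits = []
    residues = ns.residues
    for i in range(len(residues) - 2):
        lab, res = residues[i]
        x = residues[i + 1][1]
        third = residues[i + 2][1]
        if res == "N" and x != "P" and third in "ST":
            hits.append(LiabilityHit(
                kind=LiabilityKind.N_GLYC_SEQUON,
                start_label=lab,
                motif=res + x + third,
                region=rm.region_of(lab).value,
            ))
    return hits


def scan_deamidation(ns: NumberedSequence,
                     rm: Optional[RegionMap] = None) -> List[LiabilityHit]:
    """NG (primary) and NS (secondary, lower severity) deamidation motifs."""
    if rm is None:
        rm = annotate_regions(ns)
    hits = []
    residues = ns.residues
    for i in range(len(residues) - 1):
        lab, res = residues[i]
        nxt = residues[i + 1][1]
        if res == "N" and nxt in "GS":
            hits.append(LiabilityHit(
                kind=LiabilityKind.DEAMIDATION,
                start_label=lab,
                motif=res + nxt,
                region=rm.region_of(lab).value,
                severity="primary" if nxt == "G" else "secondary",
            ))
    return hits


def design_aglyco_mutation(
        ns: NumberedSequence,
        hit: LiabilityHit,
        pft=None,
        allowed_residues: Sequence[str] = ("E", "A", "D", "Q"),
) -> SubstitutionRecord:
    """Propose a sequon-destroying substitution of the glycosylated Asn.

    The replacement is the first residue of ``allowed_residues`` that is also
    observed in the germline frequency table at that position (so the fix is
    itself human-like); with no table evidence the fallback is E, the classic
    aglycosylating choice.
    """
    if hit.kind is not LiabilityKind.N_GLYC_SEQUON:
        raise LiabilityError(
            f"aglycosylation design requires a sequon hit, got {hit.kind.value}")
    if ns.residue_at(hit.start_label) != "N":
        raise LiabilityError(
            f"no Asn at {hit.start_label}; sequence/hit mismatch")
    chosen = None
    if pft is not None:
        for candidate in allowed_residues:
            if pft.frequency(hit.start_label, candidate) > 0:
                chosen = candidate
                break
    if chosen is None:
        chosen = "E"
    return SubstitutionRecord(
        position_label=hit.start_label,
        from_residue="N",
        to_residue=chosen,
        method="aglyco",
        rationale=f"destroys {hit.motif} sequon at {hit.start_label}"
                  + ("" if pft is None else "; germline-supported residue"),
    )


# ---------------------------------------------------------------------------
# theoretical pI (ProtParam convention)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSet:
    """Chains of a molecule with copy numbers; termini count per chain copy."""

    chains: Tuple[Tuple[str, int], ...]

    def __post_init__(self):
        if not self.chains:
            raise LiabilityError("ChainSet requires at least one chain")
        for seq, copies in self.chains:
            if not seq:
                raise LiabilityError("empty chain in ChainSet")
            if copies < 1:
                raise LiabilityError("chain copy number must be positive")
            bad = sorted(set(seq) - set(AMINO_ACIDS))
            if bad:
                raise LiabilityError(f"non-standard residues in chain: {bad}")


def _load_pka() -> Dict:
    with resources.files("humab.data").joinpath(
            "pka_bjellqvist.json").open() as handle:
        return json.load(handle)


_PKA = _load_pka()


def net_charge(chains: ChainSet, pH: float) -> float:
    """Net charge at a pH from composition + per-chain-copy termini."""
    nterm = _PKA["n_terminus"]
    pos = _PKA["positive_side_chains"]
    neg = _PKA["negative_side_chains"]
    cterm = _PKA["c_terminus"]
    z = 0.0
    for seq, copies in chains.chains:
        pk_n = nterm.get(seq[0], nterm["default"])
        z += copies / (1.0 + 10.0 ** (pH - pk_n))
        z -= copies / (1.0 + 10.0 ** (cterm - pH))
        for aa in seq:
            if aa in pos:
                z += copies / (1.0 + 10.0 ** (pH - pos[aa]))
            elif aa in neg:
                z -= copies / (1.0 + 10.0 ** (neg[aa] - pH))
    return z


def theoretical_pi(chains: Union[ChainSet, str, Sequence[Tuple[str, int]]],
                   tolerance: float = 1e-4) -> float:
    """Theoretical pI in the Expasy ProtParam convention, to 2 decimals.

    Bjellqvist pKa set (D, E, C, Y, H, K, R side chains plus per-chain
    N/C termini; cysteines counted as ionizable), bisection on the net
    charge until ``|Z| < tolerance``.
    """
    if isinstance(chains, str):
        chains = ChainSet(((chains, 1),))
    elif not isinstance(chains, ChainSet):
        chains = ChainSet(tuple(chains))
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        z = net_charge(chains, mid)
        if abs(z) < tolerance:
            break
        if z > 0:
            lo = mid
        else:
            hi = mid
    return round(mid, 2)


# ---------------------------------------------------------------------------
# before/after comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiabilityComparison:
    removed: Tuple[LiabilityHit, ...]
    introduced: Tuple[LiabilityHit, ...]
    retained: Tuple[LiabilityHit, ...]

    def to_jsonable(self) -> Dict:
        def dump(hits):
            return [
                {"kind": h.kind.value, "label": h.start_label,
                 "motif": h.motif, "region": h.region,
                 "severity": h.severity}
                for h in hits
            ]
        return {"removed": dump(self.removed),
                "introduced": dump(self.introduced),
                "retained": dump(self.retained)}


def _all_hits(ns: NumberedSequence) -> List[LiabilityHit]:
    rm = annotate_regions(ns)
    return scan_nglyc(ns, rm) + scan_deamidation(ns, rm)


def compare_liabilities(before: NumberedSequence,
                        after: NumberedSequence) -> LiabilityComparison:
    """Sites removed / introduced / retained between two variants."""
    if before.chain_type != after.chain_type:
        raise LiabilityError(
            "liability comparison requires matching chain types")
    hits_before = {h.key: h for h in _all_hits(before)}
    hits_after = {h.key: h for h in _all_hits(after)}
    removed = tuple(h for k, h in sorted(hits_before.items())
                    if k not in hits_after)
    introduced = tuple(h for k, h in sorted(hits_after.items())
                       if k not in hits_before)
    retained = tuple(h for k, h in sorted(hits_before.items())
                     if k in hits_after)
    return LiabilityComparison(removed, introduced, retained)
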