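"""The four humanization strategies plus the lambda-FR4 modification.

Strategies (all framework-only; Kabat CDRs and Vernier-zone residues are
invariant by construction):

* :func:`cdr_graft` — query CDRs (and Vernier residues) carried onto a
  user-supplied human acceptor framework.
* :func:`germline_substitute` — every eligible framework mismatch set to the
  top-ranked human germline V gene (tolerance-0 semantics); FR4 taken from
  the best-matching J gene, ranked separately.
* :func:`consensus_substitute` — eligible positions set to the human
  consensus residue when its germline frequency beats the query residue's by
  at least the configured margin (tolerance-20 semantics, in percentage
  points).
* :func:`structure_guided_substitute` — per position, the candidate set is
  the human residues at >= 5% germline frequency plus the query residue;
  the mutation scorer picks the predicted most stable single mutation,
  evaluated independently per position (no combinatorial search).

Excluded from substitution, all on by default: Kabat CDR positions, IMGT
CDR positions (via the packaged Kabat-range correspondence), Vernier-zone
positions, and positions where the query already matches the best germline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import HumanizationError
from .humanize_types import Method, SubstitutionRecord
from .numbering import (
    ChainType,
    IMGT_CDR_KABAT_BOUNDS,
    NumberedSequence,
    Region,
    RegionMap,
    Scheme,
    annotate_regions,
    label_key,
    region_of_label,
    vernier_positions,
)
from .repertoire import (
    GermlineRecord,
    PositionFrequencyTable,
    best_germline,
    consensus_residue,
    rank_germlines,
)
from .structure import (
    MutationScorer,
    StructureMapping,
    StructureModel,
    map_structure_to_numbering,
)
from .templates import AMINO_ACIDS

logger = logging.getLogger(__name__)

LAMBDA_FR4_TAIL = ("L", "T", "V", "L")


@dataclass(frozen=True)
class HumanizeConfig:
    """Thresholds and exclusion flags for the substitution strategies.

    Defaults mirror the humanization protocol settings: identity threshold
    50, frequent-residue (consensus) tolerance 20, germline tolerance 0
    (i.e. substitute every eligible mismatch), minimum germline frequency
    5% for structure-guided candidates, all four exclusion sets on.
    """

    identity_threshold: float = 50.0       # percent
    consensus_margin: float = 20.0         # percentage points
    min_germline_freq: float = 0.05        # fraction
    exclude_kabat_cdr: bool = True
    exclude_imgt_cdr: bool = True
    exclude_vernier: bool = True
    exclude_germline_matches: bool = True

    def __post_init__(self):
        if not 0.0 <= self.identity_threshold <= 100.0:
            raise HumanizationError("identity_threshold must be in [0, 100]")
        if not 0.0 <= self.consensus_margin <= 100.0:
            raise HumanizationError("consensus_margin must be in [0, 100]")
        if not 0.0 <= self.min_germline_freq <= 1.0:
            raise HumanizationError("min_germline_freq must be in [0, 1]")


@dataclass(frozen=True)
class HumanizationResult:
    """Input/output pair with the full substitution and exclusion audit.

    Construction enforces the core safety invariant of the whole toolkit:
    the output differs from the input exactly at the substituted positions
    (over shared labels), and every Kabat-CDR and Vernier-zone residue is
    identical between input and output.
    """

    input: NumberedSequence
    output: NumberedSequence
    substitutions: Tuple[SubstitutionRecord, ...]
    excluded: Mapping[str, Tuple[str, ...]]
    method: Method

    def __post_init__(self):
        sub_labels = {s.position_label for s in self.substitutions}
        in_map = self.input.as_dict()
        out_map = self.output.as_dict()
        for lab in in_map.keys() & out_map.keys():
            differs = in_map[lab] != out_map[lab]
            if differs and lab not in sub_labels:
                raise HumanizationError(
                    f"output differs at {lab} without a substitution record")
            if not differs and lab in sub_labels:
                raise HumanizationError(
                    f"substitution recorded at {lab} but output unchanged")
        protected = _protected_labels(self.input)
        for lab in protected & in_map.keys():
            if out_map.get(lab, in_map[lab]) != in_map[lab]:
                raise HumanizationError(
                    f"CDR/Vernier residue changed at {lab}")

    def to_jsonable(self) -> Dict:
        return {
            "method": self.method.value,
            "input_sequence": self.input.sequence,
            "output_sequence": self.output.sequence,
            "substitutions": [s.to_jsonable() for s in self.substitutions],
            "excluded": {lab: list(reasons)
                         for lab, reasons in sorted(
                             self.excluded.items(),
                             key=lambda kv: label_key(kv[0]))},
        }


def _protected_labels(ns: NumberedSequence) -> Set[str]:
    """Kabat-CDR plus Vernier labels present in the sequence."""
    cdrs = {lab for lab in ns.labels
            if region_of_label(lab, ns.chain_type).is_cdr}
    vern = vernier_positions(ns.chain_type).positions
    return cdrs | (vern & set(ns.labels))


def excluded_positions(ns: NumberedSequence, config: HumanizeConfig,
                       best_germline_record: Optional[GermlineRecord] = None,
                       ) -> Dict[str, Tuple[str, ...]]:
    """Positions barred from substitution, with reason tags.

    Union of four sets (each switchable in the config): Kabat CDRs, IMGT
    CDRs (Kabat-range correspondence), Vernier zone, and human-germline
    matches — positions where the query residue already equals the best
    germline's residue, so there is nothing to humanize.
    """
    reasons: Dict[str, List[str]] = {}

    def add(lab: str, tag: str) -> None:
        reasons.setdefault(lab, []).append(tag)

    if config.exclude_kabat_cdr:
        for lab in ns.labels:
            if region_of_label(lab, ns.chain_type, Scheme.KABAT).is_cdr:
                add(lab, "kabat_cdr")
    if config.exclude_imgt_cdr:
        for lab in ns.labels:
            if region_of_label(lab, ns.chain_type, Scheme.IMGT).is_cdr:
                add(lab, "imgt_cdr")
    if config.exclude_vernier:
        for lab in vernier_positions(ns.chain_type).positions:
            if lab in set(ns.labels):
                add(lab, "vernier")
    if config.exclude_germline_matches and best_germline_record is not None:
        germ = best_germline_record.numbered.as_dict()
        for lab, res in ns.residues:
            if germ.get(lab) == res:
                add(lab, "germline_match")
    return {lab: tuple(tags) for lab, tags in reasons.items()}


def _build_result(query: NumberedSequence,
                  subs: Sequence[SubstitutionRecord],
                  excluded: Mapping[str, Tuple[str, ...]],
                  method: Method) -> HumanizationResult:
    output = query.replaced(
        {s.position_label: s.to_residue for s in subs})
    return HumanizationResult(
        input=query, output=output,
        substitutions=tuple(sorted(subs,
                                   key=lambda s: label_key(s.position_label))),
        excluded=dict(excluded), method=method)


# ---------------------------------------------------------------------------
# CDR graft
# ---------------------------------------------------------------------------

def cdr_graft(query: NumberedSequence,
              acceptor_framework: NumberedSequence) -> HumanizationResult:
    """Graft the query's Kabat CDRs (and Vernier residues) onto an acceptor.

    The output carries the acceptor's framework with the query's CDR and
    Vernier residues; every framework difference is recorded as a ``graft``
    substitution.  An acceptor missing a non-insertion framework label that
    the query has is an unresolvable gap.
    """
    if query.chain_type != acceptor_framework.chain_type:
        raise HumanizationError(
            f"chain-type mismatch: query {query.chain_type.value}, "
            f"acceptor {acceptor_framework.chain_type.value}")
    protected = _protected_labels(query)
    acc = acceptor_framework.as_dict()
    subs: List[SubstitutionRecord] = []
    for lab, res in query.residues:
        if lab in protected:
            continue
        if lab not in acc:
            if label_key(lab)[1] > 0:
                continue  # optional insertion slot absent from acceptor: keep
            raise HumanizationError(
                f"acceptor framework lacks required label {lab}")
        if acc[lab] != res:
            subs.append(SubstitutionRecord(
                position_label=lab, from_residue=res, to_residue=acc[lab],
                method=Method.GRAFT,
                rationale="acceptor framework residue"))
    excluded = {lab: ("kabat_cdr_or_vernier",) for lab in sorted(protected)}
    return _build_result(query, subs, excluded, Method.GRAFT)


# ---------------------------------------------------------------------------
# germline substitution
# ---------------------------------------------------------------------------

def germline_substitute(query: NumberedSequence,
                        records: Sequence[GermlineRecord],
                        config: Optional[HumanizeConfig] = None,
                        ) -> HumanizationResult:
    """Substitute every eligible framework mismatch toward the top germline.

    V-region frameworks follow the best-matching V gene (tolerance-0: all
    eligible mismatches are substituted); FR4 follows the best-matching
    J gene, ranked separately on shared FR4 labels.
    """
    config = config or HumanizeConfig()
    same_chain = [r for r in records if r.chain_type == query.chain_type]
    v_records = [r for r in same_chain if not r.is_j]
    if not v_records:
        raise HumanizationError(
            f"no {query.chain_type.value} V-gene records in repertoire")
    ranking = rank_germlines(query, v_records)
    top_name, top_identity = ranking[0]
    if top_identity < config.identity_threshold:
        raise HumanizationError(
            f"best germline {top_name} at {top_identity:.1f}% framework "
            f"identity, below threshold {config.identity_threshold:.0f}")
    top = next(r for r in v_records if r.gene_name == top_name)
    excluded = excluded_positions(query, config, top)
    germ = top.numbered.as_dict()

    subs: List[SubstitutionRecord] = []
    for lab, res in query.residues:
        region = region_of_label(lab, query.chain_type)
        if region.is_cdr or region is Region.FR4:
            continue
        if lab in excluded or lab not in germ:
            continue
        if germ[lab] != res:
            subs.append(SubstitutionRecord(
                position_label=lab, from_residue=res, to_residue=germ[lab],
                method=Method.GERMLINE,
                rationale=f"{top_name} ({top_identity:.1f}% framework id)"))

    j_records = [r for r in same_chain if r.is_j]
    if j_records:
        fr4 = {lab: res for lab, res in query.residues
               if region_of_label(lab, query.chain_type) is Region.FR4}
        best_j, best_j_id = None, -1.0
        for rec in sorted(j_records, key=lambda r: r.gene_name):
            jmap = rec.numbered.as_dict()
            shared = fr4.keys() & jmap.keys()
            if not shared:
                continue
            ident = 100.0 * sum(
                1 for lab in shared if fr4[lab] == jmap[lab]) / len(shared)
            if ident > best_j_id:
                best_j, best_j_id = rec, ident
        if best_j is not None:
            jmap = best_j.numbered.as_dict()
            for lab, res in sorted(fr4.items(), key=lambda kv: label_key(kv[0])):
                if lab in excluded or lab not in jmap:
                    continue
                if jmap[lab] != res:
                    subs.append(SubstitutionRecord(
                        position_label=lab, from_residue=res,
                        to_residue=jmap[lab], method=Method.GERMLINE,
                        rationale=f"{best_j.gene_name} "
                                  f"({best_j_id:.1f}% FR4 id)"))
    else:
        logger.info("no J-gene records; FR4 left as-is")
    return _build_result(query, subs, excluded, Method.GERMLINE)


# ---------------------------------------------------------------------------
# consensus (frequent-residue) substitution
# ---------------------------------------------------------------------------

def consensus_substitute(query: NumberedSequence,
                         pft: PositionFrequencyTable,
                         config: Optional[HumanizeConfig] = None,
                         excluded: Optional[Mapping[str, Tuple[str, ...]]] = None,
                         ) -> HumanizationResult:
    """Substitute toward the human consensus where it clearly dominates.

    A framework position is changed to the consensus residue only when the
    consensus frequency exceeds the query residue's frequency by at least
    ``config.consensus_margin`` percentage points.
    """
    config = config or HumanizeConfig()
    if not pft.table:
        raise HumanizationError("empty position-frequency table")
    if pft.chain_type != query.chain_type:
        raise HumanizationError(
            f"frequency table is {pft.chain_type.value}, "
            f"query is {query.chain_type.value}")
    if excluded is None:
        excluded = excluded_positions(query, config, None)
    subs: List[SubstitutionRecord] = []
    for lab, res in query.residues:
        if region_of_label(lab, query.chain_type).is_cdr:
            continue
        if lab in excluded or lab not in pft:
            continue
        call = consensus_residue(pft, lab)
        if call.residue == res:
            continue
        margin = 100.0 * (pft.frequency(lab, call.residue)
                          - pft.frequency(lab, res))
        if margin >= config.consensus_margin:
            tie_note = " (tie, alphabet order)" if call.tied else ""
            subs.append(SubstitutionRecord(
                position_label=lab, from_residue=res,
                to_residue=call.residue, method=Method.CONSENSUS,
                rationale=f"consensus {call.residue} "
                          f"{pft.frequency(lab, call.residue):.2f} vs "
                          f"{res} {pft.frequency(lab, res):.2f}, "
                          f"margin {margin:.0f} pp{tie_note}"))
    return _build_result(query, subs, dict(excluded), Method.CONSENSUS)


# ---------------------------------------------------------------------------
# structure-guided best-single-mutation selection
# ---------------------------------------------------------------------------

def structure_guided_substitute(query: NumberedSequence,
                                model: StructureModel,
                                scorer: MutationScorer,
                                pft: PositionFrequencyTable,
                                config: Optional[HumanizeConfig] = None,
                                excluded: Optional[Mapping] = None,
                                mapping: Optional[StructureMapping] = None,
                                ) -> HumanizationResult:
    """Pick the predicted most stable human residue at each eligible position.

    Candidates at a position are the human residues with germline frequency
    >= ``config.min_germline_freq`` plus the query residue itself; the
    scorer's argmin wins, with ties broken toward higher germline frequency
    and then residue-alphabet order.  Each position is evaluated as an
    independent single mutation against the input model.
    """
    config = config or HumanizeConfig()
    if mapping is None:
        mapping = map_structure_to_numbering(model, query)
    if excluded is None:
        excluded = excluded_positions(query, config, None)
    subs: List[SubstitutionRecord] = []
    for lab, res in query.residues:
        if region_of_label(lab, query.chain_type).is_cdr:
            continue
        if lab in excluded:
            continue
        if lab not in mapping.mapping:
            logger.warning(
                "position %s absent from structure map; skipped", lab)
            continue
        freqs = pft.frequencies(lab)
        candidates = {r for r, f in freqs.items()
                      if f >= config.min_germline_freq}
        candidates.add(res)
        scored = []
        for cand in sorted(candidates):
            s = scorer.score(mapping, lab, res, cand)
            scored.append((s, -freqs.get(cand, 0.0), cand))
        scored.sort()  # score asc, then frequency desc, then alphabet
        best_score, neg_freq, best_res = scored[0]
        if best_res != res:
            subs.append(SubstitutionRecord(
                position_label=lab, from_residue=res, to_residue=best_res,
                method=Method.STRUCTURE,
                rationale=f"score {best_score:+.2f} vs query 0.00, "
                          f"germline freq {-neg_freq:.2f}"))
    return _build_result(query, subs, dict(excluded), Method.STRUCTURE)


# ---------------------------------------------------------------------------
# lambda FR4 swap
# ---------------------------------------------------------------------------

def lambda_fr4_swap(vl: NumberedSequence) -> NumberedSequence:
    """Replace the last four VL residues with LTVL (lambda-like FR4 terminus).

    On a typical kappa terminus (...LEIK) this changes exactly three
    residues; the operation is idempotent and rejects heavy chains.
    """
    if vl.chain_type is ChainType.VH:
        raise HumanizationError("lambda FR4 swap applies to light chains only")
    if len(vl) < 4:
        raise HumanizationError("VL too short for FR4 swap")
    tail_labels = [lab for lab, _ in vl.residues[-4:]]
    return vl.replaced(dict(zip(tail_labels, LAMBDA_FR4_TAIL)))
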