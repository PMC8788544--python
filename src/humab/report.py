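"""End-to-end campaign orchestration: humanize -> scan -> score -> report.

``run_campaign`` applies one humanization strategy to a VH/VL pair,
optionally applies the lambda-FR4 modification to the light chain, and
assembles a self-contained machine-readable report: sequences, the
substitution and exclusion audit, liability sites before/after, humanness
before/after, identity to the parent, scFv assembly and the theoretical pI
of the Fv pair.  Everything downstream of the inputs is deterministic; the
report embeds the configuration and a hash of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import __version__
from .errors import HumabError, HumanizationError
from .humanize import (
    HumanizationResult,
    HumanizeConfig,
    Method,
    cdr_graft,
    consensus_substitute,
    excluded_positions,
    germline_substitute,
    lambda_fr4_swap,
    structure_guided_substitute,
)
from .humanness import ToyEpitopeScorer, build_scfv, count_core_epitopes, t20_score
from .io import read_fasta
from .liabilities import LiabilityComparison, compare_liabilities, theoretical_pi
from .numbering import ChainType, NumberedSequence, Scheme, number_sequence
from .repertoire import (
    GermlineRecord,
    best_germline,
    load_repertoire,
    position_frequencies,
)
from .structure import get_scorer, map_structure_to_numbering, read_structure


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one campaign run."""

    method: str                       # graft | germline | consensus | structure
    repertoire_path: str
    acceptor_path: Optional[str] = None
    structure_path: Optional[str] = None
    db_path: Optional[str] = None     # humanness db; default = repertoire
    scorer: str = "contact"
    linker_units: int = 4
    lambda_fr4: bool = False
    humanize: HumanizeConfig = field(default_factory=HumanizeConfig)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("graft", "germline", "consensus", "structure"):
            raise HumabError(f"unknown humanization method {self.method!r}")
        if self.method == "graft" and not self.acceptor_path:
            raise HumabError("graft method requires an acceptor FASTA")
        if self.method == "structure" and not self.structure_path:
            raise HumabError("structure method requires a structure model")
        if self.linker_units < 1:
            raise HumabError("linker_units must be positive")

    def to_jsonable(self) -> Dict:
        data = dataclasses.asdict(self)
        return data

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ChainReport:
    chain: str
    result: HumanizationResult
    lambda_fr4_applied: bool
    liabilities: LiabilityComparison
    humanness_before: float
    humanness_after: float
    identity_to_parent: float
    final_sequence: str

    def to_jsonable(self) -> Dict:
        return {
            "chain": self.chain,
            "humanization": self.result.to_jsonable(),
            "lambda_fr4_applied": self.lambda_fr4_applied,
            "final_sequence": self.final_sequence,
            "liabilities": self.liabilities.to_jsonable(),
            "humanness_before": self.humanness_before,
            "humanness_after": self.humanness_after,
            "identity_to_parent_percent": self.identity_to_parent,
        }


@dataclass(frozen=True)
class CampaignReport:
    config: RunConfig
    vh: ChainReport
    vl: ChainReport
    scfv_sequence: str
    fv_pi_before: float
    fv_pi_after: float
    core_epitopes_before: int
    core_epitopes_after: int
    tool_version: str = __version__

    def to_jsonable(self) -> Dict:
        return {
            "tool_version": self.tool_version,
            "config": self.config.to_jsonable(),
            "config_hash": self.config.config_hash,
            "chains": [self.vh.to_jsonable(), self.vl.to_jsonable()],
            "scfv_sequence": self.scfv_sequence,
            "fv_theoretical_pi": {"before": self.fv_pi_before,
                                  "after": self.fv_pi_after},
            "core_epitopes": {"before": self.core_epitopes_before,
                              "after": self.core_epitopes_after},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable(), indent=2) + "\n")


def _read_chain_fasta(path, tag: str) -> str:
    for name, seq in read_fasta(path):
        if tag.lower() in name.lower():
            return seq
    raise HumabError(f"no record matching {tag!r} in {path}")


def _identity(a: NumberedSequence, b: NumberedSequence) -> float:
    amap, bmap = a.as_dict(), b.as_dict()
    shared = amap.keys() & bmap.keys()
    return 100.0 * sum(1 for lab in shared if amap[lab] == bmap[lab]) / len(shared)


def _humanize_chain(query: NumberedSequence, config: RunConfig,
                    records: Sequence[GermlineRecord],
                    acceptor: Optional[NumberedSequence],
                    structure_model) -> HumanizationResult:
    same_chain_v = [r for r in records
                    if r.chain_type == query.chain_type and not r.is_j]
    if config.method == "graft":
        return cdr_graft(query, acceptor)
    if config.method == "germline":
        return germline_substitute(query, records, config.humanize)
    pft = position_frequencies(same_chain_v)
    if config.method == "consensus":
        return consensus_substitute(query, pft, config.humanize)
    # structure-guided: default exclusion sets, incl. best-germline matches
    top = best_germline(query, same_chain_v) if same_chain_v else None
    excluded = excluded_positions(query, config.humanize, top)
    scorer = get_scorer(config.scorer)
    return structure_guided_substitute(
        query, structure_model, scorer, pft, config.humanize,
        excluded=excluded)


def run_campaign(query_vh, query_vl, config: RunConfig) -> CampaignReport:
    """Apply the configured strategy end to end and assemble the report."""
    ns_vh = (query_vh if isinstance(query_vh, NumberedSequence)
             else number_sequence(query_vh, ChainType.VH))
    ns_vl = (query_vl if isinstance(query_vl, NumberedSequence)
             else number_sequence(query_vl, ChainType.VK))

    try:
        records = load_repertoire(config.repertoire_path)
    except HumabError as exc:
        raise HumabError(f"[repertoire] {exc}") from exc

    acceptor = {}
    if config.method == "graft":
        acceptor = {
            ChainType.VH: number_sequence(
                _read_chain_fasta(config.acceptor_path, "VH"), ChainType.VH),
            ChainType.VK: number_sequence(
                _read_chain_fasta(config.acceptor_path, "VL"), ChainType.VK),
        }
    model = (read_structure(config.structure_path)
             if config.method == "structure" else None)

    chain_reports = {}
    for tag, query in (("VH", ns_vh), ("VL", ns_vl)):
        try:
            result = _humanize_chain(
                query, config, records,
                acceptor.get(query.chain_type), model)
        except HumabError as exc:
            raise HumabError(f"[humanize:{tag}] {exc}") from exc
        final = result.output
        if config.lambda_fr4 and tag == "VL":
            final = lambda_fr4_swap(final)
        db = [r for r in records
              if r.chain_type == query.chain_type and not r.is_j]
        before = t20_score(query, db).score
        after = t20_score(final, db).score
        chain_reports[tag] = ChainReport(
            chain=tag,
            result=result,
            lambda_fr4_applied=config.lambda_fr4 and tag == "VL",
            liabilities=compare_liabilities(query, final),
            humanness_before=before,
            humanness_after=after,
            identity_to_parent=_identity(query, final),
            final_sequence=final.sequence,
        )

    vh_rep, vl_rep = chain_reports["VH"], chain_reports["VL"]
    final_vh = vh_rep.result.output
    final_vl_seq = vl_rep.final_sequence
    final_vl = (vl_rep.result.output if not config.lambda_fr4
                else lambda_fr4_swap(vl_rep.result.output))
    scfv_before = build_scfv(ns_vl, ns_vh, config.linker_units)
    scfv_after = build_scfv(final_vl, final_vh, config.linker_units)
    scorer = ToyEpitopeScorer(seed=config.seed)
    return CampaignReport(
        config=config,
        vh=vh_rep,
        vl=vl_rep,
        scfv_sequence=scfv_after.sequence,
        fv_pi_before=theoretical_pi([(ns_vh.sequence, 1),
                                     (ns_vl.sequence, 1)]),
        fv_pi_after=theoretical_pi([(final_vh.sequence, 1),
                                    (final_vl_seq, 1)]),
        core_epitopes_before=count_core_epitopes(scfv_before, scorer),
        core_epitopes_after=count_core_epitopes(scfv_after, scorer),
    )
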