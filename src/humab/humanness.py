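"""Humanness scoring, identity matrices, scFv assembly, epitope counting.

The T20-style humanness score of a variable domain is the arithmetic mean of
its 20 highest pairwise percent identities against a human sequence database
(framework-only by default), on a 0-100 scale with 100 the most human.  The
reference implementation's proprietary database is not distributable, so the
scorer takes any numbered sequence collection; absolute scores are therefore
database-relative and only trends are comparable across databases.

MHC class II core-peptide counting is exposed as a pluggable
:class:`EpitopeScorer` interface (15-mer windows, 9-mer cores): a trained
predictor can be adapted to it, and deterministic toy scorers are packaged
for tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Protocol, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import HumannessError
from .numbering import (
    ChainType,
    NumberedSequence,
    Scheme,
    annotate_regions,
    region_of_label,
)
from .repertoire import GermlineRecord

WINDOW_LENGTH = 15
CORE_LENGTH = 9
G4S = "GGGGS"


@dataclass(frozen=True)
class HumannessResult:
    score: float
    top_hits: Tuple[Tuple[str, float], ...]
    region_mode: str
    db_size: int

    def __post_init__(self):
        if self.top_hits:
            mean = sum(pid for _, pid in self.top_hits) / len(self.top_hits)
            if abs(mean - self.score) > 1e-9:
                raise HumannessError("score is not the mean of top hits")
        if not 0.0 <= self.score <= 100.0:
            raise HumannessError(f"score {self.score} outside [0, 100]")

    @property
    def db_smaller_than_20(self) -> bool:
        return self.db_size < 20

    def to_jsonable(self) -> Dict:
        return {
            "score": self.score,
            "region_mode": self.region_mode,
            "db_size": self.db_size,
            "top_hits": [{"id": i, "percent_identity": p}
                         for i, p in self.top_hits],
        }


def _as_numbered(entry) -> Tuple[str, NumberedSequence]:
    if isinstance(entry, GermlineRecord):
        return entry.gene_name, entry.numbered
    if isinstance(entry, NumberedSequence):
        return entry.sequence[:8], entry
    if isinstance(entry, tuple) and len(entry) == 2:
        name, ns = entry
        if isinstance(ns, NumberedSequence):
            return name, ns
    raise HumannessError(
        "database entries must be GermlineRecord, NumberedSequence, "
        "or (id, NumberedSequence) pairs")


def _positions(ns: NumberedSequence, framework_only: bool) -> Dict[str, str]:
    if not framework_only:
        return ns.as_dict()
    return {lab: res for lab, res in ns.residues
            if not region_of_label(lab, ns.chain_type).is_cdr}


def _pair_identity(a: Mapping[str, str], b: Mapping[str, str]) -> float:
    shared = a.keys() & b.keys()
    if not shared:
        raise HumannessError("sequences share no numbered positions")
    matches = sum(1 for lab in shared if a[lab] == b[lab])
    return 100.0 * matches / len(shared)


def t20_score(query: NumberedSequence, db: Sequence,
              region_mode: str = "framework_only") -> HumannessResult:
    """Mean percent identity of the query to its 20 closest db entries.

    ``region_mode`` is ``framework_only`` (default, matching the framework-
    only humanness convention) or ``full_domain``.  With fewer than 20
    matching entries all are used and the result is flagged via
    ``db_smaller_than_20``.
    """
    if region_mode not in ("framework_only", "full_domain"):
        raise HumannessError(f"unknown region_mode {region_mode!r}")
    framework_only = region_mode == "framework_only"
    entries = [_as_numbered(e) for e in db]
    entries = [(name, ns) for name, ns in entries
               if ns.chain_type == query.chain_type]
    if not entries:
        raise HumannessError(
            f"database has no {query.chain_type.value} entries")
    qpos = _positions(query, framework_only)
    identities = sorted(
        ((name, _pair_identity(qpos, _positions(ns, framework_only)))
         for name, ns in entries),
        key=lambda item: (-item[1], item[0]))
    top = tuple(identities[:20])
    score = sum(pid for _, pid in top) / len(top)
    return HumannessResult(score=score, top_hits=top,
                           region_mode=region_mode, db_size=len(entries))


def identity_matrix(sequences: Sequence,
                    region_mode: str = "full_domain") -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix over shared labels."""
    entries = [_as_numbered(e) for e in sequences]
    if len(entries) < 2:
        raise HumannessError("identity matrix needs at least two sequences")
    chain_types = {ns.chain_type for _, ns in entries}
    if len(chain_types) > 1:
        raise HumannessError(
            f"mixed chain types: {sorted(c.value for c in chain_types)}")
    framework_only = region_mode == "framework_only"
    names = [name for name, _ in entries]
    pos = [_positions(ns, framework_only) for _, ns in entries]
    n = len(entries)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pair_identity(pos[i], pos[j])
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# scFv assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScFvConstruct:
    """VL-(G4S)n-VH single-chain construct (fixed VL -> VH orientation)."""

    vl: NumberedSequence
    vh: NumberedSequence
    linker_units: int = 4

    def __post_init__(self):
        if self.linker_units < 1:
            raise HumannessError("linker_units must be positive")

    @property
    def linker(self) -> str:
        return G4S * self.linker_units

    @property
    def sequence(self) -> str:
        return self.vl.sequence + self.linker + self.vh.sequence

    @property
    def orientation(self) -> str:
        return "VL-VH"

    @property
    def linker_span(self) -> Tuple[int, int]:
        """[start, end) indices of the linker within the assembled string."""
        start = len(self.vl.sequence)
        return start, start + len(self.linker)


def build_scfv(vl: NumberedSequence, vh: NumberedSequence,
               linker_units: int = 4) -> ScFvConstruct:
    """Assemble VL + (G4S)*units + VH; rejects two same-type domains."""
    if vl.chain_type is ChainType.VH:
        raise HumannessError("first domain must be a light chain (VL)")
    if vh.chain_type is not ChainType.VH:
        raise HumannessError("second domain must be a heavy chain (VH)")
    return ScFvConstruct(vl=vl, vh=vh, linker_units=linker_units)


# ---------------------------------------------------------------------------
# MHC class II core-peptide counting (pluggable interface)
# ---------------------------------------------------------------------------

class EpitopeScorer(Protocol):
    """Percentile-rank scorer for 9-mer core peptides.

    ``rank_core`` returns the best-allele percentile rank in [0, 100]
    (lower = stronger predicted binder), deterministic for fixed input and
    comparable across peptides.
    """

    def rank_core(self, core: str) -> float:
        ...


@dataclass(frozen=True)
class ToyEpitopeScorer:
    """Deterministic hash-based percentile ranks (test/fixture scorer)."""

    seed: int = 0

    def rank_core(self, core: str) -> float:
        digest = hashlib.sha256(f"{self.seed}:{core}".encode()).hexdigest()
        return (int(digest[:8], 16) % 10000) / 100.0


@dataclass(frozen=True)
class FixedEpitopeScorer:
    """Scorer with explicit per-core ranks (everything else = default)."""

    ranks: Mapping[str, float]
    default: float = 50.0

    def rank_core(self, core: str) -> float:
        return self.ranks.get(core, self.default)


def _cores(sequence: str) -> List[str]:
    """All 9-mer cores reachable through 15-mer windows of the sequence."""
    if len(sequence) < WINDOW_LENGTH:
        raise HumannessError(
            f"sequence of length {len(sequence)} is shorter than the "
            f"{WINDOW_LENGTH}-mer scoring window")
    cores = []
    seen = set()
    for start in range(len(sequence) - WINDOW_LENGTH + 1):
        window = sequence[start:start + WINDOW_LENGTH]
        for off in range(WINDOW_LENGTH - CORE_LENGTH + 1):
            core = window[off:off + CORE_LENGTH]
            if core not in seen:
                seen.add(core)
                cores.append(core)
    return cores


def count_core_epitopes(sequence: Union[str, ScFvConstruct],
                        scorer: EpitopeScorer,
                        top_pct: float = 0.2) -> int:
    """Number of unique core peptides ranking within the top ``top_pct`` %.

    A core counts once no matter how many windows contain it; its rank is
    its best-allele percentile as reported by the scorer.
    """
    seq = sequence.sequence if isinstance(sequence, ScFvConstruct) else sequence
    return sum(1 for core in _cores(seq) if scorer.rank_core(core) <= top_pct)


def linker_spanning_cores(construct: ScFvConstruct,
                          scorer: EpitopeScorer,
                          top_pct: float = 0.2) -> int:
    """Passing cores that overlap the (G4S)n linker (reported separately)."""
    seq = construct.sequence
    start, end = construct.linker_span
    count = 0
    seen = set()
    for i in range(len(seq) - CORE_LENGTH + 1):
        core = seq[i:i + CORE_LENGTH]
        if core in seen:
            continue
        seen.add(core)
        overlaps = i < end and i + CORE_LENGTH > start
        if overlaps and scorer.rank_core(core) <= top_pct:
            count += 1
    return count
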