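"""Kabat/IMGT position assignment for antibody variable domains.

Numbering is deterministic template alignment: the query is globally aligned
(BLOSUM62, affine gaps) against a packaged numbered human consensus template
for its chain type, template columns carry Kabat labels, and insertion codes
inside CDRs are re-normalised to the canonical Kabat anchor positions
(H1: 35, H2: 52, H3: 100, L1: 27, L2: 54, L3: 95).  Sequences whose best
alignment identity falls below the configured floor are rejected rather than
mis-labelled.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import NumberingError, RegionError, UnnumberableSequenceError
from .templates import AMINO_ACIDS, INSERTION_ALPHABET, TEMPLATES, Template

#: minimum fraction of identical residues over aligned columns
DEFAULT_IDENTITY_FLOOR = 0.45
#: minimum fraction of template columns that must be aligned at all
MIN_TEMPLATE_COVERAGE = 0.50

MIN_LENGTH, MAX_LENGTH = 90, 140


class ChainType(str, enum.Enum):
    VH = "VH"
    VK = "VK"
    VL_LAMBDA = "VL_lambda"

    @property
    def is_light(self) -> bool:
        return self is not ChainType.VH


class Scheme(str, enum.Enum):
    KABAT = "Kabat"
    IMGT = "IMGT"


class Region(str, enum.Enum):
    FR1 = "FR1"
    CDR1 = "CDR1"
    FR2 = "FR2"
    CDR2 = "CDR2"
    FR3 = "FR3"
    CDR3 = "CDR3"
    FR4 = "FR4"

    @property
    def is_cdr(self) -> bool:
        return self.value.startswith("CDR")


REGION_ORDER = (
    Region.FR1, Region.CDR1, Region.FR2, Region.CDR2,
    Region.FR3, Region.CDR3, Region.FR4,
)

# Kabat CDR bounds on the numeric part of the label (inclusive); fixed
# constants of this artifact, standard Kabat definition.
KABAT_CDR_BOUNDS: Mapping[ChainType, Tuple[Tuple[int, int], ...]] = {
    ChainType.VH: ((31, 35), (50, 65), (95, 102)),
    ChainType.VK: ((24, 34), (50, 56), (89, 97)),
    ChainType.VL_LAMBDA: ((24, 34), (50, 56), (89, 97)),
}

# IMGT CDR definition expressed directly in Kabat coordinates via the
# packaged boundary correspondence (mapping, not renumbering).  Approximate
# at insertion-heavy positions; documented constants of this artifact.
IMGT_CDR_KABAT_BOUNDS: Mapping[ChainType, Tuple[Tuple[int, int], ...]] = {
    ChainType.VH: ((26, 35), (51, 57), (93, 102)),
    ChainType.VK: ((24, 34), (50, 52), (89, 97)),
    ChainType.VL_LAMBDA: ((24, 34), (50, 52), (89, 97)),
}

# Vernier zone (Foote-Winter list, Kabat labels); disjoint from Kabat CDRs
# by construction.  The Vernier definition used by the original modeling
# software is unstated, so this packaged choice is flagged in metadata.
VERNIER_DEFINITION = "Foote-Winter"
_VERNIER_VH = frozenset(
    "2 27 28 29 30 47 48 49 67 69 71 73 78 93 94 103".split()
)
_VERNIER_VL = frozenset(
    "2 4 35 36 46 47 48 49 64 66 68 69 71 98".split()
)
VERNIER_POSITIONS: Mapping[ChainType, frozenset] = {
    ChainType.VH: _VERNIER_VH,
    ChainType.VK: _VERNIER_VL,
    ChainType.VL_LAMBDA: _VERNIER_VL,
}


def label_key(label: str) -> Tuple[int, int]:
    """Sort key for a Kabat label: numeric part, then insertion letter."""
    num = label
    letter = 0
    if label and label[-1].isalpha():
        num, ins = label[:-1], label[-1].upper()
        letter = INSERTION_ALPHABET.index(ins) + 1
    try:
        return int(num), letter
    except ValueError as exc:  # pragma: no cover - defensive
        raise NumberingError(f"malformed position label {label!r}") from exc


def region_of_label(label: str, chain_type: ChainType,
                    cdr_definition: Scheme = Scheme.KABAT) -> Region:
    """Region membership of a Kabat label under the given CDR definition."""
    num = label_key(label)[0]
    bounds = (KABAT_CDR_BOUNDS if cdr_definition is Scheme.KABAT
              else IMGT_CDR_KABAT_BOUNDS)[chain_type]
    (c1lo, c1hi), (c2lo, c2hi), (c3lo, c3hi) = bounds
    if num < c1lo:
        return Region.FR1
    if num <= c1hi:
        return Region.CDR1
    if num < c2lo:
        return Region.FR2
    if num <= c2hi:
        return Region.CDR2
    if num < c3lo:
        return Region.FR3
    if num <= c3hi:
        return Region.CDR3
    return Region.FR4


@dataclass(frozen=True)
class NumberedSequence:
    """A variable-domain sequence with one scheme label per residue.

    Invariants enforced at construction: labels strictly increase in scheme
    order, and every residue is a standard one-letter amino acid, so that
    joining the residues reproduces the input sequence exactly.
    """

    chain_type: ChainType
    scheme: Scheme
    residues: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        prev = None
        for lab, res in self.residues:
            if res not in AMINO_ACIDS:
                raise NumberingError(f"non-standard residue {res!r} at {lab}")
            key = label_key(lab)
            if prev is not None and key <= prev:
                raise NumberingError(
                    f"position labels not strictly increasing at {lab}")
            prev = key

    @property
    def sequence(self) -> str:
        return "".join(res for _, res in self.residues)

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(lab for lab, _ in self.residues)

    def as_dict(self) -> Dict[str, str]:
        return dict(self.residues)

    def residue_at(self, label: str) -> Optional[str]:
        return self.as_dict().get(label)

    def __len__(self) -> int:
        return len(self.residues)

    def replaced(self, substitutions: Mapping[str, str]) -> "NumberedSequence":
        """Return a copy with residues replaced at the given labels."""
        missing = set(substitutions) - set(self.labels)
        if missing:
            raise NumberingError(
                f"labels absent from sequence: {sorted(missing)}")
        new = tuple(
            (lab, substitutions.get(lab, res)) for lab, res in self.residues)
        return NumberedSequence(self.chain_type, self.scheme, new)


@dataclass(frozen=True)
class RegionMap:
    """FR1..FR4 / CDR1..3 tiling of a numbered sequence's labels."""

    chain_type: ChainType
    cdr_definition: Scheme
    regions: Mapping[Region, Tuple[str, ...]]

    def region_of(self, label: str) -> Region:
        return region_of_label(label, self.chain_type, self.cdr_definition)

    @property
    def cdr_labels(self) -> frozenset:
        return frozenset(
            lab for reg in REGION_ORDER if reg.is_cdr
            for lab in self.regions[reg])

    @property
    def framework_labels(self) -> Tuple[str, ...]:
        return tuple(
            lab for reg in REGION_ORDER if not reg.is_cdr
            for lab in self.regions[reg])


@dataclass(frozen=True)
class VernierSet:
    """Fixed per-chain Vernier-zone position set (Kabat labels)."""

    chain_type: ChainType
    positions: frozenset
    definition: str = VERNIER_DEFINITION


# ---------------------------------------------------------------------------
# alignment machinery
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _align_columns(template_seq: str, query: str):
    """Best global alignment as (query_index -> template_column | None)."""
    alignment = _aligner().align(template_seq, query)[0]
    col_of: List[Optional[int]] = [None] * len(query)
    matches = aligned = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            ti, qi = t0 + offset, q0 + offset
            col_of[qi] = ti
            aligned += 1
            if template_seq[ti] == query[qi]:
                matches += 1
    identity = matches / aligned if aligned else 0.0
    coverage = aligned / len(template_seq)
    return col_of, identity, coverage


def _cdr_base_labels(chain_type: ChainType, region: Region,
                     template: Template) -> Tuple[List[str], int]:
    """Canonical (un-inserted) label run for a CDR and its anchor index."""
    lo, hi = {
        Region.CDR1: KABAT_CDR_BOUNDS[chain_type][0],
        Region.CDR2: KABAT_CDR_BOUNDS[chain_type][1],
        Region.CDR3: KABAT_CDR_BOUNDS[chain_type][2],
    }[region]
    base = [str(i) for i in range(lo, hi + 1)]
    anchor = template.cdr_anchors[region.value]
    return base, base.index(anchor)


def _relabel_cdr(n: int, base: List[str], anchor_idx: int) -> List[str]:
    """Kabat labels for a CDR of observed length ``n``.

    Insertions get letters after the anchor label; deletions shrink the run
    ahead of the anchor while keeping the trailing labels (standard Kabat
    practice for e.g. short CDR-H3 loops).
    """
    left, right = base[: anchor_idx + 1], base[anchor_idx + 1:]
    if n >= len(base):
        extra = n - len(base)
        if extra > len(INSERTION_ALPHABET):
            raise NumberingError(
                f"CDR of length {n} exceeds insertion alphabet")
        inserted = [base[anchor_idx] + INSERTION_ALPHABET[i]
                    for i in range(extra)]
        return left + inserted + right
    if n >= len(right) + 1:
        return left[: n - len(right)] + right
    if n > 0:
        return right[len(right) - n:]
    return []


def _assign_labels(query: str, chain_type: ChainType,
                   template: Template,
                   col_of: List[Optional[int]]) -> List[str]:
    """Turn a column assignment into per-residue Kabat labels."""
    n = len(query)
    col_regions = [
        region_of_label(lab, chain_type) for lab in template.labels]

    # reject residues dangling beyond the template at either end
    aligned_idx = [i for i in range(n) if col_of[i] is not None]
    if not aligned_idx:
        raise NumberingError("no residue aligned to the template")
    if aligned_idx[0] != 0:
        raise NumberingError(
            f"{aligned_idx[0]} un-numbered N-terminal residue(s)")
    if aligned_idx[-1] != n - 1:
        raise NumberingError(
            f"{n - 1 - aligned_idx[-1]} un-numbered C-terminal residue(s)")

    # bucket each query residue into a region
    buckets: List[Region] = [None] * n  # type: ignore[list-item]
    for i in range(n):
        if col_of[i] is not None:
            buckets[i] = col_regions[col_of[i]]
    for i in range(n):
        if buckets[i] is None:  # inserted residue between aligned anchors
            prev_reg = next(buckets[j] for j in range(i - 1, -1, -1)
                            if buckets[j] is not None)
            next_reg = next(buckets[j] for j in range(i + 1, n)
                            if buckets[j] is not None)
            if prev_reg.is_cdr:
                buckets[i] = prev_reg
            elif next_reg.is_cdr:
                buckets[i] = next_reg
            elif prev_reg is next_reg:
                buckets[i] = prev_reg
            else:
                # insertion spanning an empty CDR between two frameworks
                mid = REGION_ORDER[REGION_ORDER.index(prev_reg) + 1]
                buckets[i] = mid

    labels: List[str] = [""] * n
    i = 0
    while i < n:
        reg = buckets[i]
        j = i
        while j < n and buckets[j] is reg:
            j += 1
        if reg.is_cdr:
            base, anchor_idx = _cdr_base_labels(chain_type, reg, template)
            labels[i:j] = _relabel_cdr(j - i, base, anchor_idx)
        else:
            pending = 0
            for k in range(i, j):
                if col_of[k] is not None:
                    labels[k] = template.labels[col_of[k]]
                    pending = 0
                else:
                    prev = labels[k - 1]
                    if prev and prev[-1].isalpha():
                        idx = INSERTION_ALPHABET.index(prev[-1]) + 1
                        if idx >= len(INSERTION_ALPHABET):
                            raise NumberingError(
                                f"insertion alphabet exhausted after {prev}")
                        labels[k] = prev[:-1] + INSERTION_ALPHABET[idx]
                    else:
                        labels[k] = prev + "A"
                    pending += 1
        i = j
    # Kabat has no insertion slots in the terminal frameworks; extra
    # residues there are un-numbered overhangs, not insertions
    for k, lab in enumerate(labels):
        if lab[-1].isalpha() and buckets[k] in (Region.FR1, Region.FR4):
            raise NumberingError(
                f"residue {query[k]!r} cannot be numbered: no insertion "
                f"slot in {buckets[k].value} (would be {lab})")
    return labels


# Approximate monotone Kabat-region -> IMGT-range correspondence used when
# an IMGT-labelled NumberedSequence is requested.
_IMGT_REGION_RANGES: Mapping[Region, Tuple[int, int]] = {
    Region.FR1: (1, 26),
    Region.CDR1: (27, 38),
    Region.FR2: (39, 55),
    Region.CDR2: (56, 65),
    Region.FR3: (66, 104),
    Region.CDR3: (105, 117),
    Region.FR4: (118, 128),
}


def _to_imgt_labels(labels: Sequence[str],
                    chain_type: ChainType) -> List[str]:
    out: List[str] = []
    counters = {reg: 0 for reg in REGION_ORDER}
    for lab in labels:
        reg = region_of_label(lab, chain_type)
        lo, hi = _IMGT_REGION_RANGES[reg]
        k = counters[reg]
        counters[reg] += 1
        if lo + k <= hi:
            out.append(str(lo + k))
        else:  # overflow beyond the IMGT range: letter the last position
            out.append(str(hi) + INSERTION_ALPHABET[lo + k - hi - 1])
    return out


def number_sequence(seq: str, chain_type: ChainType,
                    scheme: Scheme = Scheme.KABAT,
                    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                    ) -> NumberedSequence:
    """Assign scheme position labels to a variable-domain sequence.

    Parameters
    ----------
    seq
        90-140 standard one-letter residues (an Fv-length domain).
    chain_type
        Which packaged consensus template to align against.
    scheme
        ``Kabat`` (native) or ``IMGT`` (relabelled through the packaged
        correspondence table).
    identity_floor
        Minimum alignment identity to the template below which the sequence
        is rejected as unnumberable.
    """
    seq = str(seq).strip().upper()
    chain_type = ChainType(chain_type)
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise NumberingError(f"non-standard residues in input: {bad}")
    if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
        raise UnnumberableSequenceError(
            f"sequence length {len(seq)} outside the numberable range "
            f"{MIN_LENGTH}-{MAX_LENGTH}",
            template_name=TEMPLATES[chain_type.value].name, identity=0.0)
    template = TEMPLATES[chain_type.value]
    col_of, identity, coverage = _align_columns(template.sequence, seq)
    if identity < identity_floor or coverage < MIN_TEMPLATE_COVERAGE:
        raise UnnumberableSequenceError(
            f"sequence is not numberable as {chain_type.value}: best "
            f"template {template.name} identity {identity:.1%} "
            f"(floor {identity_floor:.0%}), coverage {coverage:.1%}",
            template_name=template.name, identity=identity)
    labels = _assign_labels(seq, chain_type, template, col_of)
    if Scheme(scheme) is Scheme.IMGT:
        labels = _to_imgt_labels(labels, chain_type)
    return NumberedSequence(chain_type, Scheme(scheme),
                            tuple(zip(labels, seq)))


def number_j_segment(seq: str, chain_type: ChainType) -> NumberedSequence:
    """Number a short J-gene peptide by anchoring it at the domain C-terminus.

    J segments (10-20 residues: the CDR3 tail plus FR4) are far below the
    length floor of :func:`number_sequence`; they are labelled positionally,
    last residue to the last template label and backwards from there.
    """
    seq = str(seq).strip().upper()
    chain_type = ChainType(chain_type)
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise NumberingError(f"non-standard residues in input: {bad}")
    template = TEMPLATES[chain_type.value]
    if not 4 <= len(seq) <= 25:
        raise NumberingError(
            f"J segment length {len(seq)} outside the expected 4-25 range")
    labels = list(template.labels[-len(seq):])
    return NumberedSequence(chain_type, Scheme.KABAT,
                            tuple(zip(labels, seq)))


def annotate_regions(ns: NumberedSequence,
                     cdr_definition: Scheme = Scheme.KABAT) -> RegionMap:
    """Partition a Kabat-numbered sequence into FR1..CDR3..FR4 label runs."""
    if ns.scheme is not Scheme.KABAT:
        raise RegionError(
            "region annotation requires Kabat-numbered input; "
            f"got {ns.scheme.value}")
    cdr_definition = Scheme(cdr_definition)
    regions: Dict[Region, List[str]] = {reg: [] for reg in REGION_ORDER}
    for lab, _ in ns.residues:
        regions[region_of_label(lab, ns.chain_type, cdr_definition)].append(lab)
    required = {
        ChainType.VH: ("36", "66", "103"),
        ChainType.VK: ("35", "57", "98"),
        ChainType.VL_LAMBDA: ("35", "57", "98"),
    }[ns.chain_type]
    present = set(ns.labels)
    missing = [lab for lab in required if lab not in present]
    if missing:
        raise RegionError(
            f"required framework boundary labels absent: {missing}")
    return RegionMap(ns.chain_type, cdr_definition,
                     {reg: tuple(v) for reg, v in regions.items()})


def vernier_positions(chain_type: ChainType) -> VernierSet:
    """The packaged Foote-Winter Vernier-zone set for a chain type."""
    chain_type = ChainType(chain_type)
    return VernierSet(chain_type, VERNIER_POSITIONS[chain_type])


def framework_sequence(ns: NumberedSequence,
                       rm: Optional[RegionMap] = None) -> str:
    """FR1+FR2+FR3+FR4 residues of ``ns`` concatenated (CDRs removed)."""
    if rm is None:
        rm = annotate_regions(ns)
    cdrs = rm.cdr_labels
    return "".join(res for lab, res in ns.residues if lab not in cdrs)
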