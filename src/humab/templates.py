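"""Packaged numbered consensus templates for Kabat numbering by alignment.

Each template is a human variable-domain consensus with an explicit, ordered
list of Kabat position labels (insertion-coded columns included where the
scheme has near-ubiquitous slots, e.g. VH 82A-82C).  Queries are numbered by
global alignment against the template string; the label list then carries the
column -> position correspondence.

The VH consensus follows human subgroup III, the Vkappa consensus subgroup I,
and the Vlambda consensus subgroup 1/2 usage (with the canonical one-residue
FR1 deletion at position 10).  CDR contents are placeholders of canonical
length; only framework columns are ever used as sequence authorities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

from .errors import NumberingError

#: canonical one-letter amino-acid alphabet (fixed tie-break order)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

INSERTION_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _labels(*parts) -> Tuple[str, ...]:
    out = []
    for part in parts:
        if isinstance(part, str):
            out.append(part)
        else:
            lo, hi = part
            out.extend(str(i) for i in range(lo, hi + 1))
    return tuple(out)


@dataclass(frozen=True)
class Template:
    """A numbered consensus template for one chain type."""

    name: str
    chain_type: str  # ChainType value; kept as str to avoid import cycle
    labels: Tuple[str, ...]
    sequence: str
    #: per-CDR canonical insertion anchor (label after which Kabat letters go)
    cdr_anchors: Mapping[str, str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequence):
            raise NumberingError(
                f"template {self.name}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues"
            )

    @property
    def pairs(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(zip(self.labels, self.sequence))


# ---------------------------------------------------------------------------
# VH: Kabat 1-113 plus ubiquitous 82A-82C. 116 columns.
# FR1 1-30 | CDR-H1 31-35 | FR2 36-49 | CDR-H2 50-65 | FR3 66-94 (+82A-C)
# | CDR-H3 95-102 | FR4 103-113
# ---------------------------------------------------------------------------
VH_TEMPLATE = Template(
    name="human_VH_consensus",
    chain_type="VH",
    labels=_labels((1, 82), "82A", "82B", "82C", (83, 113)),
    sequence=(
        "EVQLVESGGGLVQPGGSLRLSCAASGFTFS"  # FR1   1-30
        "SYAMS"                           # CDR1 31-35
        "WVRQAPGKGLEWVS"                  # FR2  36-49
        "AISGSGGSTYYADSVK"                # CDR2 50-65
        "RFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR"  # FR3 66-94 incl 82A-C
        "DYYGSGSY"                        # CDR3 95-102
        "WGQGTLVTVSS"                     # FR4 103-113
    ),
    cdr_anchors={"CDR1": "35", "CDR2": "52", "CDR3": "100"},
)

# ---------------------------------------------------------------------------
# Vkappa: Kabat 1-107. 107 columns.
# FR1 1-23 | CDR-L1 24-34 | FR2 35-49 | CDR-L2 50-56 | FR3 57-88
# | CDR-L3 89-97 | FR4 98-107
# ---------------------------------------------------------------------------
VK_TEMPLATE = Template(
    name="human_VK_consensus",
    chain_type="VK",
    labels=_labels((1, 107)),
    sequence=(
        "DIQMTQSPSSLSASVGDRVTITC"          # FR1   1-23
        "RASQSISSYLN"                      # CDR1 24-34
        "WYQQKPGKAPKLLIY"                  # FR2  35-49
        "AASSLQS"                          # CDR2 50-56
        "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # FR3 57-88
        "QQSYSTPPT"                        # CDR3 89-97
        "FGQGTKVEIK"                       # FR4 98-107
    ),
    cdr_anchors={"CDR1": "27", "CDR2": "54", "CDR3": "95"},
)

# ---------------------------------------------------------------------------
# Vlambda: same Kabat label layout as Vkappa, with the canonical FR1
# deletion at position 10 (22-residue FR1). 106 columns.
# ---------------------------------------------------------------------------
VL_LAMBDA_TEMPLATE = Template(
    name="human_VLambda_consensus",
    chain_type="VL_lambda",
    labels=_labels((1, 9), (11, 107)),
    sequence=(
        "QSVLTQPPSVSAAPGQKVTISC"           # FR1  1-9,11-23
        "SGSSSNIGNNY"                      # CDR1 24-34
        "WYQQLPGTAPKLLIY"                  # FR2  35-49
        "GNSNRPS"                          # CDR2 50-56
        "GVPDRFSGSKSGTSASLAITGLQAEDEADYYC"  # FR3 57-88
        "QSYDSSLSG"                        # CDR3 89-97
        "FGGGTKLTVL"                       # FR4 98-107
    ),
    cdr_anchors={"CDR1": "27", "CDR2": "54", "CDR3": "95"},
)

TEMPLATES: Mapping[str, Template] = {
    "VH": VH_TEMPLATE,
    "VK": VK_TEMPLATE,
    "VL_lambda": VL_LAMBDA_TEMPLATE,
}
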