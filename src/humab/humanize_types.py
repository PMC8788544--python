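"""Shared record types for humanization and liability-repair substitutions."""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import HumanizationError


class Method(str, enum.Enum):
    GRAFT = "graft"
    GERMLINE = "germline"
    CONSENSUS = "consensus"
    STRUCTURE = "structure"
    AGLYCO = "aglyco"  # liability-repair proposals, outside the 4 strategies


@dataclass(frozen=True)
class SubstitutionRecord:
    """One proposed residue change at a Kabat position, with its rationale."""

    position_label: str
    from_residue: str
    to_residue: str
    method: Method
    rationale: str = ""

    def __post_init__(self):
        object.__setattr__(self, "method", Method(self.method))
        if self.from_residue == self.to_residue:
            raise HumanizationError(
                f"null substitution at {self.position_label}: "
                f"{self.from_residue} -> {self.to_residue}")

    def to_jsonable(self) -> dict:
        return {
            "position": self.position_label,
            "from": self.from_residue,
            "to": self.to_residue,
            "method": self.method.value,
            "rationale": self.rationale,
        }
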