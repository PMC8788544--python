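"""Packaged public sequences: the cetuximab heavy and light chains.

Cetuximab is the chimeric anti-EGFR IgG1 whose mouse variable regions carry
the canonical developability liabilities this toolkit targets: an occupied
NDT N-glycosylation sequon at Kabat VH N85 and an NGS motif at VL N41.  The
chains here are the public amino-acid sequences; ``mature`` heavy chains
have the C-terminal lysine removed, the near-complete clipping state of
manufactured antibodies and the standard convention for sequence-based
charge calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Tuple

from .io import read_fasta
from .liabilities import ChainSet

VH_LENGTH = 119
VL_LENGTH = 107


@dataclass(frozen=True)
class CetuximabChains:
    heavy: str          # genetically encoded heavy chain (ends ...SPGK)
    light: str

    @property
    def heavy_mature(self) -> str:
        """Heavy chain with the C-terminal lysine clipped (mature mAb form)."""
        return self.heavy[:-1]

    @property
    def vh(self) -> str:
        return self.heavy[:VH_LENGTH]

    @property
    def vl(self) -> str:
        return self.light[:VL_LENGTH]

    @property
    def heavy_n85e(self) -> str:
        """Aglycosylated variant: the sequon Asn (Kabat H85) mutated to Glu."""
        target, repl = "QSNDTAIYYC", "QSEDTAIYYC"
        assert self.heavy.count(target) == 1
        return self.heavy.replace(target, repl)

    def mab_chainset(self, variant: str = "wild_type",
                     mature: bool = True) -> ChainSet:
        """2H + 2L ChainSet for the full antibody (termini per chain copy)."""
        heavy = {"wild_type": self.heavy, "n85e": self.heavy_n85e}[variant]
        if mature:
            heavy = heavy[:-1]
        return ChainSet(((heavy, 2), (self.light, 2)))


def cetuximab() -> CetuximabChains:
    """Load the packaged cetuximab chains."""
    with resources.as_file(
            resources.files("humab.data").joinpath(
                "cetuximab.fasta")) as path:
        records = dict(
            (name.split()[0], seq) for name, seq in read_fasta(path))
    return CetuximabChains(heavy=records["cetuximab_heavy"],
                           light=records["cetuximab_light"])
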