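"""Exception hierarchy for the humab toolkit."""


class HumabError(Exception):
    """Base class for all humab errors."""


class NumberingError(HumabError):
    """A sequence could not be assigned scheme positions."""


class UnnumberableSequenceError(NumberingError):
    """Alignment identity to every packaged template fell below the floor."""

    def __init__(self, message: str, template_name: str, identity: float):
        super().__init__(message)
        self.template_name = template_name
        self.identity = identity


class RegionError(NumberingError):
    """Region annotation failed (e.g. required boundary labels absent)."""


class RepertoireError(HumabError):
    """Germline repertoire loading or bookkeeping failed."""


class HumanizationError(HumabError):
    """A humanization strategy could not be applied."""


class LiabilityError(HumabError):
    """Liability scanning / pI computation rejected its input."""


class HumannessError(HumabError):
    """Humanness scoring or construct assembly rejected its input."""


class StructureError(HumabError):
    """Structure reading, mapping or scoring failed."""
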