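"""Exception hierarchy for the screen-analysis pipeline.

Exit-code mapping used by the CLI: SchemaError -> 2, DegenerateDataError -> 3.
"""


class ToxScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(ToxScreenError):
    """Input table is missing required columns or particles do not join."""


class InsufficientDataError(ToxScreenError):
    """Too few doses / sizes to fit the requested model."""


class DegenerateDataError(ToxScreenError):
    """Data admit no meaningful fit (e.g. all-zero viability)."""


class AlignmentError(ToxScreenError):
    """Paired series (e.g. GFP and autofluorescence) do not line up."""


class CensoredFitError(ToxScreenError):
    """A quantity was requested that is undefined for a censored fit."""


class GatedOutError(ToxScreenError):
    """Every dose fell below the viability gate; no verdict is possible."""
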