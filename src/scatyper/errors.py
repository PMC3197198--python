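"""Exception hierarchy shared across the package."""


class ScatyperError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ScatyperError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(ScatyperError, ValueError):
    """An input file or string does not parse (carries context, e.g. line)."""


class ConsistencyError(ScatyperError, ValueError):
    """Cross-referenced inputs disagree (e.g. a clone without metadata)."""


class NoAmpliconError(ScatyperError, ValueError):
    """A primer pair found no amplicon; ``primer`` names the failing end."""

    def __init__(self, message: str, primer: str | None = None):
        super().__init__(message)
        self.primer = primer
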