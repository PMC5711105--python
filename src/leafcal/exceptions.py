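"""Exception hierarchy for leafcal."""


class LeafcalError(Exception):
    """Base class for all leafcal errors."""


class ConfigurationError(LeafcalError):
    """Invalid machine model, layout, table or phantom configuration."""


class InvalidBeamError(LeafcalError):
    """Beam definition violates geometry (negative aperture, travel range, ...)."""


class NormalizationError(LeafcalError):
    """No open field region to normalize against."""


class EdgeNotFoundError(LeafcalError):
    """A 50%-intensity crossing could not be located on the requested side."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"no 50% intensity crossing found on the {side} side")


class DegenerateFitError(LeafcalError):
    """Least-squares fit is undetermined (e.g. all abscissae identical)."""


class ParseError(LeafcalError):
    """Malformed input file."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}"
        super().__init__(f"{where}: {message}" if where else message)
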