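"""Exception types shared across the pipeline stages."""


class LithophenoError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LithophenoError, ValueError):
    """A parameter is outside its valid range."""


class InvalidRatingError(LithophenoError, ValueError):
    """An Alda-scale rating is outside its defined range."""


class ConsistencyError(LithophenoError, ValueError):
    """Subject ids or table shapes disagree between inputs."""


class ParseError(LithophenoError, ValueError):
    """A genotype file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class DegenerateTargetError(LithophenoError, ValueError):
    """The response labels contain a single class; no tree can be grown."""


class DegenerateCodingError(LithophenoError, ValueError):
    """A genotype coding produced fewer than two non-empty groups."""


class RoutingError(LithophenoError, KeyError):
    """A record carries a predictor category unseen during tree fitting."""


class EmptySelectionError(LithophenoError, ValueError):
    """No SNPs remain for a gene after quality control."""


class StageError(LithophenoError, RuntimeError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
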