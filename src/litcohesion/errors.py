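"""Exception hierarchy shared by all modules."""


class LitCohesionError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(LitCohesionError, ValueError):
    """A configuration value violates an invariant; message names the invariant."""


class ConsistencyError(LitCohesionError, ValueError):
    """Artifacts produced under different configurations were mixed."""


class ParseError(LitCohesionError, ValueError):
    """A text input could not be parsed; carries path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f", line {line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class PipelineError(LitCohesionError, RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class CohesionUndefinedError(LitCohesionError, ValueError):
    """Fewer than two in-corpus genes: pairwise similarity is undefined."""


class UndefinedSimilarityError(LitCohesionError, ValueError):
    """A gene vector has zero norm, so its cosine is undefined."""


class DegenerateCorrelationError(LitCohesionError, ValueError):
    """Pearson correlation requested on a constant variable."""
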