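"""Exception hierarchy for the screening pipeline."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerbnetError):
    """Invalid or infeasible configuration (bad ranges, impossible constructions)."""


class ValidationError(HerbnetError):
    """Input data violates a contract (missing values, out-of-range numbers)."""


class ParseError(HerbnetError):
    """Malformed input file; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyInputError(HerbnetError):
    """An operation that requires a non-empty input received an empty one."""


class EmptyGraphError(EmptyInputError):
    """Centrality analysis requested on a graph with no nodes."""


class DegenerateInputError(HerbnetError):
    """Statistically degenerate input (e.g. zero variance in both groups)."""


class PipelineError(HerbnetError):
    """A pipeline stage failed; names the stage so partial artifacts can be inspected."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
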