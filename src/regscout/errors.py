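"""Exception hierarchy shared by all regscout stages.

Exit-code mapping used by the CLI: input/parse/argument problems are exit 2,
internal consistency violations (asymmetric maps, duplicate cohort records)
are exit 3.
"""


class RegscoutError(Exception):
    """Base class for all regscout errors."""


class InvalidArgumentError(RegscoutError, ValueError):
    """A parameter or domain-object precondition was violated."""


class IncompatibleCoordinatesError(InvalidArgumentError):
    """Operands live on different chromosomes where one is required."""


class IncompatibleResolutionError(InvalidArgumentError):
    """Bin sizes of the operands disagree."""


class ParseError(RegscoutError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class ConsistencyError(RegscoutError):
    """Inputs parsed cleanly but contradict each other."""
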