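"""Exception hierarchy for shellforge.

Parse-class errors carry a character offset into the offending text so that
command-line tools can report ``line:offset`` positions.
"""

from __future__ import annotations


class ShellforgeError(Exception):
    """Base class for all shellforge errors."""


class ParseError(ShellforgeError):
    """A piece of text could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description.
    offset:
        0-based character offset into the input text where the problem
        starts, or ``None`` when no position applies.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class GStringParseError(ParseError):
    """Malformed interpolation marker in a string literal."""


class PipelineParseError(ParseError):
    """Malformed command pipeline text."""


class EnvFileParseError(ParseError):
    """Malformed line in a key=value environment file.

    ``line_number`` is 1-based.
    """

    def __init__(self, message: str, line_number: int):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class EvaluationError(ShellforgeError):
    """A variable or environment reference could not be evaluated."""


class ResolutionError(ShellforgeError):
    """A name could not be resolved against any environment source."""


class ModelError(ShellforgeError):
    """A structurally invalid script model was supplied or constructed."""


class ModelFormatError(ShellforgeError):
    """A persisted script-model file is malformed."""


class ModelVersionError(ModelFormatError):
    """A persisted script-model file declares an unsupported format version."""


class PatternError(ShellforgeError):
    """An invalid path pattern was supplied."""


class ExecutionError(ShellforgeError):
    """A script or pipeline could not be started."""


class ReductionError(ShellforgeError):
    """A domain command could not be lowered to a core execute statement."""


class GenerationError(ShellforgeError):
    """A model could not be rendered to a runnable artifact."""


class TemplateError(ShellforgeError):
    """A phrase template could not be built or rendered."""


class PluginConfigError(ShellforgeError):
    """A plugin descriptor file is invalid."""
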