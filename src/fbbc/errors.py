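"""Exception hierarchy shared by all pipeline stages."""


class FBBCError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FBBCError):
    """A file could not be parsed as the expected container format."""


class DialectError(FormatError):
    """A keypoint file does not follow the expected column dialect."""


class ArgumentError(FBBCError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(ArgumentError):
    """Input is structurally valid but too small/empty for the operation."""


class RecipeError(ArgumentError):
    """A feature recipe references unknown keypoints or has wrong arity."""


class NotFoundError(FBBCError, KeyError):
    """A requested person, keypoint, column or cluster does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class NamingError(FBBCError, ValueError):
    """A name collision between columns or clusters."""


class ValidationError(FBBCError, ValueError):
    """A table or config failed validation; message lists the violations."""


class PipelineError(FBBCError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
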