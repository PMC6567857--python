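"""Exception hierarchy for the lamep pipeline."""


class LamepError(Exception):
    """Base class for all lamep-specific errors."""


class FormatError(LamepError):
    """A binary or text file does not match the declared layout."""


class SchemaError(FormatError):
    """A sidecar/metadata document is missing a required key."""


class ValidationError(LamepError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(LamepError, ValueError):
    """An analysis parameter is out of its admissible range."""


class GeometryError(LamepError):
    """Probe geometry is unsuitable for the requested operation."""


class AlignmentError(LamepError):
    """Two traces that must share a time grid do not."""


class EmptyResultError(LamepError):
    """An operation retained no data (e.g. every trial was dropped)."""


class LayerAssignmentError(LamepError):
    """Layer identification failed; carries per-channel diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class StageError(LamepError):
    """A pipeline stage failed; names the stage for the operator."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
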