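class ValidationError(ValueError):
    """Raised when an input value or configuration field is invalid."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed (e.g. missing upstream
    artifact or no candidate hits)."""
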