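"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails after its inputs validated."""
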