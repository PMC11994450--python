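"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition or invariant."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class NoCellsPassQCError(PipelineError):
    """Every cell was removed by quality-control filtering."""
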