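"""Exception types shared across the pipeline."""


class GliamotionError(Exception):
    """Base class for all package errors."""


class ParameterError(GliamotionError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class SpecificationError(GliamotionError, ValueError):
    """An inconsistent synthetic-data specification (e.g. overlapping masks)."""


class PipelineError(GliamotionError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
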