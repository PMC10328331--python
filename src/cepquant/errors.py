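"""Exception hierarchy for the analysis pipeline.

Every per-image failure mode raises a subclass of :class:`PipelineError`
so that batch processing can catch, log, and skip a bad frame without
aborting the run.
"""


class PipelineError(Exception):
    """Base class for recoverable per-image analysis failures."""


class InputError(PipelineError):
    """The input file is missing, unreadable, or of an unsupported kind."""


class ChannelError(InputError):
    """Multi-channel (RGB) input: the GFP channel must be extracted upstream."""


class BlankFrameError(PipelineError):
    """The frame carries no signal (zero variance or degenerate contrast)."""


class NoCellBodyError(PipelineError):
    """No connected bright cluster survives the soma threshold/area filter."""


class MultipleWormsError(PipelineError):
    """Bright clusters form >1 spatially separated group: more than one worm."""


class NoDendritesError(PipelineError):
    """No elongated vertical component found where dendrites were expected."""


class PhantomSpecError(ValueError):
    """A synthetic-image specification is internally inconsistent."""
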