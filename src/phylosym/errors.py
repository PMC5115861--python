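"""Exception types shared across the package."""


class PhylosymError(Exception):
    """Base class for all errors raised by phylosym."""


class FormatError(PhylosymError, ValueError):
    """A file or in-memory table violates its format contract.

    The message always names the offending record (sample id, OTU id,
    row/column position, ...).
    """


class TreeError(PhylosymError, ValueError):
    """A tree violates a structural precondition (leaf-set mismatch,
    duplicate labels, too few leaves, missing branch lengths...)."""


class PipelineError(PhylosymError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
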