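"""Exception hierarchy for dimorphseq."""


class DimorphSeqError(ValueError):
    """Base class for all dimorphseq errors."""


class InvalidConfigError(DimorphSeqError):
    """A simulation or pipeline configuration failed validation."""


class FormatError(DimorphSeqError):
    """A file could not be parsed as the declared format."""


class DegenerateInputError(DimorphSeqError):
    """The input is structurally valid but admits no meaningful fit
    (e.g. all-zero coverage, a single sample, identical marker points)."""


class UnknownGeneError(DimorphSeqError):
    """A gene id was not found where it is required; the message names it."""
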