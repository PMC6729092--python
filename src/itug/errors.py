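"""Exception hierarchy for the iTUG analysis pipeline.

Every stage raises a subclass of :class:`ItugError` so that the pipeline
driver can abort with the stage name and the offending recording id.
"""


class ItugError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ItugError, ValueError):
    """A delimited-text recording or manifest does not match its dialect."""


class OnsetError(ItugError, ValueError):
    """No movement onset could be located in a signal."""


class SegmentationError(ItugError, ValueError):
    """TUG phases could not be identified from yaw/pitch angles."""


class SpectrumError(ItugError, ValueError):
    """A power spectrum is undefined (e.g. all-zero input) or degenerate."""


class DesignError(ItugError, ValueError):
    """A statistical design is inestimable (empty cells, bad factors)."""


class DegenerateInputError(ItugError, ValueError):
    """Zero-variance or otherwise degenerate statistical input."""
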