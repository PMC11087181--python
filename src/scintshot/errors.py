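"""Exception hierarchy.

Every failure mode raised by this package derives from :class:`StarshotError`
so callers (and the CLI) can distinguish analysis failures from programming
errors.  Detection-type failures map to CLI exit code 2, bad inputs to 3.
"""


class StarshotError(Exception):
    """Base class for all scintshot errors."""


class BadInputError(StarshotError):
    """Malformed file, config, or argument (CLI exit code 3)."""


class ParseError(BadInputError):
    """A session CSV row or config entry could not be parsed."""


class GeometryError(StarshotError):
    """A geometric precondition is violated (parallel lines, out-of-bounds)."""


class DetectionError(StarshotError):
    """A fiducial or beam feature could not be found (CLI exit code 2)."""


class AmbiguityError(DetectionError):
    """More than one equally plausible candidate was found."""


class LowContrastError(DetectionError):
    """An intensity profile has no usable peak above background."""


class ExtractionError(DetectionError):
    """Star-line extraction failed (unpaired peaks, bad ring profile)."""


class InsufficientDataError(DetectionError):
    """Fewer features than the analysis mathematically requires."""


class NumericalError(StarshotError):
    """An iterative solver failed to converge."""
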