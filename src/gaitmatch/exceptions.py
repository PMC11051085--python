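"""Exception hierarchy shared across the package."""


class GaitMatchError(Exception):
    """Base class for all package-specific errors."""


class PoseParseError(GaitMatchError, ValueError):
    """A pose file is malformed (message names the offending frame)."""


class AmbiguousFrameError(GaitMatchError, ValueError):
    """A frame contains more than one detected person."""


class EmptyInputError(GaitMatchError, ValueError):
    """An input file or sequence contains no usable frames."""


class DegradedInputError(GaitMatchError, ValueError):
    """Cleaning dropped too many frames for the sequence to be trusted."""


class DegenerateTriangleError(GaitMatchError, ValueError):
    """A joint triple with coincident points cannot define an angle."""


class InsufficientDataError(GaitMatchError, ValueError):
    """Fewer frames than an operation requires (ranking, correlation, DTW)."""


class ShapeMismatchError(GaitMatchError, ValueError):
    """Two inputs that must share a shape or dimensionality do not."""


class ConfigurationError(GaitMatchError, ValueError):
    """Invalid parameter ranges or incompatible feature configuration."""


class NoCandidatesError(GaitMatchError, ValueError):
    """A gallery view holds no entries to match against."""


class NoVotesError(GaitMatchError, ValueError):
    """Majority voting received no per-view identities."""
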