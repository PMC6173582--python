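"""Exception hierarchy shared across the pipeline."""


class UndulalabError(Exception):
    """Base class for all package errors."""


class ParameterError(UndulalabError):
    """Invalid generator or analysis parameters."""


class RenderError(UndulalabError):
    """Synthetic rendering failed (e.g. worm out of frame)."""


class NoWormError(UndulalabError):
    """No non-border foreground component found in a frame."""


class ThresholdError(UndulalabError):
    """Frame cannot be thresholded (e.g. constant image)."""


class GeometryError(UndulalabError):
    """ROI or point geometry invalid (outside frame, zero area, coincident)."""


class EmptySeriesError(UndulalabError):
    """An operation received a series with no valid frames."""


class BaselineError(UndulalabError):
    """Track too short to establish the 5 s length baseline."""


class ProtocolError(UndulalabError):
    """Illumination-protocol epoch falls outside the recording."""


class NormalizationError(UndulalabError):
    """Trace normalization undefined (zero mean, non-positive denominator)."""


class RatioError(UndulalabError):
    """Ratiometric trace undefined (CFP <= 0 at used frames)."""


class UndefinedRatioError(UndulalabError):
    """Dorso-ventral ratio undefined (missing dorsal or ventral samples)."""


class AmbiguityError(UndulalabError):
    """Spot-identity assignment ambiguous in a frame."""


class RankError(UndulalabError):
    """Requested more principal components than the library rank."""


class InputError(UndulalabError):
    """Malformed input series (non-monotonic time, too short, ...)."""
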