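"""Exception hierarchy shared across the package."""


class LVAtlasError(Exception):
    """Base class for all lvatlas errors."""


class InvalidParameterError(LVAtlasError, ValueError):
    """A configuration or geometry parameter is out of its valid range."""


class DimensionError(LVAtlasError, ValueError):
    """Shape vectors, atlases or predictor matrices disagree in dimension."""


class GeometryError(LVAtlasError, ValueError):
    """A mesh is open, degenerate or otherwise unusable for volumetry."""


class MissingDataError(LVAtlasError, KeyError):
    """A required clinical covariate is absent; the message names the field."""
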