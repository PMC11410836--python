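"""Exception hierarchy used across the measurement pipeline."""


class HalluxmetryError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(HalluxmetryError):
    """A segment or construction has no usable direction (e.g. zero length)."""


class BoundsError(HalluxmetryError):
    """Coordinates fall outside the owning image."""


class ConfigurationError(HalluxmetryError):
    """An invalid or out-of-contract configuration value."""


class AnnotationSchemaError(HalluxmetryError):
    """An annotation document violates the JSON schema."""


class InsufficientSignalError(HalluxmetryError):
    """A heatmap channel has too few supra-threshold pixels to fit an axis."""


class DegenerateAxisError(HalluxmetryError):
    """The supra-threshold support is isotropic; no principal direction exists."""


class LayoutError(HalluxmetryError):
    """A phantom layout would place bones outside the image."""
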