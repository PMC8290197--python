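"""Exception hierarchy for msilazy."""


class MsiLazyError(Exception):
    """Base class for all msilazy errors."""


class ImzmlParseError(MsiLazyError):
    """Malformed or incomplete imzML XML."""


class IntegrityError(MsiLazyError):
    """Binary container inconsistent with the XML metadata (UUID, offsets, duplicate pixels)."""


class DialectError(MsiLazyError):
    """Spectra violate the requested imzML dialect (e.g. differing m/z axes under 'continuous')."""


class DegenerateSpectrumError(MsiLazyError):
    """A normalization factor evaluated to a non-positive value (e.g. all-zero spectrum)."""


class MissingFactorError(MsiLazyError):
    """In-file normalization requested but the spectrum record carries no factor."""


class GeometryError(MsiLazyError):
    """Raster shape mismatch between images that must share geometry."""


class EmptyWindowError(MsiLazyError):
    """Requested m/z window does not overlap the dataset's m/z range."""


class RegistrationError(MsiLazyError):
    """Image registration cannot run (degenerate image, backend failure)."""
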