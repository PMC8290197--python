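"""Ion-image generation: per-pixel reduction of an m/z window.

An ion image collapses, for every valid pixel, the processed intensities
whose m/z falls in the closed interval [center - tol, center + tol] into a
single value (mean, max, sum or median).  Spectra are loaded lazily and
discarded after reduction, so generating an ion image never holds more than
a worker's current spectrum in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artefacts import raster_shape, _pixel_key
from .errors import EmptyWindowError, GeometryError
from .imzml import DatasetMetadata, Spectrum, iterate_spectra_chunked, read_spectrum
from .signal import SignalParams, process_spectrum

__all__ = ["IonImageRequest", "generate_ion_image", "apply_mask"]

_REDUCERS = {
    "mean": np.mean,
    "max": np.max,
    "sum": np.sum,
    "median": np.median,
}


@dataclass
class IonImageRequest:
    """m/z window plus reduction and processing options for one ion image."""

    center_mz: float
    tolerance: float
    reducer: str = "max"
    signal: SignalParams = field(default_factory=SignalParams)
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.reducer not in _REDUCERS:
            raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}")


def generate_ion_image(
    meta: DatasetMetadata, request: IonImageRequest, *, n_workers: int = 1
) -> np.ndarray:
    """Render the ion image for an m/z window, one lazy pass over the pixels.

    Pixels without a spectrum, pixels excluded by ``request.mask`` and
    pixels whose window contains no samples are set to 0.  The result is
    independent of the worker count.
    """
    lo = request.center_mz - request.tolerance
    hi = request.center_mz + request.tolerance

    first = read_spectrum(meta, 0)
    if meta.mode == "continuous":
        if first.mz[-1] < lo or first.mz[0] > hi:
            raise EmptyWindowError(
                f"window [{lo}, {hi}] does not overlap m/z range "
                f"[{first.mz[0]}, {first.mz[-1]}]"
            )

    shape = raster_shape(meta)
    if request.mask is not None and request.mask.shape != shape:
        raise GeometryError(
            f"request mask shape {request.mask.shape} != raster shape {shape}"
        )

    image = np.zeros(shape, dtype=np.float64)
    reduce_fn = _REDUCERS[request.reducer]
    records = meta.spectra

    def per_spectrum(spectrum: Spectrum):
        rec = records[spectrum.index]
        key = _pixel_key(meta, rec)
        if request.mask is not None and request.mask[key] == 0:
            return 0
        _f, proc = process_spectrum(spectrum, request.signal, rec)
        mz = np.asarray(proc.mz)
        a = np.searchsorted(mz, lo, side="left")
        b = np.searchsorted(mz, hi, side="right")
        if b > a:
            image[key] = float(reduce_fn(proc.intensity[a:b]))
        return 1

    iterate_spectra_chunked(meta, n_workers, per_spectrum, lambda x, y: x + y)
    return image


def apply_mask(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero a raster outside a {0,1} mask of identical shape."""
    raster = np.asarray(raster)
    mask = np.asarray(mask)
    if raster.shape != mask.shape:
        raise GeometryError(f"shape mismatch: raster {raster.shape} vs mask {mask.shape}")
    return np.where(mask != 0, raster, 0)
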