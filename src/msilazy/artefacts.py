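"""In-memory dataset artefacts and the core memory model.

A loaded MSI dataset is represented by four same-geometry rasters
(ion-image placeholder, per-pixel normalization factors, spectrum-index map,
validity mask) plus three overview spectra (skyline = elementwise maximum,
sum, mean), all computed in a single chunked pass over the spectra.  Only
these artefacts are retained: memory is O(|I| + |S|) where |I| is the pixel
count and |S| the spectral depth, independent of the binary container size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError
from .imzml import DatasetMetadata, Spectrum, iterate_spectra_chunked, read_spectrum
from .signal import SignalParams, process_spectrum

__all__ = [
    "ImageArtefacts",
    "OverviewSpectra",
    "initialize_artefacts",
    "estimate_memory",
    "raster_shape",
]


@dataclass
class ImageArtefacts:
    """The four same-geometry rasters kept per dataset.

    I_ion: float64 placeholder for generated ion images; I_norm: float64
    per-pixel normalization factors (0 outside the mask); I_index: int32
    spectrum ordinals (-1 at invalid pixels); I_mask: int16 {0,1} validity.
    """

    I_ion: np.ndarray
    I_norm: np.ndarray
    I_index: np.ndarray
    I_mask: np.ndarray


@dataclass
class OverviewSpectra:
    """Skyline (max), sum and mean spectra over all pixels, plus their axis."""

    mz_axis: np.ndarray
    skyline: np.ndarray
    sum: np.ndarray
    mean: np.ndarray


def raster_shape(meta: DatasetMetadata) -> tuple[int, ...]:
    """(height, width) for single-slice data, (depth, height, width) for 3D."""
    if meta.image_depth > 1:
        return (meta.image_depth, meta.image_height, meta.image_width)
    return (meta.image_height, meta.image_width)


def _pixel_key(meta: DatasetMetadata, rec) -> tuple[int, ...]:
    # imzML positions are 1-based; internal rasters are 0-based row-major.
    if meta.image_depth > 1:
        return (rec.z - 1, rec.y - 1, rec.x - 1)
    return (rec.y - 1, rec.x - 1)


def initialize_artefacts(
    meta: DatasetMetadata,
    processing: SignalParams | None = None,
    *,
    n_workers: int = 1,
    common_axis_edges: np.ndarray | None = None,
) -> tuple[ImageArtefacts, OverviewSpectra]:
    """Single chunked pass building the image artefacts and overview spectra.

    Every spectrum is read lazily, pushed through the configured signal
    chain, and folded into the skyline/sum accumulators; its normalization
    factor lands in I_norm and its ordinal in I_index.  Spectrum data are
    discarded after processing.

    Parameters
    ----------
    processing
        Signal chain applied before the overviews are accumulated (pass the
        default ``SignalParams()`` or None for raw overviews).
    common_axis_edges
        Required for processed (per-spectrum axis) data: ascending bin edges
        defining the common overview axis; each spectrum's centroids are
        accumulated into these bins.  Ignored for continuous data.
    """
    if processing is None:
        processing = SignalParams()
    if meta.n_spectra == 0:
        raise ValueError("dataset has no spectra")

    if meta.mode == "processed":
        if common_axis_edges is None:
            raise ValueError(
                "processed data needs an explicit common axis (bin edges) "
                "for overview spectra"
            )
        edges = np.asarray(common_axis_edges, dtype=np.float64)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("common_axis_edges must be ascending with >= 2 entries")
        mz_axis = 0.5 * (edges[:-1] + edges[1:])
    else:
        edges = None
        mz_axis = np.asarray(read_spectrum(meta, 0).mz, dtype=np.float64)

    shape = raster_shape(meta)
    I_ion = np.zeros(shape, dtype=np.float64)
    I_norm = np.zeros(shape, dtype=np.float64)
    I_index = np.full(shape, -1, dtype=np.int32)
    I_mask = np.zeros(shape, dtype=np.int16)

    # Pixel uniqueness is checked up-front so worker threads can then write
    # to disjoint raster cells without locking.
    seen: set[tuple[int, ...]] = set()
    for rec in meta.spectra:
        key = _pixel_key(meta, rec)
        if key in seen:
            raise IntegrityError(
                f"two spectra map to pixel {key} (spectrum {rec.index})"
            )
        seen.add(key)

    depth = len(mz_axis)
    records = meta.spectra

    def per_spectrum(spectrum: Spectrum):
        rec = records[spectrum.index]
        f, proc = process_spectrum(spectrum, processing, rec)
        if edges is not None:
            inten, _ = np.histogram(proc.mz, bins=edges, weights=proc.intensity)
        else:
            inten = np.asarray(proc.intensity, dtype=np.float64)
            if len(inten) != depth:
                raise IntegrityError(
                    f"spectrum {spectrum.index}: depth {len(inten)} != axis {depth}"
                )
        key = _pixel_key(meta, rec)
        I_norm[key] = f
        I_index[key] = spectrum.index
        I_mask[key] = 1
        return inten, inten.copy()

    def reducer(a, b):
        return np.maximum(a[0], b[0]), a[1] + b[1]

    skyline, total = iterate_spectra_chunked(meta, n_workers, per_spectrum, reducer)
    mean = total / meta.n_spectra
    artefacts = ImageArtefacts(I_ion=I_ion, I_norm=I_norm, I_index=I_index, I_mask=I_mask)
    overviews = OverviewSpectra(mz_axis=mz_axis, skyline=skyline, sum=total, mean=mean)
    return artefacts, overviews


def estimate_memory(
    n_pixels: int,
    depth: int,
    n_threads: int,
    sizeof_double: int = 8,
    sizeof_int: int = 4,
    sizeof_short: int = 2,
) -> int:
    """Closed-form core-memory estimate in bytes.

    E = |I| * (2*d_double + d_int + d_short) + (3 + T) * |S| * d_double:
    two double rasters, an int raster and a short raster over |I| pixels,
    three overview spectra of depth |S|, and one working spectrum per thread.
    """
    if min(n_pixels, depth, n_threads, sizeof_double, sizeof_int, sizeof_short) < 0:
        raise ValueError("all arguments must be non-negative")
    return n_pixels * (2 * sizeof_double + sizeof_int + sizeof_short) + (
        3 * depth + n_threads * depth
    ) * sizeof_double
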