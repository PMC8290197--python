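"""Per-spectrum signal processing: normalization, smoothing, baseline removal.

The processing chain is applied in a fixed order — normalize, smooth,
baseline-correct — matching common MSI practice (pixel-to-pixel intensity
scaling is removed first, then high-frequency noise, then the slowly varying
chemical/electronic baseline).

Normalization divides every intensity by a per-spectrum scalar f
(``S(j) = S_old(j) / f``), where f is the total ion count (TIC), the median
intensity, a factor stored in the imzML file, or 1 when disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion, median_filter
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, MissingFactorError
from .imzml import Spectrum, SpectrumRecord

__all__ = [
    "SignalParams",
    "normalization_factor",
    "normalize",
    "smooth_savitzky_golay",
    "baseline_correct",
    "process_spectrum",
]

NORMALIZATION_METHODS = ("none", "tic", "median", "infile")
BASELINE_METHODS = ("none", "tophat", "running_median")


@dataclass
class SignalParams:
    """Configuration of the per-spectrum processing chain.

    Attributes
    ----------
    normalization_method : {'none', 'tic', 'median', 'infile'}
    sg_window : int or None
        Savitzky-Golay window length in samples (odd, >= 3); None (default)
        disables smoothing.  There is no standardized value; windows of
        5-9 samples are typical for profile MALDI-TOF data, sized so the
        window stays narrower than the peaks it should preserve.
    sg_order : int
        Polynomial order of the smoothing fit; must be < sg_window.
    baseline_method : {'none', 'tophat', 'running_median'}
    baseline_halfwidth : int
        Half-width, in samples, of the flat structuring element / median
        window (full width 2*halfwidth + 1).
    """

    normalization_method: str = "none"
    sg_window: int | None = None
    sg_order: int = 2
    baseline_method: str = "none"
    baseline_halfwidth: int = 25

    def __post_init__(self):
        if self.normalization_method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization {self.normalization_method!r}")
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.sg_window is not None:
            if self.sg_window < 3 or self.sg_window % 2 == 0:
                raise ValueError("sg_window must be an odd integer >= 3")
            if self.sg_order >= self.sg_window:
                raise ValueError("sg_order must be < sg_window")
        if self.baseline_halfwidth < 1:
            raise ValueError("baseline_halfwidth must be >= 1")


def normalization_factor(
    spectrum: Spectrum, method: str, record: SpectrumRecord | None = None
) -> float:
    """Per-spectrum normalization scalar f.

    tic -> sum of intensities; median -> median intensity; infile -> the
    factor stored in the spectrum's imzML record; none -> 1.
    """
    if len(spectrum.intensity) == 0:
        raise DegenerateSpectrumError("empty spectrum")
    if method == "none":
        return 1.0
    if method == "tic":
        f = float(np.sum(spectrum.intensity, dtype=np.float64))
    elif method == "median":
        f = float(np.median(spectrum.intensity))
    elif method == "infile":
        if record is None or record.in_file_normalization_factor is None:
            raise MissingFactorError(
                f"spectrum {spectrum.index}: in-file normalization selected but "
                "no factor is stored in the file"
            )
        f = float(record.in_file_normalization_factor)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    if f <= 0:
        raise DegenerateSpectrumError(
            f"spectrum {spectrum.index}: {method} normalization factor {f} <= 0"
        )
    return f


def normalize(spectrum: Spectrum, f: float) -> Spectrum:
    """Divide every intensity by f; the m/z axis is untouched."""
    if f <= 0:
        raise ValueError(f"normalization factor must be > 0, got {f}")
    return Spectrum(
        index=spectrum.index,
        mz=spectrum.mz,
        intensity=np.asarray(spectrum.intensity, dtype=np.float64) / f,
    )


def smooth_savitzky_golay(spectrum: Spectrum, window: int, order: int) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    Each point is replaced by the centre value of a polynomial of the given
    order fit over the window; the edges are filled by evaluating the
    polynomial fitted to the first/last full window (``mode='interp'``).
    """
    n = len(spectrum.intensity)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > n:
        raise ValueError(f"window {window} larger than spectrum length {n}")
    if order >= window:
        raise ValueError("order must be < window")
    smoothed = savgol_filter(
        np.asarray(spectrum.intensity, dtype=np.float64), window, order, mode="interp"
    )
    return Spectrum(index=spectrum.index, mz=spectrum.mz, intensity=smoothed)


def _running_median(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Windowed median with shrinking windows at the edges.

    Interior points use the full window of width 2*halfwidth+1; within
    halfwidth of either end the window is clipped to the array, so the first
    point's window is x[0 : halfwidth+1].  Even-length windows take the
    midpoint mean, numpy's median convention.
    """
    n = len(x)
    full = 2 * halfwidth + 1
    if n >= full:
        out = median_filter(x, size=full, mode="nearest")
        for i in range(halfwidth):
            out[i] = np.median(x[: i + halfwidth + 1])
            out[n - 1 - i] = np.median(x[n - 1 - i - halfwidth :])
    else:
        out = np.empty_like(x)
        for i in range(n):
            out[i] = np.median(x[max(0, i - halfwidth) : i + halfwidth + 1])
    return out


def baseline_correct(
    spectrum: Spectrum, method: str, halfwidth: int
) -> tuple[np.ndarray, Spectrum]:
    """Estimate and subtract the baseline.

    tophat: morphological opening (erosion then dilation) with a flat
    structuring element of width 2*halfwidth+1 — anti-extensive, so the
    baseline never exceeds the signal.  running_median: windowed median of
    the same width, edges by shrinking windows.  The corrected spectrum is
    clipped at zero.

    Returns ``(baseline, corrected_spectrum)``.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    x = np.asarray(spectrum.intensity, dtype=np.float64)
    width = 2 * halfwidth + 1
    if method == "tophat":
        eroded = grey_erosion(x, size=width, mode="reflect")
        baseline = grey_dilation(eroded, size=width, mode="reflect")
    elif method == "running_median":
        baseline = _running_median(x, halfwidth)
    elif method == "none":
        baseline = np.zeros_like(x)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    corrected = np.maximum(x - baseline, 0.0)
    return baseline, Spectrum(index=spectrum.index, mz=spectrum.mz, intensity=corrected)


def process_spectrum(
    spectrum: Spectrum,
    params: SignalParams,
    record: SpectrumRecord | None = None,
) -> tuple[float, Spectrum]:
    """Run the full chain: normalize -> smooth -> baseline-correct.

    Returns the normalization factor f together with the processed spectrum.
    """
    f = normalization_factor(spectrum, params.normalization_method, record)
    out = normalize(spectrum, f)
    if params.sg_window is not None and len(out.intensity) >= params.sg_window:
        out = smooth_savitzky_golay(out, params.sg_window, params.sg_order)
    if params.baseline_method != "none":
        _, out = baseline_correct(out, params.baseline_method, params.baseline_halfwidth)
    return f, out
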