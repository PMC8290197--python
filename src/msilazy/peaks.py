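"""Peak detection and peak-list manipulation.

Peaks are local maxima of a processed spectrum inside a sliding window,
kept when they rise above a multiple of the noise level; the noise level is
the median absolute deviation (MAD) of the intensities, scaled by 1.4826 so
it estimates a Gaussian sigma.  Monoisotopic peaks are located by Poisson
peak harvesting: candidate isotope chains (spacing ~1.00235/z Da) are scored
against a Poisson intensity envelope whose rate grows linearly with mass,
which is the averagine-style approximation for peptide isotope patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .imzml import Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "estimate_noise_mad",
    "pick_peaks",
    "bin_peaks",
    "poisson_monoisotopic",
    "sample_at_peaks",
]

MAD_SCALE = 1.4826  # consistency constant: MAD -> Gaussian sigma
ISOTOPE_SPACING = 1.00235  # average isotopologue mass difference, Da
DEFAULT_LAMBDA_SLOPE = 0.000594  # Poisson rate per Da of monoisotopic mass


@dataclass
class Peak:
    mz: float
    intensity: float
    snr: float = 0.0
    isotope_group: int | None = None
    charge: int | None = None
    is_monoisotopic: bool = True


@dataclass
class PeakList:
    """Peaks in strictly ascending m/z order, with provenance."""

    peaks: list[Peak] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak list must be strictly ascending in m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def monoisotopic(self) -> "PeakList":
        return PeakList(
            [p for p in self.peaks if p.is_monoisotopic], provenance=self.provenance
        )


def estimate_noise_mad(intensities: np.ndarray) -> float:
    """Robust noise level: 1.4826 * median(|x - median(x)|).

    Insensitive to isolated spikes: a handful of large peaks on a flat
    background leaves the estimate at the background's spread.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty intensity array")
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def pick_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 4.0,
    halfwindow: int = 10,
    provenance: str = "",
) -> PeakList:
    """Sliding-window local-maxima peak picking above an SNR threshold.

    Index i is a peak iff its intensity equals the maximum over
    [i-halfwindow, i+halfwindow] (clipped at the spectrum edges), the window
    is not constant (so flat stretches yield nothing), the intensity exceeds
    snr_threshold * MAD-noise, and i is the leftmost index of a plateau of
    equal maxima.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be > 0")
    if halfwindow < 1:
        raise ValueError("halfwindow must be >= 1")
    x = np.asarray(spectrum.intensity, dtype=np.float64)
    n = len(x)
    if n == 0:
        return PeakList([], provenance=provenance)
    noise = estimate_noise_mad(x)
    size = 2 * halfwindow + 1
    # mode='constant' with +/-inf padding makes the filters equal to the
    # clipped-window max/min at the edges.
    winmax = maximum_filter1d(x, size=size, mode="constant", cval=-np.inf)
    winmin = minimum_filter1d(x, size=size, mode="constant", cval=np.inf)
    candidate = (x == winmax) & (winmax > winmin) & (x > snr_threshold * noise)

    peaks: list[Peak] = []
    idx = np.flatnonzero(candidate)
    prev = -2
    for i in idx:
        if i == prev + 1 and x[i] == x[prev]:
            prev = i  # continuation of a plateau; leftmost already taken
            continue
        snr = float(x[i] / noise) if noise > 0 else math.inf
        peaks.append(Peak(mz=float(spectrum.mz[i]), intensity=float(x[i]), snr=snr))
        prev = i
    return PeakList(peaks, provenance=provenance)


def bin_peaks(
    lists: Iterable[PeakList | Sequence[Peak]],
    tolerance: float,
    unit: str = "da",
) -> PeakList:
    """Greedy single-linkage binning of pooled peak lists.

    Pooled peaks are sorted by m/z; a new bin starts whenever the gap to the
    previous peak exceeds the tolerance (in Da, or in ppm of the previous
    peak's m/z).  Each bin's m/z is the intensity-weighted mean of its
    members and its intensity the maximum member intensity.  The bins'
    member sets partition the input.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if unit not in ("da", "ppm"):
        raise ValueError("unit must be 'da' or 'ppm'")
    pooled: list[Peak] = []
    for lst in lists:
        pooled.extend(lst)
    if not pooled:
        return PeakList([])
    pooled.sort(key=lambda p: p.mz)

    bins: list[list[Peak]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        tol = tolerance if unit == "da" else tolerance * 1e-6 * prev.mz
        if cur.mz - prev.mz > tol:
            bins.append([cur])
        else:
            bins[-1].append(cur)

    out: list[Peak] = []
    for members in bins:
        w = np.array([max(p.intensity, 0.0) for p in members])
        mzs = np.array([p.mz for p in members])
        center = float(np.average(mzs, weights=w)) if w.sum() > 0 else float(mzs.mean())
        out.append(
            Peak(
                mz=center,
                intensity=float(max(p.intensity for p in members)),
                snr=float(max(p.snr for p in members)),
            )
        )
    return PeakList(out, provenance="binned")


def _poisson_weights(lam: float, k: int) -> np.ndarray:
    ks = np.arange(k)
    return np.exp(-lam) * lam**ks / np.array([math.factorial(int(j)) for j in ks])


def poisson_monoisotopic(
    peaks: PeakList,
    charges: Sequence[int] = (1,),
    spacing_tolerance: float = 0.01,
    lambda_slope: float = DEFAULT_LAMBDA_SLOPE,
    score_threshold: float = 0.95,
) -> PeakList:
    """Flag monoisotopic peaks by Poisson envelope harvesting.

    Starting at each unassigned peak (in ascending m/z), a candidate chain of
    peaks spaced 1.00235/z (within the spacing tolerance) is assembled
    greedily for every charge z.  A chain's relative intensities are compared
    with Poisson weights p_k = exp(-lam) lam^k / k! where
    lam = lambda_slope * monoisotopic m/z, via the normalized dot product
    (cosine score).  The best-scoring charge hypothesis wins; if its score
    clears the threshold, only the chain's first member stays monoisotopic
    and the remaining members are flagged as isotopologues.  Peaks in no
    accepted chain pass through as monoisotopic singletons.
    """
    if not charges:
        raise ValueError("charge set must be non-empty")
    n = len(peaks)
    out = [replace(p) for p in peaks]
    assigned = [False] * n
    group_id = 0
    mzs = np.array([p.mz for p in peaks])

    def assemble(start: int, spacing: float) -> list[int]:
        chain = [start]
        while True:
            target = mzs[chain[-1]] + spacing
            lo = np.searchsorted(mzs, target - spacing_tolerance)
            hi = np.searchsorted(mzs, target + spacing_tolerance, side="right")
            nxt = None
            best = spacing_tolerance + 1
            for j in range(lo, hi):
                if assigned[j] or j in chain:
                    continue
                d = abs(mzs[j] - target)
                if d < best:
                    best, nxt = d, j
            if nxt is None:
                return chain
            chain.append(nxt)

    def score_chain(chain: list[int]) -> float:
        # The Poisson rate grows linearly with the monoisotopic m/z.
        lam = lambda_slope * mzs[chain[0]]
        model = _poisson_weights(lam, len(chain))
        observed = np.array([peaks[j].intensity for j in chain], dtype=np.float64)
        denom = np.linalg.norm(observed) * np.linalg.norm(model)
        return float(observed @ model / denom) if denom > 0 else 0.0

    for start in range(n):
        if assigned[start]:
            continue
        best_score, best_chain, best_z = -1.0, None, None
        for z in sorted(charges):
            chain = assemble(start, ISOTOPE_SPACING / z)
            if len(chain) < 2:
                continue
            score = score_chain(chain)
            # Prefer the higher score; on near-ties the longer chain
            # (more explained peaks) wins.
            key = (round(score, 6), len(chain))
            if best_chain is None or key > (round(best_score, 6), len(best_chain)):
                best_score, best_chain, best_z = score, chain, z
        if best_chain is not None and best_score >= score_threshold:
            for rank, j in enumerate(best_chain):
                assigned[j] = True
                out[j].isotope_group = group_id
                out[j].charge = best_z
                out[j].is_monoisotopic = rank == 0
            group_id += 1
    return PeakList(out, provenance=peaks.provenance)


def sample_at_peaks(
    spectrum: Spectrum, common_peaks: PeakList, tolerance: float
) -> np.ndarray:
    """Max spectrum intensity within +/- tolerance of each common peak.

    Returns an array of length |common_peaks|; windows containing no sample
    yield 0.  Used to resample a spectrum onto a shared centroid axis for
    continuous-centroid export.
    """
    mz = np.asarray(spectrum.mz)
    inten = np.asarray(spectrum.intensity, dtype=np.float64)
    out = np.zeros(len(common_peaks), dtype=np.float64)
    centers = common_peaks.mz
    lo = np.searchsorted(mz, centers - tolerance, side="left")
    hi = np.searchsorted(mz, centers + tolerance, side="right")
    for k in range(len(centers)):
        if hi[k] > lo[k]:
            out[k] = inten[lo[k] : hi[k]].max()
    return out
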