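import numpy as np
import pytest

from msilazy import PhantomSpec, Region, make_phantom
from msilazy.signal import SignalParams

# The full processing chain used throughout: TIC normalization,
# Savitzky-Golay smoothing, top-hat baseline correction.
FULL_CHAIN = SignalParams(
    normalization_method="tic",
    sg_window=5,
    sg_order=2,
    baseline_method="tophat",
    baseline_halfwidth=25,
)


@pytest.fixture(scope="session")
def tiny_phantom(tmp_path_factory):
    """8x8 px, shallow axis: fast I/O-oriented fixture."""
    spec = PhantomSpec(width=8, height=8, axis_depth=256, mz_range=(600.0, 700.0), seed=101)
    return make_phantom(spec, tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def phantom64(tmp_path_factory):
    """64x64 px at the generator's default spectral conditions."""
    spec = PhantomSpec(width=64, height=64, seed=123)
    return spec, make_phantom(spec, tmp_path_factory.mktemp("phantom64"))


@pytest.fixture(scope="session")
def two_class_phantom(tmp_path_factory):
    """Two disjoint regions with one analyte each (classification phantom)."""
    spec = PhantomSpec(
        width=24,
        height=24,
        axis_depth=600,
        mz_range=(600.0, 720.0),
        regions=[
            Region(center=(0.28, 0.5), axes=(0.45, 0.8), masses=(640.0,), abundances=(1.0,)),
            Region(center=(0.75, 0.5), axes=(0.4, 0.8), masses=(690.0,), abundances=(1.0,)),
        ],
        seed=21,
    )
    return spec, make_phantom(spec, tmp_path_factory.mktemp("two_class"))


def brute_force_peak_indices(x: np.ndarray, snr_threshold: float, halfwindow: int):
    """Independent double-loop local-maxima scan (test oracle).

    A peak index satisfies: equals the max of its clipped window, the window
    is not constant, intensity exceeds snr_threshold * MAD noise, and it is
    the leftmost index of a run of equal candidates.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    noise = 1.4826 * np.median(np.abs(x - np.median(x)))
    candidates = []
    for i in range(n):
        lo, hi = max(0, i - halfwindow), min(n, i + halfwindow + 1)
        window = x[lo:hi]
        if x[i] != window.max():
            continue
        if window.max() == window.min():
            continue
        if not x[i] > snr_threshold * noise:
            continue
        candidates.append(i)
    # Keep only the leftmost index of each plateau run.
    out = []
    prev = -2
    for i in candidates:
        if i == prev + 1 and x[i] == x[prev]:
            prev = i
            continue
        out.append(i)
        prev = i
    return out
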