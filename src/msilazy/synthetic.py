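"""Deterministic synthetic MSI phantoms.

The generator emulates the structure of MALDI-TOF imaging data well enough
to exercise every stage of the pipeline with known ground truth: per-pixel
profile spectra composed of Gaussian peak shapes with Poisson-weighted
isotope envelopes, a smooth exponentially decaying baseline, additive
Gaussian noise, and pixel-to-pixel multiplicative intensity variation (the
effect TIC normalization removes).  Slice stacks add a small smooth radial
morphology drift between consecutive sections plus known rigid transforms
and consistently transformed landmark sets.

It does not model MALDI physics (matrix clusters, detector saturation,
mass-dependent resolution), so passing tests demonstrate algorithmic
correctness on idealized data, not instrument-level robustness.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .imzml import DatasetMetadata, PixelSpectrum, write_imzml
from .peaks import DEFAULT_LAMBDA_SLOPE, ISOTOPE_SPACING
from .registration import LandmarkSet, RigidTransform, TransformChain, apply_chain

__all__ = ["Region", "PhantomSpec", "Phantom", "SliceStack", "make_phantom", "make_slice_stack"]


@dataclass
class Region:
    """Elliptical tissue region carrying a set of analytes.

    center and axes are fractions of the image extent; masses in Da;
    abundances set each analyte's monoisotopic apex intensity.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    charge: int = 1
    render_weight: float = 1.0

    def mask(self, width: int, height: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        cx, cy = self.center[0] * (width - 1), self.center[1] * (height - 1)
        ax, ay = self.axes[0] * width / 2, self.axes[1] * height / 2
        return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _default_regions() -> list[Region]:
    # Three regions x five analytes in a lipid-like m/z range.
    return [
        Region(center=(0.3, 0.3), axes=(0.38, 0.34),
               masses=(620.5, 688.2, 734.6, 810.3, 885.9),
               abundances=(1.0, 0.8, 1.2, 0.9, 0.7), render_weight=1.0),
        Region(center=(0.7, 0.35), axes=(0.3, 0.4),
               masses=(645.1, 703.8, 760.4, 826.7, 902.2),
               abundances=(0.9, 1.1, 0.8, 1.0, 0.6), render_weight=0.6),
        Region(center=(0.5, 0.72), axes=(0.5, 0.3),
               masses=(632.9, 715.5, 772.1, 841.6, 918.4),
               abundances=(1.1, 0.7, 1.0, 0.85, 0.95), render_weight=0.35),
    ]


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic phantom.

    Defaults: 128x128 pixels at 20 µm, m/z 600-1000 sampled at depth 2000
    (0.2 Da spacing), three elliptical regions with five analytes each,
    Gaussian peak sigma 0.25 Da, Poisson isotope envelopes at the averagine
    rate, an exponentially decaying baseline, 2% relative Gaussian noise and
    a 0.5-2.0x per-pixel intensity scaling.
    """

    width: int = 128
    height: int = 128
    pixel_size: float = 20.0  # µm
    mz_range: tuple[float, float] = (600.0, 1000.0)
    axis_depth: int = 2000
    regions: list[Region] = field(default_factory=_default_regions)
    isotope_spacing: float = ISOTOPE_SPACING
    lambda_slope: float = DEFAULT_LAMBDA_SLOPE
    n_isotopes: int = 4
    peak_shape_sigma: float = 0.25  # Da
    baseline_amplitude: float = 0.2
    baseline_decay: float = 0.008  # per Da
    noise_sigma: float = 0.02  # relative to unit analyte abundance
    tic_variation: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.axis_depth < 16:
            raise ValueError("axis_depth must be >= 16")
        if self.peak_shape_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("all scales must be positive")


@dataclass
class Phantom:
    """A generated phantom plus its ground truth."""

    meta: DatasetMetadata
    mz_axis: np.ndarray
    region_masks: list[np.ndarray]
    analyte_masses: list[tuple[float, ...]]
    tic_factors: np.ndarray
    baseline: np.ndarray
    clean_region_spectra: list[np.ndarray]


@dataclass
class SliceStack:
    """Consecutive-section fixture with known alignment ground truth."""

    slices: list[np.ndarray]
    true_chains: list[TransformChain]
    fixed_landmarks: LandmarkSet
    moving_landmarks: list[LandmarkSet]
    pixel_size: float


def _isotope_envelope(spec: PhantomSpec, axis, mass, abundance, charge):
    lam = spec.lambda_slope * mass
    out = np.zeros_like(axis)
    p0 = math.exp(-lam)
    for k in range(spec.n_isotopes):
        pk = math.exp(-lam) * lam**k / math.factorial(k)
        center = mass + k * spec.isotope_spacing / charge
        out += (abundance * pk / p0) * np.exp(
            -0.5 * ((axis - center) / spec.peak_shape_sigma) ** 2
        )
    return out


def make_phantom(spec: PhantomSpec, out_dir: str | os.PathLike, name: str = "phantom") -> Phantom:
    """Write a continuous-profile imzML phantom and return its ground truth.

    Every pixel's spectrum is the sum of the clean spectra of the regions
    containing it, plus the shared baseline, plus Gaussian noise, all scaled
    by the pixel's multiplicative intensity factor.  Identical seeds yield
    byte-identical files (the dataset UUID is drawn from the seeded RNG).
    """
    rng = np.random.default_rng(spec.seed)
    uuid = rng.bytes(16)
    lo, hi = spec.mz_range
    axis = np.linspace(lo, hi, spec.axis_depth)

    masks = [r.mask(spec.width, spec.height) for r in spec.regions]
    clean = []
    for region in spec.regions:
        s = np.zeros_like(axis)
        for mass, abundance in zip(region.masses, region.abundances):
            s += _isotope_envelope(spec, axis, mass, abundance, region.charge)
        clean.append(s)
    baseline = spec.baseline_amplitude * np.exp(-spec.baseline_decay * (axis - lo))

    tic_lo, tic_hi = spec.tic_variation
    tic_factors = rng.uniform(tic_lo, tic_hi, size=(spec.height, spec.width))

    def spectra():
        for y in range(spec.height):
            for x in range(spec.width):
                signal = baseline.copy()
                for mask, region_spectrum in zip(masks, clean):
                    if mask[y, x]:
                        signal += region_spectrum
                noise = rng.normal(0.0, spec.noise_sigma, size=spec.axis_depth)
                intensity = np.maximum(tic_factors[y, x] * (signal + noise), 0.0)
                yield PixelSpectrum(x=x + 1, y=y + 1, mz=axis, intensity=intensity)

    os.makedirs(out_dir, exist_ok=True)
    imzml_path = os.path.join(os.fspath(out_dir), name + ".imzML")
    meta = write_imzml(
        dict(
            image_width=spec.width,
            image_height=spec.height,
            pixel_size_x=spec.pixel_size,
            pixel_size_y=spec.pixel_size,
        ),
        spectra(),
        "continuous-profile",
        imzml_path,
        uuid=uuid,
    )
    return Phantom(
        meta=meta,
        mz_axis=axis,
        region_masks=masks,
        analyte_masses=[r.masses for r in spec.regions],
        tic_factors=tic_factors,
        baseline=baseline,
        clean_region_spectra=clean,
    )


def render_structure_image(spec: PhantomSpec) -> np.ndarray:
    """A smooth structure-rich raster of the phantom's region geometry."""
    image = np.full((spec.height, spec.width), 0.05)
    for region, weight in zip(spec.regions, (r.render_weight for r in spec.regions)):
        image += weight * region.mask(spec.width, spec.height)
    return gaussian_filter(image, sigma=1.5)


def _scale_about_center(image: np.ndarray, scale: float, spacing: float) -> np.ndarray:
    """Radial zoom about the image centre (morphology drift between sections)."""
    if scale == 1.0:
        return image.astype(np.float64)
    h, w = image.shape
    center = ((w - 1) * spacing / 2.0, (h - 1) * spacing / 2.0)
    import SimpleITK as sitk

    t = sitk.Similarity2DTransform()
    t.SetCenter(center)
    t.SetScale(1.0 / scale)  # resampling map shrinks coordinates to zoom in
    img = sitk.GetImageFromArray(np.ascontiguousarray(image, dtype=np.float64))
    img.SetSpacing((spacing, spacing))
    out = sitk.Resample(img, img, t, sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    return sitk.GetArrayFromImage(out)


def _default_landmarks(spec: PhantomSpec, rng) -> np.ndarray:
    pts = []
    for region in spec.regions:
        cx = region.center[0] * (spec.width - 1) * spec.pixel_size
        cy = region.center[1] * (spec.height - 1) * spec.pixel_size
        pts.append((cx, cy))
    # Fill up with jittered points around the region centres.
    while True:
        for region in spec.regions:
            cx = region.center[0] * (spec.width - 1) * spec.pixel_size
            cy = region.center[1] * (spec.height - 1) * spec.pixel_size
            dx, dy = rng.uniform(-0.1, 0.1, 2) * spec.width * spec.pixel_size
            pts.append((cx + dx, cy + dy))
        if len(pts) >= 32:
            return np.array(pts)


def make_slice_stack(
    spec: PhantomSpec,
    n_slices: int = 10,
    transforms: list[RigidTransform] | str = "random",
    landmarks_per_slice: int = 7,
    max_theta_degrees: float = 15.0,
    max_shift_px: float = 10.0,
    morphology_drift: float = 0.02,
) -> SliceStack:
    """Build consecutive-section rasters with known rigid ground truth.

    Slice i is the phantom's structure image, radially scaled by at most
    ``morphology_drift`` (smooth across the stack) and resampled through the
    inverse of its ground-truth transform, so applying the true chain to
    slice i recovers the reference geometry.  Landmarks are the same
    physical points expressed in each slice's frame via the true transform.
    Transform units are micrometres (physical), using the spec's pixel size.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    rng = np.random.default_rng(spec.seed + 1)
    base = render_structure_image(spec)
    px = spec.pixel_size
    center = ((spec.width - 1) * px / 2.0, (spec.height - 1) * px / 2.0)

    if transforms == "random":
        chains: list[RigidTransform] = []
        for i in range(n_slices):
            if i == 0:
                chains.append(RigidTransform.identity(center))
            else:
                theta = math.radians(rng.uniform(-max_theta_degrees, max_theta_degrees))
                tx, ty = rng.uniform(-max_shift_px, max_shift_px, 2) * px
                chains.append(RigidTransform(theta=theta, tx=tx, ty=ty, center=center))
    else:
        chains = list(transforms)

    fixed_pts = _default_landmarks(spec, rng)[:landmarks_per_slice]
    fixed = LandmarkSet(slice_id=0, points=fixed_pts, modality="reference")

    slices, true_chains, moving_sets = [], [], []
    for i, rigid in enumerate(chains):
        drift_scale = 1.0 + morphology_drift * math.sin(math.pi * i / max(n_slices - 1, 1))
        drifted = _scale_about_center(base, drift_scale, px)
        chain = TransformChain([rigid], slice_id=i)
        slices.append(apply_chain(drifted, TransformChain([rigid.inverse()]), spacing=(px, px)))
        true_chains.append(chain)
        moving = np.array([rigid.point(p) for p in fixed_pts])
        moving_sets.append(LandmarkSet(slice_id=i, points=moving, modality="reference"))
    return SliceStack(
        slices=slices,
        true_chains=true_chains,
        fixed_landmarks=fixed,
        moving_landmarks=moving_sets,
        pixel_size=px,
    )
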