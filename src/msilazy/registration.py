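"""Slice-to-slice registration and 3D stack reconstruction.

Consecutive tissue sections are aligned pairwise: a rigid (2D Euler:
rotation + translation) registration driven by Mattes mutual information
under a multi-resolution Gaussian pyramid, optionally refined by a B-spline
deformable step.  Starting from a user-chosen reference slice, the stack is
reconstructed bidirectionally — each slice is registered onto its already
*aligned* neighbour, so per-slice transforms accumulate the cumulative
drift.  Transforms are stored per slice as composable chains and applied to
ion images only; spectra are never resampled.

Conventions
-----------
A :class:`RigidTransform` is the resampling map: it sends a point in the
fixed/reference frame to the corresponding point in the moving slice's
frame (``aligned(x) = moving(T(x))``).  Mapping landmark coordinates from a
slice into the reference frame therefore uses the inverse
(:meth:`TransformChain.map_to_reference`).  All coordinates are physical
(micrometre) once a pixel spacing is given; the default spacing of 1 makes
them pixel units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .errors import RegistrationError

__all__ = [
    "RigidTransform",
    "TransformChain",
    "RegistrationParams",
    "LandmarkSet",
    "pre_rotate",
    "register_rigid",
    "register_deformable",
    "reconstruct_stack",
    "apply_chain",
    "landmark_error",
    "mattes_mi",
]


@dataclass
class RigidTransform:
    """2D Euler transform: rotation by theta about ``center``, then translation.

    Point map: ``y = Rot_theta(x - center) + center + (tx, ty)``, in the
    physical units of the images it was estimated from (pixels when the
    spacing is 1, micrometres otherwise).
    """

    theta: float  # radians
    tx: float
    ty: float
    center: tuple[float, float] = (0.0, 0.0)

    def to_sitk(self) -> sitk.Euler2DTransform:
        t = sitk.Euler2DTransform()
        t.SetCenter(self.center)
        t.SetAngle(self.theta)
        t.SetTranslation((self.tx, self.ty))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler2DTransform) -> "RigidTransform":
        return cls(
            theta=float(t.GetAngle()),
            tx=float(t.GetTranslation()[0]),
            ty=float(t.GetTranslation()[1]),
            center=tuple(t.GetCenter()),
        )

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "RigidTransform":
        return cls(theta=0.0, tx=0.0, ty=0.0, center=center)

    def point(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=np.float64)
        c = np.asarray(self.center)
        ct, st = math.cos(self.theta), math.sin(self.theta)
        rot = np.array([[ct, -st], [st, ct]])
        return (xy - c) @ rot.T + c + np.array([self.tx, self.ty])

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler2DTransform(self.to_sitk().GetInverse().Downcast())
        return RigidTransform.from_sitk(inv)


@dataclass
class TransformChain:
    """Ordered transform steps for one slice; list order is application order.

    The composed point map is ``steps[0](steps[1](...(x)))`` — the first
    step listed is the outermost resampling transform, matching the order in
    which the steps were estimated (rigid first, deformable refinement
    after).  Steps may be :class:`RigidTransform` or raw SimpleITK
    transforms (e.g. B-spline fields).
    """

    steps: list = field(default_factory=list)
    slice_id: int | None = None

    def composed(self) -> sitk.Transform:
        comp = sitk.CompositeTransform(2)
        # sitk composites apply the *last added* transform to the point
        # first; our convention applies the last listed step first.
        for step in self.steps:
            comp.AddTransform(step.to_sitk() if isinstance(step, RigidTransform) else step)
        return comp

    def map_to_reference(self, points: np.ndarray) -> np.ndarray:
        """Map moving-slice coordinates into the reference frame (inverse map).

        Rigid-only chains invert analytically.  Chains containing B-spline
        steps have no closed-form inverse; the inverse point is found by
        fixed-point iteration on the residual, which converges for the small
        smooth displacements these fields represent.
        """
        comp = self.composed()
        pts = np.asarray(points, dtype=np.float64)
        try:
            inv = comp.GetInverse()
            return np.array([inv.TransformPoint(tuple(p)) for p in pts])
        except RuntimeError:
            out = []
            for q in pts:
                x = q.copy()
                for _ in range(100):
                    residual = np.asarray(comp.TransformPoint(tuple(x))) - q
                    if np.linalg.norm(residual) < 1e-9:
                        break
                    x = x - residual
                out.append(x)
            return np.array(out)

    def map_from_reference(self, points: np.ndarray) -> np.ndarray:
        """Map reference-frame coordinates into the moving slice's frame."""
        comp = self.composed()
        pts = np.asarray(points, dtype=np.float64)
        return np.array([comp.TransformPoint(tuple(p)) for p in pts])

    def is_identity(self) -> bool:
        return all(
            isinstance(s, RigidTransform)
            and abs(s.theta) < 1e-12
            and abs(s.tx) < 1e-12
            and abs(s.ty) < 1e-12
            for s in self.steps
        )


@dataclass
class RegistrationParams:
    """Settings for the pairwise registration steps.

    Defaults follow common practice for serial-section MSI reconstruction:
    a 3-level Gaussian pyramid with downsampling factors 4, 2, 1; Mattes
    mutual information (32 bins, dense sampling — deterministic); 250
    optimizer iterations for the rigid step and 750 for the B-spline
    refinement, whose final control-point spacing is 0.8 mm on the original
    resolution (scaled per level by 2, 1.5, 1).
    """

    pyramid_levels: int = 3
    downsampling_factors: tuple = (4, 2, 1)
    metric: str = "mattes_mi"
    iterations: int = 250
    deformable_iterations: int = 750
    interpolation: str = "linear"
    grid_spacing_mm: float = 0.8
    grid_spacing_scales: tuple = (2.0, 1.5, 1.0)
    histogram_bins: int = 32
    seed: int = 0

    def __post_init__(self):
        if len(self.downsampling_factors) != self.pyramid_levels:
            raise ValueError("downsampling_factors length must equal pyramid_levels")
        if self.metric not in ("mattes_mi", "mean_squares"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class LandmarkSet:
    """Physical-coordinate reference points on one slice."""

    slice_id: int
    points: np.ndarray  # (N, 2) physical coordinates
    modality: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) < 1:
            raise ValueError("landmark set needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")


def _to_sitk(image: np.ndarray, spacing=(1.0, 1.0)) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(image, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _image_center(image: np.ndarray, spacing=(1.0, 1.0)) -> tuple[float, float]:
    h, w = image.shape
    return ((w - 1) * spacing[0] / 2.0, (h - 1) * spacing[1] / 2.0)


def pre_rotate(
    image: np.ndarray, theta_degrees: float, spacing=(1.0, 1.0)
) -> tuple[np.ndarray, RigidTransform]:
    """Rotate a slice about its centre (linear interpolation).

    Used for rough manual pre-alignment of heavily rotated sections before
    automatic refinement.  Returns the rotated raster together with the
    :class:`RigidTransform` that was applied, so it can be recorded in the
    slice's chain.
    """
    if abs(theta_degrees) > 180:
        raise ValueError("|theta| must be <= 180 degrees")
    transform = RigidTransform(
        theta=math.radians(theta_degrees),
        tx=0.0,
        ty=0.0,
        center=_image_center(image, spacing),
    )
    rotated = apply_chain(image, TransformChain([transform]), spacing=spacing)
    return rotated, transform


def _check_registerable(fixed: np.ndarray, moving: np.ndarray) -> None:
    for name, img in (("fixed", fixed), ("moving", moving)):
        if img.size == 0:
            raise RegistrationError(f"{name} image is empty")
        if float(np.ptp(img)) == 0.0:
            raise RegistrationError(
                f"{name} image is constant; intensity metrics are undefined"
            )


def _configure_method(reg: sitk.ImageRegistrationMethod, params: RegistrationParams):
    if params.metric == "mattes_mi":
        reg.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=params.histogram_bins
        )
    else:
        reg.SetMetricAsMeanSquares()
    # Dense sampling keeps the metric — and hence the whole registration —
    # deterministic for fixed inputs and parameters.
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    factors = [int(f) for f in params.downsampling_factors]
    reg.SetShrinkFactorsPerLevel(shrinkFactors=factors)
    reg.SetSmoothingSigmasPerLevel(smoothingSigmas=[f / 2.0 for f in factors])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationParams | None = None,
    spacing=(1.0, 1.0),
) -> RigidTransform:
    """Estimate the 2D Euler transform aligning ``moving`` onto ``fixed``.

    Multi-resolution Mattes-MI (or mean-squares) optimization with a
    regular-step gradient descent, initialized by centre alignment.  The
    returned transform is the resampling map (reference frame -> moving
    frame); ``apply_chain(moving, TransformChain([t]))`` yields the aligned
    image.  Deterministic: the metric is evaluated densely.
    """
    if params is None:
        params = RegistrationParams()
    _check_registerable(fixed, moving)
    f_img = _to_sitk(fixed, spacing)
    m_img = _to_sitk(moving, spacing)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler2DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    _configure_method(reg, params)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-5,
        numberOfIterations=params.iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=True)
    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - backend failure path
        raise RegistrationError(f"rigid registration failed: {exc}") from exc
    return RigidTransform.from_sitk(sitk.Euler2DTransform(result.Downcast()))


def register_deformable(
    fixed: np.ndarray,
    moving: np.ndarray,
    initial: RigidTransform,
    params: RegistrationParams | None = None,
    spacing=(1.0, 1.0),
    backend=None,
) -> TransformChain:
    """B-spline refinement of a rigid pre-alignment.

    The rigid result is held fixed as the moving-image initial transform
    while the displacements of a B-spline control-point grid (final spacing
    ``params.grid_spacing_mm`` on the original resolution, coarser at the
    lower pyramid levels) are optimized under the same metric and pyramid as
    the rigid step.  Returns a chain ``[initial_rigid, bspline]``.

    A custom ``backend`` callable ``(fixed, moving, initial, params,
    spacing) -> TransformChain`` may replace the built-in engine, e.g. to
    pass a parameter file to an external registration toolbox.
    """
    if params is None:
        params = RegistrationParams()
    if backend is not None:
        return backend(fixed, moving, initial, params, spacing)
    _check_registerable(fixed, moving)
    f_img = _to_sitk(fixed, spacing)
    m_img = _to_sitk(moving, spacing)

    # Control-point spacing in physical units (spacing in µm, grid in mm).
    # One control grid at the final spacing is optimized under the image
    # pyramid; LBFGSB handles the high-dimensional B-spline parameter space
    # far more robustly than step-size optimizers.
    grid_physical = params.grid_spacing_mm * 1000.0
    size_phys = [
        (f_img.GetSize()[d] - 1) * f_img.GetSpacing()[d] for d in range(2)
    ]
    mesh = [max(1, int(round(size_phys[d] / grid_physical))) for d in range(2)]
    bspline = sitk.BSplineTransformInitializer(
        f_img, transformDomainMeshSize=mesh, order=3
    )

    reg = sitk.ImageRegistrationMethod()
    _configure_method(reg, params)
    reg.SetMovingInitialTransform(initial.to_sitk())
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=params.deformable_iterations,
    )
    try:
        reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - backend failure path
        raise RegistrationError(f"deformable registration failed: {exc}") from exc
    return TransformChain([initial, bspline])


def reconstruct_stack(
    slices: Sequence[np.ndarray],
    reference_index: int,
    params: RegistrationParams | None = None,
    spacing=(1.0, 1.0),
    deformable: bool = False,
) -> list[TransformChain]:
    """Bidirectional stack alignment from a reference slice.

    The reference slice keeps an identity chain.  Walking away from it in
    both directions, each slice is registered onto the *aligned* rendering
    of its neighbour, so every chain maps the reference frame directly onto
    its slice (cumulative transforms compose implicitly).  Spectra are never
    touched; the chains apply to ion images.
    """
    if params is None:
        params = RegistrationParams()
    n = len(slices)
    if n < 1:
        raise ValueError("empty slice stack")
    if not 0 <= reference_index < n:
        raise ValueError(f"reference index {reference_index} out of range [0, {n})")

    chains: list[TransformChain | None] = [None] * n
    center = _image_center(slices[reference_index], spacing)
    chains[reference_index] = TransformChain(
        [RigidTransform.identity(center)], slice_id=reference_index
    )

    def _align_pair(prev_idx: int, idx: int) -> TransformChain:
        fixed_aligned = apply_chain(
            slices[prev_idx], chains[prev_idx], spacing=spacing
        )
        rigid = register_rigid(fixed_aligned, slices[idx], params, spacing)
        if deformable:
            chain = register_deformable(
                fixed_aligned, slices[idx], rigid, params, spacing
            )
        else:
            chain = TransformChain([rigid])
        chain.slice_id = idx
        return chain

    for i in range(reference_index + 1, n):
        chains[i] = _align_pair(i - 1, i)
    for i in range(reference_index - 1, -1, -1):
        chains[i] = _align_pair(i + 1, i)
    return chains  # type: ignore[return-value]


_INTERPOLATORS = {
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
    "bspline3": sitk.sitkBSpline,
}


def apply_chain(
    raster: np.ndarray,
    chain: TransformChain,
    interpolation: str = "linear",
    spacing=(1.0, 1.0),
) -> np.ndarray:
    """Resample a raster through a transform chain in one interpolation pass.

    Out-of-domain pixels become 0.  Binary masks should use ``nearest``
    interpolation, which preserves {0, 1} values exactly.
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"interpolation must be one of {sorted(_INTERPOLATORS)}")
    img = _to_sitk(raster, spacing)
    resampled = sitk.Resample(
        img, img, chain.composed(), _INTERPOLATORS[interpolation], 0.0,
        sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(resampled)
    return out.astype(raster.dtype) if raster.dtype.kind in "iu" else out


def landmark_error(
    fixed_points: LandmarkSet,
    moving_points: LandmarkSet,
    chain: TransformChain,
) -> tuple[float, float, np.ndarray]:
    """Registration accuracy from corresponding landmark pairs.

    Moving-slice points are mapped into the reference frame through the
    chain; the per-point Euclidean distances to the fixed points give the
    mean and population standard deviation, in the landmarks' physical
    units.
    """
    if len(fixed_points.points) != len(moving_points.points):
        raise ValueError(
            f"landmark sets differ in length: {len(fixed_points.points)} vs "
            f"{len(moving_points.points)}"
        )
    aligned = chain.map_to_reference(moving_points.points)
    per_point = np.linalg.norm(aligned - fixed_points.points, axis=1)
    return float(per_point.mean()), float(per_point.std()), per_point


def mattes_mi(fixed: np.ndarray, moving: np.ndarray, bins: int = 32) -> float:
    """Mattes mutual information between two rasters (higher = more similar).

    SimpleITK's metric returns the negated MI; the sign is flipped here so
    larger values mean better alignment.
    """
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(sitk.TranslationTransform(2), inPlace=True)
    return -float(
        reg.MetricEvaluate(_to_sitk(fixed), _to_sitk(moving))
    )
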