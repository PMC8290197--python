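"""Dimensionality reduction over stacks of ion images.

Each valid pixel becomes a feature vector of ion-image intensities at a set
of m/z features (typically a picked peak list); PCA or t-SNE then compresses
the feature space and the scores are mapped back onto the image geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .artefacts import raster_shape
from .errors import MsiLazyError
from .imzml import DatasetMetadata
from .ionimage import IonImageRequest, generate_ion_image
from .peaks import PeakList
from .signal import SignalParams

__all__ = ["FeatureMatrix", "build_feature_matrix", "pca_images", "tsne_images"]


@dataclass
class FeatureMatrix:
    """Per-pixel feature matrix: rows = valid pixels, columns = m/z features."""

    values: np.ndarray  # (n_pixels, n_features)
    pixel_indices: np.ndarray  # flat raster indices of the rows
    shape: tuple  # raster geometry
    feature_mz: np.ndarray

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def to_raster(self, column: np.ndarray) -> np.ndarray:
        """Scatter one per-pixel vector back onto the raster geometry."""
        flat = np.zeros(int(np.prod(self.shape)), dtype=np.float64)
        flat[self.pixel_indices] = column
        return flat.reshape(self.shape)


def build_feature_matrix(
    meta: DatasetMetadata,
    peak_list: PeakList,
    tolerance: float,
    signal: SignalParams | None = None,
    mask: np.ndarray | None = None,
    *,
    n_workers: int = 1,
) -> FeatureMatrix:
    """Stack ion images at each peak into a pixels x features matrix.

    Column j is the ion image at peak j (window +/- tolerance, max reducer),
    flattened over the pixels carrying a spectrum (optionally restricted by
    ``mask``).  Column order follows peak order.
    """
    if len(peak_list) == 0:
        raise ValueError("peak list is empty")
    if signal is None:
        signal = SignalParams()
    shape = raster_shape(meta)

    valid = np.zeros(shape, dtype=bool)
    for rec in meta.spectra:
        if meta.image_depth > 1:
            valid[rec.z - 1, rec.y - 1, rec.x - 1] = True
        else:
            valid[rec.y - 1, rec.x - 1] = True
    if mask is not None:
        valid &= np.asarray(mask) != 0
    pixel_indices = np.flatnonzero(valid.ravel())
    if pixel_indices.size == 0:
        raise MsiLazyError("no valid pixels under the mask")

    columns = []
    for peak in peak_list:
        request = IonImageRequest(
            center_mz=peak.mz, tolerance=tolerance, reducer="max",
            signal=signal, mask=mask,
        )
        image = generate_ion_image(meta, request, n_workers=n_workers)
        columns.append(image.ravel()[pixel_indices])
    values = np.column_stack(columns)
    return FeatureMatrix(
        values=values,
        pixel_indices=pixel_indices,
        shape=shape,
        feature_mz=peak_list.mz,
    )


def pca_images(
    matrix: FeatureMatrix, n_components: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Principal-component score images.

    Columns are mean-centered (no variance scaling); the SVD-based scores of
    the leading components are scattered back onto the raster geometry.
    Returns ``(component_images, explained_variance_ratio)`` with the ratios
    in descending order.
    """
    n_max = min(matrix.values.shape)
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must be in [1, {n_max}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    images = [matrix.to_raster(scores[:, k]) for k in range(n_components)]
    return images, pca.explained_variance_ratio_


def tsne_images(
    matrix: FeatureMatrix,
    n_dims: int = 3,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """t-SNE embedding of the pixel features, one raster per embedding axis.

    Delegated to scikit-learn's t-SNE with PCA initialization, which makes
    the embedding deterministic for a fixed seed.  Perplexity is clipped to
    the sample count when the dataset is small.  Channels are min-max
    normalized to [0, 1] for display.  Returns an array of shape
    ``(n_dims, *raster_shape)``.
    """
    n = matrix.n_pixels
    if n < 5:
        raise MsiLazyError("t-SNE needs at least 5 pixels")
    perplexity = min(perplexity, (n - 1) / 3)
    # PCA init needs at least n_dims feature columns; the seeded random
    # fallback keeps the embedding deterministic either way.
    init = "pca" if matrix.values.shape[1] >= n_dims else "random"
    tsne = TSNE(
        n_components=n_dims,
        random_state=seed,
        init=init,
        perplexity=perplexity,
        method="exact" if n_dims > 2 else "barnes_hut",
    )
    embedding = tsne.fit_transform(matrix.values)
    channels = []
    for k in range(n_dims):
        col = embedding[:, k]
        span = col.max() - col.min()
        col = (col - col.min()) / span if span > 0 else np.zeros_like(col)
        channels.append(matrix.to_raster(col))
    return np.stack(channels)
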