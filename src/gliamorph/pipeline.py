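"""Preprocessing and segmentation chain from raw stack to labeled cells.

The chain mirrors a standard confocal quantification workflow: maximum
intensity projection, per-channel rolling-ball background subtraction,
mean-filter smoothing, unsharp masking, and constant-threshold
segmentation of the Iba1 channel.  The marker (Tmem119) channel receives
only a small-radius rolling-ball subtraction before intensity measurement,
so that cell masks come from Iba1 and intensities from Tmem119.

The rolling-ball background is a grayscale opening with a non-flat ball
structuring element: the ball is rolled under the intensity surface and the
highest surface it can touch everywhere is taken as background.  For large
radii the image is shrunk by a block-minimum, the opening run at reduced
radius, and the background re-enlarged bilinearly — the classic speedup for
this filter; small radii run exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "PipelineConfig",
    "LabelMask",
    "max_project",
    "subtract_background_rolling",
    "smooth",
    "unsharp_mask",
    "segment_cells",
    "suggest_threshold",
    "preprocess_iba1",
    "preprocess_marker",
]

# Largest radius at which the opening is computed exactly at full
# resolution; beyond this the shrink/enlarge approximation is used.
EXACT_RADIUS_LIMIT = 16


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation chain.

    ``threshold_gray`` is the constant gray-level cut-off applied to the
    preprocessed Iba1 projection; it has no default because it must be
    chosen once per staining batch (see :func:`suggest_threshold`) and then
    held constant across all images of a comparison.
    """

    threshold_gray: float
    iba1_rolling_radius_px: int = 50
    tmem_rolling_radius_px: int = 20
    smooth_kernel_px: int = 3
    unsharp_radius_px: float = 2.0
    unsharp_weight: float = 0.6
    connectivity: int = 8
    min_area_um2: float = 20.0
    exclude_border: bool = True
    perimeter_estimator: str = "polygon"

    def __post_init__(self) -> None:
        if self.threshold_gray <= 0:
            raise ValueError("threshold_gray must be positive")
        if self.iba1_rolling_radius_px < 1 or self.tmem_rolling_radius_px < 1:
            raise ValueError("rolling-ball radii must be >= 1")
        if not (0 < self.unsharp_weight < 1):
            raise ValueError("unsharp_weight must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class LabelMask:
    """2D label image: 0 = background, k = cell k (consecutive labels)."""

    data: np.ndarray
    pixel_size_um: float

    @property
    def n_cells(self) -> int:
        return int(self.data.max())

    def mask_of(self, label: int) -> np.ndarray:
        return self.data == label


def max_project(stack) -> dict[str, np.ndarray]:
    """Maximum-intensity projection along z, one 2D image per channel."""
    if stack.n_z < 1:
        raise ValueError("stack has no z-slices")
    return {
        name: np.asarray(stack.data[i].max(axis=0), dtype=float)
        for i, name in enumerate(stack.channel_names)
    }


def _ball_profile(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (x * x + y * y).astype(float)
    footprint = d2 <= radius * radius
    heights = np.zeros(footprint.shape)
    heights[footprint] = np.sqrt(radius * radius - d2[footprint]) - radius
    return footprint, heights


def _rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    footprint, heights = _ball_profile(radius)
    eroded = ndi.grey_erosion(image, footprint=footprint, structure=heights, mode="reflect")
    return ndi.grey_dilation(eroded, footprint=footprint, structure=heights, mode="reflect")


def _shrink_factor(radius: float) -> int:
    if radius <= EXACT_RADIUS_LIMIT:
        return 1
    if radius <= 32:
        return 2
    if radius <= 100:
        return 4
    return 8


def subtract_background_rolling(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Subtract the rolling-ball background estimate; result clipped at 0.

    A constant image maps to zero exactly.  Raises if the ball does not fit
    inside the image.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise ValueError(
            f"rolling-ball radius {radius_px} px too large for image {image.shape}"
        )
    shrink = _shrink_factor(radius_px)
    if shrink == 1:
        background = _rolling_ball_background(image, radius_px)
    else:
        small = ndi.minimum_filter(image, size=shrink, mode="reflect")[::shrink, ::shrink]
        small_bg = _rolling_ball_background(small, radius_px / shrink)
        zoom = (image.shape[0] / small_bg.shape[0], image.shape[1] / small_bg.shape[1])
        background = ndi.zoom(small_bg, zoom, order=1, mode="nearest")
        background = np.minimum(background, image)
    return np.clip(image - background, 0.0, None)


def smooth(image: np.ndarray, kernel_px: int = 3) -> np.ndarray:
    """Uniform mean filter (default 3x3) with reflective borders."""
    if kernel_px < 1:
        raise ValueError("kernel_px must be >= 1")
    return ndi.uniform_filter(np.asarray(image, float), size=kernel_px, mode="reflect")


def unsharp_mask(image: np.ndarray, radius_px: float = 2.0, weight: float = 0.6) -> np.ndarray:
    """Unsharp masking: ``(I - w*G_r(I)) / (1 - w)`` with negatives clipped.

    ``radius_px`` is the Gaussian sigma.  Constant images are unchanged.
    """
    if not (0 <= weight < 1):
        raise ValueError("weight must lie in [0, 1)")
    image = np.asarray(image, float)
    blurred = ndi.gaussian_filter(image, sigma=radius_px, mode="reflect")
    out = (image - weight * blurred) / (1.0 - weight)
    return np.clip(out, 0.0, None)


def segment_cells(
    image: np.ndarray, config: PipelineConfig, pixel_size_um: float
) -> LabelMask:
    """Constant-threshold segmentation of the preprocessed Iba1 projection.

    Pixels ``>= threshold_gray`` are foreground; connected components under
    the configured connectivity become cells; components below
    ``min_area_um2`` (debris) and, optionally, components touching the
    window border are removed; survivors are relabeled 1..n in scan order.
    An empty result is a valid (all-zero) mask.
    """
    image = np.asarray(image, float)
    binary = image >= config.threshold_gray
    skimage_conn = 2 if config.connectivity == 8 else 1
    labels = measure.label(binary, connectivity=skimage_conn)
    min_px = config.min_area_um2 / pixel_size_um**2
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    out = np.zeros_like(labels)
    next_label = 1
    for region in measure.regionprops(labels):
        if region.area < min_px:
            continue
        region_mask = labels == region.label
        if config.exclude_border and (region_mask & border).any():
            continue
        out[region_mask] = next_label
        next_label += 1
    return LabelMask(data=out, pixel_size_um=pixel_size_um)


def suggest_threshold(reference_image: np.ndarray, quantile: float = 0.99) -> float:
    """Gray-level quantile of a preprocessed control image.

    The segmentation cut-off is a global constant; this helper derives one
    from a reference image (e.g. an uninjured-cortex field processed with
    the same chain) as a high quantile of its gray levels.
    """
    if not (0 <= quantile <= 1):
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(np.asarray(reference_image, float), quantile))


def preprocess_iba1(projection: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Full Iba1 preprocessing: rolling-ball 50, smooth, unsharp mask."""
    img = subtract_background_rolling(projection, config.iba1_rolling_radius_px)
    img = smooth(img, config.smooth_kernel_px)
    return unsharp_mask(img, config.unsharp_radius_px, config.unsharp_weight)


def preprocess_marker(projection: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Marker-channel preprocessing: rolling-ball 20 subtraction only."""
    return subtract_background_rolling(projection, config.tmem_rolling_radius_px)
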