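"""Skin-mask segmentation for thermal and visual wound images.

Both modalities follow the same hybrid scheme: an initial per-pixel skin rule,
selection of the biggest connected area, then edge-constrained region growing
from an eroded core of the initial mask, and a final morphological cleanup.
The combination of region growing with Canny edges refines the mask at the
skin boundary: the region grows from a safely-interior core outward until it
runs against detected edges.

The initial rules differ per modality:

* thermal — a pixel is skin iff its temperature is at least ``min(T, 30)`` °C,
  where ``T`` is the mean of the two k-means cluster centers of the image's
  temperature histogram. The 30 °C cap protects scenes dominated by hot skin
  or wound, where the data-driven threshold would climb above a physiological
  skin temperature and cut away actual skin.
* visual — a pixel is skin iff its red channel is maximal among (R, G, B),
  reflecting the reddish dominance of skin under clinical lighting. Ties with
  the maximum satisfy the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature
from sklearn.cluster import KMeans

from ._growth import grow, structuring_element
from .errors import DegenerateInputError, EmptyMaskError, UsageError
from .imaging import BinaryMask, ImagePair, ThermalImage, VisualImage


@dataclass
class SkinSegmentationConfig:
    """Tunables for skin segmentation; defaults follow common practice.

    ``skin_temperature_floor`` is the physiological lower bound for skin (°C)
    used to cap the k-means threshold. ``core_fraction`` is the area fraction
    to which the initial mask is eroded before region growing. Canny
    thresholds are expressed as fractions of the grayscale intensity range.
    """

    skin_temperature_floor: float = 30.0
    kmeans_k: int = 2
    kmeans_restarts: int = 8
    rng_seed: int = 0
    core_fraction: float = 0.10
    canny_low: float = 0.10
    canny_high: float = 0.20
    canny_sigma: float = 1.0
    morph_kernel: int = 3
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction < 1.0:
            raise UsageError("core_fraction must lie in (0, 1)")
        if self.canny_low >= self.canny_high:
            raise UsageError("canny_low must be below canny_high")
        if self.morph_kernel < 3 or self.morph_kernel % 2 == 0:
            raise UsageError("morph_kernel must be odd and >= 3")
        if self.connectivity not in (4, 8):
            raise UsageError("connectivity must be 4 or 8")

    def kernel(self) -> np.ndarray:
        return np.ones((self.morph_kernel, self.morph_kernel), dtype=bool)


def kmeans_threshold(
    thermal: ThermalImage, config: SkinSegmentationConfig | None = None
) -> float:
    """Temperature threshold from k-means clustering of the pixel values.

    Runs k-means (default k=2: skin vs background) on the flattened
    temperatures with deterministic seeded restarts and returns the
    arithmetic mean of the final cluster centers.
    """
    config = config or SkinSegmentationConfig()
    values = thermal.temperatures.reshape(-1, 1)
    if np.unique(values).size < 2:
        raise DegenerateInputError("constant thermal image: k-means threshold undefined")
    km = KMeans(
        n_clusters=config.kmeans_k,
        n_init=config.kmeans_restarts,
        random_state=config.rng_seed,
    ).fit(values)
    return float(np.mean(km.cluster_centers_))


def initial_thermal_mask(
    thermal: ThermalImage, threshold: float, config: SkinSegmentationConfig | None = None
) -> BinaryMask:
    """Per-pixel thermal skin rule: temperature >= min(threshold, floor)."""
    config = config or SkinSegmentationConfig()
    if not np.isfinite(threshold):
        raise UsageError("threshold must be finite")
    cut = min(threshold, config.skin_temperature_floor)
    return BinaryMask((thermal.temperatures >= cut).astype(np.uint8), role="skin")


def initial_visual_mask(visual: VisualImage) -> BinaryMask:
    """Per-pixel visual skin rule: R is (weakly) maximal among the channels."""
    r, g, b = visual.r, visual.g, visual.b
    mask = (r >= g) & (r >= b)
    return BinaryMask(mask.astype(np.uint8), role="skin")


def largest_component(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the biggest connected area of the mask.

    Area ties are broken in favour of the component whose first pixel in
    row-major order comes first.
    """
    structure = structuring_element(connectivity)
    labels, n = ndimage.label(mask.as_bool(), structure=structure)
    if n == 0:
        raise EmptyMaskError("cannot select the biggest area of an empty mask")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1  # argmax returns the first maximum:
    # labels are assigned in row-major scan order, so this is the tie rule
    return BinaryMask((labels == best).astype(np.uint8), role=mask.role)


def detect_edges(gray: np.ndarray, config: SkinSegmentationConfig | None = None) -> BinaryMask:
    """Canny edge mask of a grayscale image.

    Hysteresis thresholds are taken as fractions of the image's intensity
    range; a constant image yields an all-zero edge mask.
    """
    config = config or SkinSegmentationConfig()
    gray = np.asarray(gray, dtype=float)
    lo, hi = gray.min(), gray.max()
    if hi <= lo:
        return BinaryMask(np.zeros(gray.shape, dtype=np.uint8), role="edges")
    norm = (gray - lo) / (hi - lo)
    edges = feature.canny(
        norm,
        sigma=config.canny_sigma,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
    )
    return BinaryMask(edges.astype(np.uint8), role="edges")


def erode_to_core(
    mask: BinaryMask,
    core_fraction: float | None = None,
    config: SkinSegmentationConfig | None = None,
) -> BinaryMask:
    """Erode a mask until its area drops to ``core_fraction`` of the original.

    Erosion is repeated with the square ``morph_kernel`` element; if one more
    step would empty the mask entirely, the last non-empty mask is returned
    even if it is still above the requested fraction. The core serves as the
    seed region for edge-constrained growth, so it must never be empty.
    """
    config = config or SkinSegmentationConfig()
    frac = config.core_fraction if core_fraction is None else core_fraction
    current = mask.as_bool()
    target = frac * current.sum()
    if current.sum() == 0:
        raise EmptyMaskError("cannot erode an empty mask to a core")
    kernel = config.kernel()
    while current.sum() > target:
        nxt = ndimage.binary_erosion(current, structure=kernel)
        if not nxt.any():
            break
        current = nxt
    return BinaryMask(current.astype(np.uint8), role="core")


def region_grow_constrained(
    seeds: BinaryMask,
    allowed: BinaryMask,
    edges: BinaryMask,
    connectivity: int = 8,
) -> BinaryMask:
    """Grow from seed pixels through ``allowed`` pixels that are not edges.

    Breadth-first growth to the fixed point: the result is exactly the set of
    pixels of ``allowed & ~edges`` reachable from the seeds, independent of
    processing order.
    """
    if seeds.area == 0:
        raise UsageError("region growing requires non-empty seeds")
    if np.any(seeds.as_bool() & ~allowed.as_bool()):
        raise UsageError("seeds must be a subset of the allowed mask")
    admissible = allowed.as_bool() & ~edges.as_bool()
    region = grow(seeds.as_bool(), admissible, connectivity=connectivity)
    return BinaryMask(region.astype(np.uint8), role=allowed.role)


def morphological_clean(
    mask: BinaryMask, config: SkinSegmentationConfig | None = None
) -> BinaryMask:
    """Opening (erosion then dilation) followed by hole filling.

    The opening smooths the mask border and deletes singular pixel-sized
    areas; holes (zero-regions not connected to the image border) are then
    filled.
    """
    config = config or SkinSegmentationConfig()
    kernel = config.kernel()
    opened = ndimage.binary_opening(mask.as_bool(), structure=kernel)
    filled = ndimage.binary_fill_holes(opened)
    return BinaryMask(filled.astype(np.uint8), role=mask.role)


def _thermal_gray(thermal: ThermalImage) -> np.ndarray:
    t = thermal.temperatures
    lo, hi = t.min(), t.max()
    if hi <= lo:
        return np.zeros_like(t)
    return (t - lo) / (hi - lo)


def segment_skin(
    pair: ImagePair, config: SkinSegmentationConfig | None = None
) -> tuple[BinaryMask, BinaryMask]:
    """Full skin segmentation for both modalities of an image pair.

    Per modality: initial rule -> biggest area -> Canny edges on the
    modality's grayscale -> erosion to a core -> edge-constrained region
    growing within the initial mask -> biggest area -> morphological cleanup.

    Returns ``(thermal_skin, visual_skin)``.
    """
    config = config or SkinSegmentationConfig()
    results = []
    for modality in ("thermal", "visual"):
        if modality == "thermal":
            threshold = kmeans_threshold(pair.thermal, config)
            initial = initial_thermal_mask(pair.thermal, threshold, config)
            gray = _thermal_gray(pair.thermal)
        else:
            initial = initial_visual_mask(pair.visual)
            gray = pair.visual.luma()
        initial = largest_component(initial, config.connectivity)
        edges = detect_edges(gray, config)
        core = erode_to_core(initial, config=config)
        grown = region_grow_constrained(core, initial, edges, config.connectivity)
        grown = largest_component(grown, config.connectivity)
        final = morphological_clean(grown, config)
        final.role = "skin"
        results.append(final)
    return results[0], results[1]
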