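"""The Infection Probability Index (IPI): four thermal wound parameters.

The IPI summarises a thermal/visual wound image pair on a 0 (no potential
infection) to 9 (potential infection) scale by summing four weighted
parameters:

==========================  ==========================================  ======
parameter                   case                                        weight
==========================  ==========================================  ======
cold spots                  none / 1-3 spots / more than 3              0/2/4
temperature difference      wound-to-intact-skin in [1, 2] / <1 / >2 °C 0/1/2
temperature distribution    homogeneous / inhomogeneous                 0/1
                            concentrated (1-3 deviating regions)        +1
thermal wound margin        discontinuous (crosses anatomical margin)   +1
==========================  ==========================================  ======

Cold spots are small (10-100 px) connected regions markedly colder than the
wound mean — typically accumulated fluids such as purulence or exudate. The
temperature difference compares the wound-base maximum against the mean of
intact skin, i.e. skin outside both the wound and the dilated thermal wound
margin; physiological healing shows a difference between 1 and 2 °C, while a
larger difference suggests infection and a smaller one pathological healing
such as necrosis. The thermal wound margin is the peri-wound band bounded by
a 1.5 °C temperature drop from wound-boundary seed temperatures; in healing
wounds it surrounds the wound equidistantly, whereas a gap through which the
outside connects to the wound base marks a discontinuous margin.

All criteria are relative temperature differences, so every sub-score is
invariant under a constant temperature offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from ._growth import grow, structuring_element
from .errors import DegenerateInputError, UsageError
from .imaging import BinaryMask, ImagePair, ThermalImage


@dataclass
class ScoringConfig:
    """Tunables of the four IPI parameters (temperatures in °C, sizes in px)."""

    cold_spot_delta: float = 2.0
    cold_spot_min_px: int = 10
    cold_spot_max_px: int = 100
    margin_drop: float = 1.5
    margin_dilation_px: int = 5
    fluctuation_tol: float = 1.2
    merge_tol: float = 1.5
    superpixel_similarity: float = 0.5
    superpixel_max_px: int = 50
    concentrated_min_regions: int = 1
    concentrated_max_regions: int = 3
    concentrated_min_region_px: int = 10
    neighborhood_px: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.cold_spot_min_px >= self.cold_spot_max_px:
            raise UsageError("cold_spot_min_px must be below cold_spot_max_px")
        for name in ("cold_spot_delta", "margin_drop", "fluctuation_tol",
                     "merge_tol", "superpixel_similarity"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")


@dataclass
class SuperPixel:
    """A connected pixel group summarised by its mean temperature."""

    pixels: np.ndarray  # (N, 2) array of (row, col)
    mean_temperature: float

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class IPIResult:
    """All four sub-scores, their intermediates, and the 0-9 total."""

    cold_spot_count: int
    cold_spot_score: int
    temperature_difference: float
    temp_diff_score: int
    inhomogeneous_flag: int
    concentrated_flag: int
    margin_crossing_flag: int
    total: int
    thermal_margin: BinaryMask | None = None
    intact_skin: BinaryMask | None = None
    cold_spot_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (
            self.cold_spot_score
            + self.temp_diff_score
            + self.inhomogeneous_flag
            + self.concentrated_flag
            + self.margin_crossing_flag
        )
        assert self.total == expected, "total must be the sum of the sub-scores"
        assert 0 <= self.total <= 9

    def to_dict(self) -> dict:
        return {
            "cold_spot_count": self.cold_spot_count,
            "cold_spot_score": self.cold_spot_score,
            "temperature_difference_C": round(self.temperature_difference, 4),
            "temp_diff_score": self.temp_diff_score,
            "inhomogeneous": self.inhomogeneous_flag,
            "concentrated": self.concentrated_flag,
            "margin_crossing": self.margin_crossing_flag,
            "ipi_total": self.total,
        }


def wound_stats(thermal: ThermalImage, wound_mask: BinaryMask) -> tuple[float, float]:
    """Mean and maximum temperature over the wound base."""
    w = wound_mask.as_bool()
    if not w.any():
        raise UsageError("wound mask is empty")
    values = thermal.temperatures[w]
    return float(values.mean()), float(values.max())


def detect_cold_spots(
    thermal: ThermalImage,
    wound_mask: BinaryMask,
    config: ScoringConfig | None = None,
    skin_mask: BinaryMask | None = None,
) -> tuple[int, np.ndarray]:
    """Count punctual cold regions within or nearby the wound base.

    The search region is the wound mask dilated by ``neighborhood_px``
    (intersected with the skin mask when given). Candidate pixels are more
    than ``cold_spot_delta`` colder than the wound mean; connected candidate
    components with an area inside ``[cold_spot_min_px, cold_spot_max_px]``
    count as cold spots. The lower size bound rejects singular-pixel
    segmentation errors; the upper one enforces the punctual character.
    """
    config = config or ScoringConfig()
    mean, _ = wound_stats(thermal, wound_mask)
    search = ndimage.binary_dilation(wound_mask.as_bool(), structure=disk(config.neighborhood_px))
    if skin_mask is not None:
        search &= skin_mask.as_bool()
    candidates = search & (thermal.temperatures < mean - config.cold_spot_delta)
    labels, n = ndimage.label(candidates, structure=structuring_element(config.connectivity))
    count = 0
    out = np.zeros_like(labels)
    for i in range(1, n + 1):
        area = int((labels == i).sum())
        if config.cold_spot_min_px <= area <= config.cold_spot_max_px:
            count += 1
            out[labels == i] = count
    return count, out


def score_cold_spots(count: int) -> int:
    """Cold-spot case distinction: none -> 0, particular (1-3) -> 2, distinct -> 4."""
    if count < 0:
        raise UsageError("cold-spot count cannot be negative")
    if count == 0:
        return 0
    return 2 if count <= 3 else 4


def _boundary(wound: np.ndarray) -> np.ndarray:
    """Wound pixels 8-adjacent to a non-wound pixel (the anatomical margin)."""
    interior = ndimage.binary_erosion(wound, structure=np.ones((3, 3), dtype=bool))
    return wound & ~interior


def margin_superpixels(
    wound_mask: BinaryMask,
    thermal: ThermalImage,
    config: ScoringConfig | None = None,
) -> list[SuperPixel]:
    """Divide the anatomical wound margin into temperature superpixels.

    The boundary pixels of the wound mask are traversed in angular order
    around their centroid and grouped greedily: a pixel joins the current
    group while its temperature stays within ``superpixel_similarity`` of the
    running group mean and the group is below ``superpixel_max_px`` pixels.
    """
    config = config or ScoringConfig()
    w = wound_mask.as_bool()
    if not w.any():
        raise UsageError("wound mask is empty")
    boundary = _boundary(w)
    coords = np.argwhere(boundary)
    centroid = coords.mean(axis=0)
    angles = np.arctan2(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
    radii = np.hypot(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
    order = np.lexsort((radii, angles))
    coords = coords[order]
    temps = thermal.temperatures[coords[:, 0], coords[:, 1]]

    groups: list[SuperPixel] = []
    current: list[int] = []
    running_sum = 0.0
    for i, t in enumerate(temps):
        if current:
            mean = running_sum / len(current)
            if len(current) >= config.superpixel_max_px or abs(t - mean) > config.superpixel_similarity:
                groups.append(SuperPixel(coords[current], mean))
                current, running_sum = [], 0.0
        current.append(i)
        running_sum += t
    if current:
        groups.append(SuperPixel(coords[current], running_sum / len(current)))
    return groups


def thermal_wound_margin(
    thermal: ThermalImage,
    wound_mask: BinaryMask,
    skin_mask: BinaryMask,
    config: ScoringConfig | None = None,
) -> BinaryMask:
    """Peri-wound band bounded by a ``margin_drop`` temperature decrease.

    Each superpixel of the anatomical margin seeds a region growing that
    admits neighbours warmer than (superpixel mean - margin_drop), excluding
    the wound interior so the margin remains a peri-wound structure. The
    union over all superpixels, intersected with the skin mask and stripped
    of wound pixels, is the thermal wound margin.
    """
    config = config or ScoringConfig()
    w = wound_mask.as_bool()
    superpixels = margin_superpixels(wound_mask, thermal, config)
    boundary = _boundary(w)
    interior = w & ~boundary
    union = np.zeros_like(w)
    for sp in superpixels:
        seeds = np.zeros_like(w)
        seeds[sp.pixels[:, 0], sp.pixels[:, 1]] = True
        allowed = (thermal.temperatures > sp.mean_temperature - config.margin_drop) & ~interior
        union |= grow(seeds, allowed, connectivity=config.connectivity)
    margin = union & skin_mask.as_bool() & ~w
    return BinaryMask(margin.astype(np.uint8), role="thermal_margin")


def intact_skin_region(
    skin_mask: BinaryMask,
    wound_mask: BinaryMask,
    thermal_margin: BinaryMask,
    config: ScoringConfig | None = None,
) -> BinaryMask:
    """Skin outside both the wound and the dilated (impaired) margin band."""
    config = config or ScoringConfig()
    if skin_mask.area == 0:
        raise UsageError("skin mask is empty")
    if config.margin_dilation_px > 0:
        impaired = ndimage.binary_dilation(
            thermal_margin.as_bool(), structure=disk(config.margin_dilation_px)
        )
    else:
        impaired = thermal_margin.as_bool()
    intact = skin_mask.as_bool() & ~wound_mask.as_bool() & ~impaired
    if not intact.any():
        raise DegenerateInputError(
            "wound and thermal margin cover the entire skin: temperature difference undefined"
        )
    return BinaryMask(intact.astype(np.uint8), role="skin")


def temperature_difference(
    thermal: ThermalImage, wound_mask: BinaryMask, intact_skin: BinaryMask
) -> float:
    """Signed difference: wound-base maximum minus intact-skin mean (°C)."""
    if wound_mask.area == 0 or intact_skin.area == 0:
        raise UsageError("temperature difference requires non-empty masks")
    _, wound_max = wound_stats(thermal, wound_mask)
    intact_mean = float(thermal.temperatures[intact_skin.as_bool()].mean())
    return wound_max - intact_mean


def score_temp_difference(delta_t: float) -> int:
    """Case distinction: [1, 2] °C -> 0 (physiological), < 1 -> 1, > 2 -> 2."""
    if not np.isfinite(delta_t):
        raise UsageError("temperature difference must be finite")
    if 1.0 <= delta_t <= 2.0:
        return 0
    return 1 if delta_t < 1.0 else 2


def inhomogeneity_flag(
    thermal: ThermalImage, wound_mask: BinaryMask, config: ScoringConfig | None = None
) -> int:
    """1 iff a strict majority of wound pixels fluctuates beyond the tolerance.

    A pixel fluctuates when its absolute deviation from the wound mean
    exceeds ``fluctuation_tol``.
    """
    config = config or ScoringConfig()
    mean, _ = wound_stats(thermal, wound_mask)
    values = thermal.temperatures[wound_mask.as_bool()]
    fraction = float(np.mean(np.abs(values - mean) > config.fluctuation_tol))
    return int(fraction > 0.5)


def _tile_regions(wound: np.ndarray, temps: np.ndarray, side: int):
    """Initial superpixels of the wound base: grid tiles clipped to the mask."""
    tile_of = (np.arange(wound.shape[0])[:, None] // side) * (
        wound.shape[1] // side + 1
    ) + (np.arange(wound.shape[1])[None, :] // side)
    tile_of = np.where(wound, tile_of + 1, 0)
    ids = np.unique(tile_of)
    ids = ids[ids > 0]
    labels = np.zeros_like(tile_of)
    sizes, means = [], []
    for new_id, old in enumerate(ids, start=1):
        member = tile_of == old
        labels[member] = new_id
        sizes.append(int(member.sum()))
        means.append(float(temps[member].mean()))
    return labels, np.array(sizes, dtype=float), np.array(means, dtype=float)


def concentration_flag(
    thermal: ThermalImage, wound_mask: BinaryMask, config: ScoringConfig | None = None
) -> int:
    """1 iff the wound base contains 1-3 concentrated deviating regions.

    The wound base is tiled into superpixels (square grid tiles of at most
    ``superpixel_max_px`` pixels clipped to the mask). Adjacent superpixels
    are merged while their mean difference stays below ``merge_tol``, the
    merged mean being the size-weighted average. Among the final regions,
    those with at least ``concentrated_min_region_px`` pixels whose mean
    deviates from the overall wound mean by more than ``merge_tol`` are
    counted; the distribution is concentrated when that count falls within
    [concentrated_min_regions, concentrated_max_regions].
    """
    config = config or ScoringConfig()
    w = wound_mask.as_bool()
    if not w.any():
        raise UsageError("wound mask is empty")
    temps = thermal.temperatures
    overall_mean, _ = wound_stats(thermal, wound_mask)
    side = max(1, int(np.floor(np.sqrt(config.superpixel_max_px))))
    labels, sizes, means = _tile_regions(w, temps, side)

    # iterative pairwise merging, closest-in-temperature neighbours first
    structure = structuring_element(config.connectivity)
    while True:
        pairs = _adjacent_pairs(labels, structure)
        best: tuple[float, int, int] | None = None
        for a, b in pairs:
            diff = abs(means[a - 1] - means[b - 1])
            if diff < config.merge_tol and (best is None or diff < best[0]):
                best = (diff, a, b)
        if best is None:
            break
        _, a, b = best
        total = sizes[a - 1] + sizes[b - 1]
        means[a - 1] = (means[a - 1] * sizes[a - 1] + means[b - 1] * sizes[b - 1]) / total
        sizes[a - 1] = total
        labels[labels == b] = a

    count = 0
    for region_id in np.unique(labels[labels > 0]):
        size = sizes[region_id - 1]
        if size < config.concentrated_min_region_px:
            continue
        if abs(means[region_id - 1] - overall_mean) > config.merge_tol:
            count += 1
    return int(config.concentrated_min_regions <= count <= config.concentrated_max_regions)


def _adjacent_pairs(labels: np.ndarray, structure: np.ndarray) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    shifts = [(0, 1), (1, 0)]
    if structure[0, 0]:
        shifts += [(1, 1), (1, -1)]
    for dr, dc in shifts:
        a = labels[max(0, -dr) : labels.shape[0] - max(0, dr),
                   max(0, -dc) : labels.shape[1] - max(0, dc)]
        b = labels[max(0, dr) : labels.shape[0] + min(0, dr) or None,
                   max(0, dc) : labels.shape[1] + min(0, dc) or None]
        both = (a > 0) & (b > 0) & (a != b)
        if both.any():
            stacked = np.sort(np.stack([a[both], b[both]]), axis=0)
            uniq = np.unique(stacked, axis=1)
            pairs.update(zip(uniq[0].tolist(), uniq[1].tolist()))
    return pairs


def margin_crossing_flag(
    wound_mask: BinaryMask,
    thermal_margin: BinaryMask,
    skin_mask: BinaryMask,
    config: ScoringConfig | None = None,
) -> int:
    """1 iff the thermal margin fails to guard the wound.

    Seeds are skin pixels on the outer side of the thermal margin; growth
    proceeds through skin pixels that belong to neither the margin nor the
    wound's guarded ring. The flag raises when the growth reaches the wound
    base, i.e. the margin ring has a gap the outside can pass through. An
    empty margin leaves the wound entirely unguarded.
    """
    config = config or ScoringConfig()
    w = wound_mask.as_bool()
    margin = thermal_margin.as_bool()
    skin = skin_mask.as_bool()
    if not w.any():
        raise UsageError("wound mask is empty")
    if not margin.any():
        return 1
    structure = structuring_element(config.connectivity)
    seeds = ndimage.binary_dilation(margin, structure=structure) & skin & ~margin & ~w
    if not seeds.any():
        return 0
    allowed = skin & ~margin
    reached = grow(seeds, allowed, connectivity=config.connectivity)
    return int(bool(np.any(reached & w)))


def compute_ipi(
    pair: ImagePair,
    wound_mask: BinaryMask,
    skin_mask: BinaryMask,
    config: ScoringConfig | None = None,
) -> IPIResult:
    """Compute all four IPI parameters and their weighted sum."""
    config = config or ScoringConfig()
    thermal = pair.thermal
    if wound_mask.area == 0:
        raise UsageError("wound mask is empty")
    if skin_mask.area == 0:
        raise UsageError("skin mask is empty")

    count, spot_labels = detect_cold_spots(thermal, wound_mask, config, skin_mask)
    cold_score = score_cold_spots(count)

    margin = thermal_wound_margin(thermal, wound_mask, skin_mask, config)
    intact = intact_skin_region(skin_mask, wound_mask, margin, config)
    delta_t = temperature_difference(thermal, wound_mask, intact)
    dt_score = score_temp_difference(delta_t)

    inhom = inhomogeneity_flag(thermal, wound_mask, config)
    conc = concentration_flag(thermal, wound_mask, config)
    crossing = margin_crossing_flag(wound_mask, margin, skin_mask, config)

    total = cold_score + dt_score + inhom + conc + crossing
    return IPIResult(
        cold_spot_count=count,
        cold_spot_score=cold_score,
        temperature_difference=delta_t,
        temp_diff_score=dt_score,
        inhomogeneous_flag=inhom,
        concentrated_flag=conc,
        margin_crossing_flag=crossing,
        total=total,
        thermal_margin=margin,
        intact_skin=intact,
        cold_spot_labels=spot_labels,
    )
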