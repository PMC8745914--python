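"""Synthetic, ground-truthed thermal/RGB wound scenes.

A phantom is a rendered wound scene with independently controllable IPI
features: a warm skin ellipse on a cool background, an off-center wound
ellipse with a controllable base temperature, punctual cold spots, hot
patches, per-pixel temperature fluctuation, and a peri-wound temperature
profile (ramp, cool moat, recovery to the intact-skin plateau) whose ring can
carry an angular gap. Because every feature is placed analytically, the
expected IPI sub-scores are known by construction, which makes phantoms the
test bed for every pipeline stage without clinical data.

The peri-wound profile drops from the wound-edge temperature at a constant
gradient down to a moat floor well below the 1.5 °C margin criterion, holds
that floor, and then recovers to the intact-skin plateau. The moat bounds the
thermal wound margin analytically (isotherm radius = margin drop / gradient)
and thermally separates the wound from intact skin so that the wound-to-
intact-skin difference equals its configured target regardless of the margin
geometry. Within an angular gap the profile sits at the moat floor all the
way to the wound edge, so no margin forms there and the outside connects to
the wound base: a discontinuous thermal margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .imaging import BinaryMask, ImagePair, ThermalImage, VisualImage, distort_points
from .imaging import CameraParameters
from .scoring import score_cold_spots, score_temp_difference

# positions of optional features in unit-ellipse coordinates of the wound
# (fraction of the wound semi-axes); chosen so spots, patches and the wound
# boundary never touch
_SPOT_ANGLES_DEG = (0.0, 36.0, 144.0, 180.0, 216.0)
_SPOT_RING = 0.6
_PATCH_POSITIONS = ((0.45, 0.0), (-0.45, 0.0))  # along the row (minor) axis


@dataclass
class PhantomSpec:
    """Generative description of one synthetic wound scene.

    Geometry defaults scale with the image size; the default size mirrors a
    typical 464 x 348 px bolometer grid. Temperatures are in °C. With all
    feature counts at zero and the default temperatures the phantom is benign
    (every IPI sub-score 0): no cold spots, a 1.5 °C wound-to-intact-skin
    difference, a homogeneous base, and a closed thermal margin.
    """

    size: tuple[int, int] = (348, 464)
    background_temp: float = 22.0
    skin_temp: float = 33.0
    wound_mean_temp: float = 34.5
    wound_max_offset: float = 0.0
    skin_center: tuple[float, float] | None = None
    skin_axes: tuple[float, float] | None = None
    wound_center: tuple[float, float] | None = None
    wound_axes: tuple[float, float] | None = None
    n_cold_spots: int = 0
    cold_spot_radius_px: float = 2.0  # disk of 13 px
    cold_spot_depth: float = 3.0
    margin_gradient: float = 0.3125  # °C/px of the peri-wound ramp
    moat_depth: float = 2.5
    moat_end_px: float = 14.0
    profile_end_px: float = 20.0
    margin_gap_degrees: float = 0.0
    fluctuation_fraction: float = 0.0
    fluctuation_amplitude: float = 1.6
    n_hot_patches: int = 0
    hot_patch_px: int = 196
    hot_patch_offset: float = 3.0
    sensor_noise_sd: float = 0.04
    rgb_noise_sd: float = 2.0
    rng_seed: int = 0
    skin_rgb: tuple[int, int, int] = (210, 150, 140)
    wound_rgb: tuple[int, int, int] = (120, 60, 55)
    background_rgb: tuple[int, int, int] = (90, 100, 110)
    crust_rgb: tuple[int, int, int] = (180, 170, 90)
    distractor: bool = False
    pair_id: str = "phantom"

    def __post_init__(self) -> None:
        h, w = self.size
        if self.skin_center is None:
            self.skin_center = (h / 2.0, w / 2.0)
        if self.skin_axes is None:
            self.skin_axes = (0.345 * h, 0.345 * w)
        if self.wound_center is None:
            self.wound_center = (h / 2.0, w / 2.0 + 0.19 * w)
        if self.wound_axes is None:
            self.wound_axes = (0.080 * h, 0.086 * w)
        self._validate()

    def _validate(self) -> None:
        if self.n_cold_spots > len(_SPOT_ANGLES_DEG):
            raise SpecError(
                f"at most {len(_SPOT_ANGLES_DEG)} cold spots are supported"
            )
        if self.n_hot_patches > len(_PATCH_POSITIONS):
            raise SpecError(
                f"at most {len(_PATCH_POSITIONS)} hot patches are supported"
            )
        if not (0.0 <= self.fluctuation_fraction <= 1.0):
            raise SpecError("fluctuation_fraction must lie in [0, 1]")
        for name in ("cold_spot_depth", "margin_gradient", "moat_depth"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        # the wound ellipse (plus its peri-wound profile) must sit inside skin
        wr, wc = self.wound_center
        sr, sc = self.skin_center
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r = wr + dr * (self.wound_axes[0] + self.profile_end_px)
            c = wc + dc * (self.wound_axes[1] + self.profile_end_px)
            u = ((r - sr) / self.skin_axes[0]) ** 2 + ((c - sc) / self.skin_axes[1]) ** 2
            if u > 1.0:
                raise SpecError("wound plus peri-wound profile exceeds the skin ellipse")

    @property
    def expected_max_offset(self) -> float:
        """Analytic offset of the wound maximum above the base temperature."""
        offsets = [0.0, self.wound_max_offset]
        if self.n_hot_patches > 0:
            offsets.append(self.hot_patch_offset)
        if self.fluctuation_fraction > 0:
            offsets.append(self.fluctuation_amplitude)
        return max(offsets)

    @property
    def expected_delta_t(self) -> float:
        return self.wound_mean_temp + self.expected_max_offset - self.skin_temp

    def expected_scores(self) -> dict[str, int]:
        cold = score_cold_spots(self.n_cold_spots)
        dt = score_temp_difference(self.expected_delta_t)
        inhom = int(self.fluctuation_fraction > 0.5)
        conc = int(1 <= self.n_hot_patches <= 3)
        crossing = int(self.margin_gap_degrees > 0)
        return {
            "cold_spot_score": cold,
            "temp_diff_score": dt,
            "inhomogeneous": inhom,
            "concentrated": conc,
            "margin_crossing": crossing,
            "total": cold + dt + inhom + conc + crossing,
        }

    @classmethod
    def from_features(
        cls,
        n_cold_spots: int = 0,
        delta_t: float = 1.5,
        inhomogeneous: bool = False,
        concentrated: bool = False,
        margin_gap: bool = False,
        size: tuple[int, int] = (348, 464),
        rng_seed: int = 0,
        **overrides,
    ) -> "PhantomSpec":
        """Build a spec expressing target IPI features.

        The intact-skin temperature is derived so the wound-to-intact-skin
        difference equals ``delta_t`` whatever other features are active
        (hot patches and fluctuation raise the wound maximum).
        """
        spec = cls(
            size=size,
            n_cold_spots=n_cold_spots,
            fluctuation_fraction=0.6 if inhomogeneous else 0.0,
            n_hot_patches=2 if concentrated else 0,
            margin_gap_degrees=20.0 if margin_gap else 0.0,
            rng_seed=rng_seed,
            **overrides,
        )
        spec.skin_temp = spec.wound_mean_temp + spec.expected_max_offset - delta_t
        return spec


@dataclass
class PhantomResult:
    """A generated scene plus its ground truth."""

    pair: ImagePair
    skin_mask: BinaryMask
    wound_mask: BinaryMask
    cold_spot_mask: BinaryMask
    margin_isotherm_radius_px: float
    expected: dict[str, int]
    expected_delta_t: float
    spec: PhantomSpec


def _ellipse(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate(spec: PhantomSpec) -> PhantomResult:
    """Render a phantom scene; deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w]
    skin = _ellipse(spec.size, spec.skin_center, spec.skin_axes)
    wound = _ellipse(spec.size, spec.wound_center, spec.wound_axes)
    b = spec.wound_mean_temp

    # --- thermal field -----------------------------------------------------
    t = np.full(spec.size, spec.background_temp, dtype=float)
    t[skin] = spec.skin_temp

    dist = ndimage.distance_transform_edt(~wound)
    ramp_len = spec.moat_depth / spec.margin_gradient
    floor = b - spec.moat_depth
    transition = floor + (spec.skin_temp - floor) * (dist - spec.moat_end_px) / max(
        spec.profile_end_px - spec.moat_end_px, 1e-9
    )
    profile = np.where(
        dist <= ramp_len,
        b - spec.margin_gradient * dist,
        np.where(dist <= spec.moat_end_px, floor, transition),
    )
    gap_profile = np.where(dist <= spec.moat_end_px, floor, transition)
    peri = skin & ~wound & (dist <= spec.profile_end_px)
    if spec.margin_gap_degrees > 0:
        angle = np.degrees(
            np.arctan2(rr - spec.wound_center[0], cc - spec.wound_center[1])
        )
        in_gap = np.abs((angle + 180.0) % 360.0 - 180.0) <= spec.margin_gap_degrees / 2.0
    else:
        in_gap = np.zeros(spec.size, dtype=bool)
    t[peri & ~in_gap] = profile[peri & ~in_gap]
    if spec.margin_gap_degrees > 0:
        t[peri & in_gap] = gap_profile[peri & in_gap]

    t[wound] = b

    # cold spots: small disks on an interior ring of the wound ellipse
    spot_mask = np.zeros(spec.size, dtype=bool)
    for theta in _SPOT_ANGLES_DEG[: spec.n_cold_spots]:
        srow = spec.wound_center[0] + _SPOT_RING * spec.wound_axes[0] * np.sin(np.radians(theta))
        scol = spec.wound_center[1] + _SPOT_RING * spec.wound_axes[1] * np.cos(np.radians(theta))
        spot = (rr - srow) ** 2 + (cc - scol) ** 2 <= spec.cold_spot_radius_px**2
        spot_mask |= spot
    t[spot_mask] = b - spec.cold_spot_depth

    # hot patches: squares large enough to dominate at least one scoring tile
    patch_mask = np.zeros(spec.size, dtype=bool)
    side = max(1, int(round(np.sqrt(spec.hot_patch_px))))
    for fr, fc in _PATCH_POSITIONS[: spec.n_hot_patches]:
        prow = spec.wound_center[0] + fr * spec.wound_axes[0]
        pcol = spec.wound_center[1] + fc * spec.wound_axes[1]
        patch = (np.abs(rr - prow) <= side / 2.0) & (np.abs(cc - pcol) <= side / 2.0)
        patch_mask |= patch
    t[patch_mask] = b + spec.hot_patch_offset

    if spot_mask.any() and patch_mask.any() and (spot_mask & patch_mask).any():
        raise SpecError("cold spots and hot patches overlap; adjust the wound geometry")
    if (spot_mask | patch_mask).any() and not ((spot_mask | patch_mask) <= wound).all():
        raise SpecError("cold spots / hot patches extend beyond the wound ellipse")

    if spec.wound_max_offset > 0:
        centre = (
            np.abs(rr - spec.wound_center[0]) <= 1.0
        ) & (np.abs(cc - spec.wound_center[1]) <= 1.0)
        t[centre & wound] = b + spec.wound_max_offset

    # fluctuation: +/- amplitude around the wound mean on interior pixels,
    # sized so the configured fraction of the wound deviates in total
    if spec.fluctuation_fraction > 0:
        interior = ndimage.binary_erosion(
            wound, structure=np.ones((3, 3), dtype=bool), iterations=2
        )
        # keep a guard band clear of fluctuation around the hot patches so no
        # scoring tile mixes patch and fluctuating pixels (mixed tiles would
        # thermally bridge the patches into the bulk during region merging)
        patch_guard = ndimage.binary_dilation(
            patch_mask, structure=np.ones((3, 3), dtype=bool), iterations=2
        )
        eligible = interior & ~spot_mask & ~patch_guard
        deviating_already = int(spot_mask.sum() + patch_mask.sum())
        target = int(round(spec.fluctuation_fraction * wound.sum()))
        n_fluct = max(0, target - deviating_already)
        n_fluct -= n_fluct % 2  # balanced +/- pairs keep the mean in place
        idx = np.flatnonzero(eligible.ravel())
        if n_fluct > idx.size:
            raise SpecError(
                "wound too small for the requested fluctuation fraction"
            )
        chosen = rng.choice(idx, size=n_fluct, replace=False)
        flat = t.ravel()
        keep = wound.ravel().copy()
        keep[chosen] = False
        centre_temp = flat[np.flatnonzero(keep)].mean()
        flat[chosen[: n_fluct // 2]] = centre_temp + spec.fluctuation_amplitude
        flat[chosen[n_fluct // 2 :]] = centre_temp - spec.fluctuation_amplitude
        t = flat.reshape(spec.size)

    if spec.distractor:
        dr = spec.skin_center[0] - 0.15 * spec.size[0]
        dc = spec.skin_center[1] - 0.25 * spec.size[1]
        distractor = _ellipse(spec.size, (dr, dc), (0.03 * spec.size[0], 0.03 * spec.size[1]))
        crust = _ellipse(
            spec.size, spec.wound_center, (0.25 * spec.wound_axes[0], 0.25 * spec.wound_axes[1])
        )
        t[distractor] = b
        t[crust] = b + 2.0
    else:
        distractor = crust = np.zeros(spec.size, dtype=bool)

    t = t + rng.normal(0.0, spec.sensor_noise_sd, size=spec.size)

    # --- visual rendering --------------------------------------------------
    rgb = np.empty((h, w, 3), dtype=float)
    rgb[:] = spec.background_rgb
    rgb[skin] = spec.skin_rgb
    rgb[wound] = spec.wound_rgb
    if spec.distractor:
        rgb[distractor] = spec.wound_rgb
        rgb[crust] = spec.crust_rgb
    rgb += rng.normal(0.0, spec.rgb_noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    pair = ImagePair(ThermalImage(t), VisualImage(rgb), pair_id=spec.pair_id)
    return PhantomResult(
        pair=pair,
        skin_mask=BinaryMask(skin.astype(np.uint8), role="skin"),
        wound_mask=BinaryMask(wound.astype(np.uint8), role="wound"),
        cold_spot_mask=BinaryMask(spot_mask.astype(np.uint8), role="other"),
        margin_isotherm_radius_px=1.5 / spec.margin_gradient,
        expected=spec.expected_scores(),
        expected_delta_t=spec.expected_delta_t,
        spec=spec,
    )


def factorial_design(
    size: tuple[int, int] = (348, 464), rng_seed: int = 0
) -> list[PhantomSpec]:
    """The 3 x 3 x 2 x 2 x 2 feature design spanning every sub-score case."""
    specs = []
    for n_spots in (0, 2, 5):
        for delta_t in (0.5, 1.5, 3.0):
            for inhom in (False, True):
                for conc in (False, True):
                    for gap in (False, True):
                        specs.append(
                            PhantomSpec.from_features(
                                n_cold_spots=n_spots,
                                delta_t=delta_t,
                                inhomogeneous=inhom,
                                concentrated=conc,
                                margin_gap=gap,
                                size=size,
                                rng_seed=rng_seed,
                            )
                        )
    return specs


def generate_distortion_grid(
    params: CameraParameters,
    dot_spacing_px: int = 32,
    size: tuple[int, int] = (240, 320),
    dot_sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic dot grid and its forward-distorted rendering.

    Returns ``(undistorted, distorted, centers_xy)`` where both images are
    float arrays with Gaussian dots and ``centers_xy`` holds the true
    (column, row) dot centers of the undistorted grid.
    """
    h, w = size
    margin = 2 * dot_spacing_px // 2
    xs = np.arange(margin, w - margin + 1, dot_spacing_px, dtype=float)
    ys = np.arange(margin, h - margin + 1, dot_spacing_px, dtype=float)
    centers = np.array([(x, y) for y in ys for x in xs])
    distorted_centers = distort_points(centers, params)

    def render(points: np.ndarray) -> np.ndarray:
        img = np.zeros(size, dtype=float)
        rr, cc = np.mgrid[0:h, 0:w]
        for x, y in points:
            img += np.exp(-(((cc - x) ** 2 + (rr - y) ** 2) / (2 * dot_sigma**2)))
        return img

    return render(centers), render(distorted_centers), centers
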