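"""Domain types and I/O for thermal/visual wound image pairs.

Conventions used throughout the package:

* arrays are indexed ``(row, column)``, 0-based, origin at the top-left;
* thermal images are 2-D float arrays of temperatures in degrees Celsius;
* visual images are ``(H, W, 3)`` uint8 RGB arrays;
* binary masks are 2-D uint8 arrays with values in ``{0, 1}``, where 1 marks
  the pixels to be considered.

Radiometric data is accepted in open dialects only: a CSV matrix, a
whitespace-separated text matrix, or a 16-bit single-channel TIFF whose raw
counts are mapped to Celsius through an affine ``value * scale + offset``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from PIL import Image
from scipy.ndimage import map_coordinates

from .errors import FormatError, UsageError, ValidationError

MIN_SIDE = 8  # minimum grid side the downstream morphological kernels support

ThermalDialect = Literal["csv", "matrix_text", "tiff16"]


@dataclass
class ThermalImage:
    """A radiometric temperature matrix in degrees Celsius."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 2:
            raise ValidationError(f"thermal image must be 2-D, got shape {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValidationError("thermal image contains non-finite temperatures")
        if t.shape[0] < MIN_SIDE or t.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"thermal image must be at least {MIN_SIDE}x{MIN_SIDE}, got {t.shape}"
            )
        self.temperatures = t

    @property
    def height(self) -> int:
        return self.temperatures.shape[0]

    @property
    def width(self) -> int:
        return self.temperatures.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass
class VisualImage:
    """An 8-bit RGB image stored as an (H, W, 3) array."""

    rgb: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.rgb)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValidationError(f"visual image must be (H, W, 3), got shape {a.shape}")
        if a.dtype != np.uint8:
            if np.any(a < 0) or np.any(a > 255):
                raise ValidationError("visual image values must lie in [0, 255]")
            a = a.astype(np.uint8)
        if a.shape[0] < MIN_SIDE or a.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"visual image must be at least {MIN_SIDE}x{MIN_SIDE}, got {a.shape[:2]}"
            )
        self.rgb = a

    @property
    def r(self) -> np.ndarray:
        return self.rgb[:, :, 0]

    @property
    def g(self) -> np.ndarray:
        return self.rgb[:, :, 1]

    @property
    def b(self) -> np.ndarray:
        return self.rgb[:, :, 2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def luma(self) -> np.ndarray:
        """Rec. 601 luma, the grayscale used for darker-than-seed growth."""
        r, g, b = (c.astype(float) for c in (self.r, self.g, self.b))
        return 0.299 * r + 0.587 * g + 0.114 * b


MaskRole = Literal["skin", "wound", "edges", "core", "thermal_margin", "other"]


@dataclass
class BinaryMask:
    """A 0/1 membership map over the same (row, column) grid as its source image."""

    values: np.ndarray
    role: MaskRole = "other"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask entries must be 0/1, found {uniq[:8]}")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass
class ImagePair:
    """One co-framed thermal + visual acquisition of a wound scene.

    The two modalities come from physically distinct cameras; after loading
    they are forced onto a common grid (nearest-neighbour resampling of the
    smaller grid to the larger) but no cross-modal registration is attempted:
    the residual offset between cameras at bedside distance is small relative
    to the region-level statistics computed downstream.
    """

    thermal: ThermalImage
    visual: VisualImage
    pair_id: str = "pair"

    def __post_init__(self) -> None:
        if self.thermal.shape != self.visual.shape:
            h = max(self.thermal.height, self.visual.shape[0])
            w = max(self.thermal.width, self.visual.shape[1])
            self.thermal = ThermalImage(
                _resample_nearest(self.thermal.temperatures, (h, w))
            )
            rgb = np.stack(
                [_resample_nearest(self.visual.rgb[:, :, c], (h, w)) for c in range(3)],
                axis=2,
            )
            self.visual = VisualImage(rgb)

    @property
    def shape(self) -> tuple[int, int]:
        return self.thermal.shape


@dataclass
class CameraParameters:
    """Pinhole intrinsics and Brown–Conrady distortion coefficients."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    modality: Literal["thermal", "visual"] = "visual"

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError("focal lengths must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraParameters":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"cannot parse camera parameters {path}: {exc}") from exc
        try:
            return cls(**{k: data[k] for k in data})
        except TypeError as exc:
            raise FormatError(f"unexpected camera-parameter keys in {path}: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _resample_nearest(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling; preserves label/intensity semantics exactly."""
    h, w = shape
    rows = np.clip(np.round(np.arange(h) * arr.shape[0] / h).astype(int), 0, arr.shape[0] - 1)
    cols = np.clip(np.round(np.arange(w) * arr.shape[1] / w).astype(int), 0, arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_thermal(
    path: str | Path,
    dialect: ThermalDialect = "csv",
    scale: float | None = None,
    offset: float = 0.0,
) -> ThermalImage:
    """Read a temperature matrix in one of the open radiometric dialects.

    For ``tiff16`` the affine conversion ``celsius = raw * scale + offset`` is
    applied; scale/offset may be given explicitly or through a JSON sidecar
    ``<path>.json`` with keys ``scale`` and ``offset``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"thermal file not found: {path}")
    if dialect == "csv":
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse CSV thermal matrix {path}: {exc}") from exc
    elif dialect == "matrix_text":
        try:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse text thermal matrix {path}: {exc}") from exc
    elif dialect == "tiff16":
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if raw.ndim != 2:
            raise FormatError(f"tiff16 thermal image must be single-channel, got {raw.shape}")
        if scale is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise FormatError(
                    f"tiff16 dialect needs scale/offset (argument or sidecar {sidecar})"
                )
            meta = json.loads(sidecar.read_text())
            scale = float(meta["scale"])
            offset = float(meta.get("offset", 0.0))
        arr = raw.astype(float) * scale + offset
    else:
        raise UsageError(f"unknown thermal dialect: {dialect!r}")
    return ThermalImage(arr)


def write_thermal_csv(image: ThermalImage, path: str | Path) -> None:
    np.savetxt(path, image.temperatures, delimiter=",", fmt="%.6f")


def read_visual(path: str | Path) -> VisualImage:
    """Read a PNG/TIFF visual image; requires >= 3 channels, drops alpha."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"visual file not found: {path}")
    try:
        arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise FormatError(f"cannot read visual image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(
            f"visual image must have >= 3 channels, got shape {arr.shape}: {path}"
        )
    return VisualImage(arr[:, :, :3])


def write_visual(image: VisualImage, path: str | Path) -> None:
    Image.fromarray(image.rgb).save(path)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with {0, 1} mapped to {0, 255}."""
    Image.fromarray((mask.values * 255).astype(np.uint8)).save(path)


def read_mask(path: str | Path, role: MaskRole = "other") -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask file not found: {path}")
    try:
        arr = np.asarray(Image.open(path).convert("L"))
    except Exception as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 255))):
        raise ValidationError(
            f"mask PNG must contain only 0/255, found values {uniq[:8]}: {path}"
        )
    return BinaryMask((arr == 255).astype(np.uint8), role=role)


# ---------------------------------------------------------------------------
# lens-distortion correction
# ---------------------------------------------------------------------------

def _distort_normalized(x: np.ndarray, y: np.ndarray, p: CameraParameters):
    """Forward Brown–Conrady model on normalized image coordinates."""
    r2 = x * x + y * y
    radial = 1.0 + p.k1 * r2 + p.k2 * r2 * r2 + p.k3 * r2 * r2 * r2
    xd = x * radial + 2.0 * p.p1 * x * y + p.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p.p1 * (r2 + 2.0 * y * y) + 2.0 * p.p2 * x * y
    return xd, yd


def distort_points(points_xy: np.ndarray, params: CameraParameters) -> np.ndarray:
    """Apply the forward distortion model to pixel coordinates ``(x, y)``."""
    pts = np.asarray(points_xy, dtype=float)
    x = (pts[:, 0] - params.cx) / params.fx
    y = (pts[:, 1] - params.cy) / params.fy
    xd, yd = _distort_normalized(x, y, params)
    return np.stack([xd * params.fx + params.cx, yd * params.fy + params.cy], axis=1)


def _undistort_array(arr: np.ndarray, params: CameraParameters, order: int) -> np.ndarray:
    if not any((params.k1, params.k2, params.k3, params.p1, params.p2)):
        return arr.astype(float).copy()  # identity model: no resampling error
    h, w = arr.shape[:2]
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = (u - params.cx) / params.fx
    y = (v - params.cy) / params.fy
    xd, yd = _distort_normalized(x, y, params)
    cols = xd * params.fx + params.cx
    rows = yd * params.fy + params.cy
    coords = np.stack([rows.ravel(), cols.ravel()])
    out = map_coordinates(arr.astype(float), coords, order=order, mode="nearest")
    return out.reshape(h, w)


def undistort(
    image: ThermalImage | VisualImage, params: CameraParameters
) -> ThermalImage | VisualImage:
    """Resample an image through the inverse of its lens-distortion model.

    Each output pixel is mapped through the forward Brown–Conrady model and
    the input image is sampled bilinearly at that location (the same scheme
    used by standard pinhole undistortion routines). With all distortion
    coefficients zero the mapping is the identity and the output is
    pixel-identical to the input.
    """
    if isinstance(image, ThermalImage):
        if params.modality != "thermal":
            raise UsageError("camera parameters are not for the thermal modality")
        return ThermalImage(_undistort_array(image.temperatures, params, order=1))
    if isinstance(image, VisualImage):
        if params.modality != "visual":
            raise UsageError("camera parameters are not for the visual modality")
        channels = [
            _undistort_array(image.rgb[:, :, c].astype(float), params, order=1)
            for c in range(3)
        ]
        rgb = np.clip(np.stack(channels, axis=2), 0, 255).round().astype(np.uint8)
        return VisualImage(rgb)
    raise UsageError(f"cannot undistort object of type {type(image).__name__}")
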