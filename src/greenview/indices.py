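"""Greenery scoring math: green-pixel classification, vegetation indices, GVI and EGVI.

The Green View Index (GVI) of a scene is the percentage of its pixels
classified as green vegetation::

    GVI = 100 * n_green / n_total

The Enhanced Green View Index (EGVI) discounts that fraction by the mean
per-pixel vegetation-health index (NDVI or VARI) over the green pixels::

    EGVI = 100 * n_green * mean_index / n_total = GVI * mean_index

NDVI = (NIR - R)/(NIR + R) requires a co-registered near-infrared band and
lies in [-1, 1]; VARI = (G - R)/(G + R - B) needs only the RGB planes but is
unbounded and measures relative rather than absolute greenness, so
NDVI-based scores are preferred when an NIR band exists.

All planes are float arrays in [0, 1]; masks are boolean arrays of the same
shape. Classification uses a hue/saturation/value box in HSV space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "RGBImage",
    "NIRImage",
    "HSVThreshold",
    "DEFAULT_THRESHOLD",
    "GreenMask",
    "IndexMap",
    "GreeneryScores",
    "RegionOfInterest",
    "CoRegistrationError",
    "rgb_to_hsv",
    "classify_green",
    "compute_ndvi",
    "compute_vari",
    "compute_gvi",
    "mean_index_over_mask",
    "compute_egvi",
    "score_region",
    "score_scene",
]

IndexKind = Literal["NDVI", "VARI"]


class CoRegistrationError(ValueError):
    """Raised when two planes that must share a pixel grid do not."""


def _as_plane(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D plane, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RGBImage:
    """Three co-registered intensity planes in [0, 1]."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self):
        for name in ("red", "green", "blue"):
            object.__setattr__(self, name, _as_plane(getattr(self, name), name))
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise CoRegistrationError(
                f"RGB planes disagree in shape: {self.red.shape}, "
                f"{self.green.shape}, {self.blue.shape}"
            )
        for name in ("red", "green", "blue"):
            plane = getattr(self, name)
            if not np.all(np.isfinite(plane)):
                raise ValueError(f"{name} plane contains non-finite values")
            if plane.size and (plane.min() < 0 or plane.max() > 1):
                raise ValueError(f"{name} plane has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    def stacked(self) -> np.ndarray:
        """Return an (H, W, 3) array; convenient for color-space routines."""
        return np.dstack([self.red, self.green, self.blue])

    def crop(self, roi: "RegionOfInterest") -> "RGBImage":
        roi.check_bounds(self.height, self.width)
        sl = roi.slices
        return RGBImage(self.red[sl], self.green[sl], self.blue[sl])


@dataclass(frozen=True)
class NIRImage:
    """Single near-infrared intensity plane in [0, 1]."""

    plane: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "plane", _as_plane(self.plane, "NIR"))
        if not np.all(np.isfinite(self.plane)):
            raise ValueError("NIR plane contains non-finite values")
        if self.plane.size and (self.plane.min() < 0 or self.plane.max() > 1):
            raise ValueError("NIR plane has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane.shape

    def crop(self, roi: "RegionOfInterest") -> "NIRImage":
        roi.check_bounds(*self.shape)
        return NIRImage(self.plane[roi.slices])


@dataclass(frozen=True)
class HSVThreshold:
    """Green-classification box in HSV space.

    A pixel is green iff hue_min <= H <= hue_max (degrees), S >= saturation_min
    and V >= value_min. The defaults bracket the vegetation hue band used in
    common green-extraction practice; all four are meant to be tuned per
    camera and lighting.
    """

    hue_min: float = 60.0
    hue_max: float = 180.0
    saturation_min: float = 0.15
    value_min: float = 0.10

    def __post_init__(self):
        if not (0 <= self.hue_min < self.hue_max < 360):
            raise ValueError(
                "require 0 <= hue_min < hue_max < 360 (wrap-around bands unsupported)"
            )
        if not (0 <= self.saturation_min <= 1 and 0 <= self.value_min <= 1):
            raise ValueError("saturation_min and value_min must lie in [0, 1]")


DEFAULT_THRESHOLD = HSVThreshold()


@dataclass(frozen=True)
class GreenMask:
    """Boolean vegetation mask with its pixel counts."""

    mask: np.ndarray
    n_green: int = field(init=False)
    n_total: int = field(init=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "n_green", int(mask.sum()))
        object.__setattr__(self, "n_total", int(mask.size))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def crop(self, roi: "RegionOfInterest") -> "GreenMask":
        roi.check_bounds(*self.shape)
        return GreenMask(self.mask[roi.slices])


@dataclass(frozen=True)
class IndexMap:
    """Per-pixel vegetation-health plane with a validity mask.

    ``valid`` is False where the defining ratio's denominator vanished; those
    pixels carry no health information and are excluded from aggregation.
    NDVI values are guaranteed in [-1, 1] where valid; VARI is unbounded.
    """

    values: np.ndarray
    valid: np.ndarray
    kind: IndexKind

    def __post_init__(self):
        values = _as_plane(self.values, "values")
        valid = np.asarray(self.valid, dtype=bool)
        if valid.shape != values.shape:
            raise CoRegistrationError("values and valid planes disagree in shape")
        if self.kind not in ("NDVI", "VARI"):
            raise ValueError(f"unknown index kind {self.kind!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def crop(self, roi: "RegionOfInterest") -> "IndexMap":
        roi.check_bounds(*self.shape)
        sl = roi.slices
        return IndexMap(self.values[sl], self.valid[sl], self.kind)


@dataclass(frozen=True)
class GreeneryScores:
    """Per-scene (or per-region) result record."""

    n_green: int
    n_total: int
    gvi: float
    mean_index: float
    egvi: float
    index_kind: str  # "NDVI", "VARI" or "none"
    n_aggregated: int

    def to_dict(self, ndigits: int | None = 2) -> dict:
        """Plain-dict form for reports; scores rounded to ``ndigits`` places."""
        r = (lambda x: round(x, ndigits)) if ndigits is not None else (lambda x: x)
        return {
            "n_total": self.n_total,
            "n_green": self.n_green,
            "gvi": r(self.gvi),
            "index_kind": self.index_kind,
            "mean_index": r(self.mean_index),
            "n_aggregated": self.n_aggregated,
            "egvi": r(self.egvi),
        }


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open 0-based pixel bounds; row 0 is the top image row."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError(f"degenerate ROI {self}")

    def check_bounds(self, height: int, width: int) -> None:
        if self.row_end > height or self.col_end > width:
            raise ValueError(
                f"ROI {self} exceeds image bounds {height}x{width}"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_end), slice(self.col_start, self.col_end))

    @classmethod
    def full_frame(cls, height: int, width: int) -> "RegionOfInterest":
        return cls(0, height, 0, width)


def rgb_to_hsv(image: RGBImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert to hexcone HSV; hue in degrees [0, 360), S and V in [0, 1].

    Achromatic pixels (R = G = B) get hue 0 and saturation 0, so they can
    never pass a classifier with saturation_min > 0.
    """
    hsv = rgb2hsv(image.stacked())
    hue = hsv[..., 0] * 360.0
    hue[hue >= 360.0] -= 360.0
    return hue, hsv[..., 1], hsv[..., 2]


def classify_green(image: RGBImage, threshold: HSVThreshold = DEFAULT_THRESHOLD) -> GreenMask:
    """Threshold the scene in HSV space into green / non-green pixels."""
    hue, sat, val = rgb_to_hsv(image)
    mask = (
        (hue >= threshold.hue_min)
        & (hue <= threshold.hue_max)
        & (sat >= threshold.saturation_min)
        & (val >= threshold.value_min)
    )
    return GreenMask(mask)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    valid = den != 0
    values = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=values, where=valid)
    finite = np.isfinite(values)
    valid &= finite
    values[~valid] = 0.0
    return values, valid


def compute_ndvi(nir: NIRImage, image: RGBImage) -> IndexMap:
    """NDVI = (NIR - R)/(NIR + R) per pixel; invalid where NIR + R = 0."""
    if nir.shape != image.shape:
        raise CoRegistrationError(
            f"NIR shape {nir.shape} does not match RGB shape {image.shape}"
        )
    values, valid = _safe_ratio(nir.plane - image.red, nir.plane + image.red)
    return IndexMap(values, valid, "NDVI")


def compute_vari(image: RGBImage) -> IndexMap:
    """VARI = (G - R)/(G + R - B) per pixel; invalid where G + R - B = 0."""
    values, valid = _safe_ratio(
        image.green - image.red, image.green + image.red - image.blue
    )
    return IndexMap(values, valid, "VARI")


def compute_gvi(mask: GreenMask) -> float:
    """Green View Index: 100 * n_green / n_total, in [0, 100]."""
    if mask.n_total == 0:
        raise ValueError("cannot score an empty image (0 pixels)")
    return 100.0 * mask.n_green / mask.n_total


def mean_index_over_mask(
    index: IndexMap, mask: GreenMask, clamp: bool = True
) -> tuple[float, int]:
    """Mean health index over pixels that are green AND valid.

    With ``clamp`` (the default) each contributing value is clipped to [0, 1]
    before averaging, so the mean acts as a health weight and EGVI <= GVI is
    guaranteed. With ``clamp=False`` raw values are averaged; negative NDVI
    (water, shadow) or over-unity VARI then flow through unchanged.

    Returns ``(mean, n_aggregated)``; an empty support gives mean 0.
    """
    if index.shape != mask.shape:
        raise CoRegistrationError(
            f"index shape {index.shape} does not match mask shape {mask.shape}"
        )
    support = mask.mask & index.valid
    n = int(support.sum())
    if n == 0:
        return 0.0, 0
    vals = index.values[support]
    if clamp:
        vals = np.clip(vals, 0.0, 1.0)
    return float(vals.mean()), n


def compute_egvi(
    mask: GreenMask, index: IndexMap | None, clamp: bool = True
) -> GreeneryScores:
    """Assemble the full score record: counts, GVI, mean index, EGVI.

    ``index=None`` scores greenery fraction only (mean index 1, EGVI = GVI,
    index_kind "none").
    """
    gvi = compute_gvi(mask)
    if index is None:
        return GreeneryScores(
            n_green=mask.n_green,
            n_total=mask.n_total,
            gvi=gvi,
            mean_index=1.0,
            egvi=gvi,
            index_kind="none",
            n_aggregated=mask.n_green,
        )
    mean_index, n_agg = mean_index_over_mask(index, mask, clamp=clamp)
    return GreeneryScores(
        n_green=mask.n_green,
        n_total=mask.n_total,
        gvi=gvi,
        mean_index=mean_index,
        egvi=gvi * mean_index,
        index_kind=index.kind,
        n_aggregated=n_agg,
    )


def score_scene(
    image: RGBImage,
    nir: NIRImage | None = None,
    threshold: HSVThreshold = DEFAULT_THRESHOLD,
    index_kind: IndexKind = "NDVI",
    clamp: bool = True,
) -> GreeneryScores:
    """Classify, build the requested index map, and score a whole scene."""
    if index_kind == "NDVI":
        if nir is None:
            raise ValueError("NDVI scoring requires a co-registered NIR band")
        index = compute_ndvi(nir, image)
    elif index_kind == "VARI":
        index = compute_vari(image)
    else:
        raise ValueError(f"unknown index kind {index_kind!r}")
    mask = classify_green(image, threshold)
    return compute_egvi(mask, index, clamp=clamp)


def score_region(
    image: RGBImage,
    nir: NIRImage | None,
    roi: RegionOfInterest,
    threshold: HSVThreshold = DEFAULT_THRESHOLD,
    index_kind: IndexKind = "NDVI",
    clamp: bool = True,
) -> GreeneryScores:
    """Score a rectangular sub-region: crop all planes, then classify and score.

    A full-frame ROI reproduces the whole-scene scores exactly.
    """
    roi.check_bounds(image.height, image.width)
    cropped = image.crop(roi)
    cropped_nir = nir.crop(roi) if nir is not None else None
    return score_scene(
        cropped, cropped_nir, threshold=threshold, index_kind=index_kind, clamp=clamp
    )
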