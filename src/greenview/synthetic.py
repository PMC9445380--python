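"""Synthetic RGB+NIR scene generator with exact ground truth.

Scenes are built from non-overlapping green regions (rectangles or ellipses)
on a non-green background, each carrying a target vegetation-health index
``v``. The NIR plane is solved per pixel from the red plane so that
``(NIR - R)/(NIR + R) = v`` exactly::

    NIR = R * (1 + v) / (1 - v)

If the solved NIR exceeds 1 at a pixel, NIR and R are both rescaled by
1/NIR — the target index is preserved and both planes stay in [0, 1], at
the cost of a darker red band there. ``v = 1`` with R > 0 is unrepresentable
and rejected, as is R = 0 with ``v < 1`` (the ratio then cannot reach v).

The two-location worked example — a 165-pixel canvas holding a 26-pixel
tree, health index 0.9 (location 1) or 0.4 (location 2) — is provided by
:func:`make_worked_example`. Default colors sit on the 1/255 grid so the
solved NIR is exactly representable in 8-bit files: green (12, 204, 12)
gives NIR 228/255 for v = 0.9 and 28/255 for v = 0.4.

Gaussian pixel noise (``noise_sd``, intensity units) is added to every
plane after the ground truth is frozen, then clipped to [0, 1]; a single
seeded generator stream makes scenes bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .imagery_io import SceneBundle
from .indices import GreeneryScores, GreenMask, IndexMap, NIRImage, RGBImage

__all__ = [
    "SceneSpecError",
    "Region",
    "SceneSpec",
    "generate_scene",
    "make_worked_example",
    "WORKED_EXAMPLE_INDEX",
]

# Default palette, on the 1/255 grid (see module docstring).
GREEN_RGB = (12 / 255, 204 / 255, 12 / 255)
BACKGROUND_RGB = (95 / 255, 95 / 255, 95 / 255)
BACKGROUND_INDEX = 0.05

#: Uniform health index assumed for the tree at each worked-example location.
WORKED_EXAMPLE_INDEX = {1: 0.9, 2: 0.4}


class SceneSpecError(ValueError):
    """Raised for an invalid or unrepresentable scene specification."""


@dataclass(frozen=True)
class Region:
    """One green region: a rectangle or an axis-aligned ellipse.

    Rectangles use half-open 0-based bounds (row_start, row_end, col_start,
    col_end). Ellipses use (center_row, center_col, radius_rows, radius_cols)
    and include pixels whose centers satisfy the ellipse inequality.
    """

    shape: Literal["rectangle", "ellipse"]
    geometry: tuple[float, float, float, float]
    rgb_color: tuple[float, float, float] = GREEN_RGB
    target_index: float = 0.9

    def __post_init__(self):
        if self.shape not in ("rectangle", "ellipse"):
            raise SceneSpecError(f"unknown region shape {self.shape!r}")
        if not -1.0 <= self.target_index <= 1.0:
            raise SceneSpecError(
                f"target_index {self.target_index} outside [-1, 1]"
            )

    def rasterize(self, height: int, width: int) -> np.ndarray:
        if self.shape == "rectangle":
            r0, r1, c0, c1 = (int(g) for g in self.geometry)
            if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
                raise SceneSpecError(
                    f"rectangle {self.geometry} outside {height}x{width} canvas"
                )
            m = np.zeros((height, width), dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        cr, cc, rr, rc = self.geometry
        if rr <= 0 or rc <= 0:
            raise SceneSpecError("ellipse radii must be positive")
        if cr - rr < -0.5 or cr + rr > height - 0.5 or cc - rc < -0.5 or cc + rc > width - 0.5:
            raise SceneSpecError(
                f"ellipse {self.geometry} extends outside {height}x{width} canvas"
            )
        rows = np.arange(height)[:, None]
        cols = np.arange(width)[None, :]
        return ((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "geometry": list(self.geometry),
            "rgb_color": list(self.rgb_color),
            "target_index": self.target_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(
            shape=d["shape"],
            geometry=tuple(d["geometry"]),
            rgb_color=tuple(d.get("rgb_color", GREEN_RGB)),
            target_index=float(d.get("target_index", 0.9)),
        )


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; expressible in YAML/JSON."""

    width: int
    height: int
    regions: tuple[Region, ...] = ()
    background_rgb: tuple[float, float, float] = BACKGROUND_RGB
    background_index: float = BACKGROUND_INDEX
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise SceneSpecError("canvas dimensions must be positive")
        if self.noise_sd < 0:
            raise SceneSpecError("noise_sd must be >= 0")
        object.__setattr__(self, "regions", tuple(self.regions))

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "regions": [r.to_dict() for r in self.regions],
            "background_rgb": list(self.background_rgb),
            "background_index": self.background_index,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            regions=tuple(Region.from_dict(r) for r in d.get("regions", [])),
            background_rgb=tuple(d.get("background_rgb", BACKGROUND_RGB)),
            background_index=float(d.get("background_index", BACKGROUND_INDEX)),
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )


def _solve_nir(red: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve NIR from the red plane and target NDVI; may rescale red.

    Returns (nir, red) with both planes in [0, 1] and
    (nir - red)/(nir + red) == target everywhere.
    """
    at_one = target >= 1.0
    if np.any(at_one & (red > 0)):
        raise SceneSpecError(
            "target_index = 1 is unrepresentable where the red band is > 0"
        )
    if np.any((red == 0) & ~at_one):
        raise SceneSpecError(
            "red = 0 pixels can only carry target_index = 1; "
            "use a color with a nonzero red component"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        nir = np.where(at_one, 1.0, red * (1.0 + target) / (1.0 - target))
    over = nir > 1.0
    red = np.where(over, red / nir, red)
    nir = np.where(over, 1.0, nir)
    return nir, red


def generate_scene(
    spec: SceneSpec,
) -> tuple[RGBImage, NIRImage, GreenMask, IndexMap]:
    """Render a spec into (RGB, NIR, ground-truth mask, ground-truth index map).

    With ``noise_sd = 0`` the outputs are exact: the default classifier
    recovers the mask pixel-for-pixel and NDVI on the rendered planes equals
    each region's target index to float precision. Identical specs (same
    seed) yield bit-identical scenes.
    """
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    red = np.full((h, w), spec.background_rgb[0], dtype=float)
    green = np.full((h, w), spec.background_rgb[1], dtype=float)
    blue = np.full((h, w), spec.background_rgb[2], dtype=float)
    target = np.full((h, w), spec.background_index, dtype=float)

    for region in spec.regions:
        m = region.rasterize(h, w)
        if np.any(m & mask):
            raise SceneSpecError("regions overlap; ground-truth counts would be ambiguous")
        mask |= m
        red[m], green[m], blue[m] = region.rgb_color
        target[m] = region.target_index

    nir, red = _solve_nir(red, target)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        planes = [red, green, blue, nir]
        for i, plane in enumerate(planes):
            planes[i] = np.clip(
                plane + rng.normal(0.0, spec.noise_sd, size=plane.shape), 0.0, 1.0
            )
        red, green, blue, nir = planes

    rgb = RGBImage(red, green, blue)
    truth_mask = GreenMask(mask)
    truth_index = IndexMap(target, np.ones_like(mask, dtype=bool), "NDVI")
    return rgb, NIRImage(nir), truth_mask, truth_index


# The 26-pixel tree: five crown rows (3, 5, 7, 5, 3 px) over a 3-px trunk,
# as non-overlapping rectangles on the 15-row x 11-column canvas. Only the
# counts matter; the shape itself is arbitrary.
_TREE_RECTANGLES = (
    (2, 3, 4, 7),
    (3, 4, 3, 8),
    (4, 5, 2, 9),
    (5, 6, 3, 8),
    (6, 7, 4, 7),
    (7, 10, 5, 6),
)

FIXTURE_HEIGHT = 15
FIXTURE_WIDTH = 11


def worked_example_spec(location: int, noise_sd: float = 0.0, seed: int = 0) -> SceneSpec:
    """SceneSpec for the two-location worked example (165 px, 26-px tree)."""
    if location not in WORKED_EXAMPLE_INDEX:
        raise ValueError(f"location must be 1 or 2, got {location}")
    v = WORKED_EXAMPLE_INDEX[location]
    regions = tuple(
        Region(shape="rectangle", geometry=rect, rgb_color=GREEN_RGB, target_index=v)
        for rect in _TREE_RECTANGLES
    )
    return SceneSpec(
        width=FIXTURE_WIDTH,
        height=FIXTURE_HEIGHT,
        regions=regions,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_worked_example(location: int) -> tuple[SceneBundle, GreeneryScores]:
    """Build the canonical worked-example scene and its formula-exact scores.

    Location 1 carries a uniform health index of 0.9, location 2 of 0.4;
    both share the same 26-green / 165-total mask, so GVI is identical and
    only EGVI discriminates between them.
    """
    spec = worked_example_spec(location)
    rgb, nir, mask, _ = generate_scene(spec)
    bundle = SceneBundle(
        scene_id=f"location-{location}",
        rgb=rgb,
        nir=nir,
        source_paths=(),
        bit_depth=8,
    )
    v = WORKED_EXAMPLE_INDEX[location]
    gvi = 100.0 * mask.n_green / mask.n_total
    expected = GreeneryScores(
        n_green=mask.n_green,
        n_total=mask.n_total,
        gvi=gvi,
        mean_index=v,
        egvi=gvi * v,
        index_kind="NDVI",
        n_aggregated=mask.n_green,
    )
    return bundle, expected
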