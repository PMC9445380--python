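"""Raster input/output: read RGB and NIR scenes, write masks and index maps.

PNG/JPEG go through Pillow, TIFF/GeoTIFF through tifffile. All intensities
are normalized on read — 8-bit sources divided by 255, 16-bit by 65535 — so
downstream index math is bit-depth independent. Alpha channels are dropped
(logged), palette PNGs expanded to RGB.

Index maps are written as float32 TIFF with NaN at invalid pixels and a
GDAL_NODATA tag of "nan" so GIS readers honour the no-data convention.
Georeferencing tags of input GeoTIFFs are not propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .indices import GreenMask, IndexMap, NIRImage, RGBImage

__all__ = [
    "SceneBundle",
    "read_rgb",
    "read_nir",
    "read_scene",
    "write_mask",
    "read_mask",
    "write_index_map",
    "read_index_map",
]

log = logging.getLogger(__name__)

# ASCII-typed private TIFF tag GDAL uses to declare the no-data value.
GDAL_NODATA_TAG = 42113

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _normalize(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Scale an integer raster into [0, 1]; return (plane, bit_depth)."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(float)
        if out.size and (np.nanmin(out) < 0 or np.nanmax(out) > 1):
            raise ValueError("float raster values must already lie in [0, 1]")
        return out, 8
    raise ValueError(f"unsupported raster dtype {arr.dtype}")


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return tifffile.imread(path)
    with Image.open(path) as im:
        if im.mode == "P":
            im = im.convert("RGB")
        return np.asarray(im)


def read_rgb(path: str | Path) -> tuple[RGBImage, int]:
    """Read a 3-or-4-channel raster as an RGBImage; returns (image, bit_depth).

    Alpha channels are discarded with a log message; a single-channel file is
    rejected because per-pixel index math needs distinct color bands.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError(
            f"{path}: expected 3 channels (RGB), got shape {arr.shape}"
        )
    if arr.shape[-1] == 4:
        log.info("%s: dropping alpha channel", path)
        arr = arr[..., :3]
    elif arr.shape[-1] > 4:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[-1]}")
    planes, depth = _normalize(arr)
    return RGBImage(planes[..., 0], planes[..., 1], planes[..., 2]), depth


def read_nir(path: str | Path, band: int | None = None) -> NIRImage:
    """Read a single-band raster as the NIR plane.

    A multi-band file is rejected unless ``band`` (0-based) selects one.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim == 3:
        if band is None:
            raise ValueError(
                f"{path}: multi-band file offered as NIR; pass a 0-based band index"
            )
        arr = arr[..., band]
    elif arr.ndim != 2:
        raise ValueError(f"{path}: cannot interpret shape {arr.shape} as a single band")
    plane, _ = _normalize(arr)
    return NIRImage(plane)


@dataclass(frozen=True)
class SceneBundle:
    """One scene's inputs: RGB, optional co-registered NIR, provenance."""

    scene_id: str
    rgb: RGBImage
    nir: NIRImage | None
    source_paths: tuple[str, ...]
    bit_depth: int

    def __post_init__(self):
        if not self.scene_id:
            raise ValueError("scene_id must be non-empty")
        if self.nir is not None and self.nir.shape != self.rgb.shape:
            raise ValueError(
                f"NIR shape {self.nir.shape} does not match RGB shape "
                f"{self.rgb.shape} for scene {self.scene_id!r}"
            )


def read_scene(
    scene_id: str,
    rgb_path: str | Path,
    nir_path: str | Path | None = None,
    nir_band: int | None = None,
) -> SceneBundle:
    """Load and pair the rasters of one scene, asserting co-registration."""
    rgb, depth = read_rgb(rgb_path)
    nir = read_nir(nir_path, band=nir_band) if nir_path else None
    paths = (str(rgb_path),) + ((str(nir_path),) if nir_path else ())
    return SceneBundle(scene_id, rgb, nir, paths, depth)


def write_mask(mask: GreenMask, path: str | Path) -> None:
    """Write the green mask as an 8-bit PNG: green=255, non-green=0."""
    arr = np.where(mask.mask, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask(path: str | Path) -> GreenMask:
    """Read back a mask PNG written by write_mask (any nonzero pixel is green)."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return GreenMask(arr > 0)


def write_index_map(index: IndexMap, path: str | Path) -> None:
    """Write a float32 TIFF with NaN no-data at invalid pixels.

    Values are stored unclipped — over-unity VARI survives the round trip;
    clamping is an aggregation-time choice, not an I/O one.
    """
    data = index.values.astype(np.float32)
    data[~index.valid] = np.nan
    tifffile.imwrite(
        Path(path),
        data,
        extratags=[(GDAL_NODATA_TAG, "s", 0, "nan")],
        metadata={"index_kind": index.kind},
    )


def read_index_map(path: str | Path, kind: str = "NDVI") -> IndexMap:
    """Read back an index-map TIFF; NaN (or the GDAL_NODATA value) is invalid."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        tag = page.tags.get(GDAL_NODATA_TAG)
        if tf.shaped_metadata:
            kind = tf.shaped_metadata[0].get("index_kind", kind)
    valid = np.isfinite(data)
    if tag is not None:
        nodata = float(tag.value)
        if np.isfinite(nodata):
            valid &= data != nodata
    data[~valid] = 0.0
    return IndexMap(data, valid, kind)  # type: ignore[arg-type]
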