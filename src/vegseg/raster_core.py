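"""Raster data model, TIFF I/O, radiometric scaling, and tiling.

The pipeline operates on multiband aerial imagery -- nominally the four
NAIP bands (blue, green, red, near-infrared) at 8-bit radiometric depth.
Everything downstream (index computation, masking, the three segmentation
engines) consumes the :class:`Raster` container defined here.

Conventions
-----------
* 0-based, row-major ``(row, col)`` pixel coordinates.
* ``values`` is ``(height, width, channels)`` float64 (after scaling) or
  the source integer dtype (before scaling).
* ``nodata_mask`` is ``(height, width)`` boolean, True = excluded pixel.
  A pixel masked in any band is masked in all derived products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Raster",
    "Tile",
    "TileGrid",
    "read_raster",
    "write_raster",
    "scale_dn",
    "tile",
    "reassemble",
    "export_class_png",
    "CLASS_PALETTE",
    "CLASS_NAMES",
]

#: Canonical land-cover classes, in label order.
CLASS_NAMES = ("water/shadow", "ground/soil", "grass", "trees/shrubs", "other")

#: Display palette for class maps (RGB). Masked pixels render black.
CLASS_PALETTE = {
    "water/shadow": (68, 114, 196),   # blue
    "ground/soil": (244, 177, 183),   # pink
    "grass": (112, 173, 71),          # green
    "trees/shrubs": (237, 125, 49),   # orange
    "other": (255, 255, 255),         # white
    "masked": (0, 0, 0),              # black
}

DEFAULT_BAND_NAMES = ("blue", "green", "red", "nir")


class RasterFormatError(ValueError):
    """Raised for unreadable or structurally invalid raster files."""


@dataclass
class Raster:
    """An in-memory multiband raster.

    Parameters
    ----------
    values : ndarray, shape (H, W, C)
        Pixel values, band-interleaved.
    channel_names : tuple of str
        One name per channel, e.g. ``("blue", "green", "red", "nir")``.
    nodata_mask : ndarray of bool, shape (H, W)
        True marks pixels excluded from all analysis.
    bit_depth : int
        Radiometric depth of the source (8 for NAIP).
    geo : dict or None
        Opaque georeferencing record (affine transform, CRS string);
        carried through unchanged by every operation.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]
    nodata_mask: np.ndarray | None = None
    bit_depth: int = 8
    geo: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError(f"values must be (H, W, C), got shape {self.values.shape}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.values.shape[2]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[2]} channels"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[:2], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[:2]:
            raise ValueError("nodata_mask shape does not match values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by name (case-insensitive)."""
        names = [c.lower() for c in self.channel_names]
        try:
            idx = names.index(name.lower())
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.values[:, :, idx]

    def with_values(self, values: np.ndarray, channel_names=None) -> "Raster":
        return Raster(
            values=values,
            channel_names=self.channel_names if channel_names is None else channel_names,
            nodata_mask=self.nodata_mask.copy(),
            bit_depth=self.bit_depth,
            geo=self.geo,
        )


@dataclass
class Tile:
    """One tile view: a Raster plus its origin offsets in the source."""

    raster: Raster
    row_off: int
    col_off: int
    is_partial: bool = False


@dataclass
class TileGrid:
    tile_height: int
    tile_width: int
    source_shape: tuple[int, int]
    tiles: list[Tile] = field(default_factory=list)

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)


def read_raster(path: str | Path) -> Raster:
    """Read a multiband TIFF into a :class:`Raster`.

    Bands are returned in file order. Channel names, nodata value, bit
    depth and the georeferencing record are recovered from the JSON
    ImageDescription written by :func:`write_raster`; for foreign files
    bands get generic names and an all-false mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:  # unreadable / not a TIFF
        raise RasterFormatError(f"cannot read raster {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise RasterFormatError(f"unsupported raster dimensionality {arr.shape}")
    # stored as (C, H, W); move to (H, W, C)
    if arr.shape[0] == 0:
        raise RasterFormatError("raster has zero bands")
    values = np.moveaxis(arr, 0, -1)

    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = meta.get("channel_names")
    if not names or len(names) != values.shape[2]:
        names = tuple(f"band_{i + 1}" for i in range(values.shape[2]))
    bit_depth = int(meta.get("bit_depth", 16 if values.dtype.itemsize > 1 else 8))
    geo = meta.get("geo")

    mask = np.zeros(values.shape[:2], dtype=bool)
    nodata = meta.get("nodata")
    if nodata is not None:
        mask |= np.all(values == nodata, axis=2)
    return Raster(values=values, channel_names=tuple(names), nodata_mask=mask,
                  bit_depth=bit_depth, geo=geo)


def write_raster(raster: Raster, path: str | Path, nodata=None) -> Path:
    """Write a Raster as a multiband TIFF (bands as planes, C×H×W).

    Metadata (channel names, bit depth, nodata value, geo record) goes
    into a JSON ImageDescription so that read_raster round-trips exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channel_names": list(raster.channel_names),
        "bit_depth": int(raster.bit_depth),
        "nodata": nodata,
        "geo": raster.geo,
    }
    data = np.moveaxis(raster.values, -1, 0)
    tifffile.imwrite(str(path), data, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def scale_dn(raster: Raster) -> Raster:
    """Scale integer digital numbers to reflectance-like values in [0, 1].

    Divides non-masked values by ``2**bit_depth - 1``. The mask is
    unchanged. Raises if any value exceeds the radiometric range.
    """
    if raster.bit_depth not in (8, 16):
        raise ValueError(f"unsupported bit depth {raster.bit_depth}")
    top = float(2 ** raster.bit_depth - 1)
    vals = np.asarray(raster.values, dtype=np.float64)
    valid = ~raster.nodata_mask
    if np.any(vals[valid] > top) or np.any(vals[valid] < 0):
        raise ValueError(f"values outside [0, {top}] for bit depth {raster.bit_depth}")
    return raster.with_values(vals / top)


def tile(raster: Raster, tile_height: int = 800, tile_width: int = 800) -> TileGrid:
    """Partition a raster into row-major tiles of the given size.

    Full tiles cover the largest multiple of the tile size; residual edge
    strips come back as smaller tiles flagged ``is_partial``. A tile
    request larger than the raster yields a single partial tile.
    """
    if tile_height < 1 or tile_width < 1:
        raise ValueError("tile dimensions must be >= 1")
    h, w = raster.height, raster.width
    grid = TileGrid(tile_height=tile_height, tile_width=tile_width, source_shape=(h, w))
    for r0 in range(0, h, tile_height):
        for c0 in range(0, w, tile_width):
            r1 = min(r0 + tile_height, h)
            c1 = min(c0 + tile_width, w)
            sub = Raster(
                values=raster.values[r0:r1, c0:c1],
                channel_names=raster.channel_names,
                nodata_mask=raster.nodata_mask[r0:r1, c0:c1],
                bit_depth=raster.bit_depth,
                geo=raster.geo,
            )
            partial = (r1 - r0 != tile_height) or (c1 - c0 != tile_width)
            grid.tiles.append(Tile(raster=sub, row_off=r0, col_off=c0, is_partial=partial))
    return grid


def reassemble(grid: TileGrid) -> np.ndarray:
    """Stitch a TileGrid back into the source value array (exact inverse of tile)."""
    h, w = grid.source_shape
    first = grid.tiles[0].raster
    out = np.empty((h, w, first.n_channels), dtype=first.values.dtype)
    for t in grid.tiles:
        th, tw = t.raster.height, t.raster.width
        out[t.row_off:t.row_off + th, t.col_off:t.col_off + tw] = t.raster.values
    return out


def export_class_png(labels: np.ndarray, class_names, path: str | Path) -> Path:
    """Render an integer class-label plane to PNG with the fixed palette.

    ``labels`` uses -1 as the masked sentinel; other values index into
    ``class_names``, which must be drawn from :data:`CLASS_NAMES` (unknown
    names render white).
    """
    from PIL import Image

    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    rgb[labels == -1] = CLASS_PALETTE["masked"]
    for lab, name in enumerate(class_names):
        rgb[labels == lab] = CLASS_PALETTE.get(name, (255, 255, 255))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb).save(path)
    return path
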