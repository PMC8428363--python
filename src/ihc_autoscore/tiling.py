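"""Whole-slide tile partitioning and tumor/non-tumor tile labelling.

A slide is partitioned into non-overlapping 800 x 800 pixel tiles on a grid
anchored at the image origin; remainder pixels at the right/bottom edges are
dropped rather than padded, so every emitted tile is full-size. A tile is a
tumor tile when its center point lies inside (boundary included) any tumor
annotation polygon.

Coordinate convention: x right, y down, 0-based pixel indices; a tile with
grid indices (i, j) covers the half-open box [i*800, (i+1)*800) x
[j*800, (j+1)*800) in (x, y), and its center is the point
(i*800 + 400, j*800 + 400).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape

TILE_SIZE = 800

__all__ = ["TILE_SIZE", "TileLabel", "Tile", "partition", "label_tile",
           "label_tiles", "load_annotations_geojson", "tile_manifest"]


class TileLabel(str, Enum):
    TUMOR = "tumor"
    NON_TUMOR = "non-tumor"
    UNLABELED = "unlabeled"


@dataclass
class Tile:
    """One full 800x800 tile cut from a slide."""

    i: int                      # grid column index (x direction)
    j: int                      # grid row index (y direction)
    x: int                      # pixel origin, x = i * TILE_SIZE
    y: int                      # pixel origin, y = j * TILE_SIZE
    pixels: np.ndarray          # (TILE_SIZE, TILE_SIZE, 3) uint8 view
    label: TileLabel = TileLabel.UNLABELED
    slide_id: str | None = None

    @property
    def center(self) -> tuple[float, float]:
        """Tile center in slide pixel coordinates (x, y)."""
        return (self.x + TILE_SIZE / 2, self.y + TILE_SIZE / 2)


def partition(image: np.ndarray, slide_id: str | None = None) -> list[Tile]:
    """Partition an RGB slide image into full, non-overlapping tiles.

    Returns floor(W/800) * floor(H/800) tiles in row-major (j, i) order.
    Right/bottom remainder strips narrower than a tile are dropped. Tile
    pixel arrays are views into ``image``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    nj, ni = h // TILE_SIZE, w // TILE_SIZE
    tiles = []
    for j in range(nj):
        for i in range(ni):
            y, x = j * TILE_SIZE, i * TILE_SIZE
            tiles.append(Tile(i=i, j=j, x=x, y=y,
                              pixels=image[y:y + TILE_SIZE, x:x + TILE_SIZE],
                              slide_id=slide_id))
    return tiles


def _validate_polygon(poly: Polygon) -> Polygon:
    if not isinstance(poly, Polygon):
        poly = Polygon(poly)
    if not poly.is_valid:
        raise ValueError(f"invalid (e.g. self-intersecting) polygon: "
                         f"{poly.wkt[:80]}...")
    return poly


def label_tile(tile: Tile, polygons: Iterable[Polygon | Sequence]) -> TileLabel:
    """Label a tile tumor iff its center lies inside or on any polygon."""
    center = Point(*tile.center)
    for poly in polygons:
        poly = _validate_polygon(poly)
        if poly.covers(center):  # covers() includes the boundary
            return TileLabel.TUMOR
    return TileLabel.NON_TUMOR


def label_tiles(tiles: Sequence[Tile],
                polygons: Iterable[Polygon | Sequence] | None) -> list[Tile]:
    """Assign labels in place; with no annotation set, tiles stay unlabeled."""
    if polygons is None:
        for t in tiles:
            t.label = TileLabel.UNLABELED
        return list(tiles)
    polys = [_validate_polygon(p) for p in polygons]
    for t in tiles:
        t.label = label_tile(t, polys)
    return list(tiles)


def load_annotations_geojson(path_or_obj) -> list[Polygon]:
    """Read tumor polygons from GeoJSON in pixel coordinates (x right, y down)."""
    if isinstance(path_or_obj, (str, bytes)) or hasattr(path_or_obj, "__fspath__"):
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    else:
        obj = path_or_obj
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    polys = []
    for f in feats:
        geom = shape(f["geometry"] if "geometry" in f else f)
        if geom.geom_type == "Polygon":
            polys.append(_validate_polygon(geom))
        elif geom.geom_type == "MultiPolygon":
            polys.extend(_validate_polygon(g) for g in geom.geoms)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
    return polys


def tile_manifest(tiles: Sequence[Tile]) -> pd.DataFrame:
    """Tile table (slide_id, i, j, x, y, label) for CSV export."""
    return pd.DataFrame(
        [{"slide_id": t.slide_id, "i": t.i, "j": t.j, "x": t.x, "y": t.y,
          "label": t.label.value} for t in tiles]
    )
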