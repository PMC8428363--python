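"""Convenience training routines for the reference backends.

Given slide records that carry ground truth (synthetic slides, or real
slides with tumor polygons and cell annotations), assemble tile-level
training sets and fit the reference tumor-tile classifier and cell model.
"""

from __future__ import annotations

from typing import Sequence

from .cells import CellAnnotation
from .detector import ReferenceCellDetector, train_cell_model
from .tiling import TILE_SIZE, label_tiles, partition
from .tumor import TumorTileClassifier, train_tile_classifier

__all__ = ["tiles_with_labels", "cell_training_set", "fit_reference_backends"]


def tiles_with_labels(records: Sequence) -> tuple[list, list]:
    """All tiles of the records, labelled from their tumor polygons."""
    tiles, labels = [], []
    for rec in records:
        ts = partition(rec.image, slide_id=rec.slide_id)
        polys = rec.annotations
        if polys is None and rec.ground_truth is not None:
            polys = rec.ground_truth.tumor_polygons
        label_tiles(ts, polys)
        tiles.extend(ts)
        labels.extend(t.label for t in ts)
    return tiles, labels


def cell_training_set(records: Sequence) -> tuple[list, list]:
    """(tumor tiles, per-tile CellAnnotation lists) from planted ground truth."""
    tiles, annotations = [], []
    for rec in records:
        gt = rec.ground_truth
        if gt is None:
            continue
        ts = partition(rec.image, slide_id=rec.slide_id)
        label_tiles(ts, gt.tumor_polygons)
        for tile in ts:
            anns = []
            for cell in gt.cells_in_tile(tile.x, tile.y, TILE_SIZE):
                local = gt.tile_local_mask(cell, tile.x, tile.y, TILE_SIZE)
                if local.any():
                    anns.append(CellAnnotation(mask=local,
                                               cell_class=cell.cell_class))
            if anns:
                tiles.append(tile)
                annotations.append(anns)
    return tiles, annotations


def fit_reference_backends(records: Sequence, seed: int = 0
                           ) -> tuple[TumorTileClassifier,
                                      ReferenceCellDetector]:
    """Fit both reference backends on ground-truth-bearing slide records."""
    tiles, labels = tiles_with_labels(records)
    tumor_model = train_tile_classifier(tiles, labels, {"seed": seed})
    cell_tiles, annotations = cell_training_set(records)
    cell_model = train_cell_model(cell_tiles, annotations, {"seed": seed})
    return tumor_model, cell_model
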