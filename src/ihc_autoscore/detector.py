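"""Cell-detection backends behind a common detect_cells contract.

Two backends are provided. The oracle backend replays planted ground truth
and exists so downstream stages (scoring, statistics) can be tested against
exact expectations. The reference backend is a classical segmentation
pipeline that runs on one CPU: color deconvolution into hematoxylin and DAB
optical densities, foreground thresholding calibrated on the training
annotations, watershed splitting of touching nuclei, then per-instance
classification — PTEN-positive iff the DAB signal inside the instance
clears a learned cutoff, tumor vs non-tumor from instance morphology and
local context via a logistic model. A deep-learning backend can stand
behind the same interface; the contract (fit -> detect, four-class output,
confidence in [0, 1], determinism for a fixed model) is what the rest of
the pipeline relies on.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hed
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .cells import CellAnnotation, CellClass, CellDetection, non_max_suppression
from .synthetic import GroundTruth
from .tiling import TILE_SIZE, Tile

__all__ = ["OracleCellDetector", "ReferenceCellDetector", "train_cell_model",
           "detect_cells"]


class OracleCellDetector:
    """Replays planted ground truth as perfect detections.

    Cells whose centroid falls in a tile are emitted with their planted
    class and confidence 1.0; masks are cropped to tile coordinates.
    """

    def __init__(self, ground_truth: GroundTruth):
        self.ground_truth = ground_truth

    def detect(self, tile: Tile) -> list[CellDetection]:
        out = []
        for cell in self.ground_truth.cells_in_tile(tile.x, tile.y, TILE_SIZE):
            local = self.ground_truth.tile_local_mask(cell, tile.x, tile.y,
                                                      TILE_SIZE)
            if local.any():
                out.append(CellDetection(mask=local, cell_class=cell.cell_class,
                                         confidence=1.0))
        return out


def _instance_features(region, centroids: np.ndarray) -> list[float]:
    cy, cx = region.centroid
    if len(centroids) > 1:
        d = np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy)
        d = np.sort(d)
        near = float(d[1:4].mean()) if d.size > 1 else 200.0
        n_close = float(np.sum(d < 40.0) - 1)
    else:
        near, n_close = 200.0, 0.0
    return [float(region.area), float(region.eccentricity),
            float(region.equivalent_diameter_area), near, n_close]


class ReferenceCellDetector(BaseEstimator):
    """Classical stain-deconvolution + watershed cell detector.

    Parameters
    ----------
    min_area : int
        Minimum instance area in pixels; smaller fragments are discarded.
    min_peak_distance : int
        Minimum distance between watershed seed peaks.
    seed : int
        Recorded seed (the pipeline itself is deterministic).

    Attributes
    ----------
    h_fg_, d_fg_ : float
        Foreground thresholds on the hematoxylin / DAB optical densities,
        calibrated as midpoints between in-mask and background means of the
        training tiles.
    dab_pos_ : float
        Per-instance mean-DAB cutoff separating PTEN-positive from
        PTEN-negative cells.
    tumor_clf_ : sklearn Pipeline
        Morphology/context logistic model for tumor vs non-tumor instances.
    """

    def __init__(self, min_area: int = 25, min_peak_distance: int = 6,
                 seed: int = 0):
        self.min_area = min_area
        self.min_peak_distance = min_peak_distance
        self.seed = seed

    # -- training ----------------------------------------------------------

    def fit(self, tiles: Sequence[Tile],
            annotations: Sequence[Sequence[CellAnnotation]]
            ) -> "ReferenceCellDetector":
        """Calibrate thresholds and the instance classifier.

        ``annotations[k]`` holds the reference cells of ``tiles[k]`` in
        tile-local coordinates. Every one of the four classes must appear at
        least once.
        """
        all_ann = [a for tile_ann in annotations for a in tile_ann]
        if not all_ann:
            raise ValueError("cannot fit a cell model on empty annotations")
        present = {a.cell_class for a in all_ann}
        missing = set(CellClass) - present
        if missing:
            raise ValueError(
                "training annotations must contain every class; missing: "
                + ", ".join(sorted(c.value for c in missing)))

        h_in, d_in, h_bg, d_bg = [], [], [], []
        dab_by_pos: dict[bool, list[float]] = {True: [], False: []}
        feats, tumor_y = [], []
        for tile, tile_ann in zip(tiles, annotations):
            px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
            hed = rgb2hed(px)
            h_ch, d_ch = hed[..., 0], hed[..., 2]
            union = np.zeros(px.shape[:2], dtype=bool)
            cents = np.array([[a.mask.nonzero()[1].mean(),
                               a.mask.nonzero()[0].mean()] for a in tile_ann]
                             ) if tile_ann else np.empty((0, 2))
            for a in tile_ann:
                m = a.mask
                union |= m
                h_in.append(float(h_ch[m].mean()))
                d_in.append(float(d_ch[m].mean()))
                dab_by_pos[a.cell_class.is_positive].append(float(d_ch[m].mean()))
                lbl = cc_label(m)
                region = max(regionprops(lbl), key=lambda r: r.area)
                feats.append(_instance_features(region, cents))
                tumor_y.append(int(a.cell_class.is_tumor))
            bg = ~union
            h_bg.append(float(h_ch[bg].mean()))
            d_bg.append(float(d_ch[bg].mean()))

        self.h_fg_ = 0.5 * (np.mean(h_in) + np.mean(h_bg))
        self.d_fg_ = 0.5 * (np.mean(d_in) + np.mean(d_bg))
        self.dab_pos_ = 0.5 * (np.mean(dab_by_pos[True])
                               + np.mean(dab_by_pos[False]))
        self.tumor_clf_ = Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(max_iter=2000, random_state=self.seed)),
        ])
        self.tumor_clf_.fit(np.asarray(feats), np.asarray(tumor_y))
        return self

    # -- inference ---------------------------------------------------------

    def _segment(self, px: np.ndarray) -> np.ndarray:
        hed = rgb2hed(px)
        fg = (hed[..., 0] > self.h_fg_) | (hed[..., 2] > self.d_fg_)
        fg = remove_small_objects(fg, max_size=self.min_area - 1)
        fg = ndi.binary_fill_holes(fg)
        if not fg.any():
            return np.zeros(px.shape[:2], dtype=int)
        dist = ndi.distance_transform_edt(fg)
        peaks = peak_local_max(dist, min_distance=self.min_peak_distance,
                               labels=fg, exclude_border=False)
        seeds = np.zeros(px.shape[:2], dtype=int)
        for k, (r, c) in enumerate(peaks, start=1):
            seeds[r, c] = k
        if seeds.max() == 0:
            return cc_label(fg)
        return watershed(-dist, seeds, mask=fg)

    def detect(self, tile: Tile) -> list[CellDetection]:
        check_is_fitted(self, "tumor_clf_")
        px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
        if px.shape[:2] != (TILE_SIZE, TILE_SIZE):
            raise ValueError(f"expected a {TILE_SIZE}x{TILE_SIZE} tile")
        hed = rgb2hed(px)
        d_ch = hed[..., 2]
        labels = self._segment(px)
        regions = [r for r in regionprops(labels) if r.area >= self.min_area]
        if not regions:
            return []
        cents = np.array([[r.centroid[1], r.centroid[0]] for r in regions])
        feats = np.asarray([_instance_features(r, cents) for r in regions])
        p_tumor = self.tumor_clf_.predict_proba(feats)[:, 1]
        detections = []
        for region, pt in zip(regions, p_tumor):
            mask = labels == region.label
            positive = float(d_ch[mask].mean()) >= self.dab_pos_
            tumor = pt >= 0.5
            if tumor:
                cls = CellClass.TUMOR_POS if positive else CellClass.TUMOR_NEG
            else:
                cls = (CellClass.NONTUMOR_POS if positive
                       else CellClass.NONTUMOR_NEG)
            conf = float(max(pt, 1.0 - pt))
            detections.append(CellDetection(mask=mask, cell_class=cls,
                                            confidence=conf))
        return non_max_suppression(detections)


def train_cell_model(tiles, annotations, config: dict | None = None
                     ) -> ReferenceCellDetector:
    """Fit the reference cell model on annotated tiles."""
    config = config or {}
    model = ReferenceCellDetector(
        min_area=config.get("min_area", 25),
        min_peak_distance=config.get("min_peak_distance", 6),
        seed=config.get("seed", 0))
    return model.fit(tiles, annotations)


def detect_cells(model, tile: Tile) -> list[CellDetection]:
    """Detect cells in one tile; warns when the tile is not a tumor tile."""
    from .tiling import TileLabel

    if isinstance(tile, Tile) and tile.label == TileLabel.NON_TUMOR:
        warnings.warn("detect_cells called on a non-tumor tile",
                      stacklevel=2)
    return model.detect(tile)
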