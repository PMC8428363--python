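"""Tumor vs non-tumor tile classification.

The reference backend summarises each tile by stain-channel statistics
(hematoxylin/eosin/DAB optical densities after color deconvolution) plus
nucleus-morphology summaries (stained-object count and size distribution),
and fits a logistic regression on the labelled tiles. The contract is the
reproducible content: any backend mapping a tile to a tumor probability in
[0, 1] with a decision threshold can stand behind the same interface.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .tiling import TILE_SIZE, Tile, TileLabel

__all__ = ["TumorTileClassifier", "tile_features", "train_tile_classifier",
           "predict_tile", "tile_accuracy"]

# optical-density thresholds. The broad pair separates any stain (including
# faint DAB cytoplasm) from background; the core pair isolates nucleus-dark
# signal so blob sizes reflect nuclei rather than cytoplasmic halos.
_H_FG = 0.032
_D_FG = 0.030
_H_CORE = 0.06
_D_CORE = 0.08


def _tile_pixels(tile) -> np.ndarray:
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    if px.shape != (TILE_SIZE, TILE_SIZE, 3):
        raise ValueError(
            f"expected a {TILE_SIZE}x{TILE_SIZE}x3 tile, got {px.shape}")
    return px


def _morphology_stats(hed: np.ndarray) -> list[float]:
    stained = (hed[..., 0] > _H_FG) | (hed[..., 2] > _D_FG)
    nuclei = (hed[..., 0] > _H_CORE) | (hed[..., 2] > _D_CORE)
    nuclei = remove_small_objects(nuclei, max_size=15)
    labelled = cc_label(nuclei)
    areas = np.array([r.area for r in regionprops(labelled)], dtype=float)
    out = [stained.mean(), nuclei.mean(), float(labelled.max())]
    if areas.size:
        out += [float(areas.mean()), float(np.median(areas)),
                float(areas.max())]
    else:
        out += [0.0, 0.0, 0.0]
    return out


def tile_features(tile) -> np.ndarray:
    """Stain and morphology summary vector for one tile.

    Statistics are computed at three scales: the whole tile and central
    400x400 and 200x200 windows. Tile labels follow the tile *center*
    (center-in-annotation rule), so the tighter windows carry the
    label-defining signal while the full-tile statistics add context.
    """
    px = _tile_pixels(tile)
    hed = rgb2hed(px)
    q, o = TILE_SIZE // 4, 3 * TILE_SIZE // 8
    center = hed[q:-q, q:-q]
    core = hed[o:-o, o:-o]
    feats = []
    for block in (hed, center, core):
        for c in range(3):
            ch = block[..., c]
            feats += [ch.mean(), ch.std(),
                      float(np.percentile(ch, 90)),
                      float(np.percentile(ch, 99))]
        feats += _morphology_stats(block)
    return np.asarray(feats)


class TumorTileClassifier(BaseEstimator, ClassifierMixin):
    """Tile-level tumor detector with a pluggable feature backend.

    Parameters
    ----------
    threshold : float
        Decision threshold on the tumor probability (default 0.5).
    C : float
        Inverse regularisation strength of the logistic head.
    seed : int
        Seed recorded for reproducibility (the reference backend is fully
        deterministic; the seed still feeds the solver for forward
        compatibility with stochastic backends).

    Attributes
    ----------
    pipeline_ : sklearn Pipeline
        Fitted scaler + logistic regression.
    classes_ : ndarray
        ``["non-tumor", "tumor"]``.
    """

    def __init__(self, threshold: float = 0.5, C: float = 1.0, seed: int = 0):
        self.threshold = threshold
        self.C = C
        self.seed = seed

    @staticmethod
    def _norm_labels(labels) -> np.ndarray:
        out = []
        for l in labels:
            l = l.value if isinstance(l, TileLabel) else str(l)
            out.append(l)
        return np.asarray(out)

    def fit(self, tiles: Sequence, labels: Sequence) -> "TumorTileClassifier":
        y = self._norm_labels(labels)
        keep = y != TileLabel.UNLABELED.value
        y = y[keep]
        tiles = [t for t, k in zip(tiles, keep) if k]
        if len(tiles) == 0:
            raise ValueError("no labelled tiles to fit on")
        present = set(y)
        if present != {TileLabel.TUMOR.value, TileLabel.NON_TUMOR.value}:
            raise ValueError(
                f"need both tumor and non-tumor tiles, got labels {present}")
        X = np.vstack([tile_features(t) for t in tiles])
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=self.C, max_iter=2000,
                                         random_state=self.seed)),
        ])
        self.pipeline_.fit(X, (y == TileLabel.TUMOR.value).astype(int))
        self.classes_ = np.array([TileLabel.NON_TUMOR.value,
                                  TileLabel.TUMOR.value])
        return self

    def predict_proba_tile(self, tile) -> float:
        """Probability that a single tile is a tumor tile."""
        check_is_fitted(self, "pipeline_")
        X = tile_features(tile)[None, :]
        p = float(self.pipeline_.predict_proba(X)[0, 1])
        return min(max(p, 0.0), 1.0)

    def predict_proba(self, tiles: Sequence) -> np.ndarray:
        return np.array([self.predict_proba_tile(t) for t in tiles])

    def predict(self, tiles: Sequence) -> np.ndarray:
        p = self.predict_proba(tiles)
        return np.where(p >= self.threshold, TileLabel.TUMOR.value,
                        TileLabel.NON_TUMOR.value)


def train_tile_classifier(tiles, labels, config: dict | None = None
                          ) -> TumorTileClassifier:
    """Fit a tumor-tile classifier from labelled tiles (unlabelled excluded)."""
    config = config or {}
    clf = TumorTileClassifier(threshold=config.get("threshold", 0.5),
                              C=config.get("C", 1.0),
                              seed=config.get("seed", 0))
    return clf.fit(tiles, labels)


def predict_tile(model: TumorTileClassifier, tile) -> float:
    """Tumor probability of one tile under a fitted model."""
    return model.predict_proba_tile(tile)


def tile_accuracy(model: TumorTileClassifier, tiles, labels) -> float:
    """Proportion of labelled tiles classified correctly."""
    y = TumorTileClassifier._norm_labels(labels)
    keep = y != TileLabel.UNLABELED.value
    y = y[keep]
    tiles = [t for t, k in zip(tiles, keep) if k]
    if len(tiles) == 0:
        raise ValueError("tile accuracy needs at least one labelled tile")
    pred = model.predict(tiles)
    return float(np.mean(pred == y))
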