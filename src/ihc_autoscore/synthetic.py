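"""Synthetic IHC slides with per-cell ground truth, and simulated cohorts.

The slide generator emulates the data regime of PTEN immunohistochemistry on
prostate tissue at 0.227 um/pixel: DAB-brown signal marks PTEN-positive
cells, hematoxylin-blue counterstain marks nuclei of PTEN-negative cells,
tumor cells sit inside annotated tumor regions. Two technical-failure modes
are supported: ``low_antibody`` (weak DAB signal) and ``no_antibody`` (no
DAB signal at all); failure slides carry a flag in their ground truth but
are otherwise rendered by the same machinery.

The cohort simulator draws biochemical-recurrence (BCR) event times from an
exponential proportional-hazards law in which PTEN-low and non-diploid
status act additively on the log hazard (with an optional interaction term
so a three-level combined marker can be planted exactly), then discretizes
event detection onto a PSA visit grid: the first visit at or after the
latent event time records a PSA at or above the recurrence level, earlier
visits stay below the 0.4 ng/mL threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping

from .cells import CellClass
from .masks import rle_encode

__all__ = [
    "FailureMode", "SlideSpec", "GroundTruthCell", "GroundTruth",
    "generate_slide", "CohortParams", "generate_cohort",
    "save_slide", "COHORT_COLUMNS",
]

# rendering palette (RGB, uint8)
_BACKGROUND = np.array([243, 241, 244], dtype=float)
_HEMATOXYLIN = np.array([70, 62, 145], dtype=float)     # blue-purple nucleus
_DAB_NUCLEUS = np.array([120, 74, 38], dtype=float)     # brown nucleus
_DAB_CYTOPLASM = np.array([190, 148, 105], dtype=float) # lighter brown halo


class FailureMode(str, Enum):
    NONE = "none"
    LOW_ANTIBODY = "low_antibody"
    NO_ANTIBODY = "no_antibody"


@dataclass(frozen=True)
class SlideSpec:
    """Parameters for one synthetic slide.

    Densities are cells per 800x800 tile area. ``positive_fraction`` is the
    planted probability that a tumor cell is PTEN-positive.
    """

    width_px: int = 1600
    height_px: int = 1600
    mpp: float = 0.227
    n_tumor_regions: int = 1
    positive_fraction: float = 0.8
    tumor_cell_density: float = 40.0
    nontumor_cell_density: float = 25.0
    nontumor_positive_fraction: float = 0.85
    failure_mode: FailureMode = FailureMode.NONE
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "failure_mode", FailureMode(self.failure_mode))
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_tumor_regions < 0:
            raise ValueError("n_tumor_regions must be >= 0")
        if self.n_tumor_regions > 0 and (self.width_px < 800 or self.height_px < 800):
            raise ValueError(
                "slides with tumor regions must be at least 800x800 px")


@dataclass
class GroundTruthCell:
    """Planted cell: tile-independent full-frame placement."""

    bbox: tuple[int, int, int, int]   # (y0, x0, y1, x1), half-open
    mask: np.ndarray                  # local boolean array, bbox-shaped
    cell_class: CellClass
    centroid: tuple[float, float]     # (x, y) in slide coordinates


@dataclass
class GroundTruth:
    tumor_polygons: list[Polygon]
    cells: list[GroundTruthCell]
    failure_mode: FailureMode = FailureMode.NONE
    mpp: float = 0.227
    seed: int = 0

    @property
    def is_failure(self) -> bool:
        return self.failure_mode is not FailureMode.NONE

    def class_counts(self) -> dict[CellClass, int]:
        counts = {c: 0 for c in CellClass}
        for cell in self.cells:
            counts[cell.cell_class] += 1
        return counts

    def tumor_positive_fraction(self) -> float | None:
        c = self.class_counts()
        denom = c[CellClass.TUMOR_POS] + c[CellClass.TUMOR_NEG]
        return c[CellClass.TUMOR_POS] / denom if denom else None

    def cells_in_tile(self, x: int, y: int, size: int = 800
                      ) -> list["GroundTruthCell"]:
        """Cells whose centroid falls inside the tile [x, x+size) x [y, y+size)."""
        out = []
        for cell in self.cells:
            cx, cy = cell.centroid
            if x <= cx < x + size and y <= cy < y + size:
                out.append(cell)
        return out

    def tile_local_mask(self, cell: GroundTruthCell, x: int, y: int,
                        size: int = 800) -> np.ndarray:
        """Crop a cell's mask into tile-local coordinates (may clip edges)."""
        local = np.zeros((size, size), dtype=bool)
        y0, x0, y1, x1 = cell.bbox
        ty0, tx0 = max(y0 - y, 0), max(x0 - x, 0)
        ty1, tx1 = min(y1 - y, size), min(x1 - x, size)
        if ty1 <= ty0 or tx1 <= tx0:
            return local
        sy0, sx0 = ty0 + y - y0, tx0 + x - x0
        local[ty0:ty1, tx0:tx1] = cell.mask[sy0:sy0 + (ty1 - ty0),
                                            sx0:sx0 + (tx1 - tx0)]
        return local


def _blob_polygon(rng: np.random.Generator, cx: float, cy: float,
                  radius: float, n_vertices: int = 14) -> Polygon:
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * rng.uniform(0.75, 1.15, n_vertices)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    poly = Polygon(zip(xs, ys)).buffer(0)
    if poly.geom_type != "Polygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _nucleus_mask(rng: np.random.Generator, r_a: float, r_b: float,
                  theta: float) -> np.ndarray:
    """Perturbed-ellipse boolean mask on a tight local grid."""
    rmax = int(np.ceil(max(r_a, r_b))) + 2
    yy, xx = np.mgrid[-rmax:rmax + 1, -rmax:rmax + 1].astype(float)
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    phi = np.arctan2(yr / r_b, xr / r_a)
    rho = np.sqrt((xr / r_a) ** 2 + (yr / r_b) ** 2)
    k = rng.integers(2, 5)
    amp = rng.uniform(0.05, 0.12)
    phase = rng.uniform(0, 2 * np.pi)
    boundary = 1.0 + amp * np.sin(k * phi + phase)
    return rho <= boundary


def _place_centers(rng: np.random.Generator, candidates: np.ndarray,
                   n_target: int, min_dist: float) -> np.ndarray:
    """Greedy blue-noise-ish acceptance of candidate centers."""
    accepted: list[np.ndarray] = []
    cell = min_dist / np.sqrt(2)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    for p in candidates:
        if len(accepted) >= n_target:
            break
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                for q in grid.get((gx + dx, gy + dy), ()):
                    if np.hypot(*(p - q)) < min_dist:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(p)
            grid.setdefault((gx, gy), []).append(p)
    return np.array(accepted) if accepted else np.empty((0, 2))


def _sample_in_polygons(rng: np.random.Generator, polys: list[Polygon],
                        n: int, bounds: tuple[float, float],
                        inside: bool, margin: float) -> np.ndarray:
    """Uniform candidate points (over-sampled) inside/outside the union."""
    w, h = bounds
    n_cand = max(int(n * 6), 64)
    xs = rng.uniform(margin, w - margin, n_cand)
    ys = rng.uniform(margin, h - margin, n_cand)
    if polys:
        hit = np.zeros(n_cand, dtype=bool)
        for poly in polys:
            hit |= shapely.contains_xy(poly, xs, ys)
    else:
        hit = np.zeros(n_cand, dtype=bool)
    keep = hit if inside else ~hit
    return np.column_stack([xs[keep], ys[keep]])


def _paint(image: np.ndarray, bbox, mask, color, alpha: float = 1.0):
    y0, x0, y1, x1 = bbox
    region = image[y0:y1, x0:x1]
    region[mask] = (1 - alpha) * region[mask] + alpha * color


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic IHC slide and its exact ground truth.

    Returns ``(image, ground_truth)`` where ``image`` is H x W x 3 uint8.
    Identical specs produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px

    # tumor regions: blobs that must fit the frame
    polys: list[Polygon] = []
    for _ in range(spec.n_tumor_regions):
        lim = min(w, h)
        radius = rng.uniform(0.28, 0.42) * lim
        if 2 * radius > min(w, h):
            raise ValueError("tumor region larger than the image")
        cx = rng.uniform(radius, w - radius)
        cy = rng.uniform(radius, h - radius)
        polys.append(_blob_polygon(rng, cx, cy, radius))

    image = np.empty((h, w, 3), dtype=float)
    image[:] = _BACKGROUND
    image += rng.normal(0, 2.0, size=(h, w, 3))

    tile_area = 800.0 * 800.0
    tumor_area = sum(p.area for p in polys)
    n_tumor = int(round(spec.tumor_cell_density * tumor_area / tile_area))
    n_nontumor = int(round(
        spec.nontumor_cell_density * max(w * h - tumor_area, 0.0) / tile_area))

    margin = 14.0
    tumor_centers = _place_centers(
        rng, _sample_in_polygons(rng, polys, n_tumor, (w, h), True, margin),
        n_tumor, min_dist=16.0)
    nontumor_centers = _place_centers(
        rng, _sample_in_polygons(rng, polys, n_nontumor, (w, h), False, margin),
        n_nontumor, min_dist=12.0)

    no_dab = spec.failure_mode is FailureMode.NO_ANTIBODY
    dab_alpha = 0.35 if spec.failure_mode is FailureMode.LOW_ANTIBODY else 1.0

    cells: list[GroundTruthCell] = []

    def add_cell(cx, cy, r_lo, r_hi, is_tumor: bool, positive: bool):
        r_a = rng.uniform(r_lo, r_hi)
        r_b = r_a * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0, np.pi)
        local = _nucleus_mask(rng, r_a, r_b, theta)
        half = local.shape[0] // 2
        y0, x0 = int(round(cy)) - half, int(round(cx)) - half
        y1, x1 = y0 + local.shape[0], x0 + local.shape[1]
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            return
        rendered_positive = positive and not no_dab
        if rendered_positive:
            # cytoplasmic halo: dilated boundary ring in light brown
            pad = 3
            halo = np.zeros((local.shape[0] + 2 * pad,
                             local.shape[1] + 2 * pad), dtype=bool)
            halo[pad:-pad, pad:-pad] = local
            from scipy.ndimage import binary_dilation
            halo = binary_dilation(halo, iterations=pad) & ~np.pad(
                local, pad, constant_values=False)
            hb = (y0 - pad, x0 - pad, y1 + pad, x1 + pad)
            if hb[0] >= 0 and hb[1] >= 0 and hb[2] <= h and hb[3] <= w:
                _paint(image, hb, halo, _DAB_CYTOPLASM, alpha=0.55 * dab_alpha)
            _paint(image, (y0, x0, y1, x1), local, _DAB_NUCLEUS,
                   alpha=0.95 * dab_alpha)
            if dab_alpha < 1.0:  # weak stain keeps a visible counterstain
                _paint(image, (y0, x0, y1, x1), local, _HEMATOXYLIN, alpha=0.35)
        else:
            _paint(image, (y0, x0, y1, x1), local, _HEMATOXYLIN, alpha=0.95)
        # ground truth records the *rendered* PTEN signal; in the no-antibody
        # failure every cell is negative by construction
        effective_positive = positive and not no_dab
        if is_tumor:
            cls = CellClass.TUMOR_POS if effective_positive else CellClass.TUMOR_NEG
        else:
            cls = (CellClass.NONTUMOR_POS if effective_positive
                   else CellClass.NONTUMOR_NEG)
        cells.append(GroundTruthCell(
            bbox=(y0, x0, y1, x1), mask=local, cell_class=cls,
            centroid=(float(cx), float(cy))))

    for cx, cy in tumor_centers:
        add_cell(cx, cy, 6.0, 10.0, True, bool(rng.random() < spec.positive_fraction))
    for cx, cy in nontumor_centers:
        add_cell(cx, cy, 4.0, 6.0, False,
                 bool(rng.random() < spec.nontumor_positive_fraction))

    image = np.clip(image, 0, 255).astype(np.uint8)
    gt = GroundTruth(tumor_polygons=polys, cells=cells,
                     failure_mode=spec.failure_mode, mpp=spec.mpp,
                     seed=spec.seed)
    return image, gt


def save_slide(image: np.ndarray, gt: GroundTruth, stem: Path | str) -> dict:
    """Write slide + sidecars: <stem>.tiff, <stem>.json, <stem>.annotations.json.

    The sidecar carries mpp/seed/failure_mode; annotations hold GeoJSON tumor
    polygons and RLE cell masks. Returns the paths written.
    """
    import tifffile

    stem = Path(stem)
    tiff_path = stem.with_suffix(".tiff")
    tifffile.imwrite(tiff_path, image)
    sidecar = {"mpp": gt.mpp, "seed": gt.seed,
               "failure_mode": gt.failure_mode.value}
    sidecar_path = stem.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    ann = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {"label": "tumor"},
                      "geometry": mapping(p)} for p in gt.tumor_polygons],
        "cells": [{"bbox": list(c.bbox), "class": c.cell_class.value,
                   "centroid": list(c.centroid), "rle": rle_encode(c.mask)}
                  for c in gt.cells],
    }
    ann_path = stem.parent / (stem.name + ".annotations.json")
    ann_path.write_text(json.dumps(ann))
    return {"image": tiff_path, "sidecar": sidecar_path, "annotations": ann_path}


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortParams:
    """Simulated validation-cohort parameters.

    Hazards follow lambda_i = baseline_hazard * exp(lp_i) with
    lp = log_hr_pten_low * [PTEN-low] + log_hr_nondiploid * [non-diploid]
       + log_hr_interaction * [both], so the default interaction of 0 gives a
    purely additive log-hazard. Event times are exponential; censoring is
    administrative at the end of follow-up. PSA visits happen every
    ``psa_visit_interval_years``; the visit at or after the latent event time
    is the first PSA >= 0.4 ng/mL.
    """

    n_patients: int = 259
    prevalence_pten_low: float = 0.17
    prevalence_nondiploid: float = 0.27
    log_hr_pten_low: float = float(np.log(3.32))
    log_hr_nondiploid: float = float(np.log(1.98))
    log_hr_interaction: float = 0.0
    baseline_hazard: float = 0.025
    followup_years: float = 10.0
    psa_visit_interval_years: float = 0.25
    psa_recurrence_level: float = 0.6
    manual_score_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if not (0 <= self.prevalence_pten_low <= 1
                and 0 <= self.prevalence_nondiploid <= 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.followup_years < 0 or self.psa_visit_interval_years <= 0:
            raise ValueError("follow-up and visit interval must be positive")
        if self.psa_recurrence_level < 0.4:
            raise ValueError("psa_recurrence_level must be >= 0.4 ng/mL")


COHORT_COLUMNS = {
    "patient_id": "unique identifier",
    "pten_score_true": "planted fraction of PTEN-positive tumor cells, [0, 1]",
    "pten_low_true": "1 if planted score < 0.5",
    "manual_score": "emulated consensus manual score (true score + noise)",
    "ploidy": "diploid / tetraploid / aneuploid",
    "capra_s": "integer CAPRA-S base score, 0-12",
    "age": "age at surgery, years",
    "event_time_true": "latent exponential event time, years",
    "event": "1 if BCR observed within follow-up",
    "time": "visit-grid event time or censoring time, years",
    "psa_years": "space-separated visit times (years after surgery)",
    "psa_values": "space-separated PSA values (ng/mL), aligned with psa_years",
}


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a patient cohort with marker-dependent BCR hazards."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    pten_low = rng.random(n) < params.prevalence_pten_low
    nondip = rng.random(n) < params.prevalence_nondiploid
    # planted continuous PTEN scores consistent with the dichotomy
    score = np.where(pten_low, rng.uniform(0.02, 0.45, n),
                     rng.uniform(0.55, 0.98, n))
    manual = np.clip(score + rng.normal(0, params.manual_score_sd, n), 0, 1)
    ploidy = np.where(nondip,
                      np.where(rng.random(n) < 0.6, "aneuploid", "tetraploid"),
                      "diploid")
    capra = np.clip(rng.poisson(2.0, n) + 2 * pten_low + 2 * nondip, 0, 12)
    age = np.round(rng.normal(62, 5, n)).astype(int)

    lp = (params.log_hr_pten_low * pten_low
          + params.log_hr_nondiploid * nondip
          + params.log_hr_interaction * (pten_low & nondip))
    lam = params.baseline_hazard * np.exp(lp)
    t_latent = rng.exponential(1.0 / lam)

    dt = params.psa_visit_interval_years
    n_visits = int(np.floor(params.followup_years / dt))
    visit_times = dt * np.arange(1, n_visits + 1)

    rows = []
    for i in range(n):
        base_psa = rng.uniform(0.02, 0.15)
        psa = np.full(n_visits, np.nan)
        noise = rng.uniform(-0.01, 0.01, n_visits)
        event_visit = np.searchsorted(visit_times, t_latent[i], side="left")
        if n_visits == 0:
            event, time = False, 0.0
            psa_t, psa_v = [], []
        elif event_visit < n_visits:
            pre = np.clip(base_psa + noise[:event_visit], 0.0, 0.39)
            post = (params.psa_recurrence_level
                    + np.abs(rng.normal(0, 0.1, n_visits - event_visit))
                    + 0.2 * np.arange(n_visits - event_visit))
            psa = np.concatenate([pre, post])
            # follow-up stops shortly after recurrence is registered
            keep = event_visit + 1
            psa_t, psa_v = visit_times[:keep], psa[:keep]
            event, time = True, float(visit_times[event_visit])
        else:
            psa = np.clip(base_psa + noise, 0.0, 0.39)
            psa_t, psa_v = visit_times, psa
            event, time = False, float(visit_times[-1])
        rows.append({
            "patient_id": f"P{i:04d}",
            "pten_score_true": score[i],
            "pten_low_true": int(pten_low[i]),
            "manual_score": manual[i],
            "ploidy": ploidy[i],
            "capra_s": int(capra[i]),
            "age": int(age[i]),
            "event_time_true": float(t_latent[i]),
            "event": int(event),
            "time": time,
            "psa_years": " ".join(f"{t:.4f}" for t in psa_t),
            "psa_values": " ".join(f"{v:.4f}" for v in psa_v),
        })
    return pd.DataFrame(rows)
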