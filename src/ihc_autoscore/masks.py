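"""Instance-mask utilities: run-length encoding and overlap measures.

Masks are boolean 2-D arrays in tile coordinates (row-major, y down).
The RLE dialect is column-major ("Fortran order") counts of alternating
background/foreground runs, starting with background, stored as plain JSON
lists so every artifact stays text.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rle_encode", "rle_decode", "mask_iou", "bbox_of_mask"]


def rle_encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as {"size": [h, w], "counts": [...]}."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    flat = mask.flatten(order="F")
    # run boundaries; leading zero-length background run kept implicit
    change = np.flatnonzero(np.diff(flat))
    counts = np.diff(np.concatenate([[0], change + 1, [flat.size]]))
    if flat.size and flat[0]:
        counts = np.concatenate([[0], counts])
    return {"size": [int(mask.shape[0]), int(mask.shape[1])],
            "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError("RLE counts do not sum to mask size")
    return flat.reshape((h, w), order="F")


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 0.0


def bbox_of_mask(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(row_min, col_min, row_max_excl, col_max_excl) of the foreground."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r = np.flatnonzero(rows)
    c = np.flatnonzero(cols)
    if r.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1
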