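"""Development-resource inventory accounting.

The scoring system this package reimplements was developed against a fixed
inventory of annotated material: tile subsets labelled tumor/non-tumor for
the tumor detector, and four-class nucleus contours drawn over a smaller
tile set for the cell classifier. The per-subset counts are data constants
here; the accounting functions derive the totals and percentages from them,
so consistency of the inventory can be checked mechanically.
"""

from __future__ import annotations

__all__ = ["DEVELOPMENT_INVENTORY", "inventory_accounting"]

DEVELOPMENT_INVENTORY = {
    # tumor-detector tile subsets: labelled tumor vs non-tumor tiles
    "tumor_detector": {
        "train": {"tumor_tiles": 241_170, "nontumor_tiles": 640_248},
        "tune": {"tumor_tiles": 97_587, "nontumor_tiles": 234_624},
    },
    # cell-classifier subsets: annotated tiles and nucleus contours by label
    "cell_classifier": {
        "train": {"tiles": 2160, "positive_cells": 46_434,
                  "negative_cells": 11_146},
        "tune": {"tiles": 900, "positive_cells": 17_396,
                 "negative_cells": 2_801},
    },
}


def inventory_accounting(inventory: dict | None = None) -> dict:
    """Totals and rounded percentages implied by the per-subset counts.

    Returns annotated tile/nucleus totals for the cell classifier and, per
    subset, the tumor-tile percentage (tumor detector) and the
    PTEN-positive cell percentage (cell classifier), rounded to whole
    percent as conventionally reported.
    """
    inv = inventory or DEVELOPMENT_INVENTORY
    cc = inv["cell_classifier"]
    td = inv["tumor_detector"]
    annotated_tiles = sum(s["tiles"] for s in cc.values())
    annotated_nuclei = sum(s["positive_cells"] + s["negative_cells"]
                           for s in cc.values())
    out = {
        "annotated_tiles_total": annotated_tiles,
        "annotated_nuclei_total": annotated_nuclei,
    }
    for subset, s in td.items():
        total = s["tumor_tiles"] + s["nontumor_tiles"]
        out[f"tumor_tile_pct_{subset}"] = round(100 * s["tumor_tiles"] / total)
    for subset, s in cc.items():
        total = s["positive_cells"] + s["negative_cells"]
        out[f"positive_cell_pct_{subset}"] = round(
            100 * s["positive_cells"] / total)
    return out
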