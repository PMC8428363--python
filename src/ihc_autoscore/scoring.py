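"""PTEN scores, dichotomization, the combined PTEN+ploidy marker, and
CAPRA-S integration.

The slide-level PTEN score is the fraction of tumor cells that are
PTEN-positive; non-tumor detections never enter numerator or denominator. A
slide with no tumor cells has an undefined score — a representable state,
not an error — and is excluded from the patient mean. A patient is PTEN-low
when the mean score is strictly below the threshold (default 0.5, i.e. the
50% cut), PTEN-high at or above it. Ploidy dichotomizes to non-diploid for
tetraploid or aneuploid tumors. The combined marker counts adverse statuses
(0 = both favorable, 1 = one adverse, 2 = both adverse). CAPRA-S
integration adds one point for PTEN-low and one for non-diploid; risk
groups are Low (0-2), Intermediate (3-5), High (>= 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .cells import CellClass, CellDetection

__all__ = [
    "SlideScore", "PtenStatus", "PloidyStatus", "CombinedMarker", "RiskGroup",
    "CapraS", "slide_pten_score", "patient_pten_score", "dichotomize_pten",
    "dichotomize_ploidy", "combined_marker", "capra_s_integrate",
    "PTEN_THRESHOLD",
]

PTEN_THRESHOLD = 0.5
NON_DIPLOID_CATEGORIES = frozenset({"tetraploid", "aneuploid"})


class PtenStatus(str, Enum):
    LOW = "PTEN-low"
    HIGH = "PTEN-high"


class PloidyStatus(str, Enum):
    DIPLOID = "diploid"
    NON_DIPLOID = "non-diploid"


class CombinedMarker(str, Enum):
    BOTH_FAVORABLE = "both-favorable"
    ONE_ADVERSE = "one-adverse"
    BOTH_ADVERSE = "both-adverse"

    @property
    def n_adverse(self) -> int:
        return {CombinedMarker.BOTH_FAVORABLE: 0,
                CombinedMarker.ONE_ADVERSE: 1,
                CombinedMarker.BOTH_ADVERSE: 2}[self]


class RiskGroup(str, Enum):
    LOW = "Low"
    INTERMEDIATE = "Intermediate"
    HIGH = "High"


@dataclass(frozen=True)
class SlideScore:
    """Four-class cell counts and the resulting slide PTEN score."""

    n_tumor_pos: int = 0
    n_tumor_neg: int = 0
    n_nontumor_pos: int = 0
    n_nontumor_neg: int = 0

    def __post_init__(self):
        for n in (self.n_tumor_pos, self.n_tumor_neg,
                  self.n_nontumor_pos, self.n_nontumor_neg):
            if n < 0:
                raise ValueError("cell counts must be non-negative")

    @property
    def score(self) -> float | None:
        """Positive tumor-cell fraction; None when no tumor cells."""
        denom = self.n_tumor_pos + self.n_tumor_neg
        return self.n_tumor_pos / denom if denom else None


def slide_pten_score(detections: Iterable[CellDetection | CellClass]) -> SlideScore:
    """Count four-class detections into a SlideScore.

    Accepts CellDetection objects or bare CellClass labels.
    """
    counts = {c: 0 for c in CellClass}
    for d in detections:
        cls = d if isinstance(d, CellClass) else CellClass(d.cell_class)
        counts[cls] += 1
    return SlideScore(n_tumor_pos=counts[CellClass.TUMOR_POS],
                      n_tumor_neg=counts[CellClass.TUMOR_NEG],
                      n_nontumor_pos=counts[CellClass.NONTUMOR_POS],
                      n_nontumor_neg=counts[CellClass.NONTUMOR_NEG])


def patient_pten_score(slide_scores: Sequence[SlideScore | float | None]
                       ) -> float | None:
    """Unweighted mean of the defined slide scores.

    Undefined slides (no tumor cells) are excluded; if every slide is
    undefined the patient score is None and the status propagates as
    missing.
    """
    vals = []
    for s in slide_scores:
        v = s.score if isinstance(s, SlideScore) else s
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"slide score {v} outside [0, 1]")
        vals.append(float(v))
    if not vals:
        return None
    return sum(vals) / len(vals)


def dichotomize_pten(score: float | None,
                     threshold: float = PTEN_THRESHOLD) -> PtenStatus | None:
    """PTEN-low iff score < threshold (strict); missing score -> None."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PTEN score {score} outside [0, 1]")
    return PtenStatus.LOW if score < threshold else PtenStatus.HIGH


def dichotomize_ploidy(category: str | None) -> PloidyStatus | None:
    if category is None or (isinstance(category, float) and math.isnan(category)):
        return None
    category = str(category).lower()
    if category == "diploid":
        return PloidyStatus.DIPLOID
    if category in NON_DIPLOID_CATEGORIES:
        return PloidyStatus.NON_DIPLOID
    raise ValueError(f"unknown ploidy category {category!r}")


def combined_marker(pten_status: PtenStatus | None,
                    ploidy: PloidyStatus | str | None
                    ) -> CombinedMarker | None:
    """Three-level combined PTEN + ploidy marker; missing input -> None.

    ``ploidy`` may be a dichotomized status or a raw category.
    """
    if pten_status is None or ploidy is None:
        return None
    if not isinstance(ploidy, PloidyStatus):
        ploidy = dichotomize_ploidy(ploidy)
        if ploidy is None:
            return None
    n_adverse = (int(PtenStatus(pten_status) is PtenStatus.LOW)
                 + int(ploidy is PloidyStatus.NON_DIPLOID))
    return [CombinedMarker.BOTH_FAVORABLE, CombinedMarker.ONE_ADVERSE,
            CombinedMarker.BOTH_ADVERSE][n_adverse]


@dataclass(frozen=True)
class CapraS:
    base: int
    integrated: int
    risk_group: RiskGroup


def _risk_group(score: int) -> RiskGroup:
    if score <= 2:
        return RiskGroup.LOW
    if score <= 5:
        return RiskGroup.INTERMEDIATE
    return RiskGroup.HIGH


def capra_s_integrate(base: int, pten_status: PtenStatus | None,
                      ploidy_status: PloidyStatus | None) -> CapraS:
    """Add 1 point for PTEN-low and 1 for non-diploid; regroup.

    Missing marker statuses contribute no points.
    """
    base = int(base)
    if base < 0:
        raise ValueError("CAPRA-S base score must be >= 0")
    extra = 0
    if pten_status is not None and PtenStatus(pten_status) is PtenStatus.LOW:
        extra += 1
    if (ploidy_status is not None
            and PloidyStatus(ploidy_status) is PloidyStatus.NON_DIPLOID):
        extra += 1
    integrated = base + extra
    return CapraS(base=base, integrated=integrated,
                  risk_group=_risk_group(integrated))
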