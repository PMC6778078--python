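"""Mesowear scoring and diet classification.

Mesowear is the macroscopic wear signature of months-to-years of feeding:
attrition (tooth-on-tooth, browse) keeps cusps high and sharp, abrasion
(grit and phytoliths, grass) lowers relief and blunts apices.  Cusp
relief/shape observations are collapsed to a single mesowear stage on the
standard 0-6 ruler (0 = high relief, sharp apices; 6 = no relief,
completely blunt), averaged per assemblage, and mapped to a dietary
class.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data_model import DietClass, DietMain, DietQualifier, MesowearSummary


class CuspRelief(str, enum.Enum):
    high = "high"
    low = "low"
    none = "none"


class CuspShape(str, enum.Enum):
    sharp = "sharp"
    rounded = "rounded"
    blunt = "blunt"


@dataclass(frozen=True)
class MesowearObservation:
    specimen_id: str
    cusp_relief: CuspRelief
    cusp_shape: CuspShape

    def __post_init__(self) -> None:
        if self.cusp_relief is CuspRelief.none and self.cusp_shape is not CuspShape.blunt:
            raise ValueError("a cusp with no relief must be blunt")


#: Seven-stage ruler.  Monotone in both axes: losing relief or gaining
#: bluntness never lowers the stage (checked exhaustively in the tests).
STAGE_TABLE: Mapping[tuple[CuspRelief, CuspShape], int] = {
    (CuspRelief.high, CuspShape.sharp): 0,
    (CuspRelief.high, CuspShape.rounded): 1,
    (CuspRelief.low, CuspShape.sharp): 2,
    (CuspRelief.low, CuspShape.rounded): 3,
    (CuspRelief.high, CuspShape.blunt): 4,
    (CuspRelief.low, CuspShape.blunt): 5,
    (CuspRelief.none, CuspShape.blunt): 6,
}

#: Default MWS cutpoints: browser [0, 1.5) | browse-dominated mixed
#: [1.5, 2.1) | grass-dominated mixed [2.1, 3.6) | grazer [3.6, 6].
#: The browse-dominated band has no published anchor and is a convention
#: (see docs/methods.md); the other three boundaries are the minimal
#: partition consistent with every published MWS -> diet statement.
DEFAULT_MWS_CUTPOINTS: tuple[float, float, float] = (1.5, 2.1, 3.6)


def score_cusp_mesowear(relief: CuspRelief, shape: CuspShape) -> int:
    """Score one cusp observation on the 0-6 mesowear stage ruler."""

    try:
        return STAGE_TABLE[(CuspRelief(relief), CuspShape(shape))]
    except KeyError:
        raise ValueError(
            f"inconsistent cusp observation (relief={relief!s}, shape={shape!s}): "
            "a cusp without relief cannot keep a sharp or rounded apex"
        ) from None


def specimen_stage(
    observations: Sequence[MesowearObservation], cusp_rule: str = "sharpest"
) -> float:
    """Collapse one specimen's cusp observations to a per-tooth stage.

    ``sharpest`` keeps the least-worn usable cusp (minimum stage);
    ``mean`` averages all scored cusps.
    """

    if not observations:
        raise ValueError("no cusp observations for specimen")
    stages = [score_cusp_mesowear(o.cusp_relief, o.cusp_shape) for o in observations]
    if cusp_rule == "sharpest":
        return float(min(stages))
    if cusp_rule == "mean":
        return float(statistics.fmean(stages))
    raise ValueError(f"unknown cusp rule {cusp_rule!r} (expected 'sharpest' or 'mean')")


def summarize_mws(stages: Iterable[float]) -> MesowearSummary:
    """Assemblage mean mesowear score with sample SD (n-1 denominator).

    The SD is reported missing for single-specimen assemblages, mirroring
    the published summary convention.
    """

    values = [float(s) for s in stages]
    if not values:
        raise ValueError("summarize_mws requires at least one stage")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else None
    return MesowearSummary(n=len(values), mws_mean=mean, mws_sd=sd)


def classify_diet_mws(
    mws_mean: float, cutpoints: Sequence[float] = DEFAULT_MWS_CUTPOINTS
) -> DietClass:
    """Map an assemblage mean mesowear score to a dietary class.

    Deterministic lookup against three configurable cutpoints
    (browser | browse-dominated mixed | grass-dominated mixed | grazer).
    """

    if not 0.0 <= mws_mean <= 6.0:
        raise ValueError(f"MWS {mws_mean} outside the 0-6 stage scale")
    c1, c2, c3 = cutpoints
    if not 0.0 <= c1 <= c2 <= c3 <= 6.0:
        raise ValueError(f"cutpoints {cutpoints} must be ordered within [0, 6]")
    if mws_mean < c1:
        return DietClass(DietMain.browser)
    if mws_mean < c2:
        return DietClass(DietMain.mixed, DietQualifier.browse_dominated)
    if mws_mean < c3:
        return DietClass(DietMain.mixed, DietQualifier.grass_dominated)
    return DietClass(DietMain.grazer)
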