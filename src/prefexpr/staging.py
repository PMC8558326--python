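"""Floral-bud morphometric staging of pineapple germline development.

Reproductive development in pineapple (variety MD2) can be staged from
floral-bud morphology: bud width and height track stages 1–8, after
which buds plateau at ~9 mm width and petal length distinguishes stages
9–12 ("petal just visible", then 1, 2.5 and 6 mm petals).  The embedded
timeline maps each of the 12 stages to the concurrent ovule (female)
and anther (male) germline events, so a dissected bud's measurements
predict which germline stage its ovules and pollen are in.

Sizes are averages, so classification is tolerance-based (±0.5 mm per
dimension by default) and may legitimately be ambiguous: stages 7 and 8
share 8×8 mm buds and are both reported, flagged ambiguous.  (The
source narrative places the functional-megaspore stage at ~9 mm width;
the tabulated value of 8 mm is used here.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = ["StageRecord", "StageCall", "STAGE_TABLE", "classify_bud", "stage_events", "stage_table"]


@dataclass(frozen=True)
class StageRecord:
    """One row of the reproductive timeline."""

    stage: int
    width_mm: float
    height_mm: Optional[float]  # None for petal-based stages 9-12
    petal_mm: Optional[float]  # None unless a petal length is tabulated
    petal_visible: bool
    ovule_event: str
    male_event: str


STAGE_TABLE: tuple[StageRecord, ...] = (
    StageRecord(1, 3, 2, None, False, "Ovule primordium initiation", "visible six anthers"),
    StageRecord(2, 4, 2, None, False, "Rapid growth of ovule primordium", "differentiation of AC in the young anther"),
    StageRecord(3, 4, 4, None, False, "Differentiation of AC in ovule and the integument having similar height as the ovule primordium", "PMC formation"),
    StageRecord(4, 5, 4, None, False, "MMC formation", "PMC enters meiosis"),
    StageRecord(5, 6, 5, None, False, "Still in MMC stage; the inner integument covers the nucellus", "pollen development at the tetrad stage"),
    StageRecord(6, 7, 7, None, False, "MMC prepares for meiosis; the out integument is longer than the inner integument", "one-nucleate microspores"),
    StageRecord(7, 8, 8, None, False, "MMC enters meiosis stage; the out integument has reached the micropylar pole", "one-nucleate microspores"),
    StageRecord(8, 8, 8, None, False, "FM formation", "one-nucleate microspores"),
    StageRecord(9, 9, None, None, True, "Two-nucleate stage of female gametophyte", "two-nucleate microspores"),
    StageRecord(10, 9, None, 1.0, True, "Four-nucleate stage of female gametophyte", "two-nucleate microspores"),
    StageRecord(11, 9, None, 2.5, True, "Eight-nucleate stage of female gametophyte", "three-nucleate microspores often visible"),
    StageRecord(12, 9, None, 6.0, True, "Mature female gametophyte", "mature pollen grain"),
)

_BY_STAGE = {r.stage: r for r in STAGE_TABLE}


@dataclass
class StageCall:
    """Result of a morphometric classification.

    ``candidates`` holds stage numbers ordered by match quality; empty
    with ``out_of_range=True`` when nothing matches within tolerance.
    """

    candidates: list[int]
    records: list[StageRecord]
    ambiguous: bool
    out_of_range: bool = False


def classify_bud(
    width_mm: float,
    height_mm: Optional[float] = None,
    petal_mm: Optional[float] = None,
    petal_visible: bool = False,
    tolerance_mm: float = 0.5,
) -> StageCall:
    """Match bud measurements to the timeline.

    Width/height (stages 1–8) are matched within ``tolerance_mm`` per
    dimension; when petal information is supplied it takes precedence
    and stages 9–12 are matched on petal length ("just visible" maps to
    stage 9).  Records tying at the best distance are all returned and
    the call flagged ambiguous.
    """
    if width_mm is not None and width_mm <= 0:
        raise ValueError("width must be positive")
    if height_mm is not None and height_mm <= 0:
        raise ValueError("height must be positive")
    if petal_mm is not None and petal_mm <= 0:
        raise ValueError("petal length must be positive")

    scored: list[tuple[float, StageRecord]] = []
    if petal_mm is not None or petal_visible:
        for rec in STAGE_TABLE[8:]:
            if petal_mm is None:
                # petal just visible, no measurable length
                if rec.petal_mm is None:
                    scored.append((0.0, rec))
            elif rec.petal_mm is not None:
                dev = abs(petal_mm - rec.petal_mm)
                if dev <= tolerance_mm:
                    scored.append((dev, rec))
    else:
        if height_mm is None:
            raise ValueError("height is required when no petal information is given")
        for rec in STAGE_TABLE[:8]:
            dw = abs(width_mm - rec.width_mm)
            dh = abs(height_mm - rec.height_mm)
            if dw <= tolerance_mm and dh <= tolerance_mm:
                scored.append((max(dw, dh), rec))

    scored.sort(key=lambda sr: (sr[0], sr[1].stage))
    if not scored:
        return StageCall(candidates=[], records=[], ambiguous=False, out_of_range=True)
    best = scored[0][0]
    ambiguous = sum(1 for s, _ in scored if s == best) > 1
    return StageCall(
        candidates=[r.stage for _, r in scored],
        records=[r for _, r in scored],
        ambiguous=ambiguous,
    )


def stage_events(stage: int) -> tuple[str, str]:
    """(ovule_event, male_event) of a timeline stage (1–12)."""
    if stage not in _BY_STAGE:
        raise ValueError(f"stage out of range 1-12: {stage}")
    rec = _BY_STAGE[stage]
    return rec.ovule_event, rec.male_event


def stage_table() -> pd.DataFrame:
    """The embedded timeline as a DataFrame (for TSV export)."""
    return pd.DataFrame([r.__dict__ for r in STAGE_TABLE]).set_index("stage")
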