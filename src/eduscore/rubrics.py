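"""Rubric instruments: personalization, comprehensiveness, safety.

Each instrument is a fixed ordered set of dimensions whose maxima sum to
100 points.  Two blinded raters score every document; if their scores on
any dimension differ by MORE than the adjudication threshold (10 points,
strict), the dimension is flagged.  Flagged dimensions resolve either to
an agreed consensus value or to the per-dimension median of three raters;
unflagged dimensions take the mean of the two raters (half-points may
result).
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "Instrument",
    "InstrumentDef",
    "INSTRUMENTS",
    "ScoreSheet",
    "Resolution",
    "ADJUDICATION_THRESHOLD",
    "validate_sheet",
    "sheet_total",
    "needs_adjudication",
    "final_score",
]

ADJUDICATION_THRESHOLD = 10


class Instrument(str, Enum):
    PERSONALIZATION = "PERSONALIZATION"
    COMPREHENSIVENESS = "COMPREHENSIVENESS"
    SAFETY = "SAFETY"


class Resolution(str, Enum):
    CONSENSUS_VALUE = "CONSENSUS_VALUE"
    THIRD_RATER = "THIRD_RATER"


@dataclass(frozen=True)
class InstrumentDef:
    """Ordered dimensions with maxima summing to 100, plus qualitative
    band anchors carried as documentation only (never enforced)."""

    instrument: Instrument
    dimensions: tuple[tuple[str, int], ...]
    anchors: str = ""

    def __post_init__(self) -> None:
        total = sum(mx for _, mx in self.dimensions)
        if total != 100:
            raise ValueError(f"dimension maxima must sum to 100, got {total}")

    @property
    def maxima(self) -> Mapping[str, int]:
        return dict(self.dimensions)

    @property
    def total_max(self) -> int:
        return 100


_CATEGORIES_5X20 = (
    ("medication_treatment", 20),
    ("nonmedication_treatment", 20),
    ("lifestyle_advice", 20),
    ("psychological_support", 20),
    ("disease_management", 20),
)

INSTRUMENTS: Mapping[Instrument, InstrumentDef] = {
    Instrument.PERSONALIZATION: InstrumentDef(
        Instrument.PERSONALIZATION,
        (("relevance", 30), ("individual_relevance", 40), ("detail_level", 30)),
        anchors="relevance: symptoms and disease stage; individual_relevance: "
        "personal characteristics, lifestyle, history; detail_level: depth "
        "and practicality",
    ),
    Instrument.COMPREHENSIVENESS: InstrumentDef(
        Instrument.COMPREHENSIVENESS,
        _CATEGORIES_5X20,
        anchors="per category: 17-20 complete coverage, 13-16 mostly covered",
    ),
    Instrument.SAFETY: InstrumentDef(
        Instrument.SAFETY,
        _CATEGORIES_5X20,
        anchors="per domain: 16-20 very safe, 0 unsafe",
    ),
}


@dataclass(frozen=True)
class ScoreSheet:
    """One rater's points per dimension for one instrument on one document.

    Raw rater points are integers; adjudicated sheets may carry
    half-integers.
    """

    doc_id: str
    instrument: Instrument
    rater_id: str
    points: Mapping[str, float]


def validate_sheet(sheet: ScoreSheet, definition: Optional[InstrumentDef] = None) -> list[str]:
    """Itemized problems with a raw rater sheet (empty list = valid)."""
    if definition is None:
        definition = INSTRUMENTS[Instrument(sheet.instrument)]
    problems = []
    maxima = definition.maxima
    for dim, mx in maxima.items():
        if dim not in sheet.points:
            problems.append(f"missing dimension {dim!r}")
            continue
        value = sheet.points[dim]
        if float(value) != int(value):
            problems.append(f"{dim}: non-integer score {value!r}")
        elif not 0 <= value <= mx:
            problems.append(f"{dim}: score {value} outside [0, {mx}]")
    for dim in sheet.points:
        if dim not in maxima:
            problems.append(f"unknown dimension {dim!r}")
    return problems


def sheet_total(sheet: ScoreSheet, definition: Optional[InstrumentDef] = None) -> float:
    """Sum of dimension points; in [0, 100] for a valid sheet."""
    problems = validate_sheet(sheet, definition)
    if problems:
        raise ValueError(f"invalid sheet {sheet.doc_id}/{sheet.rater_id}: {problems}")
    return sum(sheet.points.values())


def _check_same_target(r1: ScoreSheet, r2: ScoreSheet) -> None:
    if r1.doc_id != r2.doc_id or Instrument(r1.instrument) != Instrument(r2.instrument):
        raise ValueError(
            f"sheets target different units: {r1.doc_id}/{r1.instrument} "
            f"vs {r2.doc_id}/{r2.instrument}"
        )


def needs_adjudication(
    r1: ScoreSheet, r2: ScoreSheet, threshold: float = ADJUDICATION_THRESHOLD
) -> list[str]:
    """Dimensions where the raters differ by MORE than ``threshold``.

    Strict inequality: a difference of exactly ``threshold`` is accepted.
    """
    _check_same_target(r1, r2)
    definition = INSTRUMENTS[Instrument(r1.instrument)]
    return [
        dim
        for dim, _ in definition.dimensions
        if abs(r1.points[dim] - r2.points[dim]) > threshold
    ]


def final_score(
    r1: ScoreSheet,
    r2: ScoreSheet,
    r3: Optional[ScoreSheet] = None,
    resolution: Resolution = Resolution.THIRD_RATER,
    consensus: Optional[Mapping[str, float]] = None,
    threshold: float = ADJUDICATION_THRESHOLD,
) -> ScoreSheet:
    """Adjudicated sheet from two (or three) raters.

    Unflagged dimensions take the mean of the first two raters.  Flagged
    dimensions take the agreed consensus value (CONSENSUS_VALUE) or the
    per-dimension median of the three raters (THIRD_RATER).  The result
    never depends on rater order.
    """
    _check_same_target(r1, r2)
    resolution = Resolution(resolution)
    flagged = set(needs_adjudication(r1, r2, threshold))
    definition = INSTRUMENTS[Instrument(r1.instrument)]
    points: dict[str, float] = {}
    for dim, _ in definition.dimensions:
        if dim not in flagged:
            points[dim] = (r1.points[dim] + r2.points[dim]) / 2.0
        elif resolution is Resolution.CONSENSUS_VALUE:
            if consensus is None or dim not in consensus:
                raise ValueError(f"flagged dimension {dim!r} has no consensus value")
            points[dim] = consensus[dim]
        else:
            if r3 is None:
                raise ValueError(
                    f"flagged dimension {dim!r} requires a third rater sheet"
                )
            _check_same_target(r1, r3)
            points[dim] = statistics.median(
                (r1.points[dim], r2.points[dim], r3.points[dim])
            )
    return ScoreSheet(
        doc_id=r1.doc_id,
        instrument=Instrument(r1.instrument),
        rater_id="final",
        points=points,
    )
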