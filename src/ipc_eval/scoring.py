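"""Questionnaire scoring and blood-pressure control classification.

The compliance questionnaire has 25 five-point Likert items (Q1..Q25):
Q1-Q14 cover medication compliance, Q15-Q25 living habits.  Items
Q1 and Q6-Q13 are worded negatively and are reverse-coded (x -> 6 - x)
before any analysis, so that a higher adjusted score always means better
adherence.  The adjusted total therefore lies in [25, 125].

Blood pressure is classified as controlled when SBP <= 120 mmHg and
DBP <= 90 mmHg (both thresholds inclusive, home night-time measurement).
Questionnaires taking 10 minutes or longer are flagged as unreliable
(strict "less than 10 min" rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

ITEMS: tuple[str, ...] = tuple(f"Q{i}" for i in range(1, 26))
REVERSE_ITEMS: frozenset[str] = frozenset({"Q1"} | {f"Q{i}" for i in range(6, 14)})
MEDICATION_ITEMS: tuple[str, ...] = tuple(f"Q{i}" for i in range(1, 15))
LIFESTYLE_ITEMS: tuple[str, ...] = tuple(f"Q{i}" for i in range(15, 26))

#: Inclusive control thresholds, mmHg.
SBP_CONTROL_LIMIT = 120.0
DBP_CONTROL_LIMIT = 90.0

#: Strict upper bound on an acceptable completion time, minutes.
COMPLETION_TIME_LIMIT = 10.0


@dataclass(frozen=True)
class ScoredRecord:
    """One patient x timepoint after reverse coding and classification."""

    patient_id: str
    timepoint: int
    adjusted_items: dict[str, int]
    total_score: int
    controlled: bool
    time_ok: bool


def _check_items(item_scores: Mapping[str, int]) -> None:
    for item in ITEMS:
        if item not in item_scores:
            raise ValueError(f"missing item {item}")
        value = item_scores[item]
        if value not in (1, 2, 3, 4, 5):
            raise ValueError(f"item {item} has out-of-range value {value!r}")
    extra = set(item_scores) - set(ITEMS)
    if extra:
        raise ValueError(f"unexpected items {sorted(extra)}")


def apply_reverse_scoring(item_scores: Mapping[str, int]) -> dict[str, int]:
    """Map reverse-coded items x -> 6 - x; leave the rest unchanged.

    The mapping is an involution on the reverse-item set: applying it
    twice returns the raw scores.
    """
    _check_items(item_scores)
    return {
        item: (6 - item_scores[item]) if item in REVERSE_ITEMS else item_scores[item]
        for item in ITEMS
    }


def total_score(adjusted_items: Mapping[str, int]) -> int:
    """Sum of the 25 adjusted items; an integer in [25, 125]."""
    _check_items(adjusted_items)
    return int(sum(adjusted_items[item] for item in ITEMS))


def classify_bp_control(sbp: float, dbp: float) -> bool:
    """True iff SBP <= 120 and DBP <= 90 (both inclusive)."""
    if sbp <= 0 or dbp <= 0:
        raise ValueError(f"blood pressure must be positive, got ({sbp}, {dbp})")
    return sbp <= SBP_CONTROL_LIMIT and dbp <= DBP_CONTROL_LIMIT


def control_rate(flags: Iterable[bool]) -> float:
    """Percentage of controlled patients, rounded half-up to 2 decimals.

    69 controlled of 96 gives 71.88; 31 of 96 gives 32.29.
    """
    flags = list(flags)
    if not flags:
        raise ValueError("control_rate of an empty list is undefined")
    pct = Decimal(100 * sum(bool(f) for f in flags)) / Decimal(len(flags))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def flag_completion_time(minutes: float, limit: float = COMPLETION_TIME_LIMIT) -> bool:
    """True (acceptable) iff completion time is strictly under ``limit``."""
    if minutes < 0:
        raise ValueError(f"completion time must be nonnegative, got {minutes}")
    return minutes < limit


def score_record(record) -> ScoredRecord:
    """Score one raw :class:`~ipc_eval.synthetic.QuestionnaireRecord`."""
    adjusted = apply_reverse_scoring(record.item_scores)
    return ScoredRecord(
        patient_id=record.patient_id,
        timepoint=record.timepoint,
        adjusted_items=adjusted,
        total_score=total_score(adjusted),
        controlled=classify_bp_control(record.sbp, record.dbp),
        time_ok=flag_completion_time(record.completion_time),
    )


def score_cohort(records) -> list[ScoredRecord]:
    return [score_record(r) for r in records]
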