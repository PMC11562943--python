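"""Reliable and clinically significant improvement (RCSI) outcomes.

A treatment episode is scored separately on the PHQ-9 (depression,
range 0-27) and the GAD-7 (anxiety, range 0-21).  On each instrument the
episode falls into exactly one of three states:

``below_threshold``
    The initial score is below the instrument's clinical-significance
    threshold (10 for PHQ-9, 8 for GAD-7); improvement cannot be
    "clinically significant" because the client was not in the clinical
    range to begin with.
``rcsi``
    The initial score is at or above the clinical threshold and the
    decrease from first to last recorded score reaches the reliable-change
    margin (6 points for PHQ-9, 5 for GAD-7).
``no_rcsi``
    Clinically significant at intake but the decrease falls short of the
    reliable-change margin.

An episode's *actual case complexity* is ``Cx`` (complex) when the client
failed to reach RCSI on **both** instruments while being in the clinical
range on both (i.e. both statuses are exactly ``no_rcsi``); every other
combination — including being below threshold on either instrument — is a
standard case ``St``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "RcsiStatus",
    "InstrumentRule",
    "RcsiResult",
    "PHQ9",
    "GAD7",
    "compute_rcsi",
    "actual_complexity",
]


class RcsiStatus(str, Enum):
    """Three-state outcome on a single instrument."""

    BELOW_THRESHOLD = "below_threshold"
    NO_RCSI = "no_rcsi"
    RCSI = "rcsi"


@dataclass(frozen=True)
class InstrumentRule:
    """Scoring rule for one instrument.

    Parameters
    ----------
    instrument:
        ``"PHQ9"`` or ``"GAD7"`` (free-form for custom instruments).
    clinical_threshold:
        Minimum initial score for symptoms to count as clinically
        significant.
    reliable_change:
        Minimum first-minus-last decrease that counts as reliable
        improvement rather than measurement noise.
    score_range:
        Inclusive (low, high) valid range of the instrument.
    """

    instrument: str
    clinical_threshold: int
    reliable_change: int
    score_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.clinical_threshold <= 0:
            raise ValueError("clinical_threshold must be positive")
        if self.reliable_change <= 0:
            raise ValueError("reliable_change must be positive")
        lo, hi = self.score_range
        if not lo < hi:
            raise ValueError("score_range must be (low, high) with low < high")

    def validate_score(self, score: float) -> None:
        lo, hi = self.score_range
        if not lo <= score <= hi:
            raise ValueError(
                f"{self.instrument} score {score} outside valid range [{lo}, {hi}]"
            )


#: Default rules: clinical thresholds 10 / 8, reliable-change margins 6 / 5.
PHQ9 = InstrumentRule("PHQ9", clinical_threshold=10, reliable_change=6, score_range=(0, 27))
GAD7 = InstrumentRule("GAD7", clinical_threshold=8, reliable_change=5, score_range=(0, 21))


@dataclass(frozen=True)
class RcsiResult:
    """Outcome of :func:`compute_rcsi` for one instrument."""

    status: RcsiStatus
    initial: float
    last: float

    @property
    def change(self) -> float:
        """First-minus-last score decrease (positive = improvement)."""
        return self.initial - self.last


def compute_rcsi(initial: float, last: float, rule: InstrumentRule) -> RcsiResult:
    """Classify an (initial, last) score pair under ``rule``.

    Pure function; raises ``ValueError`` on out-of-range scores.
    """
    rule.validate_score(initial)
    rule.validate_score(last)
    if initial < rule.clinical_threshold:
        status = RcsiStatus.BELOW_THRESHOLD
    elif initial - last >= rule.reliable_change:
        status = RcsiStatus.RCSI
    else:
        status = RcsiStatus.NO_RCSI
    return RcsiResult(status=status, initial=initial, last=last)


def actual_complexity(phq: RcsiResult, gad: RcsiResult) -> str:
    """Actual case-complexity label: ``"Cx"`` or ``"St"``.

    Complex means *no RCSI on both instruments*: both statuses are exactly
    ``no_rcsi``.  An episode below the clinical threshold on either
    instrument is standard regardless of the other instrument.
    """
    if phq.status is RcsiStatus.NO_RCSI and gad.status is RcsiStatus.NO_RCSI:
        return "Cx"
    return "St"
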