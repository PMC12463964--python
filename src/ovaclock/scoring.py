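"""Ovarian reserve score: (1 - predicted POR probability) x 100.

The score maps POR risk onto an intuitive 0-100 scale where higher is
better.  Two anchor points carry clinical meaning: probability 0.15
(score 85) is the diminished-ovarian-reserve classification threshold used
for the population aging curve, and probability 0.5 (score 50) marks the
diminished-reserve milestone.  The default grade bands are anchored at
those two scores and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import OutOfRangeError

#: Default grade bands as (lower score bound inclusive, label), descending.
DEFAULT_GRADE_BANDS: tuple[tuple[float, str], ...] = (
    (85.0, "good"),
    (50.0, "adequate"),
    (0.0, "diminished"),
)


@dataclass(frozen=True)
class ReserveScore:
    p_por: float
    score: float
    grade: str


def score_from_probability(
    p: float, bands: tuple[tuple[float, str], ...] = DEFAULT_GRADE_BANDS
) -> ReserveScore:
    """Convert a POR probability into the 0-100 reserve score with grade.

    The transform ``score = (1 - p) * 100`` is a strictly decreasing
    bijection from [0, 1] onto [0, 100].
    """
    if not 0.0 <= p <= 1.0:
        raise OutOfRangeError(f"probability {p} outside [0, 1]")
    score = (1.0 - p) * 100.0
    return ReserveScore(p_por=float(p), score=float(score), grade=grade_from_score(score, bands))


def probability_from_score(score: float) -> float:
    """Inverse transform: p = 1 - score/100."""
    if not 0.0 <= score <= 100.0:
        raise OutOfRangeError(f"score {score} outside [0, 100]")
    return 1.0 - score / 100.0


def grade_from_score(
    score: float, bands: tuple[tuple[float, str], ...] = DEFAULT_GRADE_BANDS
) -> str:
    """Qualitative grade for a score; each band is inclusive at its lower bound."""
    if not 0.0 <= score <= 100.0:
        raise OutOfRangeError(f"score {score} outside [0, 100]")
    for lower, label in sorted(bands, key=lambda b: -b[0]):
        if score >= lower:
            return label
    return bands[-1][1]
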