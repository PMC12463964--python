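"""Fixed-interval prediction of future reproductive milestones.

Individual ovarian-aging trajectories are assumed to share the shape of the
population curve, differing only in a horizontal offset (the fixed-interval
hypothesis).  The interval a woman needs to move from her current predicted
POR probability to a target probability is therefore the difference of the
corresponding endocrine ages on the population curve, and her chronological
age at the milestone is

    age_at(p_target) = age_now + [curve^{-1}(p_target) - curve^{-1}(p_now)]

Two milestones are reported: the score-50 milestone (probability 0.5, the
diminished-reserve point) and perimenopause.  The probability defining
perimenopause — the lowest reserve score seen in an ART population — is a
configuration parameter; it can also be estimated from a training cohort as
the maximum predicted probability observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aging_curve import AgingCurve, CLAMP_EPS, curve_probability, endocrine_age
from .errors import ConfigError
from .por_models import FittedPorModel, predict_por_probabilities, predict_por_probability
from .records import CohortRecord
from .scoring import score_from_probability

#: POR probability defining the diminished-reserve (score 50) milestone.
P_SCORE50 = 0.5
#: Default POR probability defining perimenopause onset.
DEFAULT_P_PERI = 0.95


@dataclass(frozen=True)
class MilestoneConfig:
    p_score50: float = P_SCORE50
    p_peri: float = DEFAULT_P_PERI

    def __post_init__(self) -> None:
        if not 0.0 < self.p_score50 < self.p_peri < 1.0:
            raise ConfigError(
                f"need 0 < p_score50 ({self.p_score50}) < p_peri ({self.p_peri}) < 1"
            )


@dataclass(frozen=True)
class MilestoneReport:
    subject_id: str
    chronological_age: float
    amh_ng_ml: float
    p_current: float
    score_current: float
    grade: str
    endocrine_age: float
    age_at_score50: float
    age_at_perimenopause: float
    flags: tuple[str, ...]

    def to_dict(self, round_ages: bool = True) -> dict:
        """Serializable report; ages rounded to 0.1 year for presentation."""

        def _age(v: float) -> float:
            return round(v, 1) if round_ages else v

        return {
            "subject_id": self.subject_id,
            "chronological_age": self.chronological_age,
            "amh_ng_ml": self.amh_ng_ml,
            "p_por": round(self.p_current, 4),
            "score": round(self.score_current, 1),
            "grade": self.grade,
            "endocrine_age": _age(self.endocrine_age),
            "age_at_score50": _age(self.age_at_score50),
            "age_at_perimenopause": _age(self.age_at_perimenopause),
            "flags": list(self.flags),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def predict_milestone_age(
    curve: AgingCurve,
    chronological_age: float,
    p_current: float,
    p_target: float,
) -> float:
    """Chronological age at which ``p_target`` is reached.

    The fixed-interval hypothesis shifts the population curve horizontally
    through the individual's current position, so the answer is the current
    age plus the endocrine-age gap between target and current probability.
    A target at or below the current probability yields an age at or below
    the chronological age (milestone already reached); callers flag it.
    """
    return chronological_age + (
        endocrine_age(curve, p_target) - endocrine_age(curve, p_current)
    )


def estimate_p_peri(model: FittedPorModel, cohort: Sequence[CohortRecord]) -> float:
    """Perimenopause probability as the maximum predicted POR probability
    observed in a cohort (the lowest reserve score seen)."""
    probs = predict_por_probabilities(model, cohort)
    return float(np.max(probs))


def milestone_report(
    model: FittedPorModel,
    curve: AgingCurve,
    record: CohortRecord,
    config: MilestoneConfig = MilestoneConfig(),
) -> MilestoneReport:
    """Full per-subject report: probability, score, endocrine age, milestones.

    Flags raised:

    * ``plateau`` — the predicted probability lies below the population
      curve's value at the youngest fitted age: the subject sits on the flat
      high-reserve plateau where endocrine age is poorly identified and may
      stay there for years.
    * ``clamped`` — the probability was clamped before inversion.
    * ``score50_reached`` / ``perimenopause_reached`` — milestone already
      at or behind the chronological age.
    """
    p = predict_por_probability(model, record)
    reserve = score_from_probability(p)
    flags: list[str] = []
    if p < curve_probability(curve, curve.age_domain[0]):
        flags.append("plateau")
    if p < CLAMP_EPS or p > 1.0 - CLAMP_EPS:
        flags.append("clamped")

    e_age = endocrine_age(curve, p)
    age50 = predict_milestone_age(curve, record.age_years, p, config.p_score50)
    age_peri = predict_milestone_age(curve, record.age_years, p, config.p_peri)
    if age50 <= record.age_years:
        flags.append("score50_reached")
    if age_peri <= record.age_years:
        flags.append("perimenopause_reached")

    return MilestoneReport(
        subject_id=record.subject_id,
        chronological_age=record.age_years,
        amh_ng_ml=record.amh_ng_ml,
        p_current=p,
        score_current=reserve.score,
        grade=reserve.grade,
        endocrine_age=e_age,
        age_at_score50=age50,
        age_at_perimenopause=age_peri,
        flags=tuple(flags),
    )
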