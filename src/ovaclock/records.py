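"""Cohort records: one woman / one stimulation cycle.

Each record carries chronological age (years), serum AMH (ng/mL) and the
poor-ovarian-response (POR) outcome.  POR is the clinical endpoint: retrieval
of fewer than five oocytes after controlled ovarian stimulation.  When only
the oocyte count is available the binary label is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidRecordError

#: Oocyte-count threshold below which a cycle is a poor ovarian response.
POR_OOCYTE_THRESHOLD = 5

AGE_MIN, AGE_MAX = 15.0, 60.0

COHORT_COLUMNS = [
    "subject_id",
    "age_years",
    "amh_ng_ml",
    "oocytes_retrieved",
    "por",
    "cycle_day",
]


@dataclass(frozen=True)
class CohortRecord:
    """A single woman/cycle observation.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    age_years : float
        Chronological age at the AMH draw; must lie in [15, 60].
    amh_ng_ml : float
        Serum anti-Müllerian hormone, ng/mL, non-negative.  Zero values are
        legitimate observations (exhausted reserve) and are retained.
    oocytes_retrieved : int, optional
        Oocyte count after stimulation, if the cycle completed retrieval.
    por : bool, optional
        Poor ovarian response label.  Derived as ``oocytes_retrieved < 5``
        when absent but the count is present.
    cycle_day : int, optional
        Menstrual/stimulation cycle day of the AMH draw (day 2 is the
        early-follicular reference).
    """

    subject_id: str
    age_years: float
    amh_ng_ml: float
    oocytes_retrieved: int | None = None
    por: bool | None = field(default=None)
    cycle_day: int | None = None

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise InvalidRecordError(
                f"age_years={self.age_years} outside [{AGE_MIN}, {AGE_MAX}] "
                f"for subject {self.subject_id!r}"
            )
        if not self.amh_ng_ml >= 0:
            raise InvalidRecordError(
                f"amh_ng_ml={self.amh_ng_ml} is negative for subject "
                f"{self.subject_id!r}"
            )
        if self.por is None and self.oocytes_retrieved is not None:
            object.__setattr__(
                self, "por", bool(self.oocytes_retrieved < POR_OOCYTE_THRESHOLD)
            )

    @property
    def has_outcome(self) -> bool:
        return self.por is not None


def cohort_to_frame(cohort: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tabulate a cohort as a DataFrame with the standard columns."""
    rows = [
        {
            "subject_id": r.subject_id,
            "age_years": r.age_years,
            "amh_ng_ml": r.amh_ng_ml,
            "oocytes_retrieved": r.oocytes_retrieved,
            "por": r.por,
            "cycle_day": r.cycle_day,
        }
        for r in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[CohortRecord]:
    """Build records from a DataFrame with the standard columns."""

    def _opt(value, cast):
        return None if pd.isna(value) else cast(value)

    records = []
    for _, row in frame.iterrows():
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                age_years=float(row["age_years"]),
                amh_ng_ml=float(row["amh_ng_ml"]),
                oocytes_retrieved=_opt(row.get("oocytes_retrieved"), int),
                por=_opt(row.get("por"), lambda v: bool(int(v))),
                cycle_day=_opt(row.get("cycle_day"), int),
            )
        )
    return records


def outcome_subset(cohort: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Records usable for fitting: both predictors and an outcome present."""
    return [r for r in cohort if r.has_outcome]
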