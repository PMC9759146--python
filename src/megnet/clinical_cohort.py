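"""Clinical cohort handling for the pediatric focal-epilepsy study design.

The packaged fixture holds the 35-patient cohort of children newly diagnosed
with self-limited epilepsy with centrotemporal spikes (SeLECTS): gender, age
(years), disease course (months), seizure count, and a flag marking the
cognitively-impaired subgroup (full-scale IQ below 80 on the WISC-IV).
Functions here load and validate the table, compute per-group summaries
(mean, sample SD) and compare the two patient groups with an independent
two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "CohortTable",
    "GroupSummary",
    "CohortValidationError",
    "IMPAIRED",
    "NON_IMPAIRED",
    "load_cohort",
    "summarize_group",
    "compare_groups_ttest",
]

IMPAIRED = "FSIQ<80"
NON_IMPAIRED = "FSIQ>80"

COLUMNS = ["subject_id", "gender", "age", "course_months", "n_seizures", "impaired_flag"]
VARIABLES = {"age": "age", "course": "course_months", "n_seizures": "n_seizures"}


class CohortValidationError(ValueError):
    """A cohort table failed validation; the message names the offending row."""


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the clinical cohort table."""

    subject_id: int
    gender: str
    age: float
    course: float
    n_seizures: int
    impaired_flag: bool

    def validate(self) -> None:
        if self.subject_id <= 0:
            raise CohortValidationError(f"subject {self.subject_id}: id must be positive")
        if self.gender not in ("F", "M"):
            raise CohortValidationError(f"subject {self.subject_id}: gender must be F or M, got {self.gender!r}")
        if not 6 <= self.age <= 13:
            raise CohortValidationError(
                f"subject {self.subject_id}: age {self.age} outside the 6-13 year inclusion range"
            )
        if self.course <= 0:
            raise CohortValidationError(f"subject {self.subject_id}: disease course must be > 0 months")
        if self.n_seizures < 1:
            raise CohortValidationError(f"subject {self.subject_id}: seizure count must be >= 1")

    @property
    def group(self) -> str:
        return IMPAIRED if self.impaired_flag else NON_IMPAIRED


@dataclass
class CohortTable:
    """Ordered collection of subject records with a group label per subject."""

    records: list[SubjectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def group_labels(self) -> dict[int, str]:
        return {r.subject_id: r.group for r in self.records}

    def group_members(self, group: str) -> list[SubjectRecord]:
        if group not in (IMPAIRED, NON_IMPAIRED):
            raise KeyError(f"unknown group {group!r}; expected {IMPAIRED!r} or {NON_IMPAIRED!r}")
        return [r for r in self.records if r.group == group]

    def values(self, group: str, variable: str) -> np.ndarray:
        if variable not in VARIABLES:
            raise KeyError(f"unknown variable {variable!r}; expected one of {sorted(VARIABLES)}")
        attr = {"age": "age", "course": "course", "n_seizures": "n_seizures"}[variable]
        return np.array([getattr(r, attr) for r in self.group_members(group)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "gender": [r.gender for r in self.records],
                "age": [r.age for r in self.records],
                "course_months": [r.course for r in self.records],
                "n_seizures": [r.n_seizures for r in self.records],
                "impaired_flag": [int(r.impaired_flag) for r in self.records],
            }
        )

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD (n-1 denominator) of one variable over one group."""

    group: str
    variable: str
    n: int
    mean: float
    sd: float | None  # None when n < 2 (SD undefined)

    def rounded(self, ndigits: int = 2) -> tuple[float, float | None]:
        """Reporting-layer rounding; internal values stay unrounded."""
        sd = None if self.sd is None else round(self.sd, ndigits)
        return round(self.mean, ndigits), sd


def _records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {missing}")
    if df.empty:
        raise CohortValidationError("cohort table is empty")
    records = []
    seen: set[int] = set()
    for _, row in df.iterrows():
        try:
            rec = SubjectRecord(
                subject_id=int(row["subject_id"]),
                gender=str(row["gender"]).strip(),
                age=float(row["age"]),
                course=float(row["course_months"]),
                n_seizures=int(row["n_seizures"]),
                impaired_flag=bool(int(row["impaired_flag"])),
            )
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"malformed row (subject_id={row['subject_id']!r}): {exc}") from exc
        if rec.subject_id in seen:
            raise CohortValidationError(f"duplicate subject id {rec.subject_id}")
        seen.add(rec.subject_id)
        rec.validate()
        records.append(rec)
    return records


def load_cohort(source: str | Path | None = None, sep: str | None = None) -> CohortTable:
    """Load and validate a cohort table.

    With no argument, loads the packaged 35-patient fixture (17 impaired,
    18 non-impaired). Otherwise *source* is a comma- or tab-delimited file
    with header ``subject_id,gender,age,course_months,n_seizures,impaired_flag``.
    """
    if source is None:
        with resources.files("megnet.data").joinpath("table1_cohort.csv").open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    return CohortTable(records=_records_from_frame(df))


def summarize_group(cohort: CohortTable, group: str, variable: str) -> GroupSummary:
    """Mean and sample SD of *variable* over the members of *group*.

    SD uses the n-1 denominator and is reported as ``None`` for a single
    subject. Raises on an unknown group/variable or an empty group.
    """
    x = cohort.values(group, variable)
    if x.size == 0:
        raise ValueError(f"group {group!r} is empty")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return GroupSummary(group=group, variable=variable, n=int(x.size), mean=float(np.mean(x)), sd=sd)


def compare_groups_ttest(
    cohort_or_samples: CohortTable | tuple[Iterable[float], Iterable[float]],
    variable: str | None = None,
    equal_var: bool = True,
) -> dict[str, float]:
    """Two-sided independent two-sample t-test between the two patient groups.

    Default is the pooled-variance Student form; pass ``equal_var=False``
    for Welch. Returns ``{"t", "p", "df"}``. Degenerate case: zero pooled
    variance with equal means yields t=0, p=1; zero variance with unequal
    means yields p=0 (infinite t).
    """
    if isinstance(cohort_or_samples, CohortTable):
        if variable is None:
            raise ValueError("variable required when passing a cohort")
        a = cohort_or_samples.values(IMPAIRED, variable)
        b = cohort_or_samples.values(NON_IMPAIRED, variable)
    else:
        a, b = (np.asarray(list(v), dtype=float) for v in cohort_or_samples)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2 for a t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "p": 1.0, "df": float(len(a) + len(b) - 2)}
        sign = math.copysign(1.0, float(np.mean(a) - np.mean(b)))
        return {"t": sign * math.inf, "p": 0.0, "df": float(len(a) + len(b) - 2)}
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": float(res.df)}
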