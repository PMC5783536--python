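"""Records, covariate recoding and design matrices for the activity models.

The outcome is weekly minutes of leisure-time physical activity (LTPA), a
semicontinuous variable: exactly zero for participants who report no such
activity, continuous and right-skewed among the active.  Covariates follow
the cohort-study coding: gender, age in years, a four-level education
variable and annual per-capita family income in US$.  For interpretability
age enters the models in 10-year units and income in US$1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GENDER_LEVELS",
    "EDUCATION_LEVELS",
    "ACTIVITY_CATEGORIES",
    "WEEKLY_TARGET_MINUTES",
    "ParticipantRecord",
    "CategoricalTerm",
    "NumericTerm",
    "DesignSpec",
    "DesignMatrix",
    "OutcomeViews",
    "default_design_spec",
    "weekly_minutes",
    "categorize",
    "categorize_minutes",
    "outcome_views",
    "build_design",
    "records_to_frame",
    "read_participants_csv",
    "write_participants_csv",
]

GENDER_LEVELS = ("female", "male")
EDUCATION_LEVELS = ("basic", "high_school", "college", "graduate")
ACTIVITY_CATEGORIES = ("none", "low", "high")

#: Recommended minimum of weekly moderate activity used as the upper cut-off.
WEEKLY_TARGET_MINUTES = 150.0

# Accepted spellings -> canonical level (matching is case-insensitive and
# ignores surrounding whitespace; spaces and hyphens map to underscores).
_CANONICAL = {
    "female": "female",
    "f": "female",
    "woman": "female",
    "women": "female",
    "male": "male",
    "m": "male",
    "man": "male",
    "men": "male",
    "basic": "basic",
    "basic_education": "basic",
    "high_school": "high_school",
    "highschool": "high_school",
    "college": "college",
    "graduate": "graduate",
}


def _canon(value: str, allowed: Sequence[str], what: str) -> str:
    key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    canon = _CANONICAL.get(key, key)
    if canon not in allowed:
        raise ValueError(f"unknown {what} level {value!r}; expected one of {allowed}")
    return canon


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: raw covariates plus the weekly-minutes outcome."""

    id: object
    gender: str
    age_years: float
    education: str
    income_usd: float
    weekly_minutes: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", _canon(self.gender, GENDER_LEVELS, "gender"))
        object.__setattr__(
            self, "education", _canon(self.education, EDUCATION_LEVELS, "education")
        )
        if self.income_usd is not None and not np.isnan(self.income_usd):
            if self.income_usd < 0:
                raise ValueError("income_usd must be non-negative")
        if self.weekly_minutes is not None and not np.isnan(self.weekly_minutes):
            if self.weekly_minutes < 0:
                raise ValueError("weekly_minutes must be non-negative")


def weekly_minutes(days_per_week: int, minutes_per_day: float) -> float:
    """Weekly LTPA minutes as days-of-activity times minutes per day.

    This is the questionnaire scoring rule: an approximate weekly total from
    the reported frequency (0-7 days) and usual duration.
    """
    days = int(days_per_week)
    if days != days_per_week:
        raise ValueError("days_per_week must be an integer")
    if not 0 <= days <= 7:
        raise ValueError("days_per_week must be between 0 and 7")
    if minutes_per_day < 0:
        raise ValueError("minutes_per_day must be non-negative")
    return float(days * minutes_per_day)


def categorize(y_minutes: float) -> str:
    """Three-category view: none (exact 0), low (0,150), high (>=150)."""
    if y_minutes < 0:
        raise ValueError("weekly minutes must be non-negative")
    if y_minutes == 0:
        return "none"
    return "high" if y_minutes >= WEEKLY_TARGET_MINUTES else "low"


def categorize_minutes(y: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize`."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("weekly minutes must be non-negative")
    out = np.where(y == 0, "none", np.where(y >= WEEKLY_TARGET_MINUTES, "high", "low"))
    return out.astype(object)


@dataclass(frozen=True)
class OutcomeViews:
    """The three synchronised views of the outcome used across the models."""

    y_minutes: np.ndarray
    any_activity: np.ndarray
    category3: np.ndarray


def outcome_views(y: Iterable[float]) -> OutcomeViews:
    y = np.asarray(list(y) if not isinstance(y, np.ndarray) else y, dtype=float)
    if np.any(y < 0) or np.any(~np.isfinite(y)):
        raise ValueError("weekly minutes must be finite and non-negative")
    return OutcomeViews(
        y_minutes=y,
        any_activity=(y > 0).astype(int),
        category3=categorize_minutes(y),
    )


@dataclass(frozen=True)
class CategoricalTerm:
    name: str
    levels: tuple
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels {self.levels}"
            )

    @property
    def columns(self) -> list:
        return [lv for lv in self.levels if lv != self.reference]


@dataclass(frozen=True)
class NumericTerm:
    name: str
    scale: float = 1.0  # variable is divided by this before entering the model
    column: str | None = None

    @property
    def column_name(self) -> str:
        return self.column if self.column is not None else self.name


Term = Union[CategoricalTerm, NumericTerm]


@dataclass(frozen=True)
class DesignSpec:
    """Ordered covariate terms with reference levels and scalings.

    The default maps gender (reference female), education (reference basic),
    age in decades and income in US$1,000 to the fixed column order
    ``intercept, male, high_school, college, graduate, age_decades, income_k``
    so coefficient vectors are comparable across runs.
    """

    terms: tuple = field(default_factory=tuple)

    @property
    def column_names(self) -> list:
        cols = ["intercept"]
        for term in self.terms:
            if isinstance(term, CategoricalTerm):
                cols.extend(term.columns)
            else:
                cols.append(term.column_name)
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def default_design_spec() -> DesignSpec:
    return DesignSpec(
        terms=(
            CategoricalTerm("gender", GENDER_LEVELS, reference="female"),
            CategoricalTerm("education", EDUCATION_LEVELS, reference="basic"),
            NumericTerm("age_years", scale=10.0, column="age_decades"),
            NumericTerm("income_usd", scale=1000.0, column="income_k"),
        )
    )


@dataclass(frozen=True)
class DesignMatrix:
    """A dense design with named columns; first column is the intercept."""

    columns: tuple
    values: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "gender": r.gender,
            "age_years": r.age_years,
            "education": r.education,
            "income_usd": r.income_usd,
            "weekly_minutes": r.weekly_minutes,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def build_design(
    data: Union[pd.DataFrame, Iterable[ParticipantRecord]],
    spec: DesignSpec | None = None,
    *,
    return_complete_index: bool = False,
):
    """Build the model matrix from participant data, complete cases only.

    Rows missing any modelled variable are dropped and counted in
    ``n_dropped`` (complete-case analysis; nothing is imputed).  Categorical
    levels are validated and dummy-coded against the declared reference;
    numeric terms are divided by their declared scale.
    """
    if spec is None:
        spec = default_design_spec()
    if not isinstance(data, pd.DataFrame):
        data = records_to_frame(data)

    needed = [t.name for t in spec.terms]
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks required columns: {missing_cols}")

    sub = data[needed].copy()
    for term in spec.terms:
        if isinstance(term, NumericTerm):
            sub[term.name] = pd.to_numeric(sub[term.name], errors="coerce")
        else:
            notna = sub[term.name].notna()
            sub.loc[notna, term.name] = [
                _canon(v, term.levels, term.name) for v in sub.loc[notna, term.name]
            ]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    sub = sub.loc[complete]

    cols = [np.ones(len(sub))]
    for term in spec.terms:
        if isinstance(term, CategoricalTerm):
            for level in term.columns:
                cols.append((sub[term.name] == level).to_numpy(dtype=float))
        else:
            cols.append(sub[term.name].to_numpy(dtype=float) / term.scale)
    values = np.column_stack(cols) if len(sub) else np.empty((0, spec.n_columns))
    dm = DesignMatrix(
        columns=tuple(spec.column_names), values=values, n_dropped=n_dropped
    )
    if return_complete_index:
        return dm, complete.to_numpy()
    return dm


_CSV_COLUMNS = ["id", "gender", "age_years", "education", "income_usd", "weekly_minutes"]


def read_participants_csv(path) -> pd.DataFrame:
    """Read the flat participant table (UTF-8, '.' decimal, empty = missing)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant CSV lacks required columns: {missing}")
    for col in ("age_years", "income_usd", "weekly_minutes"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["weekly_minutes"].dropna() < 0).any():
        raise ValueError("weekly_minutes contains negative values")
    return df


def write_participants_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_CSV_COLUMNS, encoding="utf-8")
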