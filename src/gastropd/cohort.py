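"""Cohort data structures, validation and long-format I/O.

The analysis consumes a tidy, three-table long-format cohort:

* ``patients`` — one row per patient with baseline covariates (demographics,
  clinical TNM staging, histology, treatment arm) and, for operated patients,
  pathologic ``ypT``/``ypN`` staging.
* ``visits`` — one row per patient-visit carrying the ordered-categorical
  clinical response variable ``response_dv`` (0 = partial response,
  1 = stable disease, 2 = disease progression).  By convention every patient
  is in category 2 at the diagnosis visit.
* ``events`` — one row per (patient, event type) for metastasis appearance
  and death, with right-censoring flags.

TNM categories are stored as integer ranks on declared ordinal scales:
T: 0 < 1 < 2 < 3 < 4a < 4b mapped to 0..5; N: 0 < 1 < 2 < 3a < 3b mapped to
0..4; clinical stage: Ib < II < III mapped to 1 < 2 < 3.  Ranks, rather than
labels, are what the up/down-staging rule and the Spearman concordance
analyses operate on.

Spreadsheet exports with arbitrary column names (e.g. an anonymized trial
dataset) are ingested through a user-supplied column map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "T_RANKS",
    "N_RANKS",
    "STAGE_RANKS",
    "PatientRecord",
    "VisitObservation",
    "EventRecord",
    "CohortTable",
    "CohortValidationError",
    "ColumnMapError",
    "derive_response",
    "derive_pcr",
    "read_cohort",
    "write_cohort",
]

# Ordinal encodings for TNM categories (label -> integer rank).
T_RANKS: dict[str, int] = {"T0": 0, "T1": 1, "T2": 2, "T3": 3, "T4a": 4, "T4b": 5}
N_RANKS: dict[str, int] = {"N0": 0, "N1": 1, "N2": 2, "N3a": 3, "N3b": 4}
STAGE_RANKS: dict[str, int] = {"Ib": 1, "II": 2, "III": 3}

#: Canonical columns of each table; booleans serialized as 0/1, missing as "".
PATIENT_COLUMNS = [
    "patient_id", "age_years", "sex", "ecog", "tumor_site", "location",
    "linitis", "lauren", "grade", "her2", "ctnm_stage", "treatment",
    "dose_intensity", "ct_n_positive", "ypt", "ypn",
]
VISIT_COLUMNS = ["patient_id", "visit_index", "time_days", "clinical_t",
                 "clinical_n", "response_dv"]
EVENT_COLUMNS = ["patient_id", "event_type", "time_days", "observed"]

_CATEGORICAL_LEVELS = {
    "sex": {"male", "female"},
    "tumor_site": {"gastric", "gej"},
    "location": {"cardias", "antrum", "body", "pylorus"},
    "lauren": {"diffuse", "intestinal"},
    "grade": {"well", "moderate", "poor"},
    "treatment": {"ChT", "CRT"},
}


class CohortValidationError(ValueError):
    """Raised when a cohort violates its invariants.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "cohort validation failed with %d violation(s):\n  %s"
            % (len(self.violations), "\n  ".join(self.violations))
        )


class ColumnMapError(KeyError):
    """A mandatory canonical field is missing from the column map / file."""


@dataclass
class PatientRecord:
    patient_id: str
    age_years: float
    sex: str
    ecog: int
    tumor_site: str
    location: str
    linitis: bool
    lauren: str
    grade: str
    her2: bool | None
    ctnm_stage: int
    treatment: str
    dose_intensity: float | None = None
    ct_n_positive: bool = False
    ypt: int | None = None
    ypn: int | None = None


@dataclass
class VisitObservation:
    patient_id: str
    visit_index: int
    time_days: float
    response_dv: int | None
    clinical_t: int | None = None
    clinical_n: bool | None = None


@dataclass
class EventRecord:
    patient_id: str
    event_type: str  # "metastasis" | "death"
    time_days: float
    observed: bool


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return x is pd.NA


@dataclass
class CohortTable:
    """Validated container of the three long-format tables.

    The tables are plain :class:`pandas.DataFrame` objects with the canonical
    column sets; optional fields use pandas missing values (``NA``/``NaN``).
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self):
        self.patients = _normalize(self.patients, PATIENT_COLUMNS)
        self.visits = _normalize(self.visits, VISIT_COLUMNS)
        self.events = _normalize(self.events, EVENT_COLUMNS)
        if len(self.visits):
            self.visits = self.visits.sort_values(
                ["patient_id", "visit_index"], kind="stable"
            ).reset_index(drop=True)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        patients: Iterable[PatientRecord],
        visits: Iterable[VisitObservation] = (),
        events: Iterable[EventRecord] = (),
        validate: bool = True,
    ) -> "CohortTable":
        def frame(records, columns):
            rows = [{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in records]
            return pd.DataFrame(rows, columns=columns)

        cohort = cls(
            frame(patients, PATIENT_COLUMNS),
            frame(visits, VISIT_COLUMNS),
            frame(events, EVENT_COLUMNS),
        )
        if validate:
            cohort.validate()
        return cohort

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    # -- validation -------------------------------------------------------
    def validation_report(self) -> list[str]:
        """Return every invariant violation (empty list means valid)."""
        v: list[str] = []
        pat = self.patients
        ids = pat["patient_id"]
        dup = ids[ids.duplicated()]
        for pid in dup:
            v.append(f"duplicate patient_id {pid!r}")
        known = set(ids)

        for i, row in pat.iterrows():
            pid = row["patient_id"]
            if not _is_missing(row["age_years"]) and row["age_years"] < 18:
                v.append(f"patient {pid!r}: age_years {row['age_years']} < 18")
            if row["ecog"] not in (0, 1) and not _is_missing(row["ecog"]):
                v.append(f"patient {pid!r}: ecog {row['ecog']} not in {{0,1}}")
            for col, levels in _CATEGORICAL_LEVELS.items():
                val = row[col]
                if not _is_missing(val) and val not in levels:
                    v.append(f"patient {pid!r}: {col}={val!r} not in {sorted(levels)}")
            if not _is_missing(row["ctnm_stage"]) and row["ctnm_stage"] not in (1, 2, 3):
                v.append(f"patient {pid!r}: ctnm_stage {row['ctnm_stage']} outside ranks 1..3")
            # ypT and ypN travel together: present iff the patient was operated
            if _is_missing(row["ypt"]) != _is_missing(row["ypn"]):
                v.append(f"patient {pid!r}: ypt/ypn must be both present or both missing")
            if not _is_missing(row["dose_intensity"]):
                di = row["dose_intensity"]
                if not (0 < di <= 1):
                    v.append(f"patient {pid!r}: dose_intensity {di} outside (0,1]")

        vis = self.visits
        for pid in vis["patient_id"].unique():
            if pid not in known:
                v.append(f"visit references unknown patient_id {pid!r}")
        for pid, g in vis.groupby("patient_id", sort=False):
            if not (1 <= len(g) <= 4):
                v.append(f"patient {pid!r}: {len(g)} visits outside 1..4")
            t = g["time_days"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                v.append(f"patient {pid!r}: visit times not strictly increasing")
            first = g.iloc[0]
            if int(first["visit_index"]) == 1 and not _is_missing(first["response_dv"]):
                if int(first["response_dv"]) != 2:
                    v.append(
                        f"patient {pid!r}: response_dv at diagnosis visit is "
                        f"{first['response_dv']}, expected 2"
                    )
            bad = g["response_dv"].dropna()
            if len(bad) and not bad.isin([0, 1, 2]).all():
                v.append(f"patient {pid!r}: response_dv outside {{0,1,2}}")

        ev = self.events
        for pid in ev["patient_id"].unique():
            if pid not in known:
                v.append(f"event references unknown patient_id {pid!r}")
        if len(ev):
            if not ev["event_type"].isin(["metastasis", "death"]).all():
                bad = sorted(set(ev["event_type"]) - {"metastasis", "death"})
                v.append(f"unknown event_type values {bad}")
            dup_ev = ev[ev.duplicated(["patient_id", "event_type"])]
            for _, row in dup_ev.iterrows():
                v.append(
                    f"patient {row['patient_id']!r}: duplicate {row['event_type']} record"
                )
            if (ev["time_days"].to_numpy(dtype=float) <= 0).any():
                v.append("event time_days must be positive")
            wide = ev.pivot_table(
                index="patient_id", columns="event_type", values="time_days",
                aggfunc="first",
            )
            if "metastasis" in wide and "death" in wide:
                both = wide.dropna()
                late = both[both["metastasis"] > both["death"]]
                for pid in late.index:
                    v.append(f"patient {pid!r}: metastasis after death/censoring time")
        return v

    def validate(self) -> "CohortTable":
        violations = self.validation_report()
        if violations:
            raise CohortValidationError(violations)
        return self

    def equals(self, other: "CohortTable") -> bool:
        """Structural equality ignoring row order of patients/events."""
        def canon(df, keys):
            return df.sort_values(keys, kind="stable").reset_index(drop=True)

        try:
            pd.testing.assert_frame_equal(
                canon(self.patients, ["patient_id"]),
                canon(other.patients, ["patient_id"]),
                check_dtype=False,
            )
            pd.testing.assert_frame_equal(
                canon(self.visits, ["patient_id", "visit_index"]),
                canon(other.visits, ["patient_id", "visit_index"]),
                check_dtype=False,
            )
            pd.testing.assert_frame_equal(
                canon(self.events, ["patient_id", "event_type"]),
                canon(other.events, ["patient_id", "event_type"]),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


_BOOL_COLUMNS = {"linitis", "her2", "ct_n_positive", "clinical_n", "observed"}
_INT_COLUMNS = {"ecog", "ctnm_stage", "ypt", "ypn", "visit_index", "response_dv",
                "clinical_t"}
_FLOAT_COLUMNS = {"age_years", "dose_intensity", "time_days"}


def _coerce_bool(x):
    if _is_missing(x) or x == "":
        return pd.NA
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot interpret {x!r} as boolean")
    return bool(int(x)) if not isinstance(x, bool) else x


def _normalize(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Coerce a raw frame to canonical columns and nullable dtypes."""
    out = pd.DataFrame(index=range(len(df)))
    for col in columns:
        if col in df.columns:
            s = df[col]
        else:
            s = pd.Series([pd.NA] * len(df))
        s = s.mask(s == "", pd.NA)
        if col in _BOOL_COLUMNS:
            out[col] = pd.array([_coerce_bool(x) for x in s], dtype="boolean")
        elif col in _INT_COLUMNS:
            out[col] = pd.array(
                [pd.NA if _is_missing(x) else int(float(x)) for x in s], dtype="Int64"
            )
        elif col in _FLOAT_COLUMNS:
            out[col] = pd.array(
                [pd.NA if _is_missing(x) else float(x) for x in s], dtype="Float64"
            )
        else:
            out[col] = pd.array(
                [pd.NA if _is_missing(x) else str(x) for x in s], dtype="string"
            )
    return out


# ---------------------------------------------------------------------------
# response-category derivation
# ---------------------------------------------------------------------------

def derive_response(stage_sequence: Sequence[int | None]) -> list[int | None]:
    """Map an ordered sequence of TNM stage ranks to response categories.

    The diagnosis visit is category 2 (disease progression) by convention.
    Thereafter each visit is compared with the previous one: a lower rank is
    downstaging (0, partial response), equal rank is no change (1, stable
    disease), a higher rank is upstaging (2, progression).  A missing interior
    stage yields a missing response, and the next comparison falls back to the
    last observed stage.
    """
    stages = list(stage_sequence)
    if not stages:
        raise ValueError("stage_sequence must contain at least one visit")
    out: list[int | None] = [2]
    prev = stages[0]
    for s in stages[1:]:
        if _is_missing(s) or _is_missing(prev):
            out.append(None)
            if not _is_missing(s):
                prev = s
            continue
        if s < prev:
            out.append(0)
        elif s == prev:
            out.append(1)
        else:
            out.append(2)
        prev = s
    return out


def derive_response_combined(
    t_sequence: Sequence[int | None], n_sequence: Sequence[int | None]
) -> list[int | None]:
    """Response categories from joint (T, N) rank sequences.

    Any upstaging in T or N dominates (category 2); downstaging in either
    without upstaging in the other is category 0; otherwise 1.
    """
    if len(t_sequence) != len(n_sequence):
        raise ValueError("t_sequence and n_sequence must have equal length")
    out: list[int | None] = [2]
    prev_t, prev_n = t_sequence[0], n_sequence[0]
    for t, n in zip(t_sequence[1:], n_sequence[1:]):
        deltas = []
        if not (_is_missing(t) or _is_missing(prev_t)):
            deltas.append(np.sign(t - prev_t))
        if not (_is_missing(n) or _is_missing(prev_n)):
            deltas.append(np.sign(n - prev_n))
        if not deltas:
            out.append(None)
        elif any(d > 0 for d in deltas):
            out.append(2)
        elif any(d < 0 for d in deltas):
            out.append(0)
        else:
            out.append(1)
        prev_t = t if not _is_missing(t) else prev_t
        prev_n = n if not _is_missing(n) else prev_n
    return out


def derive_pcr(patient: PatientRecord | Mapping) -> bool | None:
    """Complete pathologic response: no residual tumor, i.e. ypT0 and ypN0.

    Returns ``None`` when pathology is unavailable (patient not operated).
    """
    ypt = patient.ypt if isinstance(patient, PatientRecord) else patient["ypt"]
    ypn = patient.ypn if isinstance(patient, PatientRecord) else patient["ypn"]
    if _is_missing(ypt) or _is_missing(ypn):
        return None
    return int(ypt) == 0 and int(ypn) == 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = {
    "patients": ["patient_id", "age_years", "sex", "ecog", "tumor_site",
                 "linitis", "lauren", "grade", "ctnm_stage", "treatment"],
    "visits": ["patient_id", "visit_index", "time_days", "response_dv"],
    "events": ["patient_id", "event_type", "time_days", "observed"],
}


def _read_table(path: Path, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(path, dtype=object)
        else:
            raw = pd.read_csv(path, dtype=object, keep_default_na=False)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if column_map:
        missing_src = [src for src in column_map.values() if src not in raw.columns]
        if missing_src:
            raise ColumnMapError(
                f"{path}: mapped source column(s) {missing_src} absent from file"
            )
        raw = raw.rename(columns={src: canon for canon, src in column_map.items()})
    return raw


def read_cohort(
    directory: str | Path,
    column_maps: Mapping[str, Mapping[str, str]] | None = None,
    validate: bool = True,
) -> CohortTable:
    """Read a cohort from ``patients.csv``/``visits.csv``/``events.csv``.

    ``directory`` holds the three canonical files (``events`` optional;
    ``.xlsx`` variants are accepted).  ``column_maps`` optionally maps
    canonical field name -> source column name per table, for files exported
    with non-canonical headers.  Unknown columns are ignored; mandatory
    canonical fields must resolve or a :class:`ColumnMapError` is raised.
    """
    directory = Path(directory)
    frames = {}
    for name in ("patients", "visits", "events"):
        cand = [directory / f"{name}.csv", directory / f"{name}.xlsx"]
        found = next((p for p in cand if p.exists()), None)
        if found is None:
            if name == "events":
                frames[name] = pd.DataFrame(columns=EVENT_COLUMNS)
                continue
            raise FileNotFoundError(f"missing {name}.csv (or .xlsx) in {directory}")
        cmap = (column_maps or {}).get(name)
        raw = _read_table(found, cmap)
        missing = [c for c in _MANDATORY[name] if c not in raw.columns]
        if missing:
            raise ColumnMapError(
                f"{found}: mandatory field(s) {missing} not present; "
                "provide a column map entry for them"
            )
        frames[name] = raw
    cohort = CohortTable(frames["patients"], frames["visits"], frames["events"])
    if validate:
        cohort.validate()
    return cohort


def write_cohort(cohort: CohortTable, directory: str | Path) -> None:
    """Write the three canonical CSV files (UTF-8, RFC-4180, empty cell = NA)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in (("patients", cohort.patients), ("visits", cohort.visits),
                     ("events", cohort.events)):
        out = df.copy()
        for col in out.columns:
            if col in _BOOL_COLUMNS:
                out[col] = out[col].map({True: 1, False: 0}).astype("Int64")
        out.to_csv(directory / f"{name}.csv", index=False, na_rep="")
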