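"""Reading visit records and turning them into first-occurrence disease paths.

A patient's medical history is represented as a *path*: the ordered
sequence of dates at which each 3-digit ICD-9-CM category appears for the
first time in that patient's record. Several categories first appearing on
the same visit date share one bucket. Supplementary-classification codes
(V01-V91, E000-E999) are excluded, and codes are truncated to their 3-digit
base category before first occurrences are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`truncate_code` for V/E supplementary codes.
EXCLUDED = "__excluded__"


@dataclass(frozen=True)
class VisitRecord:
    """One diagnosis event: a code recorded for a patient on a visit date."""

    patient_id: str
    visit_date: date
    code: str


@dataclass(frozen=True)
class PatientMeta:
    """Demographics needed by the cohort filters and the fatality metric."""

    patient_id: str
    birth_date: date | None = None
    death_date: date | None = None
    sex: str = "unknown"  # "male" | "female" | "unknown"

    def __post_init__(self) -> None:
        if (
            self.birth_date is not None
            and self.death_date is not None
            and self.death_date < self.birth_date
        ):
            raise ValueError(
                f"patient {self.patient_id}: death_date precedes birth_date"
            )


@dataclass
class PatientPath:
    """Ordered first-occurrence buckets: (date, set of 3-digit codes)."""

    patient_id: str
    buckets: list[tuple[date, frozenset[str]]] = field(default_factory=list)

    def codes(self) -> set[str]:
        out: set[str] = set()
        for _, bucket in self.buckets:
            out |= bucket
        return out

    def first_date(self, code: str) -> date | None:
        for d, bucket in self.buckets:
            if code in bucket:
                return d
        return None


class IngestError(ValueError):
    """Raised for unreadable sources or invalid configuration."""


def _parse_date(value) -> date | None:
    ts = pd.to_datetime(value, errors="coerce", format="ISO8601")
    if pd.isna(ts):
        return None
    return ts.date()


def parse_records(
    source,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[VisitRecord], int]:
    """Read a delimited visits table into :class:`VisitRecord` objects.

    Parameters
    ----------
    source:
        Path or file-like object with one diagnosis code per row
        (long format): columns for patient id, visit date (ISO-8601) and
        ICD-9 code.
    column_map:
        Maps the logical names ``patient_id``, ``visit_date``, ``code``
        to the column names present in the file. Defaults to the
        identical names with ``icd9`` accepted as an alias for ``code``.
    delimiter:
        Field delimiter; ``None`` auto-detects comma vs tab.

    Returns
    -------
    (records, n_rejected):
        Parsed records and the count of malformed rows (bad date or
        empty code), which are logged and dropped rather than raised.
    """
    import csv as _csv

    try:
        df = pd.read_csv(source, sep=delimiter, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        return [], 0
    except _csv.Error:
        # delimiter sniffing fails on single-column or header-only input
        if hasattr(source, "seek"):
            source.seek(0)
        try:
            df = pd.read_csv(source, sep=",", dtype=str)
        except pd.errors.EmptyDataError:
            return [], 0
    except (OSError, pd.errors.ParserError) as exc:
        raise IngestError(f"cannot read visits source: {exc}") from exc

    cmap = {"patient_id": "patient_id", "visit_date": "visit_date", "code": "code"}
    if column_map:
        cmap.update(column_map)
    if cmap["code"] not in df.columns and "icd9" in df.columns:
        cmap["code"] = "icd9"
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise IngestError(f"visits source lacks required columns: {missing}")

    records: list[VisitRecord] = []
    rejected = 0
    for pid, raw_date, raw_code in zip(
        df[cmap["patient_id"]], df[cmap["visit_date"]], df[cmap["code"]]
    ):
        code = "" if pd.isna(raw_code) else str(raw_code).strip()
        d = _parse_date(raw_date)
        if d is None or not code or pd.isna(pid):
            rejected += 1
            continue
        records.append(VisitRecord(str(pid).strip(), d, code))
    if rejected:
        logger.warning("parse_records: rejected %d malformed rows", rejected)
    return records, rejected


def parse_patients(source, delimiter: str | None = None) -> dict[str, PatientMeta]:
    """Read the patients table (patient_id, birth_date, death_date, sex)."""
    try:
        df = pd.read_csv(source, sep=delimiter, engine="python", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise IngestError(f"cannot read patients source: {exc}") from exc
    except pd.errors.EmptyDataError:
        return {}
    meta: dict[str, PatientMeta] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        sex = str(row.get("sex", "unknown")).strip().lower()
        if sex not in ("male", "female"):
            sex = "unknown"
        meta[pid] = PatientMeta(
            patient_id=pid,
            birth_date=_parse_date(row.get("birth_date")),
            death_date=_parse_date(row.get("death_date")),
            sex=sex,
        )
    return meta


def _age_years(birth: date, at: date) -> float:
    return (at - birth).days / 365.25


def filter_cohort(
    records: Sequence[VisitRecord],
    meta: Mapping[str, PatientMeta],
    max_age: float = 99.0,
    reference_date: date = date(2018, 10, 1),
    sex_filter: str | None = "male",
) -> list[VisitRecord]:
    """Keep records of patients passing the sex filter and age cutoff.

    A patient older than ``max_age`` years at ``reference_date`` is
    dropped. Patients with no birth date are retained (the age filter is
    inapplicable); patients with unknown sex are dropped whenever a sex
    filter is active.
    """
    keep: dict[str, bool] = {}
    out = []
    for rec in records:
        pid = rec.patient_id
        if pid not in keep:
            m = meta.get(pid)
            ok = True
            if sex_filter is not None:
                ok = m is not None and m.sex == sex_filter
            if ok and m is not None and m.birth_date is not None:
                ok = _age_years(m.birth_date, reference_date) <= max_age
            keep[pid] = ok
        if keep[pid]:
            out.append(rec)
    return out


def truncate_code(code: str) -> str | None:
    """Reduce an ICD-9-CM code to its 3-digit base category.

    Numeric codes keep the first three digits before any decimal point,
    left-zero-padded to width 3 ("42" -> "042", "250.01" -> "250").
    Supplementary V/E codes return the :data:`EXCLUDED` marker; anything
    else returns ``None`` (malformed, to be counted by the caller).
    """
    code = code.strip().upper()
    if not code:
        return None
    if code[0] in ("V", "E"):
        return EXCLUDED
    head = code.split(".", 1)[0]
    if not head.isdigit():
        return None
    return head[:3].zfill(3)


def extract_paths(records: Iterable[VisitRecord]) -> list[PatientPath]:
    """Build per-patient first-occurrence paths from filtered records.

    For each patient, each distinct 3-digit code is assigned to the date
    of its earliest record; codes sharing a first-occurrence date share a
    bucket. V/E codes are excluded and malformed codes dropped (counted
    in the log). Paths are returned sorted by patient id; buckets are
    strictly increasing in date.
    """
    first_seen: dict[str, dict[str, date]] = {}
    malformed = 0
    for rec in records:
        t = truncate_code(rec.code)
        if t is EXCLUDED or t == EXCLUDED:
            continue
        if t is None:
            malformed += 1
            continue
        per = first_seen.setdefault(rec.patient_id, {})
        if t not in per or rec.visit_date < per[t]:
            per[t] = rec.visit_date
    if malformed:
        logger.warning("extract_paths: dropped %d malformed codes", malformed)

    paths: list[PatientPath] = []
    for pid in sorted(first_seen):
        by_date: dict[date, set[str]] = {}
        for code, d in first_seen[pid].items():
            by_date.setdefault(d, set()).add(code)
        buckets = [(d, frozenset(by_date[d])) for d in sorted(by_date)]
        paths.append(PatientPath(patient_id=pid, buckets=buckets))
    return paths


def paths_to_frame(paths: Sequence[PatientPath]) -> pd.DataFrame:
    """Serialize paths as a long table (patient_id, rank, date, code)."""
    rows = []
    for p in paths:
        for rank, (d, bucket) in enumerate(p.buckets):
            for code in sorted(bucket):
                rows.append((p.patient_id, rank, d.isoformat(), code))
    return pd.DataFrame(rows, columns=["patient_id", "rank", "date", "code"])
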