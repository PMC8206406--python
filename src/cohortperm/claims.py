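"""Claims-data substrate: domain types, delimited readers/writers, code
mapping, enrollment windowing and fact counting.

The on-disk layout is three UTF-8, comma-delimited tables with header rows and
ISO-8601 dates:

* ``members.csv``    — ``member_id,sex,birth_year``
* ``enrollment.csv`` — ``member_id,start,end`` (closed date intervals)
* ``events.csv``     — ``member_id,date,kind,system,code,value``

One event row is one claim line; each distinct claim counts as a separate
visit downstream.  ``value`` is populated only for lab results (units are
per-code: percent for HbA1c, mg/dL for glucose).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("diagnosis", "procedure", "pharmacy", "lab_result")
CODE_SYSTEMS = ("ICD9", "ICD10", "CPT", "NDC", "LOINC")
SEXES = ("male", "female")

MEMBER_COLUMNS = ("member_id", "sex", "birth_year")
ENROLLMENT_COLUMNS = ("member_id", "start", "end")
EVENT_COLUMNS = ("member_id", "date", "kind", "system", "code", "value")

#: Default grace period: enrollment spans separated by at most this many days
#: are treated as continuous (administrative gaps are common in claims feeds).
DEFAULT_MAX_GAP_DAYS = 31


class ClaimsSchemaError(ValueError):
    """A required column is missing or a field fails to parse."""


class CodeMapError(ValueError):
    """A code required by a mapping is absent under the strict policy."""


def window_length_days(years: int) -> int:
    """Calendar length of an observation window in days (closed interval).

    Four years spans 1461 days (one leap day included); the general rule is
    ``round(365.25 * years)`` so counts are reproducible across start dates.
    """
    return int(round(365.25 * years))


@dataclass
class MemberRecord:
    """A covered member: identity, demographics and enrollment spans."""

    member_id: str
    sex: str
    birth_year: int
    enrollment_spans: list[tuple[date, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        spans = sorted(self.enrollment_spans)
        for start, end in spans:
            if end < start:
                raise ValueError(f"enrollment span ends before it starts: {start}..{end}")
        for (_, prev_end), (nxt_start, _) in zip(spans, spans[1:]):
            if nxt_start <= prev_end:
                raise ValueError("enrollment spans overlap")
        self.enrollment_spans = spans


@dataclass(frozen=True)
class ObservationWindow:
    """The fixed-length phenotyping window at the start of qualifying coverage."""

    member_id: str
    start_date: date
    end_date: date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class ClaimsDataset:
    """Normalized member / enrollment / event tables."""

    members: pd.DataFrame
    enrollment: pd.DataFrame
    events: pd.DataFrame

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def validate(self) -> None:
        for name, frame, cols in (
            ("members", self.members, MEMBER_COLUMNS),
            ("enrollment", self.enrollment, ENROLLMENT_COLUMNS),
            ("events", self.events, EVENT_COLUMNS),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ClaimsSchemaError(f"{name} table missing columns: {missing}")
        bad_kind = set(self.events["kind"].unique()) - set(EVENT_KINDS)
        if bad_kind:
            raise ClaimsSchemaError(f"unknown event kinds: {sorted(bad_kind)}")
        bad_sys = set(self.events["system"].unique()) - set(CODE_SYSTEMS)
        if bad_sys:
            raise ClaimsSchemaError(f"unknown code systems: {sorted(bad_sys)}")
        has_value = self.events["value"].notna()
        if (has_value & (self.events["kind"] != "lab_result")).any():
            raise ClaimsSchemaError("value present on a non-lab_result event")
        if (self.events["code"].astype(str).str.len() == 0).any():
            raise ClaimsSchemaError("empty event code")

    def copy(self) -> "ClaimsDataset":
        return ClaimsDataset(
            self.members.copy(), self.enrollment.copy(), self.events.copy()
        )


def _parse_dates(frame: pd.DataFrame, table: str, columns: list[str]) -> pd.DataFrame:
    for col in columns:
        parsed = pd.to_datetime(frame[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            # +2: header row plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ClaimsSchemaError(
                f"{table}: unparseable date {frame[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )
        frame[col] = parsed
    return frame


def _load_table(path: Path, table: str, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"member_id": str, "code": str})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ClaimsSchemaError(f"{table} ({path}): missing required columns {missing}")
    extra = [c for c in frame.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", table, extra)
        frame = frame.drop(columns=extra)
    return frame[list(required)]


def read_claims(directory: str | Path) -> ClaimsDataset:
    """Read the three claims tables from ``directory`` into a dataset.

    Raises :class:`ClaimsSchemaError` naming the column if a required column
    is absent, or naming the line if a date fails to parse.  Unknown columns
    are dropped with a logged warning.
    """
    directory = Path(directory)
    members = _load_table(directory / "members.csv", "members", MEMBER_COLUMNS)
    enrollment = _load_table(directory / "enrollment.csv", "enrollment", ENROLLMENT_COLUMNS)
    events = _load_table(directory / "events.csv", "events", EVENT_COLUMNS)
    enrollment = _parse_dates(enrollment, "enrollment", ["start", "end"])
    events = _parse_dates(events, "events", ["date"])
    members["birth_year"] = members["birth_year"].astype(int)
    events["value"] = pd.to_numeric(events["value"], errors="raise")
    ds = ClaimsDataset(members, enrollment, events)
    if len(members):
        ds.validate()
    return ds


def write_claims(ds: ClaimsDataset, directory: str | Path) -> None:
    """Write the dataset as the canonical three CSV tables (ISO dates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds.members.to_csv(directory / "members.csv", index=False)
    enr = ds.enrollment.copy()
    for col in ("start", "end"):
        enr[col] = pd.to_datetime(enr[col]).dt.strftime("%Y-%m-%d")
    enr.to_csv(directory / "enrollment.csv", index=False)
    ev = ds.events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(directory / "events.csv", index=False)


@dataclass
class CodeMap:
    """A many-to-one code translation (e.g. ICD-10-CM to ICD-9-CM)."""

    source_system: str
    target_system: str
    entries: dict[str, str]

    @classmethod
    def from_csv(cls, path: str | Path, source_system: str = "ICD10",
                 target_system: str = "ICD9") -> "CodeMap":
        frame = pd.read_csv(path, dtype=str)
        if frame.shape[1] < 2:
            raise ClaimsSchemaError(f"code map {path} needs two columns (source,target)")
        src, tgt = frame.columns[:2]
        return cls(source_system, target_system, dict(zip(frame[src], frame[tgt])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"source": list(self.entries), "target": list(self.entries.values())}
        ).to_csv(path, index=False)


def apply_code_map(ds: ClaimsDataset, code_map: CodeMap, policy: str = "strict") -> ClaimsDataset:
    """Translate all events in ``code_map.source_system`` to the target system.

    ``policy="strict"`` raises :class:`CodeMapError` listing any unmapped
    source codes; ``policy="drop"`` drops such events with a logged warning.
    Idempotent: once no source-system events remain, the dataset is returned
    unchanged.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    out = ds.copy()
    mask = out.events["system"] == code_map.source_system
    if not mask.any():
        return out
    codes = out.events.loc[mask, "code"]
    unmapped = sorted(set(codes) - set(code_map.entries))
    if unmapped:
        if policy == "strict":
            raise CodeMapError(
                f"unmapped {code_map.source_system} codes: {unmapped}"
            )
        logger.warning("dropping %d events with unmapped codes %s",
                       int(codes.isin(unmapped).sum()), unmapped)
        drop = mask & out.events["code"].isin(unmapped)
        out.events = out.events.loc[~drop].reset_index(drop=True)
        mask = out.events["system"] == code_map.source_system
        codes = out.events.loc[mask, "code"]
    out.events.loc[mask, "code"] = codes.map(code_map.entries)
    out.events.loc[mask, "system"] = code_map.target_system
    return out


def merge_spans(spans: list[tuple[date, date]],
                max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> list[tuple[date, date]]:
    """Coalesce sorted enrollment spans separated by administrative gaps."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for start, end in spans[1:]:
        prev_start, prev_end = merged[-1]
        if (start - prev_end).days - 1 <= max_gap_days:
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def qualifying_window(member: MemberRecord, years: int = 4,
                      max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> ObservationWindow | None:
    """First fixed-length observation window inside continuous coverage.

    Returns the window starting on the first day of the earliest (merged)
    enrollment span of at least ``years`` length, or ``None`` if the member
    never accrues that much continuous coverage.  Ineligibility is a
    ``None`` return, not an error.
    """
    n_days = window_length_days(years)
    for start, end in merge_spans(member.enrollment_spans, max_gap_days):
        if (end - start).days + 1 >= n_days:
            return ObservationWindow(member.member_id, start, start + timedelta(days=n_days - 1))
    return None


def qualifying_windows(enrollment: pd.DataFrame, years: int = 4,
                       max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> pd.DataFrame:
    """Vectorized :func:`qualifying_window` over an enrollment table.

    Returns a frame ``member_id,start,end`` with one row per eligible member.
    """
    n_days = window_length_days(years)
    enr = enrollment.sort_values(["member_id", "start"]).reset_index(drop=True)
    start = pd.to_datetime(enr["start"])
    end = pd.to_datetime(enr["end"])
    same = enr["member_id"].eq(enr["member_id"].shift())
    gap = (start - end.shift()).dt.days - 1
    new_block = ~(same & (gap <= max_gap_days))
    block = new_block.cumsum()
    grouped = pd.DataFrame({
        "member_id": enr["member_id"], "block": block, "start": start, "end": end,
    }).groupby("block", sort=True).agg(
        member_id=("member_id", "first"), start=("start", "min"), end=("end", "max"),
    )
    long_enough = (grouped["end"] - grouped["start"]).dt.days + 1 >= n_days
    eligible = grouped.loc[long_enough].groupby("member_id", sort=True).first().reset_index()
    eligible["end"] = eligible["start"] + pd.Timedelta(days=n_days - 1)
    return eligible[["member_id", "start", "end"]]


def facts_per_year(ds: ClaimsDataset, window: ObservationWindow, years: int = 4) -> float:
    """Diagnosis codes recorded per year inside the observation window."""
    ev = ds.events
    start = pd.Timestamp(window.start_date)
    end = pd.Timestamp(window.end_date)
    inside = (
        (ev["member_id"] == window.member_id)
        & (ev["kind"] == "diagnosis")
        & (ev["date"] >= start)
        & (ev["date"] <= end)
    )
    return float(inside.sum()) / years


def facts_per_year_table(events: pd.DataFrame, windows: pd.DataFrame,
                         years: int = 4) -> pd.Series:
    """Per-member diagnosis-code rate over each member's window (vectorized).

    ``windows`` is the frame produced by :func:`qualifying_windows`; the
    result is indexed by member_id and includes zero rates for members with
    no in-window diagnoses.
    """
    dx = events.loc[events["kind"] == "diagnosis", ["member_id", "date"]]
    merged = dx.merge(windows, on="member_id", how="inner")
    inside = (merged["date"] >= merged["start"]) & (merged["date"] <= merged["end"])
    counts = merged.loc[inside].groupby("member_id").size()
    rates = counts.reindex(windows["member_id"], fill_value=0) / years
    rates.name = "facts_per_year"
    return rates.astype(float)
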