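"""Canonical event-log data model, validation, readers/writers and fixtures.

The atom of the pipeline is the :class:`PumpEvent`: one timestamped record
from an infusion pump's event log (an infusion start, an alarm, a restart
after an alarm, or an infusion stop).  Event logs travel as CSV or JSON-lines
files with ISO-8601 timestamps; in memory, timestamps are seconds since a
fixed epoch on a 0.25 s grid, the granularity at which pump firmware stamps
events.

This module also ships the published per-care-area alarm/infusion count
tables as an in-repo fixture (:func:`load_fixture_tables`): raw counts only,
never derived percentages or ratios — those are recomputed by
:mod:`infuselog.metrics`.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("infuselog")

#: Origin for the internal seconds-since-epoch timescale.
EPOCH = datetime(2017, 1, 1, tzinfo=timezone.utc)

#: Timestamp grid, in seconds.
TICK = 0.25


class SchemaError(ValueError):
    """A file or record does not conform to the event-log schema."""


class PumpModel(str, Enum):
    """Device class: large-volume (peristaltic) pump or syringe pump."""

    LVP = "LVP"
    SP = "SP"


class EventKind(str, Enum):
    INFUSION_START = "INFUSION_START"
    ALARM = "ALARM"
    RESTART = "RESTART"
    INFUSION_STOP = "INFUSION_STOP"


class AlarmType(str, Enum):
    """The twelve alarm states mined from the pump logs."""

    FLOW_ERROR = "FLOW_ERROR"                      # drip-counter flow error
    AIR_ACCUMULATION = "AIR_ACCUMULATION"          # air-in-line accumulation exceeded
    AIR_SINGLE_BUBBLE = "AIR_SINGLE_BUBBLE"        # air-in-line single bubble exceeded
    CALLBACK = "CALLBACK"                          # low-priority reminder (pump on hold)
    DOOR_OPEN = "DOOR_OPEN"                        # door open while infusing
    DRIVE_ENGAGE_FAILURE = "DRIVE_ENGAGE_FAILURE"
    END_OF_INFUSION = "END_OF_INFUSION"
    NEAR_END_OF_INFUSION = "NEAR_END_OF_INFUSION"
    OCCLUSION_DOWNSTREAM = "OCCLUSION_DOWNSTREAM"  # pump-to-patient blockage
    OCCLUSION_UPSTREAM = "OCCLUSION_UPSTREAM"      # container-to-pump blockage
    SYRINGE_DISENGAGED = "SYRINGE_DISENGAGED"
    END_OF_SYRINGE = "END_OF_SYRINGE"


class Priority(str, Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"
    NORMAL = "NORMAL"


class Beacon(str, Enum):
    RED = "RED"
    AMBER = "AMBER"
    GREEN = "GREEN"


class Tone(str, Enum):
    RAPID_HIGH = "RAPID_HIGH"
    RAPID_LOW = "RAPID_LOW"
    SLOW_LOW = "SLOW_LOW"
    NIL = "NIL"


#: The pumps' priority scheme: priority fixes beacon colour and alarm tone.
PRIORITY_SCHEME: Mapping[Priority, tuple[Beacon, Tone]] = {
    Priority.HIGH: (Beacon.RED, Tone.RAPID_HIGH),
    Priority.MEDIUM: (Beacon.AMBER, Tone.RAPID_LOW),
    Priority.LOW: (Beacon.AMBER, Tone.SLOW_LOW),
    Priority.NORMAL: (Beacon.GREEN, Tone.NIL),
}

# Per-alarm priority assignment supplied by this package (infusion-stopping
# states high, advisory states lower); the published scheme defines only the
# priority -> beacon/tone pairing, not the per-alarm mapping.
ALARM_PRIORITY: Mapping[AlarmType, Priority] = {
    AlarmType.FLOW_ERROR: Priority.HIGH,
    AlarmType.AIR_ACCUMULATION: Priority.HIGH,
    AlarmType.AIR_SINGLE_BUBBLE: Priority.HIGH,
    AlarmType.CALLBACK: Priority.LOW,
    AlarmType.DOOR_OPEN: Priority.MEDIUM,
    AlarmType.DRIVE_ENGAGE_FAILURE: Priority.HIGH,
    AlarmType.END_OF_INFUSION: Priority.HIGH,
    AlarmType.NEAR_END_OF_INFUSION: Priority.MEDIUM,
    AlarmType.OCCLUSION_DOWNSTREAM: Priority.HIGH,
    AlarmType.OCCLUSION_UPSTREAM: Priority.HIGH,
    AlarmType.SYRINGE_DISENGAGED: Priority.HIGH,
    AlarmType.END_OF_SYRINGE: Priority.HIGH,
}


def notification_for(alarm_type: AlarmType) -> tuple[Priority, Beacon, Tone]:
    """Return (priority, beacon colour, tone) for an alarm type."""
    prio = ALARM_PRIORITY[alarm_type]
    beacon, tone = PRIORITY_SCHEME[prio]
    return prio, beacon, tone


def quantize(t: float) -> float:
    """Snap a time in seconds to the 0.25 s event-log grid (half-up)."""
    return math.floor(t / TICK + 0.5) * TICK


@dataclass(slots=True)
class PumpEvent:
    """One timestamped pump event-log record."""

    pump_id: str
    pump_model: PumpModel
    timestamp: float               # seconds since EPOCH, 0.25 s grid
    event_kind: EventKind
    alarm_type: AlarmType | None = None
    profile_text: str = ""         # free-text care-area / profile name
    drug_text: str | None = None   # free-text drug name; None when unknown
    in_library: bool = False       # infusion programmed from the drug library

    def validate(self) -> None:
        if self.timestamp < 0:
            raise SchemaError(f"negative timestamp {self.timestamp!r}")
        if (self.alarm_type is not None) != (self.event_kind is EventKind.ALARM):
            raise SchemaError(
                "alarm_type must be present exactly when event_kind is ALARM "
                f"(got kind={self.event_kind.value}, alarm_type={self.alarm_type})"
            )


CSV_COLUMNS = (
    "pump_id",
    "pump_model",
    "timestamp",
    "event_kind",
    "alarm_type",
    "profile_text",
    "drug_text",
    "in_library",
)


def format_timestamp(t: float) -> str:
    """Internal seconds -> ISO-8601 UTC string with millisecond precision."""
    return (EPOCH + timedelta(seconds=t)).isoformat(timespec="milliseconds")


def parse_timestamp(text: str) -> float:
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return (dt - EPOCH).total_seconds()


def _event_to_record(ev: PumpEvent) -> dict[str, object]:
    return {
        "pump_id": ev.pump_id,
        "pump_model": ev.pump_model.value,
        "timestamp": format_timestamp(ev.timestamp),
        "event_kind": ev.event_kind.value,
        "alarm_type": ev.alarm_type.value if ev.alarm_type else None,
        "profile_text": ev.profile_text,
        "drug_text": ev.drug_text,
        "in_library": ev.in_library,
    }


def _event_from_record(rec: Mapping[str, object]) -> PumpEvent:
    def _opt(v: object) -> str | None:
        if v is None:
            return None
        s = str(v)
        return s if s != "" else None

    alarm_raw = _opt(rec.get("alarm_type"))
    in_lib_raw = rec.get("in_library")
    if isinstance(in_lib_raw, bool):
        in_library = in_lib_raw
    else:
        s = str(in_lib_raw or "").strip().lower()
        if s not in {"true", "false"}:
            raise SchemaError(f"in_library must be true/false, got {in_lib_raw!r}")
        in_library = s == "true"
    ev = PumpEvent(
        pump_id=str(rec["pump_id"]),
        pump_model=PumpModel(str(rec["pump_model"])),
        timestamp=parse_timestamp(str(rec["timestamp"])),
        event_kind=EventKind(str(rec["event_kind"])),
        alarm_type=AlarmType(alarm_raw) if alarm_raw else None,
        profile_text=str(rec.get("profile_text") or ""),
        drug_text=_opt(rec.get("drug_text")),
        in_library=in_library,
    )
    ev.validate()
    return ev


@dataclass
class ReadReport:
    """Per-file parse diagnostics from :func:`read_event_log`."""

    n_rows: int = 0
    bad_rows: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)
    non_monotone_pumps: list[str] = field(default_factory=list)


def read_event_log(
    path: str | Path,
    dialect: str = "csv",
    *,
    return_report: bool = False,
):
    """Read an event log, returning events sorted by (pump_id, timestamp).

    Unparseable rows are reported with their line numbers (warning log and
    :class:`ReadReport`) and skipped; a missing required column raises
    :class:`SchemaError`.  Non-monotone timestamps within a pump produce a
    warning only, since raw logs may interleave channels.
    """
    path = Path(path)
    events: list[PumpEvent] = []
    report = ReadReport()

    if dialect == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in CSV_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"{path}: missing required column(s) {missing}")
            for lineno, row in enumerate(reader, start=2):
                report.n_rows += 1
                try:
                    events.append(_event_from_record(row))
                except (SchemaError, ValueError, KeyError) as exc:
                    report.bad_rows.append((lineno, str(exc)))
                    logger.warning("%s:%d: unparseable row: %s", path, lineno, exc)
    elif dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                report.n_rows += 1
                try:
                    rec = json.loads(line)
                    missing = [c for c in CSV_COLUMNS if c not in rec]
                    if missing:
                        raise SchemaError(f"missing key(s) {missing}")
                    events.append(_event_from_record(rec))
                except (SchemaError, ValueError, KeyError) as exc:
                    report.bad_rows.append((lineno, str(exc)))
                    logger.warning("%s:%d: unparseable row: %s", path, lineno, exc)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    # warn on per-pump timestamp regressions in file order, then sort
    last: dict[str, float] = {}
    for ev in events:
        if ev.pump_id in last and ev.timestamp < last[ev.pump_id]:
            if ev.pump_id not in report.non_monotone_pumps:
                report.non_monotone_pumps.append(ev.pump_id)
                logger.warning(
                    "%s: non-monotone timestamps for pump %s", path, ev.pump_id
                )
        last[ev.pump_id] = ev.timestamp
    events.sort(key=lambda e: (e.pump_id, e.timestamp))

    if return_report:
        return events, report
    return events


def write_event_log(
    events: Iterable[PumpEvent], path: str | Path, dialect: str = "csv"
) -> Path:
    """Write events to ``path``; absent fields become empty/null, never "None"."""
    path = Path(path)
    events = list(events)
    for ev in events:
        ev.validate()
    if dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for ev in events:
                rec = _event_to_record(ev)
                rec["in_library"] = "true" if rec["in_library"] else "false"
                rec = {k: ("" if v is None else v) for k, v in rec.items()}
                writer.writerow(rec)
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for ev in events:
                fh.write(json.dumps(_event_to_record(ev), sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# --------------------------------------------------------------------------
# Published count-table fixtures


class CountRow(Mapping[str, int]):
    """Read-only metric -> count mapping with attribute access.

    A metric that was printed as N/A for this care area is *absent*, not zero:
    attribute access raises ``AttributeError`` and ``get`` returns ``None``.
    """

    def __init__(self, counts: Mapping[str, int]):
        self._counts = dict(counts)

    def __getitem__(self, key: str) -> int:
        return self._counts[key]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __getattr__(self, name: str) -> int:
        try:
            return self._counts[name]
        except KeyError:
            raise AttributeError(
                f"metric {name!r} is absent (printed N/A) for this row"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountRow({self._counts!r})"


class _Table5:
    """Per-drug CSHL count rows, addressable by canonical name or short code."""

    _ALIASES = {
        "DOB": "DOBUTAMINE",
        "DA": "DOPAMINE",
        "AD": "ADRENALINE",
        "NAD": "NORADRENALINE",
        "TOTAL": "FOUR_DRUG_TOTAL",
    }

    def __init__(self, rows: Mapping[str, CountRow]):
        self._rows = dict(rows)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(k for k in self._rows if k != "FOUR_DRUG_TOTAL")

    def __getattr__(self, name: str) -> CountRow:
        key = self._ALIASES.get(name, name)
        try:
            return self._rows[key]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> CountRow:
        return self._rows[self._ALIASES.get(name, name)]


@dataclass(frozen=True)
class CountTableFixture:
    """Raw cells of the published infusion/alarm count tables.

    ``area_counts`` holds, per care area (NICU, GICU, CICU, PICU, the printed
    critical-care ``ALL_CRITICAL_CARE`` column and ``WHOLE_HOSPITAL``), the
    total infusion starts, the printed total alarms, and the count for each
    alarm type that was reported for that area.  ``cshl_counts`` holds the
    NICU critical-short-half-life breakdown per canonical drug.
    """

    area_counts: Mapping[str, CountRow]
    cshl_counts: Mapping[str, CountRow]

    CRITICAL_AREAS = ("NICU", "GICU", "CICU", "PICU")

    def area(self, name: str) -> CountRow:
        return self.area_counts[name]

    @property
    def table5(self) -> _Table5:
        return _Table5(self.cshl_counts)

    def __getattr__(self, name: str) -> CountRow:
        try:
            return self.area_counts[name]
        except KeyError:
            raise AttributeError(name) from None


def _read_count_csv(name: str, key_col: str) -> dict[str, CountRow]:
    text = resources.files("infuselog.data").joinpath(name).read_text(encoding="utf-8")
    rows: dict[str, dict[str, int]] = {}
    for rec in csv.DictReader(io.StringIO(text)):
        rows.setdefault(rec[key_col], {})[rec["metric"]] = int(rec["count"])
    return {k: CountRow(v) for k, v in rows.items()}


def load_fixture_tables() -> CountTableFixture:
    """Load the embedded published count tables (raw counts only)."""
    return CountTableFixture(
        area_counts=_read_count_csv("alarm_counts.csv", "care_area"),
        cshl_counts=_read_count_csv("cshl_counts.csv", "drug"),
    )
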