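"""Data model and I/O for contactless home-sensor streams.

Three stream types are supported, mirroring a typical zero-interaction
home-monitoring deployment for older adults:

* room-level passive-infrared (PIR) activity epochs on a strict 2-s grid
  (0.5 Hz on/off states),
* reed-switch door events (entrance door and fridge door, open/close),
* an under-mattress bed sensor emitting nightly records with heart rate,
  respiration rate, in-bed activity and sleep stages on a 4-s grid
  (0.25 Hz), plus toss-and-turn and bed-exit events.

All timestamps are timezone-aware; daily windows run local midnight to
midnight (23/25-h days across DST changes are accepted) and nights are
anchored noon-to-noon to the evening's calendar date, the standard
actigraphy convention. All windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PIR_PERIOD_S = 2.0  # PIR epoch length (0.5 Hz)
BED_PERIOD_S = 4.0  # bed-sensor channel sampling (0.25 Hz)


class ParseError(ValueError):
    """Raised on malformed stream files; names file, line and field."""

    def __init__(self, file: str, line: int | None, field: str, message: str):
        self.file, self.line, self.field = str(file), line, field
        where = f"{file}" + (f":{line}" if line is not None else "")
        super().__init__(f"{where} [{field}]: {message}")


class ValidationError(ValueError):
    """Raised when in-memory sensor objects violate their invariants."""


class Room(str, enum.Enum):
    ENTRANCE = "entrance"
    BATHROOM = "bathroom"
    BEDROOM = "bedroom"
    LIVINGROOM = "livingroom"
    KITCHEN = "kitchen"
    OTHER = "other"


#: Rooms a deployment must cover; `other` aggregates any extra sensors.
ESSENTIAL_ROOMS = (
    Room.ENTRANCE,
    Room.BATHROOM,
    Room.BEDROOM,
    Room.LIVINGROOM,
    Room.KITCHEN,
)

DOORS = ("entrance", "fridge")

#: Sleep-stage integer codes used in the uniform stage channel.
STAGE_CODES = {"awake": 0, "rem": 1, "deep": 2, "light": 3, "missing": -1}
STAGE_NAMES = {v: k for k, v in STAGE_CODES.items()}
STAGE_AWAKE, STAGE_REM, STAGE_DEEP, STAGE_LIGHT, STAGE_MISSING = 0, 1, 2, 3, -1


@dataclass
class PirEpochSeries:
    """Uniform 2-s on/off activity epochs for one room.

    ``states`` holds the motion flag per epoch; ``observed`` marks epochs the
    sensor actually reported (device outages leave holes in real recordings,
    so coverage must be representable in memory even though the on-disk
    format simply omits unobserved epochs).
    """

    room: Room
    start: pd.Timestamp
    states: np.ndarray
    observed: np.ndarray | None = None
    period: float = PIR_PERIOD_S

    def __post_init__(self):
        self.room = Room(self.room)
        if self.start.tzinfo is None:
            raise ValidationError("PIR series start must be timezone-aware")
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.size == 0:
            raise ValidationError("PIR series must be non-empty")
        if self.observed is None:
            self.observed = np.ones(self.states.size, dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.size != self.states.size:
                raise ValidationError("observed mask length mismatch")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.period * self.states.size)

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class DoorEvent:
    door: str
    time: pd.Timestamp
    state: str

    def __post_init__(self):
        if self.door not in DOORS:
            raise ValidationError(f"unknown door {self.door!r}")
        if self.state not in ("open", "close"):
            raise ValidationError(f"unknown door state {self.state!r}")
        if self.time.tzinfo is None:
            raise ValidationError("door event time must be timezone-aware")


@dataclass
class NightRecord:
    """One in-bed period with channels on a shared 4-s grid.

    ``hr``/``rr``/``activity`` are float arrays with NaN for missing samples;
    ``stage`` uses :data:`STAGE_CODES` (−1 for missing).
    """

    start: pd.Timestamp
    end: pd.Timestamp
    hr: np.ndarray
    rr: np.ndarray
    activity: np.ndarray
    stage: np.ndarray
    toss_turn_times: list = field(default_factory=list)
    bed_exit_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("night end must be after start")
        n = int(round((self.end - self.start).total_seconds() / BED_PERIOD_S))
        self.hr = np.asarray(self.hr, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.stage = np.asarray(self.stage, dtype=np.int8)
        for name in ("hr", "rr", "activity", "stage"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValidationError(
                    f"{name} length {arr.size} != grid length {n}"
                )
        for name in ("hr", "rr"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise ValidationError(f"{name} must be strictly positive")
        if np.any(self.activity[np.isfinite(self.activity)] < 0):
            raise ValidationError("activity must be non-negative")
        prev_end = None
        for s, e in sorted(self.bed_exit_intervals, key=lambda x: x[0]):
            if s < self.start or e > self.end:
                raise ValidationError("bed exit outside in-bed window")
            if prev_end is not None and s < prev_end:
                raise ValidationError("bed exits overlap")
            prev_end = e

    @property
    def n_samples(self) -> int:
        return self.stage.size

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def grid_times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_samples) * BED_PERIOD_S, unit="s"
        )


@dataclass
class HomeRecording:
    """One participant's full multi-stream record."""

    participant_id: str
    pir: dict  # Room -> PirEpochSeries
    doors: list  # DoorEvent list, time-ordered
    nights: list  # NightRecord list, disjoint, time-ordered
    timezone: str = "UTC"

    def __post_init__(self):
        self.pir = {Room(k): v for k, v in self.pir.items()}
        self.doors = sorted(self.doors, key=lambda e: (e.time, e.door))
        self.nights = sorted(self.nights, key=lambda n: n.start)
        for a, b in zip(self.nights, self.nights[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"nights overlap: {a.end} > {b.start}"
                )

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp] | None:
        """Half-open [first, last) observation window over all streams."""
        starts, ends = [], []
        for s in self.pir.values():
            starts.append(s.start)
            ends.append(s.end)
        for e in self.doors:
            starts.append(e.time)
            ends.append(e.time + pd.Timedelta(seconds=1))
        for n in self.nights:
            starts.append(n.start)
            ends.append(n.end)
        if not starts:
            return None
        return min(starts), max(ends)

    def is_empty(self) -> bool:
        return self.span() is None


@dataclass(frozen=True)
class DayWindow:
    date: Date
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def n_pir_epochs(self) -> int:
        return int(round((self.end - self.start).total_seconds() / PIR_PERIOD_S))


@dataclass(frozen=True)
class ValidityCriteria:
    """Day-inclusion rules per sensor system.

    Defaults: a day counts for the PIR/door system when the union of the five
    essential rooms' PIR coverage spans at least ``min_pir_coverage_hours``
    and the union activity signal changed state at least once; a day counts
    for the bed system when its anchored night exists and carries at least
    ``min_night_stage_hours`` of non-missing sleep-stage samples. Both are
    configurable because deployments differ in sensor reliability.
    """

    min_pir_coverage_hours: float = 20.0
    min_night_stage_hours: float = 3.0


# ---------------------------------------------------------------------------
# Reading / writing


def _parse_ts(raw: str, file: str, line: int, field_name: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(raw)
    except Exception:
        raise ParseError(file, line, field_name, f"bad timestamp {raw!r}") from None
    if ts.tzinfo is None:
        raise ParseError(file, line, field_name, f"timestamp {raw!r} lacks timezone")
    return ts


def normalize_door_events(events: Sequence[DoorEvent]) -> tuple[list, int]:
    """Deduplicate and state-normalize a door stream.

    Real reed switches drop events; downstream outing detection needs strict
    open/close alternation per door. Exact duplicate rows are removed and a
    repeated state triggers insertion of the complementary event at the
    midpoint of the offending interval (logged). Returns the normalized,
    time-sorted list and the number of synthetic insertions.
    """
    inserted = 0
    out: list[DoorEvent] = []
    for door in DOORS:
        evs = sorted(
            {(e.time, e.state) for e in events if e.door == door}
        )
        prev: tuple | None = None
        for t, s in evs:
            if prev is not None and prev[1] == s:
                mid = prev[0] + (t - prev[0]) / 2
                comp = "close" if s == "open" else "open"
                out.append(DoorEvent(door, mid, comp))
                inserted += 1
                logger.warning(
                    "door %s: consecutive %r events at %s and %s; inserted "
                    "synthetic %r at midpoint %s", door, s, prev[0], t, comp, mid
                )
            out.append(DoorEvent(door, t, s))
            prev = (t, s)
    out.sort(key=lambda e: (e.time, e.door))
    return out, inserted


def _read_pir_csv(path, timezone: str) -> dict:
    rooms: dict[Room, list] = {}
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        rle = "timestamp_start" in header
        idx = {name: i for i, name in enumerate(header)}
        for col in ("participant_id", "room", "state"):
            if col not in idx:
                raise ParseError(path, 1, col, "missing column")
        if not rle and "timestamp" not in idx:
            raise ParseError(path, 1, "timestamp", "missing column")
        for ln, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != len(header):
                raise ParseError(path, ln, "row", f"expected {len(header)} fields")
            try:
                room = Room(parts[idx["room"]])
            except ValueError:
                raise ParseError(
                    path, ln, "room", f"unknown room {parts[idx['room']]!r}"
                ) from None
            state = parts[idx["state"]]
            if state not in ("0", "1"):
                raise ParseError(path, ln, "state", f"state must be 0/1, got {state!r}")
            if rle:
                t0 = _parse_ts(parts[idx["timestamp_start"]], path, ln, "timestamp_start")
                t1 = _parse_ts(parts[idx["timestamp_end"]], path, ln, "timestamp_end")
                if t1 <= t0:
                    raise ParseError(path, ln, "timestamp_end", "end before start")
            else:
                t0 = _parse_ts(parts[idx["timestamp"]], path, ln, "timestamp")
                t1 = t0 + pd.Timedelta(seconds=PIR_PERIOD_S)
            runs = rooms.setdefault(room, [])
            if runs and t0 < runs[-1][1]:
                raise ParseError(path, ln, "timestamp", "non-monotone timestamps")
            runs.append((t0, t1, state == "1"))
    series = {}
    for room, runs in rooms.items():
        start, end = runs[0][0], runs[-1][1]
        n = int(round((end - start).total_seconds() / PIR_PERIOD_S))
        states = np.zeros(n, dtype=bool)
        observed = np.zeros(n, dtype=bool)
        for t0, t1, st in runs:
            i0 = int(round((t0 - start).total_seconds() / PIR_PERIOD_S))
            i1 = int(round((t1 - start).total_seconds() / PIR_PERIOD_S))
            states[i0:i1] = st
            observed[i0:i1] = True
        series[room] = PirEpochSeries(
            room=room, start=start.tz_convert(timezone), states=states,
            observed=observed,
        )
    return series


def _read_door_csv(path, timezone: str) -> list:
    events = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("participant_id", "door", "timestamp", "event"):
            if col not in idx:
                raise ParseError(path, 1, col, "missing column")
        for ln, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            door = parts[idx["door"]]
            if door not in DOORS:
                raise ParseError(path, ln, "door", f"unknown door {door!r}")
            ev = parts[idx["event"]]
            if ev not in ("open", "close"):
                raise ParseError(path, ln, "event", f"unknown event {ev!r}")
            t = _parse_ts(parts[idx["timestamp"]], path, ln, "timestamp")
            events.append(DoorEvent(door, t.tz_convert(timezone), ev))
    return events


def _read_bed_jsonl(path, timezone: str) -> list:
    nights = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as e:
                raise ParseError(path, ln, "json", str(e)) from None
            for key in ("start", "end", "hr", "rr", "activity", "stage"):
                if key not in rec:
                    raise ParseError(path, ln, key, "missing field")
            start = _parse_ts(rec["start"], path, ln, "start").tz_convert(timezone)
            end = _parse_ts(rec["end"], path, ln, "end").tz_convert(timezone)
            stage_raw = rec["stage"]
            stage = np.full(len(stage_raw), STAGE_MISSING, dtype=np.int8)
            for i, s in enumerate(stage_raw):
                if s is None:
                    continue
                if s not in STAGE_CODES:
                    raise ParseError(path, ln, "stage", f"unknown stage {s!r}")
                stage[i] = STAGE_CODES[s]

            def _chan(key):
                return np.array(
                    [np.nan if v is None else float(v) for v in rec[key]],
                    dtype=float,
                )

            try:
                nights.append(
                    NightRecord(
                        start=start,
                        end=end,
                        hr=_chan("hr"),
                        rr=_chan("rr"),
                        activity=_chan("activity"),
                        stage=stage,
                        toss_turn_times=[
                            _parse_ts(t, path, ln, "toss_turns").tz_convert(timezone)
                            for t in rec.get("toss_turns", [])
                        ],
                        bed_exit_intervals=[
                            (
                                _parse_ts(s, path, ln, "bed_exits").tz_convert(timezone),
                                _parse_ts(e, path, ln, "bed_exits").tz_convert(timezone),
                            )
                            for s, e in rec.get("bed_exits", [])
                        ],
                    )
                )
            except ValidationError as e:
                raise ParseError(path, ln, "night", str(e)) from None
    return nights


def read_recording(
    pir_path,
    door_path,
    bed_path,
    participant_id: str,
    timezone: str = "UTC",
) -> HomeRecording:
    """Read and validate one participant's three stream files.

    Malformed rows raise :class:`ParseError` naming file, line and field.
    Door events are deduplicated and state-normalized (synthetic
    complementary events inserted at interval midpoints, logged).
    """
    pir = _read_pir_csv(pir_path, timezone)
    doors, _ = normalize_door_events(_read_door_csv(door_path, timezone))
    nights = _read_bed_jsonl(bed_path, timezone)
    return HomeRecording(
        participant_id=participant_id, pir=pir, doors=doors, nights=nights,
        timezone=timezone,
    )


def _pir_runs(series: PirEpochSeries) -> Iterable[tuple]:
    """Yield (start, end, state) runs over observed epochs only."""
    obs = series.observed
    st = series.states
    n = st.size
    i = 0
    while i < n:
        if not obs[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and obs[j + 1] and st[j + 1] == st[i]:
            j += 1
        t0 = series.start + pd.Timedelta(seconds=i * series.period)
        t1 = series.start + pd.Timedelta(seconds=(j + 1) * series.period)
        yield t0, t1, st[i]
        i = j + 1


def _iso(ts: pd.Timestamp) -> str:
    return ts.isoformat()


def write_recording(rec: HomeRecording, pir_path, door_path, bed_path) -> None:
    """Write a recording in canonical on-disk form (deterministic byte-wise)."""
    with open(pir_path, "w") as fh:
        fh.write("participant_id,room,timestamp_start,timestamp_end,state\n")
        for room in sorted(rec.pir, key=lambda r: r.value):
            for t0, t1, st in _pir_runs(rec.pir[room]):
                fh.write(
                    f"{rec.participant_id},{room.value},{_iso(t0)},{_iso(t1)},"
                    f"{int(st)}\n"
                )
    with open(door_path, "w") as fh:
        fh.write("participant_id,door,timestamp,event\n")
        for e in rec.doors:
            fh.write(f"{rec.participant_id},{e.door},{_iso(e.time)},{e.state}\n")
    with open(bed_path, "w") as fh:
        for night in rec.nights:
            def _num(arr):
                return [None if not np.isfinite(v) else round(float(v), 6) for v in arr]

            obj = {
                "participant_id": rec.participant_id,
                "start": _iso(night.start),
                "end": _iso(night.end),
                "hr": _num(night.hr),
                "rr": _num(night.rr),
                "activity": _num(night.activity),
                "stage": [
                    None if s == STAGE_MISSING else STAGE_NAMES[int(s)]
                    for s in night.stage
                ],
                "toss_turns": [_iso(t) for t in night.toss_turn_times],
                "bed_exits": [
                    [_iso(s), _iso(e)] for s, e in night.bed_exit_intervals
                ],
            }
            fh.write(json.dumps(obj, separators=(",", ":")) + "\n")


# ---------------------------------------------------------------------------
# Calendar windowing


def split_days(rec: HomeRecording) -> list:
    """Tile the recording span with local midnight-to-midnight windows.

    Windows are 24 h except across DST shifts (23/25 h). Every observation
    falls in exactly one window because windows are half-open.
    """
    span = rec.span()
    if span is None:
        return []
    t0 = span[0].tz_convert(rec.timezone)
    t1 = span[1].tz_convert(rec.timezone)
    days = []
    d = t0.date()
    last = (t1 - pd.Timedelta(nanoseconds=1)).date()  # span end is exclusive
    while d <= last:
        start = pd.Timestamp(d).tz_localize(rec.timezone)
        end = pd.Timestamp(d + timedelta(days=1)).tz_localize(rec.timezone)
        days.append(DayWindow(date=d, start=start, end=end))
        d = d + timedelta(days=1)
    return days


def assign_nights(rec: HomeRecording) -> dict:
    """Anchor each night to a calendar date, noon-to-noon.

    A night starting after local noon belongs to that date, otherwise to the
    previous date (the evening it began). When several nights anchor to one
    date, the longest is kept as the main night; shorter ones are naps and
    excluded. Returns ``{date: NightRecord}``.
    """
    by_date: dict[Date, NightRecord] = {}
    for night in rec.nights:
        local = night.start.tz_convert(rec.timezone)
        anchor = local.date()
        if local.hour < 12:
            anchor = anchor - timedelta(days=1)
        cur = by_date.get(anchor)
        if cur is None or night.duration_hours > cur.duration_hours:
            if cur is not None:
                logger.info(
                    "%s: night of %.1f h flagged as nap for %s",
                    rec.participant_id, cur.duration_hours, anchor,
                )
            by_date[anchor] = night
        else:
            logger.info(
                "%s: night of %.1f h flagged as nap for %s",
                rec.participant_id, night.duration_hours, anchor,
            )
    return by_date


def pir_day_grid(
    rec: HomeRecording, day: DayWindow, rooms: Sequence[Room] | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-room activity/observed arrays on the day's common 2-s grid.

    Returns ``(active, observed, room_order)`` where ``active`` and
    ``observed`` are (n_rooms, n_epochs) boolean arrays.
    """
    if rooms is None:
        rooms = [r for r in Room if r in rec.pir]
    n = day.n_pir_epochs
    active = np.zeros((len(rooms), n), dtype=bool)
    observed = np.zeros((len(rooms), n), dtype=bool)
    for k, room in enumerate(rooms):
        series = rec.pir.get(room)
        if series is None:
            continue
        off = (day.start - series.start).total_seconds() / series.period
        i0 = int(math.floor(off))
        src0, dst0 = max(i0, 0), max(-i0, 0)
        src1 = min(i0 + n, len(series))
        if src1 <= src0:
            continue
        m = src1 - src0
        active[k, dst0:dst0 + m] = series.states[src0:src1]
        observed[k, dst0:dst0 + m] = series.observed[src0:src1]
    return active, observed, list(rooms)


def day_validity(
    rec: HomeRecording,
    day: DayWindow,
    system: str,
    criteria: ValidityCriteria = ValidityCriteria(),
    nights_by_date: Mapping | None = None,
) -> bool:
    """Decide whether a day's data are usable for one sensor system."""
    if system == "pir_door":
        active, observed, _ = pir_day_grid(rec, day, rooms=ESSENTIAL_ROOMS)
        union_obs = observed.any(axis=0)
        coverage_h = union_obs.sum() * PIR_PERIOD_S / 3600.0
        if coverage_h < criteria.min_pir_coverage_hours:
            return False
        union_act = (active & observed).any(axis=0)[union_obs]
        return union_act.size > 1 and bool(np.any(union_act[1:] != union_act[:-1]))
    if system == "bed":
        if nights_by_date is None:
            nights_by_date = assign_nights(rec)
        night = nights_by_date.get(day.date)
        if night is None:
            return False
        good = np.count_nonzero(night.stage != STAGE_MISSING)
        return good * BED_PERIOD_S / 3600.0 >= criteria.min_night_stage_hours
    raise ValueError(f"unknown system {system!r}; expected 'pir_door' or 'bed'")
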