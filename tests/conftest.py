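"""Shared fixtures: small scripted recordings built in memory."""

from __future__ import annotations

from datetime import date as Date

import numpy as np
import pandas as pd
import pytest

from exhaust.sensor_io import (
    BED_PERIOD_S,
    PIR_PERIOD_S,
    STAGE_CODES,
    DoorEvent,
    HomeRecording,
    NightRecord,
    PirEpochSeries,
    Room,
)

TZ = "UTC"
DAY0 = pd.Timestamp("2021-03-01", tz=TZ)


def pir_series(room, active_spans_h, days=1, start=DAY0, tz=TZ):
    """Dense PIR series with activity in the given [start_h, end_h) spans."""
    n = int(days * 86400 / PIR_PERIOD_S)
    states = np.zeros(n, dtype=bool)
    for h0, h1 in active_spans_h:
        i0 = int(h0 * 3600 / PIR_PERIOD_S)
        i1 = int(h1 * 3600 / PIR_PERIOD_S)
        states[i0:i1] = True
    return PirEpochSeries(room=Room(room), start=start, states=states)


def make_night(start_h, duration_h, day=0, stage="light", hr=60.0, rr=14.0,
               activity=1.0, toss_turns=(), bed_exits=(), start=DAY0):
    """One night on the 4-s grid with constant or per-sample channels."""
    t0 = start + pd.Timedelta(hours=day * 24 + start_h)
    n = int(duration_h * 3600 / BED_PERIOD_S)
    end = t0 + pd.Timedelta(seconds=n * BED_PERIOD_S)

    def chan(v):
        return np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)

    if isinstance(stage, str):
        stage_arr = np.full(n, STAGE_CODES[stage], dtype=np.int8)
    else:
        stage_arr = np.asarray(stage, dtype=np.int8)
    tts = [t0 + pd.Timedelta(hours=h) for h in toss_turns]
    bes = [
        (t0 + pd.Timedelta(hours=a), t0 + pd.Timedelta(hours=b))
        for a, b in bed_exits
    ]
    return NightRecord(start=t0, end=end, hr=chan(hr), rr=chan(rr),
                       activity=chan(activity), stage=stage_arr,
                       toss_turn_times=tts, bed_exit_intervals=bes)


def full_coverage_pir(days=1, start=DAY0):
    """All five essential rooms observed all day, kitchen active 8–9 h."""
    return {
        Room(r): pir_series(r, [(8, 9)] if r == "kitchen" else [], days, start)
        for r in ("entrance", "bathroom", "bedroom", "livingroom", "kitchen")
    }


def door(door_name, hours, state, day=0, start=DAY0):
    return DoorEvent(
        door_name, start + pd.Timedelta(hours=day * 24 + hours), state
    )


@pytest.fixture
def simple_recording():
    """One full day: full PIR coverage, a few doors, one night."""
    doors = [
        door("entrance", 9.0, "open"), door("entrance", 9.004, "close"),
        door("entrance", 11.0, "open"), door("entrance", 11.004, "close"),
        door("fridge", 7.0, "open"), door("fridge", 7.005, "close"),
        door("fridge", 12.0, "open"), door("fridge", 12.005, "close"),
        door("fridge", 19.0, "open"), door("fridge", 19.005, "close"),
    ]
    night = make_night(start_h=22.0, duration_h=8.0)
    return HomeRecording(
        participant_id="t1",
        pir=full_coverage_pir(days=2),
        doors=doors,
        nights=[night],
        timezone=TZ,
    )
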