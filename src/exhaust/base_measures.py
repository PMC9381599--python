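"""Daily/nightly base measures extracted from the sensor streams.

The measure layer is organised as a registry of hypothesis-driven base
measures. Each daily or nightly measure yields one value per day (NaN when
the day is invalid or the quantity is undefined); per-segment measures
(cosinor rest–activity rhythm parameters) are computed from raw bi-weekly
data in the aggregation layer. The built-in registry covers the measure
families of interest in passive monitoring of older adults: room-level
activity, room transitions, outings, fridge use, door-event times of day,
sleep architecture, bed exits, toss-and-turns, in-bed activity, nocturnal
heart rate (including within-night dipping), respiration, spectral content
of the night channels, and circadian rhythmicity.

Time-of-day measures for door events are decimal hours in [0, 24). Sleep
onset/offset use a noon-anchored clock (hours since midnight, plus 24 h for
times after midnight) so that a 23:30 and a 00:30 onset are 1 h apart, not
23 h — essential for meaningful quantiles across a segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .sensor_io import (
    BED_PERIOD_S,
    ESSENTIAL_ROOMS,
    PIR_PERIOD_S,
    STAGE_AWAKE,
    STAGE_MISSING,
    DayWindow,
    HomeRecording,
    NightRecord,
    Room,
    ValidityCriteria,
    assign_nights,
    day_validity,
    pir_day_grid,
    split_days,
)

MISSING = float("nan")

#: Default spectral bands (Hz) applied to the nightly HR/RR/activity channels.
DEFAULT_BANDS = ((0.0, 0.01), (0.01, 0.04), (0.04, 0.125))
BAND_NAMES = ("low", "mid", "high")


@dataclass(frozen=True)
class BaseMeasureDef:
    """Declaration of one base measure in the registry."""

    measure_id: str
    source: str  # pir | door | bed
    granularity: str  # daily | nightly | per_segment
    unit: str
    description: str

    def __post_init__(self):
        if self.source not in ("pir", "door", "bed"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.granularity not in ("daily", "nightly", "per_segment"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


@dataclass
class CosinorFit:
    """24-h cosinor fit: rhythm-adjusted mean (MESOR), amplitude, peak time."""

    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period)
    r_squared: float


class DailyMeasureTable:
    """Per-day values of all registered daily/nightly base measures.

    Thin wrapper around a wide DataFrame (index = date, columns = measure
    ids, NaN = MISSING) keeping the participant identity attached.
    """

    def __init__(self, participant_id: str, frame: pd.DataFrame):
        self.participant_id = participant_id
        self.frame = frame

    @property
    def dates(self):
        return list(self.frame.index)

    def to_long(self) -> pd.DataFrame:
        long = self.frame.reset_index(names="date").melt(
            id_vars="date", var_name="measure_id", value_name="value"
        )
        long.insert(0, "participant_id", self.participant_id)
        return long


# ---------------------------------------------------------------------------
# Registry

_HYPOTHESES = {
    "total_activity": "Overall daily movement declines with frailty and depression.",
    "room_transition_count": "Fewer within-home transfers reflect reduced mobility.",
    "activity_fragmentation": "Fragmented activity bouts accompany cognitive decline.",
    "room_entropy": "Concentration of activity in fewer rooms narrows the life-space.",
    "outing_count": "Fewer outings indicate withdrawal and reduced life-space.",
    "outing_duration_total": "Shorter time outside tracks frailty and low mood.",
    "fridge_use_count": "Reduced fridge use flags nutritional-risk behaviour change.",
    "sleep_duration": "Longer, less consolidated sleep accompanies poor outcomes.",
    "sleep_efficiency": "Low efficiency marks disturbed sleep.",
    "waso": "Wake after sleep onset increases with depression and pain.",
    "bed_exit_count": "Nocturia-driven bed exits raise nocturnal fall risk.",
    "toss_turn_count": "Restlessness in bed reflects sleep quality.",
    "activity_in_bed": "Elevated in-bed movement marks restless sleep and fall risk.",
    "hr_dipping": "Blunted or erratic nocturnal heart-rate dipping accompanies "
                  "autonomic and cognitive decline.",
}


def _default_defs() -> list:
    defs: list[BaseMeasureDef] = []

    def add(mid, source, gran, unit, desc=None):
        defs.append(BaseMeasureDef(mid, source, gran, unit,
                                   desc or _HYPOTHESES.get(mid, "")))

    add("total_activity", "pir", "daily", "min")
    for room in ESSENTIAL_ROOMS:
        add(f"activity_{room.value}", "pir", "daily", "min",
            f"Daily PIR activity in the {room.value}.")
    add("room_transition_count", "pir", "daily", "count")
    add("activity_fragmentation", "pir", "daily", "1/min")
    add("room_entropy", "pir", "daily", "nat")

    add("outing_count", "door", "daily", "count")
    add("outing_duration_total", "door", "daily", "min")
    add("fridge_use_count", "door", "daily", "count")
    for door in ("entrance", "fridge"):
        for which in ("first", "middle", "last"):
            add(f"{door}_door_tod_{which}", "door", "daily", "h",
                f"Time of day of the {which} {door}-door event.")

    add("sleep_duration", "bed", "nightly", "h")
    add("time_in_bed", "bed", "nightly", "h", "Nightly in-bed duration.")
    add("sleep_onset_tod", "bed", "nightly", "h", "Noon-anchored sleep onset time.")
    add("sleep_offset_tod", "bed", "nightly", "h", "Noon-anchored final wake time.")
    add("sleep_efficiency", "bed", "nightly", "fraction")
    for st in ("rem", "deep", "light", "awake"):
        add(f"stage_frac_{st}", "bed", "nightly", "fraction",
            f"Fraction of the night scored {st}.")
    add("bed_exit_count", "bed", "nightly", "count")
    add("toss_turn_count", "bed", "nightly", "count")
    add("activity_in_bed", "bed", "nightly", "a.u.")
    add("waso", "bed", "nightly", "min")

    add("hr_mean", "bed", "nightly", "bpm", "Mean nocturnal heart rate.")
    add("hr_min", "bed", "nightly", "bpm", "Minimum nocturnal heart rate.")
    add("hr_max", "bed", "nightly", "bpm", "Maximum nocturnal heart rate.")
    add("hr_sd", "bed", "nightly", "bpm", "Nocturnal heart-rate variability (SD).")
    add("hr_dipping", "bed", "nightly", "fraction")
    add("rr_mean", "bed", "nightly", "brpm", "Mean nocturnal respiration rate.")
    add("rr_sd", "bed", "nightly", "brpm", "Respiration-rate variability (SD).")

    for ch in ("hr", "rr", "activity"):
        add(f"{ch}_total_power", "bed", "nightly", "a.u.",
            f"Total spectral power of the nightly {ch} channel.")
        for band in BAND_NAMES:
            add(f"{ch}_bandpower_{band}", "bed", "nightly", "fraction",
                f"Fraction of {ch} spectral power in the {band} band.")
        add(f"{ch}_spectral_entropy", "bed", "nightly", "fraction",
            f"Normalised spectral entropy of the nightly {ch} channel.")

    for mid, unit, desc in (
        ("cosinor_mesor", "min/bin", "Rhythm-adjusted mean of 24-h activity."),
        ("cosinor_amplitude", "min/bin", "Amplitude of the 24-h activity rhythm."),
        ("cosinor_acrophase", "h", "Peak time of the 24-h activity rhythm."),
        ("cosinor_rsquared", "fraction", "Strength of the 24-h rhythm (R^2)."),
    ):
        defs.append(BaseMeasureDef(mid, "pir", "per_segment", unit, desc))
    return defs


_REGISTRY: dict[str, BaseMeasureDef] = {d.measure_id: d for d in _default_defs()}


def registry() -> list:
    """The current base-measure registry (built-ins plus user additions)."""
    return list(_REGISTRY.values())


def register_measure(defn: BaseMeasureDef) -> None:
    """Register a user-supplied base measure; duplicate ids are rejected."""
    if defn.measure_id in _REGISTRY:
        raise ValueError(f"measure_id {defn.measure_id!r} already registered")
    _REGISTRY[defn.measure_id] = defn


def unregister_measure(measure_id: str) -> None:
    if measure_id not in _REGISTRY:
        raise KeyError(measure_id)
    del _REGISTRY[measure_id]


def registry_catalogue() -> list:
    """JSON-ready catalogue of the registry."""
    return [
        {
            "measure_id": d.measure_id,
            "source": d.source,
            "granularity": d.granularity,
            "unit": d.unit,
            "description": d.description,
        }
        for d in registry()
    ]


# ---------------------------------------------------------------------------
# PIR daily measures


def daily_activity_measures(
    rec: HomeRecording, day: DayWindow
) -> dict:
    """Room-level activity measures for one valid day.

    total_activity: minutes with motion in any room (union signal).
    activity_<room>: active minutes per essential room.
    room_transition_count: changes of the most-recently-active room.
    activity_fragmentation: active/inactive bout alternations of the union
    signal per active minute (duration-invariant restlessness index).
    room_entropy: Shannon entropy (nats) of the distribution of active
    epochs over the five essential rooms.
    """
    rooms = [r for r in Room if r in rec.pir]
    active, observed, room_order = pir_day_grid(rec, day, rooms=rooms)
    act = active & observed
    out: dict[str, float] = {}

    union = act.any(axis=0)
    out["total_activity"] = union.sum() * PIR_PERIOD_S / 60.0
    ess_counts = {}
    for room in ESSENTIAL_ROOMS:
        if room in room_order:
            cnt = int(act[room_order.index(room)].sum())
        else:
            cnt = 0
        ess_counts[room] = cnt
        out[f"activity_{room.value}"] = cnt * PIR_PERIOD_S / 60.0

    # transitions of the most-recently-active room
    any_act = union
    if any_act.any():
        first_active = np.argmax(act, axis=0)  # lowest-index active room
        seq = first_active[any_act]
        out["room_transition_count"] = float(np.count_nonzero(seq[1:] != seq[:-1]))
    else:
        out["room_transition_count"] = MISSING

    active_min = out["total_activity"]
    if active_min > 0:
        alternations = int(np.count_nonzero(union[1:] != union[:-1]))
        out["activity_fragmentation"] = alternations / active_min
    else:
        out["activity_fragmentation"] = MISSING

    total = sum(ess_counts.values())
    if total > 0:
        p = np.array([c / total for c in ess_counts.values() if c > 0])
        out["room_entropy"] = float(-(p * np.log(p)).sum())
    else:
        out["room_entropy"] = MISSING
    return out


def _tod_hours(ts: pd.Timestamp, timezone: str) -> float:
    loc = ts.tz_convert(timezone)
    return loc.hour + loc.minute / 60.0 + loc.second / 3600.0


def daily_door_measures(
    rec: HomeRecording,
    day: DayWindow,
    min_outing_minutes: float = 5.0,
) -> dict:
    """Door-derived measures for one valid day.

    An outing is a pair of consecutive entrance-door events enclosing a gap
    with zero PIR activity in any room; gaps shorter than
    ``min_outing_minutes`` are treated as answering the door, not leaving.
    Time-of-day (tod) measures report first/median/last event times in
    decimal hours; days without the relevant events yield MISSING tods and
    zero counts.
    """
    out: dict[str, float] = {}
    events = [e for e in rec.doors if day.start <= e.time < day.end]
    active, observed, _ = pir_day_grid(rec, day)
    union = (active & observed).any(axis=0)

    entrance = sorted(
        (e for e in events if e.door == "entrance"), key=lambda e: e.time
    )
    outings = []
    for a, b in zip(entrance, entrance[1:]):
        gap_min = (b.time - a.time).total_seconds() / 60.0
        if gap_min < min_outing_minutes:
            continue
        i0 = int(math.ceil((a.time - day.start).total_seconds() / PIR_PERIOD_S))
        i1 = int(math.floor((b.time - day.start).total_seconds() / PIR_PERIOD_S))
        i0, i1 = max(i0, 0), min(i1, union.size)
        if i1 > i0 and union[i0:i1].any():
            continue
        outings.append(gap_min)
    out["outing_count"] = float(len(outings))
    out["outing_duration_total"] = float(sum(outings))
    out["fridge_use_count"] = float(
        sum(1 for e in events if e.door == "fridge" and e.state == "open")
    )

    for door in ("entrance", "fridge"):
        times = sorted(
            _tod_hours(e.time, rec.timezone)
            for e in events
            if e.door == door
        )
        if times:
            out[f"{door}_door_tod_first"] = times[0]
            out[f"{door}_door_tod_middle"] = float(np.median(times))
            out[f"{door}_door_tod_last"] = times[-1]
        else:
            for which in ("first", "middle", "last"):
                out[f"{door}_door_tod_{which}"] = MISSING
    return out


# ---------------------------------------------------------------------------
# Bed-sensor nightly measures


def _noon_anchored_hours(ts: pd.Timestamp, timezone: str) -> float:
    """Decimal clock hours, +24 for times after midnight (range [12, 36))."""
    h = _tod_hours(ts, timezone)
    return h + 24.0 if h < 12.0 else h


def nightly_sleep_measures(night: NightRecord, timezone: str = "UTC") -> dict:
    """Sleep-architecture measures from the staged night."""
    out = {}
    stage = night.stage
    known = stage != STAGE_MISSING
    sleep = known & (stage != STAGE_AWAKE)
    out["time_in_bed"] = night.duration_hours
    out["sleep_duration"] = sleep.sum() * BED_PERIOD_S / 3600.0
    out["sleep_efficiency"] = (
        out["sleep_duration"] / out["time_in_bed"]
        if out["time_in_bed"] > 0 else MISSING
    )
    if known.any():
        nk = known.sum()
        for name, code in (("rem", 1), ("deep", 2), ("light", 3), ("awake", 0)):
            out[f"stage_frac_{name}"] = np.count_nonzero(stage == code) / nk
    else:
        for name in ("rem", "deep", "light", "awake"):
            out[f"stage_frac_{name}"] = MISSING

    if sleep.any():
        idx = np.flatnonzero(sleep)
        onset = night.start + pd.Timedelta(seconds=float(idx[0]) * BED_PERIOD_S)
        offset = night.start + pd.Timedelta(seconds=float(idx[-1] + 1) * BED_PERIOD_S)
        out["sleep_onset_tod"] = _noon_anchored_hours(onset, timezone)
        out["sleep_offset_tod"] = _noon_anchored_hours(offset, timezone)
        inner = stage[idx[0]: idx[-1] + 1]
        out["waso"] = np.count_nonzero(inner == STAGE_AWAKE) * BED_PERIOD_S / 60.0
    else:
        out["sleep_onset_tod"] = out["sleep_offset_tod"] = out["waso"] = MISSING

    out["bed_exit_count"] = float(len(night.bed_exit_intervals))
    out["toss_turn_count"] = float(len(night.toss_turn_times))
    act = night.activity[np.isfinite(night.activity)]
    out["activity_in_bed"] = float(act.mean()) if act.size else MISSING
    return out


def nightly_cardio_measures(
    night: NightRecord,
    min_hr_minutes: float = 30.0,
    baseline_minutes: float = 30.0,
    rolling_minutes: float = 10.0,
) -> dict:
    """Nocturnal heart-rate and respiration measures.

    ``hr_dipping`` is a within-night proxy for nocturnal dipping: relative
    drop from the early-night baseline B (mean HR over the first
    ``baseline_minutes`` in bed) to the trough T (minimum
    ``rolling_minutes``-rolling-mean HR during the night), (B − T)/B. The
    bed sensor records no daytime HR, so the classical day/night ratio is
    not computable and an early-night anchor is used instead.
    """
    keys = ("hr_mean", "hr_min", "hr_max", "hr_sd", "hr_dipping",
            "rr_mean", "rr_sd")
    hr = night.hr
    good = np.isfinite(hr)
    if good.sum() * BED_PERIOD_S / 60.0 < min_hr_minutes:
        return {k: MISSING for k in keys}
    out = {}
    vals = hr[good]
    out["hr_mean"] = float(vals.mean())
    out["hr_min"] = float(vals.min())
    out["hr_max"] = float(vals.max())
    out["hr_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    nb = int(round(baseline_minutes * 60.0 / BED_PERIOD_S))
    base = hr[:nb]
    base = base[np.isfinite(base)]
    win = int(round(rolling_minutes * 60.0 / BED_PERIOD_S))
    roll = (
        pd.Series(hr)
        .rolling(win, min_periods=max(win // 2, 1))
        .mean()
        .min()
    )
    if base.size and np.isfinite(roll) and base.mean() > 0:
        b = float(base.mean())
        out["hr_dipping"] = (b - float(roll)) / b
    else:
        out["hr_dipping"] = MISSING

    rr = night.rr[np.isfinite(night.rr)]
    out["rr_mean"] = float(rr.mean()) if rr.size else MISSING
    out["rr_sd"] = (
        float(rr.std(ddof=1)) if rr.size > 1 else (0.0 if rr.size else MISSING)
    )
    return out


# ---------------------------------------------------------------------------
# Spectral measures


def spectral_measures(
    channel: np.ndarray,
    fs: float = 1.0 / BED_PERIOD_S,
    bands: Sequence = DEFAULT_BANDS,
    band_names: Sequence = BAND_NAMES,
    min_samples: int = 256,
    max_gap_s: float = 60.0,
    prefix: str = "",
) -> dict:
    """Welch band powers and spectral entropy of one uniform night channel.

    Gaps up to ``max_gap_s`` are linearly interpolated; longer gaps split the
    channel and the averaged periodogram is a chunk-length-weighted mean of
    the per-chunk Welch estimates (Hann window, 256-sample segments, 50%
    overlap). Band powers are reported as fractions of total power (the f=0
    bin is excluded; channels are mean-detrended). Constant channels have no
    power and yield MISSING fractions/entropy.
    """
    keys = [f"{prefix}total_power"] + [
        f"{prefix}bandpower_{b}" for b in band_names
    ] + [f"{prefix}spectral_entropy"]
    x = pd.Series(np.asarray(channel, dtype=float))
    limit = int(max_gap_s / (1.0 / fs))
    x = x.interpolate(limit=limit, limit_area="inside")
    arr = x.to_numpy()

    # split at remaining NaN runs
    finite = np.isfinite(arr)
    chunks = []
    i = 0
    n = arr.size
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j < n and finite[j]:
            j += 1
        if j - i >= min_samples:
            chunks.append(arr[i:j])
        i = j
    if not chunks:
        return {k: MISSING for k in keys}

    nper = min(min_samples, min(len(c) for c in chunks))
    psd = None
    wsum = 0.0
    for c in chunks:
        f, p = sp_signal.welch(
            c, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
            detrend="constant",
        )
        w = len(c)
        psd = p * w if psd is None else psd + p * w
        wsum += w
    psd = psd / wsum
    # drop DC bin
    f, psd = f[1:], psd[1:]
    total = float(psd.sum())
    out = {f"{prefix}total_power": total}
    if total <= 1e-12:
        for b in band_names:
            out[f"{prefix}bandpower_{b}"] = MISSING
        out[f"{prefix}spectral_entropy"] = MISSING
        return out
    for (lo, hi), name in zip(bands, band_names):
        sel = (f > lo) & (f <= hi)
        out[f"{prefix}bandpower_{name}"] = float(psd[sel].sum()) / total
    p_norm = psd / total
    p_norm = p_norm[p_norm > 0]
    ent = float(-(p_norm * np.log(p_norm)).sum())
    out[f"{prefix}spectral_entropy"] = (
        ent / math.log(psd.size) if psd.size > 1 else MISSING
    )
    return out


# ---------------------------------------------------------------------------
# Cosinor


def fit_cosinor(
    times_h: np.ndarray,
    values: np.ndarray,
    period: float = 24.0,
) -> CosinorFit:
    """Least-squares single-component cosinor fit.

    Fits y(t) = M + A·cos(2πt/period − φ) through the linearisation
    y = M + β₁cos(ωt) + β₂sin(ωt); A = √(β₁² + β₂²), φ = atan2(β₂, β₁)
    mapped to hours in [0, period). ``times_h`` are hours from an arbitrary
    origin; the acrophase is reported on the clock of that origin.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    good = np.isfinite(y)
    t, y = t[good], y[good]
    if t.size < 3:
        return CosinorFit(MISSING, MISSING, MISSING, MISSING)
    w = 2.0 * math.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = (float(b) for b in beta)
    amplitude = math.hypot(b1, b2)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 1e-24:
        return CosinorFit(mesor, 0.0, MISSING, 0.0)
    r2 = max(0.0, min(1.0, 1.0 - float((resid ** 2).sum()) / tss))
    if amplitude <= 1e-12:
        return CosinorFit(mesor, 0.0, MISSING, r2)
    acro = (math.atan2(b2, b1) * period / (2.0 * math.pi)) % period
    return CosinorFit(mesor, amplitude, acro, r2)


def binned_union_activity(
    rec: HomeRecording,
    start: pd.Timestamp,
    end: pd.Timestamp,
    bin_minutes: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Union PIR activity minutes per time bin over [start, end).

    Returns (bin centre times in hours since `start`, active minutes per
    bin); bins with no observed epochs are NaN.
    """
    n_bins = int(round((end - start).total_seconds() / (bin_minutes * 60.0)))
    per_bin = int(round(bin_minutes * 60.0 / PIR_PERIOD_S))
    vals = np.full(n_bins, np.nan)
    rooms = [r for r in Room if r in rec.pir]
    if rooms:
        n_epochs = n_bins * per_bin
        day = DayWindow(date=start.date(), start=start,
                        end=start + pd.Timedelta(seconds=n_epochs * PIR_PERIOD_S))
        active, observed, _ = pir_day_grid(rec, day, rooms=rooms)
        union = (active & observed).any(axis=0).reshape(n_bins, per_bin)
        obs = observed.any(axis=0).reshape(n_bins, per_bin)
        counts = union.sum(axis=1)
        has_obs = obs.any(axis=1)
        vals[has_obs] = counts[has_obs] * PIR_PERIOD_S / 60.0
    centres = (np.arange(n_bins) + 0.5) * bin_minutes / 60.0
    return centres, vals


# ---------------------------------------------------------------------------
# Daily extraction driver


def extract_daily(
    rec: HomeRecording,
    criteria: ValidityCriteria = ValidityCriteria(),
    min_outing_minutes: float = 5.0,
) -> DailyMeasureTable:
    """Compute every registered daily/nightly measure for each calendar day.

    Invalid days (per :func:`exhaust.sensor_io.day_validity`) yield MISSING
    for the corresponding system's measures.
    """
    days = split_days(rec)
    nights = assign_nights(rec)
    reg = registry()
    daily_ids = [d.measure_id for d in reg if d.granularity in ("daily", "nightly")]
    rows = {}
    for day in days:
        row = dict.fromkeys(daily_ids, MISSING)
        if day_validity(rec, day, "pir_door", criteria):
            row.update(daily_activity_measures(rec, day))
            row.update(daily_door_measures(rec, day, min_outing_minutes))
        if day_validity(rec, day, "bed", criteria, nights_by_date=nights):
            night = nights[day.date]
            row.update(nightly_sleep_measures(night, rec.timezone))
            row.update(nightly_cardio_measures(night))
            for ch in ("hr", "rr", "activity"):
                row.update(
                    spectral_measures(getattr(night, ch), prefix=f"{ch}_")
                )
        rows[day.date] = {k: row.get(k, MISSING) for k in daily_ids}
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame = frame.reindex(columns=daily_ids)
    frame.index.name = "date"
    return DailyMeasureTable(rec.participant_id, frame)
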