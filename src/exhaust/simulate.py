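"""Synthetic cohort generator for the zero-interaction sensing pipeline.

Emulates the statistical structure of a contactless home-monitoring
deployment: a semi-Markov room-occupancy process drives 2-s PIR epochs and
door events (outings appear as entrance-door events bracketing interior
silence), and one nightly bed-sensor record per day carries heart rate with
a configurable nocturnal dip, respiration, in-bed activity, a Markovian
sleep-stage sequence, toss-and-turn events, and bed exits on the 4-s grid.

Phenotypes (fall risk, frailty, depression, cognitive impairment) act on the
routine parameters through per-assessment effect maps whose default
directions mirror the qualitative pattern expected in ageing cohorts (less
movement and fewer outings, longer sleep, more restless nights, more
variable nocturnal heart-rate dipping), with magnitudes as free
configuration. Device outages delete stream spans so that segment-validity
rules are exercised end to end. Everything is reproducible from a single
integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import extract_exhaust
from .sensor_io import (
    BED_PERIOD_S,
    PIR_PERIOD_S,
    STAGE_MISSING,
    DoorEvent,
    HomeRecording,
    NightRecord,
    PirEpochSeries,
    Room,
)

logger = logging.getLogger(__name__)

ASSESSMENTS = ("TUG", "POMA", "EFS", "GDS", "MoCA")

EPOCHS_PER_DAY = int(round(86400 / PIR_PERIOD_S))
EPOCHS_PER_MINUTE = int(round(60 / PIR_PERIOD_S))


@dataclass
class RoutineParams:
    """Behavioural/physiological parameters of one simulated resident."""

    sleep_onset_mean: float = 22.5     # h, local clock
    sleep_onset_sd: float = 0.75       # h
    sleep_duration_mean: float = 7.5   # h
    sleep_duration_sd: float = 0.75    # h
    room_dwell_rates: dict = field(default_factory=lambda: {
        Room.LIVINGROOM: 40.0, Room.KITCHEN: 15.0, Room.BEDROOM: 20.0,
        Room.BATHROOM: 5.0, Room.ENTRANCE: 2.0, Room.OTHER: 10.0,
    })                                  # mean dwell minutes per visit
    transition_rate: float = 55.0       # expected room changes / day
    activity_duty: float = 0.35         # fraction of occupied minutes with motion
    outing_rate: float = 1.2            # outings / day
    outing_duration_mean: float = 90.0  # min
    fridge_rate: float = 6.0            # opens / day
    hr_baseline: float = 65.0           # bpm
    hr_dip_frac: float = 0.12           # nocturnal dip fraction
    hr_dip_frac_sd: float = 0.03        # night-to-night sd of the dip
    hr_noise_sd: float = 1.0            # bpm, AR(1) innovation scale
    hr_ar: float = 0.9                  # AR(1) coefficient at 4-s steps
    rr_baseline: float = 14.0           # breaths / min
    rr_noise_sd: float = 0.4
    stage_transition_matrix: np.ndarray = field(default_factory=lambda: np.array([
        # awake  rem    deep   light      (4-s steps)
        [0.980, 0.004, 0.002, 0.014],  # awake
        [0.003, 0.990, 0.001, 0.006],  # rem
        [0.002, 0.001, 0.991, 0.006],  # deep
        [0.005, 0.005, 0.006, 0.984],  # light
    ]))
    toss_turn_rate: float = 8.0         # events / night
    bed_exit_rate: float = 1.0          # events / night
    activity_in_bed_mean: float = 2.0   # a.u.

    def validate(self) -> None:
        rates = (self.transition_rate, self.outing_rate, self.fridge_rate,
                 self.toss_turn_rate, self.bed_exit_rate,
                 self.activity_in_bed_mean, self.outing_duration_mean)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.hr_dip_frac <= 1.0):
            raise ValueError("hr_dip_frac must lie in [0, 1]")
        P = np.asarray(self.stage_transition_matrix, dtype=float)
        if P.shape != (4, 4) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("stage matrix must be 4x4 row-stochastic")


#: Default per-assessment phenotype effects: (parameter, mode, coefficient)
#: applied per unit latent severity; "mul" scales by (1 + coef·s), "add"
#: shifts by coef·s. Directions: worse outcomes mean less home movement and
#: fewer outings, longer sleep, more restless nights, and (for cognitive
#: impairment) more variable nocturnal heart-rate dipping.
DEFAULT_EFFECTS: dict = {
    "MoCA": {
        "transition_rate": ("mul", -0.45),
        "fridge_rate": ("mul", -0.45),
        "outing_rate": ("mul", -0.40),
        "hr_dip_frac_sd": ("add", 0.07),
        "sleep_duration_mean": ("add", 1.0),
        "sleep_onset_sd": ("add", 0.6),
    },
    "EFS": {
        "fridge_rate": ("mul", -0.50),
        "transition_rate": ("mul", -0.50),
        "outing_rate": ("mul", -0.50),
        "sleep_duration_mean": ("add", 1.2),
    },
    "TUG": {
        "activity_in_bed_mean": ("mul", 0.80),
        "bed_exit_rate": ("add", 1.5),
        "toss_turn_rate": ("mul", 0.60),
        "transition_rate": ("mul", -0.30),
    },
    "POMA": {
        "activity_in_bed_mean": ("mul", 0.50),
        "bed_exit_rate": ("add", 1.0),
        "transition_rate": ("mul", -0.25),
    },
    "GDS": {
        "outing_rate": ("mul", -0.60),
        "sleep_duration_mean": ("add", 1.0),
        "transition_rate": ("mul", -0.30),
        "fridge_rate": ("mul", -0.30),
    },
}


@dataclass
class PhenotypeSpec:
    """Latent severities per assessment plus their effects on the routine."""

    severities: dict = field(default_factory=dict)  # assessment -> [0, 1]
    effects: dict = field(default_factory=lambda: DEFAULT_EFFECTS)

    def validate(self) -> None:
        for a, s in self.severities.items():
            if a not in ASSESSMENTS:
                raise ValueError(f"unknown assessment {a!r}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"severity for {a} outside [0, 1]")

    def apply(self, routine: RoutineParams) -> RoutineParams:
        out = replace(routine, room_dwell_rates=dict(routine.room_dwell_rates))
        for assessment, sev in self.severities.items():
            for param, (mode, coef) in self.effects.get(assessment, {}).items():
                cur = getattr(out, param)
                new = cur * (1.0 + coef * sev) if mode == "mul" else cur + coef * sev
                setattr(out, param, new)
        out.hr_dip_frac = float(np.clip(out.hr_dip_frac, 0.0, 1.0))
        out.hr_dip_frac_sd = max(out.hr_dip_frac_sd, 0.0)
        for name in ("transition_rate", "outing_rate", "fridge_rate",
                     "toss_turn_rate", "bed_exit_rate", "activity_in_bed_mean"):
            setattr(out, name, max(getattr(out, name), 0.0))
        out.sleep_duration_mean = float(np.clip(out.sleep_duration_mean, 4.0, 11.0))
        return out


@dataclass
class OutageModel:
    """Technical-failure model: outages per month deleting stream spans."""

    rate_per_month: float = 0.0
    duration_mean_hours: float = 24.0
    affected_system: str = "both"  # pir_door | bed | both

    def __post_init__(self):
        if self.rate_per_month < 0 or self.duration_mean_hours < 0:
            raise ValueError("outage rate/duration must be non-negative")
        if self.affected_system not in ("pir_door", "bed", "both"):
            raise ValueError(f"unknown system {self.affected_system!r}")


# ---------------------------------------------------------------------------
# Single-participant stream synthesis


def _ar1(rng, n: int, sd: float, ar: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - ar * ar, 1e-9)), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = ar * out[i - 1] + innov[i]
    return out


def _stage_sequence(rng, n: int, P: np.ndarray) -> np.ndarray:
    """Markov stage chain sampled run-wise (geometric dwell per stage)."""
    stages = np.empty(n, dtype=np.int8)
    s = 3  # start in light sleep
    i = 0
    while i < n:
        p_stay = P[s, s]
        run = int(rng.geometric(max(1.0 - p_stay, 1e-6)))
        run = min(run, n - i)
        stages[i:i + run] = s
        i += run
        if i < n:
            probs = P[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(4, p=probs))
    return stages


def _simulate_night(
    rng, routine: RoutineParams, start_s: float, duration_h: float,
    t0: pd.Timestamp,
) -> NightRecord:
    start = t0 + pd.Timedelta(seconds=round(start_s / BED_PERIOD_S) * BED_PERIOD_S)
    n = int(round(duration_h * 3600.0 / BED_PERIOD_S))
    end = start + pd.Timedelta(seconds=n * BED_PERIOD_S)

    dip = float(np.clip(
        rng.normal(routine.hr_dip_frac, routine.hr_dip_frac_sd), 0.0, 1.0
    ))
    b = routine.hr_baseline + rng.normal(0.0, 1.0)
    tmin = np.arange(n) * BED_PERIOD_S / 60.0
    total_min = n * BED_PERIOD_S / 60.0
    # plateau 30 min, ramp down over 60 min, trough, ramp up last 30 min
    prof = np.ones(n)
    ramp = np.clip((tmin - 30.0) / 60.0, 0.0, 1.0)
    prof = 1.0 - dip * ramp
    tail = np.clip((total_min - tmin) / 30.0, 0.0, 1.0)
    prof = 1.0 - (1.0 - prof) * tail
    hr = np.maximum(b * prof + _ar1(rng, n, routine.hr_noise_sd, routine.hr_ar), 25.0)
    rr = np.maximum(
        routine.rr_baseline + _ar1(rng, n, routine.rr_noise_sd, routine.hr_ar), 5.0
    )
    activity = rng.exponential(max(routine.activity_in_bed_mean, 1e-6), size=n)
    stage = _stage_sequence(rng, n, np.asarray(routine.stage_transition_matrix))

    n_tt = rng.poisson(routine.toss_turn_rate)
    tt_off = np.sort(rng.uniform(0.0, n * BED_PERIOD_S, size=n_tt))
    toss_turns = [start + pd.Timedelta(seconds=round(float(o))) for o in tt_off]
    for o in tt_off:
        i = int(o / BED_PERIOD_S)
        activity[i:i + 3] += routine.activity_in_bed_mean * 4.0

    exits = []
    n_ex = rng.poisson(routine.bed_exit_rate)
    if n_ex and total_min > 90.0:
        starts = np.sort(rng.uniform(35.0, total_min - 20.0, size=n_ex))
        prev_end = -1.0
        for s0 in starts:
            dur = float(np.clip(rng.normal(5.0, 2.0), 2.0, 10.0))
            if s0 <= prev_end:
                continue
            i0 = int(s0 * 60.0 / BED_PERIOD_S)
            i1 = min(int((s0 + dur) * 60.0 / BED_PERIOD_S), n)
            hr[i0:i1] = np.nan
            rr[i0:i1] = np.nan
            activity[i0:i1] = np.nan
            stage[i0:i1] = STAGE_MISSING
            exits.append((
                start + pd.Timedelta(seconds=i0 * BED_PERIOD_S),
                start + pd.Timedelta(seconds=i1 * BED_PERIOD_S),
            ))
            prev_end = s0 + dur
    return NightRecord(
        start=start, end=end, hr=hr, rr=rr, activity=activity, stage=stage,
        toss_turn_times=toss_turns, bed_exit_intervals=exits,
    )


def simulate_participant(
    routine: RoutineParams | None = None,
    phenotype: PhenotypeSpec | None = None,
    days: int = 14,
    seed: int = 0,
    participant_id: str = "p000",
    timezone: str = "UTC",
    start_date: Date = Date(2021, 3, 1),
) -> HomeRecording:
    """Generate one participant's full multi-stream recording.

    PIR epochs sit on a strict 2-s grid starting at local midnight of
    ``start_date``; bed channels on a strict 4-s grid. The same
    (parameters, seed) always yields byte-identical streams.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    routine = routine or RoutineParams()
    routine.validate()
    if phenotype is not None:
        phenotype.validate()
        routine = phenotype.apply(routine)
    rng = np.random.default_rng(seed)

    t0 = pd.Timestamp(start_date).tz_localize(timezone)
    n_epochs = days * EPOCHS_PER_DAY
    rooms = list(routine.room_dwell_rates)
    states = {r: np.zeros(n_epochs, dtype=bool) for r in rooms}
    doors: list[DoorEvent] = []
    nights: list[NightRecord] = []

    dwell_means = np.array([routine.room_dwell_rates[r] for r in rooms])
    move_probs = dwell_means / dwell_means.sum()

    def _door(door, t_s, state):
        doors.append(DoorEvent(door, t0 + pd.Timedelta(seconds=round(t_s)), state))

    def _mark(room, t_start_s, t_end_s):
        """Duty-cycled PIR activity while a room is occupied."""
        i0 = max(int(t_start_s / PIR_PERIOD_S), 0)
        i1 = min(int(t_end_s / PIR_PERIOD_S), n_epochs)
        if i1 <= i0:
            return
        n_min = (i1 - i0 + EPOCHS_PER_MINUTE - 1) // EPOCHS_PER_MINUTE
        on = rng.random(n_min) < routine.activity_duty
        mask = np.repeat(on, EPOCHS_PER_MINUTE)[: i1 - i0]
        states[room][i0:i1] |= mask

    wake_s = 7.0 * 3600.0  # first morning
    for day in range(days):
        onset_h = rng.normal(routine.sleep_onset_mean, routine.sleep_onset_sd)
        onset_s = day * 86400.0 + onset_h * 3600.0
        dur_h = float(np.clip(
            rng.normal(routine.sleep_duration_mean, routine.sleep_duration_sd),
            4.0, 12.0,
        ))
        waking = (wake_s, max(onset_s, wake_s + 3600.0))

        # outings: entrance events bracketing interior silence
        outage_spans = []
        n_out = rng.poisson(routine.outing_rate)
        for _ in range(n_out):
            dur_min = float(np.clip(
                rng.exponential(routine.outing_duration_mean), 10.0, 300.0
            ))
            s0 = rng.uniform(waking[0] + 600.0, waking[1] - dur_min * 60.0 - 600.0) \
                if waking[1] - waking[0] > dur_min * 60.0 + 1800.0 else None
            if s0 is None:
                continue
            s1 = s0 + dur_min * 60.0
            if any(s0 < e and s1 > s for s, e in outage_spans):
                continue
            outage_spans.append((s0, s1))
            _mark(Room.ENTRANCE, s0 - 60.0, s0 + 8.0)
            _door("entrance", s0, "open")
            _door("entrance", s0 + 15.0, "close")
            _door("entrance", s1, "open")
            _door("entrance", s1 + 15.0, "close")
            _mark(Room.ENTRANCE, s1 + 20.0, s1 + 80.0)
        outage_spans.sort()

        def _at_home(t_s):
            return not any(s <= t_s < e for s, e in outage_spans)

        # semi-Markov occupancy over at-home waking time
        scale = ((waking[1] - waking[0]) / 60.0 / max(routine.transition_rate, 1.0)
                 ) / dwell_means.mean()
        room_i = int(rng.choice(len(rooms), p=move_probs))
        t = waking[0]
        while t < waking[1]:
            dwell_s = float(np.clip(
                rng.exponential(dwell_means[room_i] * scale * 60.0), 30.0, 7200.0
            ))
            t_end = min(t + dwell_s, waking[1])
            seg_start = t
            for s0, s1 in outage_spans + [(waking[1], waking[1])]:
                a = max(seg_start, 0.0)
                b = min(t_end, s0)
                if b > a:
                    _mark(rooms[room_i], a, b)
                seg_start = max(seg_start, s1)
                if seg_start >= t_end:
                    break
            t = t_end
            room_i = int(rng.choice(len(rooms), p=move_probs))

        # fridge events while at home
        n_fr = rng.poisson(routine.fridge_rate)
        fr_times = np.sort(rng.uniform(waking[0], waking[1], size=n_fr))
        for ft in fr_times:
            if not _at_home(ft):
                continue
            _door("fridge", ft, "open")
            _door("fridge", ft + 20.0, "close")
            _mark(Room.KITCHEN, ft - 30.0, ft + 40.0)

        nights.append(_simulate_night(rng, routine, onset_s, dur_h, t0))
        wake_s = onset_s + dur_h * 3600.0

    pir = {
        room: PirEpochSeries(room=room, start=t0, states=states[room])
        for room in rooms
    }
    # door streams are alternation-clean by construction; sort handled by
    # HomeRecording
    return HomeRecording(
        participant_id=participant_id, pir=pir, doors=doors, nights=nights,
        timezone=timezone,
    )


# ---------------------------------------------------------------------------
# Outage injection


def inject_missingness(
    rec: HomeRecording, outages: OutageModel, seed: int = 0
) -> HomeRecording:
    """Delete data in sampled outage intervals; returns a new recording."""
    span = rec.span()
    pir = {
        room: PirEpochSeries(
            room=room, start=s.start, states=s.states.copy(),
            observed=s.observed.copy(), period=s.period,
        )
        for room, s in rec.pir.items()
    }
    doors = list(rec.doors)
    nights = list(rec.nights)
    if span is not None and outages.rate_per_month > 0:
        rng = np.random.default_rng(seed)
        span_s = (span[1] - span[0]).total_seconds()
        n_ev = rng.poisson(outages.rate_per_month * span_s / (30.0 * 86400.0))
        for _ in range(n_ev):
            o0 = span[0] + pd.Timedelta(
                seconds=float(rng.uniform(0.0, span_s))
            )
            o1 = o0 + pd.Timedelta(
                hours=float(rng.exponential(outages.duration_mean_hours))
            )
            if outages.affected_system in ("pir_door", "both"):
                for s in pir.values():
                    i0 = int(max((o0 - s.start).total_seconds() / s.period, 0))
                    i1 = int(min((o1 - s.start).total_seconds() / s.period,
                                 len(s)))
                    if i1 > i0:
                        s.observed[i0:i1] = False
                doors = [e for e in doors if not (o0 <= e.time < o1)]
            if outages.affected_system in ("bed", "both"):
                nights = [
                    n for n in nights if n.end <= o0 or n.start >= o1
                ]
    return HomeRecording(
        participant_id=rec.participant_id, pir=pir, doors=doors,
        nights=nights, timezone=rec.timezone,
    )


# ---------------------------------------------------------------------------
# Cohort generation

#: Score ranges (control, case) consistent with the standard cut-offs
#: (TUG ≥ 12 s, POMA < 19, EFS > 5, GDS ≥ 5, MoCA < 23).
SCORE_RANGES = {
    "TUG": ((7.0, 11.5), (12.5, 24.0)),
    "POMA": ((20.0, 28.0), (10.0, 18.5)),
    "EFS": ((0.0, 4.9), (6.0, 13.0)),
    "GDS": ((0.0, 4.4), (5.0, 12.0)),
    "MoCA": ((23.5, 30.0), (14.0, 22.4)),
}


@dataclass
class ParticipantPlan:
    participant_id: str
    seed: int
    severities: dict
    case: dict          # assessment -> bool (post label-noise group)
    scores: dict        # assessment -> float
    age: float
    sex: str
    cohort: str


def plan_cohort(
    n: int,
    case_fraction: Mapping[str, float] | float = 0.5,
    seed: int = 0,
    label_noise: float = 0.0,
    effects: dict | None = None,
) -> list:
    """Draw the latent design of a cohort (labels, severities, demographics).

    Case counts are exact: ``round(fraction · n)`` participants per
    assessment are cases. With ``label_noise`` > 0 a participant's recorded
    score may land on the wrong side of the cut-off.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not isinstance(case_fraction, Mapping):
        case_fraction = {a: float(case_fraction) for a in ASSESSMENTS}
    for a, f in case_fraction.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"case fraction for {a} outside [0, 1]")
    rng = np.random.default_rng(seed)
    case_flags = {}
    for a in ASSESSMENTS:
        frac = case_fraction.get(a, 0.0)
        n_case = int(round(frac * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_case]] = True
        case_flags[a] = flags
    plans = []
    for i in range(n):
        severities, cases, scores = {}, {}, {}
        for a in ASSESSMENTS:
            is_case = bool(case_flags[a][i])
            severities[a] = (
                float(rng.uniform(0.7, 1.0)) if is_case
                else float(rng.uniform(0.0, 0.3))
            )
            scored_case = is_case
            if label_noise > 0 and rng.random() < label_noise:
                scored_case = not is_case
            lo, hi = SCORE_RANGES[a][1 if scored_case else 0]
            cases[a] = scored_case
            scores[a] = float(rng.uniform(lo, hi))
        plans.append(
            ParticipantPlan(
                participant_id=f"p{i:03d}",
                seed=int(rng.integers(0, 2**31 - 1)),
                severities=severities,
                case=cases,
                scores=scores,
                age=float(np.clip(round(rng.normal(84.0, 6.0)), 70, 99)),
                sex=str(rng.choice(["female", "male"])),
                cohort=str(rng.choice(["cohort1", "cohort2"])),
            )
        )
    return plans


def _plan_tables(
    plans: Sequence[ParticipantPlan], start_date: Date, days: int
) -> tuple:
    mid = start_date + timedelta(days=days // 2)
    assessments = pd.DataFrame(
        [
            {"participant_id": p.participant_id, "assessment": a,
             "date": mid, "score": p.scores[a]}
            for p in plans for a in ASSESSMENTS
        ]
    )
    demographics = pd.DataFrame(
        [
            {"participant_id": p.participant_id, "age": p.age,
             "sex": p.sex, "cohort": p.cohort}
            for p in plans
        ]
    )
    return assessments, demographics


def simulate_cohort(
    n: int,
    case_fraction: Mapping[str, float] | float = 0.5,
    days: int = 84,
    outages: OutageModel | None = None,
    seed: int = 0,
    routine: RoutineParams | None = None,
    effects: dict | None = None,
    label_noise: float = 0.0,
    start_date: Date = Date(2021, 3, 1),
    timezone: str = "UTC",
) -> tuple:
    """Generate a full cohort: recordings, assessment table, demographics."""
    plans = plan_cohort(n, case_fraction, seed, label_noise)
    base = routine or RoutineParams()
    eff = effects if effects is not None else DEFAULT_EFFECTS
    recordings = []
    for p in plans:
        phen = PhenotypeSpec(severities=p.severities, effects=eff)
        rec = simulate_participant(
            routine=base, phenotype=phen, days=days, seed=p.seed,
            participant_id=p.participant_id, timezone=timezone,
            start_date=start_date,
        )
        if outages is not None and outages.rate_per_month > 0:
            rec = inject_missingness(rec, outages, seed=p.seed + 1)
        recordings.append(rec)
    assessments, demographics = _plan_tables(plans, start_date, days)
    return recordings, assessments, demographics


def simulate_exhaust_cohort(
    n: int,
    case_fraction: Mapping[str, float] | float = 0.5,
    days: int = 84,
    outages: OutageModel | None = None,
    seed: int = 0,
    routine: RoutineParams | None = None,
    effects: dict | None = None,
    label_noise: float = 0.0,
    start_date: Date = Date(2021, 3, 1),
    timezone: str = "UTC",
) -> tuple:
    """Streamed cohort generation straight to exhaust vectors.

    Identical draws to :func:`simulate_cohort` but each recording is
    extracted and discarded immediately, keeping memory flat for large
    cohorts. Returns (exhaust DataFrame, assessments, demographics).
    """
    plans = plan_cohort(n, case_fraction, seed, label_noise)
    base = routine or RoutineParams()
    eff = effects if effects is not None else DEFAULT_EFFECTS
    frames = []
    for p in plans:
        phen = PhenotypeSpec(severities=p.severities, effects=eff)
        rec = simulate_participant(
            routine=base, phenotype=phen, days=days, seed=p.seed,
            participant_id=p.participant_id, timezone=timezone,
            start_date=start_date,
        )
        if outages is not None and outages.rate_per_month > 0:
            rec = inject_missingness(rec, outages, seed=p.seed + 1)
        frames.append(extract_exhaust(rec))
        del rec
    exhaust = pd.concat(frames)
    assessments, demographics = _plan_tables(plans, start_date, days)
    return exhaust, assessments, demographics
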