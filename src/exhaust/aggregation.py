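"""Bi-weekly segmentation and the summary-statistic layer.

Daily/nightly base measures are aggregated over non-overlapping 14-day
segments starting at each participant's first recorded day. For every base
measure with at least ``min_days`` (default 10) valid days in a segment, a
set of descriptive statistics is emitted — quantiles (q10…q90), the
interquartile range, mean, coefficient of variation, and the quantile-based
robust skewness (sk3) and kurtosis (kr3) estimators of the Kim–White
naming convention; otherwise every derivate is MISSING. Derived measure ids
follow ``<stat>_<base_measure_id>``. Per-segment measures (cosinor rhythm
parameters) are computed from the raw bi-weekly PIR stream under the same
minimum-days gate and keep their bare ids.

MISSING propagates and is never imputed here; the downstream classifier
handles missing values natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .base_measures import (
    BaseMeasureDef,
    DailyMeasureTable,
    binned_union_activity,
    fit_cosinor,
    registry as default_registry,
)
from .sensor_io import HomeRecording, ValidityCriteria, day_validity, split_days

MISSING = float("nan")

SEGMENT_DAYS = 14

#: Summary statistics applied to each daily/nightly base measure.
DEFAULT_STATS = ("q10", "q25", "q50", "q75", "q90", "iqr",
                 "mean", "coefvar", "kr3", "sk3")

_QUANTILE_STATS = {"q10": 0.10, "q25": 0.25, "q50": 0.50, "q75": 0.75, "q90": 0.90}

#: Normal-calibration constant for kr3: the population value of the Hogg
#: tail-mean ratio (U.05 − L.05)/(U.50 − L.50) for a standard normal,
#: phi(z.95)/0.05 · 2 / (phi(0)/0.5 · 2) = 4.1254/1.5958 ≈ 2.59.
KR3_CENTERING = 2.59

#: Minimum sample size for the kr3 tail-mean estimator to be stable.
KR3_MIN_N = 20


@dataclass(frozen=True)
class SummaryStatSet:
    stats: tuple = DEFAULT_STATS

    def __post_init__(self):
        allowed = set(DEFAULT_STATS)
        bad = [s for s in self.stats if s not in allowed]
        if bad:
            raise ValueError(f"unknown summary statistics: {bad}")


@dataclass
class BiweeklySegment:
    """One participant's 14-day aggregation window."""

    participant_id: str
    index: int
    start_date: object
    dates: list
    daily: pd.DataFrame  # rows restricted to `dates`
    valid_day_count: pd.Series  # per measure_id

    def __post_init__(self):
        if len(self.dates) != SEGMENT_DAYS:
            raise ValueError("segment must hold exactly 14 dates")


def segment_biweekly(daily: DailyMeasureTable) -> list:
    """Split a daily table into non-overlapping 14-day segments.

    Segments are recording-relative: they start at the participant's first
    recorded date and advance by 14 days; a trailing partial segment is
    dropped.
    """
    dates = sorted(daily.frame.index)
    if not dates:
        return []
    first = dates[0]
    segments = []
    idx = 0
    start = first
    while True:
        seg_dates = [start + timedelta(days=i) for i in range(SEGMENT_DAYS)]
        if seg_dates[-1] > dates[-1]:
            break
        sub = daily.frame.reindex(seg_dates)
        segments.append(
            BiweeklySegment(
                participant_id=daily.participant_id,
                index=idx,
                start_date=start,
                dates=seg_dates,
                daily=sub,
                valid_day_count=sub.notna().sum(),
            )
        )
        idx += 1
        start = start + timedelta(days=SEGMENT_DAYS)
    return segments


# ---------------------------------------------------------------------------
# Robust statistics


def robust_skew_sk3(values: Sequence[float]) -> float:
    """Quantile/moment hybrid robust skewness (Groeneveld–Meeden form):

        sk3 = (mean − median) / mean(|x − median|)

    Zero for exactly symmetric samples. A constant sample is symmetric, so
    a vanishing denominator with a vanishing numerator yields 0; a vanishing
    denominator alone yields MISSING. Requires ≥ 3 present values.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        return MISSING
    med = float(np.median(x))
    denom = float(np.abs(x - med).mean())
    num = float(x.mean() - med)
    if denom < 1e-12:
        return 0.0 if abs(num) < 1e-12 else MISSING
    return num / denom


def _tail_mean(x_sorted: np.ndarray, alpha: float, upper: bool) -> float:
    """Mean of the upper/lower alpha-fraction of order statistics.

    Uses fractional weighting of the boundary order statistic so the
    estimator varies smoothly with n·alpha.
    """
    n = x_sorted.size
    k = alpha * n
    f = int(math.floor(k))
    frac = k - f
    if upper:
        total = x_sorted[n - f:].sum() if f else 0.0
        if frac > 0:
            total += frac * x_sorted[n - f - 1]
    else:
        total = x_sorted[:f].sum() if f else 0.0
        if frac > 0:
            total += frac * x_sorted[f]
    return float(total) / k


def robust_kurt_kr3(
    values: Sequence[float],
    centering: float = KR3_CENTERING,
    min_n: int = KR3_MIN_N,
) -> float:
    """Hogg-style robust kurtosis:

        kr3 = (U_.05 − L_.05) / (U_.5 − L_.5) − c

    where U_a/L_a are means of the upper/lower a-fraction of order
    statistics and c = 2.59 centres the estimator at ~0 for the normal
    distribution. Requires ≥ ``min_n`` present values for the 5% tail means
    to be meaningful.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        return MISSING
    xs = np.sort(x)
    denom = _tail_mean(xs, 0.5, True) - _tail_mean(xs, 0.5, False)
    if abs(denom) < 1e-12:
        return MISSING
    num = _tail_mean(xs, 0.05, True) - _tail_mean(xs, 0.05, False)
    return num / denom - centering


def summarize(values: Sequence[float], statset: SummaryStatSet | None = None) -> dict:
    """Descriptive statistics over the present values of one segment.

    Quantiles use linear interpolation between closest order statistics;
    coefvar is the (n−1)-denominator SD over the mean (MISSING for a ~0
    mean). With no present values everything is MISSING; with exactly one,
    only mean and q50 are defined.
    """
    statset = statset or SummaryStatSet()
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    out = dict.fromkeys(statset.stats, MISSING)
    if x.size == 0:
        return out
    if x.size == 1:
        v = float(x[0])
        for s in ("mean", "q50"):
            if s in out:
                out[s] = v
        return out
    qnames = [s for s in statset.stats if s in _QUANTILE_STATS]
    if qnames or "iqr" in out:
        need = sorted({_QUANTILE_STATS[s] for s in qnames} | {0.25, 0.75})
        qv = dict(zip(need, np.quantile(x, need, method="linear")))
        for s in qnames:
            out[s] = float(qv[_QUANTILE_STATS[s]])
        if "iqr" in out:
            out["iqr"] = float(qv[0.75] - qv[0.25])
    mean = float(x.mean())
    if "mean" in out:
        out["mean"] = mean
    if "coefvar" in out:
        sd = float(x.std(ddof=1))
        out["coefvar"] = MISSING if abs(mean) < 1e-12 else sd / mean
    if "sk3" in out:
        out["sk3"] = robust_skew_sk3(x)
    if "kr3" in out:
        out["kr3"] = robust_kurt_kr3(x)
    return out


# ---------------------------------------------------------------------------
# Exhaust vectors


def exhaust_columns(
    reg: Sequence[BaseMeasureDef] | None = None,
    statset: SummaryStatSet | None = None,
) -> list:
    """Derived-measure column ids; a pure function of (registry, statset)."""
    reg = list(reg) if reg is not None else default_registry()
    statset = statset or SummaryStatSet()
    cols = []
    for d in reg:
        if d.granularity == "per_segment":
            cols.append(d.measure_id)
        else:
            cols.extend(f"{s}_{d.measure_id}" for s in statset.stats)
    return cols


def _segment_cosinor(
    rec: HomeRecording,
    seg: BiweeklySegment,
    criteria: ValidityCriteria,
    min_days: int,
) -> dict:
    tz = rec.timezone
    start = pd.Timestamp(seg.dates[0]).tz_localize(tz)
    end = pd.Timestamp(seg.dates[-1] + timedelta(days=1)).tz_localize(tz)
    days = [d for d in split_days(rec) if seg.dates[0] <= d.date <= seg.dates[-1]]
    n_valid = sum(1 for d in days if day_validity(rec, d, "pir_door", criteria))
    out = dict.fromkeys(
        ("cosinor_mesor", "cosinor_amplitude", "cosinor_acrophase",
         "cosinor_rsquared"),
        MISSING,
    )
    if n_valid < min_days:
        return out
    t, y = binned_union_activity(rec, start, end)
    fit = fit_cosinor(t, y)
    out["cosinor_mesor"] = fit.mesor
    out["cosinor_amplitude"] = fit.amplitude
    # report peak time on the local clock of the segment's first midnight
    out["cosinor_acrophase"] = fit.acrophase
    out["cosinor_rsquared"] = fit.r_squared
    return out


def build_exhaust(
    segments: Sequence[BiweeklySegment],
    reg: Sequence[BaseMeasureDef] | None = None,
    statset: SummaryStatSet | None = None,
    min_days: int = 10,
    recording: HomeRecording | None = None,
    criteria: ValidityCriteria = ValidityCriteria(),
) -> pd.DataFrame:
    """Turn one participant's segments into exhaust vectors.

    Returns a DataFrame indexed by (participant_id, segment_index) whose
    column set depends only on (registry, statset). Base measures with fewer
    than ``min_days`` valid days in a segment contribute MISSING derivates;
    per-segment cosinor measures need ``recording`` and obey the same gate
    on valid PIR days.
    """
    reg = list(reg) if reg is not None else default_registry()
    statset = statset or SummaryStatSet()
    cols = exhaust_columns(reg, statset)
    agg_defs = [d for d in reg if d.granularity in ("daily", "nightly")]
    seg_defs = [d for d in reg if d.granularity == "per_segment"]
    rows = {}
    for seg in segments:
        unknown = [
            d.measure_id for d in agg_defs if d.measure_id not in seg.daily.columns
        ]
        if unknown:
            raise ValueError(f"registry measures absent from daily table: {unknown}")
        row = {}
        for d in agg_defs:
            vals = seg.daily[d.measure_id].to_numpy()
            if seg.valid_day_count[d.measure_id] >= min_days:
                stats = summarize(vals, statset)
            else:
                stats = dict.fromkeys(statset.stats, MISSING)
            for s, v in stats.items():
                row[f"{s}_{d.measure_id}"] = v
        if seg_defs:
            if recording is not None:
                row.update(_segment_cosinor(recording, seg, criteria, min_days))
            else:
                row.update({d.measure_id: MISSING for d in seg_defs})
        rows[(seg.participant_id, seg.index)] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if rows:
        frame = frame.reindex(columns=cols)
        frame.index = pd.MultiIndex.from_tuples(
            frame.index, names=["participant_id", "segment_index"]
        )
    else:
        frame = pd.DataFrame(
            columns=cols,
            index=pd.MultiIndex.from_tuples([], names=["participant_id",
                                                       "segment_index"]),
            dtype=float,
        )
    return frame


def extract_exhaust(
    rec: HomeRecording,
    reg: Sequence[BaseMeasureDef] | None = None,
    statset: SummaryStatSet | None = None,
    min_days: int = 10,
    criteria: ValidityCriteria = ValidityCriteria(),
) -> pd.DataFrame:
    """Full pipeline for one participant: streams → exhaust vectors."""
    from .base_measures import extract_daily

    daily = extract_daily(rec, criteria)
    segments = segment_biweekly(daily)
    return build_exhaust(
        segments, reg, statset, min_days, recording=rec, criteria=criteria
    )


def measure_source(derived_id: str,
                   reg: Sequence[BaseMeasureDef] | None = None) -> str:
    """Sensor system of a derived measure: 'pir_door' or 'bed'.

    PIR and door sensors share one hardware system (a failure usually takes
    both out), so their measures form one validity block.
    """
    reg = list(reg) if reg is not None else default_registry()
    by_id = {d.measure_id: d for d in reg}
    base = derived_id
    if base not in by_id:
        parts = derived_id.split("_", 1)
        if len(parts) == 2 and parts[0] in DEFAULT_STATS and parts[1] in by_id:
            base = parts[1]
        else:
            raise KeyError(f"unknown derived measure {derived_id!r}")
    src = by_id[base].source
    return "bed" if src == "bed" else "pir_door"
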