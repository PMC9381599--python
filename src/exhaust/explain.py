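"""Digital-biomarker discovery: SHAP aggregation and export.

The global importance of a measure m is the sum over simulation iterations
of the mean absolute SHAP value of m on that iteration's test samples:

    shap_global_m = Σ_i mean(|SHAP_m^i|)

which is additive over disjoint iteration sets and permutation-invariant.
A separate single full-data model with fixed hyperparameters backs the
beeswarm export (per-sample SHAP values for the top-k measures plus the
summed remainder); the two rankings may therefore differ slightly. SHAP
values are exact TreeSHAP contributions in log-odds units.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coa import (
    MIDPOINT_PARAMS,
    CoaDataset,
    ShapMatrix,
    make_classifier,
    shap_contributions,
)


def global_shap(
    matrices: Sequence[ShapMatrix], allow_union: bool = False
) -> pd.DataFrame:
    """Aggregate per-iteration SHAP matrices into global importances.

    Returns a DataFrame (measure_id, shap_global, rank) sorted by descending
    importance with dense ranks. A feature column absent from an iteration
    contributes 0 for that iteration (with a warning) when
    ``allow_union=True``; otherwise inconsistent columns raise.
    """
    if not matrices:
        raise ValueError("need at least one SHAP matrix")
    col_sets = [tuple(m.columns) for m in matrices]
    if len(set(col_sets)) > 1:
        if not allow_union:
            raise ValueError("inconsistent SHAP columns across iterations; "
                             "pass allow_union=True to aggregate over the union")
        warnings.warn("aggregating over the union of feature columns; "
                      "absent columns contribute 0")
    all_cols: list = []
    for cs in col_sets:
        for c in cs:
            if c not in all_cols:
                all_cols.append(c)
    totals = pd.Series(0.0, index=all_cols)
    for m in matrices:
        mean_abs = np.abs(m.values).mean(axis=0)
        totals.loc[list(m.columns)] += mean_abs
    out = totals.rename("shap_global").rename_axis("measure_id").reset_index()
    out = out.sort_values("shap_global", ascending=False, kind="mergesort")
    out["rank"] = (
        out["shap_global"].rank(method="dense", ascending=False).astype(int)
    )
    return out.reset_index(drop=True)


def fit_full_model(
    dataset: CoaDataset,
    scenario: str = "exhaust",
    params: Mapping | None = None,
    seed: int = 0,
):
    """One model over the entire dataset with fixed hyperparameters."""
    cols = dataset.scenario_columns(scenario)
    clf = make_classifier(dict(params or MIDPOINT_PARAMS), seed=seed)
    clf.fit(dataset.features[cols], dataset.labels)
    return clf, cols


def beeswarm_export(
    model, X: pd.DataFrame, top_k: int = 9
) -> pd.DataFrame:
    """Long-format beeswarm data for the top-k measures of one model.

    Rows: (sample, feature, shap_value, feature_value, order) for the top_k
    features by mean |SHAP|, plus a synthetic ``sum_of_remaining`` feature
    holding the row-sums of every other feature's SHAP values (its
    feature_value is NaN). Per-row SHAP sums plus the base value equal the
    model's log-odds output exactly.
    """
    vals, base = shap_contributions(model, X)
    cols = list(X.columns)
    if top_k > len(cols):
        warnings.warn(f"top_k={top_k} exceeds feature count {len(cols)}; clamped")
        top_k = len(cols)
    mean_abs = np.abs(vals).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    top_idx = order[:top_k]
    rest_idx = order[top_k:]
    records = []
    for rank, j in enumerate(top_idx):
        for i in range(vals.shape[0]):
            records.append({
                "sample": i,
                "feature": cols[j],
                "shap_value": float(vals[i, j]),
                "feature_value": float(X.iloc[i, j]),
                "order": rank,
            })
    remainder = vals[:, rest_idx].sum(axis=1) if len(rest_idx) else np.zeros(
        vals.shape[0]
    )
    for i in range(vals.shape[0]):
        records.append({
            "sample": i,
            "feature": "sum_of_remaining",
            "shap_value": float(remainder[i]),
            "feature_value": float("nan"),
            "order": top_k,
        })
    out = pd.DataFrame.from_records(records)
    out.attrs["base_value"] = base
    return out


def group_average_exhaust(
    vectors: pd.DataFrame, labels: Mapping[str, int]
) -> pd.DataFrame:
    """Group-averaged z-normalised exhaust (heatmap data layer).

    Chain: per-participant mean over segments (MISSING ignored) →
    z-normalisation per measure across participants (population SD) →
    group means for the positive (label 1) and negative (label 0) outcome
    groups. Measures missing for every participant stay MISSING in both
    outputs.
    """
    lab = pd.Series(labels)
    per_pid = vectors.groupby(level="participant_id").mean()
    per_pid = per_pid.loc[per_pid.index.isin(lab.index)]
    lab = lab.loc[per_pid.index]
    if lab.nunique() < 2:
        raise ValueError("need at least one participant per outcome group")
    mu = per_pid.mean()
    sd = per_pid.std(ddof=0)
    z = (per_pid - mu) / sd.replace(0.0, np.nan)
    out = pd.DataFrame({
        "mean_positive_group": z.loc[lab == 1].mean(),
        "mean_negative_group": z.loc[lab == 0].mean(),
    })
    out.index.name = "measure_id"
    return out
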