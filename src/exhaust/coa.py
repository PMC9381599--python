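"""Machine-learning digital clinical outcome assessments.

Builds labeled datasets by joining exhaust vectors to demographics and a
dichotomized clinical label (standard geriatric cut-offs: TUG ≥ 12 s and
POMA < 19 for fall risk, EFS > 5 for frailty, GDS ≥ 5 for depression,
MoCA < 23 for cognitive impairment), then evaluates a gradient-boosted
tree classifier (XGBoost, native missing-value handling) with a repeated
participant-level 70/30 stratified resampling protocol: hyperparameters are
tuned per iteration with inner stratified 3-fold cross-validation and
random search, segments are the training rows, and test predictions are
soft-voted per participant before ROC AUC / PrAUC are computed. Per-model
SHAP matrices are retained for the global-importance aggregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .aggregation import measure_source

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # negative health outcome


@dataclass(frozen=True)
class AssessmentRecord:
    participant_id: str
    assessment: str
    date: object
    score: float

    def __post_init__(self):
        if self.assessment not in ("TUG", "POMA", "EFS", "GDS", "MoCA"):
            raise ValueError(f"unknown assessment {self.assessment!r}")
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass(frozen=True)
class CutoffRule:
    assessment: str
    comparator: str  # ge | gt | lt
    threshold: float
    outcome_name: str

    def applies(self, score: float) -> int:
        if self.comparator == "ge":
            return int(score >= self.threshold)
        if self.comparator == "gt":
            return int(score > self.threshold)
        if self.comparator == "lt":
            return int(score < self.threshold)
        raise ValueError(f"unknown comparator {self.comparator!r}")


DEFAULT_CUTOFFS = {
    "TUG": CutoffRule("TUG", "ge", 12.0, "fall_risk"),
    "POMA": CutoffRule("POMA", "lt", 19.0, "fall_risk"),
    "EFS": CutoffRule("EFS", "gt", 5.0, "frailty"),
    "GDS": CutoffRule("GDS", "ge", 5.0, "depression"),
    "MoCA": CutoffRule("MoCA", "lt", 23.0, "mci"),
}

DEMOGRAPHIC_FEATURES = ("age", "sex", "cohort")


@dataclass
class CoaDataset:
    """Exhaust vectors + demographics + one dichotomized label per participant."""

    features: pd.DataFrame  # index (participant_id, segment_index)
    labels: pd.Series       # per row, broadcast from the participant label
    participant_labels: pd.Series  # per participant
    feature_sources: dict   # feature -> pir_door | bed | demographics
    assessment: str
    matched_assessment_date: pd.Series | None = None

    @property
    def participants(self) -> np.ndarray:
        return self.features.index.get_level_values("participant_id").to_numpy()

    def scenario_columns(self, scenario: str) -> list:
        demo = [c for c in self.features.columns
                if self.feature_sources[c] == "demographics"]
        exh = [c for c in self.features.columns
               if self.feature_sources[c] != "demographics"]
        if scenario == "demographics":
            return demo
        if scenario == "exhaust":
            return exh
        if scenario == "both":
            return exh + demo
        raise ValueError(f"unknown scenario {scenario!r}")


def dichotomize(scores: Sequence[float], rule: CutoffRule) -> int:
    """Average a participant's scores, then apply the cut-off comparator."""
    vals = [s.score if isinstance(s, AssessmentRecord) else float(s)
            for s in scores]
    if not vals:
        raise ValueError("dichotomize needs at least one score")
    return rule.applies(float(np.mean(vals)))


def _encode_demographics(demographics: pd.DataFrame) -> pd.DataFrame:
    demo = demographics.set_index("participant_id")
    enc = pd.DataFrame(index=demo.index)
    enc["age"] = demo["age"].astype(float)
    enc["sex"] = (demo["sex"].astype(str) == "male").astype(float)
    enc["cohort"] = (demo["cohort"].astype(str) == "cohort2").astype(float)
    return enc


def match_labels(
    vectors: pd.DataFrame,
    assessments: pd.DataFrame,
    assessment: str,
    rule: CutoffRule | None = None,
    demographics: pd.DataFrame | None = None,
    exclude_measures: Sequence[str] = (),
    segment_dates: Mapping[tuple, object] | None = None,
) -> CoaDataset:
    """Join exhaust vectors with a dichotomized assessment label.

    The participant-level label averages all of a participant's scores for
    the assessment and applies the cut-off. Each segment is additionally
    annotated with its temporally closest assessment date (ties broken
    toward the earlier assessment). Participants without any record of the
    assessment are dropped (logged).
    """
    rule = rule or DEFAULT_CUTOFFS[assessment]
    sub = assessments[assessments["assessment"] == assessment]
    by_pid = sub.groupby("participant_id")
    labels = by_pid["score"].apply(lambda s: rule.applies(float(s.mean())))

    vec_pids = vectors.index.get_level_values("participant_id")
    have = vec_pids.isin(labels.index)
    dropped = vec_pids[~have].unique()
    if len(dropped):
        logger.info(
            "%s: dropped %d participants without assessment records",
            assessment, len(dropped),
        )
    feats = vectors.loc[have].copy()
    feats = feats.drop(columns=[c for c in exclude_measures if c in feats],
                       errors="ignore")
    sources = {c: measure_source(c) for c in feats.columns}

    # per-segment closest assessment date (auxiliary annotation); needs the
    # caller to say when each segment was recorded
    if segment_dates is not None:
        nearest = match_segment_assessment(segment_dates, assessments, assessment)
        matched_dates = pd.Series(
            [nearest.get(key, pd.NaT) for key in feats.index], index=feats.index
        )
    else:
        matched_dates = None

    if demographics is not None:
        enc = _encode_demographics(demographics)
        for col in enc.columns:
            feats[col] = enc[col].reindex(
                feats.index.get_level_values("participant_id")
            ).to_numpy()
            sources[col] = "demographics"

    row_labels = pd.Series(
        labels.reindex(feats.index.get_level_values("participant_id")).to_numpy(),
        index=feats.index, name="label",
    ).astype(int)
    return CoaDataset(
        features=feats,
        labels=row_labels,
        participant_labels=labels.loc[labels.index.isin(vec_pids)].astype(int),
        feature_sources=sources,
        assessment=assessment,
        matched_assessment_date=matched_dates,
    )


def match_segment_assessment(
    segment_dates: Mapping[tuple, object], assessments: pd.DataFrame,
    assessment: str,
) -> dict:
    """Closest-in-time assessment per segment; equidistant → earlier wins."""
    sub = assessments[assessments["assessment"] == assessment]
    by_pid = {
        pid: sorted(pd.to_datetime(g["date"]).tolist())
        for pid, g in sub.groupby("participant_id")
    }
    out = {}
    for key, date in segment_dates.items():
        pid = key[0]
        ds = by_pid.get(pid)
        if not ds:
            continue
        d = pd.Timestamp(date)
        best = min(ds, key=lambda x: (abs((x - d).total_seconds()), x))
        out[key] = best
    return out


def filter_valid_segments(
    dataset: CoaDataset,
    max_missing_frac: float = 0.30,
    rule: str = "fig5",
) -> CoaDataset:
    """Drop segments with too much missingness per sensor-system block.

    ``rule='fig5'`` keeps segments whose missing fraction is < ``max_missing
    _frac`` within *each* system block (default); ``rule='methods'`` keeps
    segments where at least ``max_missing_frac`` of each block is present
    (i.e. missing ≤ 1 − 0.30).
    """
    blocks = {}
    for sys_name in ("pir_door", "bed"):
        cols = [c for c, s in dataset.feature_sources.items() if s == sys_name]
        if cols:
            blocks[sys_name] = cols
    keep = pd.Series(True, index=dataset.features.index)
    for cols in blocks.values():
        frac = dataset.features[cols].isna().mean(axis=1)
        if rule == "fig5":
            keep &= frac < max_missing_frac
        elif rule == "methods":
            keep &= (1.0 - frac) >= max_missing_frac
        else:
            raise ValueError(f"unknown rule {rule!r}")
    feats = dataset.features.loc[keep]
    kept_pids = feats.index.get_level_values("participant_id").unique()
    return CoaDataset(
        features=feats,
        labels=dataset.labels.loc[keep],
        participant_labels=dataset.participant_labels.loc[
            dataset.participant_labels.index.isin(kept_pids)
        ],
        feature_sources=dataset.feature_sources,
        assessment=dataset.assessment,
        matched_assessment_date=(
            dataset.matched_assessment_date.loc[keep]
            if dataset.matched_assessment_date is not None else None
        ),
    )


def screen_cohort_bias(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    auc_threshold: float = 0.95,
    manual_exclude: Sequence[str] = (),
) -> list:
    """Flag measures that essentially identify cohort membership.

    Computes the single-feature ranking AUC of each measure for the cohort
    indicator (symmetric: max(AUC, 1−AUC), missing values excluded) and
    flags measures at or above ``auc_threshold``, plus anything on the
    manual exclusion list.
    """
    demo = demographics.set_index("participant_id")
    cohorts = demo["cohort"].astype(str)
    if cohorts.nunique() < 2:
        warnings.warn("single cohort present; no bias screen possible")
        return sorted(set(manual_exclude) & set(features.columns))
    y_all = (cohorts == sorted(cohorts.unique())[-1]).astype(int)
    pids = features.index.get_level_values("participant_id")
    y = y_all.reindex(pids).to_numpy()
    flagged = set(m for m in manual_exclude if m in features.columns)
    for col in features.columns:
        x = features[col].to_numpy()
        good = np.isfinite(x)
        if good.sum() < 4 or len(set(y[good])) < 2:
            continue
        auc = roc_auc_score(y[good], x[good])
        if max(auc, 1.0 - auc) >= auc_threshold:
            flagged.add(col)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Evaluation protocol


def participant_soft_vote(segment_probs: Mapping[str, Sequence[float]]) -> dict:
    """Average segment-level probabilities into one score per participant."""
    out = {}
    for pid, probs in segment_probs.items():
        probs = list(probs)
        if not probs:
            raise ValueError(f"participant {pid} has no segment predictions")
        out[pid] = float(np.mean(probs))
    return out


def evaluate(y_true: Sequence[int], y_prob: Sequence[float]) -> tuple:
    """Participant-level ROC AUC and PrAUC (positive = negative outcome)."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if len(set(y_true.tolist())) < 2:
        warnings.warn("one class only; metrics undefined")
        return float("nan"), float("nan")
    return (
        float(roc_auc_score(y_true, y_prob)),
        float(average_precision_score(y_true, y_prob, pos_label=POSITIVE_LABEL)),
    )


def summarize_ci(
    metric_samples: Sequence[float], level: float = 0.95, method: str = "normal"
) -> tuple:
    """Mean and CI half-width over iteration metrics (`mean ± hw` style)."""
    from scipy import stats as sp_stats

    x = np.asarray(list(metric_samples), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mean = float(x.mean())
    if method == "normal":
        z = float(sp_stats.norm.ppf(0.5 + level / 2.0))
        hw = z * float(x.std(ddof=1)) / np.sqrt(x.size)
    elif method == "percentile":
        lo, hi = np.quantile(x, [(1 - level) / 2, 0.5 + level / 2])
        hw = float((hi - lo) / 2.0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return mean, float(hw)


#: Hyperparameter search space for the gradient-boosted classifier.
DEFAULT_SEARCH_SPACE = {
    "n_estimators": ("int", 50, 500),
    "max_depth": ("int", 2, 8),
    "learning_rate": ("log", 0.01, 0.3),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample_bytree": ("uniform", 0.3, 1.0),
    "min_child_weight": ("int", 1, 10),
}

#: Midpoints of the search space; used for single full-data models.
MIDPOINT_PARAMS = {
    "n_estimators": 275, "max_depth": 5, "learning_rate": 0.055,
    "subsample": 0.75, "colsample_bytree": 0.65, "min_child_weight": 5,
}


def _sample_params(rng, space: Mapping) -> dict:
    out = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        elif kind == "uniform":
            out[name] = float(rng.uniform(lo, hi))
        elif kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    return out


def make_classifier(params: Mapping, seed: int = 0) -> xgb.XGBClassifier:
    # max_bin=16: datasets here are a few hundred segments, so coarse
    # histogram bins lose no split resolution and cut fit time severalfold
    return xgb.XGBClassifier(
        **params,
        tree_method="hist",
        max_bin=16,
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        verbosity=0,
    )


@dataclass
class ShapMatrix:
    """Per-iteration SHAP contributions (log-odds) on the test samples."""

    iteration: int
    values: np.ndarray        # (n_samples, n_features)
    columns: list
    base_value: float

    def __post_init__(self):
        if self.values.shape[1] != len(self.columns):
            raise ValueError("SHAP column count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SHAP values must be finite")


@dataclass
class SimulationResult:
    assessment: str
    scenario: str
    roc_auc: list
    pr_auc: list
    shap_matrices: list
    feature_names: list
    n_resampled: int = 0
    #: per-iteration (train participants, test participants) audit trail
    split_log: list = field(default_factory=list)

    def summary(self, level: float = 0.95, method: str = "normal") -> dict:
        out = {}
        for name, samples in (("roc_auc", self.roc_auc), ("pr_auc", self.pr_auc)):
            vals = [v for v in samples if np.isfinite(v)]
            mean, hw = summarize_ci(vals, level, method)
            out[name] = {"mean": mean, "ci_half_width": hw}
        return out


def shap_contributions(model: xgb.XGBClassifier, X: pd.DataFrame) -> tuple:
    """Exact TreeSHAP contributions and base value for a fitted model."""
    dm = xgb.DMatrix(X, missing=np.nan)
    contribs = model.get_booster().predict(dm, pred_contribs=True)
    return contribs[:, :-1], float(contribs[0, -1])


def run_simulation(
    dataset: CoaDataset,
    scenario: str = "exhaust",
    n_iterations: int = 100,
    train_frac: float = 0.70,
    cv_folds: int = 3,
    search_trials: int = 50,
    seed: int = 0,
    search_space: Mapping | None = None,
    collect_shap: bool = True,
) -> SimulationResult:
    """Repeated participant-stratified 70/30 evaluation of one scenario.

    Per iteration: participants are split label-stratified into train/test
    (all segments of a participant on one side — asserted); random-search
    hyperparameter tuning with inner participant-level stratified K-fold CV
    (selection metric: segment-level ROC AUC); refit on the full training
    split; test-segment probabilities soft-voted per participant; ROC AUC
    and PrAUC recorded. Fully reproducible from ``seed``.
    """
    space = dict(search_space or DEFAULT_SEARCH_SPACE)
    cols = dataset.scenario_columns(scenario)
    X = dataset.features[cols]
    # structurally all-missing columns (e.g. kr3 derivates on 14-day
    # segments) carry no splits; dropping them up front saves fit time
    informative = [c for c in cols if X[c].notna().any()]
    if len(informative) < len(cols):
        logger.info("dropping %d all-missing feature columns",
                    len(cols) - len(informative))
        cols = informative
        X = X[cols]
    pids_series = pd.Series(
        dataset.features.index.get_level_values("participant_id"),
        index=dataset.features.index,
    )
    plabels = dataset.participant_labels
    participants = np.asarray(sorted(plabels.index))
    y_part = plabels.loc[participants].to_numpy()
    if min(np.bincount(y_part, minlength=2)) < 2:
        raise ValueError("need at least 2 participants per class")

    rng = np.random.default_rng(seed)
    roc_list, pr_list, shap_list = [], [], []
    split_log = []
    n_resampled = 0
    for it in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(20):
            train_p, test_p = train_test_split(
                participants,
                train_size=train_frac,
                stratify=y_part,
                random_state=(it_seed + attempt) % (2**31 - 1),
            )
            ytr = plabels.loc[train_p]
            yte = plabels.loc[test_p]
            if ytr.nunique() == 2 and yte.nunique() == 2:
                break
            n_resampled += 1
        else:
            raise ValueError("unsatisfiable stratification")
        assert not set(train_p) & set(test_p)
        split_log.append((frozenset(train_p), frozenset(test_p)))

        tr_mask = pids_series.isin(train_p).to_numpy()
        te_mask = pids_series.isin(test_p).to_numpy()
        X_tr, y_tr = X.loc[tr_mask], dataset.labels.loc[tr_mask]
        X_te = X.loc[te_mask]

        best_params, best_score = None, -np.inf
        it_rng = np.random.default_rng(it_seed)
        folds = _participant_folds(train_p, plabels, cv_folds, it_seed)
        for trial in range(search_trials):
            params = _sample_params(it_rng, space)
            scores = []
            for fold_tr, fold_va in folds:
                m_tr = pids_series.loc[tr_mask].isin(fold_tr).to_numpy()
                m_va = pids_series.loc[tr_mask].isin(fold_va).to_numpy()
                yva = y_tr[m_va]
                if len(set(yva.tolist())) < 2:
                    continue
                clf = make_classifier(params, seed=it_seed % (2**31 - 1))
                clf.fit(X_tr.loc[m_tr], y_tr[m_tr])
                p = clf.predict_proba(X_tr.loc[m_va])[:, 1]
                scores.append(roc_auc_score(yva, p))
            score = float(np.mean(scores)) if scores else -np.inf
            if best_params is None or score > best_score:
                best_score, best_params = score, params

        clf = make_classifier(best_params, seed=it_seed % (2**31 - 1))
        clf.fit(X_tr, y_tr)
        probs = clf.predict_proba(X_te)[:, 1]
        te_pids = pids_series.loc[te_mask].to_numpy()
        by_pid: dict[str, list] = {}
        for pid, p in zip(te_pids, probs):
            by_pid.setdefault(pid, []).append(float(p))
        voted = participant_soft_vote(by_pid)
        order = sorted(voted)
        roc, pr = evaluate(
            plabels.loc[order].to_numpy(), [voted[pid] for pid in order]
        )
        roc_list.append(roc)
        pr_list.append(pr)
        if collect_shap:
            vals, base = shap_contributions(clf, X_te)
            shap_list.append(
                ShapMatrix(iteration=it, values=vals, columns=list(cols),
                           base_value=base)
            )
    return SimulationResult(
        assessment=dataset.assessment, scenario=scenario,
        roc_auc=roc_list, pr_auc=pr_list, shap_matrices=shap_list,
        feature_names=list(cols), n_resampled=n_resampled,
        split_log=split_log,
    )


def _participant_folds(train_p, plabels, cv_folds: int, seed: int) -> list:
    """Label-stratified participant-level folds, expanded lazily.

    Fold count is clamped to the minority-class participant count; with
    fewer than 2 participants per class no CV is possible and the first
    sampled hyperparameter set wins (logged).
    """
    train_p = np.asarray(train_p)
    y = plabels.loc[train_p].to_numpy()
    n_min = int(min(np.bincount(y, minlength=2)))
    if n_min < 2:
        logger.warning("too few participants per class for inner CV; "
                       "hyperparameter search degenerates to first trial")
        return []
    skf = StratifiedKFold(n_splits=min(cv_folds, n_min), shuffle=True,
                          random_state=seed % (2**31 - 1))
    folds = []
    for tr_idx, va_idx in skf.split(train_p, y):
        folds.append((set(train_p[tr_idx]), set(train_p[va_idx])))
    return folds
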