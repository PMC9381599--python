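"""Dataset assembly, cut-offs, evaluation protocol and metrics."""

import numpy as np
import pandas as pd
import pytest

from exhaust import coa
from exhaust.coa import (
    DEFAULT_CUTOFFS,
    CoaDataset,
    dichotomize,
    evaluate,
    filter_valid_segments,
    match_labels,
    match_segment_assessment,
    participant_soft_vote,
    run_simulation,
    screen_cohort_bias,
    summarize_ci,
)


def brute_force_auc(y, p):
    """Pairwise pos/neg comparison AUC with half-credit ties."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestDichotomize:
    @pytest.mark.parametrize("assessment,score,label", [
        ("TUG", 12.0, 1), ("TUG", 11.9, 0),
        ("POMA", 19.0, 0), ("POMA", 18.9, 1),
        ("EFS", 5.0, 0), ("EFS", 5.1, 1),
        ("GDS", 5.0, 1), ("GDS", 4.9, 0),
        ("MoCA", 23.0, 0), ("MoCA", 22.9, 1),
    ])
    def test_cutoff_boundaries(self, assessment, score, label):
        assert dichotomize([score], DEFAULT_CUTOFFS[assessment]) == label

    @pytest.mark.parametrize("assessment,scores,label", [
        ("TUG", [14.5], 1), ("MoCA", [20.5], 1), ("GDS", [3.1], 0),
    ])
    def test_typical_cohort_means(self, assessment, scores, label):
        assert dichotomize(scores, DEFAULT_CUTOFFS[assessment]) == label

    def test_multiple_scores_averaged_first(self):
        # 11 and 14 average to 12.5 ≥ 12 → fall risk
        assert dichotomize([11.0, 14.0], DEFAULT_CUTOFFS["TUG"]) == 1

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            dichotomize([], DEFAULT_CUTOFFS["TUG"])


def _vectors(data, pids):
    idx = pd.MultiIndex.from_tuples(
        [(pid, i) for pid in pids for i in range(len(data) // len(pids))],
        names=["participant_id", "segment_index"],
    )
    cols = ["mean_total_activity", "mean_sleep_duration"]
    return pd.DataFrame(np.asarray(data, dtype=float), index=idx, columns=cols)


class TestMatchLabels:
    def _assessments(self):
        return pd.DataFrame([
            {"participant_id": "a", "assessment": "MoCA",
             "date": pd.Timestamp("2017-04-20"), "score": 20.0},
            {"participant_id": "a", "assessment": "MoCA",
             "date": pd.Timestamp("2017-06-20"), "score": 24.0},
            {"participant_id": "b", "assessment": "MoCA",
             "date": pd.Timestamp("2017-05-01"), "score": 28.0},
        ])

    def test_participant_label_from_averaged_scores(self):
        vecs = _vectors([[1, 2], [3, 4], [5, 6], [7, 8]], ["a", "b"])
        ds = match_labels(vecs, self._assessments(), "MoCA")
        # a: mean 22 < 23 → 1; b: 28 → 0
        assert ds.participant_labels.to_dict() == {"a": 1, "b": 0}
        assert (ds.labels.loc["a"] == 1).all()

    def test_participant_without_assessment_dropped(self):
        vecs = _vectors([[1, 2], [3, 4], [5, 6], [7, 8]], ["a", "c"])
        ds = match_labels(vecs, self._assessments(), "MoCA")
        assert set(ds.participants) == {"a"}

    def test_nearest_assessment_ties_break_earlier(self):
        nearest = match_segment_assessment(
            {("a", 0): pd.Timestamp("2017-05-20")}, self._assessments(), "MoCA")
        # 2017-05-20 is 30 days from both 04-20 and 06-20 → earlier wins
        assert nearest[("a", 0)] == pd.Timestamp("2017-04-20")

    def test_closest_in_time_matching(self):
        nearest = match_segment_assessment(
            {("a", 0): pd.Timestamp("2017-05-01")}, self._assessments(), "MoCA")
        assert nearest[("a", 0)] == pd.Timestamp("2017-04-20")


class TestFilterValidSegments:
    def _dataset(self, rows, sources):
        idx = pd.MultiIndex.from_tuples(
            [("p", i) for i in range(len(rows))],
            names=["participant_id", "segment_index"],
        )
        feats = pd.DataFrame(rows, index=idx,
                             columns=list(sources))
        labels = pd.Series(1, index=idx)
        return CoaDataset(
            features=feats, labels=labels,
            participant_labels=pd.Series({"p": 1}),
            feature_sources=dict(sources), assessment="MoCA",
        )

    def test_complete_segment_kept_all_bed_missing_dropped(self):
        sources = {"a": "pir_door", "b": "pir_door", "c": "bed", "d": "bed"}
        ds = self._dataset(
            [[1, 1, 1, 1], [1, 1, np.nan, np.nan]], sources)
        out = filter_valid_segments(ds)
        assert list(out.features.index.get_level_values(1)) == [0]

    def test_boundary_just_below_30_percent_kept(self):
        # 10 features per block, 2 missing = 20% < 30% → kept; 3 = 30% → dropped
        sources = {f"p{i}": "pir_door" for i in range(10)}
        sources.update({f"b{i}": "bed" for i in range(10)})
        ok = [1.0] * 8 + [np.nan] * 2 + [1.0] * 8 + [np.nan] * 2
        bad = [1.0] * 7 + [np.nan] * 3 + [1.0] * 10
        ds = self._dataset([ok, bad], sources)
        out = filter_valid_segments(ds)
        assert list(out.features.index.get_level_values(1)) == [0]

    def test_methods_text_variant_is_looser(self):
        sources = {f"p{i}": "pir_door" for i in range(10)}
        sources.update({f"b{i}": "bed" for i in range(10)})
        half = [1.0] * 5 + [np.nan] * 5 + [1.0] * 5 + [np.nan] * 5
        ds = self._dataset([half], sources)
        assert len(filter_valid_segments(ds, rule="fig5").features) == 0
        assert len(filter_valid_segments(ds, rule="methods").features) == 1


class TestCohortBiasScreen:
    def test_cohort_indicator_feature_flagged(self):
        rng = np.random.default_rng(0)
        pids = [f"p{i}" for i in range(40)]
        demo = pd.DataFrame({
            "participant_id": pids,
            "age": 80, "sex": "female",
            "cohort": ["cohort1"] * 20 + ["cohort2"] * 20,
        })
        idx = pd.MultiIndex.from_tuples(
            [(p, 0) for p in pids], names=["participant_id", "segment_index"])
        biased = np.r_[np.zeros(20), np.ones(20)] + rng.normal(0, 0.01, 40)
        clean = rng.normal(0, 1, 40)
        feats = pd.DataFrame({"biased_m": biased, "clean_m": clean}, index=idx)
        flagged = screen_cohort_bias(feats, demo)
        assert "biased_m" in flagged
        assert "clean_m" not in flagged

    def test_manual_exclusion_respected(self):
        pids = ["a", "b"]
        demo = pd.DataFrame({"participant_id": pids, "age": 80,
                             "sex": "f", "cohort": ["cohort1", "cohort2"]})
        idx = pd.MultiIndex.from_tuples(
            [(p, 0) for p in pids], names=["participant_id", "segment_index"])
        feats = pd.DataFrame({"q50_fridge_door_tod_middle": [1.0, 2.0]},
                             index=idx)
        flagged = screen_cohort_bias(
            feats, demo, manual_exclude=["q50_fridge_door_tod_middle"])
        assert flagged == ["q50_fridge_door_tod_middle"]

    def test_single_cohort_warns_and_flags_nothing(self):
        demo = pd.DataFrame({"participant_id": ["a"], "age": 80,
                             "sex": "f", "cohort": ["cohort1"]})
        idx = pd.MultiIndex.from_tuples(
            [("a", 0)], names=["participant_id", "segment_index"])
        feats = pd.DataFrame({"m": [1.0]}, index=idx)
        with pytest.warns(UserWarning, match="single cohort"):
            assert screen_cohort_bias(feats, demo) == []


class TestSoftVoteAndMetrics:
    @pytest.mark.parametrize("probs,expected", [
        ([0.2, 0.8], 0.5), ([0.7], 0.7), ([0.1, 0.2, 0.3], 0.2),
    ])
    def test_soft_vote_is_arithmetic_mean(self, probs, expected):
        assert participant_soft_vote({"p": probs})["p"] == pytest.approx(expected)

    def test_soft_vote_empty_rejected(self):
        with pytest.raises(ValueError):
            participant_soft_vote({"p": []})

    def test_perfect_separation(self):
        roc, pr = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc == 1.0 and pr == 1.0

    def test_constant_scores_give_half_auc(self):
        roc, _ = evaluate([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert roc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        roc, _ = evaluate([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert roc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, n)
            if len(set(y.tolist())) < 2:
                continue
            p = np.round(rng.random(n), 2)  # force some ties
            roc, _ = evaluate(y, p)
            assert roc == pytest.approx(brute_force_auc(y, p), abs=1e-12)

    def test_one_class_warns_and_returns_missing(self):
        with pytest.warns(UserWarning):
            roc, pr = evaluate([1, 1], [0.5, 0.6])
        assert np.isnan(roc) and np.isnan(pr)


class TestSummarizeCi:
    def test_identical_values_zero_width(self):
        mean, hw = summarize_ci([0.7] * 100)
        assert mean == pytest.approx(0.7)
        assert hw == pytest.approx(0.0, abs=1e-12)

    def test_balanced_binary_closed_form(self):
        samples = [0.0] * 50 + [1.0] * 50
        mean, hw = summarize_ci(samples)
        sd = np.std(samples, ddof=1)
        assert mean == 0.5
        assert hw == pytest.approx(1.959963985 * sd / 10.0, rel=1e-6)

    def test_width_grows_with_level(self):
        x = list(np.random.default_rng(1).normal(size=30))
        assert summarize_ci(x, level=0.99)[1] > summarize_ci(x, level=0.95)[1]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_ci([0.5])


def _toy_dataset(n_part=12, n_seg=3, n_feat=8, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    pids = [f"p{i:02d}" for i in range(n_part)]
    labels = pd.Series(([0, 1] * n_part)[:n_part], index=pids)
    idx = pd.MultiIndex.from_tuples(
        [(p, s) for p in pids for s in range(n_seg)],
        names=["participant_id", "segment_index"],
    )
    X = rng.normal(0, 1, (len(idx), n_feat))
    if informative:
        y_rows = labels.reindex(idx.get_level_values(0)).to_numpy()
        X[:, 0] += 3.0 * y_rows
    feats = pd.DataFrame(X, index=idx,
                         columns=[f"mean_f{i}" for i in range(n_feat)])
    sources = {c: "pir_door" for c in feats.columns}
    return CoaDataset(
        features=feats,
        labels=labels.reindex(idx.get_level_values(0)).set_axis(idx),
        participant_labels=labels,
        feature_sources=sources,
        assessment="MoCA",
    )


class TestRunSimulation:
    def test_no_participant_leaks_and_signal_detected(self):
        ds = _toy_dataset(informative=True, n_part=16, n_seg=4)
        res = run_simulation(ds, "exhaust", n_iterations=4, search_trials=3,
                             seed=5)
        assert len(res.roc_auc) == 4
        assert np.mean(res.roc_auc) > 0.75  # one strongly separating feature
        for m in res.shap_matrices:
            assert m.values.shape[1] == len(res.feature_names)

    def test_null_labels_give_chance_auc(self):
        ds = _toy_dataset(informative=False, n_part=16, seed=3)
        res = run_simulation(ds, "exhaust", n_iterations=10, search_trials=2,
                             seed=11, collect_shap=False)
        assert 0.25 <= float(np.mean(res.roc_auc)) <= 0.75

    def test_determinism(self):
        ds = _toy_dataset()
        a = run_simulation(ds, "exhaust", n_iterations=2, search_trials=2,
                           seed=42, collect_shap=False)
        b = run_simulation(ds, "exhaust", n_iterations=2, search_trials=2,
                           seed=42, collect_shap=False)
        assert a.roc_auc == b.roc_auc and a.pr_auc == b.pr_auc

    def test_scenario_column_selection(self):
        ds = _toy_dataset()
        ds.features["age"] = 80.0
        ds.feature_sources["age"] = "demographics"
        assert ds.scenario_columns("demographics") == ["age"]
        assert "age" not in ds.scenario_columns("exhaust")
        assert set(ds.scenario_columns("both")) == set(ds.features.columns)

    def test_too_few_participants_per_class_rejected(self):
        ds = _toy_dataset(n_part=3)
        with pytest.raises(ValueError, match="2 participants"):
            run_simulation(ds, "exhaust", n_iterations=1, search_trials=1)
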