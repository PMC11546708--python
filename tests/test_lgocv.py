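import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lipidsig as ls
from lipidsig.boruta import BorutaConfig
from lipidsig.classifiers import ClassifierSpec, default_suite, predict_score, registry
from lipidsig.errors import ConfigurationError, InsufficientDataError
from lipidsig.lgocv import IterationRecord, _rank_auc, average_prediction_matrix
from sklearn.linear_model import LogisticRegression

FAST_BORUTA = BorutaConfig(importance_kind="impurity_fast", n_iter=40, n_trees=60, seed=0)


class TestMakeSplits:
    def test_test_sizes(self):
        y = np.repeat([0, 1], 5)
        plan = ls.make_splits(y, n_iter=20, test_fraction=0.2, seed=0)
        assert all(len(te) == 2 for _, te in plan.splits)
        y = np.repeat([0, 1], 128)
        plan = ls.make_splits(y, n_iter=3, test_fraction=0.2, seed=0)
        assert all(len(te) == 51 for _, te in plan.splits)  # round(51.2)

    def test_stratification_exact_on_balanced_classes(self):
        y = np.repeat([0, 1], 5)
        plan = ls.make_splits(y, n_iter=50, test_fraction=0.2, stratified=True, seed=1)
        for _, te in plan.splits:
            assert sorted(y[te]) == [0, 1]

    def test_partition_property(self):
        y = np.repeat([0, 1], 20)
        plan = ls.make_splits(y, n_iter=10, seed=2)
        for tr, te in plan.splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 40

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            ls.make_splits(np.repeat([0, 1], 10), n_iter=1, test_fraction=0.001)


class TestVoteAndCertainty:
    def test_tie_goes_to_cancer(self):
        assert ls.ensemble_vote(np.array([1] * 9 + [0] * 9)) == 1

    def test_score_fraction(self):
        votes = np.array([1] * 10 + [0] * 8)
        assert ls.ensemble_score(votes) == pytest.approx(10 / 18)
        assert ls.ensemble_vote(votes) == 1
        assert ls.ensemble_vote(np.zeros(18)) == 0 and ls.ensemble_score(np.zeros(18)) == 0.0

    @pytest.mark.parametrize(
        "agree,expected",
        [(18, "high"), (15, "medium"), (12, "low")],
    )
    def test_certainty_levels(self, agree, expected):
        votes = np.array([1] * agree + [0] * (18 - agree))
        assert ls.certainty(votes) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(votes=st.lists(st.integers(0, 1), min_size=1, max_size=25))
    def test_certainty_consistent_with_agreement(self, votes):
        votes = np.array(votes)
        agree = max(votes.sum(), len(votes) - votes.sum()) / len(votes)
        level = ls.certainty(votes)
        if agree == 1:
            assert level == "high"
        elif agree >= 0.8:
            assert level == "medium"
        else:
            assert level == "low"


class TestNestedTune:
    def test_single_candidate_space(self):
        spec = ClassifierSpec("fixed", lambda p, s: LogisticRegression(), {})
        rng = np.random.default_rng(0)
        assert ls.nested_tune(np.zeros((10, 1)), np.repeat([0, 1], 5), spec, rng=rng) == {}

    def test_picks_the_good_candidate(self):
        """Two-candidate space where C=1 is sound and C=1e-8 collapses to the
        prior: the sound setting wins nearly always."""
        spec = ClassifierSpec(
            "logit2",
            lambda p, s: LogisticRegression(C=p["C"], max_iter=500),
            {"C": ("choice", [1e-8, 1.0])},
        )
        rng_data = np.random.default_rng(3)
        wins = 0
        for r in range(20):
            n = 80
            y = np.repeat([0, 1], n // 2)
            X = rng_data.normal(size=(n, 4))
            X[y == 1] += 1.2
            params = ls.nested_tune(
                X, y, spec, n_nested=8, tune_len=6, rng=np.random.default_rng(100 + r)
            )
            wins += params["C"] == 1.0
        assert wins >= 18

    def test_deterministic_under_rng(self):
        spec = registry("smoke")["logistic"]
        X = np.random.default_rng(1).normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        a = ls.nested_tune(X, y, spec, n_nested=4, tune_len=4, rng=np.random.default_rng(5))
        b = ls.nested_tune(X, y, spec, n_nested=4, tune_len=4, rng=np.random.default_rng(5))
        assert a == b


@pytest.fixture(scope="module")
def small_discovery(planted_xy):
    X, y, names, truth = planted_xy
    suite = default_suite("smoke")
    plan = ls.make_splits(y, n_iter=8, seed=11)
    records = ls.discovery_run(X, y, names, suite, FAST_BORUTA, plan,
                               n_nested=3, tune_len=2)
    return X, y, names, truth, suite, plan, records


class TestDiscovery:
    def test_no_leakage_audit(self, small_discovery):
        """Feature selection and tuning consumed only training rows."""
        _, _, _, _, _, plan, records = small_discovery
        violations = 0
        for r, (tr, te) in zip(records, plan.splits):
            for stage in ("selection_rows", "tuning_rows"):
                rows = r.audit[stage]
                if not np.array_equal(np.sort(rows), np.sort(tr)):
                    violations += 1
                if len(np.intersect1d(rows, te)):
                    violations += 1
        assert violations == 0

    def test_selection_frequency_ranks_planted_first(self, small_discovery):
        _, _, names, truth, _, _, records = small_discovery
        freq = ls.selection_frequency(records, names)
        top = ls.top_k(freq, 5)
        assert set(top) == set(truth.informative_lipids)
        never = freq.loc[freq["proportion"] == 0]
        assert (never["rank"] > 5).all()

    def test_strong_signal_accuracy(self, small_discovery):
        _, _, _, _, _, _, records = small_discovery
        accs = [r.ensemble_metrics["accuracy"] for r in records]
        assert np.mean(accs) > 0.8

    def test_average_prediction_matrix_bookkeeping(self, small_discovery):
        X, y, _, _, suite, _, records = small_discovery
        avg = average_prediction_matrix(records, len(y))
        assert set(avg.columns) == {s.name for s in suite} | {"ensemble"}
        sub = avg.dropna()
        assert ((sub >= 0) & (sub <= 1)).all().all()

    def test_top_k_rejects_too_large_k(self, small_discovery):
        _, _, names, _, _, _, records = small_discovery
        freq = ls.selection_frequency(records, names)
        with pytest.raises(ConfigurationError):
            ls.top_k(freq, int((freq["proportion"] > 0).sum()) + 1)


def _fake_record(i, accs, params):
    metrics = {n: {"accuracy": a, "sensitivity": a, "specificity": a} for n, a in accs.items()}
    return IterationRecord(
        index=i, train_idx=np.arange(5), test_idx=np.arange(5, 8),
        selected_features=[], fallback_all=False,
        boruta_mean_importance=pd.Series(dtype=float),
        classifier_params={n: {"p": params} for n in accs},
        classifier_votes={}, classifier_metrics=metrics,
        ensemble_fraction=np.zeros(3), ensemble_pred=np.zeros(3, int),
        ensemble_metrics={}, audit={},
    )


class TestPickFinalHyperparams:
    def test_hand_worked_rank_median_rule(self):
        """Ranks (2,1,1) with accuracies (0.8, 0.7, 0.9): among the rank-1
        runs {0.7, 0.9} the lower median 0.7 wins."""
        records = [
            _fake_record(0, {"A": 0.8, "B": 0.9}, params="it0"),
            _fake_record(1, {"A": 0.7, "B": 0.6}, params="it1"),
            _fake_record(2, {"A": 0.9, "B": 0.8}, params="it2"),
        ]
        assert ls.pick_final_hyperparams(records, "A") == {"p": "it1"}

    def test_single_iteration(self):
        records = [_fake_record(0, {"A": 0.5}, params="only")]
        assert ls.pick_final_hyperparams(records, "A") == {"p": "only"}

    def test_identical_iterations_pick_first(self):
        records = [_fake_record(i, {"A": 0.5, "B": 0.4}, params=f"it{i}") for i in range(4)]
        assert ls.pick_final_hyperparams(records, "A") == {"p": "it0"}


class TestFinalEvaluation:
    def test_strong_signal_summary(self, small_discovery):
        X, y, names, truth, suite, plan, records = small_discovery
        fixed = {s.name: ls.pick_final_hyperparams(records, s.name) for s in suite}
        summary = ls.final_evaluation(X, y, names, list(truth.informative_lipids),
                                      suite, fixed, plan)
        assert summary.accuracy_mean > 0.8
        assert summary.auc_mean > 0.9
        # summary mean equals the mean of per-iteration metrics
        assert summary.accuracy_mean == pytest.approx(
            summary.per_iteration["accuracy"].mean()
        )
        # certainty percentages sum to 100 within each outcome class
        for outcome in ("correct", "incorrect"):
            tot = summary.certainty.loc[outcome]["percent"].sum()
            assert tot == pytest.approx(100.0, abs=0.1) or tot == 0.0

    def test_unanimous_suite_matches_single_classifier(self, planted_xy):
        """Identical classifiers vote identically; ensemble metrics equal
        each member's metrics exactly."""
        X, y, names, truth = planted_xy
        spec = registry("smoke")["logistic"]
        clones = [
            ClassifierSpec(f"c{i}", spec.factory, {}) for i in range(3)
        ]
        plan = ls.make_splits(y, n_iter=4, seed=3)
        fixed = {c.name: {"C": 1.0} for c in clones}
        for c in clones:  # factory expects a C parameter
            fixed[c.name] = {"C": 1.0}
        summary = ls.final_evaluation(X, y, names, list(truth.informative_lipids),
                                      clones, fixed, plan)
        for name in ("c0", "c1", "c2"):
            row = summary.classifier_means.loc[name]
            assert row["accuracy"] == pytest.approx(summary.accuracy_mean)
        # unanimity means every prediction is high-certainty
        assert summary.certainty.loc[("correct", "high"), "percent"] == pytest.approx(100.0)


class TestSensitivity:
    def test_flat_beyond_signal_size(self, small_discovery):
        X, y, names, truth, suite, plan, records = small_discovery
        freq = ls.selection_frequency(records, names)
        fixed = {s.name: ls.pick_final_hyperparams(records, s.name) for s in suite}
        res = ls.sensitivity_analysis(
            X, y, names, list(freq.index), suite, fixed, plan, sizes=[5, 7, 9],
        )
        assert res.chosen_k == 5  # all signal is in the top 5 lipids
        t = res.table
        assert ((t["q05"] <= t["median"]) & (t["median"] <= t["q95"])).all()

    def test_single_size(self, small_discovery):
        X, y, names, truth, suite, plan, records = small_discovery
        freq = ls.selection_frequency(records, names)
        fixed = {s.name: ls.pick_final_hyperparams(records, s.name) for s in suite}
        res = ls.sensitivity_analysis(
            X, y, names, list(freq.index), suite, fixed, plan, sizes=[6],
        )
        assert res.chosen_k == 6 and len(res.table) == 1


class TestComparePanels:
    def test_identical_panels(self):
        out = ls.compare_panels({"A": ["x", "y"], "B": ["x", "y"]})
        center = out[out.region == "A&B"].iloc[0]
        assert center["n_lipids"] == 2
        assert out[out.region == "A"].iloc[0]["n_lipids"] == 0

    def test_disjoint_panels(self):
        out = ls.compare_panels({"A": ["x"], "B": ["y"]})
        assert out[out.region == "A&B"].iloc[0]["n_lipids"] == 0

    def test_planted_triple_overlap(self):
        panels = {
            "P1": ["a", "b", "c", "d"],
            "P2": ["a", "b", "e"],
            "P3": ["a", "b", "f", "g"],
        }
        out = ls.compare_panels(panels)
        center = out[out.region == "P1&P2&P3"].iloc[0]
        assert center["lipids"] == "a;b"
        assert out[out.region == "P1"].iloc[0]["lipids"] == "c;d"


class TestRankAuc:
    def test_perfect_and_reverse(self):
        y = np.array([0, 0, 1, 1])
        assert _rank_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert _rank_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0
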