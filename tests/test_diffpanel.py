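import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lipidsig as ls
from lipidsig.diffpanel import _rank_auc
from lipidsig.errors import DataError, InsufficientDataError

from test_preprocess import _table


def _bh_brute(p):
    """Textbook step-up definition: q_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestDaTest:
    def test_f_equals_squared_t_on_toy(self):
        """Single-factor model: the group F statistic is t^2, p-values match."""
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [9.0]])
        t = ls.log_transform(_table(np.exp2(vals)), pseudo=0.0)
        da = ls.da_test(t, blocking=())
        y = t.labels().to_numpy()
        x = vals[:, 0]
        tt = stats.ttest_ind(x[y == 1], x[y == 0])
        assert da["p"].iloc[0] == pytest.approx(tt.pvalue, rel=1e-10)

    def test_identical_means_give_unit_fc(self):
        # samples alternate control/cancer; both groups see values {1, 2}
        vals = np.exp2(np.array([[1.0], [2.0], [2.0], [1.0]]))
        da = ls.da_test(ls.log_transform(_table(vals), pseudo=0.0), blocking=())
        assert da["fc"].iloc[0] == pytest.approx(1.0)

    def test_planted_fold_change_consistency(self):
        schema = ls.build_lipid_schema(10, 5, seed=0)
        cfg = ls.GeneratorConfig(
            n_control=2000, n_cancer=2000, n_lipids=10, n_classes=5,
            n_informative=5, effect_log2fc=1.0, within_class_corr=0.0,
            batch_sd=0.0, sigma_tech_plasma=0.0, seed=21,
        )
        table, truth = ls.simulate_cohort(cfg, schema, "plasma")
        da = ls.da_test(ls.log_transform(table))
        fcs = da.loc[truth.informative_lipids, "fc"]
        assert np.all((fcs > 1.9) & (fcs < 2.1))

    def test_mixed_model_agrees_with_fixed_on_balanced_data(self, planted_small):
        _, _, table, truth = planted_small
        tl = ls.log_transform(table)
        sub = tl.subset_lipids(list(tl.values.columns[:8]))
        fixed = ls.da_test(sub)
        mixed = ls.da_test(sub, method="mixed")
        np.testing.assert_allclose(fixed["log2fc"], mixed["log2fc"], atol=0.05)

    def test_constant_lipid_warns(self):
        vals = np.hstack([np.ones((6, 1)), np.exp2(np.arange(6))[:, None]])
        with pytest.warns(UserWarning, match="zero residual variance"):
            da = ls.da_test(ls.log_transform(_table(vals), pseudo=0.0), blocking=())
        assert da["p"].iloc[0] == 1.0 and da["fc"].iloc[0] == 1.0


class TestBhAdjust:
    def test_hand_worked_example(self):
        q = ls.bh_adjust(np.array([0.01, 0.02, 0.04, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.0533333333, 0.5], rtol=1e-8)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(ls.bh_adjust(np.full(7, 0.2)), 0.2)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(ls.bh_adjust(p), _bh_brute(p), rtol=1e-10)

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            ls.bh_adjust(np.array([0.5, 1.2]))


def _da_frame(rows):
    """rows: lipid_id -> (fc, q)"""
    df = pd.DataFrame(rows, index=["fc", "q"]).T
    df["log2fc"] = np.log2(df["fc"])
    df["p"] = df["q"]
    df.index.name = "lipid_id"
    return df


def _schema_for(lipids, isomer_groups=None):
    return pd.DataFrame(
        {
            "lipid_class": "PC",
            "annotation": "PC 34:1",
            "mz": 700.0,
            "isomer_group": isomer_groups or list(lipids),
        },
        index=pd.Index(list(lipids), name="lipid_id"),
    )


class TestSelectPanel:
    def test_threshold_rules(self):
        da = _da_frame({"a": (1.3, 0.04), "b": (0.70, 0.04), "c": (1.3, 0.06), "d": (1.1, 0.01)})
        panel = ls.select_panel(da, _schema_for("abcd"))
        assert set(panel.lipid_ids) == {"a", "b"}  # decreased lipid b counts

    def test_isomer_mate_included(self):
        da = _da_frame({"a": (2.0, 0.001), "b": (1.0, 0.9), "c": (1.0, 0.9)})
        schema = _schema_for("abc", isomer_groups=["g1", "g1", "c"])
        panel = ls.select_panel(da, schema)
        assert panel.lipid_ids == ["a", "b"]
        assert bool(panel.provenance.loc["b", "isomer_included"])
        assert not bool(panel.provenance.loc["b", "da_selected"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        lipids = [f"L{i}" for i in range(12)]
        da = _da_frame({l: (rng.uniform(0.5, 2.0), rng.uniform()) for l in lipids})
        schema = _schema_for(lipids)
        tight = set(ls.select_panel(da, schema, fc_min=1.3, q_max=0.05).lipid_ids)
        loose = set(ls.select_panel(da, schema, fc_min=1.1, q_max=0.2).lipid_ids)
        assert tight <= loose


class TestStepwise:
    def _panel(self, lipids):
        return ls.PanelSpec(
            lipid_ids=list(lipids),
            provenance=pd.DataFrame(
                {"da_selected": True, "isomer_included": False, "stepwise_retained": False},
                index=pd.Index(list(lipids), name="lipid_id"),
            ),
        )

    def test_single_informative_group_retained(self, planted_small):
        _, _, table, truth = planted_small
        tl = ls.log_transform(table)
        panel = self._panel(truth.informative_lipids[:1])
        out = ls.stepwise_restrict(tl, panel)
        assert out.lipid_ids == panel.lipid_ids

    def test_recovers_informative_groups(self):
        """5 independent informative m/z groups and 13 noise groups: AIC
        keeps exactly the informative ones."""
        rng = np.random.default_rng(5)
        n = 160
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 18))
        X[y == 1, :5] += 1.6
        # the 13 non-informative groups duplicate informative columns, so
        # adding them can never improve the likelihood: AIC keeps exactly 5
        for j in range(5, 18):
            X[:, j] = X[:, j % 5]
        t = ls.log_transform(_table(np.exp2(X)), pseudo=0.0)
        # distinct m/z per lipid = one group per lipid (informative first)
        t.lipid_meta["mz"] = np.arange(18, dtype=float)
        t.sample_meta.loc[~t.qc_mask, "group"] = np.where(y == 1, "cancer", "control")
        panel = self._panel(list(t.values.columns))
        out = ls.stepwise_restrict(t, panel)
        assert set(out.lipid_ids) == set(t.values.columns[:5])

    def test_duplicate_column_invariance(self):
        rng = np.random.default_rng(8)
        n = 60
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=n) + 1.2 * y
        base = np.column_stack([x, rng.normal(size=n)])
        t1 = ls.log_transform(_table(np.exp2(base)))
        t1.lipid_meta["mz"] = [500.0, 600.0]
        t1.sample_meta.loc[~t1.qc_mask, "group"] = np.where(y == 1, "cancer", "control")
        dup = np.column_stack([x, x, rng.normal(size=n)])
        t2 = ls.log_transform(_table(np.exp2(dup)))
        t2.lipid_meta["mz"] = [500.0, 500.0, 600.0]  # duplicates share the m/z group
        t2.sample_meta.loc[~t2.qc_mask, "group"] = np.where(y == 1, "cancer", "control")
        out1 = ls.stepwise_restrict(t1, self._panel(["L0", "L1"]))
        out2 = ls.stepwise_restrict(t2, self._panel(["L0", "L1", "L2"]))
        assert {t1.lipid_meta.loc[l, "mz"] for l in out1.lipid_ids} == {
            t2.lipid_meta.loc[l, "mz"] for l in out2.lipid_ids
        }


class TestOptimizeThreshold:
    def test_separated_scores(self):
        scores = np.array([0.1, 0.1, 0.9, 0.9])
        y = np.array([0, 0, 1, 1])
        t = ls.optimize_threshold(scores, y)
        assert t == pytest.approx(0.5)
        assert np.mean((scores > t) == y) == 1.0

    def test_all_scores_equal(self):
        scores = np.full(6, 0.4)
        y = np.array([1, 1, 1, 1, 0, 0])
        t = ls.optimize_threshold(scores, y)
        assert t == -np.inf  # predict-everything-cancer side, tie rule
        assert np.mean((scores > t).astype(int) == y) == pytest.approx(4 / 6)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = rng.integers(4, 25)
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], n)  # force ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            t = ls.optimize_threshold(scores, y)
            acc = np.mean((scores > t).astype(int) == y)
            brute = max(
                np.mean((scores > c).astype(int) == y)
                for c in np.concatenate([[-np.inf, np.inf], np.unique(scores)])
            )
            assert acc == pytest.approx(brute)


class TestLoocv:
    def test_perfectly_separable(self, planted_small):
        _, _, table, truth = planted_small
        tl = ls.log_transform(table)
        # boost effect by using all informative lipids of a clean fixture
        panel = ls.PanelSpec(
            lipid_ids=list(truth.informative_lipids),
            provenance=pd.DataFrame(
                {"da_selected": True, "isomer_included": False, "stepwise_retained": False},
                index=pd.Index(truth.informative_lipids, name="lipid_id"),
            ),
        )
        res = ls.loocv_logistic(tl, panel)
        assert res.auc > 0.95
        assert res.tp + res.fn == int(tl.labels().sum())
        assert res.tn + res.fp == int((1 - tl.labels()).sum())
        assert res.accuracy == pytest.approx((res.tp + res.tn) / tl.biological().n_samples)

    def test_auc_equals_pairwise_concordance_with_ties(self):
        scores = np.array([0.1, 0.4, 0.4, 0.4, 0.8, 0.2, 0.4, 0.9, 0.6, 0.4, 0.3, 0.7])
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        conc = 0.0
        for sp in scores[y == 1]:
            for sn in scores[y == 0]:
                conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        brute = conc / ((y == 1).sum() * (y == 0).sum())
        assert _rank_auc(scores, y) == pytest.approx(brute)

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(2)
        aucs = [
            _rank_auc(rng.uniform(size=200), rng.permutation(np.repeat([0, 1], 100)))
            for _ in range(1000)
        ]
        assert 0.47 < np.mean(aucs) < 0.53

    def test_needs_minimum_samples(self):
        t = ls.log_transform(_table(np.ones((4, 2))))
        panel = ls.PanelSpec(
            lipid_ids=["L0"],
            provenance=pd.DataFrame(
                {"da_selected": True, "isomer_included": False, "stepwise_retained": False},
                index=pd.Index(["L0"], name="lipid_id"),
            ),
        )
        with pytest.raises(InsufficientDataError):
            ls.loocv_logistic(t, panel)


class TestSubjectCorrelation:
    def test_closed_form_pearson(self):
        assert np.corrcoef([1, 2, 3], [2, 4, 7])[0, 1] == pytest.approx(0.99339, abs=1e-5)

    def test_reversed_profiles_give_minus_one(self):
        schema = ls.build_lipid_schema(5, 2, seed=0)
        cfg = ls.GeneratorConfig(
            n_control=4, n_cancer=4, n_lipids=5, n_classes=2, n_informative=2,
            sigma_tech_plasma=0.0, sigma_tech_ev=0.0, batch_sd=0.0, seed=2,
        )
        ev, plasma, _ = ls.simulate_matched_pair(cfg, schema)
        # anti-correlated plasma: c - log2(ev) per subject
        flipped = plasma.with_values(
            pd.DataFrame(
                np.exp2(20.0 - np.log2(ev.values.to_numpy())),
                index=plasma.values.index,
                columns=plasma.values.columns,
            )
        )
        panel = ls.PanelSpec(
            lipid_ids=list(schema.index),
            provenance=pd.DataFrame(
                {"da_selected": True, "isomer_included": False, "stepwise_retained": False},
                index=schema.index,
            ),
        )
        corr = ls.subject_correlation(ev, flipped, panel)
        np.testing.assert_allclose(corr.table["r"], -1.0, atol=1e-9)

    def test_too_few_lipids(self):
        schema = ls.build_lipid_schema(5, 2, seed=0)
        cfg = ls.GeneratorConfig(n_control=4, n_cancer=4, n_lipids=5, n_classes=2,
                                 n_informative=2, seed=2)
        ev, plasma, _ = ls.simulate_matched_pair(cfg, schema)
        panel = ls.PanelSpec(
            lipid_ids=["LID0000"],
            provenance=pd.DataFrame(
                {"da_selected": True, "isomer_included": False, "stepwise_retained": False},
                index=pd.Index(["LID0000"], name="lipid_id"),
            ),
        )
        with pytest.raises(InsufficientDataError):
            ls.subject_correlation(ev, plasma, panel)
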