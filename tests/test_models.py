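import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from rulemine import (
    Condition,
    DiscretizedDataset,
    Rule,
    VariableMeta,
    build_model,
    chi2_select,
    fit_l2_logistic,
    rules_to_features,
)
from rulemine.models import FittedModel, prepare_features
from rulemine.synth import SyntheticSpec, generate


class TestChi2Select:
    def test_constant_variable_never_selected(self):
        data = pd.DataFrame({"c": [1] * 30, "v": [1] * 15 + [2] * 15}, index=range(30))
        target = pd.Series(["below60"] * 15 + ["at_least_60"] * 15, index=data.index)
        ds = DiscretizedDataset(
            data=data,
            variables=[VariableMeta("c", "ordinal", 2), VariableMeta("v", "ordinal", 2)],
            target=target,
        )
        assert "c" not in chi2_select(ds)

    def test_perfectly_split_variable_selected(self):
        # renal failure entirely in bins 1-5, the others in bins 6-10, n=110
        rng = np.random.default_rng(0)
        col = np.concatenate([rng.integers(1, 6, 86), rng.integers(6, 11, 24)])
        data = pd.DataFrame({"v": col}, index=range(110))
        target = pd.Series(["below60"] * 86 + ["at_least_60"] * 24, index=data.index)
        ds = DiscretizedDataset(
            data=data, variables=[VariableMeta("v", "ordinal", 10)], target=target
        )
        assert chi2_select(ds) == ["v"]

    def test_matches_scipy_contingency(self, planted_dataset):
        # the vectorized statistic must reproduce the classical Pearson chi2
        ds, _, _ = planted_dataset
        from scipy.stats import chi2 as chi2_dist

        y = ds.modality_indicator("below60")
        for name in ds.variable_names[:6]:
            codes = ds.codes(name)
            table = pd.crosstab(codes, y)
            if table.shape[0] < 2:
                continue
            stat, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
            # recompute our p from the same selection internals
            from rulemine.models import chi2_select as _  # noqa: F401

            obs1 = np.array([((codes == lv) & y).sum() for lv in np.unique(codes)])
            tot = np.array([(codes == lv).sum() for lv in np.unique(codes)])
            n1 = y.sum()
            n = len(y)
            exp1 = tot * n1 / n
            exp0 = tot * (n - n1) / n
            ours = ((obs1 - exp1) ** 2 / exp1).sum() + (
                ((tot - obs1) - exp0) ** 2 / exp0
            ).sum()
            assert ours == pytest.approx(stat, rel=1e-10)
            assert chi2_dist.sf(ours, len(tot) - 1) == pytest.approx(p, rel=1e-8)

    def test_shuffled_labels_rarely_select(self):
        # Bonferroni keeps the familywise false-selection count near alpha
        rng = np.random.default_rng(1)
        total_selected = 0
        for seed in range(20):
            ds, _ = generate(SyntheticSpec(n_buckets=40, seed=seed))
            shuffled = ds.with_target(
                pd.Series(rng.permutation(ds.target.to_numpy()), index=ds.target.index)
            )
            total_selected += len(chi2_select(shuffled))
        # E[selections per family] <= 0.05; 20 families => ~1 expected
        assert total_selected <= 5


class TestRulesToFeatures:
    def test_empty_ruleset(self, null_dataset):
        out = rules_to_features([], null_dataset)
        assert out.shape == (null_dataset.n_subjects, 0)

    def test_column_sums_equal_coverage(self, planted_dataset):
        ds, _, _ = planted_dataset
        from rulemine import mine_rules

        rules = mine_rules(ds, variables=ds.variable_names[:3], dims=(1,))
        feats = rules_to_features(rules.rules, ds)
        assert np.array_equal(feats.sum(axis=0), [r.coverage for r in rules])

    def test_hand_fixture(self):
        data = pd.DataFrame({"v": [1, 5, 2, 9]}, index=["s1", "s2", "s3", "s4"])
        target = pd.Series(["below60", "below60", "at_least_60", "below60"], index=data.index)
        ds = DiscretizedDataset(
            data=data, variables=[VariableMeta("v", "ordinal", 10)], target=target
        )
        rule = Rule(
            conditions=(Condition("v", lo=1, hi=2),),
            modality="below60",
            coverage=2,
            modality_size=1,
            z=2.0,
        )
        assert rules_to_features([rule], ds)[:, 0].tolist() == [1.0, 0.0, 1.0, 0.0]


class TestL2Logistic:
    def test_separable_large_C(self):
        x = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        w, b = fit_l2_logistic(x, y, C=1e6)
        pred = (x @ w + b) > 0
        assert np.array_equal(pred, y.astype(bool))

    def test_small_C_shrinks_to_majority(self):
        x = np.array([[0.0], [0.1], [0.9], [1.0], [0.5]])
        y = np.array([0, 0, 1, 1, 1])
        w, b = fit_l2_logistic(x, y, C=1e-8)
        assert np.abs(w).max() < 1e-3
        assert b > 0  # majority class is 1

    def test_weight_norm_monotone_in_C(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 4))
        y = (x[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        norms = [np.linalg.norm(fit_l2_logistic(x, y, C)[0]) for C in (0.001, 0.01, 0.1, 1, 10)]
        assert all(a <= b + 1e-9 for a, b in zip(norms, norms[1:]))


class TestBuildModel:
    def test_all_models_beat_majority_f1(self, planted_dataset):
        from rulemine import f1

        ds, _, _ = planted_dataset
        majority = pd.Series(["below60"] * ds.n_subjects, index=ds.data.index)
        base = f1(ds.target, majority, "macro", ds.modalities)
        for mt in ("global", "local_1d", "local_1and2d"):
            model = build_model(ds, mt, C=1.0)
            score = f1(ds.target, model.predict(ds), "macro", ds.modalities)
            assert score > base

    def test_local_1and2d_has_at_least_1d_features(self, planted_dataset):
        ds, _, _ = planted_dataset
        m1 = build_model(ds, "local_1d", C=1.0)
        m2 = build_model(ds, "local_1and2d", C=1.0)
        assert m2.complexity >= m1.complexity

    def test_global_complexity_is_selected_variable_count(self, planted_dataset):
        ds, _, _ = planted_dataset
        model = build_model(ds, "global", C=1.0)
        assert model.complexity == len(chi2_select(ds))

    def test_local_models_mine_only_chi2_selected(self, planted_dataset):
        ds, _, _ = planted_dataset
        selected = set(chi2_select(ds))
        model = build_model(ds, "local_1and2d", C=1.0)
        assert set(model.rules.provenance["variables"]) <= selected

    def test_intercept_only_fallback_predicts_majority(self, null_dataset):
        shuffled = null_dataset  # pure noise: chi2 selects nothing (usually)
        prep = prepare_features(shuffled, "local_1d", alpha=1e-12)
        from rulemine.models import fit_prepared

        model = fit_prepared(prep, 1.0)
        assert model.complexity == 0
        assert set(model.predict(shuffled)) == {"below60"}

    def test_serialization_roundtrip(self, tmp_path, planted_dataset):
        ds, _, _ = planted_dataset
        model = build_model(ds, "local_1and2d", C=0.1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedModel.from_json(path)
        assert back.model_type == model.model_type
        assert back.complexity == model.complexity
        assert np.allclose(back.weights, model.weights)
        assert back.predict(ds).equals(model.predict(ds))

    def test_predict_recomputes_rule_features_on_new_subjects(self, planted_dataset):
        ds, _, _ = planted_dataset
        train = ds.subset(np.arange(0, 90))
        test = ds.subset(np.arange(90, 110))
        model = build_model(train, "local_1d", C=1.0)
        feats = model.feature_matrix(test)
        for j, rule in enumerate(model.selected_features):
            assert np.array_equal(feats[:, j], rule.mask(test).astype(float))

    def test_deterministic(self, planted_dataset):
        ds, _, _ = planted_dataset
        a = build_model(ds, "local_1d", C=1.0)
        b = build_model(ds, "local_1d", C=1.0)
        assert np.allclose(a.weights, b.weights) and a.intercept == b.intercept
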