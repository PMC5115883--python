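import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulemine import (
    Condition,
    DiscretizedDataset,
    Rule,
    RuleSet,
    VariableMeta,
    enumerate_candidates,
    enumerate_conditions_1d,
    mine_rules,
    minimize,
    select_significant,
    support,
    z_score,
)
from rulemine.mining import z_from_counts
from rulemine.synth import SyntheticSpec, generate


class TestEnumeration:
    def test_ordinal_ranges_match_brute_force(self):
        var = VariableMeta("v", "ordinal", 10)
        conds = enumerate_conditions_1d(var)
        brute = {(a, b) for a in range(1, 11) for b in range(a, 11)}
        assert {(c.lo, c.hi) for c in conds} == brute
        assert len(conds) == 55  # k(k+1)/2

    def test_single_level_ordinal(self):
        conds = enumerate_conditions_1d(VariableMeta("v", "ordinal", 1))
        assert len(conds) == 1 and (conds[0].lo, conds[0].hi) == (1, 1)

    def test_nominal_subsets(self):
        var = VariableMeta("sex", "nominal", 2, level_labels=("M", "F"))
        conds = enumerate_conditions_1d(var)
        assert {frozenset(c.categories) for c in conds} == {
            frozenset({"M"}),
            frozenset({"F"}),
            frozenset({"M", "F"}),
        }

    def test_nominal_guard(self):
        var = VariableMeta("x", "nominal", 7, level_labels=tuple("abcdefg"))
        with pytest.raises(ValueError, match="pre-group"):
            enumerate_conditions_1d(var)

    def test_pair_product_count(self):
        vars2 = [VariableMeta("a", "ordinal", 10), VariableMeta("b", "ordinal", 10)]
        pairs = list(enumerate_candidates(vars2, dims=2))
        assert len(pairs) == 55 * 55

    def test_1d_count_scales_with_variables(self):
        vars3 = [VariableMeta(f"v{i}", "ordinal", 10) for i in range(3)]
        assert len(list(enumerate_candidates(vars3, dims=1))) == 55 * 3

    def test_no_self_pairs(self):
        vars3 = [VariableMeta(f"v{i}", "ordinal", 4) for i in range(3)]
        for ca, cb in enumerate_candidates(vars3, dims=2):
            assert ca.variable != cb.variable


class TestSupport:
    def test_full_range_covers_all(self, tiny_dataset):
        mask = support((Condition("bucket 1.00", lo=1, hi=4),), tiny_dataset)
        assert mask.all()

    def test_brute_force_membership(self, tiny_dataset):
        # enumerate every 1D/2D candidate and re-check each subject by hand
        for conds in itertools.chain(
            enumerate_candidates(tiny_dataset.variables, 1),
            enumerate_candidates(tiny_dataset.variables, 2),
        ):
            mask = support(conds, tiny_dataset)
            for i, subj in enumerate(tiny_dataset.subjects):
                expected = True
                for c in conds:
                    val = tiny_dataset.data.loc[subj, c.variable]
                    if c.is_ordinal:
                        expected &= c.lo <= val <= c.hi
                    else:
                        expected &= val in c.categories
                assert mask[i] == expected

    def test_disjoint_supports_intersect_empty(self, tiny_dataset):
        conds = (
            Condition("bucket 1.00", lo=1, hi=1),  # only subject s0
            Condition("Sex", categories=frozenset({"M"})),
        )
        assert support(conds, tiny_dataset).sum() == 0


class TestZScore:
    def test_full_population_is_zero(self, null_dataset):
        mask = np.ones(null_dataset.n_subjects, dtype=bool)
        assert z_score(mask, "below60", null_dataset) == pytest.approx(0.0, abs=1e-12)

    def test_spec_proportions_example(self):
        # n=110 with 86 carriers; a 20-subject support made entirely of
        # carriers: z = (1 - 86/110) / sqrt(p0 (1-p0) / 20)
        z = z_from_counts(n_r=20, k_r=20, n=110, k_mod=86)
        assert z == pytest.approx(2.36, abs=0.01)

    def test_subsample_at_population_rate_is_zero(self):
        # support of 55 with exactly 43 carriers: p_r == p_0 (86/110)
        assert z_from_counts(55, 43, 110, 86) == pytest.approx(0.0)

    def test_invariant_to_subject_order(self, null_dataset):
        rng = np.random.default_rng(0)
        mask = rng.random(null_dataset.n_subjects) < 0.3
        z1 = z_score(mask, "below60", null_dataset)
        perm = rng.permutation(null_dataset.n_subjects)
        z2 = z_score(mask[perm], "below60", null_dataset.subset(perm))
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_enrichment_sign_flips_between_modalities(self, null_dataset):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mask = rng.random(null_dataset.n_subjects) < rng.uniform(0.1, 0.9)
            if mask.sum() == 0:
                continue
            za = z_score(mask, "below60", null_dataset)
            zb = z_score(mask, "at_least_60", null_dataset)
            assert za * zb <= 1e-12  # opposite signs (or both zero)

    def test_degenerate_target_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_from_counts(10, 5, 100, 0)


class TestSelectSignificant:
    def test_modality_size_threshold_is_inclusive(self):
        # variable separating the classes; condition covering exactly 10
        # carriers passes at size 10 and fails at size 9
        n = 40
        data = pd.DataFrame({"v": [1] * 10 + [2] * 10 + [3] * 20}, index=range(n))
        target = pd.Series(["below60"] * 20 + ["at_least_60"] * 20, index=data.index)
        ds = DiscretizedDataset(
            data=data, variables=[VariableMeta("v", "ordinal", 3)], target=target
        )
        ten = select_significant([(Condition("v", lo=1, hi=1),)], ds)
        assert [r.modality_size for r in ten] == [10]
        nine = select_significant(
            [(Condition("v", lo=1, hi=1),)], ds, min_modality_size=11
        )
        assert nine == []

    def test_emitted_rules_annotated(self, planted_dataset):
        ds, _, _ = planted_dataset
        cands = [(c,) for c in enumerate_conditions_1d(ds.variable("bucket 0.16"))]
        rules = select_significant(cands, ds)
        assert rules
        for r in rules:
            mask = support(r.conditions, ds)
            assert r.coverage == int(mask.sum())
            y = ds.modality_indicator(r.modality)
            assert r.modality_size == int((mask & y).sum())
            assert r.z == pytest.approx(z_score(mask, r.modality, ds))

    def test_null_survivor_rate_matches_tail_expectation(self):
        # on label-shuffled data the z >= 1.96 one-sided tail keeps roughly
        # alpha of the size-eligible candidates per modality
        rng = np.random.default_rng(42)
        survivors, eligible = 0, 0
        for seed in range(10):
            ds, _ = generate(SyntheticSpec(n_buckets=20, seed=seed))
            shuffled = ds.with_target(
                pd.Series(
                    rng.permutation(ds.target.to_numpy()), index=ds.target.index
                )
            )
            cands = list(enumerate_candidates(shuffled.variables[:20], 1))
            kept = select_significant(cands, shuffled)
            survivors += len(kept)
            for conds in cands:
                mask = support(conds, shuffled)
                for m in shuffled.modalities:
                    y = shuffled.modality_indicator(m)
                    if (mask & y).sum() >= 10:
                        eligible += 1
        rate = survivors / eligible
        # candidates are heavily correlated (nested ranges), so allow a wide
        # Monte-Carlo band around the 2.5% normal tail
        assert 0.002 < rate < 0.10


def brute_force_minimize(rules):
    """Independent oracle: literal pairwise dominance filter."""
    kept = []
    for r in rules:
        dominated = False
        for other in rules:
            if other is r or other.modality != r.modality:
                continue
            if other.variables != r.variables:
                continue
            larger = other.contains(r) and not r.contains(other)
            smaller = r.contains(other) and not other.contains(r)
            if (larger and other.z >= r.z) or (smaller and other.z > r.z):
                dominated = True
                break
        if not dominated:
            kept.append(r)
    return kept


def _rule_1d(lo, hi, z, var="v", modality="below60"):
    return Rule(
        conditions=(Condition(var, lo=lo, hi=hi),),
        modality=modality,
        coverage=hi - lo + 1,
        modality_size=0,
        z=z,
    )


class TestMinimize:
    def test_nested_larger_wins_on_higher_z(self):
        a, b = _rule_1d(2, 3, 2.0), _rule_1d(1, 4, 2.5)
        assert minimize([a, b]) == [b]

    def test_nested_smaller_wins_on_strictly_higher_z(self):
        a, b = _rule_1d(2, 3, 2.5), _rule_1d(1, 4, 2.0)
        assert minimize([a, b]) == [a]

    def test_equal_z_keeps_larger(self):
        a, b = _rule_1d(2, 3, 2.0), _rule_1d(1, 4, 2.0)
        assert minimize([a, b]) == [b]

    def test_incomparable_rules_untouched(self):
        rules = [
            _rule_1d(1, 3, 2.0),
            _rule_1d(2, 5, 3.0),  # overlapping, not nested
            _rule_1d(1, 3, 4.0, var="w"),  # different variable
        ]
        assert minimize(rules) == rules

    def test_2d_never_compared_with_1d(self):
        one = _rule_1d(1, 4, 5.0)
        two = Rule(
            conditions=(Condition("v", lo=1, hi=4), Condition("w", lo=1, hi=4)),
            modality="below60",
            coverage=4,
            modality_size=0,
            z=1.0,
        )
        assert minimize([one, two]) == [one, two]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_agrees_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rules = []
        for _ in range(rng.integers(2, 60)):
            lo = int(rng.integers(1, 10))
            hi = int(rng.integers(lo, 10))
            rules.append(
                _rule_1d(
                    lo,
                    hi,
                    float(np.round(rng.uniform(1.96, 6), 2)),
                    var=rng.choice(["v", "w"]),
                    modality=rng.choice(["below60", "at_least_60"]),
                )
            )
        out = minimize(rules)
        assert out == brute_force_minimize(rules)
        assert minimize(out) == out
        assert all(r in rules for r in out)
        # no two survivors on the same variables are strictly nested
        # (exact duplicates with differing z can coexist in random instances)
        for a in out:
            for b in out:
                if a is not b:
                    assert not (a.contains(b) and not b.contains(a))


class TestMineRules:
    def test_perfect_separator_yields_range_rule(self):
        # all renal-failure subjects in bins 1-3, the rest in bins 4-6
        rng = np.random.default_rng(2)
        n_below, n_above = 60, 40
        col = np.concatenate(
            [rng.integers(1, 4, n_below), rng.integers(4, 7, n_above)]
        )
        data = pd.DataFrame({"v": col}, index=range(100))
        target = pd.Series(
            ["below60"] * n_below + ["at_least_60"] * n_above, index=data.index
        )
        ds = DiscretizedDataset(
            data=data, variables=[VariableMeta("v", "ordinal", 6)], target=target
        )
        rules = mine_rules(ds, dims=(1,))
        below_rules = rules.for_modality("below60")
        assert any(
            c.lo == 1 and c.hi == 3 for r in below_rules for c in r.conditions
        )

    def test_fast_path_agrees_with_reference(self, tiny_dataset):
        ds, _ = generate(SyntheticSpec(n_buckets=4, planted_1d=((0, (1, 5), 0.8),), seed=3))
        fast = mine_rules(ds, variables=ds.variable_names[:4], dims=(1, 2))
        cands = list(
            itertools.chain(
                enumerate_candidates([ds.variable(v) for v in ds.variable_names[:4]], 1),
                enumerate_candidates([ds.variable(v) for v in ds.variable_names[:4]], 2),
            )
        )
        reference = minimize(select_significant(cands, ds))
        assert sorted(r.identity() for r in fast) == sorted(
            r.identity() for r in reference
        )
        assert {r.identity(): r.z for r in fast} == pytest.approx(
            {r.identity(): r.z for r in reference}
        )

    def test_planted_2d_needs_dims_2(self, planted_dataset):
        ds, truth, spec = planted_dataset
        pair_vars = sorted(truth.rules[-1].variables)
        both = mine_rules(ds, variables=pair_vars, dims=(1, 2))
        only1 = mine_rules(ds, variables=pair_vars, dims=(1,))
        assert any(r.dimension == 2 for r in both)
        assert len(only1) == 0  # balanced margins: 1D mining is blind

    def test_every_emitted_rule_passes_thresholds(self, planted_dataset):
        ds, _, _ = planted_dataset
        rules = mine_rules(ds, variables=ds.variable_names[:8], dims=(1, 2))
        assert rules.provenance["min_modality_size"] == 10
        assert rules.provenance["min_z"] == 1.96
        for r in rules:
            assert r.modality_size >= 10
            assert r.z >= 1.96

    def test_serialization_roundtrip(self, tmp_path, planted_dataset):
        ds, _, _ = planted_dataset
        rules = mine_rules(ds, variables=ds.variable_names[:3] + ["Sex"], dims=(1, 2))
        path = tmp_path / "rules.jsonl"
        rules.to_jsonl(path)
        back = RuleSet.from_jsonl(path)
        assert [r.identity() for r in back] == [r.identity() for r in rules]
        assert [r.z for r in back] == [r.z for r in rules]

    def test_rendering_matches_field_syntax(self):
        r = _rule_1d(1, 4, 2.0, var="bucket 2.14")
        assert r.render() == "{variable: 'bucket 2.14'; condition: bins 1 to 4}"
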