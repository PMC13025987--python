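"""Semi-quantification and univariate statistics against hand-computed
and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aromastages import (
    AbundanceTable,
    CompoundInfo,
    ValidationError,
    class_composition,
    duncan_mrt,
    log2_fold_change,
    normalize_to_internal_standard,
    one_way_anova,
    relative_content,
    volcano_classify,
)
from aromastages.datamodel import ChemicalClass, UnitTag
from aromastages.quant import _benjamini_hochberg, univariate_table


def _raw_table(data, columns, is_id=None):
    df = pd.DataFrame(data, columns=columns,
                      index=[f"s{i + 1}" for i in range(len(data))])
    return AbundanceTable(values=df, unit_tag=UnitTag.raw_area,
                          internal_standard_id=is_id)


class TestInternalStandard:
    def test_hand_arithmetic_microgram_per_gram(self):
        # analyte area = 2 x IS area; 10 µL x 50 µg/mL spike = 0.5 µg
        # into 0.5 g tea -> 2 x 0.5/0.5 = 2.0 µg/g
        t = _raw_table([[2000.0, 1000.0]], ["analyte", "IS"], is_id="IS")
        out = normalize_to_internal_standard(t, is_amount=0.5, sample_mass=0.5)
        assert out.values.loc["s1", "analyte"] == pytest.approx(2.0)
        assert out.unit_tag is UnitTag.is_normalized
        assert "IS" not in out.compound_ids

    def test_zero_analyte_stays_zero(self):
        t = _raw_table([[0.0, 1000.0]], ["analyte", "IS"], is_id="IS")
        out = normalize_to_internal_standard(t)
        assert out.values.loc["s1", "analyte"] == 0.0

    def test_zero_is_area_errors_naming_sample(self):
        t = _raw_table([[5.0, 0.0]], ["analyte", "IS"], is_id="IS")
        with pytest.raises(ValidationError, match="s1"):
            normalize_to_internal_standard(t)

    def test_missing_is_column_errors(self):
        t = _raw_table([[5.0, 2.0]], ["a", "b"])
        with pytest.raises(ValidationError, match="internal_standard"):
            normalize_to_internal_standard(t)


class TestRelativeContent:
    def test_forced_arithmetic(self):
        t = _raw_table([[1.0, 3.0]], ["a", "b"])
        out = relative_content(t)
        assert list(out.values.loc["s1"]) == [25.0, 75.0]
        assert out.unit_tag is UnitTag.percent

    def test_single_compound_is_100(self):
        t = _raw_table([[7.0]], ["a"])
        assert relative_content(t).values.loc["s1", "a"] == 100.0

    def test_all_zero_sample_errors(self):
        t = _raw_table([[0.0, 0.0]], ["a", "b"])
        with pytest.raises(ValidationError, match="zero total"):
            relative_content(t)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        data = rng.lognormal(0, 1, size=(3, 5))
        t1 = _raw_table(data, list("abcde"))
        t2 = _raw_table(k * data, list("abcde"))
        np.testing.assert_allclose(relative_content(t1).values,
                                   relative_content(t2).values, rtol=1e-9)

    def test_rows_sum_to_100(self, default_dataset):
        out = relative_content(default_dataset[0])
        np.testing.assert_allclose(out.values.sum(axis=1), 100.0, atol=1e-9)


class TestClassComposition:
    def test_study_inventory_percentages(self):
        counts = {ChemicalClass.hydrocarbon: 33, ChemicalClass.alcohol: 22,
                  ChemicalClass.ketone: 15, ChemicalClass.ester: 13,
                  ChemicalClass.aldehyde: 13, ChemicalClass.heterocyclic: 12,
                  ChemicalClass.aromatic: 8, ChemicalClass.phenol: 6,
                  ChemicalClass.acid: 5, ChemicalClass.other: 7}
        compounds = [
            CompoundInfo(f"c{i}_{cls.value}", "x", cls)
            for cls, n in counts.items() for i in range(n)
        ]
        cc = class_composition(compounds)
        assert cc.total_count == 134
        assert cc.percentages[ChemicalClass.hydrocarbon] == 24.63
        assert cc.percentages[ChemicalClass.alcohol] == 16.42
        assert cc.percentages[ChemicalClass.ketone] == 11.19
        assert cc.percentages[ChemicalClass.ester] == 9.70
        assert cc.percentages[ChemicalClass.heterocyclic] == 8.96
        assert cc.percentages[ChemicalClass.acid] == 3.73

    def test_single_class_is_100(self):
        cc = class_composition([CompoundInfo("a", "a", ChemicalClass.ester)])
        assert cc.percentages[ChemicalClass.ester] == 100.00

    def test_thirds_round_half_up(self):
        compounds = [CompoundInfo("a", "a", ChemicalClass.ester),
                     CompoundInfo("b", "b", ChemicalClass.acid),
                     CompoundInfo("c", "c", ChemicalClass.phenol)]
        cc = class_composition(compounds)
        assert all(p == 33.33 for p in cc.percentages.values())

    def test_percentages_sum_to_100_within_rounding(self, default_dataset):
        cc = class_composition(default_dataset[1])
        assert sum(cc.percentages.values()) == pytest.approx(100.0, abs=0.05)


class TestAnova:
    def test_hand_computed_f(self):
        # SSB = 1.5, SSW = 4, df = (1, 4) -> F = 1.5
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5, abs=1e-12)
        assert p == pytest.approx(float(stats.f.sf(1.5, 1, 4)), abs=1e-12)

    def test_identical_constant_groups(self):
        f, p = one_way_anova([[2, 2, 2], [2, 2, 2]])
        assert (f, p) == (0.0, 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_two_group_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=4)
        f, p_f = one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t ** 2, rel=1e-9)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_shift_invariance_and_scale_invariance(self):
        groups = [[1.0, 2.0, 5.0], [0.5, 3.0, 4.0], [2.0, 2.5, 9.0]]
        f0, _ = one_way_anova(groups)
        f_shift, _ = one_way_anova([[x + 7 for x in g] for g in groups])
        f_scale, _ = one_way_anova([[x * 3 for x in g] for g in groups])
        assert f_shift == pytest.approx(f0, rel=1e-12)
        assert f_scale == pytest.approx(f0, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestDuncan:
    def test_identical_groups_share_letter(self):
        letters = duncan_mrt([[5, 5.1, 4.9], [5, 5.1, 4.9], [5.0, 5.05, 4.95]])
        assert set(letters.values()) == {"a"}

    def test_three_well_separated_groups(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 0.1, 5) for m in (0.0, 10.0, 20.0)]
        letters = duncan_mrt(groups, labels=["lo", "mid", "hi"])
        assert letters == {"hi": "a", "mid": "b", "lo": "c"}

    @pytest.mark.parametrize("seed", range(12))
    def test_k2_matches_pooled_t_decision(self, seed):
        # at k = 2 the single studentized range at span 2 is equivalent
        # to the two-sided pooled t-test at the same alpha
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(rng.uniform(0, 2.5), 1.0, 5)
        letters = duncan_mrt([a, b], alpha=0.05, labels=["a", "b"])
        separated = not (set(letters["a"]) & set(letters["b"]))
        _, p = stats.ttest_ind(a, b, equal_var=True)
        assert separated == (p < 0.05)

    def test_mid_group_can_share_both_letters(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, 4) for m in (0.0, 1.2, 2.4)]
        letters = duncan_mrt(groups, labels=["lo", "mid", "hi"])
        # every group carries at least one letter
        assert all(letters.values())


class TestFoldChangeVolcano:
    @pytest.mark.parametrize("a,b,pseudo,expected", [
        (2.0, 8.0, 0.0, 2.0),
        (5.0, 5.0, 0.0, 0.0),
        (0.0, 4.0, 1.0, np.log2(5.0)),
    ])
    def test_log2fc_values(self, a, b, pseudo, expected):
        assert log2_fold_change(a, b, pseudo) == pytest.approx(expected)

    def test_both_zero_without_pseudo_errors(self):
        with pytest.raises(ValidationError, match="undefined"):
            log2_fold_change(0.0, 0.0, 0.0)

    @pytest.mark.parametrize("l2fc,p,expected", [
        (2.0, 0.001, "increased"),
        (-3.0, 0.01, "decreased"),
        (2.0, 0.2, "unchanged"),
        (1.0, 0.001, "increased"),    # boundary: log2fc == log2(fc)
        (0.5, 0.001, "unchanged"),
    ])
    def test_volcano_rules(self, l2fc, p, expected):
        assert volcano_classify(l2fc, p, 2.0, 0.05) == expected

    @given(st.floats(min_value=-50, max_value=50),
           st.floats(min_value=0, max_value=1))
    @settings(max_examples=100, deadline=None)
    def test_partition_exhaustive_and_exclusive(self, l2fc, p):
        out = volcano_classify(l2fc, p)
        assert out in {"increased", "decreased", "unchanged"}


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
    adj = _benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_univariate_table_uses_raw_p_by_default(default_contents):
    rel, _, samples, _ = default_contents
    ids_a = [s.sample_id for s in samples if s.batch == "F1" and s.stage.value == "RM"]
    ids_b = [s.sample_id for s in samples if s.batch == "F1" and s.stage.value == "IF"]
    raw = univariate_table(rel, ids_a, ids_b)
    adj = univariate_table(rel, ids_a, ids_b, bh_adjust=True)
    assert (adj["p"].to_numpy() >= raw["p"].to_numpy() - 1e-12).all()
    assert set(raw["regulation"]) <= {"increased", "decreased", "unchanged"}
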