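import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from diabtype.features import FeatureConfig, count_codes, featurize
from diabtype.rules import (ALIASES, CodeCountClassifier, CodeRatioClassifier,
                            PrescriptionClassifier, RuleCombination,
                            candidate_registry, classify, registry)

D0 = pd.Timestamp("2010-01-01")


def _one_person(builder, **kwargs):
    builder.person("P1", **kwargs)
    builder.lab("P1", D0, "hba1c", 7.0)
    return builder


def _features(builder):
    tables, _ = builder.build()
    cohort = pd.DataFrame({"person_id": ["P1"], "diagnosis_date": [D0]})
    return tables, featurize(tables, cohort)


class TestCountCodes:
    def test_counts_split_by_source(self, builder):
        b = _one_person(builder)
        b.encounter("P1", "2010-02-01", "250.01", source="principal")
        b.encounter("P1", "2010-03-01", "250.01", source="principal")
        b.encounter("P1", "2010-04-01", "250.03", source="mixed")
        tables, X = _features(b)
        row = X.loc["P1"]
        assert (row["n_type1"], row["n_type2"]) == (3, 0)
        assert (row["n_type1_principal"], row["n_type1_mixed"]) == (2, 1)
        counts = count_codes(tables.encounters, D0, pd.Timestamp("2016-12-31"))
        assert counts["n_type1"] == 3 and counts["n_type2"] == 0

    def test_codes_before_diagnosis_not_counted(self, builder):
        b = _one_person(builder)
        b.encounter("P1", "2009-12-31", "250.01")
        b.encounter("P1", "2010-01-01", "250.00")
        _, X = _features(b)
        assert X.loc["P1", "n_type1"] == 0
        assert X.loc["P1", "n_type2"] == 1

    def test_untyped_codes_ignored(self, builder):
        b = _one_person(builder)
        b.encounter("P1", "2010-02-01", "428.0")
        b.encounter("P1", "2010-02-01", "250.1")
        _, X = _features(b)
        assert X.loc["P1", ["n_type1", "n_type2"]].sum() == 0


class TestCodeRatio:
    @pytest.mark.parametrize("n1,n2,r,expected", [
        (3, 0, 4.0, True),    # zero denominator, numerator >= 1 -> positive
        (0, 0, 0.5, False),
        (2, 1, 2.0, True),    # inclusive threshold
        (2, 1, 3.0, False),
        (1, 1, 0.5, True),
        (1, 2, 0.5, True),
        (1, 3, 0.5, False),
    ])
    def test_ratio_semantics(self, n1, n2, r, expected):
        X = pd.DataFrame({"n_type1": [n1], "n_type2": [n2]})
        assert bool(CodeRatioClassifier(threshold=r).positive(X).iloc[0]) is expected

    @given(st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=120, derandomize=True)
    def test_threshold_monotonicity(self, n1, n2):
        """Raising the ratio threshold never turns a negative positive."""
        X = pd.DataFrame({"n_type1": [n1], "n_type2": [n2]})
        calls = [bool(CodeRatioClassifier(threshold=r).positive(X).iloc[0])
                 for r in (0.5, 0.75, 1, 2, 3, 4)]
        assert calls == sorted(calls, reverse=True)


class TestPrescriptionRules:
    def test_any_insulin_within_window(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-11", 90)
        _, X = _features(b)
        est = PrescriptionClassifier(variant="any_insulin", window_days=90)
        assert est.fit(X).predict(X)[0] == "T1D"

    def test_short_duration_insulin_never_qualifies(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-11", 27)
        _, X = _features(b)
        assert not X.loc["P1", "has_insulin_full"]

    def test_insulin_outside_window_negative(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-06-01", 90)  # day 151
        _, X = _features(b)
        assert not X.loc["P1", "has_insulin_90"]
        assert X.loc["P1", "has_insulin_180"]

    def test_no_other_glm_scoped_to_window(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-11", 90)
        b.rx("P1", "sulfonylurea", "2010-01-31", 60)   # day 30, inside 90d
        _, X = _features(b)
        strict = PrescriptionClassifier(variant="insulin_no_other_glm", window_days=90)
        assert strict.fit(X).predict(X)[0] == "T2D"

    def test_except_metformin_permits_metformin(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-11", 90)
        b.rx("P1", "metformin", "2010-01-31", 60)
        _, X = _features(b)
        strict = PrescriptionClassifier(variant="insulin_no_other_glm", window_days=90)
        lenient = PrescriptionClassifier(
            variant="insulin_no_other_glm_except_metformin", window_days=90)
        assert strict.fit(X).predict(X)[0] == "T2D"
        assert lenient.fit(X).predict(X)[0] == "T1D"

    def test_mdi_requires_both_components_coinitiated(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-06", 90)
        b.rx("P1", "insulin_short", "2010-01-06", 90)
        _, X = _features(b)
        assert X.loc["P1", "mdi_90"]
        est = PrescriptionClassifier(variant="mdi_no_other_glm", window_days=None)
        assert est.fit(X).predict(X)[0] == "T1D"

    def test_mdi_coinit_gap_beyond_limit_fails(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-06", 90)
        b.rx("P1", "insulin_short", "2010-03-01", 90)  # 54 days later
        _, X = _features(b)
        assert not X.loc["P1", "mdi_full"]
        relaxed = featurize(b.build()[0],
                            pd.DataFrame({"person_id": ["P1"], "diagnosis_date": [D0]}),
                            FeatureConfig(mdi_coinit_days=60))
        assert relaxed.loc["P1", "mdi_full"]

    def test_window_monotonicity_for_simple_insulin_family(self, small_synthetic):
        """Widening the window never shrinks the positive set for plain
        'at least one insulin' rules (not asserted for no-other-GLM forms)."""
        tables, labels, _ = small_synthetic
        from diabtype.cohort import build_cohort
        cohort, _ = build_cohort(tables, labels)
        X = featurize(tables, cohort)
        prev = None
        for w in (90, 180, 365, None):
            pos = set(X.index[PrescriptionClassifier("any_insulin", w).positive(X)])
            if prev is not None:
                assert prev <= pos
            prev = pos


class TestCombinations:
    def test_or_and_semantics(self, builder):
        b = _one_person(builder)
        b.rx("P1", "insulin_long", "2010-01-11", 90)  # C positive, B negative
        tables, X = _features(b)
        reg = registry()
        assert reg["B_or_C"].fit(X).predict(X)[0] == "T1D"
        assert reg["B_and_C"].fit(X).predict(X)[0] == "T2D"

    def test_set_inclusions(self, small_synthetic):
        """positives(X and Y) <= positives(X) <= positives(X or Y)."""
        tables, labels, _ = small_synthetic
        from diabtype.cohort import build_cohort
        cohort, _ = build_cohort(tables, labels)
        X = featurize(tables, cohort)
        reg = registry()
        for lhs in ("A", "B"):
            for rhs in ("C", "D"):
                p_l = set(X.index[np.asarray(reg[lhs].positive(X), dtype=bool)])
                p_and = set(X.index[np.asarray(
                    reg[f"{lhs}_and_{rhs}"].positive(X), dtype=bool)])
                p_or = set(X.index[np.asarray(
                    reg[f"{lhs}_or_{rhs}"].positive(X), dtype=bool)])
                assert p_and <= p_l <= p_or

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_combination_agrees_with_brute_force_tree_evaluation(self, data):
        """RuleCombination matches naive evaluation of the boolean tree."""
        n1 = data.draw(st.integers(0, 6))
        n2 = data.draw(st.integers(0, 6))
        ins90 = data.draw(st.booleans())
        mdi = data.draw(st.booleans())
        glm = data.draw(st.booleans())
        op = data.draw(st.sampled_from(["and", "or"]))
        r = data.draw(st.sampled_from([0.5, 4.0]))
        X = pd.DataFrame({
            "n_type1": [n1], "n_type2": [n2],
            "has_insulin_90": [ins90 or mdi], "mdi_90": [mdi], "has_glm_90": [glm],
            "has_glm_exmet_90": [glm], "has_metformin_90": [False],
            "has_insulin_full": [ins90 or mdi], "mdi_full": [mdi], "has_glm_full": [glm],
            "has_glm_exmet_full": [glm], "has_metformin_full": [False],
        })
        left = CodeRatioClassifier(threshold=r)
        right = PrescriptionClassifier("any_insulin", 90)
        combo = RuleCombination(left=left, right=right, op=op)
        lp = bool(left.positive(X).iloc[0])
        rp = bool(right.positive(X).iloc[0])
        expected = (lp and rp) if op == "and" else (lp or rp)
        assert bool(combo.positive(X).iloc[0]) is expected


class TestRegistry:
    def test_twelve_distinct_algorithms_plus_aliases(self):
        reg = registry()
        core = [k for k in reg if k not in ALIASES]
        assert len(core) == 12
        for alias, target in ALIASES.items():
            assert reg[alias] is reg[target]

    def test_headline_aliases_definition(self):
        reg = registry()
        opt = reg["optimized"]
        assert isinstance(opt.left, CodeRatioClassifier) and opt.left.threshold == 4.0
        assert opt.right.variant == "any_insulin" and opt.right.window_days == 90
        assert opt.op == "and"
        assert reg["high_ppv_t1"].right.variant == "mdi_no_other_glm"
        assert reg["high_sensitivity_t1"].op == "or"

    def test_estimators_are_sklearn_compatible(self):
        est = registry()["optimized"]
        params = est.get_params(deep=True)
        assert params["left__threshold"] == 4.0
        cloned = clone(est)
        cloned_params = cloned.get_params(deep=True)
        for key, value in params.items():
            if "__" in key or key == "op":  # leaf params; nested estimators are re-instantiated
                assert cloned_params[key] == value
        assert cloned is not est and cloned.left is not est.left

    def test_candidate_registry_covers_screened_families(self):
        cands = candidate_registry()
        families = {c["family"] for c in cands.values()}
        assert families == {"code", "rx"}
        assert len(cands) == 38

    def test_classify_total_function_never_abstains(self, builder):
        b = _one_person(builder)  # no events at all beyond the onset lab
        tables, _ = b.build()
        cohort = pd.DataFrame({"person_id": ["P1"], "diagnosis_date": [D0]})
        for name in ("A", "C", "optimized"):
            call = classify(tables, cohort, name)
            assert call.loc["P1"] in {"T1D", "T2D"}

    def test_unknown_algorithm_raises(self, builder):
        b = _one_person(builder)
        tables, _ = b.build()
        cohort = pd.DataFrame({"person_id": ["P1"], "diagnosis_date": [D0]})
        with pytest.raises(KeyError, match="unknown algorithm"):
            classify(tables, cohort, "nonsense")
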