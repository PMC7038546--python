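"""Classification rules as scikit-learn estimators.

Each estimator maps the person-level feature frame produced by
:func:`diabtype.features.featurize` to a binary diabetes-type call:
a positive rule evaluation is labelled ``"T1D"`` and a negative one
``"T2D"`` (rules never abstain).  Estimators follow the scikit-learn
protocol (``fit``/``predict``/``get_params``), so they compose with
pipelines and with :class:`RuleCombination`, which implements the
"and"/"or" pairing algebra used to build the combination algorithms.

The registry exposes the four selected single rules and their eight
pairings under their conventional letters:

* ``A``  - ratio of type 1 to type 2 codes >= 0.5
* ``B``  - ratio of type 1 to type 2 codes >= 4
* ``C``  - at least one insulin prescription within 90 days of diagnosis
* ``D``  - multiple daily injections with no other glucose-lowering drug

with aliases ``high_sensitivity_t1`` = B or C, ``high_ppv_t1`` = B and D,
and ``optimized`` = B and C for the three headline combinations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FeatureConfig, featurize, window_label

POSITIVE_LABEL = "T1D"
NEGATIVE_LABEL = "T2D"

RX_VARIANTS = (
    "any_insulin",
    "insulin_no_other_glm",
    "insulin_no_other_glm_except_metformin",
    "mdi",
    "mdi_no_other_glm",
    "mdi_no_other_glm_except_metformin",
    "any_metformin",
    "other_glm_only",
)


class BaseRuleClassifier(ClassifierMixin, BaseEstimator):
    """Common fit/predict plumbing for deterministic rule classifiers."""

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in self.required_columns_() if c not in X.columns]
        if missing:
            raise ValueError(f"feature frame missing columns: {missing}")
        self.classes_ = np.array([POSITIVE_LABEL, NEGATIVE_LABEL])
        self.n_features_in_ = X.shape[1]
        self.is_fitted_ = True
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.positive(X), dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not getattr(self, "is_fitted_", False):
            self.fit(X)
        pos = np.asarray(self.positive(X), dtype=bool)
        return np.where(pos, POSITIVE_LABEL, NEGATIVE_LABEL)

    # subclasses implement:
    def positive(self, X: pd.DataFrame) -> pd.Series:  # pragma: no cover
        raise NotImplementedError

    def required_columns_(self) -> tuple[str, ...]:  # pragma: no cover
        raise NotImplementedError


class CodeCountClassifier(BaseRuleClassifier):
    """Positive when at least ``min_count`` diabetes codes of one type exist.

    ``source`` restricts counting to principal or mixed encounter codes.
    """

    def __init__(self, code_class: str = "type1", source: str = "any", min_count: int = 1):
        self.code_class = code_class
        self.source = source
        self.min_count = min_count

    def _column(self) -> str:
        if self.code_class not in ("type1", "type2"):
            raise ValueError(f"code_class must be type1|type2, got {self.code_class!r}")
        if self.source == "any":
            return f"n_{self.code_class}"
        if self.source in ("principal", "mixed"):
            return f"n_{self.code_class}_{self.source}"
        raise ValueError(f"source must be any|principal|mixed, got {self.source!r}")

    def required_columns_(self):
        return (self._column(),)

    def positive(self, X):
        return X[self._column()] >= self.min_count


class CodeRatioClassifier(BaseRuleClassifier):
    """Positive when the ratio of type 1 to type 2 codes meets ``threshold``.

    With zero type 2 codes the ratio is treated as +infinity, so the rule is
    positive whenever at least one type 1 code exists; with no typed codes
    at all it is negative.
    """

    def __init__(self, threshold: float = 4.0):
        self.threshold = threshold

    def required_columns_(self):
        return ("n_type1", "n_type2")

    def positive(self, X):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        n1, n2 = X["n_type1"], X["n_type2"]
        return pd.Series(
            np.where(n2 > 0, n1 >= self.threshold * n2, n1 >= 1),
            index=X.index,
        )


class PrescriptionClassifier(BaseRuleClassifier):
    """Prescription-pattern rules (insulin timing, MDI, co-medication).

    ``window_days`` is 90, 180, 365 or None (all follow-up).  Insulin means
    a long-term prescription (>= 28 days); "no other glucose-lowering
    medication" is scoped to the same window as the insulin requirement,
    and the ``*_except_metformin`` forms permit metformin.
    """

    def __init__(self, variant: str = "any_insulin", window_days: int | None = None):
        self.variant = variant
        self.window_days = window_days

    def required_columns_(self):
        w = window_label(self.window_days)
        return (f"has_insulin_{w}", f"mdi_{w}", f"has_glm_{w}",
                f"has_glm_exmet_{w}", f"has_metformin_{w}")

    def positive(self, X):
        w = window_label(self.window_days)
        v = self.variant
        if v == "any_insulin":
            return X[f"has_insulin_{w}"]
        if v == "insulin_no_other_glm":
            return X[f"has_insulin_{w}"] & ~X[f"has_glm_{w}"]
        if v == "insulin_no_other_glm_except_metformin":
            return X[f"has_insulin_{w}"] & ~X[f"has_glm_exmet_{w}"]
        if v == "mdi":
            return X[f"mdi_{w}"]
        if v == "mdi_no_other_glm":
            return X[f"mdi_{w}"] & ~X[f"has_glm_{w}"]
        if v == "mdi_no_other_glm_except_metformin":
            return X[f"mdi_{w}"] & ~X[f"has_glm_exmet_{w}"]
        if v == "any_metformin":
            return X[f"has_metformin_{w}"]
        if v == "other_glm_only":
            return X[f"has_glm_exmet_{w}"]
        raise ValueError(f"unknown prescription variant {self.variant!r}")


class RuleCombination(BaseRuleClassifier):
    """Boolean pairing of two single rules with ``and`` or ``or``."""

    def __init__(self, left: BaseRuleClassifier = None, right: BaseRuleClassifier = None,
                 op: str = "and"):
        self.left = left
        self.right = right
        self.op = op

    def required_columns_(self):
        return tuple(self.left.required_columns_()) + tuple(self.right.required_columns_())

    def positive(self, X):
        if self.op not in ("and", "or"):
            raise ValueError(f"op must be 'and' or 'or', got {self.op!r}")
        lp = np.asarray(self.left.positive(X), dtype=bool)
        rp = np.asarray(self.right.positive(X), dtype=bool)
        combined = lp & rp if self.op == "and" else lp | rp
        return pd.Series(combined, index=X.index)


ALIASES = {
    "high_sensitivity_t1": "B_or_C",
    "high_ppv_t1": "B_and_D",
    "optimized": "B_and_C",
}


def _singles() -> dict[str, BaseRuleClassifier]:
    return {
        "A": CodeRatioClassifier(threshold=0.5),
        "B": CodeRatioClassifier(threshold=4.0),
        "C": PrescriptionClassifier(variant="any_insulin", window_days=90),
        "D": PrescriptionClassifier(variant="mdi_no_other_glm", window_days=None),
    }


def registry() -> dict[str, BaseRuleClassifier]:
    """The 12 evaluated algorithms (A-D and their 8 pairings) plus aliases."""
    algos = _singles()
    for lhs in ("A", "B"):
        for rhs in ("C", "D"):
            for op in ("and", "or"):
                algos[f"{lhs}_{op}_{rhs}"] = RuleCombination(
                    left=_singles()[lhs], right=_singles()[rhs], op=op
                )
    for alias, target in ALIASES.items():
        algos[alias] = algos[target]
    return algos


def candidate_registry() -> dict[str, dict]:
    """Every candidate single algorithm screened on the derivation cohort.

    Returns name -> {"estimator": classifier, "family": "code"|"rx"}, in a
    fixed order that doubles as the deterministic residual tie-break.
    """
    cands: dict[str, dict] = {}

    def add(name, est, family):
        cands[name] = {"estimator": est, "family": family}

    for cls in ("type1", "type2"):
        n = cls[-1]
        add(f"ge1_type{n}_code", CodeCountClassifier(code_class=cls, source="any"), "code")
        add(f"ge1_type{n}_principal", CodeCountClassifier(code_class=cls, source="principal"), "code")
        add(f"ge1_type{n}_mixed", CodeCountClassifier(code_class=cls, source="mixed"), "code")
    for r in (0.5, 0.75, 1, 2, 3, 4):
        add(f"ratio_ge_{r}", CodeRatioClassifier(threshold=float(r)), "code")

    windowed = (
        "any_insulin",
        "insulin_no_other_glm",
        "insulin_no_other_glm_except_metformin",
        "mdi",
        "mdi_no_other_glm",
        "mdi_no_other_glm_except_metformin",
    )
    for variant in windowed:
        for w in (None, 90, 180, 365):
            suffix = "any_time" if w is None else f"w{w}"
            add(f"{variant}_{suffix}", PrescriptionClassifier(variant=variant, window_days=w), "rx")
    add("any_metformin", PrescriptionClassifier(variant="any_metformin", window_days=None), "rx")
    add("other_glm", PrescriptionClassifier(variant="other_glm_only", window_days=None), "rx")
    return cands


def classify(
    tables, cohort: pd.DataFrame, algorithm, feature_cfg: FeatureConfig | None = None
) -> pd.Series:
    """Run one algorithm over event tables; returns T1D/T2D per person.

    ``algorithm`` is a registry name or an estimator instance.
    """
    if isinstance(algorithm, str):
        try:
            algorithm = registry()[algorithm]
        except KeyError:
            raise KeyError(
                f"unknown algorithm {algorithm!r}; known: {sorted(registry())}"
            ) from None
    X = featurize(tables, cohort, feature_cfg)
    calls = algorithm.fit(X).predict(X)
    return pd.Series(calls, index=X.index, name="call")
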