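"""Validation metrics: 2x2 counts, exact intervals, kappa, stratification.

The positive class is T1D throughout.  Proportion confidence intervals are
exact (Clopper-Pearson), computed from beta quantiles; Cohen's kappa is the
chance-corrected agreement of the algorithm with the reference standard.
Display rounding is half-up to one decimal for percentages and two decimals
for kappa; all internal values are unrounded.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import beta

POSITIVE_LABEL = "T1D"
NEGATIVE_LABEL = "T2D"

DEFAULT_STRATA_EDGES = (20.0, 40.0)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_classes(self) -> "ConfusionMatrix":
        """The same 2x2 table with T2D treated as the positive class."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclasses.dataclass(frozen=True)
class Proportion:
    """A proportion with its exact 95% interval; undefined when n = 0."""

    point: float | None
    lower: float | None
    upper: float | None
    defined: bool = True

    def as_percent(self) -> tuple[float, float, float]:
        if not self.defined:
            raise ValueError("proportion is undefined")
        return 100 * self.point, 100 * self.lower, 100 * self.upper


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (1.25 -> 1.3 at one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(calls: pd.Series, labels: pd.Series) -> ConfusionMatrix:
    """Cross-tabulate algorithm calls against reference labels.

    Both series are indexed by person_id; every call must have a label.
    """
    if len(calls) == 0:
        raise ValueError("no calls to evaluate")
    calls, labels = pd.Series(calls), pd.Series(labels)
    unmatched = calls.index.difference(labels.index)
    if len(unmatched):
        raise ValueError(f"calls without reference labels: {list(unmatched[:10])}")
    lab = labels.loc[calls.index]
    pos_call = calls == POSITIVE_LABEL
    pos_lab = lab == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int((pos_call & pos_lab).sum()),
        fp=int((pos_call & ~pos_lab).sum()),
        fn=int((~pos_call & pos_lab).sum()),
        tn=int((~pos_call & ~pos_lab).sum()),
    )


def exact_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval for x successes in n trials."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa of the 2x2 table: (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _proportion(x: int, n: int, level: float) -> Proportion:
    if n == 0:
        return Proportion(None, None, None, defined=False)
    lo, hi = exact_ci(x, n, level)
    return Proportion(x / n, lo, hi)


@dataclasses.dataclass(frozen=True)
class TestCharacteristics:
    cm: ConfusionMatrix
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    kappa: float
    ppv_defined: bool
    calculated_t1_proportion: float  # fraction of cohort called T1D
    true_t1_proportion: float        # fraction of cohort labelled T1D


def characteristics(
    cm: ConfusionMatrix,
    level: float = 0.95,
    ppv_convention: str = "tp_zero",
) -> TestCharacteristics:
    """Sensitivity, specificity, PPV, NPV with exact CIs, plus kappa.

    ``ppv_convention`` controls when PPV is reported as undefined:
    ``"tp_zero"`` (default) marks it undefined whenever no true positives
    were identified, even if false positives exist; ``"standard"`` marks it
    undefined only when there are no positive calls at all.  Degenerate
    denominators never raise; the affected metric is simply undefined.
    """
    if ppv_convention not in ("tp_zero", "standard"):
        raise ValueError("ppv_convention must be 'tp_zero' or 'standard'")
    ppv = _proportion(cm.tp, cm.tp + cm.fp, level)
    ppv_defined = ppv.defined and not (ppv_convention == "tp_zero" and cm.tp == 0)
    return TestCharacteristics(
        cm=cm,
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, level),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, level),
        ppv=ppv,
        npv=_proportion(cm.tn, cm.tn + cm.fn, level),
        kappa=kappa(cm),
        ppv_defined=ppv_defined,
        calculated_t1_proportion=(cm.tp + cm.fp) / cm.total,
        true_t1_proportion=(cm.tp + cm.fn) / cm.total,
    )


def strata_assign(ages: pd.Series, edges=DEFAULT_STRATA_EDGES) -> pd.Series:
    """Map ages to ordered stratum labels: all edges define left-closed bins."""
    edges = tuple(edges)
    labels = stratum_labels(edges)[1:]  # skip "all"
    bins = [-np.inf, *edges, np.inf]
    return pd.cut(ages, bins=bins, labels=labels, right=False).astype(str)


def stratum_labels(edges=DEFAULT_STRATA_EDGES) -> list[str]:
    edges = tuple(edges)
    labels = ["all"]
    prev = None
    for e in edges:
        if prev is None:
            labels.append(f"<{e:g}")
        elif float(e).is_integer():
            labels.append(f"{prev:g}-{int(e) - 1:g}")  # [20, 40) printed as 20-39
        else:
            labels.append(f"{prev:g}-<{e:g}")
        prev = e
    labels.append(f">={prev:g}")
    return labels


def _char_row(name: str, stratum: str, cm: ConfusionMatrix | None, level: float) -> dict:
    row: dict = {"algorithm": name, "stratum": stratum}
    if cm is None:
        row.update({k: np.nan for k in (
            "tp", "fp", "fn", "tn", "sensitivity", "specificity", "ppv", "npv",
            "kappa", "calculated_t1_proportion", "true_t1_proportion")})
        return row
    ch = characteristics(cm, level=level)
    row.update(tp=cm.tp, fp=cm.fp, fn=cm.fn, tn=cm.tn, kappa=ch.kappa,
               calculated_t1_proportion=ch.calculated_t1_proportion,
               true_t1_proportion=ch.true_t1_proportion)
    for metric in ("sensitivity", "specificity", "ppv", "npv"):
        p: Proportion = getattr(ch, metric)
        defined = p.defined and not (metric == "ppv" and not ch.ppv_defined)
        row[metric] = p.point if p.defined else np.nan
        row[f"{metric}_lo"] = p.lower if p.defined else np.nan
        row[f"{metric}_hi"] = p.upper if p.defined else np.nan
        if metric == "ppv":
            row["ppv_defined"] = defined
    return row


def evaluate_stratified(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    edges=DEFAULT_STRATA_EDGES,
    level: float = 0.95,
) -> pd.DataFrame:
    """Test characteristics per (algorithm, age stratum).

    ``cohort`` needs person_id, age_at_diagnosis and true_type;
    ``calls`` is a frame indexed by person_id with one column per
    algorithm.  The "all" stratum is the union of the age bins; empty
    strata yield rows with undefined metrics.
    """
    labels = cohort.set_index("person_id")["true_type"]
    ages = cohort.set_index("person_id")["age_at_diagnosis"]
    strat = strata_assign(ages, edges)
    rows = []
    for name in calls.columns:
        col = calls[name]
        for stratum in stratum_labels(edges):
            idx = col.index if stratum == "all" else strat.index[strat == stratum]
            idx = col.index.intersection(idx)
            cm = confusion(col.loc[idx], labels) if len(idx) else None
            rows.append(_char_row(name, stratum, cm, level))
    return pd.DataFrame(rows)


def proportion_curve(
    ages: pd.Series, is_t1d: pd.Series, window_years: float = 15.0
) -> pd.DataFrame:
    """Moving-average T1D proportion over age at diagnosis.

    For each integer age the proportion of persons whose age at diagnosis
    lies in the centered window [a - w/2, a + w/2] and who are classified
    (or labelled) T1D.  Ages whose window is empty are omitted.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    ages = np.asarray(ages, dtype=float)
    flag = np.asarray(is_t1d, dtype=bool)
    if len(ages) == 0:
        return pd.DataFrame(columns=["age", "proportion", "n"])
    half = window_years / 2.0
    grid = np.arange(int(np.floor(ages.min())), int(np.ceil(ages.max())) + 1)
    rows = []
    for a in grid:
        sel = (ages >= a - half) & (ages <= a + half)
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append({"age": int(a), "proportion": flag[sel].mean(), "n": n})
    return pd.DataFrame(rows)


def plot_proportion_curves(curves: dict[str, pd.DataFrame], ax=None):
    """Plot one or more proportion-vs-age curves (percent scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        style = {"linestyle": "--"} if label.lower().startswith("reference") else {}
        ax.plot(curve["age"], 100 * curve["proportion"], label=label, **style)
    ax.set_xlabel("Age at diagnosis (years)")
    ax.set_ylabel("Classified as type 1 (%)")
    ax.legend()
    return ax
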