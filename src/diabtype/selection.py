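"""Algorithm selection on the derivation cohort.

From the screened single candidates the procedure keeps, per family
(code-based and prescription-based), the most sensitive rule and the most
predictive rule: A/C by sensitivity, B/D by PPV.  The winners are paired
with "and" / "or" into eight combination algorithms, and among the twelve
resulting rules the headline picks are the arg-max by sensitivity, by PPV
and by kappa (the "optimized" algorithm).

Tie handling.  Ties are resolved by the greatest sensitivity + PPV sum.
For the sensitivity pick, the two top-ranked candidates are treated as
effectively tied when they disagree on at most ``near_tie_cases`` true
cases (default 1): nested rule variants routinely differ by a single case
while ranking oppositely on sensitivity and PPV, and the head-to-head sum
then decides.  PPV and kappa picks use exact ties only.  Residual ties
fall back to candidate order, so the procedure is a deterministic pure
function of its input metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

REQUIRED = ("name", "tp", "fp", "fn", "tn")


def _with_metrics(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"candidate frame missing columns: {missing}")
    out = df.copy().reset_index(drop=True)
    out["order"] = np.arange(len(out))
    out["sensitivity"] = out["tp"] / (out["tp"] + out["fn"])
    pos = out["tp"] + out["fp"]
    out["ppv"] = np.where(pos > 0, out["tp"] / pos.replace(0, 1), 0.0)
    n = out[["tp", "fp", "fn", "tn"]].sum(axis=1)
    p_o = (out["tp"] + out["tn"]) / n
    p_e = ((out["tp"] + out["fp"]) * (out["tp"] + out["fn"])
           + (out["fn"] + out["tn"]) * (out["fp"] + out["tn"])) / n**2
    out["kappa"] = np.where(p_e == 1.0, np.where(p_o == 1.0, 1.0, 0.0),
                            (p_o - p_e) / (1.0 - p_e))
    out["sum_sens_ppv"] = out["sensitivity"] + out["ppv"]
    return out


def _pick(df: pd.DataFrame, metric: str, near_tie_cases: int = 0) -> str:
    """Arg-max by ``metric`` with the tie policy described in the module."""
    ranked = df.sort_values(
        [metric, "sum_sens_ppv", "order"], ascending=[False, False, True],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    if len(ranked) > 1:
        runner = ranked.iloc[1]
        exact_tie = top[metric] == runner[metric]
        near_tie = (
            metric == "sensitivity"
            and abs(int(top["tp"]) - int(runner["tp"])) <= near_tie_cases
        )
        if exact_tie or near_tie:
            pair = ranked.iloc[:2].sort_values(
                ["sum_sens_ppv", "order"], ascending=[False, True], kind="mergesort"
            )
            return str(pair.iloc[0]["name"])
    return str(top["name"])


def select_single_algorithms(
    candidates: pd.DataFrame, near_tie_cases: int = 1
) -> dict[str, str]:
    """Pick A-D from the screened candidates.

    ``candidates`` needs columns name, family ("code"/"rx"), tp, fp, fn, tn,
    evaluated on the derivation cohort across all ages.
    """
    df = _with_metrics(candidates)
    if "family" not in df.columns:
        raise ValueError("candidate frame missing 'family' column")
    picks = {}
    for family, sens_key, ppv_key in (("code", "A", "B"), ("rx", "C", "D")):
        fam = df[df["family"] == family]
        if fam.empty:
            raise ValueError(f"no candidates for family {family!r}")
        picks[sens_key] = _pick(fam, "sensitivity", near_tie_cases)
        picks[ppv_key] = _pick(fam, "ppv")
    return picks


def combination_names(picks: dict[str, str]) -> list[tuple[str, str, str, str]]:
    """(combo label, left, op, right) for the eight pairings of A/B x C/D."""
    out = []
    for lhs in ("A", "B"):
        for rhs in ("C", "D"):
            for op in ("and", "or"):
                out.append((f"{lhs}_{op}_{rhs}", picks[lhs], op, picks[rhs]))
    return out


def select_headline(results: pd.DataFrame) -> dict[str, str]:
    """Best-sensitivity, best-PPV and best-kappa among the twelve rules."""
    df = _with_metrics(results)
    return {
        "best_sensitivity": _pick(df, "sensitivity"),
        "best_ppv": _pick(df, "ppv"),
        "best_kappa": _pick(df, "kappa"),
    }


def select_algorithms(
    candidates: pd.DataFrame,
    combined_results: pd.DataFrame | None = None,
    near_tie_cases: int = 1,
) -> dict[str, str]:
    """Full selection: A-D from the candidate screen, headline from the 12.

    When ``combined_results`` (metrics of the four winners plus their eight
    pairings) is omitted, only the A-D assignments are returned.
    """
    picks = select_single_algorithms(candidates, near_tie_cases)
    if combined_results is not None:
        picks.update(select_headline(combined_results))
    return picks


class AlgorithmSelector(BaseEstimator):
    """Estimator wrapper around the selection procedure.

    ``fit`` consumes the candidate screen (and optionally the metrics of
    the twelve final rules) and exposes the picks as fitted attributes
    ``A_`` ... ``D_``, ``best_sensitivity_``, ``best_ppv_``, ``best_kappa_``.
    """

    def __init__(self, near_tie_cases: int = 1):
        self.near_tie_cases = near_tie_cases

    def fit(self, X: pd.DataFrame, y=None, combined_results: pd.DataFrame | None = None):
        picks = select_algorithms(X, combined_results, self.near_tie_cases)
        for key, value in picks.items():
            setattr(self, f"{key}_", value)
        self.picks_ = picks
        return self
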