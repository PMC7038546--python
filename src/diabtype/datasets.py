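"""Published benchmark data for the classification rules.

These tables transcribe the operating characteristics reported by the
registry-based development and validation study the rule set originates
from: the derivation-cohort screen of every candidate single algorithm
(counts of rule-positive persons among 60 T1D and 10,136 T2D cases), and
the per-algorithm, per-age-stratum confusion matrices from the derivation
(n = 10,196) and validation (n = 5,101) cohorts.  They serve as inputs to
the selection procedure and as golden values for end-to-end checks; no
metric here is ever used inside the classification rules themselves.
"""

from __future__ import annotations

import pandas as pd

DERIVATION_N_T1D = 60
DERIVATION_N_T2D = 10136

#: candidate name -> (family, positives among T1D, positives among T2D)
CANDIDATE_SCREEN: dict[str, tuple[str, int, int]] = {
    "ge1_type1_code": ("code", 50, 142),
    "ge1_type1_principal": ("code", 42, 65),
    "ge1_type1_mixed": ("code", 38, 108),
    "ge1_type2_code": ("code", 43, 92),
    "ge1_type2_principal": ("code", 29, 25),
    "ge1_type2_mixed": ("code", 21, 66),
    "ratio_ge_0.5": ("code", 50, 97),
    "ratio_ge_0.75": ("code", 49, 81),
    "ratio_ge_1": ("code", 49, 78),
    "ratio_ge_2": ("code", 47, 47),
    "ratio_ge_3": ("code", 46, 38),
    "ratio_ge_4": ("code", 43, 32),
    "any_insulin_any_time": ("rx", 59, 3408),
    "any_insulin_w90": ("rx", 58, 615),
    "any_insulin_w180": ("rx", 58, 715),
    "any_insulin_w365": ("rx", 58, 844),
    "insulin_no_other_glm_any_time": ("rx", 36, 80),
    "insulin_no_other_glm_w90": ("rx", 43, 362),
    "insulin_no_other_glm_w180": ("rx", 44, 483),
    "insulin_no_other_glm_w365": ("rx", 45, 653),
    "insulin_no_other_glm_except_metformin_any_time": ("rx", 50, 275),
    "insulin_no_other_glm_except_metformin_w90": ("rx", 53, 451),
    "insulin_no_other_glm_except_metformin_w180": ("rx", 54, 566),
    "insulin_no_other_glm_except_metformin_w365": ("rx", 54, 727),
    "mdi_any_time": ("rx", 47, 273),
    "mdi_w90": ("rx", 7, 5),
    "mdi_w180": ("rx", 8, 9),
    "mdi_w365": ("rx", 12, 13),
    "mdi_no_other_glm_any_time": ("rx", 32, 9),
    "mdi_no_other_glm_w90": ("rx", 7, 2),
    "mdi_no_other_glm_w180": ("rx", 8, 6),
    "mdi_no_other_glm_w365": ("rx", 12, 11),
    "mdi_no_other_glm_except_metformin_any_time": ("rx", 42, 26),
    "mdi_no_other_glm_except_metformin_w90": ("rx", 7, 2),
    "mdi_no_other_glm_except_metformin_w180": ("rx", 8, 6),
    "mdi_no_other_glm_except_metformin_w365": ("rx", 12, 11),
    "any_metformin": ("rx", 22, 8979),
    "other_glm": ("rx", 10, 7673),
}

#: (algorithm, stratum) -> (tp, fp, fn, tn), derivation cohort
DERIVATION_MATRICES: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("A", "all"): (50, 97, 10, 10039),
    ("B", "all"): (43, 32, 17, 10104),
    ("C", "all"): (58, 615, 2, 9521),
    ("D", "all"): (32, 9, 28, 10127),
    ("A_and_C", "all"): (49, 52, 11, 10084),
    ("A_and_D", "all"): (28, 5, 32, 10131),
    ("B_and_C", "all"): (42, 19, 18, 10117),
    ("B_and_D", "all"): (25, 4, 35, 10132),
    ("A_or_C", "all"): (59, 660, 1, 9476),
    ("A_or_D", "all"): (54, 101, 6, 10035),
    ("B_or_C", "all"): (59, 628, 1, 9508),
    ("B_or_D", "all"): (50, 37, 10, 10099),
    ("A", "<20"): (23, 9, 0, 26),
    ("B", "<20"): (21, 5, 2, 30),
    ("C", "<20"): (23, 13, 0, 22),
    ("D", "<20"): (16, 3, 7, 32),
    ("A_and_C", "<20"): (23, 8, 0, 27),
    ("A_and_D", "<20"): (16, 2, 7, 33),
    ("B_and_C", "<20"): (21, 5, 2, 30),
    ("B_and_D", "<20"): (15, 2, 8, 33),
    ("A_or_C", "<20"): (23, 14, 0, 21),
    ("A_or_D", "<20"): (23, 10, 0, 25),
    ("B_or_C", "<20"): (23, 13, 0, 22),
    ("B_or_D", "<20"): (22, 6, 1, 29),
    ("A", "20-39"): (21, 53, 5, 700),
    ("B", "20-39"): (19, 16, 7, 737),
    ("C", "20-39"): (25, 80, 1, 673),
    ("D", "20-39"): (13, 3, 13, 750),
    ("A_and_C", "20-39"): (20, 23, 6, 730),
    ("A_and_D", "20-39"): (10, 1, 16, 752),
    ("B_and_C", "20-39"): (18, 8, 8, 745),
    ("B_and_D", "20-39"): (10, 1, 16, 752),
    ("A_or_C", "20-39"): (26, 110, 0, 643),
    ("A_or_D", "20-39"): (24, 55, 2, 698),
    ("B_or_C", "20-39"): (26, 88, 0, 665),
    ("B_or_D", "20-39"): (22, 18, 4, 735),
    ("A", ">=40"): (6, 35, 5, 9313),
    ("B", ">=40"): (3, 11, 8, 9337),
    ("C", ">=40"): (10, 522, 1, 8826),
    ("D", ">=40"): (3, 3, 8, 9345),
    ("A_and_C", ">=40"): (6, 21, 5, 9327),
    ("A_and_D", ">=40"): (2, 2, 9, 9346),
    ("B_and_C", ">=40"): (3, 6, 8, 9342),
    ("B_and_D", ">=40"): (0, 1, 11, 9347),
    ("A_or_C", ">=40"): (10, 536, 1, 8812),
    ("A_or_D", ">=40"): (7, 36, 4, 9312),
    ("B_or_C", ">=40"): (10, 527, 1, 8821),
    ("B_or_D", ">=40"): (6, 13, 5, 9335),
}

#: (algorithm, stratum) -> (tp, fp, fn, tn), validation cohort
VALIDATION_MATRICES: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("high_sensitivity_t1", "all"): (41, 280, 2, 4778),
    ("high_sensitivity_t1", "<20"): (14, 6, 0, 21),
    ("high_sensitivity_t1", "20-39"): (19, 41, 2, 300),
    ("high_sensitivity_t1", ">=40"): (8, 233, 0, 4457),
    ("high_ppv_t1", "all"): (16, 0, 27, 5058),
    ("high_ppv_t1", "<20"): (8, 0, 6, 27),
    ("high_ppv_t1", "20-39"): (6, 0, 15, 341),
    ("high_ppv_t1", ">=40"): (2, 0, 6, 4690),
    ("optimized", "all"): (28, 9, 15, 5049),
    ("optimized", "<20"): (12, 0, 2, 27),
    ("optimized", "20-39"): (12, 7, 9, 334),
    ("optimized", ">=40"): (4, 2, 4, 4688),
}


def candidate_screen() -> pd.DataFrame:
    """Derivation-cohort candidate screen as a selection-ready frame."""
    rows = []
    for name, (family, pos_t1d, pos_t2d) in CANDIDATE_SCREEN.items():
        rows.append({
            "name": name, "family": family,
            "tp": pos_t1d, "fp": pos_t2d,
            "fn": DERIVATION_N_T1D - pos_t1d,
            "tn": DERIVATION_N_T2D - pos_t2d,
        })
    return pd.DataFrame(rows)


def _matrix_frame(matrices: dict) -> pd.DataFrame:
    rows = [
        {"name": algo, "stratum": stratum, "tp": tp, "fp": fp, "fn": fn, "tn": tn}
        for (algo, stratum), (tp, fp, fn, tn) in matrices.items()
    ]
    return pd.DataFrame(rows)


def derivation_matrices(stratum: str | None = None) -> pd.DataFrame:
    df = _matrix_frame(DERIVATION_MATRICES)
    return df if stratum is None else df[df["stratum"] == stratum].reset_index(drop=True)


def validation_matrices(stratum: str | None = None) -> pd.DataFrame:
    df = _matrix_frame(VALIDATION_MATRICES)
    return df if stratum is None else df[df["stratum"] == stratum].reset_index(drop=True)
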