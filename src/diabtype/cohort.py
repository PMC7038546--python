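"""Cohort construction: onset detection, exclusions, labels, and the split.

Diabetes onset is the first occurrence of any of four criteria: outpatient
HbA1c >= 6.5%, outpatient fasting plasma glucose >= 7 mmol/L, a non-insulin
glucose-lowering prescription, or a long-term (>= 28 day) insulin
prescription.  Inpatient glucose measurements are ignored to avoid calling
acute stress hyperglycemia diabetes, and candidate events inside gestational
windows are discarded so that gestational diabetes is not mistaken for
incident diabetes.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd

from .icd9 import is_pregnancy_code
from .tables import EventTables, INSULIN_CLASSES

ONSET_PRIORITY = ("hba1c", "fpg", "glm_non_insulin", "long_term_insulin")


@dataclasses.dataclass
class OnsetConfig:
    """Thresholds, windows and calendar bounds for onset detection.

    Months are calendar months (pandas DateOffset arithmetic with
    end-of-month clamping), not 30-day blocks.
    """

    hba1c_threshold: float = 6.5          # %
    fpg_threshold: float = 7.0            # mmol/L
    insulin_min_duration: int = 28        # days
    delivery_pre_window: int = 9          # months before a delivery
    delivery_post_window: int = 6         # months after a delivery
    pregnancy_window: int = 9             # months around a pregnancy encounter
    enrol_start: str = "2002-01-01"
    enrol_end: str = "2015-12-31"
    followup_end: str = "2016-12-31"
    min_age: float = 1.5                  # years; excludes neonatal diabetes
    max_age: float = 100.0
    exclude_inpatient_hba1c: bool = True  # treat HbA1c like glucose when inpatient

    def __post_init__(self):
        self.enrol_start = pd.Timestamp(self.enrol_start)
        self.enrol_end = pd.Timestamp(self.enrol_end)
        self.followup_end = pd.Timestamp(self.followup_end)
        if not (self.enrol_start < self.enrol_end <= self.followup_end):
            raise ValueError("require enrol_start < enrol_end <= followup_end")
        if min(self.hba1c_threshold, self.fpg_threshold) <= 0:
            raise ValueError("thresholds must be positive")


def _merge_intervals(intervals: list[tuple[pd.Timestamp, pd.Timestamp]]):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def gestational_exclusion_windows(
    deliveries: pd.DataFrame,
    pregnancy_encounters: pd.DataFrame,
    cfg: OnsetConfig,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Closed date intervals around deliveries and pregnancy encounters.

    Each delivery contributes [delivery - pre, delivery + post]; each
    pregnancy-related encounter not already inside a delivery window
    contributes a symmetric window around itself.  Overlapping intervals
    are merged.
    """
    delivery_windows = [
        (d - pd.DateOffset(months=cfg.delivery_pre_window),
         d + pd.DateOffset(months=cfg.delivery_post_window))
        for d in pd.to_datetime(deliveries["date"]) if pd.notna(d)
    ]
    windows = list(delivery_windows)
    for d in pd.to_datetime(pregnancy_encounters["date"]):
        if pd.isna(d):
            continue
        if any(lo <= d <= hi for lo, hi in delivery_windows):
            continue
        windows.append(
            (d - pd.DateOffset(months=cfg.pregnancy_window),
             d + pd.DateOffset(months=cfg.pregnancy_window))
        )
    return _merge_intervals(windows)


def _onset_candidates(tables: EventTables, cfg: OnsetConfig) -> pd.DataFrame:
    """All candidate onset events: person_id, date, criterion, priority."""
    labs = tables.labs
    out: list[pd.DataFrame] = []

    hba1c = labs[(labs["test"] == "hba1c") & (labs["value"] >= cfg.hba1c_threshold)]
    if cfg.exclude_inpatient_hba1c:
        hba1c = hba1c[hba1c["setting"] == "outpatient"]
    out.append(pd.DataFrame({"person_id": hba1c["person_id"], "date": hba1c["date"],
                             "criterion": "hba1c"}))

    fpg = labs[(labs["test"] == "fpg") & (labs["value"] >= cfg.fpg_threshold)
               & (labs["setting"] == "outpatient")]
    out.append(pd.DataFrame({"person_id": fpg["person_id"], "date": fpg["date"],
                             "criterion": "fpg"}))

    rx = tables.prescriptions
    glm = rx[~rx["drug_class"].isin(INSULIN_CLASSES)]
    out.append(pd.DataFrame({"person_id": glm["person_id"], "date": glm["start_date"],
                             "criterion": "glm_non_insulin"}))

    ins = rx[rx["drug_class"].isin(INSULIN_CLASSES)
             & (rx["duration_days"] >= cfg.insulin_min_duration)]
    out.append(pd.DataFrame({"person_id": ins["person_id"], "date": ins["start_date"],
                             "criterion": "long_term_insulin"}))

    cand = pd.concat(out, ignore_index=True)
    cand["priority"] = cand["criterion"].map({c: i for i, c in enumerate(ONSET_PRIORITY)})
    return cand


def _drop_gestational(cand: pd.DataFrame, tables: EventTables, cfg: OnsetConfig) -> pd.DataFrame:
    """Discard candidates inside per-person gestational exclusion windows."""
    enc = tables.encounters
    preg_enc = enc[enc["icd9"].map(is_pregnancy_code)] if len(enc) else enc
    flagged = set(tables.deliveries["person_id"]) | set(preg_enc["person_id"])
    if not flagged:
        return cand
    keep = np.ones(len(cand), dtype=bool)
    for pid in flagged:
        windows = gestational_exclusion_windows(
            tables.deliveries[tables.deliveries["person_id"] == pid],
            preg_enc[preg_enc["person_id"] == pid],
            cfg,
        )
        if not windows:
            continue
        mask = cand["person_id"] == pid
        if not mask.any():
            continue
        dates = cand.loc[mask, "date"]
        inside = np.zeros(mask.sum(), dtype=bool)
        for lo, hi in windows:
            inside |= ((dates >= lo) & (dates <= hi)).to_numpy()
        keep[np.flatnonzero(mask)] = ~inside
    return cand[keep]


def detect_onsets(tables: EventTables, cfg: OnsetConfig | None = None) -> pd.DataFrame:
    """Earliest surviving onset candidate per person.

    Returns a frame with columns person_id, diagnosis_date, onset_criterion;
    persons with no qualifying event are absent.  Same-day ties are broken
    by criterion priority (hba1c > fpg > glm_non_insulin > long_term_insulin).
    """
    cfg = cfg or OnsetConfig()
    cand = _onset_candidates(tables, cfg)
    cand = cand.dropna(subset=["date"])
    cand = _drop_gestational(cand, tables, cfg)
    if cand.empty:
        return pd.DataFrame(columns=["person_id", "diagnosis_date", "onset_criterion"])
    first = (
        cand.sort_values(["person_id", "date", "priority"], kind="mergesort")
        .groupby("person_id", as_index=False)
        .first()
    )
    return first.rename(columns={"date": "diagnosis_date", "criterion": "onset_criterion"})[
        ["person_id", "diagnosis_date", "onset_criterion"]
    ]


def detect_onset(person_tables: EventTables, cfg: OnsetConfig | None = None):
    """Single-person convenience wrapper; returns (date, criterion) or None."""
    res = detect_onsets(person_tables, cfg)
    if res.empty:
        return None
    row = res.iloc[0]
    return row["diagnosis_date"], row["onset_criterion"]


def build_cohort(
    tables: EventTables,
    labels: pd.DataFrame,
    cfg: OnsetConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply onset detection and eligibility rules; return cohort + ledger.

    The exclusion ledger counts persons removed at each step, applied in
    order: no detected onset, onset outside the enrolment window, age at
    diagnosis outside [min_age, max_age], monogenic/secondary diabetes,
    missing diabetes type.  Counts sum to (input persons - cohort size).
    """
    cfg = cfg or OnsetConfig()
    persons = tables.persons
    onsets = detect_onsets(tables, cfg)
    ledger: dict[str, int] = {}

    merged = persons.merge(onsets, on="person_id", how="left")
    ledger["no_onset"] = int(merged["diagnosis_date"].isna().sum())
    merged = merged.dropna(subset=["diagnosis_date"])

    in_window = (merged["diagnosis_date"] >= cfg.enrol_start) & (
        merged["diagnosis_date"] <= cfg.enrol_end
    )
    ledger["out_of_window"] = int((~in_window).sum())
    merged = merged[in_window]

    age = (merged["diagnosis_date"] - merged["birth_date"]).dt.days / 365.25
    merged = merged.assign(age_at_diagnosis=age)
    age_ok = (merged["age_at_diagnosis"] >= cfg.min_age) & (
        merged["age_at_diagnosis"] <= cfg.max_age
    )
    ledger["age"] = int((~age_ok).sum())
    merged = merged[age_ok]

    unlabeled = set(merged["person_id"]) - set(labels["person_id"])
    if unlabeled:
        raise ValueError(
            f"persons with detected onset but no reference label: {sorted(unlabeled)[:10]}"
        )
    merged = merged.merge(labels[["person_id", "true_type"]], on="person_id")

    mono = merged["true_type"] == "monogenic_secondary"
    ledger["monogenic_secondary"] = int(mono.sum())
    merged = merged[~mono]
    missing = merged["true_type"] == "missing"
    ledger["missing_label"] = int(missing.sum())
    merged = merged[~missing]

    cohort = merged[
        ["person_id", "diagnosis_date", "age_at_diagnosis", "onset_criterion", "true_type"]
    ].reset_index(drop=True)
    return cohort, ledger


def split_assignment(person_id: str, seed: int, fraction_derivation: float) -> str:
    """Deterministic per-person split: pure function of (seed, person_id)."""
    digest = hashlib.blake2b(
        f"{seed}|{person_id}".encode(), digest_size=8
    ).digest()
    u = int.from_bytes(digest, "big") / 2**64
    return "derivation" if u < fraction_derivation else "validation"


def randomize_split(
    cohort: pd.DataFrame, seed: int, fraction_derivation: float = 2 / 3
) -> pd.DataFrame:
    """Assign each person independently at random to derivation/validation.

    The assignment hashes (seed, person_id), so it is reproducible across
    machines and stable under re-ordering of input rows.
    """
    if not 0 < fraction_derivation <= 1:
        raise ValueError("fraction_derivation must be in (0, 1]")
    out = cohort.copy()
    out["split"] = [
        split_assignment(pid, seed, fraction_derivation) for pid in out["person_id"]
    ]
    return out
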