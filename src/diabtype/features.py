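"""Person-level features for the classification rules.

Every rule in the registry is a function of a small set of post-diagnosis
summaries: diabetes-typed code counts (split by principal vs mixed source)
and windowed prescription indicators.  ``featurize`` computes all of them
in one vectorized pass so that rule evaluation is pure column arithmetic.

Windowed quantities use start dates in the closed interval
[diagnosis_date, diagnosis_date + w days]; the unlimited window runs to
``followup_end``.  Only long-term insulin prescriptions (duration >= 28
days) count as insulin; non-insulin agents carry no duration minimum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .icd9 import code_type
from .tables import EventTables, INSULIN_CLASSES

#: window labels -> days (None = through followup_end)
WINDOWS: dict[str, int | None] = {"90": 90, "180": 180, "365": 365, "full": None}

COUNT_COLUMNS = (
    "n_type1", "n_type2",
    "n_type1_principal", "n_type1_mixed",
    "n_type2_principal", "n_type2_mixed",
)


@dataclasses.dataclass
class FeatureConfig:
    followup_end: str = "2016-12-31"
    insulin_min_duration: int = 28    # days
    mdi_coinit_days: int = 31         # long- and short-acting started within this many days

    def __post_init__(self):
        self.followup_end = pd.Timestamp(self.followup_end)


def window_label(window_days: int | None) -> str:
    for label, days in WINDOWS.items():
        if days == window_days:
            return label
    raise ValueError(f"unsupported window: {window_days!r} (choose from {list(WINDOWS.values())})")


def count_codes(
    encounters: pd.DataFrame, diagnosis_date, horizon_end
) -> dict[str, int]:
    """Diabetes-typed code counts for one person in [diagnosis, horizon]."""
    enc = encounters[
        (encounters["date"] >= pd.Timestamp(diagnosis_date))
        & (encounters["date"] <= pd.Timestamp(horizon_end))
    ]
    types = enc["icd9"].map(code_type)
    counts = {}
    for t in ("type1", "type2"):
        sel = enc[types == t]
        counts[f"n_{t}"] = len(sel)
        counts[f"n_{t}_principal"] = int((sel["source"] == "principal").sum())
        counts[f"n_{t}_mixed"] = int((sel["source"] == "mixed").sum())
    return counts


def _window_end(d0: pd.Series, days: int | None, cfg: FeatureConfig) -> pd.Series:
    if days is None:
        return pd.Series(cfg.followup_end, index=d0.index)
    return d0 + pd.to_timedelta(days, unit="D")


def featurize(
    tables: EventTables,
    cohort: pd.DataFrame,
    cfg: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Compute the full feature frame, indexed by person_id.

    ``cohort`` needs columns person_id and diagnosis_date.  Output columns:
    the six code counts plus, per window w in {90, 180, 365, full}:
    has_insulin_w, mdi_w, has_glm_w (any non-insulin agent),
    has_glm_exmet_w (non-insulin agents other than metformin), and
    has_metformin_w.
    """
    cfg = cfg or FeatureConfig()
    idx = cohort["person_id"].to_numpy()
    d0 = cohort.set_index("person_id")["diagnosis_date"]
    out = pd.DataFrame(index=pd.Index(idx, name="person_id"))

    # --- code counts -----------------------------------------------------
    enc = tables.encounters.merge(
        cohort[["person_id", "diagnosis_date"]], on="person_id", how="inner"
    )
    enc = enc[(enc["date"] >= enc["diagnosis_date"]) & (enc["date"] <= cfg.followup_end)]
    enc = enc.assign(ct=enc["icd9"].map(code_type))
    enc = enc[enc["ct"].isin(("type1", "type2"))]
    for col in COUNT_COLUMNS:
        out[col] = 0
    if len(enc):
        grouped = enc.groupby(["person_id", "ct", "source"]).size()
        for (t, s), name in (
            (("type1", "principal"), "n_type1_principal"),
            (("type1", "mixed"), "n_type1_mixed"),
            (("type2", "principal"), "n_type2_principal"),
            (("type2", "mixed"), "n_type2_mixed"),
        ):
            try:
                sub = grouped.xs((t, s), level=("ct", "source"))
            except KeyError:
                continue
            out[name] = sub.reindex(out.index).fillna(0).astype(int)
        out["n_type1"] = out["n_type1_principal"] + out["n_type1_mixed"]
        out["n_type2"] = out["n_type2_principal"] + out["n_type2_mixed"]

    # --- prescriptions ---------------------------------------------------
    rx = tables.prescriptions.merge(
        cohort[["person_id", "diagnosis_date"]], on="person_id", how="inner"
    )
    rx = rx[rx["start_date"] >= rx["diagnosis_date"]]
    is_ins = rx["drug_class"].isin(INSULIN_CLASSES)
    qual_ins = rx[is_ins & (rx["duration_days"] >= cfg.insulin_min_duration)]
    non_ins = rx[~is_ins]

    for label, days in WINDOWS.items():
        for name, sub in (
            (f"has_insulin_{label}", qual_ins),
            (f"has_glm_{label}", non_ins),
            (f"has_glm_exmet_{label}", non_ins[non_ins["drug_class"] != "metformin"]),
            (f"has_metformin_{label}", non_ins[non_ins["drug_class"] == "metformin"]),
        ):
            if len(sub):
                end = _window_end(sub["diagnosis_date"], days, cfg)
                hit = sub.loc[sub["start_date"] <= end, "person_id"].unique()
            else:
                hit = []
            out[name] = out.index.isin(hit)

    # --- multiple daily injections ---------------------------------------
    # every (long, short) start-date pair per person; MDI in a window needs
    # both starts inside it and within mdi_coinit_days of each other
    long_rx = qual_ins[qual_ins["drug_class"] == "insulin_long"]
    short_rx = qual_ins[qual_ins["drug_class"] == "insulin_short"]
    for label in WINDOWS:
        out[f"mdi_{label}"] = False
    if len(long_rx) and len(short_rx):
        pairs = long_rx[["person_id", "start_date", "diagnosis_date"]].merge(
            short_rx[["person_id", "start_date"]],
            on="person_id",
            suffixes=("_long", "_short"),
        )
        close = (
            (pairs["start_date_long"] - pairs["start_date_short"]).dt.days.abs()
            <= cfg.mdi_coinit_days
        )
        for label, days in WINDOWS.items():
            end = _window_end(pairs["diagnosis_date"], days, cfg)
            ok = close & (pairs["start_date_long"] <= end) & (pairs["start_date_short"] <= end)
            hit = pairs.loc[ok, "person_id"].unique()
            out[f"mdi_{label}"] = out.index.isin(hit)

    return out


def feature_columns() -> list[str]:
    cols = list(COUNT_COLUMNS)
    for label in WINDOWS:
        cols += [
            f"has_insulin_{label}", f"mdi_{label}", f"has_glm_{label}",
            f"has_glm_exmet_{label}", f"has_metformin_{label}",
        ]
    return cols
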