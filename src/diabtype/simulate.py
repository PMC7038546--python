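"""Seeded synthetic EHR generator emulating a diabetes-register population.

The generator emits the five event tables plus reference labels with the
statistical structure the classification rules exploit: a small T1D
fraction with young ages at onset, type-concordant diabetes coding, and
sharply different prescription profiles between types (nearly universal
early insulin and multiple daily injections in T1D; metformin and other
oral agents dominating T2D).

Default parameters are the study conditions of the derivation registry:
age at diagnosis 22.7 (SD 12.6) years for T1D and 55.9 (11.4) for T2D;
per-type prescription probabilities (e.g. P(any insulin | T1D) = 0.983,
P(insulin within 90 days | T1D) = 0.967, P(metformin | T2D) = 0.886); and
code-count marginals matched to the registry's printed medians and
interquartile ranges via negative-binomial quantile fits.

Binary prescription events are drawn through a Gaussian copula tied to a
per-person latent "severity" variable, which induces the within-person
correlation between coding intensity and prescribing while leaving every
configured marginal probability exact.  Nesting is enforced by
construction: one uniform drives the insulin chain, so insulin-within-90-
days implies any-insulin; the multiple-daily-injection draw is conditional
on insulin use.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm, truncnorm

from .metrics import ConfusionMatrix
from .tables import EventTables, empty_event_tables

NOISE_CODES = ("401.9", "272.4", "428.0", "486", "599.0")


@dataclasses.dataclass
class AgeAtOnsetModel:
    """Truncated-normal age at diagnosis per type (years)."""

    t1d_mean: float = 22.7
    t1d_sd: float = 12.6
    t2d_mean: float = 55.9
    t2d_sd: float = 11.4
    min_age: float = 1.5
    max_age: float = 100.0

    def draw(self, rng: np.random.Generator, is_t1d: np.ndarray) -> np.ndarray:
        mean = np.where(is_t1d, self.t1d_mean, self.t2d_mean)
        sd = np.where(is_t1d, self.t1d_sd, self.t2d_sd)
        a = (self.min_age - mean) / sd
        b = (self.max_age - mean) / sd
        return truncnorm.ppf(rng.uniform(size=len(mean)), a, b, loc=mean, scale=sd)


@dataclasses.dataclass
class CodeCountModel:
    """Negative-binomial code-count marginals fitted to median/IQR.

    ``median``/``iqr`` are the target quantiles; for the degenerate
    median-0/IQR-0 case ``p_positive`` (the fraction with at least one
    code) identifies the distribution instead (geometric fit).
    """

    median: float
    iqr: float
    p_positive: float | None = None

    def nb_params(self) -> tuple[float, float]:
        return fit_nbinom_quantiles(self.median, self.iqr, self.p_positive)


@dataclasses.dataclass
class CodingModel:
    type1: CodeCountModel
    type2: CodeCountModel
    p_principal_type1: float = 0.65
    p_principal_type2: float = 0.5


@dataclasses.dataclass
class RxModel:
    """Per-type prescription event probabilities (all in [0, 1])."""

    p_any_insulin: float
    p_insulin_90d: float
    p_mdi: float
    p_metformin: float
    p_other_glm: float

    def validate(self):
        probs = dataclasses.asdict(self)
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if self.p_insulin_90d > self.p_any_insulin:
            raise ValueError(
                "infeasible nesting: p_insulin_90d exceeds p_any_insulin"
            )
        if self.p_mdi > self.p_any_insulin:
            raise ValueError("infeasible nesting: p_mdi exceeds p_any_insulin")


def _default_coding() -> dict[str, CodingModel]:
    return {
        "T1D": CodingModel(
            type1=CodeCountModel(median=3, iqr=4),
            type2=CodeCountModel(median=0, iqr=1),
        ),
        "T2D": CodingModel(
            type1=CodeCountModel(median=0, iqr=0, p_positive=0.014),
            type2=CodeCountModel(median=1, iqr=3),
        ),
    }


def _default_rx() -> dict[str, RxModel]:
    return {
        "T1D": RxModel(p_any_insulin=0.983, p_insulin_90d=0.967, p_mdi=0.783,
                       p_metformin=0.367, p_other_glm=0.167),
        "T2D": RxModel(p_any_insulin=0.336, p_insulin_90d=0.061, p_mdi=0.027,
                       p_metformin=0.886, p_other_glm=0.757),
    }


@dataclasses.dataclass
class SyntheticConfig:
    n_persons: int = 15297
    seed: int = 0
    t1d_fraction: float = 0.008
    p_female_t1d: float = 0.533
    p_female_t2d: float = 0.439
    age_model: AgeAtOnsetModel = dataclasses.field(default_factory=AgeAtOnsetModel)
    coding_model: dict[str, CodingModel] = dataclasses.field(default_factory=_default_coding)
    rx_model: dict[str, RxModel] = dataclasses.field(default_factory=_default_rx)
    severity_rho: float = 0.5            # latent coding/prescribing coupling
    pregnancy_rate: float = 0.04         # fraction of women with a delivery
    onset_lab_mix: float = 0.7           # share of onsets anchored by HbA1c (rest FPG)
    p_inpatient_glucose_noise: float = 0.1
    enrol_start: str = "2002-01-01"
    enrol_end: str = "2015-12-31"
    followup_end: str = "2016-12-31"

    def validate(self):
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        if not 0 <= self.t1d_fraction <= 1:
            raise ValueError("t1d_fraction must be in [0, 1]")
        if not -1 < self.severity_rho < 1:
            raise ValueError("severity_rho must be in (-1, 1)")
        for model in self.rx_model.values():
            model.validate()


def fit_nbinom_quantiles(
    median: float, iqr: float, p_positive: float | None = None
) -> tuple[float, float]:
    """Fit scipy ``nbinom`` parameters (r, p) to target quantiles.

    When median = IQR = 0 the quantiles are uninformative and a geometric
    distribution is identified from ``p_positive`` instead.  Otherwise a
    deterministic grid search over dispersion and mean minimizes the
    absolute error in (median, IQR), preferring a mean close to the median
    among equally good fits.
    """
    if median == 0 and iqr == 0:
        if not p_positive or not (0 < p_positive < 1):
            raise ValueError("median-0/IQR-0 count model needs p_positive in (0, 1)")
        mean = p_positive / (1 - p_positive)  # geometric: P(X=0) = 1/(1+mean)
        r = 1.0
        return r, r / (r + mean)
    rs = np.geomspace(0.2, 16.0, 40)
    means = np.linspace(0.05, 3.0 * max(median, 1.0) + 3.0, 120)
    rr, mm = np.meshgrid(rs, means, indexing="ij")
    pp = rr / (rr + mm)
    q25 = nbinom.ppf(0.25, rr, pp)
    q50 = nbinom.ppf(0.50, rr, pp)
    q75 = nbinom.ppf(0.75, rr, pp)
    score = np.abs(q50 - median) + np.abs((q75 - q25) - iqr) + 0.01 * np.abs(mm - median)
    i, j = np.unravel_index(int(np.argmin(score)), score.shape)
    r, mean = float(rs[i]), float(means[j])
    return r, r / (r + mean)


def _copula_uniform(rng, z, rho, n):
    """Uniform marginals correlated with the latent severity z."""
    eps = rng.standard_normal(n)
    return norm.cdf(rho * z + np.sqrt(1 - rho**2) * eps)


def generate(config: SyntheticConfig) -> tuple[EventTables, pd.DataFrame, dict[str, Any]]:
    """Generate event tables, reference labels and a ground-truth record.

    Fully reproducible from ``config.seed``; all dates are day-resolution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    if n == 0:
        return empty_event_tables(), pd.DataFrame(columns=["person_id", "true_type"]), {
            "config": _params_record(config), "n_persons": 0,
        }

    enrol_start = pd.Timestamp(config.enrol_start)
    enrol_days = (pd.Timestamp(config.enrol_end) - enrol_start).days
    followup_end = pd.Timestamp(config.followup_end)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    is_t1d = rng.uniform(size=n) < config.t1d_fraction
    true_type = np.where(is_t1d, "T1D", "T2D")
    female = rng.uniform(size=n) < np.where(is_t1d, config.p_female_t1d, config.p_female_t2d)
    age = config.age_model.draw(rng, is_t1d)
    d0 = enrol_start + pd.to_timedelta(rng.integers(0, enrol_days + 1, size=n), unit="D")
    birth = d0 - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")
    horizon = (followup_end - d0).days.to_numpy()

    z = rng.standard_normal(n)  # latent severity
    rho = config.severity_rho

    persons = pd.DataFrame({
        "person_id": pid,
        "sex": np.where(female, "female", "male"),
        "birth_date": birth,
    })
    labels = pd.DataFrame({"person_id": pid, "true_type": true_type})

    # --- code counts (severity-coupled for the type-concordant count) ----
    nb = {
        t: {
            c: config.coding_model[t].__dict__[c].nb_params()
            for c in ("type1", "type2")
        }
        for t in ("T1D", "T2D")
    }
    counts = {}
    for c in ("type1", "type2"):
        u_coupled = _copula_uniform(rng, z, rho, n)
        u_free = rng.uniform(size=n)
        # concordant count (type1 codes for T1D, type2 for T2D) follows severity
        concordant = is_t1d if c == "type1" else ~is_t1d
        u = np.where(concordant, u_coupled, u_free)
        r_arr = np.where(is_t1d, nb["T1D"][c][0], nb["T2D"][c][0])
        p_arr = np.where(is_t1d, nb["T1D"][c][1], nb["T2D"][c][1])
        counts[c] = nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), r_arr, p_arr).astype(int)

    enc_rows = []
    for c, code_pool in (("type1", ("250.01", "250.03")), ("type2", ("250.00", "250.02"))):
        total = counts[c]
        reps = np.repeat(np.arange(n), total)
        if len(reps) == 0:
            continue
        p_prin = np.where(
            is_t1d[reps],
            config.coding_model["T1D"].__dict__[f"p_principal_{c}"],
            config.coding_model["T2D"].__dict__[f"p_principal_{c}"],
        )
        principal = rng.uniform(size=len(reps)) < p_prin
        offsets = rng.integers(0, np.minimum(horizon[reps], 1460) + 1)
        enc_rows.append(pd.DataFrame({
            "person_id": pid[reps],
            "date": d0[reps] + pd.to_timedelta(offsets, unit="D"),
            "icd9": rng.choice(code_pool, size=len(reps)),
            "source": np.where(principal, "principal", "mixed"),
            "setting": np.where(principal, "inpatient", "outpatient"),
        }))

    # background (non-diabetes) coding noise
    n_noise = rng.poisson(1.0, size=n)
    reps = np.repeat(np.arange(n), n_noise)
    if len(reps):
        offsets = rng.integers(-365, np.minimum(horizon[reps], 1460) + 1)
        enc_rows.append(pd.DataFrame({
            "person_id": pid[reps],
            "date": d0[reps] + pd.to_timedelta(offsets, unit="D"),
            "icd9": rng.choice(NOISE_CODES, size=len(reps)),
            "source": rng.choice(["principal", "mixed"], size=len(reps), p=[0.2, 0.8]),
            "setting": rng.choice(["inpatient", "outpatient"], size=len(reps), p=[0.3, 0.7]),
        }))

    # --- prescriptions ----------------------------------------------------
    rxm = config.rx_model
    p_any = np.where(is_t1d, rxm["T1D"].p_any_insulin, rxm["T2D"].p_any_insulin)
    p_90 = np.where(is_t1d, rxm["T1D"].p_insulin_90d, rxm["T2D"].p_insulin_90d)
    p_mdi = np.where(is_t1d, rxm["T1D"].p_mdi, rxm["T2D"].p_mdi)
    p_met = np.where(is_t1d, rxm["T1D"].p_metformin, rxm["T2D"].p_metformin)
    p_oth = np.where(is_t1d, rxm["T1D"].p_other_glm, rxm["T2D"].p_other_glm)

    # single copula uniform drives the nested insulin chain, so
    # within-90-days implies any-insulin by construction
    u_ins = _copula_uniform(rng, z, rho, n)
    ins_90 = u_ins < p_90
    ins_any = u_ins < p_any
    # conditional MDI draw keeps the marginal exactly p_mdi
    with np.errstate(divide="ignore", invalid="ignore"):
        p_mdi_cond = np.where(p_any > 0, np.minimum(p_mdi / np.maximum(p_any, 1e-12), 1.0), 0.0)
    mdi = ins_any & (rng.uniform(size=n) < p_mdi_cond)
    metformin = rng.uniform(size=n) < p_met
    other_glm = rng.uniform(size=n) < p_oth

    ins_start = np.where(
        ins_90,
        rng.integers(0, 91, size=n),
        rng.integers(91, 367, size=n),
    )
    rx_rows = []

    def add_rx(mask, drug_class, start_days, duration):
        if not np.any(mask):
            return
        rx_rows.append(pd.DataFrame({
            "person_id": pid[mask],
            "drug_class": drug_class,
            "start_date": d0[mask] + pd.to_timedelta(start_days[mask], unit="D"),
            "duration_days": duration,
        }))

    add_rx(ins_any & mdi, "insulin_long", ins_start, 90)
    add_rx(ins_any & mdi, "insulin_short", ins_start, 90)
    single_class = rng.choice(["insulin_intermediate", "insulin_premixed"], size=n, p=[0.6, 0.4])
    for cls in ("insulin_intermediate", "insulin_premixed"):
        add_rx(ins_any & ~mdi & (single_class == cls), cls, ins_start, 90)
    add_rx(metformin, "metformin", rng.integers(0, 366, size=n), 60)
    other_class = rng.choice(["sulfonylurea", "dpp4", "agi"], size=n, p=[0.7, 0.2, 0.1])
    oth_start = rng.integers(0, 366, size=n)
    for cls in ("sulfonylurea", "dpp4", "agi"):
        add_rx(other_glm & (other_class == cls), cls, oth_start, 60)
    # sub-threshold insulin noise: never qualifies as long-term insulin
    noise_ins = rng.uniform(size=n) < 0.05
    add_rx(noise_ins, "insulin_short", rng.integers(0, 301, size=n), 7)

    # --- labs -------------------------------------------------------------
    lab_rows = []
    use_hba1c = rng.uniform(size=n) < config.onset_lab_mix
    lab_rows.append(pd.DataFrame({
        "person_id": pid,
        "date": d0,
        "test": np.where(use_hba1c, "hba1c", "fpg"),
        "value": np.where(
            use_hba1c,
            np.maximum(6.6, rng.normal(8.0, 1.5, size=n)).round(1),
            np.maximum(7.1, rng.normal(9.0, 1.5, size=n)).round(1),
        ),
        "setting": "outpatient",
    }))
    # routine follow-up HbA1c, sometimes below the diagnostic threshold
    fu_off = rng.integers(90, 366, size=n)
    lab_rows.append(pd.DataFrame({
        "person_id": pid,
        "date": d0 + pd.to_timedelta(fu_off, unit="D"),
        "test": "hba1c",
        "value": np.maximum(4.5, rng.normal(7.4, 1.0, size=n)).round(1),
        "setting": "outpatient",
    }))
    # pre-diagnosis inpatient stress hyperglycemia (must not trigger onset)
    stress = rng.uniform(size=n) < config.p_inpatient_glucose_noise
    if np.any(stress):
        off = rng.integers(30, 401, size=n)
        lab_rows.append(pd.DataFrame({
            "person_id": pid[stress],
            "date": d0[stress] - pd.to_timedelta(off[stress], unit="D"),
            "test": "fpg",
            "value": rng.uniform(7.5, 15.0, size=int(stress.sum())).round(1),
            "setting": "inpatient",
        }))

    # --- deliveries -------------------------------------------------------
    pregnant = female & (rng.uniform(size=n) < config.pregnancy_rate)
    delivery_off = rng.integers(480, 901, size=n)
    deliveries = pd.DataFrame({
        "person_id": pid[pregnant],
        "date": d0[pregnant] + pd.to_timedelta(delivery_off[pregnant], unit="D"),
        "kind": "delivery",
    })
    if np.any(pregnant):
        enc_rows.append(pd.DataFrame({
            "person_id": pid[pregnant],
            "date": d0[pregnant] + pd.to_timedelta(delivery_off[pregnant] - 240, unit="D"),
            "icd9": "650",
            "source": "mixed",
            "setting": "outpatient",
        }))

    def _concat(rows, table):
        if rows:
            df = pd.concat(rows, ignore_index=True)
            return df.sort_values(["person_id", df.columns[1]], kind="mergesort").reset_index(drop=True)
        from .tables import empty_table
        return empty_table(table)

    tables = EventTables(
        persons=persons,
        encounters=_concat(enc_rows, "encounters"),
        prescriptions=_concat(rx_rows, "prescriptions"),
        labs=_concat(lab_rows, "labs"),
        deliveries=deliveries.reset_index(drop=True),
    )
    params = {
        "config": _params_record(config),
        "n_persons": n,
        "n_t1d": int(is_t1d.sum()),
        "nbinom_fits": {t: {c: nb[t][c] for c in nb[t]} for t in nb},
    }
    return tables, labels, params


def _params_record(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)


def empirical_rx_probabilities(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Observed per-type frequencies of the configured prescription events.

    Used by parameter-recovery checks: rows are the rx-model probabilities,
    columns T1D/T2D.
    """
    lab = labels.loc[features.index]
    rows = {}
    for name, col in (
        ("p_any_insulin", "has_insulin_full"),
        ("p_insulin_90d", "has_insulin_90"),
        ("p_mdi", "mdi_full"),
        ("p_metformin", "has_metformin_full"),
        ("p_other_glm", "has_glm_exmet_full"),
    ):
        rows[name] = {
            t: float(features.loc[lab == t, col].mean()) for t in ("T1D", "T2D")
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# constructive cohorts from a target confusion matrix

_POSITIVE_CODES = ("250.01", "250.01", "250.03", "250.01")


def _archetype_events(pid: str, d0: pd.Timestamp, positive: bool, onset_value: float):
    """Events making every registry rule fire (positive) or stay silent."""
    enc, rx = [], []
    if positive:
        for i, code in enumerate(_POSITIVE_CODES):
            enc.append({"person_id": pid, "date": d0 + pd.Timedelta(days=10 * (i + 1)),
                        "icd9": code,
                        "source": "principal" if i < 2 else "mixed",
                        "setting": "inpatient" if i < 2 else "outpatient"})
        for cls in ("insulin_long", "insulin_short"):
            rx.append({"person_id": pid, "drug_class": cls,
                       "start_date": d0 + pd.Timedelta(days=10), "duration_days": 90})
    else:
        enc.append({"person_id": pid, "date": d0 + pd.Timedelta(days=10),
                    "icd9": "250.00", "source": "mixed", "setting": "outpatient"})
        rx.append({"person_id": pid, "drug_class": "metformin",
                   "start_date": d0 + pd.Timedelta(days=5), "duration_days": 30})
    lab = {"person_id": pid, "date": d0, "test": "hba1c",
           "value": onset_value, "setting": "outpatient"}
    return enc, rx, lab


def generate_from_matrix(
    cm: ConfusionMatrix,
    seed: int = 0,
    age: float = 30.0,
    start: str = "2005-01-01",
) -> tuple[EventTables, pd.DataFrame]:
    """Construct a minimal cohort realizing ``cm`` under every registry rule.

    True-positive and false-positive persons receive the positive archetype
    (four type 1 codes, no type 2 codes, co-initiated long- and short-acting
    insulin 10 days after diagnosis, no other glucose-lowering drug);
    false-negative and true-negative persons the negative archetype (one
    type 2 code, metformin only).  Labels are T1D for the tp/fn groups and
    T2D for fp/tn, so classify -> confusion round-trips to ``cm`` exactly
    for any rule in the registry, including all combinations.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    groups = (("tp", True, "T1D", cm.tp), ("fp", True, "T2D", cm.fp),
              ("fn", False, "T1D", cm.fn), ("tn", False, "T2D", cm.tn))
    persons, encs, rxs, labs, label_rows = [], [], [], [], []
    i = 0
    for tag, positive, label, count in groups:
        for _ in range(count):
            pid = f"M{i:06d}"
            d0 = start + pd.Timedelta(days=int(rng.integers(0, 365)))
            onset_value = float(np.round(rng.uniform(6.6, 10.0), 1))
            enc, rx, lab = _archetype_events(pid, d0, positive, onset_value)
            encs += enc
            rxs += rx
            labs.append(lab)
            persons.append({
                "person_id": pid,
                "sex": "female" if i % 2 == 0 else "male",
                "birth_date": d0 - pd.Timedelta(days=int(round(age * 365.25))),
            })
            label_rows.append({"person_id": pid, "true_type": label})
            i += 1
    from .tables import empty_table

    def frame(rows, table):
        return pd.DataFrame(rows) if rows else empty_table(table)

    tables = EventTables(
        persons=frame(persons, "persons"),
        encounters=frame(encs, "encounters"),
        prescriptions=frame(rxs, "prescriptions"),
        labs=frame(labs, "labs"),
        deliveries=empty_table("deliveries"),
    )
    return tables, frame(label_rows, "labels")
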