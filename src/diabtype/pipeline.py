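"""End-to-end orchestration: simulate/ingest -> cohort -> classify -> select.

All randomness flows from the single top-level seed; re-running with an
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import OnsetConfig, build_cohort, randomize_split
from .features import FeatureConfig, featurize
from .metrics import (DEFAULT_STRATA_EDGES, evaluate_stratified, round_half_up)
from .rules import ALIASES, candidate_registry, registry
from .selection import select_headline, select_single_algorithms
from .simulate import SyntheticConfig, generate
from .tables import EventTables, read_event_tables, read_labels

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    input_dir: str | None = None      # None -> simulate
    algorithms: tuple[str, ...] = ("A", "B", "C", "D", "A_and_C", "A_and_D",
                                   "B_and_C", "B_and_D", "A_or_C", "A_or_D",
                                   "B_or_C", "B_or_D")
    strata_edges: tuple[float, float] = DEFAULT_STRATA_EDGES
    fraction_derivation: float = 2 / 3
    run_selection: bool = True
    onset: OnsetConfig = dataclasses.field(default_factory=OnsetConfig)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("onset", OnsetConfig), ("features", FeatureConfig),
                         ("synthetic", SyntheticConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        if "strata_edges" in kwargs:
            kwargs["strata_edges"] = tuple(kwargs["strata_edges"])
        cfg = cls(**kwargs)
        cfg.synthetic.seed = cfg.seed
        return cfg


def _resolve(names) -> dict[str, object]:
    reg = registry()
    out = {}
    for name in names:
        if name not in reg:
            raise KeyError(f"unknown algorithm {name!r}")
        out[name] = reg[name]
    return out


def classify_all(tables: EventTables, cohort: pd.DataFrame, algorithms,
                 feature_cfg: FeatureConfig) -> pd.DataFrame:
    """One call column per algorithm, indexed by person_id."""
    X = featurize(tables, cohort, feature_cfg)
    calls = {}
    for name, est in algorithms.items():
        calls[name] = pd.Series(est.fit(X).predict(X), index=X.index)
    return pd.DataFrame(calls)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (optionally write) the report."""
    if config.input_dir is None:
        config.synthetic.seed = config.seed
        tables, labels, sim_params = generate(config.synthetic)
    else:
        tables = read_event_tables(config.input_dir)
        labels = read_labels(Path(config.input_dir) / "labels.csv")
        sim_params = None

    cohort, ledger = build_cohort(tables, labels, config.onset)
    cohort = randomize_split(cohort, seed=config.seed,
                             fraction_derivation=config.fraction_derivation)

    algorithms = _resolve(config.algorithms)
    calls = classify_all(tables, cohort, algorithms, config.features)
    results = evaluate_stratified(cohort, calls, edges=config.strata_edges)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "exclusion_ledger": ledger,
        "cohort": {
            "n": int(len(cohort)),
            "n_derivation": int((cohort["split"] == "derivation").sum()),
            "n_validation": int((cohort["split"] == "validation").sum()),
            "n_t1d": int((cohort["true_type"] == "T1D").sum()),
        },
        "results": _results_records(results),
    }
    if sim_params is not None:
        report["synthetic"] = {"n_t1d_true": sim_params["n_t1d"]}

    if config.run_selection:
        deriv = cohort[cohort["split"] == "derivation"]
        if len(deriv) and (deriv["true_type"] == "T1D").any():
            report["selection"] = _run_selection(tables, deriv, config)

    report_json = json.dumps(report, indent=2, sort_keys=True, default=float)
    report["config_hash"] = hashlib.sha256(report_json.encode()).hexdigest()[:16]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_out = cohort.copy()
        cohort_out["diagnosis_date"] = cohort_out["diagnosis_date"].dt.strftime("%Y-%m-%d")
        cohort_out.to_csv(out / "cohort.csv", index=False)
        calls.rename_axis("person_id").to_csv(out / "calls.csv")
        results.to_csv(out / "metrics.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                    default=float))
    return report


def _run_selection(tables, derivation: pd.DataFrame, config: RunConfig) -> dict:
    """Candidate screen + headline selection on the derivation cohort."""
    cands = candidate_registry()
    X_calls = classify_all(
        tables, derivation, {n: c["estimator"] for n, c in cands.items()},
        config.features,
    )
    screen = evaluate_stratified(derivation, X_calls, edges=config.strata_edges)
    screen = screen[screen["stratum"] == "all"].rename(columns={"algorithm": "name"})
    screen["family"] = screen["name"].map(lambda n: cands[n]["family"])
    picks = select_single_algorithms(screen)

    final_calls = classify_all(tables, derivation, _resolve(
        [a for a in config.algorithms]), config.features)
    final = evaluate_stratified(derivation, final_calls, edges=config.strata_edges)
    final = final[final["stratum"] == "all"].rename(columns={"algorithm": "name"})
    picks.update(select_headline(final))
    return picks


def _results_records(results: pd.DataFrame) -> list[dict]:
    records = []
    for _, row in results.iterrows():
        rec = {k: row[k] for k in ("algorithm", "stratum")}
        for k in ("tp", "fp", "fn", "tn"):
            rec[k] = None if pd.isna(row[k]) else int(row[k])
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            if pd.isna(row[k]):
                rec[k] = None
            else:
                rec[k] = float(row[k])
                rec[f"{k}_display"] = f"{round_half_up(100 * row[k], 1):.1f}"
        rec["kappa"] = None if pd.isna(row["kappa"]) else float(row["kappa"])
        if rec["kappa"] is not None:
            rec["kappa_display"] = f"{round_half_up(row['kappa'], 2):.2f}"
        if "ppv_defined" in row.index and row.get("ppv_defined") is False:
            rec["ppv_display"] = "undefined"
        records.append(rec)
    return records
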