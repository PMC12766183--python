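"""End-to-end pipeline: simulate/load -> filter -> impute -> split ->
standardize -> sex-specific selection -> model fitting -> evaluation ->
report.

Each stage reads its inputs from and writes its artifacts to the run
directory, so the CLI can execute stages individually; a manifest records
the config hash and every artifact so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from proteorisk import evaluation as ev
from proteorisk import preprocess as pp
from proteorisk.models import (RiskModel, fit_base_and_extended,
                               protein_associations)
from proteorisk.selection import SelectionConfig, SelectionResult, run_sex_specific_selection
from proteorisk.simulate import (CohortTable, SimConfig, generate_cohort,
                                 inject_missingness, read_cohort, write_cohort)

log = logging.getLogger("proteorisk")

__all__ = ["RunConfig", "run_pipeline", "make_report"]

STAGES = ["simulate", "preprocess", "select", "fit", "evaluate", "report"]


@dataclass
class RunConfig:
    """Declarative run description (YAML/JSON serializable)."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None     # SimConfig fields
    input: dict | None = None        # covariates/proteins/lod_flags paths
    preprocess: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValueError("exactly one of 'simulate' and 'input' must be given")
        self.sim_config()      # validate eagerly
        self.selection_config()

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data.update(overrides)
        return cls(**data)

    def sim_config(self) -> SimConfig | None:
        if self.simulate is None:
            return None
        d = dict(self.simulate)
        d.setdefault("seed", self.seed)
        for k in ("informative_male", "informative_female"):
            if k in d and d[k] is not None:
                d[k] = {int(i): float(v) for i, v in dict(d[k]).items()}
        for k in ("missing_rate_range", "lod_quantile_range"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        cfg = SimConfig(**d)
        cfg.validate()
        return cfg

    def selection_config(self) -> SelectionConfig:
        d = dict(self.selection)
        d.setdefault("seed", self.seed)
        cfg = SelectionConfig(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()

    @property
    def horizon(self) -> float:
        if self.simulate is not None:
            return float(self.simulate.get("horizon", 10.0))
        return float((self.input or {}).get("horizon", 10.0))

    @property
    def cuts(self) -> tuple[float, ...]:
        return tuple(self.evaluation.get("cuts", (0.05, 0.10)))


def _timed(manifest: dict, stage: str):
    class _T:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            if exc_type is not None:
                manifest["failed_stage"] = stage
                log.error("stage %s: FAILED after %.1fs", stage, dt)
                return False
            log.info("stage %s: done in %.1fs", stage, dt)
            return False
    return _T()


def _paths(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    return {
        "cohort_dir": out / "cohort",
        "covariates": out / "cohort" / "covariates.csv",
        "proteins": out / "cohort" / "proteins.csv",
        "lod_flags": out / "cohort" / "lod_flags.csv",
        "filter_report": out / "preprocess" / "filter_report.json",
        "analyzed_covariates": out / "preprocess" / "covariates_analyzed.csv",
        "proteins_std": out / "preprocess" / "proteins_imputed_std.csv",
        "scaler": out / "preprocess" / "scaler.csv",
        "split": out / "preprocess" / "split.json",
        "selection_male": out / "selection" / "selection_male.json",
        "selection_female": out / "selection" / "selection_female.json",
        "selection_male_tsv": out / "selection" / "selection_male.tsv",
        "selection_female_tsv": out / "selection" / "selection_female.tsv",
        "overlap": out / "selection" / "overlap.json",
        "models": out / "models" / "models.json",
        "associations": out / "models" / "associations.csv",
        "predictions": out / "models" / "predictions.csv",
        "evaluation_dir": out / "evaluation",
        "report": out / "report.md",
        "manifest": out / "manifest.json",
    }


def _load_cohort(cfg: RunConfig) -> CohortTable:
    p = _paths(cfg)
    return read_cohort(p["covariates"], p["proteins"], p["lod_flags"],
                       horizon=cfg.horizon)


def stage_simulate(cfg: RunConfig) -> CohortTable:
    p = _paths(cfg)
    if cfg.simulate is not None:
        sim = cfg.sim_config()
        cohort = inject_missingness(generate_cohort(sim), sim)
        write_cohort(cohort, p["cohort_dir"], config=sim)
    else:
        inp = cfg.input
        cohort = read_cohort(inp["covariates"], inp["proteins"],
                             inp.get("lod_flags"), horizon=cfg.horizon)
        write_cohort(cohort, p["cohort_dir"])
    return cohort


def stage_preprocess(cfg: RunConfig) -> None:
    p = _paths(cfg)
    cohort = _load_cohort(cfg)
    pre = cfg.preprocess
    retained, report = pp.filter_proteins(
        cohort.proteins, cohort.lod_flags,
        max_missing=pre.get("max_missing_protein", 0.20),
        max_lod=pre.get("max_lod", 0.25))
    prot = cohort.proteins[retained]
    keep_rows = pp.filter_participants(prot, max_missing=pre.get("max_missing_participant", 0.50))
    report.participants_excluded = len(prot) - len(keep_rows)
    cov = cohort.covariates.iloc[keep_rows].reset_index(drop=True)
    prot = prot.iloc[keep_rows].reset_index(drop=True)

    prot_complete = pp.impute(prot, covariates=cov,
                              n_iterations=pre.get("impute_iterations", 5),
                              seed=cfg.seed,
                              estimator=pre.get("impute_estimator", "forest"))
    analyzed = CohortTable(cov, prot_complete,
                           pd.DataFrame(np.zeros(prot_complete.shape, dtype=bool),
                                        columns=prot_complete.columns),
                           cfg.horizon)
    assignment = pp.split(analyzed, pre.get("derivation_fraction", 0.70), seed=cfg.seed)
    der_rows = cov.index[cov["participant_id"].isin(set(assignment.derivation_ids))]
    prot_std, scaler = pp.standardize(prot_complete, der_rows)

    p["filter_report"].parent.mkdir(parents=True, exist_ok=True)
    p["filter_report"].write_text(json.dumps(report.to_dict(), indent=2))
    cov.to_csv(p["analyzed_covariates"], index=False)
    prot_std.to_csv(p["proteins_std"], index=False)
    scaler.to_csv(p["scaler"], index_label="protein")
    p["split"].write_text(json.dumps(assignment.to_dict(), indent=2))


def _load_analyzed(cfg: RunConfig) -> tuple[CohortTable, dict]:
    p = _paths(cfg)
    cov = pd.read_csv(p["analyzed_covariates"])
    prot = pd.read_csv(p["proteins_std"])
    split = json.loads(p["split"].read_text())
    cohort = CohortTable(cov, prot,
                         pd.DataFrame(np.zeros(prot.shape, dtype=bool),
                                      columns=prot.columns), cfg.horizon)
    return cohort, split


def stage_select(cfg: RunConfig, sex: str = "both") -> None:
    p = _paths(cfg)
    cohort, split = _load_analyzed(cfg)
    derivation = cohort.subset(split["derivation_ids"])
    sel_cfg = cfg.selection_config()
    if sex == "both":
        res_m, res_f, overlap = run_sex_specific_selection(derivation, sel_cfg)
        results = {"male": res_m, "female": res_f}
        p["overlap"].parent.mkdir(parents=True, exist_ok=True)
        p["overlap"].write_text(json.dumps(overlap, indent=2))
    else:
        from proteorisk.selection import bootstrap_stability
        res = bootstrap_stability(derivation.stratum(sex), sel_cfg, sex_stratum=sex)
        results = {sex: res}
        p["overlap"].parent.mkdir(parents=True, exist_ok=True)
    for s, res in results.items():
        p[f"selection_{s}"].write_text(json.dumps(res.to_dict(), indent=2))
        res.to_frame().to_csv(p[f"selection_{s}_tsv"], sep="\t", index=False)


def _load_selection(cfg: RunConfig, sex: str) -> SelectionResult:
    p = _paths(cfg)
    d = json.loads(p[f"selection_{sex}"].read_text())
    return SelectionResult(
        sex_stratum=d["sex_stratum"],
        frequencies=pd.Series(d["frequencies"], name="frequency"),
        selected=d["selected"], n_bootstrap=d["n_bootstrap"],
        frequency_threshold=d["frequency_threshold"],
        per_bootstrap_lambda=d.get("per_bootstrap_lambda", []))


def stage_fit(cfg: RunConfig) -> None:
    p = _paths(cfg)
    cohort, split = _load_analyzed(cfg)
    derivation = cohort.subset(split["derivation_ids"])
    validation = cohort.subset(split["validation_ids"])
    selections = {s: _load_selection(cfg, s) for s in ("male", "female")}
    models = fit_base_and_extended(derivation, selections, horizon=cfg.horizon)

    p["models"].parent.mkdir(parents=True, exist_ok=True)
    p["models"].write_text(json.dumps(
        {sex: {"base": base.to_dict(), "extended": ext.to_dict()}
         for sex, (base, ext) in models.items()}, indent=2))

    union = sorted(set(selections["male"].selected) | set(selections["female"].selected))
    if union:
        assoc = protein_associations(validation, union, horizon=cfg.horizon)
        pd.DataFrame([dataclasses.asdict(a) for a in assoc]).to_csv(
            p["associations"], index=False)
    else:
        pd.DataFrame(columns=["protein", "sex_stratum", "hazard_ratio_per_sd",
                              "ci_low", "ci_high", "p_value", "interaction_p"]
                     ).to_csv(p["associations"], index=False)

    frames = []
    for sex, (base, ext) in models.items():
        stratum = validation.stratum(sex)
        rb, re_ = ev.model_risks(stratum, base, ext)
        frames.append(pd.DataFrame({
            "participant_id": stratum.covariates["participant_id"],
            "sex": sex, "base_risk": rb, "extended_risk": re_}))
    pd.concat(frames).sort_values("participant_id").to_csv(p["predictions"], index=False)


def stage_evaluate(cfg: RunConfig) -> dict[str, ev.EvalReport]:
    p = _paths(cfg)
    cohort, split = _load_analyzed(cfg)
    derivation = cohort.subset(split["derivation_ids"])
    validation = cohort.subset(split["validation_ids"])
    models_raw = json.loads(p["models"].read_text())
    preds = pd.read_csv(p["predictions"])
    eval_cfg = cfg.evaluation
    n_boot = int(eval_cfg.get("n_bootstrap_ci", 1000))
    status = eval_cfg.get("status_method", "km")
    out_dir = p["evaluation_dir"]
    out_dir.mkdir(parents=True, exist_ok=True)

    reports: dict[str, ev.EvalReport] = {}
    merged = validation.covariates.merge(preds, on="participant_id", suffixes=("", "_pred"))
    for stratum in ("male", "female", "overall"):
        if stratum == "overall":
            sub = merged
        else:
            sub = merged[merged["sex"] == stratum]
        rep = ev.evaluate_predictions(
            sub["follow_up_time"].to_numpy(), sub["event"].to_numpy(),
            sub["base_risk"].to_numpy(), sub["extended_risk"].to_numpy(),
            ids=sub["participant_id"].to_numpy(), cuts=cfg.cuts,
            horizon=cfg.horizon, status=status, n_boot=n_boot,
            seed=cfg.seed, stratum=stratum)
        if stratum != "overall":
            sel = _load_selection(cfg, stratum)
            base = RiskModel.from_dict(models_raw[stratum]["base"])
            rep.incremental_c = ev.incremental_c(
                base, sel.selected, derivation.stratum(stratum),
                validation.stratum(stratum), horizon=cfg.horizon)
            rep.incremental_c.to_csv(out_dir / f"incremental_c_{stratum}.csv", index=False)
        (out_dir / f"eval_{stratum}.json").write_text(
            json.dumps(rep.to_dict(), indent=2))
        rep.calibration_base.to_csv(out_dir / f"calibration_base_{stratum}.csv", index=False)
        rep.calibration_extended.to_csv(out_dir / f"calibration_extended_{stratum}.csv",
                                        index=False)
        roc_b, _ = ev.roc_at_horizon(sub["base_risk"].to_numpy(),
                                     sub["follow_up_time"].to_numpy(),
                                     sub["event"].to_numpy(), cfg.horizon, status)
        roc_e, _ = ev.roc_at_horizon(sub["extended_risk"].to_numpy(),
                                     sub["follow_up_time"].to_numpy(),
                                     sub["event"].to_numpy(), cfg.horizon, status)
        roc_b.to_csv(out_dir / f"roc_base_{stratum}.csv", index=False)
        roc_e.to_csv(out_dir / f"roc_extended_{stratum}.csv", index=False)
        reports[stratum] = rep

    rows = []
    for metric, get in (
            ("c_base", lambda r: r.c_base[0]),
            ("c_base_ci_low", lambda r: r.c_base[1]),
            ("c_base_ci_high", lambda r: r.c_base[2]),
            ("c_extended", lambda r: r.c_extended[0]),
            ("c_extended_ci_low", lambda r: r.c_extended[1]),
            ("c_extended_ci_high", lambda r: r.c_extended[2]),
            ("delta_c_p", lambda r: r.delta_c_p),
            ("nri_total_pct", lambda r: 100 * r.nri.nri_total),
            ("nri_events_pct", lambda r: 100 * r.nri.nri_events),
            ("nri_nonevents_pct", lambda r: 100 * r.nri.nri_nonevents),
            ("idi", lambda r: r.idi.idi)):
        rows.append({"metric": metric,
                     **{s: get(reports[s]) for s in reports}})
    pd.DataFrame(rows).to_csv(out_dir / "performance.tsv", sep="\t", index=False)
    return reports


def stage_report(cfg: RunConfig) -> str:
    from proteorisk.report import make_report
    return make_report(cfg)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the evaluation reports plus manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                      "seed": cfg.seed, "stages": []}
    reports = None
    try:
        with _timed(manifest, "simulate"):
            stage_simulate(cfg)
        manifest["stages"].append("simulate")
        with _timed(manifest, "preprocess"):
            stage_preprocess(cfg)
        manifest["stages"].append("preprocess")
        with _timed(manifest, "select"):
            stage_select(cfg)
        manifest["stages"].append("select")
        with _timed(manifest, "fit"):
            stage_fit(cfg)
        manifest["stages"].append("fit")
        with _timed(manifest, "evaluate"):
            reports = stage_evaluate(cfg)
        manifest["stages"].append("evaluate")
        with _timed(manifest, "report"):
            stage_report(cfg)
        manifest["stages"].append("report")
    finally:
        p = _paths(cfg)
        manifest["artifacts"] = sorted(
            str(q.relative_to(out)) for q in out.rglob("*") if q.is_file()
            and q.name != "manifest.json")
        manifest["complete"] = len(manifest["stages"]) == len(STAGES)
        p["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"reports": reports, "manifest": manifest}


def make_report(cfg: RunConfig) -> str:
    from proteorisk.report import make_report as _mk
    return _mk(cfg)
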