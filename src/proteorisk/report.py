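"""Human-readable markdown run summary.

Mirrors the usual epidemiological reporting layout: a baseline
characteristics table compared by event status (t-tests for continuous
variables, chi-square without continuity correction for categorical ones),
the discrimination/reclassification performance table, per-protein hazard
ratios (forest-plot data) and per-protein incremental C.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["make_report", "baseline_table", "chi2_stat"]

CONTINUOUS = ["age", "sbp", "total_cholesterol", "hdl_cholesterol"]
CATEGORICAL = [("current_smoker", "Current smoker"), ("sex", "Male sex")]


def chi2_stat(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (no continuity correction)."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def baseline_table(covariates: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by event status with significance tests."""
    ev = covariates["event"].astype(bool)
    groups = {"no_event": covariates[~ev], "event": covariates[ev]}
    rows = []
    for col in CONTINUOUS:
        a = groups["no_event"][col].dropna()
        b = groups["event"][col].dropna()
        p = stats.ttest_ind(a, b).pvalue if len(a) > 1 and len(b) > 1 else np.nan
        rows.append({
            "characteristic": col,
            "total": f"{covariates[col].mean():.1f} ({covariates[col].std():.1f})",
            "no_event": f"{a.mean():.1f} ({a.std():.1f})",
            "event": f"{b.mean():.1f} ({b.std():.1f})",
            "p_value": _fmt_p(p)})
    for col, label in CATEGORICAL:
        ind = ((covariates[col] == "male") if col == "sex"
               else covariates[col].astype(bool))
        tab = pd.crosstab(ind, ev).reindex(index=[False, True], columns=[False, True],
                                           fill_value=0).to_numpy()
        p = chi2_stat(tab)[1] if tab.min() >= 0 and (tab.sum(axis=1) > 0).all() else np.nan
        def _pct(mask):
            return f"{ind[mask].sum()} ({100 * ind[mask].mean():.1f})"
        rows.append({
            "characteristic": label,
            "total": f"{ind.sum()} ({100 * ind.mean():.1f})",
            "no_event": _pct(~ev), "event": _pct(ev), "p_value": _fmt_p(p)})
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame) -> str:
    lines = ["| " + " | ".join(str(c) for c in df.columns) + " |",
             "|" + "---|" * len(df.columns)]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def _fmt_ci(point: float, lo: float, hi: float, scale: float = 1.0,
            digits: int = 3) -> str:
    return (f"{point * scale:.{digits}f} ({lo * scale:.{digits}f}, "
            f"{hi * scale:.{digits}f})")


def _performance_rows(reports: dict[str, dict]) -> pd.DataFrame:
    rows = []
    order = [s for s in ("male", "female", "overall") if s in reports]
    metrics = [
        ("C-statistic (base)", lambda r: _fmt_ci(*r["c_base"])),
        ("C-statistic (+proteins)", lambda r: _fmt_ci(*r["c_extended"])),
        ("P for C comparison", lambda r: _fmt_p(r["delta_c_p"])),
        ("NRI total (%)", lambda r: _fmt_ci(r["nri"]["nri_total"],
                                            *r["nri"]["ci_total"], scale=100, digits=1)),
        ("NRI events (%)", lambda r: _fmt_ci(r["nri"]["nri_events"],
                                             *r["nri"]["ci_events"], scale=100, digits=1)),
        ("NRI non-events (%)", lambda r: _fmt_ci(r["nri"]["nri_nonevents"],
                                                 *r["nri"]["ci_nonevents"], scale=100, digits=1)),
        ("IDI", lambda r: _fmt_ci(r["idi"]["idi"], r["idi"]["ci_low"],
                                  r["idi"]["ci_high"])),
    ]
    for name, fn in metrics:
        row = {"metric": name}
        for s in order:
            row[s] = fn(reports[s])
        rows.append(row)
    return pd.DataFrame(rows)


def make_report(cfg) -> str:
    """Assemble report.md from pipeline artifacts; returns the text."""
    out = Path(cfg.out_dir)
    needed = {
        "analyzed covariates": out / "preprocess" / "covariates_analyzed.csv",
        "filter report": out / "preprocess" / "filter_report.json",
        "selection overlap": out / "selection" / "overlap.json",
        "evaluation": out / "evaluation" / "eval_overall.json",
    }
    for label, path in needed.items():
        if not path.exists():
            raise FileNotFoundError(f"missing pipeline artifact for report: {label} ({path})")

    cov = pd.read_csv(needed["analyzed covariates"])
    filt = json.loads(needed["filter report"].read_text())
    overlap = json.loads(needed["selection overlap"].read_text())
    reports = {}
    for s in ("male", "female", "overall"):
        path = out / "evaluation" / f"eval_{s}.json"
        if path.exists():
            reports[s] = json.loads(path.read_text())

    parts = ["# Risk model extension run report", ""]
    parts += ["## Cohort and filtering", "",
              f"- analyzed participants: {len(cov)} "
              f"({int(cov['event'].sum())} events)",
              f"- proteins in: {filt['proteins_in']}, retained: {filt['proteins_retained']} "
              f"(excluded for missingness: {filt['proteins_excluded_missing']}, "
              f"for below-LOD: {filt['proteins_excluded_lod']})",
              f"- participants excluded by protein missingness: {filt['participants_excluded']}",
              ""]
    parts += ["## Baseline characteristics by event status", "",
              _md_table(baseline_table(cov)), ""]

    parts += ["## Selected proteins", ""]
    n_sel = sum(len(v) for v in overlap.values())
    if n_sel == 0:
        parts += ["No proteins selected in either sex stratum.", ""]
    else:
        for key, label in (("shared", "Both sexes"), ("male_only", "Male only"),
                           ("female_only", "Female only")):
            vals = ", ".join(overlap[key]) if overlap[key] else "(none)"
            parts += [f"- {label}: {vals}"]
        parts += [""]

    if reports:
        parts += ["## Predictive performance (validation set)", "",
                  _md_table(_performance_rows(reports)), ""]

    assoc_path = out / "models" / "associations.csv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path)
        parts += ["## Per-protein adjusted hazard ratios (per SD, validation set)", ""]
        if len(assoc) == 0:
            parts += ["No proteins selected; no associations to report.", ""]
        else:
            view = assoc.copy()
            view["HR (95% CI)"] = [
                _fmt_ci(r.hazard_ratio_per_sd, r.ci_low, r.ci_high, digits=2)
                for r in assoc.itertuples()]
            view["p"] = [_fmt_p(p) for p in assoc["p_value"]]
            view["p interaction"] = [_fmt_p(p) for p in assoc["interaction_p"]]
            parts += [_md_table(view[["protein", "sex_stratum", "HR (95% CI)",
                                      "p", "p interaction"]]), ""]

    inc_parts = []
    for s in ("male", "female"):
        path = out / "evaluation" / f"incremental_c_{s}.csv"
        if path.exists():
            inc = pd.read_csv(path)
            if len(inc):
                inc = inc.sort_values("delta_c", ascending=False)
                view = inc.copy()
                view["delta_c"] = view["delta_c"].map(lambda v: f"{v:.4f}")
                view["p_value"] = view["p_value"].map(_fmt_p)
                inc_parts += [f"### {s.capitalize()}", "",
                              _md_table(view[["protein", "delta_c", "p_value"]]), ""]
    if inc_parts:
        parts += ["## Incremental C-index per protein", ""] + inc_parts

    text = "\n".join(parts)
    (out / "report.md").write_text(text)
    return text
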