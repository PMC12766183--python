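"""Validation battery: discrimination, reclassification and calibration.

Harrell's C and the correlated-C difference test share one pairwise pass that
also yields per-subject influence functions, from which the U-statistic
variance of a single C and of a C difference follow.  Event status at the
horizon (for NRI, IDI, ROC and reclassification) uses Kaplan-Meier-weighted
fractional status by default, so participants censored before the horizon
contribute their conditional event probability; complete-case handling is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from proteorisk._utils import child_rng, km_survival, km_survival_at
from proteorisk.models import (RiskModel, SCORE2_COVARIATES, fit_cox,
                               predict_risk)

__all__ = ["EvalReport", "NRIResult", "IDIResult", "harrell_c", "compare_c",
           "categorical_nri", "idi", "calibration_deciles", "roc_at_horizon",
           "incremental_c", "reclassification_table", "evaluate_models",
           "risk_categories"]

_Z = 1.959963984540054


def _pair_stats(time, event, risks: list[np.ndarray], chunk: int = 512):
    """One pass over all subject pairs.

    A pair is usable when the earlier time belongs to an event, or when the
    times are tied with exactly one event.  Returns, per risk vector, the
    per-subject concordance-score sums ``u`` and, shared, the per-subject
    comparable-pair counts ``v`` (each unordered pair contributes to both of
    its members).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rs = [np.asarray(r, dtype=float) for r in risks]
    u = [np.zeros(n) for _ in rs]
    v = np.zeros(n)
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        dt_lt = t[sl, None] < t[None, :]
        dt_eq = t[sl, None] == t[None, :]
        di = d[sl, None]
        dj = d[None, :]
        dir1 = di & (dt_lt | (dt_eq & ~dj))          # i is the earlier event
        dir2 = dj & (~dt_lt & ~dt_eq | (dt_eq & ~di))  # j is the earlier event
        a = dir1 | dir2
        v[sl] += a.sum(axis=1)
        for k, r in enumerate(rs):
            rd = r[sl, None] - r[None, :]
            tie = 0.5 * (rd == 0)
            s1 = (rd > 0) + tie   # concordant when the earlier event has higher risk
            s2 = (rd < 0) + tie
            u[k][sl] += np.where(dir1, s1, 0.0).sum(axis=1) + np.where(dir2, s2, 0.0).sum(axis=1)
    return u, v


def _c_and_influence(u: np.ndarray, v: np.ndarray):
    V = v.sum()
    if V == 0:
        raise ValueError("no comparable pairs")
    c = u.sum() / V
    infl = 2.0 * (u - c * v) / (V / v.size)  # scaled so var(C) = sum(infl^2)/n^2
    return c, infl


def harrell_c(time, event, risk) -> tuple[float, float, float]:
    """Harrell's concordance index with a U-statistic 95% CI."""
    if np.asarray(event).sum() < 1:
        raise ValueError("need at least one event")
    (u,), v = _pair_stats(time, event, [risk])
    c, infl = _c_and_influence(u, v)
    n = v.size
    se = np.sqrt(np.sum(infl**2)) / n
    return float(c), float(max(c - _Z * se, 0.0)), float(min(c + _Z * se, 1.0))


def compare_c(time, event, risk_base, risk_new) -> tuple[float, float]:
    """Difference of correlated C-indices with a normal-approximation p-value.

    The two concordance estimators are computed on the identical comparable
    pair set; the variance of their difference comes from the joint
    U-statistic influence functions.
    """
    (u_b, u_n), v = _pair_stats(time, event, [risk_base, risk_new])
    c_b, infl_b = _c_and_influence(u_b, v)
    c_n, infl_n = _c_and_influence(u_n, v)
    delta = c_n - c_b
    n = v.size
    diff = infl_n - infl_b
    var = np.sum(diff**2) / n**2
    if var <= 1e-24:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


def _horizon_weights(time, event, horizon: float, status: str = "km"):
    """Per-subject (event-by-horizon, non-event) weights.

    km: subjects censored before the horizon get their conditional event
    probability from the overall Kaplan-Meier curve; weights sum to 1 per
    subject.  complete: those subjects are dropped (weight 0/0).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    w_e = np.where(d & (t <= horizon), 1.0, 0.0)
    w_ne = np.where(t >= horizon, 1.0, 0.0)
    w_ne[d & (t <= horizon)] = 0.0
    unknown = (~d) & (t < horizon)
    if status == "km":
        if unknown.any():
            kt, ks = km_survival(t, d)
            s_t = km_survival_at(kt, ks, t[unknown])
            s_h = km_survival_at(kt, ks, np.array([horizon]))[0]
            frac = np.where(s_t > 0, 1.0 - s_h / np.where(s_t > 0, s_t, 1.0), 0.0)
            w_e[unknown] = frac
            w_ne[unknown] = 1.0 - frac
    elif status == "complete":
        pass  # unknowns keep weight 0 in both classes
    else:
        raise ValueError(f"status must be 'km' or 'complete', got {status!r}")
    return w_e, w_ne


def risk_categories(risk, cuts=(0.05, 0.10)) -> np.ndarray:
    """Category index with left-open upper intervals: a risk exactly at a cut
    falls in the lower category ([0, c1], (c1, c2], (c2, 1])."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(risk, dtype=float),
                           side="left")


@dataclass
class NRIResult:
    nri_total: float
    nri_events: float
    nri_nonevents: float
    ci_total: tuple[float, float] = (np.nan, np.nan)
    ci_events: tuple[float, float] = (np.nan, np.nan)
    ci_nonevents: tuple[float, float] = (np.nan, np.nan)

    def to_dict(self) -> dict:
        return {"nri_total": self.nri_total, "nri_events": self.nri_events,
                "nri_nonevents": self.nri_nonevents,
                "ci_total": list(self.ci_total), "ci_events": list(self.ci_events),
                "ci_nonevents": list(self.ci_nonevents)}


@dataclass
class IDIResult:
    idi: float
    ci_low: float = np.nan
    ci_high: float = np.nan

    def to_dict(self) -> dict:
        return {"idi": self.idi, "ci_low": self.ci_low, "ci_high": self.ci_high}


def _nri_point(cat_b, cat_n, w_e, w_ne):
    se, sne = w_e.sum(), w_ne.sum()
    if se <= 0 or sne <= 0:
        raise ValueError("need both events and non-events at the horizon")
    up = (cat_n > cat_b).astype(float)
    down = (cat_n < cat_b).astype(float)
    nri_e = float(np.sum(w_e * (up - down)) / se)
    nri_ne = float(np.sum(w_ne * (down - up)) / sne)
    return nri_e + nri_ne, nri_e, nri_ne


def categorical_nri(risk_base, risk_new, time, event, cuts=(0.05, 0.10),
                    horizon: float = 10.0, status: str = "km",
                    n_boot: int = 1000, seed: int = 0) -> NRIResult:
    """Categorical net reclassification improvement with bootstrap CIs."""
    rb = np.asarray(risk_base, dtype=float)
    rn = np.asarray(risk_new, dtype=float)
    if np.any((rb < 0) | (rb > 1)) or np.any((rn < 0) | (rn > 1)):
        raise ValueError("risks must lie in [0, 1]")
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    cat_b = risk_categories(rb, cuts)
    cat_n = risk_categories(rn, cuts)
    w_e, w_ne = _horizon_weights(t, d, horizon, status)
    total, ev, ne = _nri_point(cat_b, cat_n, w_e, w_ne)
    res = NRIResult(total, ev, ne)
    if n_boot > 0:
        rng = child_rng(seed, "nri-boot")
        samples = np.empty((n_boot, 3))
        n = t.size
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                we_b, wne_b = _horizon_weights(t[idx], d[idx], horizon, status)
                samples[b] = _nri_point(cat_b[idx], cat_n[idx], we_b, wne_b)
            except ValueError:
                samples[b] = np.nan
        lo, hi = np.nanpercentile(samples, [2.5, 97.5], axis=0)
        res.ci_total = (float(lo[0]), float(hi[0]))
        res.ci_events = (float(lo[1]), float(hi[1]))
        res.ci_nonevents = (float(lo[2]), float(hi[2]))
    return res


def _idi_point(rb, rn, w_e, w_ne):
    se, sne = w_e.sum(), w_ne.sum()
    if se <= 0 or sne <= 0:
        raise ValueError("need both events and non-events at the horizon")
    slope_new = np.sum(w_e * rn) / se - np.sum(w_ne * rn) / sne
    slope_base = np.sum(w_e * rb) / se - np.sum(w_ne * rb) / sne
    return float(slope_new - slope_base)


def idi(risk_base, risk_new, time, event, horizon: float = 10.0,
        status: str = "km", n_boot: int = 1000, seed: int = 0) -> IDIResult:
    """Integrated discrimination improvement (discrimination-slope
    difference) with a bootstrap CI."""
    rb = np.asarray(risk_base, dtype=float)
    rn = np.asarray(risk_new, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    w_e, w_ne = _horizon_weights(t, d, horizon, status)
    point = _idi_point(rb, rn, w_e, w_ne)
    res = IDIResult(point)
    if n_boot > 0:
        rng = child_rng(seed, "idi-boot")
        n = t.size
        samples = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                we_b, wne_b = _horizon_weights(t[idx], d[idx], horizon, status)
                samples[b] = _idi_point(rb[idx], rn[idx], we_b, wne_b)
            except ValueError:
                samples[b] = np.nan
        res.ci_low, res.ci_high = (float(x) for x in
                                   np.nanpercentile(samples, [2.5, 97.5]))
    return res


def calibration_deciles(risk, time, event, horizon: float = 10.0,
                        ids=None) -> pd.DataFrame:
    """Mean predicted risk vs Kaplan-Meier observed event probability at the
    horizon across deciles of predicted risk (ties broken by stable order,
    or by ``ids`` when given)."""
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    n = r.size
    if n < 10:
        raise ValueError("need at least 10 subjects for deciles")
    if ids is not None:
        order = np.lexsort((np.asarray(ids), r))
    else:
        order = np.argsort(r, kind="stable")
    groups = np.array_split(order, 10)
    rows = []
    for k, g in enumerate(groups, start=1):
        kt, ks = km_survival(t[g], d[g])
        obs = 1.0 - km_survival_at(kt, ks, np.array([horizon]))[0]
        rows.append({"decile": k, "n": len(g),
                     "mean_predicted": float(r[g].mean()),
                     "observed": float(obs)})
    return pd.DataFrame(rows)


def calibration_slope(table: pd.DataFrame) -> float:
    """OLS slope of observed on predicted decile event rates."""
    x = table["mean_predicted"].to_numpy()
    y = table["observed"].to_numpy()
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))


def roc_at_horizon(risk, time, event, horizon: float = 10.0,
                   status: str = "km") -> tuple[pd.DataFrame, float]:
    """ROC over horizon event status (KM-weighted by default) and its
    trapezoidal AUC."""
    r = np.asarray(risk, dtype=float)
    w_e, w_ne = _horizon_weights(np.asarray(time, float),
                                 np.asarray(event).astype(bool), horizon, status)
    se, sne = w_e.sum(), w_ne.sum()
    if se <= 0 or sne <= 0:
        raise ValueError("need both events and non-events at the horizon")
    order = np.argsort(-r, kind="stable")
    rs = r[order]
    uniq_mask = np.r_[True, rs[1:] != rs[:-1]]
    stops = np.r_[np.flatnonzero(uniq_mask), rs.size]
    tp = np.cumsum(w_e[order])
    fp = np.cumsum(w_ne[order])
    idx = stops[1:] - 1
    tpr = np.r_[0.0, tp[idx] / se]
    fpr = np.r_[0.0, fp[idx] / sne]
    thresholds = np.r_[np.inf, rs[stops[:-1]]]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, auc


def reclassification_table(risk_base, risk_new, time, event,
                           cuts=(0.05, 0.10), horizon: float = 10.0,
                           status: str = "km",
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 base-vs-new category cross-tabulations among events and among
    non-events (KM-weighted counts by default; integers when uncensored)."""
    cat_b = risk_categories(np.asarray(risk_base, float), cuts)
    cat_n = risk_categories(np.asarray(risk_new, float), cuts)
    w_e, w_ne = _horizon_weights(np.asarray(time, float),
                                 np.asarray(event).astype(bool), horizon, status)
    k = len(cuts) + 1
    labels = ["low", "intermediate", "high"][:k]
    tabs = []
    for w in (w_e, w_ne):
        tab = np.zeros((k, k))
        np.add.at(tab, (cat_b, cat_n), w)
        tabs.append(pd.DataFrame(tab, index=pd.Index(labels, name="base"),
                                 columns=pd.Index(labels, name="new")))
    return tabs[0], tabs[1]


def incremental_c(base_model: RiskModel, selected, derivation, validation,
                  proteins_derivation: pd.DataFrame | None = None,
                  proteins_validation: pd.DataFrame | None = None,
                  horizon: float = 10.0) -> pd.DataFrame:
    """Per-protein discrimination gain: refit base + single protein on the
    derivation stratum, evaluate C on the validation stratum, and test the
    C difference against the base model."""
    prot_der = derivation.proteins if proteins_derivation is None else proteins_derivation
    prot_val = validation.proteins if proteins_validation is None else proteins_validation
    cov_d = derivation.covariates
    cov_v = validation.covariates
    t_v = cov_v["follow_up_time"].to_numpy()
    e_v = cov_v["event"].to_numpy()
    risk_base = predict_risk(base_model, cov_v)
    c_base, _, _ = harrell_c(t_v, e_v, risk_base)
    rows = []
    for name in selected:
        design = cov_d[SCORE2_COVARIATES].copy().reset_index(drop=True)
        design[name] = prot_der[name].to_numpy()
        model = fit_cox(design, cov_d["follow_up_time"].to_numpy(),
                        cov_d["event"].to_numpy(), horizon=horizon,
                        sex_stratum=base_model.sex_stratum)
        design_v = cov_v[SCORE2_COVARIATES].copy().reset_index(drop=True)
        design_v[name] = prot_val[name].to_numpy()
        risk_p = predict_risk(model, design_v)
        c_p, _, _ = harrell_c(t_v, e_v, risk_p)
        delta, p = compare_c(t_v, e_v, risk_base, risk_p)
        rows.append({"protein": name, "c_base": c_base, "c_with_protein": c_p,
                     "delta_c": delta, "p_value": p})
    return pd.DataFrame(rows, columns=["protein", "c_base", "c_with_protein",
                                       "delta_c", "p_value"])


@dataclass
class EvalReport:
    """Performance summary for one evaluation stratum."""

    stratum: str
    n: int
    n_events: int
    c_base: tuple[float, float, float]
    c_extended: tuple[float, float, float]
    delta_c: float
    delta_c_p: float
    nri: NRIResult
    idi: IDIResult
    calibration_base: pd.DataFrame
    calibration_extended: pd.DataFrame
    auc_base: float
    auc_extended: float
    reclassification_events: pd.DataFrame
    reclassification_nonevents: pd.DataFrame
    incremental_c: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "n_events": self.n_events,
            "c_base": list(self.c_base),
            "c_extended": list(self.c_extended),
            "delta_c": self.delta_c,
            "delta_c_p": self.delta_c_p,
            "nri": self.nri.to_dict(),
            "idi": self.idi.to_dict(),
            "auc_base": self.auc_base,
            "auc_extended": self.auc_extended,
            "calibration_base": self.calibration_base.to_dict(orient="records"),
            "calibration_extended": self.calibration_extended.to_dict(orient="records"),
            "reclassification_events": self.reclassification_events.to_numpy().tolist(),
            "reclassification_nonevents": self.reclassification_nonevents.to_numpy().tolist(),
            "incremental_c": (None if self.incremental_c is None
                              else self.incremental_c.to_dict(orient="records")),
        }


def evaluate_predictions(time, event, risk_base, risk_extended, ids=None,
                         cuts=(0.05, 0.10), horizon: float = 10.0,
                         status: str = "km", n_boot: int = 1000, seed: int = 0,
                         stratum: str = "all") -> EvalReport:
    """Run the full battery on already-computed absolute risks."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    risk_base = np.asarray(risk_base, dtype=float)
    risk_extended = np.asarray(risk_extended, dtype=float)
    c_b = harrell_c(t, e, risk_base)
    c_e = harrell_c(t, e, risk_extended)
    delta, p = compare_c(t, e, risk_base, risk_extended)
    nri_res = categorical_nri(risk_base, risk_extended, t, e, cuts=cuts,
                              horizon=horizon, status=status, n_boot=n_boot, seed=seed)
    idi_res = idi(risk_base, risk_extended, t, e, horizon=horizon, status=status,
                  n_boot=n_boot, seed=seed)
    cal_b = calibration_deciles(risk_base, t, e, horizon=horizon, ids=ids)
    cal_e = calibration_deciles(risk_extended, t, e, horizon=horizon, ids=ids)
    _, auc_b = roc_at_horizon(risk_base, t, e, horizon=horizon, status=status)
    _, auc_e = roc_at_horizon(risk_extended, t, e, horizon=horizon, status=status)
    rec_e, rec_ne = reclassification_table(risk_base, risk_extended, t, e,
                                           cuts=cuts, horizon=horizon, status=status)
    return EvalReport(
        stratum=stratum, n=t.size, n_events=int(e.sum()), c_base=c_b,
        c_extended=c_e, delta_c=delta, delta_c_p=p, nri=nri_res, idi=idi_res,
        calibration_base=cal_b, calibration_extended=cal_e, auc_base=auc_b,
        auc_extended=auc_e, reclassification_events=rec_e,
        reclassification_nonevents=rec_ne)


def model_risks(validation, base_model: RiskModel, extended_model: RiskModel,
                proteins: pd.DataFrame | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Absolute risks from a base and an extended model on a cohort stratum."""
    prot = validation.proteins if proteins is None else proteins
    cov = validation.covariates
    design_base = cov[SCORE2_COVARIATES].reset_index(drop=True)
    extra = [c for c in extended_model.covariate_names if c not in cov.columns]
    design_ext = pd.concat([design_base, prot[extra].reset_index(drop=True)], axis=1) \
        if extra else design_base
    risk_base = predict_risk(base_model, design_base[base_model.covariate_names])
    risk_ext = predict_risk(extended_model, design_ext[extended_model.covariate_names])
    return risk_base, risk_ext


def evaluate_models(validation, base_model: RiskModel, extended_model: RiskModel,
                    proteins: pd.DataFrame | None = None, cuts=(0.05, 0.10),
                    horizon: float = 10.0, status: str = "km",
                    n_boot: int = 1000, seed: int = 0,
                    stratum: str = "all") -> EvalReport:
    """Run the full battery for one stratum of an evaluation cohort."""
    risk_base, risk_ext = model_risks(validation, base_model, extended_model, proteins)
    cov = validation.covariates
    return evaluate_predictions(
        cov["follow_up_time"].to_numpy(), cov["event"].to_numpy(),
        risk_base, risk_ext, ids=cov["participant_id"].to_numpy(),
        cuts=cuts, horizon=horizon, status=status, n_boot=n_boot, seed=seed,
        stratum=stratum)
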