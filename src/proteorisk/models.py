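"""Cox proportional-hazards risk models and 10-year absolute risk.

The solver maximizes the partial likelihood (Breslow tie handling by
default, Efron as an option) by Newton-Raphson with step halving, to a
gradient max-norm below 1e-9.  The baseline cumulative hazard is the Breslow
estimator evaluated at the horizon for the covariate-mean-centered linear
predictor, so ``risk = 1 - exp(-H0 * exp(lp))`` with ``lp`` centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RiskModel", "ProteinAssociation", "CoxConvergenceError", "fit_cox",
           "predict_risk", "fit_base_and_extended", "protein_associations",
           "sex_interaction_test", "SCORE2_COVARIATES", "cox_loglik"]

#: variable set of the base (non-proteomic) risk model; sex enters by
#: stratified fitting rather than as a column.
SCORE2_COVARIATES = ["age", "sbp", "total_cholesterol", "hdl_cholesterol",
                     "current_smoker"]


class CoxConvergenceError(RuntimeError):
    pass


def _prepare(time: np.ndarray, event: np.ndarray):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("follow-up times must be finite and > 0")
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    _, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(d, first)
    return order, t, d, first, deaths


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _breslow_quantities(X: np.ndarray, t: np.ndarray, d: np.ndarray,
                        first: np.ndarray, deaths: np.ndarray, beta: np.ndarray,
                        need_hessian: bool = True):
    n, p = X.shape
    eta = X @ beta
    m = eta.max() if n else 0.0
    we = np.exp(eta - m)
    S = _rev_cumsum(we)[first]                       # risk-set sums per group
    M1 = _rev_cumsum(we[:, None] * X)[first]         # (G, p)
    dead = d > 0
    ev = deaths > 0
    loglik = float(np.sum(eta[dead] - m) - np.sum(deaths[ev] * np.log(S[ev])))
    ratio = M1[ev] / S[ev, None]
    U = X[dead].sum(axis=0) - deaths[ev] @ ratio
    H = None
    if need_hessian:
        if n * p * p <= 6e7:
            M2 = _rev_cumsum(we[:, None, None] * (X[:, :, None] * X[:, None, :]))[first]
            H = np.einsum("g,gij->ij", deaths[ev] / S[ev], M2[ev])
        else:  # group-wise accumulation to bound memory on wide designs
            H = np.zeros((p, p))
            acc = np.zeros((p, p))
            g_idx = len(first) - 1
            stops = list(first) + [n]
            for g in range(g_idx, -1, -1):
                sl = slice(stops[g], stops[g + 1])
                Xw = X[sl] * we[sl, None]
                acc += Xw.T @ X[sl]
                if deaths[g] > 0:
                    H += deaths[g] / S[g] * acc
        H -= np.einsum("g,gi,gj->ij", deaths[ev], ratio, ratio)
    return loglik, U, H


def _efron_quantities(X: np.ndarray, t: np.ndarray, d: np.ndarray,
                      first: np.ndarray, deaths: np.ndarray, beta: np.ndarray,
                      need_hessian: bool = True):
    n, p = X.shape
    eta = X @ beta
    m = eta.max() if n else 0.0
    we = np.exp(eta - m)
    Ssuf = _rev_cumsum(we)
    M1suf = _rev_cumsum(we[:, None] * X)
    M2suf = None
    if need_hessian:
        if n * p * p > 6e7:  # pragma: no cover - wide designs use breslow
            raise MemoryError("efron ties unsupported for this design size")
        M2suf = _rev_cumsum(we[:, None, None] * (X[:, :, None] * X[:, None, :]))
    stops = list(first) + [n]
    dead = d > 0
    loglik = float(np.sum(eta[dead] - m))
    U = X[dead].sum(axis=0).astype(float)
    H = np.zeros((p, p)) if need_hessian else None
    for g in range(len(first)):
        dg = int(round(deaths[g]))
        if dg == 0:
            continue
        sl = slice(stops[g], stops[g + 1])
        in_g = dead[sl]
        Dw = we[sl][in_g].sum()
        D1 = (we[sl, None] * X[sl])[in_g].sum(axis=0)
        Xg = X[sl][in_g]
        D2 = (Xg * we[sl][in_g, None]).T @ Xg if need_hessian else None
        S = Ssuf[first[g]]
        M1 = M1suf[first[g]]
        M2 = M2suf[first[g]] if need_hessian else None
        for l in range(dg):
            f = l / dg
            denom = S - f * Dw
            m1 = M1 - f * D1
            loglik -= np.log(denom)
            U -= m1 / denom
            if need_hessian:
                m2 = M2 - f * D2
                H += m2 / denom - np.outer(m1, m1) / denom**2
    return loglik, U, H


@dataclass
class RiskModel:
    """Fitted Cox model with everything needed for absolute risk."""

    sex_stratum: str
    covariate_names: list[str]
    coefficients: np.ndarray
    baseline_cumulative_hazard: float
    centering_values: np.ndarray
    horizon: float
    standard_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str = "breslow"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.centering_values = np.asarray(self.centering_values, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.baseline_cumulative_hazard < 0:
            raise ValueError("baseline cumulative hazard must be >= 0")

    def linear_predictor(self, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _design(covariates, self.covariate_names)
        return (X - self.centering_values) @ self.coefficients

    def summary(self) -> pd.DataFrame:
        z = np.divide(self.coefficients, self.standard_errors,
                      out=np.zeros_like(self.coefficients),
                      where=self.standard_errors > 0)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.coefficients,
            "se": self.standard_errors,
            "hr": np.exp(self.coefficients),
            "ci_low": np.exp(self.coefficients - 1.959963984540054 * self.standard_errors),
            "ci_high": np.exp(self.coefficients + 1.959963984540054 * self.standard_errors),
            "p": p,
        }, index=self.covariate_names)

    def to_dict(self) -> dict:
        return {
            "sex_stratum": self.sex_stratum,
            "covariate_names": list(self.covariate_names),
            "coefficients": self.coefficients.tolist(),
            "baseline_cumulative_hazard": self.baseline_cumulative_hazard,
            "centering_values": self.centering_values.tolist(),
            "horizon": self.horizon,
            "standard_errors": self.standard_errors.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        d = dict(d)
        p = len(d["covariate_names"])
        d.setdefault("covariance", np.full((p, p), np.nan))
        for k in ("coefficients", "centering_values", "standard_errors"):
            d[k] = np.asarray(d[k], dtype=float)
        d["covariance"] = np.asarray(d["covariance"], dtype=float)
        return cls(**d)


@dataclass
class ProteinAssociation:
    protein: str
    sex_stratum: str
    hazard_ratio_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    interaction_p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio_per_sd <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


def _design(covariates, names: list[str] | None) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        if names is not None:
            missing = [c for c in names if c not in covariates.columns]
            if missing:
                raise ValueError(f"missing covariate column(s): {missing}")
            return covariates[names].to_numpy(dtype=float)
        return covariates.to_numpy(dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is not None and X.shape[1] != len(names):
        raise ValueError("covariate matrix width does not match model")
    return X


def fit_cox(covariates, time, event, names: list[str] | None = None,
            horizon: float = 10.0, ties: str = "breslow",
            sex_stratum: str = "all", max_iter: int = 100,
            tol: float = 1e-9) -> RiskModel:
    """Maximum partial likelihood Cox fit with Breslow baseline hazard.

    ``covariates`` may be a DataFrame (column names are used) or an array
    (``names`` optional).  Raises :class:`CoxConvergenceError` on
    non-convergence or monotone likelihood (perfect separation).
    """
    if isinstance(covariates, pd.DataFrame) and names is None:
        names = list(covariates.columns)
    X = _design(covariates, names)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain non-finite values")
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant covariate column(s): {bad}")

    center = X.mean(axis=0)
    Xc = X - center
    order, t, d, first, deaths = _prepare(time, event)
    Xs = Xc[order]
    quantities = _breslow_quantities if ties == "breslow" else _efron_quantities
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")

    beta = np.zeros(p)
    ll, U, H = quantities(Xs, t, d, first, deaths, beta)
    for _ in range(max_iter):
        if np.max(np.abs(U)) < tol:
            break
        try:
            delta = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _half in range(40):
            cand = beta + step * delta
            ll_new, U_new, H_new = quantities(Xs, t, d, first, deaths, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise CoxConvergenceError("step halving failed to improve the likelihood")
        beta, ll, U, H = cand, ll_new, U_new, H_new
        if np.max(np.abs(beta)) > 80:
            raise CoxConvergenceError(
                "monotone likelihood (perfect separation?) - coefficients diverge")
    else:
        raise CoxConvergenceError(
            f"Newton iterations exhausted (gradient max-norm {np.max(np.abs(U)):.3g})")

    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # Breslow baseline cumulative hazard at the horizon (centered covariates)
    eta = Xs @ beta
    m = eta.max()
    S = _rev_cumsum(np.exp(eta - m))[first]
    ev = deaths > 0
    tg = t[first]
    within = ev & (tg <= horizon)
    H0 = float(np.sum(deaths[within] / (S[within] * np.exp(m))))

    return RiskModel(
        sex_stratum=sex_stratum, covariate_names=list(names), coefficients=beta,
        baseline_cumulative_hazard=H0, centering_values=center, horizon=horizon,
        standard_errors=se, covariance=cov, loglik=ll, n=n, n_events=n_events,
        ties=ties)


def cox_loglik(model: RiskModel, covariates, time, event) -> float:
    """Partial log-likelihood of a fitted model's coefficients on a dataset."""
    X = _design(covariates, model.covariate_names) - model.centering_values
    order, t, d, first, deaths = _prepare(np.asarray(time, float), np.asarray(event, float))
    ll, _, _ = _breslow_quantities(X[order], t, d, first, deaths,
                                   model.coefficients, need_hessian=False)
    return ll


def predict_risk(model: RiskModel, covariates) -> np.ndarray:
    """Absolute event risk by the horizon: ``1 - exp(-H0 * exp(lp))``."""
    lp = model.linear_predictor(covariates)
    return 1.0 - np.exp(-model.baseline_cumulative_hazard * np.exp(lp))


def fit_base_and_extended(derivation, selections: dict, proteins: pd.DataFrame | None = None,
                          horizon: float = 10.0, ties: str = "breslow") -> dict:
    """Fit, per sex stratum, the base model (SCORE2 variable set) and the
    extended model (base + that stratum's selected proteins).

    ``derivation`` is a CohortTable whose ``proteins`` (or the ``proteins``
    override, aligned row-wise) are already imputed and standardized.
    ``selections`` maps ``'male'``/``'female'`` to objects with a
    ``selected`` attribute (or to plain protein-name lists).
    """
    prot = derivation.proteins if proteins is None else proteins
    out = {}
    for sex in ("male", "female"):
        mask = (derivation.covariates["sex"] == sex).to_numpy()
        cov = derivation.covariates.loc[mask]
        sel = selections.get(sex, [])
        sel_names = list(getattr(sel, "selected", sel))
        design_base = cov[SCORE2_COVARIATES].reset_index(drop=True)
        t = cov["follow_up_time"].to_numpy()
        e = cov["event"].to_numpy()
        base = fit_cox(design_base, t, e, horizon=horizon, ties=ties, sex_stratum=sex)
        if sel_names:
            design_ext = pd.concat(
                [design_base, prot.loc[mask, sel_names].reset_index(drop=True)], axis=1)
            ext = fit_cox(design_ext, t, e, horizon=horizon, ties=ties, sex_stratum=sex)
        else:
            ext = base
        out[sex] = (base, ext)
    return out


def _per_sd(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("protein column has zero variance")
    return (x - x.mean()) / sd


def _single_protein_fit(cov: pd.DataFrame, prot_col: np.ndarray, name: str,
                        horizon: float, sex: str) -> tuple[float, float, float, float]:
    design = cov[SCORE2_COVARIATES].copy().reset_index(drop=True)
    design[name] = _per_sd(prot_col)  # HR is per SD whatever the input scale
    model = fit_cox(design, cov["follow_up_time"].to_numpy(),
                    cov["event"].to_numpy(), horizon=horizon, sex_stratum=sex)
    j = model.covariate_names.index(name)
    b, s = model.coefficients[j], model.standard_errors[j]
    z = b / s if s > 0 else 0.0
    return (float(np.exp(b)), float(np.exp(b - 1.959963984540054 * s)),
            float(np.exp(b + 1.959963984540054 * s)), float(2 * stats.norm.sf(abs(z))))


def protein_associations(validation, protein_names, proteins: pd.DataFrame | None = None,
                         horizon: float = 10.0,
                         with_interaction: bool = True) -> list[ProteinAssociation]:
    """Per-protein adjusted Cox associations (HR per SD) in each sex stratum,
    each protein individually added to the SCORE2 variable set, plus a pooled
    protein-by-sex interaction p-value."""
    prot = validation.proteins if proteins is None else proteins
    results: list[ProteinAssociation] = []
    for name in protein_names:
        inter_p = (sex_interaction_test(validation, name, proteins=prot, horizon=horizon)
                   if with_interaction else np.nan)
        for sex in ("male", "female"):
            mask = (validation.covariates["sex"] == sex).to_numpy()
            hr, lo, hi, p = _single_protein_fit(
                validation.covariates.loc[mask], prot.loc[mask, name].to_numpy(),
                name, horizon, sex)
            results.append(ProteinAssociation(
                protein=name, sex_stratum=sex, hazard_ratio_per_sd=hr,
                ci_low=lo, ci_high=hi, p_value=p, interaction_p=inter_p))
    return results


def sex_interaction_test(cohort, protein: str, proteins: pd.DataFrame | None = None,
                         horizon: float = 10.0) -> float:
    """Wald p-value for the protein-by-sex interaction in a pooled Cox model
    adjusted for the SCORE2 variable set plus a sex main effect."""
    prot = cohort.proteins if proteins is None else proteins
    cov = cohort.covariates
    sexes = set(cov["sex"])
    if not {"male", "female"} <= sexes:
        raise ValueError("both sexes must be present for an interaction test")
    design = cov[SCORE2_COVARIATES].copy().reset_index(drop=True)
    male = (cov["sex"] == "male").astype(float).to_numpy()
    x = _per_sd(prot[protein].to_numpy())
    design["male"] = male
    design[protein] = x
    design[f"{protein}:male"] = x * male
    model = fit_cox(design, cov["follow_up_time"].to_numpy(),
                    cov["event"].to_numpy(), horizon=horizon, sex_stratum="pooled")
    j = model.covariate_names.index(f"{protein}:male")
    z = model.coefficients[j] / model.standard_errors[j]
    return float(2 * stats.norm.sf(abs(z)))
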