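"""Sex-specific protein selection by bootstrapped LASSO-Cox.

For each of ``n_bootstrap`` resamples (with replacement, at the original
stratum size) the L1 penalty is tuned by event-stratified k-fold
cross-validation minimizing the out-of-fold partial-likelihood deviance
(Verweij & van Houwelingen form), the model is refit on the resample at the
tuned penalty, and the proteins with nonzero coefficients are recorded.
Proteins present in at least ``frequency_threshold`` of the resamples (the
count rounded up, e.g. >= 190 of 200 at 0.95) form the selected set.

The base risk-factor columns are included unpenalized by default so
selection is incremental over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from proteorisk import _coxnet
from proteorisk._utils import child_rng
from proteorisk.models import SCORE2_COVARIATES

__all__ = ["SelectionConfig", "SelectionResult", "CVResult", "fit_lasso_cox",
           "cv_select_lambda", "bootstrap_stability", "run_sex_specific_selection"]


@dataclass
class SelectionConfig:
    n_bootstrap: int = 200
    n_folds: int = 10
    frequency_threshold: float = 0.95
    #: "auto" builds a log-spaced grid from the data's lambda_max downward
    lambda_grid: str | np.ndarray = "auto"
    n_lambda: int = 100
    lambda_decades: float = 4.0
    penalize_score2_covariates: bool = False
    cv_rule: str = "min"  # or "1se"
    seed: int = 0

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ValueError("frequency_threshold must be in (0, 1]")
        if isinstance(self.lambda_grid, str):
            if self.lambda_grid != "auto":
                raise ValueError("lambda_grid must be 'auto' or an array of positive reals")
            if self.n_lambda < 1:
                raise ValueError("n_lambda must be >= 1")
        else:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("lambda grid is empty")
            if np.any(grid <= 0) or np.any(~np.isfinite(grid)):
                raise ValueError("lambda grid entries must be positive and finite")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")

    @property
    def selection_count(self) -> int:
        """Minimum bootstrap count for selection (ceil of threshold * B)."""
        return int(np.ceil(self.frequency_threshold * self.n_bootstrap - 1e-9))


@dataclass
class SelectionResult:
    sex_stratum: str
    frequencies: pd.Series       # per-protein bootstrap counts
    selected: list[str]
    n_bootstrap: int
    frequency_threshold: float
    per_bootstrap_lambda: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = self.frequencies
        if len(f) and (f.min() < 0 or f.max() > self.n_bootstrap):
            raise ValueError("frequencies must lie in [0, n_bootstrap]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.frequencies.index,
            "frequency": self.frequencies.to_numpy(),
            "selected": [p in set(self.selected) for p in self.frequencies.index],
        })

    def to_dict(self) -> dict:
        return {"sex_stratum": self.sex_stratum,
                "frequencies": {k: int(v) for k, v in self.frequencies.items()},
                "selected": list(self.selected),
                "n_bootstrap": self.n_bootstrap,
                "frequency_threshold": self.frequency_threshold,
                "per_bootstrap_lambda": [float(x) for x in self.per_bootstrap_lambda]}


@dataclass
class CVResult:
    lambda_star: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray


def _check_inputs(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if event.sum() < 1:
        raise ValueError("need at least one event")


def fit_lasso_cox(X, time, event, lam: float, unpenalized=None,
                  tol: float = 1e-10, max_outer: int = 500) -> np.ndarray:
    """L1-penalized Cox coefficients at a single penalty value.

    Minimizes ``-partial_loglik(beta) + lam * sum |beta_j|`` over the
    penalized columns (Breslow ties); ``unpenalized`` lists column indices
    carrying no penalty.  At ``lam=0`` this solves the ordinary Cox score
    equations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    _check_inputs(X, time, event)
    if lam < 0 or not np.isfinite(lam):
        raise ValueError("lambda must be a nonnegative finite number")
    pen = np.ones(X.shape[1], dtype=bool)
    if unpenalized is not None:
        pen[np.asarray(list(unpenalized), dtype=int)] = False
    Xs, d, first, deaths, _ = _coxnet.prepare_cox_data(X, time, event)
    coefs = _coxnet.fit_penalized_path(Xs, d, first, deaths, np.array([lam]),
                                       pen, tol=tol, max_outer=max_outer,
                                       kkt_tol=1e-8)
    return coefs[0]


def _auto_grid(Xs, d, first, deaths, pen, config: SelectionConfig) -> np.ndarray:
    lmax = _coxnet.lambda_max(Xs, d, first, deaths, pen)
    return np.logspace(np.log10(lmax), np.log10(lmax) - config.lambda_decades,
                       config.n_lambda)


def _stratified_folds(event: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Event-stratified fold labels so every training part keeps events."""
    n = event.size
    folds = np.empty(n, dtype=np.int64)
    for cls in (1, 0):
        idx = np.flatnonzero(event == cls)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def cv_select_lambda(X, time, event, config: SelectionConfig,
                     rng: np.random.Generator | None = None,
                     unpenalized=None) -> CVResult:
    """Tune the penalty by k-fold CV on the partial-likelihood deviance.

    The per-fold deviance is ``-2 * (loglik_all(beta_f) - loglik_train(beta_f))``
    so held-out folds are scored through the full-sample partial likelihood,
    which is well defined even for folds with few events.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    _check_inputs(X, time, event)
    if rng is None:
        rng = child_rng(config.seed, "cv")
    pen = np.ones(X.shape[1], dtype=bool)
    if unpenalized is not None:
        pen[np.asarray(list(unpenalized), dtype=int)] = False

    Xs_all, d_all, first_all, deaths_all, _ = _coxnet.prepare_cox_data(X, time, event)
    if isinstance(config.lambda_grid, str):
        grid = _auto_grid(Xs_all, d_all, first_all, deaths_all, pen, config)
    else:
        grid = np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]

    folds = _stratified_folds(event, config.n_folds, rng)
    dev = np.zeros((config.n_folds, grid.size))
    for f in range(config.n_folds):
        train = folds != f
        if event[train].sum() < 1:  # pragma: no cover - stratification prevents this
            continue
        Xs, d, first, deaths, _ = _coxnet.prepare_cox_data(
            X[train], time[train], event[train])
        coefs = _coxnet.fit_penalized_path(Xs, d, first, deaths, grid, pen,
                                           tol=1e-5, max_outer=25)
        for k in range(grid.size):
            ll_train = _coxnet.cox_loglik_sorted(Xs, d, first, deaths, coefs[k])
            ll_all = _coxnet.cox_loglik_sorted(Xs_all, d_all, first_all,
                                               deaths_all, coefs[k])
            dev[f, k] = -2.0 * (ll_all - ll_train)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
    k_min = int(np.argmin(mean_dev))
    if config.cv_rule == "1se":
        bound = mean_dev[k_min] + se_dev[k_min]
        k_sel = int(np.flatnonzero(mean_dev <= bound)[0])  # grid descends: largest lambda
    else:
        k_sel = k_min
    return CVResult(float(grid[k_sel]), grid, mean_dev, se_dev)


def _stratum_design(stratum, proteins: pd.DataFrame | None,
                    penalize_covariates: bool):
    cov = stratum.covariates
    prot = stratum.proteins if proteins is None else proteins
    protein_names = list(prot.columns)
    X = np.column_stack([cov[SCORE2_COVARIATES].to_numpy(dtype=float),
                         prot.to_numpy(dtype=float)]) if protein_names else \
        cov[SCORE2_COVARIATES].to_numpy(dtype=float)
    # internal z-scoring: required for a scale-equivariant L1 penalty
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad_idx = np.flatnonzero(sd == 0)
        names = SCORE2_COVARIATES + protein_names
        raise ValueError(f"constant design column(s): {[names[j] for j in bad_idx]}")
    Xz = (X - mu) / sd
    n_cov = len(SCORE2_COVARIATES)
    unpen = None if penalize_covariates else range(n_cov)
    time = cov["follow_up_time"].to_numpy(dtype=float)
    event = cov["event"].to_numpy(dtype=float)
    return Xz, time, event, protein_names, n_cov, unpen


def bootstrap_stability(stratum, config: SelectionConfig,
                        proteins: pd.DataFrame | None = None,
                        sex_stratum: str | None = None) -> SelectionResult:
    """Bootstrap selection frequencies for one (single-sex) stratum.

    ``stratum`` is a CohortTable whose proteins are imputed and standardized
    (pass ``proteins`` to override the matrix).  Bootstrap ``b`` draws its
    randomness from a child seed of ``(config.seed, b)``.
    """
    config.validate()
    sexes = set(stratum.covariates["sex"])
    if len(sexes) > 1:
        raise ValueError(f"stratum must be single-sex, got {sorted(sexes)}")
    if sex_stratum is None:
        sex_stratum = next(iter(sexes)) if sexes else "all"
    Xz, time, event, protein_names, n_cov, unpen = _stratum_design(
        stratum, proteins, config.penalize_score2_covariates)
    if event.sum() < 1:
        raise ValueError("stratum has zero events")
    n = Xz.shape[0]
    pen = np.ones(Xz.shape[1], dtype=bool)
    if unpen is not None:
        pen[np.asarray(list(unpen), dtype=int)] = False

    counts = np.zeros(len(protein_names), dtype=np.int64)
    lambdas: list[float] = []
    for b in range(config.n_bootstrap):
        rng = child_rng(config.seed, "bootstrap", b)
        for _retry in range(100):
            idx = rng.integers(0, n, n)
            if event[idx].sum() >= 1:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a bootstrap resample with events")
        Xb, tb, eb = Xz[idx], time[idx], event[idx]
        cv = cv_select_lambda(Xb, tb, eb, config, rng=rng, unpenalized=unpen)
        Xs, d, first, deaths, _ = _coxnet.prepare_cox_data(Xb, tb, eb)
        # warm-started path down to lambda*: cheap and better conditioned
        path = cv.lambdas[cv.lambdas >= cv.lambda_star]
        coefs = _coxnet.fit_penalized_path(Xs, d, first, deaths, path, pen,
                                           tol=1e-6, max_outer=50)
        beta = coefs[-1]
        nz = beta[n_cov:] != 0.0
        counts += nz.astype(np.int64)
        lambdas.append(cv.lambda_star)

    freq = pd.Series(counts, index=protein_names, name="frequency")
    selected = [p for p, c in freq.items() if c >= config.selection_count]
    return SelectionResult(sex_stratum=sex_stratum, frequencies=freq,
                           selected=selected, n_bootstrap=config.n_bootstrap,
                           frequency_threshold=config.frequency_threshold,
                           per_bootstrap_lambda=lambdas)


def run_sex_specific_selection(derivation, config: SelectionConfig,
                               proteins: pd.DataFrame | None = None,
                               ) -> tuple[SelectionResult, SelectionResult, dict]:
    """Independent selection per sex stratum plus an overlap summary
    (shared / male-only / female-only selected sets).

    Both strata use the same master seed so the procedure is symmetric under
    swapping the sex labels.
    """
    results = {}
    for sex in ("male", "female"):
        mask = (derivation.covariates["sex"] == sex).to_numpy()
        if not mask.any():
            raise ValueError(f"no participants in the {sex} stratum")
        stratum = derivation.stratum(sex)
        prot = None if proteins is None else proteins.loc[mask].reset_index(drop=True)
        results[sex] = bootstrap_stability(stratum, config, proteins=prot,
                                           sex_stratum=sex)
    m = set(results["male"].selected)
    f = set(results["female"].selected)
    overlap = {"shared": sorted(m & f), "male_only": sorted(m - f),
               "female_only": sorted(f - m)}
    return results["male"], results["female"], overlap
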