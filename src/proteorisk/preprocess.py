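"""Protein/participant filters, single imputation, split and standardization.

Filter boundaries follow the strict "more than X%" convention: a protein with
exactly 20% missing values is retained, one with 20% + one observation more
is excluded; likewise 25% below-LOD for proteins and 50% missing for
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from proteorisk._utils import child_rng
from proteorisk.simulate import CohortTable

__all__ = ["FilterReport", "SplitAssignment", "filter_proteins",
           "filter_participants", "impute", "split", "standardize",
           "apply_standardization"]


@dataclass
class FilterReport:
    proteins_in: int
    proteins_excluded_missing: int
    proteins_excluded_lod: int
    proteins_retained: int
    participants_excluded: int = 0

    def __post_init__(self) -> None:
        if min(asdict(self).values()) < 0:
            raise ValueError("FilterReport counts must be >= 0")
        if (self.proteins_retained + self.proteins_excluded_missing
                + self.proteins_excluded_lod != self.proteins_in):
            raise ValueError("FilterReport counts do not partition proteins_in")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitAssignment:
    derivation_ids: list
    validation_ids: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.derivation_ids) & set(self.validation_ids):
            raise ValueError("derivation and validation sets overlap")

    def to_dict(self) -> dict:
        return {"derivation_ids": list(self.derivation_ids),
                "validation_ids": list(self.validation_ids),
                "seed": self.seed}


def filter_proteins(proteins: pd.DataFrame, lod_flags: pd.DataFrame | None = None,
                    max_missing: float = 0.20, max_lod: float = 0.25,
                    ) -> tuple[list[str], FilterReport]:
    """Exclude proteins with missing fraction > ``max_missing`` or a
    below-LOD fraction (among observed values) > ``max_lod``.

    Proteins failing both criteria are counted once, under the missingness
    reason.
    """
    p = proteins.shape[1]
    if p == 0:
        return [], FilterReport(0, 0, 0, 0)
    miss_frac = proteins.isna().mean().to_numpy()
    if lod_flags is not None:
        observed = proteins.notna().to_numpy()
        flagged = lod_flags.to_numpy(dtype=bool) & observed
        denom = observed.sum(axis=0)
        lod_frac = np.divide(flagged.sum(axis=0), denom,
                             out=np.zeros(p), where=denom > 0)
    else:
        lod_frac = np.zeros(p)
    excl_miss = miss_frac > max_missing
    excl_lod = (lod_frac > max_lod) & ~excl_miss
    retained = [c for c, bad in zip(proteins.columns, excl_miss | excl_lod) if not bad]
    report = FilterReport(
        proteins_in=p,
        proteins_excluded_missing=int(excl_miss.sum()),
        proteins_excluded_lod=int(excl_lod.sum()),
        proteins_retained=len(retained),
    )
    return retained, report


def filter_participants(proteins: pd.DataFrame, max_missing: float = 0.50) -> np.ndarray:
    """Row indices of participants whose protein missing fraction is
    <= ``max_missing`` (strictly more is excluded)."""
    if proteins.shape[1] == 0:
        return np.arange(len(proteins))
    frac = proteins.isna().mean(axis=1).to_numpy()
    return np.flatnonzero(frac <= max_missing)


def impute(proteins: pd.DataFrame, covariates: pd.DataFrame | None = None,
           n_iterations: int = 5, seed: int = 0,
           estimator: str = "forest") -> pd.DataFrame:
    """Single imputation by iterative chained equations.

    Each incomplete variable is modelled on all others with a seeded
    regression learner for a fixed number of round-robin iterations
    (``estimator='forest'`` uses a small extra-trees ensemble,
    ``'ridge'`` a Bayesian ridge, which is much faster on wide panels).
    Observed entries are passed through unchanged.  Numeric columns of
    ``covariates`` participate as predictors and are imputed jointly.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    all_missing = proteins.columns[proteins.isna().all()]
    if len(all_missing):
        raise ValueError(
            f"column(s) entirely missing (should have been filtered): {list(all_missing)}")
    if not proteins.isna().any().any():
        return proteins.copy()

    design = proteins
    n_prot = proteins.shape[1]
    if covariates is not None:
        num = covariates.select_dtypes(include=[np.number])
        num = num.drop(columns=[c for c in ("participant_id", "follow_up_time", "event")
                                if c in num.columns])
        design = pd.concat([proteins.reset_index(drop=True),
                            num.reset_index(drop=True)], axis=1)

    rng_seed = int(child_rng(seed, "impute").integers(2**31 - 1))
    if estimator == "forest":
        from sklearn.ensemble import ExtraTreesRegressor
        learner = ExtraTreesRegressor(n_estimators=10, max_depth=10,
                                      random_state=rng_seed, n_jobs=1)
    elif estimator == "ridge":
        from sklearn.linear_model import BayesianRidge
        learner = BayesianRidge()
    else:
        raise ValueError(f"unknown imputation estimator {estimator!r}")

    imputer = IterativeImputer(estimator=learner, max_iter=n_iterations,
                               random_state=rng_seed, skip_complete=True,
                               sample_posterior=False, tol=0.0)
    import warnings
    with warnings.catch_warnings():
        # a fixed iteration count is intentional, not a convergence failure
        warnings.filterwarnings("ignore", message=".*Early stopping criterion.*")
        completed = imputer.fit_transform(design.to_numpy(dtype=float))
    out = pd.DataFrame(completed[:, :n_prot], columns=proteins.columns,
                       index=proteins.index)
    observed = proteins.notna()
    out = out.where(~observed, proteins)
    return out


def split(cohort: CohortTable, derivation_fraction: float = 0.70,
          seed: int = 0) -> SplitAssignment:
    """Random derivation/validation split, performed independently within
    each sex stratum so both strata carry the target derivation fraction."""
    if not (0.0 < derivation_fraction < 1.0):
        raise ValueError(
            f"derivation_fraction must be in (0, 1), got {derivation_fraction}")
    if cohort.n == 0:
        raise ValueError("cannot split an empty cohort")
    rng = child_rng(seed, "split")
    derivation: list = []
    validation: list = []
    for sex in ("female", "male"):
        ids = cohort.covariates.loc[cohort.covariates["sex"] == sex,
                                    "participant_id"].to_numpy()
        ids = np.sort(ids)
        perm = rng.permutation(len(ids))
        n_der = int(round(derivation_fraction * len(ids)))
        derivation.extend(ids[perm[:n_der]].tolist())
        validation.extend(ids[perm[n_der:]].tolist())
    return SplitAssignment(sorted(derivation), sorted(validation), seed)


def standardize(proteins: pd.DataFrame, reference_index,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale each protein by the mean and SD (ddof=1) computed on the
    reference rows only; returns the standardized matrix (all rows) and the
    scaling metadata for reuse on held-out data."""
    ref = proteins.loc[reference_index]
    if len(ref) == 0:
        raise ValueError("reference set for standardization is empty")
    mean = ref.mean()
    sd = ref.std(ddof=1)
    bad = sd[(~np.isfinite(sd)) | (sd <= 0)]
    if len(bad):
        raise ValueError(f"zero/degenerate SD for protein(s): {list(bad.index)}")
    scaler = pd.DataFrame({"mean": mean, "sd": sd})
    return (proteins - mean) / sd, scaler


def apply_standardization(proteins: pd.DataFrame, scaler: pd.DataFrame) -> pd.DataFrame:
    """Apply previously computed scaling metadata to new rows."""
    missing = set(proteins.columns) - set(scaler.index)
    if missing:
        raise ValueError(f"scaler lacks protein(s): {sorted(missing)}")
    return (proteins - scaler["mean"]) / scaler["sd"]
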