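"""Predictor-set assembly, endpoint eligibility rules and leakage-free
imputation / standardization / encoding.

Predictor sets mirror common primary-prevention practice: Age+Sex
(demographics only), ASCVD (the cardiovascular panel: smoking, systolic
blood pressure, total and HDL cholesterol, diabetes and antihypertensive
medication), and PANEL (ASCVD plus lifestyle, physical measurements and
laboratory values).  Each can be combined with the endpoint's scalar
metabolomic state (MET).  PANELnoLaboratory is PANEL minus the laboratory
columns.

The preprocessor imputes missing continuous values with chained equations
(round-robin conditional models), then standardizes continuous columns and
one-hot encodes categoricals.  All statistics are fitted on training rows
only and reused verbatim on validation/test rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import IterativeImputer

from .synthetic import GroundTruthEndpoint, LABORATORY_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTOR_SETS",
    "predictor_set_columns",
    "assemble_predictor_set",
    "apply_endpoint_exclusions",
    "eligibility_masks",
    "Preprocessor",
]

_AGESEX = ["age", "sex"]
_ASCVD = _AGESEX + ["smoking_status", "systolic_bp", "total_cholesterol",
                    "hdl_cholesterol", "diabetes", "antihypertensive"]
_PANEL = _ASCVD + ["alcohol_units", "physical_activity", "education", "bmi",
                   "waist_circumference", "lipid_lowering", "glucose_lab",
                   "creatinine_lab", "crp_lab", "albumin_lab"]

PREDICTOR_SETS: Dict[str, List[str]] = {
    "MET": [],
    "AgeSex": _AGESEX,
    "ASCVD": _ASCVD,
    "PANEL": _PANEL,
    "PANELnoLaboratory": [c for c in _PANEL if c not in LABORATORY_COLUMNS],
    "AgeSex+MET": _AGESEX,
    "ASCVD+MET": _ASCVD,
    "PANEL+MET": _PANEL,
}

#: the seven covariate sets evaluated per endpoint
CORE_SETS = ["MET", "AgeSex", "ASCVD", "PANEL", "AgeSex+MET", "ASCVD+MET", "PANEL+MET"]


def predictor_set_columns(set_name: str) -> List[str]:
    if set_name not in PREDICTOR_SETS:
        raise KeyError(
            f"unknown predictor set {set_name!r}; valid options: "
            f"{sorted(PREDICTOR_SETS)}"
        )
    return list(PREDICTOR_SETS[set_name])


def state_column(endpoint: str) -> str:
    return f"met_state_{endpoint}"


def assemble_predictor_set(
    cohort: pd.DataFrame,
    set_name: str,
    states: Optional[pd.DataFrame] = None,
    endpoint: Optional[str] = None,
) -> pd.DataFrame:
    """Named predictor matrix for one covariate set.

    MET-suffixed sets (and MET itself) append exactly one state column for
    ``endpoint``, taken from ``states`` (participants x endpoints, indexed
    like the cohort).
    """
    cols = predictor_set_columns(set_name)
    out = cohort[cols].copy()
    if set_name == "MET" or set_name.endswith("+MET"):
        if states is None or endpoint is None:
            raise ValueError(f"predictor set {set_name!r} requires states and endpoint")
        if endpoint not in states.columns:
            raise KeyError(f"no state column for endpoint {endpoint!r}")
        out[state_column(endpoint)] = (
            states.loc[cohort["participant_id"], endpoint].to_numpy()
        )
    return out


def apply_endpoint_exclusions(cohort: pd.DataFrame, spec: GroundTruthEndpoint) -> pd.Series:
    """Eligibility mask for one endpoint.

    Excludes participants prevalent for this endpoint; lipid-lowering
    medication users if the endpoint is cardiovascular; and the non-target
    sex for sex-restricted endpoints.
    """
    prev_col = f"{spec.name}_prevalent"
    if prev_col not in cohort.columns:
        raise KeyError(f"unknown endpoint {spec.name!r}: column {prev_col} missing")
    eligible = ~cohort[prev_col].to_numpy(dtype=bool)
    if spec.cardiovascular_flag:
        eligible &= ~cohort["lipid_lowering"].to_numpy(dtype=bool)
    if spec.sex_restriction != "none":
        eligible &= (cohort["sex"] == spec.sex_restriction).to_numpy()
    return pd.Series(eligible, index=cohort.index, name=spec.name)


def eligibility_masks(cohort: pd.DataFrame,
                      specs: List[GroundTruthEndpoint]) -> pd.DataFrame:
    """participants x endpoints eligibility table."""
    return pd.DataFrame({s.name: apply_endpoint_exclusions(cohort, s) for s in specs})


# ---------------------------------------------------------------------------
# Preprocessor
# ---------------------------------------------------------------------------


@dataclass
class Preprocessor:
    """Chained-equation imputation + standardization + one-hot encoding.

    Fitted on training rows; ``transform`` never refits.  Continuous columns
    are imputed on the raw scale, then z-scored with training statistics.
    Categorical columns are one-hot encoded against the training level map,
    dropping the first level; levels unseen at fit time map to all-zeros
    with a logged warning.  Boolean columns pass through as 0/1.
    """

    conditional_learner: str = "regression"  # or "forest"
    max_sweeps: int = 10
    tol: float = 1e-3
    seed: int = 0

    continuous_: List[str] = field(default_factory=list, init=False)
    categorical_: List[str] = field(default_factory=list, init=False)
    boolean_: List[str] = field(default_factory=list, init=False)
    means_: Dict[str, float] = field(default_factory=dict, init=False)
    sds_: Dict[str, float] = field(default_factory=dict, init=False)
    levels_: Dict[str, List[str]] = field(default_factory=dict, init=False)
    imputer_: Optional[IterativeImputer] = field(default=None, init=False)
    provenance_: Dict[str, object] = field(default_factory=dict, init=False)

    def fit(self, train: pd.DataFrame, fold_id: Optional[int] = None) -> "Preprocessor":
        if len(train) == 0:
            raise ValueError("training rows must be non-empty")
        self.continuous_, self.categorical_, self.boolean_ = [], [], []
        for col in train.columns:
            s = train[col]
            if s.dtype == bool:
                self.boolean_.append(col)
            elif pd.api.types.is_numeric_dtype(s):
                self.continuous_.append(col)
            else:
                self.categorical_.append(col)

        if self.continuous_ and train[self.continuous_].isna().any().any():
            if self.conditional_learner == "forest":
                est = RandomForestRegressor(n_estimators=25, max_depth=8,
                                            random_state=self.seed, n_jobs=1)
            else:
                est = None  # BayesianRidge default
            self.imputer_ = IterativeImputer(
                estimator=est, max_iter=self.max_sweeps, tol=self.tol,
                random_state=self.seed, sample_posterior=False,
            )
            imputed = self.imputer_.fit_transform(train[self.continuous_])
        else:
            self.imputer_ = None
            imputed = train[self.continuous_].to_numpy(dtype=float) if self.continuous_ else None

        for j, col in enumerate(self.continuous_):
            vals = imputed[:, j]
            mu, sd = float(np.mean(vals)), float(np.std(vals))
            if sd == 0.0 or train[col].nunique(dropna=True) < 2:
                raise ValueError(f"continuous column {col!r} is constant in training rows")
            self.means_[col], self.sds_[col] = mu, sd

        for col in self.categorical_:
            self.levels_[col] = sorted(train[col].dropna().astype(str).unique().tolist())

        self.provenance_ = {"fold_id": fold_id, "n_rows": int(len(train))}
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        cols = self.continuous_ + self.categorical_ + self.boolean_
        missing = [c for c in cols if c not in rows.columns]
        if missing:
            raise KeyError(f"rows missing fitted columns: {missing}")
        out = {}
        if self.continuous_:
            block = rows[self.continuous_]
            if self.imputer_ is not None and block.isna().any().any():
                arr = self.imputer_.transform(block)
            else:
                arr = block.to_numpy(dtype=float)
            for j, col in enumerate(self.continuous_):
                out[col] = (arr[:, j] - self.means_[col]) / self.sds_[col]
        for col in self.categorical_:
            vals = rows[col].astype(str)
            levels = self.levels_[col]
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                logger.warning("column %r: unseen categories %s mapped to all-zeros",
                               col, sorted(unseen))
            # drop the first level as reference
            for lev in levels[1:]:
                out[f"{col}_{lev}"] = (vals == lev).to_numpy(dtype=float)
        for col in self.boolean_:
            out[col] = rows[col].to_numpy(dtype=float)
        return pd.DataFrame(out, index=rows.index)

    def inverse_transform_continuous(self, mat: pd.DataFrame) -> pd.DataFrame:
        out = mat.copy()
        for col in self.continuous_:
            out[col] = mat[col] * self.sds_[col] + self.means_[col]
        return out

    def column_sd(self, col: str) -> float:
        """Training s.d. of a continuous column (1.0 for encoded/boolean)."""
        return self.sds_.get(col, 1.0)
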