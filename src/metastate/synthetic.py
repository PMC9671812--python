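"""Synthetic cohort generator with retained ground truth.

Emulates the statistical structure of a large population cohort with NMR
metabolomics: 168 correlated circulating markers organised in
lipoprotein-like blocks plus independent small molecules, clinical
predictors with realistic inter-correlations, recruitment centers with mild
covariate shift, and per-endpoint right-censored survival outcomes generated
under an exponential-baseline proportional-hazards model.  The true
per-participant log-hazard of every endpoint is retained so that learned
risk states can be benchmarked against an oracle.

Event times use inverse-transform sampling: with constant baseline hazard
``h0`` and participant log-hazard ``eta``, ``T = -log(U) / (h0 * exp(eta))``
is exponential with rate ``h0 * exp(eta)``, which satisfies proportional
hazards exactly — the assumption every downstream model makes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "GroundTruthEndpoint",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "oracle_state",
    "default_endpoints",
    "marker_names",
    "CLINICAL_CONTINUOUS",
    "CLINICAL_CATEGORICAL",
    "CLINICAL_BINARY",
    "LABORATORY_COLUMNS",
    "DEFAULT_MISSINGNESS_COLUMNS",
]

# ---------------------------------------------------------------------------
# Clinical covariate schema
# ---------------------------------------------------------------------------

# (name, mean, sd) on the measurement scale; the generator also keeps the
# standardized latent, which is what ground-truth betas act on.
CLINICAL_CONTINUOUS: List[Tuple[str, float, float]] = [
    ("age", 56.0, 8.1),
    ("systolic_bp", 138.0, 18.0),
    ("bmi", 27.2, 4.6),
    ("waist_circumference", 90.0, 13.0),
    ("total_cholesterol", 5.7, 1.1),
    ("hdl_cholesterol", 1.45, 0.38),
    ("glucose_lab", 5.1, 1.2),
    ("creatinine_lab", 72.0, 17.0),
    ("crp_lab", 2.5, 4.0),
    ("albumin_lab", 45.2, 2.6),
    ("alcohol_units", 10.0, 9.0),
    ("physical_activity", 30.0, 20.0),
]
CLINICAL_CATEGORICAL: Dict[str, List[str]] = {
    "smoking_status": ["never", "former", "current"],
    "education": ["low", "medium", "high"],
}
CLINICAL_BINARY: List[str] = ["diabetes", "antihypertensive", "lipid_lowering"]
LABORATORY_COLUMNS: List[str] = [
    "total_cholesterol",
    "hdl_cholesterol",
    "glucose_lab",
    "creatinine_lab",
    "crp_lab",
    "albumin_lab",
]
DEFAULT_MISSINGNESS_COLUMNS: List[str] = [
    "systolic_bp",
    "bmi",
    "waist_circumference",
    "glucose_lab",
    "crp_lab",
    "albumin_lab",
    "alcohol_units",
    "physical_activity",
]


def marker_names(n_markers: int) -> List[str]:
    return [f"marker_{i:03d}" for i in range(n_markers)]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthEndpoint:
    """True outcome model for one synthetic endpoint.

    Exactly one of ``baseline_hazard`` (per-year rate) or
    ``target_event_rate_10y`` (10-year cumulative incidence the baseline is
    calibrated to) must be positive.
    """

    name: str
    baseline_hazard: float = 0.0
    target_event_rate_10y: float = 0.0
    clinical_betas: Dict[str, float] = field(default_factory=dict)
    marker_betas: Optional[np.ndarray] = None
    nonlinear_terms: List[Tuple[Tuple[int, int], float]] = field(default_factory=list)
    sex_restriction: str = "none"  # none | female | male
    prevalence_at_baseline: float = 0.02
    cardiovascular_flag: bool = False

    def __post_init__(self):
        if self.baseline_hazard < 0:
            raise ValueError(f"{self.name}: baseline_hazard must be >= 0")
        if not 0.0 <= self.prevalence_at_baseline < 1.0:
            raise ValueError(f"{self.name}: prevalence_at_baseline must be in [0,1)")
        if self.sex_restriction not in ("none", "female", "male"):
            raise ValueError(f"{self.name}: bad sex_restriction {self.sex_restriction!r}")


@dataclass
class CohortConfig:
    n_participants: int
    n_centers: int = 22
    n_markers: int = 168
    marker_block_sizes: Optional[List[int]] = None
    marker_block_correlation: float = 0.5
    endpoint_specs: Optional[List[GroundTruthEndpoint]] = None
    censoring_rate: float = 0.02
    horizon_years: float = 10.0
    admin_slack_years: float = 5.0
    missingness_fraction: float = 0.05
    missingness_columns: Optional[List[str]] = None
    missingness_mar_on_age: bool = False
    center_shift_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")
        if self.marker_block_sizes is None:
            # 14 lipoprotein-like blocks of 10 plus 28 independent small molecules
            if self.n_markers == 168:
                self.marker_block_sizes = [10] * 14 + [1] * 28
            else:
                self.marker_block_sizes = [1] * self.n_markers
        if sum(self.marker_block_sizes) != self.n_markers:
            raise ValueError(
                f"marker_block_sizes sum to {sum(self.marker_block_sizes)}, "
                f"expected n_markers={self.n_markers}"
            )
        if not 0.0 <= self.marker_block_correlation < 1.0:
            raise ValueError("marker_block_correlation must be in [0,1)")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if not 0.0 <= self.missingness_fraction < 1.0:
            raise ValueError("missingness_fraction must be in [0,1)")
        if self.endpoint_specs is None:
            self.endpoint_specs = default_endpoints(self.n_markers)
        if self.missingness_columns is None:
            self.missingness_columns = list(DEFAULT_MISSINGNESS_COLUMNS)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for ep in d["endpoint_specs"]:
            if ep["marker_betas"] is not None:
                ep["marker_betas"] = np.asarray(ep["marker_betas"]).tolist()
            ep["nonlinear_terms"] = [
                [list(pair), float(c)] for pair, c in ep["nonlinear_terms"]
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        eps = []
        for ep in d.pop("endpoint_specs", []) or []:
            if ep.get("marker_betas") is not None:
                ep["marker_betas"] = np.asarray(ep["marker_betas"], dtype=float)
            ep["nonlinear_terms"] = [
                ((int(p[0]), int(p[1])), float(c)) for p, c in ep.get("nonlinear_terms", [])
            ]
            eps.append(GroundTruthEndpoint(**ep))
        return cls(endpoint_specs=eps or None, **d)


@dataclass
class GroundTruth:
    """Oracle companion to a generated cohort."""

    endpoints: List[str]
    log_hazard: pd.DataFrame          # participants x endpoints
    baseline_hazards: Dict[str, float]
    config: CohortConfig
    seed: int

    def true_risk_at(self, endpoint: str, horizon: float) -> np.ndarray:
        """True cumulative incidence by ``horizon`` years, per participant."""
        h0 = self.baseline_hazards[endpoint]
        eta = self.log_hazard[endpoint].to_numpy()
        return 1.0 - np.exp(-h0 * np.exp(eta) * horizon)


# ---------------------------------------------------------------------------
# Default endpoint suite
# ---------------------------------------------------------------------------


def _beta_pattern(n_markers: int, entries: Dict[int, float]) -> np.ndarray:
    b = np.zeros(n_markers)
    for idx, val in entries.items():
        if idx < n_markers:
            b[idx] = val
    return b


def default_endpoints(n_markers: int = 168) -> List[GroundTruthEndpoint]:
    """Eight endpoints spanning the spectrum seen across common diseases.

    Three with strong metabolomic signal (as for type 2 diabetes, renal and
    liver disease), three mixed clinical/metabolomic (heart failure, MACE,
    dementia analogues), and two with zero metabolomic signal (the
    breast-cancer-like null, plus a rare neurological null).  Ten-year event
    rates span roughly 0.6% to 8.7%.  Coefficients are log-hazards per s.d.
    """

    def strong(entries):
        return _beta_pattern(n_markers, entries)

    # strong-metabolomic endpoints: the signal lives almost entirely in the
    # markers (clinical effects kept small), so a marker-only state can in
    # principle approach the oracle's discrimination
    t2d_like = GroundTruthEndpoint(
        name="t2d_like",
        target_event_rate_10y=0.042,
        clinical_betas={"age": 0.10, "bmi": 0.08},
        marker_betas=strong({0: 0.72, 1: -0.36, 2: 0.36, 10: 0.44, 11: -0.28,
                             20: 0.28, 140: 0.44, 141: -0.24, 150: 0.24}),
        nonlinear_terms=[((0, 0), 0.08)],
        prevalence_at_baseline=0.05,
    )
    renal_like = GroundTruthEndpoint(
        name="renal_like",
        target_event_rate_10y=0.040,
        clinical_betas={"age": 0.10},
        marker_betas=strong({30: 0.70, 31: 0.44, 32: -0.35, 40: 0.44, 41: -0.40,
                             145: 0.40, 146: 0.35}),
        prevalence_at_baseline=0.02,
    )
    liver_like = GroundTruthEndpoint(
        name="liver_like",
        target_event_rate_10y=0.030,
        clinical_betas={"age": 0.08, "alcohol_units": 0.10},
        marker_betas=strong({50: 0.70, 51: -0.42, 52: 0.37, 60: 0.42, 61: 0.33,
                             148: -0.37, 152: 0.33}),
        prevalence_at_baseline=0.01,
    )
    hf_like = GroundTruthEndpoint(
        name="heart_failure_like",
        target_event_rate_10y=0.030,
        clinical_betas={"age": 0.55, "systolic_bp": 0.30, "bmi": 0.25,
                        "antihypertensive": 0.20},
        marker_betas=strong({70: 0.45, 71: -0.3, 80: 0.35, 81: 0.25, 155: 0.3}),
        cardiovascular_flag=True,
        prevalence_at_baseline=0.02,
    )
    mace_like = GroundTruthEndpoint(
        name="mace_like",
        target_event_rate_10y=0.087,
        clinical_betas={"age": 0.60, "systolic_bp": 0.30, "total_cholesterol": 0.25,
                        "hdl_cholesterol": -0.20, "smoking_status": 0.25},
        marker_betas=strong({0: 0.35, 3: 0.25, 90: 0.35, 91: -0.25, 156: 0.25}),
        cardiovascular_flag=True,
        prevalence_at_baseline=0.05,
    )
    dementia_like = GroundTruthEndpoint(
        name="dementia_like",
        target_event_rate_10y=0.015,
        clinical_betas={"age": 0.85, "education": -0.15},
        marker_betas=strong({100: 0.4, 101: -0.35, 110: 0.3, 160: -0.3}),
        prevalence_at_baseline=0.005,
    )
    breast_cancer_like = GroundTruthEndpoint(
        name="breast_cancer_like",
        target_event_rate_10y=0.020,
        clinical_betas={"age": 0.25, "bmi": 0.10},
        marker_betas=np.zeros(n_markers),
        sex_restriction="female",
        prevalence_at_baseline=0.02,
    )
    parkinsons_like = GroundTruthEndpoint(
        name="parkinsons_like",
        target_event_rate_10y=0.006,
        clinical_betas={"age": 0.50},
        marker_betas=np.zeros(n_markers),
        prevalence_at_baseline=0.003,
    )
    return [t2d_like, renal_like, liver_like, hf_like, mace_like,
            dementia_like, breast_cancer_like, parkinsons_like]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _calibrate_baseline_hazard(target_rate: float, eta: np.ndarray, horizon: float) -> float:
    """Solve E[1 - exp(-h0 * exp(eta) * horizon)] = target_rate for h0."""

    def f(log_h0):
        return np.mean(1.0 - np.exp(-np.exp(log_h0) * np.exp(eta) * horizon)) - target_rate

    return float(np.exp(brentq(f, -25.0, 5.0, xtol=1e-12)))


def generate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort table plus its ground truth.

    Returns a DataFrame with one row per participant — id, center, sex,
    clinical covariates, marker concentrations, medication flags and, per
    endpoint, columns ``<name>_prevalent``, ``<name>_event``, ``<name>_time``
    — and a :class:`GroundTruth` holding the true log-hazards.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cfg = config

    center_id = rng.integers(0, cfg.n_centers, size=n)
    sex = np.where(rng.random(n) < 0.542, "female", "male")

    # latent factors inducing realistic clinical correlation structure
    adiposity = rng.normal(size=n)
    lipid = rng.normal(size=n)

    z: Dict[str, np.ndarray] = {}
    z["age"] = rng.normal(size=n)
    z["bmi"] = 0.80 * adiposity + 0.60 * rng.normal(size=n)
    z["waist_circumference"] = 0.85 * adiposity + 0.53 * rng.normal(size=n)
    z["systolic_bp"] = 0.40 * adiposity + 0.25 * z["age"] + 0.88 * rng.normal(size=n)
    z["total_cholesterol"] = 0.70 * lipid + 0.71 * rng.normal(size=n)
    z["hdl_cholesterol"] = -0.45 * lipid - 0.30 * adiposity + 0.84 * rng.normal(size=n)
    z["glucose_lab"] = 0.35 * adiposity + 0.94 * rng.normal(size=n)
    z["creatinine_lab"] = 0.20 * z["age"] + 0.98 * rng.normal(size=n)
    z["crp_lab"] = 0.40 * adiposity + 0.92 * rng.normal(size=n)
    z["albumin_lab"] = -0.20 * z["age"] + 0.98 * rng.normal(size=n)
    z["alcohol_units"] = rng.normal(size=n)
    z["physical_activity"] = -0.30 * adiposity + 0.95 * rng.normal(size=n)

    # mild per-center mean shift on continuous covariates and markers
    clin_shift = rng.normal(0.0, cfg.center_shift_sd, size=(cfg.n_centers, len(z)))
    for j, name in enumerate(z):
        z[name] = z[name] + clin_shift[center_id, j]

    smoking_p = np.array([0.55, 0.35, 0.10])
    smoking = rng.choice(CLINICAL_CATEGORICAL["smoking_status"], size=n, p=smoking_p)
    education = rng.choice(CLINICAL_CATEGORICAL["education"], size=n,
                           p=[0.25, 0.45, 0.30])
    diabetes = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-3.2 + 0.8 * z["glucose_lab"]))))
    antihypertensive = (rng.random(n) <
                        1.0 / (1.0 + np.exp(-(-1.8 + 0.7 * z["systolic_bp"]))))
    lipid_lowering = (rng.random(n) <
                      1.0 / (1.0 + np.exp(-(-1.9 + 0.6 * z["total_cholesterol"]
                                            + 0.4 * z["age"]))))

    # markers: block-correlated standard normals with center shift; the
    # lipid latent loads on the first block so markers correlate with labs
    rho = cfg.marker_block_correlation
    markers = np.empty((n, cfg.n_markers))
    col = 0
    block_id = 0
    for size in cfg.marker_block_sizes:
        if size == 1:
            markers[:, col] = rng.normal(size=n)
        else:
            factor = rng.normal(size=n)
            if block_id == 0:
                factor = 0.5 * lipid + np.sqrt(1 - 0.25) * factor
            noise = rng.normal(size=(n, size))
            markers[:, col:col + size] = (
                np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * noise
            )
            block_id += 1
        col += size
    marker_shift = rng.normal(0.0, cfg.center_shift_sd, size=(cfg.n_centers, cfg.n_markers))
    markers += marker_shift[center_id]

    # categorical/binary effects enter ground truth as crude standardized codes
    z_eff = dict(z)
    z_eff["smoking_status"] = (smoking == "current").astype(float) * 2.0 - 0.2
    z_eff["education"] = (education == "high").astype(float) - (education == "low")
    z_eff["diabetes"] = diabetes.astype(float) * 2.0
    z_eff["antihypertensive"] = antihypertensive.astype(float)
    z_eff["lipid_lowering"] = lipid_lowering.astype(float)

    data: Dict[str, object] = {
        "participant_id": np.arange(n, dtype=np.int64),
        "center_id": center_id,
        "sex": sex,
        "smoking_status": smoking,
        "education": education,
        "diabetes": diabetes,
        "antihypertensive": antihypertensive,
        "lipid_lowering": lipid_lowering,
    }
    for name, mean, sd in CLINICAL_CONTINUOUS:
        data[name] = mean + sd * z[name]
    for j, mname in enumerate(marker_names(cfg.n_markers)):
        data[mname] = markers[:, j]

    eta_cols: Dict[str, np.ndarray] = {}
    baselines: Dict[str, float] = {}
    female = sex == "female"
    for ep in cfg.endpoint_specs:
        eta = np.zeros(n)
        for cname, beta in ep.clinical_betas.items():
            eta += beta * z_eff[cname]
        if ep.marker_betas is not None and np.any(ep.marker_betas):
            eta += markers @ np.asarray(ep.marker_betas, dtype=float)
        for (i, j), c in ep.nonlinear_terms:
            if i == j:
                eta += c * (markers[:, i] ** 2 - 1.0)
            else:
                eta += c * markers[:, i] * markers[:, j]
        eta -= eta.mean()
        eta_cols[ep.name] = eta

        if ep.baseline_hazard > 0:
            h0 = ep.baseline_hazard
        elif ep.target_event_rate_10y > 0:
            h0 = _calibrate_baseline_hazard(ep.target_event_rate_10y, eta, 10.0)
        else:
            raise ValueError(f"{ep.name}: need baseline_hazard or target_event_rate_10y")
        baselines[ep.name] = h0

        t_event = -np.log(rng.random(n)) / (h0 * np.exp(eta))
        if cfg.censoring_rate > 0:
            c_random = -np.log(rng.random(n)) / cfg.censoring_rate
        else:
            c_random = np.full(n, np.inf)
        c_admin = cfg.horizon_years + rng.random(n) * cfg.admin_slack_years
        censor = np.minimum(c_random, c_admin)
        event = t_event <= censor
        time = np.minimum(t_event, censor)

        eligible_sex = np.ones(n, dtype=bool)
        if ep.sex_restriction == "female":
            eligible_sex = female
        elif ep.sex_restriction == "male":
            eligible_sex = ~female
        event &= eligible_sex
        time = np.where(eligible_sex, time, censor)

        prevalent = (rng.random(n) < ep.prevalence_at_baseline) & eligible_sex

        data[f"{ep.name}_prevalent"] = prevalent
        data[f"{ep.name}_event"] = event
        data[f"{ep.name}_time"] = np.maximum(time, 1e-6)

    cohort = pd.DataFrame(data)

    # missingness in designated clinical columns only
    if cfg.missingness_fraction > 0:
        for cname in cfg.missingness_columns:
            if cfg.missingness_mar_on_age:
                p = cfg.missingness_fraction * 2.0 / (1.0 + np.exp(-(z["age"])))
                mask = rng.random(n) < p
            else:
                mask = rng.random(n) < cfg.missingness_fraction
            cohort.loc[mask, cname] = np.nan

    truth = GroundTruth(
        endpoints=[ep.name for ep in cfg.endpoint_specs],
        log_hazard=pd.DataFrame(eta_cols, index=cohort["participant_id"]),
        baseline_hazards=baselines,
        config=cfg,
        seed=cfg.seed,
    )
    return cohort, truth


def oracle_state(cohort: pd.DataFrame, truth: GroundTruth, endpoint: str) -> np.ndarray:
    """True log-hazard vector — the upper-bound comparator for learned states."""
    if endpoint not in truth.endpoints:
        raise KeyError(
            f"unknown endpoint {endpoint!r}; available: {truth.endpoints}"
        )
    return truth.log_hazard.loc[cohort["participant_id"], endpoint].to_numpy()
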