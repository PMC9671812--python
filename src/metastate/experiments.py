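"""Self-contained verification studies for the pipeline's core claims.

Each function builds its own inputs (synthetic data or constructed
fixtures), runs the package's implementation, and measures the result
against an independent reference — an enumerated oracle, a closed form, a
coverage count, or the generator's retained ground truth.  The test suite
and the reproduction script both call these; the oracle code here is kept
deliberately naive (explicit loops, direct formulas) and separate from the
implementation paths it checks.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .evaluation import calibration_curve, decision_curve, harrell_c
from .preprocessing import eligibility_masks
from .state_model import (StateModelConfig, build_model, cox_ph_loss,
                          train_state_model)
from .survival import fit_cph, hr_per_sd
from .synthetic import CohortConfig, generate_cohort, marker_names, oracle_state

__all__ = [
    "cox_loss_vs_enumeration",
    "linear_limit_vs_cph",
    "concordance_vs_enumeration",
    "desk_recovery_config",
    "recovery_study",
    "hr_coverage_study",
    "utility_formula_checks",
    "attribution_additivity_study",
    "calibration_self_consistency_study",
    "leakage_audit_study",
    "determinism_study",
]


# ---------------------------------------------------------------------------
# 1. Cox partial-likelihood oracle
# ---------------------------------------------------------------------------


def _enumerated_breslow_nll(s, t, d) -> float:
    total, k = 0.0, 0
    for i in range(len(s)):
        if d[i]:
            k += 1
            rs = [np.exp(s[j]) for j in range(len(s)) if t[j] >= t[i]]
            total -= s[i] - np.log(sum(rs))
    return total / k


def cox_loss_vs_enumeration(seed: int, n_instances: int = 50) -> float:
    """Max |cox_ph_loss - enumerated Breslow NLL| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 31))
        s = rng.normal(size=n)
        t = np.round(rng.random(n) * 10, 1)  # induce occasional ties
        d = rng.random(n) < 0.6
        if not d.any():
            d[rng.integers(n)] = True
        worst = max(worst, abs(cox_ph_loss(s, t, d)
                               - _enumerated_breslow_nll(s, t, d)))
    return worst


# ---------------------------------------------------------------------------
# 2. Linear-limit equivalence
# ---------------------------------------------------------------------------


def linear_limit_vs_cph(seed: int, n: int = 5000) -> float:
    """Max |linear state-model coefficient - classical CPH coefficient|.

    A degenerate (single linear map, no normalization/dropout) state model
    trained to convergence on one endpoint with three standardized
    covariates, against the maximum partial-likelihood estimate.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    beta_true = np.array([0.5, -0.3, 0.2])
    t = -np.log(rng.random(n)) / (0.03 * np.exp(X @ beta_true))
    d = t <= 12.0
    t = np.minimum(t, 12.0)

    cfg = StateModelConfig(
        n_markers=3, n_endpoints=1, linear=True, weight_averaging=False,
        batch_size=n, learning_rate=0.05, max_epochs=400,
        schedule_steps=(250, 320, 370), early_stopping_patience=60, seed=seed)
    n_tr = int(0.85 * n)
    tm = train_state_model(
        build_model(cfg),
        (X[:n_tr], t[:n_tr, None], d[:n_tr, None], np.ones((n_tr, 1), bool)),
        (X[n_tr:], t[n_tr:, None], d[n_tr:, None], np.ones((n - n_tr, 1), bool)),
        cfg)
    # the linear head acts on z-scored inputs; rescale to raw-coefficient units
    w = tm.net.heads_linear[0].W.value[:, 0] / tm.marker_sd

    fit = fit_cph(pd.DataFrame(X[:n_tr], columns=["x0", "x1", "x2"]),
                  t[:n_tr], d[:n_tr])
    return float(np.max(np.abs(w - fit.params.to_numpy())))


# ---------------------------------------------------------------------------
# 3. Concordance oracle
# ---------------------------------------------------------------------------


def _enumerated_c(t, d, s) -> float:
    num = den = 0.0
    for i in range(len(t)):
        if not d[i]:
            continue
        for j in range(len(t)):
            if i == j:
                continue
            if t[i] < t[j] or (t[i] == t[j] and not d[j]):
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


def concordance_vs_enumeration(seed: int, n_instances: int = 100) -> int:
    """Number of instances where harrell_c differs from pair enumeration."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        n = 50
        t = rng.integers(1, 25, size=n).astype(float)
        d = rng.random(n) < 0.7
        if not d.any():
            d[0] = True
        s = np.round(rng.normal(size=n), 1)
        if abs(harrell_c(t, d, s) - _enumerated_c(t, d, s)) > 1e-12:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# 4. Multitask recovery
# ---------------------------------------------------------------------------


def desk_recovery_config(seed: int) -> StateModelConfig:
    """Desk-scale multitask recipe (see docs/methods.md)."""
    return StateModelConfig(
        n_markers=168, n_endpoints=8,
        shared_widths=(24, 24, 24), head_mlp_widths=(12, 8, 8),
        skip_widths=(8, 8, 8), post_merge_widths=(8, 8),
        shared_dropout=0.05, head_dropout=0.05, weight_decay=0.1,
        batch_size=512, learning_rate=5e-3, schedule_steps=(20, 30, 36),
        max_epochs=40, weight_averaging=False,
        checkpoint_selection="per_endpoint", early_stopping_patience=15,
        seed=seed)


STRONG_ENDPOINTS = ("t2d_like", "renal_like", "liver_like")
NULL_ENDPOINTS = ("breast_cancer_like", "parkinsons_like")


def recovery_study(seed: int, n_participants: int = 20000,
                   n_test_centers: int = 4) -> Dict[str, Dict[str, float]]:
    """Train the multitask model on one spatial split; C vs oracle per endpoint.

    Test set pools ``n_test_centers`` centers; validation is 10% of the
    remainder.  Returns {endpoint: {"oracle_c", "learned_c", "events"}}.
    """
    cfg = CohortConfig(n_participants=n_participants, seed=seed)
    cohort, truth = generate_cohort(cfg)
    endpoints = truth.endpoints
    masks = eligibility_masks(cohort, cfg.endpoint_specs)
    mcols = marker_names(cfg.n_markers)
    center = cohort["center_id"].to_numpy()
    test = np.isin(center, np.arange(n_test_centers))
    rng = np.random.default_rng(seed + 1)
    pool = np.flatnonzero(~test)
    valid_idx = rng.choice(pool, size=len(pool) // 10, replace=False)
    valid = np.zeros(len(cohort), bool)
    valid[valid_idx] = True
    train = ~test & ~valid

    def pack(rows):
        sub = cohort.loc[rows]
        return (sub[mcols].to_numpy(float),
                np.column_stack([sub[f"{e}_time"] for e in endpoints]),
                np.column_stack([sub[f"{e}_event"] for e in endpoints]),
                masks.loc[rows, endpoints].to_numpy(bool))

    scfg = desk_recovery_config(seed)
    model = train_state_model(build_model(scfg), pack(train), pack(valid),
                              scfg, endpoints)
    states = model.predict_states(cohort.loc[test, mcols].to_numpy(float))
    out = {}
    test_rows = cohort.loc[test]
    for i, e in enumerate(endpoints):
        el = masks.loc[test, e].to_numpy(bool)
        t = test_rows[f"{e}_time"].to_numpy()[el]
        d = test_rows[f"{e}_event"].to_numpy()[el]
        out[e] = {
            "oracle_c": harrell_c(t, d, oracle_state(test_rows, truth, e)[el]),
            "learned_c": harrell_c(t, d, states[el, i]),
            "events": int(d.sum()),
        }
    return out


# ---------------------------------------------------------------------------
# 5. HR recovery coverage
# ---------------------------------------------------------------------------


def hr_coverage_study(seed: int, n_replicates: int = 100, n: int = 2000,
                      true_log_hr: float = 0.6) -> int:
    """How many 95% CIs for the per-s.d. state HR cover the truth.

    Each replicate simulates age/sex plus a standardized state with per-s.d.
    log hazard ratio ``true_log_hr``, fits CPH on (age, sex, state), and
    checks the CI from hr_per_sd against exp(true_log_hr).
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        age = rng.normal(size=n)
        sex = (rng.random(n) < 0.5).astype(float)
        state = rng.normal(size=n)
        eta = 0.4 * age + 0.2 * sex + true_log_hr * state
        t = -np.log(rng.random(n)) / (0.02 * np.exp(eta))
        d = t <= 12.0
        t = np.minimum(t, 12.0)
        fit = fit_cph(pd.DataFrame({"age": age, "sex": sex, "state": state}),
                      t, d)
        sd = float(np.std(state))
        _, (lo, hi) = hr_per_sd(fit, "state")
        covered += lo <= np.exp(true_log_hr * sd) <= hi
    return covered


# ---------------------------------------------------------------------------
# 6. Utility formulas
# ---------------------------------------------------------------------------


def utility_formula_checks() -> Dict[str, float]:
    """Net benefit on a constructed confusion table, plus limiting values."""
    # n=100: 30 flagged at risk 0.3 (10 events, 20 non); 70 below threshold,
    # 5 of them events (prevalence 0.15)
    risks = np.r_[np.full(30, 0.3), np.full(70, 0.1)]
    events = np.r_[np.ones(10), np.zeros(20), np.ones(5), np.zeros(65)] > 0
    times = np.where(events, 5.0, 20.0)
    dc = decision_curve(risks, times, events, [0.001, 0.2], horizon=10.0)
    at_02 = dc[dc["threshold"] == 0.2].iloc[0]
    near_zero = dc.iloc[0]
    return {
        "net_benefit_at_0.2": float(at_02["net_benefit"]),
        "snb_at_0.2": float(at_02["snb"]),
        "treat_none_max_abs": float(dc["treat_none"].abs().max()),
        "treat_all_snb_near_zero_threshold": float(near_zero["treat_all_snb"]),
    }


# ---------------------------------------------------------------------------
# 7. Attribution additivity
# ---------------------------------------------------------------------------


def attribution_additivity_study(seed: int, n_samples: int = 1000
                                 ) -> Dict[str, float]:
    """Additivity of network attributions and the linear closed form."""
    from .attribution import additivity_residuals, compute_attributions
    from .state_model import TrainedStateModel

    rng = np.random.default_rng(seed)
    cfg = StateModelConfig(n_markers=30, n_endpoints=2,
                           shared_widths=(16, 16, 24),
                           head_mlp_widths=(12, 8, 6), skip_widths=(8, 8, 6),
                           post_merge_widths=(8, 8), seed=seed)
    net = build_model(cfg)
    net.forward(rng.normal(size=(256, 30)), training=True)  # settle BN stats
    model = TrainedStateModel(net=net, marker_mean=rng.normal(size=30),
                              marker_sd=np.abs(rng.normal(size=30)) + 0.5,
                              config=cfg, endpoints=["a", "b"])
    X = rng.normal(size=(n_samples, 30))
    bg = rng.normal(size=(64, 30))
    res = compute_attributions(model, X, bg, "a")
    resid = additivity_residuals(res)

    lin_cfg = StateModelConfig(n_markers=12, n_endpoints=1, linear=True,
                               seed=seed + 1)
    lin_net = build_model(lin_cfg)
    lin_model = TrainedStateModel(net=lin_net, marker_mean=np.zeros(12),
                                  marker_sd=np.ones(12), config=lin_cfg,
                                  endpoints=["a"])
    Xl = rng.normal(size=(200, 12))
    bgl = rng.normal(size=(32, 12))
    res_l = compute_attributions(lin_model, Xl, bgl, "a")
    w = lin_net.heads_linear[0].W.value[:, 0]
    closed = w * (Xl - bgl.mean(axis=0))
    return {
        "fraction_within_5pct": float((resid < 0.05).mean()),
        "max_relative_residual": float(resid.max()),
        "linear_closed_form_max_err": float(np.abs(res_l.phi - closed).max()),
    }


# ---------------------------------------------------------------------------
# 8. Calibration self-consistency
# ---------------------------------------------------------------------------


def calibration_self_consistency_study(seed: int, n: int = 20000,
                                       endpoint: str = "t2d_like"
                                       ) -> Dict[str, object]:
    """Score the cohort with its true 10-year risks; bins must sit on the
    diagonal within the Kaplan-Meier Greenwood CIs."""
    cfg = CohortConfig(n_participants=n, seed=seed)
    cohort, truth = generate_cohort(cfg)
    risks = truth.true_risk_at(endpoint, 10.0)
    cal = calibration_curve(risks, cohort[f"{endpoint}_time"].to_numpy(),
                            cohort[f"{endpoint}_event"].to_numpy(),
                            horizon=10.0, n_bins=10)
    within = ((cal["mean_predicted"] >= cal["observed_lo"])
              & (cal["mean_predicted"] <= cal["observed_hi"]))
    return {"bins_within_ci": int(within.sum()), "n_bins": len(cal),
            "curve": cal}


# ---------------------------------------------------------------------------
# 9. Leakage audit
# ---------------------------------------------------------------------------


def leakage_audit_study(seed: int) -> Dict[str, bool]:
    """Partition disjointness, preprocessor invariance, duplicate tripwire."""
    from .partitioning import audit_partitions, make_partitions
    from .preprocessing import Preprocessor
    from .survival import aggregate_test_predictions

    cfg = CohortConfig(n_participants=3000, n_centers=6, seed=seed)
    cohort, _ = generate_cohort(cfg)
    plan = make_partitions(cohort, seed=seed)
    partitions_ok = audit_partitions(plan, cohort)["passed"]

    fold = plan.folds[0]
    train_rows = cohort.set_index("participant_id").loc[fold.train_ids]
    cols = ["age", "systolic_bp", "bmi"]
    p1 = Preprocessor(seed=0).fit(train_rows[cols])
    _ = cohort  # full cohort (incl. test rows) remains in memory
    p2 = Preprocessor(seed=0).fit(train_rows[cols])
    preproc_ok = (p1.means_ == p2.means_ and p1.sds_ == p2.sds_)

    dup_tripped = False
    try:
        aggregate_test_predictions([
            pd.DataFrame({"participant_id": [1, 2], "lp": [0.0, 0.1]}),
            pd.DataFrame({"participant_id": [2, 3], "lp": [0.2, 0.3]}),
        ])
    except ValueError:
        dup_tripped = True
    return {"partitions_disjoint": bool(partitions_ok),
            "preprocessor_invariant": bool(preproc_ok),
            "duplicate_id_tripwire": dup_tripped}


# ---------------------------------------------------------------------------
# 10. End-to-end determinism
# ---------------------------------------------------------------------------


def determinism_study(seed: int, tmp_dir) -> bool:
    """Two smoke-profile runs with one master seed: byte-identical reports."""
    from pathlib import Path

    from .pipeline import run_pipeline, smoke_run_config

    tmp_dir = Path(tmp_dir)
    reports = []
    for tag in ("a", "b"):
        cfg = smoke_run_config(out_dir=str(tmp_dir / tag), master_seed=seed)
        cfg.cohort.n_participants = 2000
        cfg.cohort.n_centers = 4
        cfg.state.max_epochs = 5
        cfg.state.swa_start_epoch = 3
        cfg.eval.bootstrap_iterations = 40
        cfg.attribution_max_samples = 80
        cfg.attribution.background_size = 16
        path = run_pipeline(cfg)
        reports.append((path / "report.json").read_bytes())
    return reports[0] == reports[1]
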