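"""End-to-end orchestration: simulate -> partition -> train -> integrate ->
evaluate -> attribute, with deterministic seed fan-out and a leakage audit.

Every stage derives its seed by stable hashing of (master seed, stage name,
fold id), so a run is reproducible from the master seed alone; rerunning
with an identical config produces a byte-identical evaluation report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import survival as sv
from .attribution import (AttributionConfig, additivity_residuals,
                          compute_attributions, global_importance)
from .evaluation import EvaluationConfig
from .partitioning import audit_partitions, make_partitions
from .preprocessing import (CORE_SETS, Preprocessor, assemble_predictor_set,
                            eligibility_masks, state_column)
from .state_model import (StateModelConfig, build_model, export_model,
                          train_state_model)
from .synthetic import CohortConfig, generate_cohort, marker_names

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "smoke_run_config"]

#: delta comparisons evaluated per endpoint (baseline vs baseline + state)
DELTA_PAIRS = [("AgeSex", "AgeSex+MET"), ("ASCVD", "ASCVD+MET"),
               ("PANEL", "PANEL+MET")]


def stage_seed(master_seed: int, stage: str, fold: Optional[int] = None) -> int:
    """Stable (master, stage, fold) -> seed fan-out, below 2**31."""
    key = f"{master_seed}:{stage}:{fold if fold is not None else '-'}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    cohort: CohortConfig
    state: StateModelConfig
    eval: EvaluationConfig = field(default_factory=EvaluationConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    out_dir: str = "run"
    master_seed: int = 0
    valid_fraction: float = 0.10
    fold_subset: Optional[List[int]] = None
    run_attribution: bool = True
    run_embedding: bool = False
    attribution_max_samples: int = 500
    export_models: bool = True
    write_parquet: bool = True


def smoke_run_config(out_dir: str = "run_smoke", master_seed: int = 0) -> RunConfig:
    """Small profile: 2 folds, 4 endpoints, n=3,000, reduced widths."""
    from .synthetic import default_endpoints

    eps = [e for e in default_endpoints(168)
           if e.name in ("t2d_like", "mace_like", "heart_failure_like",
                         "breast_cancer_like")]
    cohort = CohortConfig(n_participants=3000, n_centers=6, endpoint_specs=eps,
                          seed=0)
    state = StateModelConfig(
        n_markers=168, n_endpoints=len(eps),
        shared_widths=(32, 32, 48), head_mlp_widths=(32, 16, 8),
        skip_widths=(16, 16, 8), post_merge_widths=(16, 16),
        batch_size=512, max_epochs=8, swa_start_epoch=5,
        early_stopping_patience=4,
    )
    evcfg = EvaluationConfig(
        bootstrap_iterations=50,
        threshold_grid=np.round(np.arange(0.02, 0.31, 0.02), 4),
        calibration_bins=5,
    )
    att = AttributionConfig(background_size=32)
    return RunConfig(cohort=cohort, state=state, eval=evcfg, attribution=att,
                     out_dir=out_dir, master_seed=master_seed,
                     fold_subset=[0, 1], attribution_max_samples=150,
                     export_models=False, write_parquet=False)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def _log_line(fh, **kwargs):
    kwargs["ts"] = round(time.time(), 3)
    fh.write(json.dumps(kwargs, sort_keys=True, cls=_JSONEncoder) + "\n")
    fh.flush()


def _survival_arrays(cohort: pd.DataFrame, endpoints: List[str],
                     masks: pd.DataFrame, rows: np.ndarray):
    sub = cohort.loc[rows]
    t = np.column_stack([sub[f"{e}_time"].to_numpy() for e in endpoints])
    d = np.column_stack([sub[f"{e}_event"].to_numpy() for e in endpoints])
    m = masks.loc[rows, endpoints].to_numpy(dtype=bool)
    return t, d, m


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    The run directory contains the partition plan, per-fold model exports,
    pooled test predictions, the evaluation report (JSON + tidy CSVs),
    attribution outputs and a line-delimited JSON log.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_fh = open(out / "log.jsonl", "w")

    # ---- simulate ---------------------------------------------------------
    cohort_cfg = dataclasses.replace(
        cfg.cohort, seed=stage_seed(cfg.master_seed, "simulate"))
    cohort, truth = generate_cohort(cohort_cfg)
    endpoints = truth.endpoints
    specs = {s.name: s for s in cohort_cfg.endpoint_specs}
    mcols = marker_names(cohort_cfg.n_markers)
    _log_line(log_fh, stage="simulate", seed=cohort_cfg.seed,
              n=len(cohort), endpoints=endpoints)
    if cfg.write_parquet:
        cohort.to_parquet(out / "cohort.parquet")
    cohort_cfg.to_yaml(out / "cohort_config.yaml")

    # ---- partition --------------------------------------------------------
    plan = make_partitions(cohort, cfg.valid_fraction,
                           seed=stage_seed(cfg.master_seed, "partition"))
    plan.to_json(out / "partitions.json")
    audit = audit_partitions(plan, cohort)
    _log_line(log_fh, stage="partition", **audit)

    masks = eligibility_masks(cohort, list(specs.values()))
    masks.index = cohort.index
    masks.set_index(cohort["participant_id"]).to_csv(out / "eligibility.csv")
    by_id = cohort.set_index("participant_id", drop=False)
    fold_ids = cfg.fold_subset if cfg.fold_subset is not None else list(range(len(plan.folds)))

    # ---- train + integrate per fold --------------------------------------
    predictions: Dict[str, Dict[str, List[pd.DataFrame]]] = {
        e: {s: [] for s in CORE_SETS} for e in endpoints}
    fold_models = {}
    preproc_audit_ok = True
    for k in fold_ids:
        fold = plan.folds[k]
        tr_rows = by_id.index.get_indexer(fold.train_ids)
        va_rows = by_id.index.get_indexer(fold.valid_ids)
        te_rows = by_id.index.get_indexer(fold.test_ids)
        x_tr = cohort.iloc[tr_rows][mcols].to_numpy(dtype=float)
        x_va = cohort.iloc[va_rows][mcols].to_numpy(dtype=float)

        scfg = dataclasses.replace(cfg.state,
                                   seed=stage_seed(cfg.master_seed, "train", k),
                                   n_endpoints=len(endpoints))
        net = build_model(scfg)
        trained = train_state_model(
            net,
            (x_tr, *_survival_arrays(cohort, endpoints, masks, cohort.index[tr_rows])),
            (x_va, *_survival_arrays(cohort, endpoints, masks, cohort.index[va_rows])),
            scfg, endpoints)
        fold_models[k] = trained
        if cfg.export_models:
            export_model(trained, out / "models" / f"fold_{k:02d}")
        _log_line(log_fh, stage="train", fold=k, seed=scfg.seed,
                  epochs=len(trained.history), selected=trained.selected)

        states = trained.states_frame(cohort, mcols)

        train_df = cohort.iloc[tr_rows]
        test_df = cohort.iloc[te_rows]
        for e in endpoints:
            elig_tr = masks.iloc[tr_rows][e].to_numpy()
            elig_te = masks.iloc[te_rows][e].to_numpy()
            if elig_tr.sum() == 0 or train_df.loc[elig_tr, f"{e}_event"].sum() == 0:
                logger.warning("fold %d endpoint %s: no eligible training events", k, e)
                continue
            for set_name in CORE_SETS:
                frame_tr = assemble_predictor_set(train_df, set_name, states, e)
                frame_te = assemble_predictor_set(test_df, set_name, states, e)
                scol = state_column(e)
                clin_cols = [c for c in frame_tr.columns if c != scol]
                if clin_cols:
                    prep = Preprocessor(seed=stage_seed(cfg.master_seed, "preprocess", k))
                    prep.fit(frame_tr[clin_cols], fold_id=k)
                    enc_tr = prep.transform(frame_tr[clin_cols])
                    enc_te = prep.transform(frame_te[clin_cols])
                else:
                    enc_tr = pd.DataFrame(index=frame_tr.index)
                    enc_te = pd.DataFrame(index=frame_te.index)
                if scol in frame_tr.columns:
                    # the state is already on a log-hazard-like scale
                    enc_tr[scol] = frame_tr[scol].to_numpy()
                    enc_te[scol] = frame_te[scol].to_numpy()
                # sex-restricted endpoints make some columns constant
                etr = enc_tr.loc[elig_tr]
                keep_cols = [c for c in etr.columns if etr[c].nunique() > 1]
                dropped = sorted(set(etr.columns) - set(keep_cols))
                if dropped:
                    logger.info("fold %d %s %s: dropping constant columns %s",
                                k, e, set_name, dropped)
                fit = sv.fit_cph(
                    enc_tr[keep_cols],
                    train_df[f"{e}_time"].to_numpy(),
                    train_df[f"{e}_event"].to_numpy(),
                    eligible=elig_tr, endpoint=e, set_name=set_name, fold_id=k)
                te_sub = enc_te.loc[elig_te, keep_cols]
                lp = sv.linear_predictor(fit, te_sub)
                risk = sv.predict_risk_at_horizon(fit, te_sub, cfg.eval.horizon)
                predictions[e][set_name].append(pd.DataFrame({
                    "participant_id": test_df.loc[elig_te, "participant_id"].to_numpy(),
                    "fold": k,
                    "lp": lp,
                    "risk": risk,
                    "time": test_df.loc[elig_te, f"{e}_time"].to_numpy(),
                    "event": test_df.loc[elig_te, f"{e}_event"].to_numpy(),
                    "state": (enc_te.loc[elig_te, scol].to_numpy()
                              if scol in enc_te.columns else np.nan),
                }))
        # preprocessor leakage audit: statistics must not change when test
        # rows are absent from memory
        probe_cols = ["age", "systolic_bp", "bmi"]
        p1 = Preprocessor(seed=1).fit(train_df[probe_cols])
        p2 = Preprocessor(seed=1).fit(
            pd.concat([train_df, test_df])[probe_cols].iloc[:len(train_df)])
        preproc_audit_ok &= (p1.means_ == p2.means_ and p1.sds_ == p2.sds_)
        _log_line(log_fh, stage="integrate", fold=k)

    # ---- pool + evaluate --------------------------------------------------
    eval_seed = stage_seed(cfg.master_seed, "evaluate")
    B = cfg.eval.bootstrap_iterations
    report: Dict[str, object] = {
        "master_seed": cfg.master_seed,
        "folds": list(fold_ids),
        "endpoints": endpoints,
        "covariate_sets": CORE_SETS,
        "leakage_audit": {"partitions": audit, "preprocessor_invariant": bool(preproc_audit_ok)},
        "results": {},
    }
    curves_rows = []
    pooled_all: Dict[str, Dict[str, pd.DataFrame]] = {}
    for e in endpoints:
        report["results"][e] = {}
        pooled_all[e] = {}
        for set_name in CORE_SETS:
            frames = predictions[e][set_name]
            if not frames:
                continue
            pooled = sv.aggregate_test_predictions(frames)
            pooled_all[e][set_name] = pooled
            t, d, lp = (pooled["time"].to_numpy(), pooled["event"].to_numpy(dtype=bool),
                        pooled["lp"].to_numpy())
            c_mid, c_ci = ev.bootstrap_ci(
                lambda ti, di, si: ev.harrell_c(ti, di, si), [t, d, lp],
                B, seed=eval_seed)
            entry: Dict[str, object] = {"n": int(len(pooled)),
                                        "events": int(d.sum()),
                                        "c_index": {"median": c_mid, "ci": list(c_ci)}}
            risk = pooled["risk"].to_numpy()
            cal = ev.calibration_curve(risk, t, d, cfg.eval.horizon,
                                       cfg.eval.calibration_bins)
            entry["calibration"] = cal.round(6).to_dict("records")
            dc = ev.decision_curve(risk, t, d, cfg.eval.threshold_grid,
                                   cfg.eval.horizon)
            entry["decision_curve"] = {
                "prevalence": dc.attrs["prevalence"],
                "n_excluded_censored": dc.attrs["n_excluded_censored"],
            }
            for _, r in dc.iterrows():
                curves_rows.append({"endpoint": e, "set": set_name,
                                    "curve": "decision", **r.to_dict()})
            y, known = ev.horizon_status(t, d, cfg.eval.horizon)
            if y[known].sum() > 0 and (1 - y[known]).sum() > 0:
                mf = ev.metrics_at_fpr(risk[known], y[known].astype(bool),
                                       cfg.eval.fpr_grid)
                entry["metrics_at_fpr"] = mf.round(6).to_dict("records")
            report["results"][e][set_name] = entry

        # state-based stratification (MET score) and deltas
        if "MET" in pooled_all[e]:
            pm = pooled_all[e]["MET"]
            s, y = pm["state"].to_numpy(), pm["event"].to_numpy(dtype=bool)
            curve = ev.event_rate_by_percentile(s, y, n_bins=min(100, len(pm) // 5))
            for _, r in curve.iterrows():
                curves_rows.append({"endpoint": e, "set": "MET",
                                    "curve": "percentile", **r.to_dict()})
            report["results"][e]["stratification"] = ev.decile_rate_ratio(
                s, y, n_iterations=B, seed=eval_seed)
        deltas = {}
        for base, combo in DELTA_PAIRS:
            if base in pooled_all[e] and combo in pooled_all[e]:
                a = pooled_all[e][combo].set_index("participant_id")
                bdf = pooled_all[e][base].set_index("participant_id")
                common = a.index.intersection(bdf.index)
                deltas[f"{combo}_vs_{base}"] = ev.c_delta(
                    a.loc[common, "lp"].to_numpy(),
                    bdf.loc[common, "lp"].to_numpy(),
                    a.loc[common, "time"].to_numpy(),
                    a.loc[common, "event"].to_numpy(dtype=bool),
                    n_iterations=B, seed=eval_seed)
        report["results"][e]["c_deltas"] = deltas
    _log_line(log_fh, stage="evaluate", seed=eval_seed)

    # assert the full endpoint x seven-covariate-set grid exists
    for e in endpoints:
        fitted_sets = [s for s in CORE_SETS if s in report["results"][e]]
        assert fitted_sets == CORE_SETS, (
            f"incomplete covariate-set grid for {e}: {fitted_sets}")

    # ---- attribution ------------------------------------------------------
    if cfg.run_attribution and fold_ids:
        k0 = fold_ids[0]
        trained = fold_models[k0]
        rng = np.random.default_rng(stage_seed(cfg.master_seed, "attribute", k0))
        fold = plan.folds[k0]
        te_rows = by_id.index.get_indexer(fold.test_ids)
        tr_rows = by_id.index.get_indexer(fold.train_ids)
        samp = rng.choice(te_rows, size=min(cfg.attribution_max_samples, len(te_rows)),
                          replace=False)
        bg = rng.choice(tr_rows, size=min(cfg.attribution.background_size, len(tr_rows)),
                        replace=False)
        X = cohort.iloc[samp][mcols].to_numpy(dtype=float)
        Xb = cohort.iloc[bg][mcols].to_numpy(dtype=float)
        phis = {}
        att_summary = {}
        for e in endpoints:
            res = compute_attributions(trained, X, Xb, e)
            phis[e] = res.phi
            resid = additivity_residuals(res)
            att_summary[e] = {
                "mean_abs_phi": float(np.abs(res.phi).mean()),
                "additivity_ok_fraction": float(
                    (resid < cfg.attribution.additivity_tolerance).mean()),
            }
        gi = global_importance(phis, mcols)
        gi.to_csv(out / "global_importance.csv")
        report["attribution"] = att_summary
        if cfg.run_embedding:
            from .attribution import embed_attributions
            emb = embed_attributions(phis[endpoints[0]],
                                     seed=cfg.attribution.embedding_seed)
            pd.DataFrame(emb, columns=["umap_1", "umap_2"]).to_csv(
                out / f"embedding_{endpoints[0]}.csv", index=False)
        _log_line(log_fh, stage="attribute", fold=k0, n_samples=len(samp))

    # ---- write outputs ----------------------------------------------------
    pooled_frames = []
    for e in endpoints:
        for set_name, pooled in pooled_all[e].items():
            pf = pooled.copy()
            pf["endpoint"] = e
            pf["set"] = set_name
            pooled_frames.append(pf)
    pooled_df = pd.concat(pooled_frames, ignore_index=True)
    if cfg.write_parquet:
        pooled_df.to_parquet(out / "pooled_predictions.parquet")
    else:
        pooled_df.to_csv(out / "pooled_predictions.csv", index=False)
    pd.DataFrame(curves_rows).to_csv(out / "curves.csv", index=False)
    tidy_rows = []
    for e in endpoints:
        for set_name in CORE_SETS:
            entry = report["results"][e].get(set_name)
            if not entry:
                continue
            lo, hi = entry["c_index"]["ci"]
            tidy_rows += [
                {"endpoint": e, "set": set_name, "metric": "c_index",
                 "value": entry["c_index"]["median"], "lo": lo, "hi": hi},
                {"endpoint": e, "set": set_name, "metric": "events",
                 "value": entry["events"], "lo": np.nan, "hi": np.nan},
            ]
        for name, d in report["results"][e]["c_deltas"].items():
            tidy_rows.append({"endpoint": e, "set": name, "metric": "c_delta",
                              "value": d["delta"], "lo": d["ci"][0],
                              "hi": d["ci"][1]})
    pd.DataFrame(tidy_rows).to_csv(out / "metrics.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, cls=_JSONEncoder)
    log_fh.close()
    return out
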