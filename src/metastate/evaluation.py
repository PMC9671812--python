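"""Discrimination, stratification, calibration and clinical-utility metrics
with bootstrap uncertainty.

Harrell's C is implemented to its pairwise contract: a pair is comparable
iff the earlier observed time is an event (a censored member tied with an
event is comparable, two events tied in time are not); concordance means the
earlier event carries the higher risk score; tied scores count 1/2.

Horizon-status classifications (decision curves, fixed-FPR metrics) exclude
participants censored before the horizon without an event; with zero
censoring they reduce exactly to the naive binary computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "harrell_c",
    "bootstrap_ci",
    "c_delta",
    "event_rate_by_percentile",
    "decile_rate_ratio",
    "calibration_curve",
    "decision_curve",
    "metrics_at_fpr",
    "horizon_status",
]


@dataclass
class EvaluationConfig:
    horizon: float = 10.0
    bootstrap_iterations: int = 1000
    decile_cut: float = 0.10
    threshold_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.5001, 0.005), 4))
    fpr_grid: Tuple[float, ...] = (0.05, 0.10, 0.20)
    calibration_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.threshold_grid, dtype=float)
        if np.any((t <= 0) | (t >= 1)) or np.any(np.diff(t) < 0):
            raise ValueError("threshold grid must be sorted within (0,1)")
        for f in self.fpr_grid:
            if not 0.0 < f < 1.0:
                raise ValueError("fpr grid values must be in (0,1)")


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def harrell_c(times, events, scores) -> float:
    """Harrell's concordance index; higher scores should mean earlier events."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (len(t) == len(d) == len(s)):
        raise ValueError("times, events, scores must have equal length")
    ev = np.flatnonzero(d)
    if ev.size == 0:
        raise ValueError("no comparable pairs: no events")
    num = 0.0
    den = 0
    # chunk over events to keep memory bounded at large n
    for start in range(0, ev.size, 512):
        chunk = ev[start:start + 512]
        ti = t[chunk][:, None]
        si = s[chunk][:, None]
        later = t[None, :] > ti
        tied_cens = (t[None, :] == ti) & (~d[None, :])
        comp = later | tied_cens
        comp[np.arange(len(chunk)), chunk] = False
        # among two events, the pair is handled once, from the earlier one
        n_comp = comp.sum()
        conc = ((si > s[None, :]) & comp).sum()
        ties = ((si == s[None, :]) & comp).sum()
        num += conc + 0.5 * ties
        den += n_comp
    # event pairs tied in both time are excluded; event-event pairs with
    # t_i < t_j were counted once (from i, j qualifying via `later`), but the
    # reverse direction also counted j's comparable set including i?  No:
    # from j, i has t_i < t_j, so i is not in j's later/tied-censored set.
    if den == 0:
        raise ValueError("no comparable pairs")
    return float(num / den)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence[np.ndarray],
    n_iterations: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> Tuple[float, Tuple[float, float]]:
    """Percentile bootstrap: (median, (2.5%, 97.5%)) over resamples.

    ``data`` is a sequence of aligned arrays passed positionally to
    ``statistic``.  Resamples on which the statistic is undefined (raises or
    returns non-finite) are redrawn; the count is logged.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iterations)
    redraws = 0
    for b in range(n_iterations):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                v = statistic(*[a[idx] for a in arrays])
            except Exception:
                v = np.nan
            if np.isfinite(v):
                vals[b] = v
                break
            redraws += 1
        else:
            raise RuntimeError("statistic undefined on too many resamples")
    if redraws:
        logger.info("bootstrap redrew %d undefined resamples", redraws)
    lo, mid, hi = np.percentile(vals, [2.5, 50.0, 97.5])
    return float(mid), (float(lo), float(hi))


def c_delta(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_iterations: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """Paired bootstrap of C(a) - C(b) on identical participants.

    Significant iff the 95% CI excludes 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    if not (len(a) == len(b) == len(t) == len(d)):
        raise ValueError("paired inputs must be scored on identical participants")

    def stat(ai, bi, ti, di):
        return harrell_c(ti, di, ai) - harrell_c(ti, di, bi)

    mid, (lo, hi) = bootstrap_ci(stat, [a, b, t, d], n_iterations, seed)
    return {"delta": mid, "ci": (lo, hi), "significant": bool(lo > 0 or hi < 0)}


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def event_rate_by_percentile(scores, events, n_bins: int = 100) -> pd.DataFrame:
    """Observed event frequency per equal-count score percentile bin."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(events, dtype=bool)
    order = np.argsort(s, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(splits):
        rows.append({"percentile": i + 1, "n": len(idx),
                     "events": int(y[idx].sum()),
                     "rate": float(y[idx].mean()) if len(idx) else np.nan,
                     "mean_score": float(s[idx].mean()) if len(idx) else np.nan})
    return pd.DataFrame(rows)


def decile_rate_ratio(
    scores,
    events,
    n_iterations: int = 1000,
    seed: int = 0,
    cut: float = 0.10,
) -> Dict[str, object]:
    """Top-vs-bottom decile event rates: risk ratio and odds ratio.

    Both are reported because printed decile rates in the field are
    sometimes labelled OR while matching the plain rate ratio; labels here
    are explicit.  A zero-event bottom decile yields a flagged lower bound
    (the bottom rate is replaced by 1/(n_bottom + 1)).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(events, dtype=bool)

    def rates(si, yi):
        lo_thr, hi_thr = np.quantile(si, [cut, 1.0 - cut])
        bot, top = yi[si <= lo_thr], yi[si >= hi_thr]
        return float(top.mean()), float(bot.mean()), len(bot)

    top_rate, bot_rate, n_bot = rates(s, y)
    lower_bound_flag = bot_rate == 0.0
    eff_bot = bot_rate if bot_rate > 0 else 1.0 / (n_bot + 1)
    ratio = top_rate / eff_bot
    odds = lambda p: p / (1.0 - p) if p < 1.0 else np.inf
    oratio = odds(top_rate) / odds(eff_bot)

    def stat(si, yi):
        tr, br, nb = rates(si, yi)
        br = br if br > 0 else 1.0 / (nb + 1)
        return tr / br

    _, ci = bootstrap_ci(stat, [s, y], n_iterations, seed)
    return {"rate_ratio": float(ratio), "odds_ratio": float(oratio),
            "ci": ci, "top_rate": top_rate, "bottom_rate": bot_rate,
            "lower_bound_flag": bool(lower_bound_flag)}


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibration_curve(
    predicted_risks,
    times,
    events,
    horizon: float = 10.0,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin mean predicted risk vs Kaplan-Meier observed incidence.

    Bins are equal-count over predicted risk; the observed incidence is
    ``1 - KM(horizon)`` within the bin, with Greenwood 95% CI.
    """
    p = np.asarray(predicted_risks, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0,1]")
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(splits):
        if len(idx) == 0:
            raise ValueError(f"calibration bin {i} empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[idx], d[idx])
        surv = float(kmf.survival_function_at_times(horizon).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        tgrid = ci.index.to_numpy(dtype=float)
        pos = max(np.searchsorted(tgrid, horizon, side="right") - 1, 0)
        s_lo, s_hi = float(ci.iloc[pos, 0]), float(ci.iloc[pos, 1])
        rows.append({
            "bin": i + 1, "n": len(idx),
            "mean_predicted": float(p[idx].mean()),
            "observed": 1.0 - surv,
            "observed_lo": 1.0 - s_hi,
            "observed_hi": 1.0 - s_lo,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical utility
# ---------------------------------------------------------------------------


def horizon_status(times, events, horizon: float) -> Tuple[np.ndarray, np.ndarray]:
    """(binary outcome by horizon, known-status mask).

    Outcome is 1 for an event at or before the horizon; participants
    censored before the horizon without an event have unknown status.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    y = d & (t <= horizon)
    known = y | (t >= horizon)
    return y.astype(int), known


def decision_curve(
    predicted_risks,
    times,
    events,
    thresholds,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """Net benefit and standardized net benefit across a threshold grid.

    NB(p) = TP/n - (FP/n) * p/(1-p) against horizon outcome status;
    sNB = NB / prevalence; treat-all and treat-none references included.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0,1)")
    p = np.asarray(predicted_risks, dtype=float)
    y, known = horizon_status(times, events, horizon)
    p, y = p[known], y[known]
    n = len(y)
    prev = y.mean() if n else np.nan
    rows = []
    for thr in thresholds:
        pos = p >= thr
        tp = float((pos & (y == 1)).sum()) / n
        fp = float((pos & (y == 0)).sum()) / n
        w = thr / (1.0 - thr)
        nb = tp - fp * w
        nb_all = prev - (1.0 - prev) * w
        rows.append({
            "threshold": float(thr),
            "net_benefit": nb,
            "snb": nb / prev if prev > 0 else np.nan,
            "treat_all": nb_all,
            "treat_all_snb": nb_all / prev if prev > 0 else np.nan,
            "treat_none": 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["prevalence"] = float(prev)
    out.attrs["n_excluded_censored"] = int((~known).sum())
    if prev == 0:
        logger.warning("zero prevalence: standardized net benefit undefined")
    return out


def metrics_at_fpr(predicted_risks, outcomes, fpr_grid) -> pd.DataFrame:
    """Sensitivity, PPV and LR+ at thresholds hit at target false-positive rates.

    The threshold is the (1 - fpr) quantile of the non-event scores; with
    ties the nearest achievable FPR is used and reported.
    """
    p = np.asarray(predicted_risks, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    neg = p[~y]
    pos = p[y]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("need both events and non-events")
    rows = []
    for fpr in np.asarray(fpr_grid, dtype=float):
        thr = np.quantile(neg, 1.0 - fpr, method="higher")
        achieved = float((neg >= thr).mean())
        sens = float((pos >= thr).mean())
        n_pos_pred = (p >= thr).sum()
        ppv = float((pos >= thr).sum() / n_pos_pred) if n_pos_pred else np.nan
        rows.append({
            "target_fpr": float(fpr), "achieved_fpr": achieved,
            "threshold": float(thr), "sensitivity": sens, "ppv": ppv,
            "lr_plus": sens / achieved if achieved > 0 else np.inf,
        })
    return pd.DataFrame(rows)
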