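"""The multitask residual metabolomic state model.

A shared fully connected trunk (168 -> 256 -> 256 -> 512, batch norm,
dropout 0.3, SiLU) feeds endpoint-specific residual heads.  Each head sees
both the shared representation and the raw markers: an MLP
(512 -> 256 -> 128 -> 32, dropout 0.6) transforms the representation, a
skip network (168 -> 128 -> 128 -> 32) transforms the markers, the two
32-dim outputs are added, passed through a 128 -> 128 block and a final
single-output linear layer with identity activation.  The scalar output per
endpoint is the metabolomic state, on a relative log-hazard scale.

Training minimizes, per endpoint, the negative mean log Cox partial
likelihood over the eligible in-batch events (Breslow ties, batch-local
risk sets), averaged within each endpoint and summed across endpoints.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn

logger = logging.getLogger(__name__)

__all__ = [
    "StateModelConfig",
    "MultiTaskStateNet",
    "TrainedStateModel",
    "build_model",
    "cox_ph_loss",
    "cox_ph_loss_grad",
    "multitask_loss",
    "train_state_model",
    "export_model",
    "load_model",
    "hyperparameter_search",
]


@dataclass
class StateModelConfig:
    n_markers: int = 168
    n_endpoints: int = 24
    shared_widths: Tuple[int, ...] = (256, 256, 512)
    shared_dropout: float = 0.3
    head_mlp_widths: Tuple[int, ...] = (256, 128, 32)
    head_dropout: float = 0.6
    skip_widths: Tuple[int, ...] = (128, 128, 32)
    post_merge_widths: Tuple[int, ...] = (128, 128)
    batch_size: int = 1024
    learning_rate: float = 0.001
    schedule_steps: Tuple[int, ...] = (20, 30, 40)
    schedule_gamma: float = 0.1
    max_epochs: int = 100
    weight_decay: float = 0.0  # L2 on weights; useful at small event counts
    weight_averaging: bool = True
    swa_start_epoch: int = 20
    early_stopping_patience: int = 10
    checkpoint_selection: str = "global"  # or "per_endpoint"
    linear: bool = False  # degenerate single-linear-map mode (no trunk/heads)
    seed: int = 0

    def __post_init__(self):
        for w in (*self.shared_widths, *self.head_mlp_widths,
                  *self.skip_widths, *self.post_merge_widths):
            if w <= 0:
                raise ValueError("all widths must be positive")
        for d in (self.shared_dropout, self.head_dropout):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropout must be in [0,1)")
        if self.checkpoint_selection not in ("global", "per_endpoint"):
            raise ValueError("checkpoint_selection must be 'global' or 'per_endpoint'")
        if not self.linear and self.head_mlp_widths[-1] != self.skip_widths[-1]:
            raise ValueError(
                "head MLP and skip network must end in equal widths for the "
                f"residual addition (got {self.head_mlp_widths[-1]} vs "
                f"{self.skip_widths[-1]})"
            )

    def n_parameters(self) -> int:
        """Closed-form trainable parameter count for this architecture."""
        if self.linear:
            return self.n_endpoints * (self.n_markers + 1)

        def block_chain(n_in, widths, bn=True):
            total, prev = 0, n_in
            for w in widths:
                total += prev * w + w          # linear
                if bn:
                    total += 2 * w             # gamma, beta
                prev = w
            return total

        total = block_chain(self.n_markers, self.shared_widths)
        rep = self.shared_widths[-1]
        per_head = (
            block_chain(rep, self.head_mlp_widths)
            + block_chain(self.n_markers, self.skip_widths)
            + block_chain(self.head_mlp_widths[-1], self.post_merge_widths)
            + self.post_merge_widths[-1] * 1 + 1
        )
        return total + self.n_endpoints * per_head


def _block(n_in: int, n_out: int, dropout: float, rng) -> List[nn.Layer]:
    layers: List[nn.Layer] = [nn.Linear(n_in, n_out, rng), nn.BatchNorm(n_out), nn.SiLU()]
    if dropout > 0:
        layers.append(nn.Dropout(dropout, rng))
    return layers


class _Head:
    """One endpoint head: MLP on the shared representation plus marker skip."""

    def __init__(self, cfg: StateModelConfig, rng):
        rep = cfg.shared_widths[-1]
        mlp_layers, prev = [], rep
        for w in cfg.head_mlp_widths:
            mlp_layers += _block(prev, w, cfg.head_dropout, rng)
            prev = w
        self.mlp = nn.Sequential(mlp_layers)
        skip_layers, prev = [], cfg.n_markers
        for w in cfg.skip_widths:
            skip_layers += _block(prev, w, 0.0, rng)
            prev = w
        self.skip = nn.Sequential(skip_layers)
        post_layers, prev = [], cfg.head_mlp_widths[-1]
        for w in cfg.post_merge_widths:
            post_layers += _block(prev, w, cfg.head_dropout, rng)
            prev = w
        self.post = nn.Sequential(post_layers)
        self.final = nn.Linear(cfg.post_merge_widths[-1], 1, rng)

    def forward(self, h, x, training):
        m = self.mlp.forward(h, training)
        s = self.skip.forward(x, training)
        z = self.post.forward(m + s, training)
        return self.final.forward(z, training)

    def backward(self, g):
        gz = self.final.backward(g)
        gms = self.post.backward(gz)
        gh = self.mlp.backward(gms)
        gx = self.skip.backward(gms)
        return gh, gx

    def params(self):
        return (self.mlp.params() + self.skip.params()
                + self.post.params() + self.final.params())


class MultiTaskStateNet:
    """Shared trunk + per-endpoint residual heads (or a bare linear map)."""

    def __init__(self, config: StateModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.linear = config.linear
        if self.linear:
            self.trunk = nn.Sequential([])
            self.heads_linear = [nn.Linear(config.n_markers, 1, rng)
                                 for _ in range(config.n_endpoints)]
            self.heads: List[_Head] = []
        else:
            trunk_layers, prev = [], config.n_markers
            for w in config.shared_widths:
                trunk_layers += _block(prev, w, config.shared_dropout, rng)
                prev = w
            self.trunk = nn.Sequential(trunk_layers)
            self.heads = [_Head(config, rng) for _ in range(config.n_endpoints)]
            self.heads_linear = []

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.n_markers:
            raise ValueError(
                f"expected input of shape (n, {self.config.n_markers}), got {x.shape}"
            )
        n = x.shape[0]
        out = np.empty((n, self.config.n_endpoints))
        if self.linear:
            for e, head in enumerate(self.heads_linear):
                out[:, e] = head.forward(x, training)[:, 0]
            return out
        h = self.trunk.forward(x, training)
        for e, head in enumerate(self.heads):
            out[:, e] = head.forward(h, x, training)[:, 0]
        return out

    def backward(self, grad_states: np.ndarray) -> None:
        if self.linear:
            for e, head in enumerate(self.heads_linear):
                head.backward(grad_states[:, e:e + 1])
            return
        gh_total = None
        for e, head in enumerate(self.heads):
            gh, _ = head.backward(grad_states[:, e:e + 1])
            gh_total = gh if gh_total is None else gh_total + gh
        self.trunk.backward(gh_total)

    def params(self) -> List[nn.Param]:
        ps = self.trunk.params()
        for head in self.heads:
            ps += head.params()
        for head in self.heads_linear:
            ps += head.params()
        return ps

    def _bn_layers(self) -> List[nn.BatchNorm]:
        out = []

        def collect(seq):
            out.extend(l for l in seq.layers if isinstance(l, nn.BatchNorm))

        collect(self.trunk)
        for head in self.heads:
            collect(head.mlp), collect(head.skip), collect(head.post)
        return out

    def state_arrays(self) -> List[np.ndarray]:
        """All learned arrays: parameters plus batch-norm running statistics."""
        arrs = [p.value for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def load_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


def build_model(config: StateModelConfig) -> MultiTaskStateNet:
    return MultiTaskStateNet(config)


# ---------------------------------------------------------------------------
# Cox partial-likelihood loss
# ---------------------------------------------------------------------------


def cox_ph_loss_grad(
    states: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    eligible: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray, int]:
    """Negative mean log partial likelihood (Breslow) and its gradient.

    Risk sets are formed within the supplied rows among eligible members
    with time >= the event time; ineligible rows contribute neither as
    events nor as risk-set members.  Returns (loss, d loss / d states,
    number of eligible events); with zero eligible events the loss is a
    flagged 0.0 with zero gradient.
    """
    states = np.asarray(states, dtype=np.float64).ravel()
    times = np.asarray(times, dtype=np.float64).ravel()
    events = np.asarray(events, dtype=bool).ravel()
    n = len(states)
    if not (len(times) == n and len(events) == n):
        raise ValueError("states, times and events must have equal length")
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    else:
        eligible = np.asarray(eligible, dtype=bool).ravel()
        if len(eligible) != n:
            raise ValueError("eligible must match states in length")

    grad = np.zeros(n)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return 0.0, grad, 0
    s = states[idx]
    t = times[idx]
    d = events[idx]
    k = int(d.sum())
    if k == 0:
        return 0.0, grad, 0

    order = np.argsort(t, kind="stable")
    s, t, d = s[order], t[order], d[order]
    smax = s.max()
    es = np.exp(s - smax)
    # sum of exp over rows with time >= each position's time (tie groups share)
    rev_cum = np.cumsum(es[::-1])[::-1]
    _, first_idx, counts = np.unique(t, return_index=True, return_counts=True)
    group_of = np.repeat(np.arange(len(first_idx)), counts)
    denom_group = rev_cum[first_idx]                   # per tie group
    denom = denom_group[group_of]                      # per row

    loss = -np.sum(np.where(d, (s - smax) - np.log(denom), 0.0)) / k

    # gradient: -(1/k) [ d_j - exp(s_j) * sum_{events with t_i <= t_j} 1/denom_i ]
    ev_over_denom = np.where(d, 1.0 / denom, 0.0)
    grp_sum = np.bincount(group_of, weights=ev_over_denom, minlength=len(first_idx))
    cum_by_group = np.cumsum(grp_sum)
    a = cum_by_group[group_of]
    g_sorted = -(d.astype(float) - es * a) / k
    g = np.zeros_like(g_sorted)
    g[order] = g_sorted
    grad[idx] = g
    return float(loss), grad, k


def cox_ph_loss(states, times, events, eligible=None) -> float:
    """Scalar version of :func:`cox_ph_loss_grad`."""
    return cox_ph_loss_grad(states, times, events, eligible)[0]


def multitask_loss(per_endpoint_losses: Sequence[float],
                   valid_flags: Optional[Sequence[bool]] = None) -> float:
    """Sum of per-endpoint mean losses over endpoints with valid contributions."""
    losses = np.asarray(per_endpoint_losses, dtype=float)
    if valid_flags is None:
        valid = np.ones(len(losses), dtype=bool)
    else:
        valid = np.asarray(valid_flags, dtype=bool)
        if len(valid) != len(losses):
            raise ValueError("valid_flags must match per_endpoint_losses in length")
    if not valid.any():
        warnings.warn("all endpoints invalid in this batch; multitask loss is 0")
        return 0.0
    return float(losses[valid].sum())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedStateModel:
    net: MultiTaskStateNet
    marker_mean: np.ndarray
    marker_sd: np.ndarray
    config: StateModelConfig
    endpoints: List[str]
    history: List[Dict[str, float]] = field(default_factory=list)
    selected: str = "best_checkpoint"
    # populated under per-endpoint checkpoint selection: one full weight set
    # per endpoint, each frozen at that endpoint's best validation epoch
    per_endpoint_arrays: Optional[List[List[np.ndarray]]] = None

    def predict_states(self, markers) -> np.ndarray:
        """States (n x endpoints) from raw marker values; deterministic."""
        x = np.asarray(markers, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != len(self.marker_mean):
            raise ValueError(
                f"expected markers of shape (n, {len(self.marker_mean)}), got {x.shape}"
            )
        xz = (x - self.marker_mean) / self.marker_sd
        if self.per_endpoint_arrays is None:
            return self.net.forward(xz, training=False)
        out = np.empty((len(xz), self.config.n_endpoints))
        for e, arrays in enumerate(self.per_endpoint_arrays):
            self.net.load_arrays(arrays)
            out[:, e] = self.net.forward(xz, training=False)[:, e]
        return out

    def states_frame(self, cohort: pd.DataFrame, marker_cols: List[str]) -> pd.DataFrame:
        out = pd.DataFrame(self.predict_states(cohort[marker_cols].to_numpy()),
                           columns=self.endpoints,
                           index=pd.Index(cohort["participant_id"], name="participant_id"))
        return out


def _reestimate_bn_stats(net: MultiTaskStateNet, x: np.ndarray) -> None:
    """Recompute batch-norm running statistics with one full pass.

    Weight-averaged networks need their normalization statistics refreshed:
    the average of running stats collected along the trajectory does not
    describe the averaged weights.  Dropout is disabled and momentum set to
    1 so the pass installs the full-data activation statistics.
    """
    bns = net._bn_layers()
    saved_momentum = [bn.momentum for bn in bns]
    drops = [l for seq in [net.trunk] + [
        s for h in net.heads for s in (h.mlp, h.skip, h.post)]
        for l in seq.layers if isinstance(l, nn.Dropout)]
    saved_p = [d.p for d in drops]
    try:
        for bn in bns:
            bn.momentum = 1.0
        for d in drops:
            d.p = 0.0
        net.forward(x, training=True)
    finally:
        for bn, m in zip(bns, saved_momentum):
            bn.momentum = m
        for d, p in zip(drops, saved_p):
            d.p = p


def _dataset_losses(net, x, times, events, eligible, batch=8192):
    """Per-endpoint losses in inference mode, with validity flags."""
    losses, valid = [], []
    states = np.vstack([net.forward(x[i:i + batch], training=False)
                        for i in range(0, len(x), batch)])
    for e in range(states.shape[1]):
        l, _, k = cox_ph_loss_grad(states[:, e], times[:, e], events[:, e], eligible[:, e])
        losses.append(l)
        valid.append(k > 0)
    return losses, valid


def _dataset_loss(net, x, times, events, eligible, batch=8192) -> float:
    losses, valid = _dataset_losses(net, x, times, events, eligible, batch)
    return multitask_loss(losses, valid)


def train_state_model(
    net: MultiTaskStateNet,
    train: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    valid: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    config: StateModelConfig,
    endpoints: Optional[List[str]] = None,
) -> TrainedStateModel:
    """Minibatch Adam on the multitask Cox loss.

    ``train``/``valid`` are (markers_raw, times, events, eligible) with
    times/events/eligible of shape (n, n_endpoints).  Markers are z-scored
    with training statistics, which are stored in the returned model.
    Learning-rate decay by ``schedule_gamma`` at ``schedule_steps``;
    stochastic weight averaging from ``swa_start_epoch``; early stopping on
    validation multitask loss; the returned network is the best-validation
    checkpoint (or the SWA average if it validates better).
    """
    x_tr_raw, t_tr, d_tr, m_tr = train
    x_va_raw, t_va, d_va, m_va = valid
    if len(x_va_raw) == 0:
        raise ValueError("validation set is empty")
    E = config.n_endpoints
    endpoints = endpoints or [f"endpoint_{e}" for e in range(E)]

    mean = x_tr_raw.mean(axis=0)
    sd = x_tr_raw.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    x_tr = (x_tr_raw - mean) / sd
    x_va = (x_va_raw - mean) / sd

    opt = nn.Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(x_tr)
    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_arrays = None
    best_epoch = -1
    per_endpoint = config.checkpoint_selection == "per_endpoint"
    best_val_e = np.full(E, np.inf)
    best_arrays_e: List[Optional[List[np.ndarray]]] = [None] * E
    swa_arrays = None
    swa_count = 0
    patience_left = config.early_stopping_patience

    for epoch in range(1, config.max_epochs + 1):
        decays = sum(epoch > step for step in config.schedule_steps)
        opt.lr = config.learning_rate * (config.schedule_gamma ** decays)

        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            rows = perm[start:start + config.batch_size]
            if len(rows) < 2:
                continue
            xb = x_tr[rows]
            opt.zero_grad()
            states = net.forward(xb, training=True)
            grad = np.zeros_like(states)
            losses, valid_flags = [], []
            for e in range(E):
                l, g, k = cox_ph_loss_grad(states[:, e], t_tr[rows, e],
                                           d_tr[rows, e], m_tr[rows, e])
                losses.append(l)
                valid_flags.append(k > 0)
                grad[:, e] = g
            batch_loss = multitask_loss(losses, valid_flags)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={batch_loss}); "
                    f"lr={opt.lr}, batch={len(rows)}"
                )
            net.backward(grad)
            if config.weight_decay > 0:
                for p in net.params():
                    p.grad += config.weight_decay * p.value
            opt.step()
            epoch_losses.append(batch_loss)

        val_losses, val_valid = _dataset_losses(net, x_va, t_va, d_va, m_va)
        val_loss = multitask_loss(val_losses, val_valid)
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "valid_loss": float(val_loss), "lr": float(opt.lr)})

        if per_endpoint:
            improved_any = False
            cur = None
            for e in range(E):
                if val_valid[e] and val_losses[e] < best_val_e[e] - 1e-9:
                    if cur is None:
                        cur = [a.copy() for a in net.state_arrays()]
                    best_val_e[e] = val_losses[e]
                    best_arrays_e[e] = cur
                    improved_any = True

        if config.weight_averaging and epoch >= config.swa_start_epoch:
            cur = [a.copy() for a in net.state_arrays()]
            if swa_arrays is None:
                swa_arrays, swa_count = cur, 1
            else:
                swa_count += 1
                for acc, c in zip(swa_arrays, cur):
                    acc += (c - acc) / swa_count

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_arrays = [a.copy() for a in net.state_arrays()]
            best_epoch = epoch
        improved = (improved_any if per_endpoint else best_epoch == epoch)
        if improved:
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
                break

    if per_endpoint:
        fallback = best_arrays or [a.copy() for a in net.state_arrays()]
        per_e = [arrs if arrs is not None else fallback for arrs in best_arrays_e]
        net.load_arrays(best_arrays if best_arrays is not None
                        else net.state_arrays())
        return TrainedStateModel(net=net, marker_mean=mean, marker_sd=sd,
                                 config=config, endpoints=list(endpoints),
                                 history=history,
                                 selected="per_endpoint_checkpoints",
                                 per_endpoint_arrays=per_e)

    selected = "best_checkpoint"
    if best_arrays is not None:
        net.load_arrays(best_arrays)
    if swa_arrays is not None:
        candidate = copy.deepcopy(net)
        candidate.load_arrays(swa_arrays)
        if not candidate.linear:
            _reestimate_bn_stats(candidate, x_tr)
        swa_val = _dataset_loss(candidate, x_va, t_va, d_va, m_va)
        if swa_val < best_val:
            net.load_arrays(candidate.state_arrays())
            best_val = swa_val
            selected = "swa"

    return TrainedStateModel(net=net, marker_mean=mean, marker_sd=sd,
                             config=config, endpoints=list(endpoints),
                             history=history, selected=selected)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_model(trained: TrainedStateModel, path) -> Path:
    """Write a portable artifact: weight bundle + JSON sidecar + history CSV.

    The sidecar carries the architecture config, endpoint names and the
    marker normalization statistics fitted at training time, so the bundle
    reproduces states on raw marker input.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = trained.net.state_arrays()
    payload = {f"arr_{i:04d}": a for i, a in enumerate(arrays)}
    if trained.per_endpoint_arrays is not None:
        for e, arrs in enumerate(trained.per_endpoint_arrays):
            payload.update({f"ep{e:02d}_arr_{i:04d}": a
                            for i, a in enumerate(arrs)})
    np.savez(path / "weights.npz", **payload)
    cfg = dataclasses.asdict(trained.config)
    for key in ("shared_widths", "head_mlp_widths", "skip_widths",
                "post_merge_widths", "schedule_steps"):
        cfg[key] = list(cfg[key])
    meta = {
        "config": cfg,
        "endpoints": trained.endpoints,
        "marker_mean": trained.marker_mean.tolist(),
        "marker_sd": trained.marker_sd.tolist(),
        "selected": trained.selected,
        "n_arrays": len(arrays),
        "per_endpoint": trained.per_endpoint_arrays is not None,
    }
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    pd.DataFrame(trained.history).to_csv(path / "history.csv", index=False)
    return path


def load_model(path) -> TrainedStateModel:
    path = Path(path)
    with open(path / "metadata.json") as fh:
        meta = json.load(fh)
    cfg_d = dict(meta["config"])
    for key in ("shared_widths", "head_mlp_widths", "skip_widths",
                "post_merge_widths", "schedule_steps"):
        cfg_d[key] = tuple(cfg_d[key])
    config = StateModelConfig(**cfg_d)
    net = build_model(config)
    per_e = None
    with np.load(path / "weights.npz") as z:
        arrays = [z[f"arr_{i:04d}"] for i in range(meta["n_arrays"])]
        if meta.get("per_endpoint"):
            per_e = [[z[f"ep{e:02d}_arr_{i:04d}"]
                      for i in range(meta["n_arrays"])]
                     for e in range(config.n_endpoints)]
    net.load_arrays(arrays)
    hist_path = path / "history.csv"
    history = (pd.read_csv(hist_path).to_dict("records")
               if hist_path.exists() else [])
    return TrainedStateModel(
        net=net,
        marker_mean=np.asarray(meta["marker_mean"], dtype=float),
        marker_sd=np.asarray(meta["marker_sd"], dtype=float),
        config=config,
        endpoints=list(meta["endpoints"]),
        history=history,
        selected=meta["selected"],
        per_endpoint_arrays=per_e,
    )


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


def hyperparameter_search(
    space: Dict[str, List],
    budget: int,
    seed: int,
    train: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    valid: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    base_config: StateModelConfig,
    endpoints: Optional[List[str]] = None,
) -> Tuple[StateModelConfig, List[Dict]]:
    """Uniform random search over ``space``, scored by validation loss.

    ``space`` maps StateModelConfig field names to candidate value lists.
    Returns the best config and the full trial log.
    """
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials: List[Dict] = []
    best_cfg, best_val = None, np.inf
    for trial in range(budget):
        overrides = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cfg = dataclasses.replace(base_config, **overrides)
        net = build_model(cfg)
        fitted = train_state_model(net, train, valid, cfg, endpoints)
        val = min(h["valid_loss"] for h in fitted.history)
        trials.append({"trial": trial, "overrides": overrides, "valid_loss": val})
        if val < best_val:
            best_val, best_cfg = val, cfg
    return best_cfg, trials
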