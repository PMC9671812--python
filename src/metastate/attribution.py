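"""Per-sample metabolite attributions for each endpoint state.

Attributions use the DeepLIFT rescale rule propagated through the state
network's layer graph, evaluated against each background sample and
averaged — the same quantity DeepSHAP's DeepExplainer computes for this
layer family.  For every background b the rescale rule is exactly additive:
sum_i phi_i(x, b) = f(x) - f(b), so the averaged attributions satisfy
sum_i phi_i(x) = f(x) - mean_b f(b) to numerical precision.  For a single
linear layer the rule reduces to the closed form
phi_i = w_i * (x_i - mean_b b_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .state_model import MultiTaskStateNet, TrainedStateModel

__all__ = [
    "AttributionConfig",
    "AttributionResult",
    "compute_attributions",
    "additivity_residuals",
    "global_importance",
    "percentile_profile",
    "high_impact_mask",
    "embed_attributions",
]


@dataclass
class AttributionConfig:
    background_size: int = 256
    high_impact_bounds: Tuple[float, float] = (0.01, 0.99)
    embedding_seed: int = 0
    additivity_tolerance: float = 0.05

    def __post_init__(self):
        lo, hi = self.high_impact_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("high-impact percentile bounds must satisfy 0 < lo < hi < 1")


@dataclass
class AttributionResult:
    """Attributions for one endpoint: samples x markers, in state units."""

    phi: np.ndarray
    f_x: np.ndarray
    f_background: np.ndarray
    endpoint: str
    background_description: str

    @property
    def expected_background(self) -> float:
        return float(self.f_background.mean())


def _endpoint_index(model: TrainedStateModel, endpoint) -> int:
    if isinstance(endpoint, (int, np.integer)):
        return int(endpoint)
    try:
        return model.endpoints.index(endpoint)
    except ValueError:
        raise KeyError(f"unknown endpoint {endpoint!r}; have {model.endpoints}")


def _head_multipliers(net: MultiTaskStateNet, e: int,
                      acts_x: dict, acts_r: dict, n: int) -> np.ndarray:
    """DeepLIFT multipliers on the normalized marker input for endpoint e."""
    if net.linear:
        head = net.heads_linear[e]
        return np.broadcast_to(head.W.value[:, 0], (n, head.W.value.shape[0])).copy()
    head = net.heads[e]
    m = np.ones((n, 1))
    m = head.final.dl_multiplier(m, None, None)
    m = head.post.dl_pass(m, acts_x["post"][e], acts_r["post"][e])
    # the residual addition fans the multiplier to both branches unchanged
    m_h = head.mlp.dl_pass(m, acts_x["mlp"][e], acts_r["mlp"][e])
    m_x_skip = head.skip.dl_pass(m, acts_x["skip"][e], acts_r["skip"][e])
    m_x_trunk = net.trunk.dl_pass(m_h, acts_x["trunk"], acts_r["trunk"])
    return m_x_trunk + m_x_skip


def _capture(net: MultiTaskStateNet, xz: np.ndarray):
    """Inference forward recording every layer input along all branches."""
    acts = {"mlp": {}, "skip": {}, "post": {}}
    if net.linear:
        out = net.forward(xz, training=False)
        return out, acts
    h, acts["trunk"] = net.trunk.forward_capture(xz)
    outs = []
    for e, head in enumerate(net.heads):
        m, acts["mlp"][e] = head.mlp.forward_capture(h)
        s, acts["skip"][e] = head.skip.forward_capture(xz)
        z, acts["post"][e] = head.post.forward_capture(m + s)
        outs.append(head.final.forward(z, training=False)[:, 0])
    return np.column_stack(outs), acts


def compute_attributions(
    model: TrainedStateModel,
    samples: np.ndarray,
    background: np.ndarray,
    endpoint,
) -> AttributionResult:
    """DeepLIFT-rescale attributions averaged over the background sample.

    ``samples`` and ``background`` are raw marker matrices; normalization
    uses the model's stored training statistics.  Attribution values are
    identical on the raw and normalized scales because z-scoring is affine.
    """
    e = _endpoint_index(model, endpoint)
    x = np.asarray(samples, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D matrix")
    if bg.shape[1] != x.shape[1] or x.shape[1] != len(model.marker_mean):
        raise ValueError(
            f"marker dimension mismatch: samples {x.shape[1]}, background "
            f"{bg.shape[1]}, model {len(model.marker_mean)}"
        )
    xz = (x - model.marker_mean) / model.marker_sd
    bz = (bg - model.marker_mean) / model.marker_sd
    n = len(xz)

    out_x, acts_x = _capture(model.net, xz)
    f_x = out_x[:, e]
    phi = np.zeros_like(xz)
    f_b = np.empty(len(bz))
    for bi in range(len(bz)):
        out_r, acts_r = _capture(model.net, bz[bi:bi + 1])
        f_b[bi] = out_r[0, e]
        m = _head_multipliers(model.net, e, acts_x, acts_r, n)
        phi += m * (xz - bz[bi:bi + 1])
    phi /= len(bz)
    return AttributionResult(
        phi=phi, f_x=f_x, f_background=f_b,
        endpoint=model.endpoints[e] if model.endpoints else str(e),
        background_description=f"{len(bz)} background rows",
    )


def additivity_residuals(result: AttributionResult, eps: float = 1e-8) -> np.ndarray:
    """Relative residual |sum(phi) - (f(x) - E_b f)| / (|f(x) - E_b f| + eps)."""
    delta = result.f_x - result.expected_background
    return np.abs(result.phi.sum(axis=1) - delta) / (np.abs(delta) + eps)


def global_importance(attributions: Dict[str, np.ndarray],
                      marker_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Sum of absolute attributions per marker and endpoint."""
    if not attributions:
        raise ValueError("empty attribution collection")
    cols = {}
    for endpoint, phi in attributions.items():
        phi = np.asarray(phi)
        if phi.size == 0:
            raise ValueError(f"empty attribution tensor for {endpoint!r}")
        cols[endpoint] = np.abs(phi).sum(axis=0)
    idx = (list(marker_names) if marker_names is not None
           else [f"marker_{i:03d}" for i in range(len(next(iter(cols.values()))))])
    return pd.DataFrame(cols, index=pd.Index(idx, name="marker"))


def percentile_profile(
    phi: np.ndarray,
    marker_values: np.ndarray,
    n_bins: int = 100,
) -> Dict[str, np.ndarray]:
    """Per-marker attribution profile over attribution percentiles.

    For each marker, participants are ranked by attribution and split into
    equal-count bins; each bin reports the mean attribution and the mean raw
    marker value (used for coloring in circular profile plots).
    Returns arrays of shape (n_markers, n_bins).
    """
    phi = np.asarray(phi, dtype=float)
    vals = np.asarray(marker_values, dtype=float)
    if phi.shape != vals.shape:
        raise ValueError("attributions and marker values must align")
    n, d = phi.shape
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} participants, got {n}")
    mean_phi = np.empty((d, n_bins))
    mean_val = np.empty((d, n_bins))
    for j in range(d):
        order = np.argsort(phi[:, j], kind="stable")
        splits = np.array_split(order, n_bins)
        for b, idx in enumerate(splits):
            mean_phi[j, b] = phi[idx, j].mean()
            mean_val[j, b] = vals[idx, j].mean()
    return {"mean_attribution": mean_phi, "mean_marker_value": mean_val}


def high_impact_mask(
    phi: np.ndarray,
    bounds: Tuple[float, float] = (0.01, 0.99),
    reference: Optional[np.ndarray] = None,
    fixed_interval: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Flag attributions outside the 1%/99% percentiles of the pooled
    per-endpoint distribution (the interval is data-derived, not a constant).

    ``reference`` supplies the distribution the percentiles are computed
    from (defaults to ``phi`` itself); ``fixed_interval`` switches to a
    fixed numeric interval instead.
    """
    phi = np.asarray(phi, dtype=float)
    if fixed_interval is not None:
        lo, hi = fixed_interval
    else:
        ref = phi if reference is None else np.asarray(reference, dtype=float)
        pooled = ref.ravel()
        if np.ptp(pooled) == 0:
            raise ValueError("degenerate (constant) attribution distribution")
        lo, hi = np.quantile(pooled, [bounds[0], bounds[1]])
    return (phi < lo) | (phi > hi)


def embed_attributions(phi: np.ndarray, seed: int = 0,
                       n_neighbors: int = 15, min_rows: int = 20) -> np.ndarray:
    """2-D UMAP embedding of the attribution space, deterministic per seed."""
    import umap  # deferred: numba compilation is expensive at import

    phi = np.asarray(phi, dtype=float)
    if len(phi) < max(min_rows, n_neighbors + 1):
        raise ValueError(
            f"need at least {max(min_rows, n_neighbors + 1)} rows, got {len(phi)}"
        )
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    return np.asarray(reducer.fit_transform(phi), dtype=float)
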