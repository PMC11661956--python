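"""Meta-state analysis: independent connectivity patterns and dynamism metrics.

Pooled windowed FNC is decomposed into a small number of maximally
independent connectivity patterns (spatial ICA over the pair dimension); each
window is expressed as a weight vector over the patterns by least-squares
projection, the weights are discretized into signed quartiles (+/-1..4), and
four dynamism metrics summarize the resulting trajectory through pattern
space: number of distinct meta-states, number of meta-state changes
(fluidity), span and total distance in city-block geometry (dynamic range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import FastICA

from .dynamic_fnc import WindowedFNC

__all__ = [
    "MetaParams",
    "MetaStateModel",
    "MetaStateMetrics",
    "fit_meta_states",
    "project_weights",
    "discretize_weights",
    "meta_state_metrics",
    "metrics_table",
]


@dataclass
class MetaParams:
    """Meta-state settings: pattern count (model order) and seed."""

    model_order: int = 5
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.model_order < 2:
            raise ValueError("model order must be >= 2")


@dataclass
class MetaStateModel:
    """Independent connectivity patterns plus per-subject weight trajectories."""

    patterns: np.ndarray  # (model_order x P), unit norm, sign-normalized
    weights: dict[str, np.ndarray]  # subject -> (W x model_order)
    params: MetaParams
    pair_names: list[str] = field(default_factory=list)

    @property
    def model_order(self) -> int:
        return self.patterns.shape[0]


def _normalize_patterns(patterns: np.ndarray) -> np.ndarray:
    """Unit-norm rows with the largest-magnitude entry positive."""
    out = patterns.copy()
    for i in range(out.shape[0]):
        nrm = np.linalg.norm(out[i])
        if nrm > 0:
            out[i] /= nrm
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def project_weights(x: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    """Least-squares weights of each row of ``x`` on the patterns.

    Solves min ||x - w @ patterns||; works for held-out windows too.
    """
    w, *_ = np.linalg.lstsq(patterns.T, x.T, rcond=None)
    return w.T


def fit_meta_states(wfnc: WindowedFNC, params: MetaParams | None = None) -> MetaStateModel:
    """Estimate maximally independent connectivity patterns from pooled windows.

    Each window's FNC vector is modeled as a mixture of ``model_order``
    patterns with maximally independent weights across windows; the patterns
    are the columns of the fitted mixing matrix, and per-window weights come
    from least-squares projection onto them (so held-out subjects can be
    projected onto a fitted model).  Patterns are unit-norm with the
    largest-magnitude entry positive; deterministic given the seed.
    """
    params = params or MetaParams()
    x, _ = wfnc.pooled()
    if x.shape[0] < params.model_order:
        raise ValueError("fewer pooled windows than the model order")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < params.model_order:
        raise ValueError(
            f"pooled windowed FNC has rank {rank} < model order {params.model_order}"
        )
    ica = FastICA(
        n_components=params.model_order,
        random_state=params.seed,
        max_iter=params.max_iter,
        tol=params.tol,
        whiten="unit-variance",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter on hard data
        ica.fit(x)  # windows are mixtures of the patterns
    patterns = _normalize_patterns(ica.mixing_.T)
    weights: dict[str, np.ndarray] = {}
    for sid, z in wfnc.z.items():
        weights[sid] = project_weights(z, patterns)
    return MetaStateModel(
        patterns=patterns, weights=weights, params=params, pair_names=list(wfnc.pair_names)
    )


def _quartile_boundaries(absw: np.ndarray) -> np.ndarray:
    """25/50/75 percentiles of |weight|, nudged apart when degenerate ties occur."""
    b = np.percentile(absw, [25, 50, 75])
    if not (b[0] < b[1] < b[2]):
        scale = max(absw.max(), 1.0)
        eps = 1e-9 * scale
        warnings.warn("degenerate quartile boundaries; applying stable tie-break nudges")
        for i in range(1, 3):
            if b[i] <= b[i - 1]:
                b[i] = b[i - 1] + eps
    return b


def discretize_weights(model: MetaStateModel) -> dict[str, np.ndarray]:
    """Signed-quartile discretization of the weight trajectories.

    Quartile boundaries of |weight| are pooled over all subjects' windows per
    pattern; each weight maps to sign(w) * quartile(|w|) in {+/-1..+/-4}
    (zero weights map to +1).
    """
    pooled = np.vstack([w for w in model.weights.values()])
    order = model.model_order
    bounds = [_quartile_boundaries(np.abs(pooled[:, j])) for j in range(order)]
    out: dict[str, np.ndarray] = {}
    for sid, w in model.weights.items():
        disc = np.empty(w.shape, dtype=int)
        for j in range(order):
            level = 1 + np.searchsorted(bounds[j], np.abs(w[:, j]), side="left")
            sign = np.where(w[:, j] >= 0, 1, -1)
            disc[:, j] = sign * level
        out[sid] = disc
    return out


@dataclass
class MetaStateMetrics:
    """Fluidity and range of one discretized trajectory."""

    n_meta_states: int
    n_changes: int
    span: float
    total_distance: float

    def as_tuple(self) -> tuple:
        return (self.n_meta_states, self.n_changes, self.span, self.total_distance)


def meta_state_metrics(traj: np.ndarray) -> MetaStateMetrics:
    """Fluidity (distinct states, changes) and range (span, total distance).

    span is the largest city-block distance between any two occupied vectors;
    total distance sums successive city-block steps.  A constant trajectory
    yields (1, 0, 0, 0).
    """
    traj = np.asarray(traj)
    if traj.ndim != 2 or traj.shape[0] < 1:
        raise ValueError("trajectory must be (windows x order) with >= 1 window")
    uniq = np.unique(traj, axis=0)
    n_states = uniq.shape[0]
    steps = np.abs(np.diff(traj, axis=0)).sum(axis=1)
    n_changes = int((steps > 0).sum())
    total = float(steps.sum())
    span = float(pdist(uniq, metric="cityblock").max()) if n_states > 1 else 0.0
    return MetaStateMetrics(
        n_meta_states=int(n_states), n_changes=n_changes, span=span, total_distance=total
    )


def metrics_table(trajectories: dict[str, np.ndarray], groups=None):
    """Tidy per-subject meta-state metric table."""
    import pandas as pd

    rows = []
    for sid, traj in trajectories.items():
        m = meta_state_metrics(traj)
        row = {"subject_id": sid}
        if groups is not None:
            row["group"] = groups[sid] if isinstance(groups, dict) else groups.loc[sid]
        row.update(
            n_meta_states=m.n_meta_states, n_changes=m.n_changes,
            span=m.span, total_distance=m.total_distance,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
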