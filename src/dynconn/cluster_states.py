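"""Recurring connectivity states: k-means clustering and dwell statistics.

All subjects' windowed FNC vectors are pooled and clustered with k-means
under the city-block (L1) metric with median centroid updates, the natural
pairing for L1 geometry (squared-Euclidean with mean updates is available as
an option).  Per-subject state-assignment sequences yield mean dwell time,
fraction time and the number of transitions (NT); per-state group contrasts
compare subjects' state-conditional mean connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .dynamic_fnc import WindowedFNC
from .group_stats import bh_fdr
from .types import StatResult

__all__ = [
    "ClusterParams",
    "ClusterStateModel",
    "StateMetrics",
    "kmeans_cityblock",
    "fit_cluster_states",
    "run_lengths",
    "state_metrics",
    "metrics_table",
    "per_state_group_compare",
    "sweep_k",
    "match_labels",
    "label_agreement",
]


@dataclass
class ClusterParams:
    """k-means settings: state count, restarts, metric, seed."""

    k: int = 5
    n_replicates: int = 100
    distance: str = "cityblock"  # or "sqeuclidean"
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.distance not in ("cityblock", "sqeuclidean"):
            raise ValueError("distance must be 'cityblock' or 'sqeuclidean'")


@dataclass
class ClusterStateModel:
    """Fitted state model: centroids, per-subject assignments, cost."""

    centroids: np.ndarray  # (k x P)
    assignments: dict[str, np.ndarray]  # subject -> (W,) state ids in 0..k-1
    cost: float
    params: ClusterParams
    median_states: np.ndarray | None = None  # (k x P) median of member windows

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _assign(x: np.ndarray, cent: np.ndarray, metric: str) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(x, cent, metric="cityblock" if metric == "cityblock" else "sqeuclidean")
    lab = d.argmin(axis=1)
    return lab, d[np.arange(len(lab)), lab]


def kmeans_cityblock(
    x: np.ndarray, k: int, rng: np.random.Generator,
    metric: str = "cityblock", max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run: k-means++-style init, median (or mean) updates.

    Returns (centroids, labels, total cost).  Cost is the summed L1 (or
    squared L2) distance of each point to its centroid.
    """
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of windows {n}")
    # k-means++ style seeding under the chosen metric
    cent = np.empty((k, x.shape[1]))
    cent[0] = x[rng.integers(n)]
    d2 = cdist(x, cent[:1], metric="cityblock" if metric == "cityblock" else "sqeuclidean").ravel()
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        cent[j] = x[rng.choice(n, p=probs)]
        dj = cdist(x, cent[j : j + 1], metric="cityblock" if metric == "cityblock" else "sqeuclidean").ravel()
        d2 = np.minimum(d2, dj)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        new_labels, dist = _assign(x, cent, metric)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if len(members) == 0:
                # re-seed an empty cluster at the farthest point
                far = int(np.argmax(dist))
                cent[j] = x[far]
            elif metric == "cityblock":
                cent[j] = np.median(members, axis=0)
            else:
                cent[j] = members.mean(axis=0)
    labels, dist = _assign(x, cent, metric)
    return cent, labels, float(dist.sum())


def fit_cluster_states(wfnc: WindowedFNC, params: ClusterParams | None = None) -> ClusterStateModel:
    """Cluster all pooled windows; best of ``n_replicates`` random restarts.

    States are relabeled in decreasing order of occupancy so that state ids
    are stable across runs; assignments are mapped back per subject in window
    order.  Deterministic given the seed.
    """
    params = params or ClusterParams()
    x, _ = wfnc.pooled()
    if len(np.unique(x, axis=0)) < params.k:
        raise ValueError(f"k={params.k} exceeds the number of distinct windows")
    root = np.random.SeedSequence(params.seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for child in root.spawn(params.n_replicates):
        cent, lab, cost = kmeans_cityblock(
            x, params.k, np.random.default_rng(child), params.distance, params.max_iter
        )
        if best is None or cost < best[0]:
            best = (cost, cent, lab)
    cost, cent, lab = best
    # stable state order: decreasing occupancy, ties by first occurrence
    counts = np.bincount(lab, minlength=params.k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(params.k, dtype=int)
    remap[order] = np.arange(params.k)
    cent = cent[order]
    lab = remap[lab]
    medians = np.vstack([
        np.median(x[lab == j], axis=0) if (lab == j).any() else cent[j]
        for j in range(params.k)
    ])
    assignments: dict[str, np.ndarray] = {}
    pos = 0
    for sid in wfnc.subject_ids:
        w = wfnc.z[sid].shape[0]
        assignments[sid] = lab[pos : pos + w].copy()
        pos += w
    return ClusterStateModel(
        centroids=cent, assignments=assignments, cost=cost,
        params=params, median_states=medians,
    )


def run_lengths(seq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs of a sequence as (state, length) pairs."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return []
    change = np.nonzero(np.diff(seq) != 0)[0]
    bounds = np.concatenate([[-1], change, [len(seq) - 1]])
    return [(int(seq[bounds[i] + 1]), int(bounds[i + 1] - bounds[i])) for i in range(len(bounds) - 1)]


@dataclass
class StateMetrics:
    """Dwell/fraction/transition summaries of one assignment sequence."""

    mean_dwell: dict[int, float]  # windows; 0 for unvisited states
    fraction: dict[int, float]
    n_transitions: int
    visited: dict[int, bool]
    n_windows: int


def state_metrics(seq: np.ndarray, k: int | None = None) -> StateMetrics:
    """Mean dwell (windows), fraction time, and transition count of a sequence.

    Mean dwell is the mean length of maximal constant runs per state; NT is
    the count of adjacent unequal pairs.  Unvisited states report dwell 0 and
    fraction 0 with ``visited`` False.
    """
    seq = np.asarray(seq, dtype=int)
    if seq.size == 0:
        raise ValueError("empty assignment sequence")
    if k is None:
        k = int(seq.max()) + 1
    runs = run_lengths(seq)
    dwell: dict[int, float] = {}
    frac: dict[int, float] = {}
    visited: dict[int, bool] = {}
    for s in range(k):
        lens = [ln for st, ln in runs if st == s]
        visited[s] = bool(lens)
        dwell[s] = float(np.mean(lens)) if lens else 0.0
        frac[s] = float((seq == s).sum() / len(seq))
    nt = int((np.diff(seq) != 0).sum())
    return StateMetrics(
        mean_dwell=dwell, fraction=frac, n_transitions=nt,
        visited=visited, n_windows=len(seq),
    )


def metrics_table(model: ClusterStateModel, groups=None):
    """Tidy per-subject metric table (dwell_1..k, frac_1..k, NT)."""
    import pandas as pd

    rows = []
    for sid, seq in model.assignments.items():
        m = state_metrics(seq, model.k)
        row = {"subject_id": sid}
        if groups is not None:
            row["group"] = groups[sid] if isinstance(groups, dict) else groups.loc[sid]
        for s in range(model.k):
            row[f"dwell_{s + 1}"] = m.mean_dwell[s]
            row[f"frac_{s + 1}"] = m.fraction[s]
            row[f"visited_{s + 1}"] = m.visited[s]
        row["NT"] = m.n_transitions
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def per_state_group_compare(
    wfnc: WindowedFNC,
    model: ClusterStateModel,
    groups: dict[str, str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> dict[int, list[StatResult]]:
    """Two-sample t tests per state and connectivity pair.

    A subject's summary in a state is the mean Fisher-z over their windows
    assigned to it; subjects with no window in the state are excluded from
    that state's tests.  States visited by fewer than two subjects per group
    are skipped (empty result list).  Raw alpha by default; optional per-state
    BH-FDR.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    out: dict[int, list[StatResult]] = {}
    for s in range(model.k):
        sums_a, sums_b = [], []
        for sid, z in wfnc.z.items():
            mask = model.assignments[sid] == s
            if not mask.any():
                continue
            summary = z[mask].mean(axis=0)
            (sums_a if groups[sid] == ga else sums_b).append(summary)
        if len(sums_a) < 2 or len(sums_b) < 2:
            out[s] = []
            continue
        a = np.vstack(sums_a)
        b = np.vstack(sums_b)
        res = stats.ttest_ind(a, b, axis=0)
        praw = np.asarray(res.pvalue)
        padj = bh_fdr(praw, alpha)[0] if fdr else praw
        results = []
        for j, pair in enumerate(wfnc.pair_names):
            results.append(
                StatResult(
                    test="student-t",
                    statistic=float(np.asarray(res.statistic)[j]),
                    p_value=float(praw[j]),
                    corrected_p=float(max(padj[j], praw[j])) if fdr else None,
                    correction="BH-FDR" if fdr else None,
                    direction=int(np.sign(a[:, j].mean() - b[:, j].mean())),
                    n=(a.shape[0], b.shape[0]),
                    detail={"state": s + 1, "pair": pair},
                )
            )
        out[s] = results
    return out


def sweep_k(
    wfnc: WindowedFNC, k_values=(4, 5, 6), params: ClusterParams | None = None, groups=None
) -> dict[int, dict]:
    """Refit the state model across k values; per-k model and metric table."""
    params = params or ClusterParams()
    out: dict[int, dict] = {}
    for k in k_values:
        p = ClusterParams(
            k=k, n_replicates=params.n_replicates,
            distance=params.distance, seed=params.seed, max_iter=params.max_iter,
        )
        model = fit_cluster_states(wfnc, p)
        out[k] = {"model": model, "metrics": metrics_table(model, groups), "cost": model.cost}
    return out


def match_labels(estimated: np.ndarray, truth: np.ndarray, k: int) -> np.ndarray:
    """Permutation of estimated labels maximizing overlap with truth (Hungarian)."""
    conf = np.zeros((k, k))
    for e, t in zip(estimated, truth):
        conf[e, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    remap = np.empty(k, dtype=int)
    remap[rows] = cols
    return remap[estimated]


def label_agreement(estimated: np.ndarray, truth: np.ndarray, k: int | None = None) -> float:
    """Fraction of windows whose label matches truth after optimal relabeling."""
    estimated = np.asarray(estimated, dtype=int)
    truth = np.asarray(truth, dtype=int)
    kk = k or int(max(estimated.max(), truth.max())) + 1
    matched = match_labels(estimated, truth, kk)
    return float((matched == truth).mean())
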