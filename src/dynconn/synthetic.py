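"""Synthetic two-group cohorts with known connectivity-state dynamics.

The generator emulates the measurement problem of windowed connectivity
analyses: a hidden Markov chain switches, at TR resolution, between a small
set of planted component-correlation "states"; observations are multivariate
Gaussian draws from the active state's correlation plus slow drift, sparse
spikes and white noise.  Group structure enters through group-specific
transition models (dwell/dynamism differences) and group-specific head-motion
levels; a clinical score is linearly coupled to each subject's true dynamism
so that brain-behavior recovery can be tested against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MotionTrace, TimecourseSet, vec_upper

__all__ = [
    "BlockSpec",
    "PlantedStateSet",
    "TransitionModel",
    "ArtifactSpec",
    "ScoreCoupling",
    "CohortSpec",
    "CohortGroundTruth",
    "make_planted_states",
    "simulate_subject",
    "simulate_motion",
    "simulate_cohort",
]


@dataclass
class BlockSpec:
    """Block-structured correlation layout shared by all planted states.

    ``within[s]`` gives state ``s``'s within-block correlation (scalar, or one
    value per block); ``between[s]`` the between-block correlation (scalar).
    """

    block_sizes: Sequence[int]
    within: Sequence
    between: Sequence | float = 0.0


@dataclass
class PlantedStateSet:
    """Ground-truth correlation states of the switching process."""

    states: list[np.ndarray]
    labels: list[str]
    min_pairwise_l1: float = np.nan

    def __post_init__(self) -> None:
        for lab, m in zip(self.labels, self.states):
            m = np.asarray(m, dtype=float)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"state {lab}: matrix not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError(f"state {lab}: diagonal must be 1")
            off = m[~np.eye(m.shape[0], dtype=bool)]
            if off.size and (np.abs(off) >= 1).any():
                raise ValueError(f"state {lab}: off-diagonal entries must be in (-1, 1)")
            w = np.linalg.eigvalsh(m)
            if w.min() <= 0:
                raise ValueError(
                    f"state {lab}: not positive definite (min eigenvalue {w.min():.3g})"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_components(self) -> int:
        return self.states[0].shape[0]


@dataclass
class TransitionModel:
    """Row-stochastic Markov transition matrix plus initial distribution."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("transition probabilities must be in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = p
        if self.initial_distribution is None:
            self.initial_distribution = np.full(p.shape[0], 1.0 / p.shape[0])
        pi = np.asarray(self.initial_distribution, dtype=float)
        if pi.shape != (p.shape[0],) or not np.isclose(pi.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must be a length-S probability vector")
        self.initial_distribution = pi

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @classmethod
    def sticky(cls, n_states: int, stay: float) -> "TransitionModel":
        """Uniform off-diagonal chain with P(stay) = ``stay``."""
        if not 0 <= stay <= 1:
            raise ValueError("stay probability must be in [0, 1]")
        off = (1.0 - stay) / (n_states - 1) if n_states > 1 else 0.0
        p = np.full((n_states, n_states), off)
        np.fill_diagonal(p, stay if n_states > 1 else 1.0)
        return cls(p)


@dataclass
class ArtifactSpec:
    """Additive artifact model for one subject's time courses.

    drift_amplitude: peak amplitude (signal SD units) of the linear ramp and
    of a slow sinusoidal trend; spike_rate: per-TR, per-component probability
    of an impulse; spike_mad: impulse magnitude in multiples of the series
    MAD; noise_sd: white observation noise SD (signal SD units).
    """

    drift_amplitude: float = 0.0
    spike_rate: float = 0.0
    spike_mad: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike rate must be a probability")


def _block_matrix(block_sizes: Sequence[int], within, between: float) -> np.ndarray:
    n = int(np.sum(block_sizes))
    m = np.full((n, n), float(between))
    within = np.broadcast_to(np.asarray(within, dtype=float), (len(block_sizes),))
    start = 0
    for size, r in zip(block_sizes, within):
        m[start : start + size, start : start + size] = r
        start += size
    np.fill_diagonal(m, 1.0)
    return m


def make_planted_states(
    n_states: int,
    n_components: int,
    block_spec: BlockSpec,
    seed: int | None = None,  # noqa: ARG001 - construction is deterministic
) -> PlantedStateSet:
    """Build ``n_states`` block-structured correlation matrices.

    Each state is positive definite with unit diagonal; construction fails
    with a diagnostic naming the offending state/block when the requested
    correlation levels are incompatible with positive definiteness.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    sizes = list(block_spec.block_sizes)
    if int(np.sum(sizes)) != n_components:
        raise ValueError(f"block sizes {sizes} do not sum to n_components={n_components}")
    withins = list(block_spec.within)
    if len(withins) != n_states:
        raise ValueError("need one within-correlation entry per state")
    betweens = block_spec.between
    if np.isscalar(betweens):
        betweens = [float(betweens)] * n_states
    states, labels = [], []
    for s in range(n_states):
        w = np.broadcast_to(np.asarray(withins[s], dtype=float), (len(sizes),))
        if (np.abs(w) >= 1).any() or abs(betweens[s]) >= 1:
            raise ValueError(f"state {s}: correlation levels must be in (-1, 1)")
        # per-block PD precondition: r > -1/(b-1) within a block of size b
        for b, (size, r) in enumerate(zip(sizes, w)):
            if size > 1 and r <= -1.0 / (size - 1):
                raise ValueError(
                    f"state {s}, block {b} (size {size}): within-correlation "
                    f"{r} makes the block non-positive-definite"
                )
        m = _block_matrix(sizes, w, betweens[s])
        eig = np.linalg.eigvalsh(m)
        if eig.min() <= 0:
            raise ValueError(
                f"state {s}: within {list(w)} with between {betweens[s]} is not "
                f"positive definite (min eigenvalue {eig.min():.3g}); "
                "reduce the between-block level"
            )
        states.append(m)
        labels.append(f"S{s + 1}")
    min_l1 = np.nan
    if n_states > 1:
        dists = [
            np.abs(vec_upper(a) - vec_upper(b)).sum()
            for i, a in enumerate(states)
            for b in states[i + 1 :]
        ]
        min_l1 = float(min(dists))
    return PlantedStateSet(states=states, labels=labels, min_pairwise_l1=min_l1)


def _simulate_chain(tm: TransitionModel, n: int, rng: np.random.Generator) -> np.ndarray:
    seq = np.empty(n, dtype=int)
    seq[0] = rng.choice(tm.n_states, p=tm.initial_distribution)
    p = tm.transition_matrix
    for t in range(1, n):
        seq[t] = rng.choice(tm.n_states, p=p[seq[t - 1]])
    return seq


def simulate_subject(
    states: PlantedStateSet,
    tm: TransitionModel,
    n_timepoints: int,
    tr: float,
    artifact_spec: ArtifactSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one subject's (T x C) time courses and the true state sequence.

    The hidden state follows the Markov chain at TR resolution; the
    observation at each TR is a zero-mean multivariate normal draw with the
    active state's correlation, plus (optionally) linear drift, a slow
    sinusoidal trend, sparse MAD-scaled spikes, and white noise.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if tm.n_states != states.n_states:
        raise ValueError(
            f"transition model has {tm.n_states} states, planted set has {states.n_states}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    art = artifact_spec or ArtifactSpec()
    c = states.n_components
    seq = _simulate_chain(tm, n_timepoints, rng)
    chols = [np.linalg.cholesky(m) for m in states.states]
    z = rng.standard_normal((n_timepoints, c))
    y = np.empty_like(z)
    for s in range(states.n_states):
        idx = seq == s
        y[idx] = z[idx] @ chols[s].T
    if art.spike_rate > 0 and art.spike_mad > 0:
        mad = np.median(np.abs(y - np.median(y, axis=0)), axis=0)
        hits = rng.random((n_timepoints, c)) < art.spike_rate
        signs = rng.choice([-1.0, 1.0], size=(n_timepoints, c))
        y = y + hits * signs * art.spike_mad * mad
    if art.drift_amplitude > 0:
        t = np.arange(n_timepoints) / max(n_timepoints - 1, 1)
        slope = rng.uniform(-1, 1, c)
        phase = rng.uniform(0, 2 * np.pi, c)
        # slow trend: about 1.5 cycles across the record
        y = y + art.drift_amplitude * (
            np.outer(t, slope) + np.sin(2 * np.pi * 1.5 * t[:, None] + phase)
        )
    if art.noise_sd > 0:
        y = y + art.noise_sd * rng.standard_normal((n_timepoints, c))
    return y, seq


def simulate_motion(
    n_timepoints: int,
    mean_fd_target: float,
    rng: np.random.Generator,
    head_radius_mm: float = 50.0,
) -> MotionTrace:
    """Random-walk motion parameters calibrated to a target mean FD (mm)."""
    if mean_fd_target < 0:
        raise ValueError("mean FD target must be non-negative")
    # FD sums |increments| over 6 params; E|N(0,s)| = s*sqrt(2/pi)
    s = mean_fd_target / (6 * np.sqrt(2 / np.pi)) if mean_fd_target > 0 else 0.0
    inc = s * rng.standard_normal((n_timepoints, 6))
    inc[0] = 0.0
    params = np.cumsum(inc, axis=0)
    trans = params[:, :3]
    rot_deg = np.rad2deg(params[:, 3:] / head_radius_mm)
    return MotionTrace(translations=trans, rotations=rot_deg, head_radius_mm=head_radius_mm)


@dataclass
class ScoreCoupling:
    """Linear-Gaussian link from true dynamism to a clinical score.

    score = intercept + slope * (true number of state transitions) + N(0, sd).
    """

    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    name: str = "score"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort."""

    states: PlantedStateSet
    transition_models: dict[str, TransitionModel]
    n_per_group: dict[str, int]
    n_timepoints: int = 400
    tr: float = 0.72
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    coupling: ScoreCoupling = field(default_factory=ScoreCoupling)
    mean_fd: dict[str, float] = field(default_factory=lambda: {"EP": 0.18, "HC": 0.12})
    age_mean_sd: dict[str, tuple] = field(
        default_factory=lambda: {"EP": (22.8, 3.9), "HC": (24.8, 4.2)}
    )
    cpz_mean_sd: dict[str, tuple] = field(
        default_factory=lambda: {"EP": (165.8, 217.0), "HC": (0.0, 0.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g}: size must be >= 1")
        for g in self.n_per_group:
            if g not in self.transition_models:
                raise ValueError(f"group {g}: no transition model given")


@dataclass
class CohortGroundTruth:
    """Per-subject hidden truth for recovery tests."""

    state_sequences: dict[str, np.ndarray]
    true_nt: dict[str, int]
    true_path_length: dict[str, float]
    coupling: ScoreCoupling
    transition_models: dict[str, TransitionModel]
    seed: int


def _true_path_length(seq: np.ndarray, states: PlantedStateSet) -> float:
    vecs = [vec_upper(m) for m in states.states]
    changes = np.nonzero(np.diff(seq) != 0)[0]
    return float(
        sum(np.abs(vecs[seq[i + 1]] - vecs[seq[i]]).sum() for i in changes)
    )


def simulate_cohort(spec: CohortSpec) -> tuple[TimecourseSet, CohortGroundTruth]:
    """Simulate the full cohort: time courses, motion, metadata, ground truth.

    Deterministic given ``spec`` (including its seed).  Clinical scores are
    a linear function of each subject's true number of state transitions plus
    Gaussian noise; motion traces are drawn with group-specific mean-FD
    targets so that group FD contrasts can be planted.
    """
    root = np.random.SeedSequence(spec.seed)
    data: dict[str, np.ndarray] = {}
    motion: dict[str, MotionTrace] = {}
    rows = []
    sequences: dict[str, np.ndarray] = {}
    true_nt: dict[str, int] = {}
    true_path: dict[str, float] = {}
    groups = sorted(spec.n_per_group)
    n_total = sum(spec.n_per_group.values())
    children = root.spawn(n_total)
    k = 0
    for g in groups:
        tm = spec.transition_models[g]
        for i in range(spec.n_per_group[g]):
            rng = np.random.default_rng(children[k])
            k += 1
            sid = f"{g}{i + 1:03d}"
            y, seq = simulate_subject(
                spec.states, tm, spec.n_timepoints, spec.tr, spec.artifact, seed=rng
            )
            mt = simulate_motion(spec.n_timepoints, spec.mean_fd.get(g, 0.12), rng)
            nt = int((np.diff(seq) != 0).sum())
            score = (
                spec.coupling.intercept
                + spec.coupling.slope * nt
                + spec.coupling.noise_sd * rng.standard_normal()
            )
            age_m, age_s = spec.age_mean_sd.get(g, (25.0, 4.0))
            cpz_m, cpz_s = spec.cpz_mean_sd.get(g, (0.0, 0.0))
            cpz = max(0.0, rng.normal(cpz_m, cpz_s)) if cpz_s > 0 or cpz_m > 0 else 0.0
            data[sid] = y
            motion[sid] = mt
            sequences[sid] = seq
            true_nt[sid] = nt
            true_path[sid] = _true_path_length(seq, spec.states)
            rows.append(
                {
                    "subject_id": sid,
                    "group": g,
                    "age": float(rng.normal(age_m, age_s)),
                    spec.coupling.name: float(score),
                    "cpz_equiv": float(cpz),
                    "mean_fd": mt.mean_fd,
                    "rms_motion": mt.rms_motion,
                }
            )
    table = pd.DataFrame(rows).set_index("subject_id")
    tcs = TimecourseSet(
        data=data,
        tr=spec.tr,
        subjects=table,
        motion=motion,
        component_labels=[f"C{i + 1}" for i in range(spec.states.n_components)],
    )
    gt = CohortGroundTruth(
        state_sequences=sequences,
        true_nt=true_nt,
        true_path_length=true_path,
        coupling=spec.coupling,
        transition_models=spec.transition_models,
        seed=spec.seed,
    )
    if spec.coupling.slope != 0 and spec.coupling.noise_sd == 0:
        warnings.warn("noise-free score coupling: scores are a deterministic map of dynamism")
    return tcs, gt
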