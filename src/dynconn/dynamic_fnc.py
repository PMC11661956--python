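"""Windowed, regularized connectivity trajectories.

Each subject's conditioned time courses are cut into tapered sliding windows
(boxcar convolved with a Gaussian), a weighted covariance is computed per
window, sparsified with the graphical lasso (L1-penalized inverse
covariance), converted back to correlation and Fisher-z transformed.  The L1
penalty is chosen per subject by held-out log-likelihood over random window
splits.  Head-motion summaries can be regressed out of the windowed
connectivity series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso

from .types import MotionTrace, TimecourseSet, pair_labels, vec_upper

__all__ = [
    "WindowParams",
    "GlassoParams",
    "WindowedFNC",
    "n_windows",
    "window_starts",
    "make_taper",
    "windowed_covariance",
    "cov_to_corr",
    "glasso_regularize",
    "select_penalty",
    "window_fnc_subject",
    "window_fnc",
    "regress_motion_from_windows",
]

_Z_CLIP = 1.0 - 1e-7


@dataclass
class WindowParams:
    """Sliding-window geometry: width and step in TRs, Gaussian sigma in TRs."""

    width: int = 30
    gauss_alpha: float = 3.0
    step: int = 1

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be >= 2 TRs")
        if self.step < 1:
            raise ValueError("step must be >= 1 TR")
        if self.gauss_alpha <= 0:
            raise ValueError("gauss_alpha must be positive")


@dataclass
class GlassoParams:
    """Graphical-lasso settings: penalty grid, split repetitions, tolerance."""

    penalty_grid: tuple = tuple(np.logspace(-3, 0, 10))
    n_repetitions: int = 10
    tol: float = 1e-4
    max_iter: int = 200

    def __post_init__(self) -> None:
        if len(self.penalty_grid) == 0:
            raise ValueError("penalty grid must be non-empty")
        if any(a < 0 for a in self.penalty_grid):
            raise ValueError("penalties must be >= 0")


@dataclass
class WindowedFNC:
    """Per-subject windows x pairs Fisher-z connectivity trajectories."""

    z: dict[str, np.ndarray]  # subject -> (W x P)
    window_starts: np.ndarray  # 0-based TR start index per window
    params: WindowParams
    pair_names: list[str]
    penalty: dict[str, float] = field(default_factory=dict)
    tr: float = 0.72

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.z)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack all subjects' windows: (total windows x pairs, subject index)."""
        mats, idx = [], []
        for i, (sid, m) in enumerate(self.z.items()):
            mats.append(m)
            idx.append(np.full(m.shape[0], i))
        return np.vstack(mats), np.concatenate(idx)


def n_windows(t: int, width: int, step: int) -> int:
    """floor((T - width)/step) + 1 sliding windows."""
    if width > t:
        raise ValueError(f"window width {width} exceeds record length {t}")
    return (t - width) // step + 1


def window_starts(t: int, params: WindowParams) -> np.ndarray:
    return np.arange(n_windows(t, params.width, params.step)) * params.step


def make_taper(width: int, gauss_alpha: float, t: int | None = None) -> np.ndarray:
    """Gaussian-smoothed boxcar taper, truncated to the window and sum-1.

    A boxcar of length ``width`` is convolved with a unit-area Gaussian kernel
    of sigma ``gauss_alpha`` TRs; the central ``width`` samples are kept and
    renormalized.  As gauss_alpha -> 0 the taper tends to uniform weights.
    """
    if t is not None and width > t:
        raise ValueError(f"window width {width} exceeds record length {t}")
    box = np.ones(width)
    half = max(1, int(np.ceil(4 * gauss_alpha)))
    grid = np.arange(-half, half + 1, dtype=float)
    kern = np.exp(-0.5 * (grid / gauss_alpha) ** 2)
    kern /= kern.sum()
    full = np.convolve(box, kern, mode="full")  # length width + 2*half
    w = full[half : half + width]
    w = (w + w[::-1]) / 2.0  # enforce exact symmetry against fp drift
    return w / w.sum()


def windowed_covariance(tc: np.ndarray, weights: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Weighted covariance per window, shape (W x C x C).

    Weights sum to 1 over the window; the weighted mean is removed first.
    """
    tc = np.asarray(tc, dtype=float)
    width = len(weights)
    covs = np.empty((len(starts), tc.shape[1], tc.shape[1]))
    for wi, s in enumerate(starts):
        seg = tc[s : s + width]
        mu = weights @ seg
        d = seg - mu
        covs[wi] = (d * weights[:, None]).T @ d
    return covs


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    d[d == 0] = 1.0
    corr = cov / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def glasso_regularize(cov: np.ndarray, penalty: float, params: GlassoParams | None = None) -> np.ndarray:
    """L1-regularized correlation estimate of one window covariance.

    Penalty 0 returns the sample correlation itself (the unpenalized limit);
    otherwise the graphical lasso is solved on the correlation matrix and the
    implied covariance is renormalized to correlation.
    """
    params = params or GlassoParams()
    corr = cov_to_corr(np.asarray(cov, dtype=float))
    if penalty == 0:
        return corr
    # ill-conditioned window correlations can break the coordinate-descent
    # solver at small penalties; a tiny diagonal shrinkage stabilizes it
    for shrink in (0.0, 1e-3, 1e-2, 5e-2):
        target = corr if shrink == 0 else (1 - shrink) * corr + shrink * np.eye(len(corr))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov_est, _ = graphical_lasso(
                    target, alpha=penalty, tol=params.tol, max_iter=params.max_iter
                )
            return cov_to_corr(cov_est)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
    raise RuntimeError(
        f"graphical lasso failed at penalty {penalty}; retry with the "
        f"largest grid penalty {max(params.penalty_grid)}"
    )


def _gauss_loglik(prec: np.ndarray, emp_cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(emp_cov @ prec))


def select_penalty(
    covs: np.ndarray, params: GlassoParams, rng: np.random.Generator
) -> float:
    """Pick the grid penalty maximizing held-out Gaussian log-likelihood.

    Windows are split at random into halves ``n_repetitions`` times; for each
    split a graphical lasso is fitted to the mean train-window correlation and
    scored on the mean test-window correlation.
    """
    grid = sorted(params.penalty_grid)
    if len(grid) == 1:
        return float(grid[0])
    w = covs.shape[0]
    scores = np.zeros(len(grid))
    valid = np.zeros(len(grid), dtype=bool)
    for _ in range(params.n_repetitions):
        perm = rng.permutation(w)
        tr_idx, te_idx = perm[: w // 2], perm[w // 2 :]
        c_tr = cov_to_corr(covs[tr_idx].mean(axis=0))
        c_te = cov_to_corr(covs[te_idx].mean(axis=0))
        for gi, a in enumerate(grid):
            try:
                if a == 0:
                    prec = np.linalg.inv(c_tr)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, prec = graphical_lasso(
                            c_tr, alpha=a, tol=params.tol, max_iter=params.max_iter
                        )
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
            ll = _gauss_loglik(prec, c_te)
            if np.isfinite(ll):
                scores[gi] += ll
                valid[gi] = True
    if not valid.any():
        raise RuntimeError(
            "graphical lasso did not converge at any grid penalty; "
            f"consider the largest penalty {grid[-1]} as a fallback"
        )
    scores[~valid] = -np.inf
    return float(grid[int(np.argmax(scores))])


def window_fnc_subject(
    tc: np.ndarray,
    wparams: WindowParams,
    gparams: GlassoParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One subject's windowed Fisher-z connectivity: (W x P, penalty, starts)."""
    gparams = gparams or GlassoParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = tc.shape[0]
    starts = window_starts(t, wparams)
    taper = make_taper(wparams.width, wparams.gauss_alpha, t)
    covs = windowed_covariance(tc, taper, starts)
    penalty = select_penalty(covs, gparams, rng)
    p = tc.shape[1] * (tc.shape[1] - 1) // 2
    z = np.empty((len(starts), p))
    for wi in range(len(starts)):
        corr = glasso_regularize(covs[wi], penalty, gparams)
        z[wi] = np.arctanh(np.clip(vec_upper(corr), -_Z_CLIP, _Z_CLIP))
    return z, penalty, starts


def window_fnc(
    tcs: TimecourseSet,
    wparams: WindowParams | None = None,
    gparams: GlassoParams | None = None,
    seed: int = 0,
    regress_motion: bool = False,
) -> WindowedFNC:
    """Windowed connectivity for every subject in the set."""
    wparams = wparams or WindowParams()
    gparams = gparams or GlassoParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(tcs.n_subjects)
    z: dict[str, np.ndarray] = {}
    penalties: dict[str, float] = {}
    starts = None
    for child, sid in zip(children, tcs.subject_ids):
        zi, pen, starts = window_fnc_subject(
            tcs.data[sid], wparams, gparams, seed=np.random.default_rng(child)
        )
        z[sid] = zi
        penalties[sid] = pen
    labels = tcs.component_labels
    wfnc = WindowedFNC(
        z=z, window_starts=starts, params=wparams,
        pair_names=pair_labels(labels), penalty=penalties, tr=tcs.tr,
    )
    if regress_motion:
        wfnc = regress_motion_from_windows(wfnc, tcs.motion)
    return wfnc


def _window_motion_regressors(
    mt: MotionTrace, taper: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Taper-weighted windowed motion summaries: mean FD + mean |dparam| x6."""
    fd = mt.framewise_displacement()
    dpar = np.zeros_like(mt.params_mm())
    dpar[1:] = np.abs(np.diff(mt.params_mm(), axis=0))
    width = len(taper)
    cols = np.column_stack([fd, dpar])
    out = np.empty((len(starts), cols.shape[1]))
    for wi, s in enumerate(starts):
        out[wi] = taper @ cols[s : s + width]
    return out


def regress_motion_from_windows(
    wfnc: WindowedFNC, motion: dict[str, MotionTrace]
) -> WindowedFNC:
    """Residualize each pair's window series on windowed motion summaries.

    Ordinary least squares with an intercept; the intercept (window-mean
    level) is restored so only motion-locked fluctuation is removed.
    Constant motion regressors are dropped with a warning.
    """
    taper = make_taper(wfnc.params.width, wfnc.params.gauss_alpha)
    z_out: dict[str, np.ndarray] = {}
    for sid, z in wfnc.z.items():
        mt = motion.get(sid)
        if mt is None:
            raise ValueError(f"subject {sid}: no motion trace for regression")
        regs = _window_motion_regressors(mt, taper, wfnc.window_starts)
        sd = regs.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"subject {sid}: dropping constant motion regressors")
        regs = regs[:, keep]
        if regs.shape[1] == 0:
            z_out[sid] = z.copy()
            continue
        x = np.column_stack([np.ones(z.shape[0]), regs - regs.mean(axis=0)])
        beta, *_ = np.linalg.lstsq(x, z, rcond=None)
        fitted_motion = x[:, 1:] @ beta[1:]
        z_out[sid] = z - fitted_motion
    return WindowedFNC(
        z=z_out, window_starts=wfnc.window_starts, params=wfnc.params,
        pair_names=wfnc.pair_names, penalty=dict(wfnc.penalty), tr=wfnc.tr,
    )
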