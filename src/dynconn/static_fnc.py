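"""Static functional network connectivity and covariate-adjusted group tests.

A subject's static FNC is the Fisher-z transformed pairwise correlation
matrix of the conditioned component time courses.  Group analysis works on
the vectorized upper triangle (subjects x pairs): features are reduced by
PCA, each predictor in the design (age, diagnosis, mean FD, RMS motion)
receives a Pillai-trace multivariate F test adjusting for the others, and the
least significant predictor is removed iteratively until all survivors pass
FDR.  Univariate partial-F tests then localize which connectivity pairs drive
a retained predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import bh_fdr
from .types import StatResult, vec_upper

__all__ = [
    "compute_fnc",
    "fnc_features",
    "pillai_test",
    "SelectionResult",
    "mancova_backward_select",
    "univariate_effects",
]

_R_CLIP = 1.0 - 1e-7


def compute_fnc(tc: np.ndarray) -> np.ndarray:
    """Fisher-z FNC matrix of a conditioned (T x C) time-course matrix.

    Correlations are clipped to +/-(1 - 1e-7) before arctanh so every entry is
    finite; the diagonal is 0 by convention.  A constant component yields zero
    correlations with a warning rather than NaNs.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = tc.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"constant components at indices {np.nonzero(constant)[0].tolist()}")
        tc = tc.copy()
        # give constant columns unit noise-free variance placeholder: corr -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(tc, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def fnc_features(fnc_by_subject: dict[str, np.ndarray]) -> pd.DataFrame:
    """Stack per-subject FNC matrices into a subjects x pairs feature table."""
    rows = {sid: vec_upper(m) for sid, m in fnc_by_subject.items()}
    n = next(iter(fnc_by_subject.values())).shape[0]
    cols = [f"{i + 1}|{j + 1}" for i in range(n) for j in range(i + 1, n)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def pillai_test(y: np.ndarray, x_full: np.ndarray, cols_tested: list[int]) -> tuple[float, float, float, float, float]:
    """Pillai-trace F approximation for dropping ``cols_tested`` from ``x_full``.

    Returns (pillai, F, df1, df2, p).  ``y`` is (n x p) responses, ``x_full``
    the (n x r) design including intercept.
    """
    n, p = y.shape
    keep = [i for i in range(x_full.shape[1]) if i not in cols_tested]
    x_red = x_full[:, keep]

    def rss_mat(x: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return resid.T @ resid

    e_full = rss_mat(x_full)
    e_red = rss_mat(x_red)
    h = e_red - e_full
    q = len(cols_tested)  # hypothesis df
    v = n - np.linalg.matrix_rank(x_full)  # error df
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (v - p - 1) / 2.0
    eigvals = np.linalg.eigvals(np.linalg.solve(e_full + h, h))
    pillai = float(np.real(eigvals).sum())
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or s - pillai <= 0:
        return pillai, np.inf, df1, max(df2, 1e-9), 0.0
    f = (pillai / (s - pillai)) * (df2 / df1)
    pval = float(stats.f.sf(f, df1, df2))
    return pillai, float(f), float(df1), float(df2), pval


def _pca_reduce(features: np.ndarray, variance_kept: float) -> np.ndarray:
    """Column-standardize then project onto principal axes keeping the stated
    fraction of variance (at least one axis)."""
    x = np.asarray(features, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    u, svals, _ = np.linalg.svd(xs, full_matrices=False)
    var = svals**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, variance_kept) + 1)
    k = min(k, len(svals))
    return u[:, :k] * svals[:k]


@dataclass
class SelectionResult:
    """Backward-selection outcome: survivors plus the per-step trace."""

    retained: list[str]
    steps: list[dict] = field(default_factory=list)
    final_pvalues: dict[str, float] = field(default_factory=dict)
    n_dims: int = 0


def mancova_backward_select(
    features: pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    alpha: float = 0.05,
    variance_kept: float = 0.95,
) -> SelectionResult:
    """Backward step-wise multivariate predictor selection.

    Features are PCA-reduced (``variance_kept`` of variance); each candidate
    predictor gets a Pillai-trace F test adjusting for the others; the least
    significant predictor is dropped until every survivor passes BH-FDR at
    ``alpha``.  Deterministic given inputs.
    """
    x_df = design.copy()
    const = [c for c in x_df.columns if np.asarray(x_df[c]).std() == 0]
    if const:
        warnings.warn(f"dropping constant predictors: {const}")
        x_df = x_df.drop(columns=const)
    names = list(x_df.columns)
    xmat = np.column_stack([np.ones(len(x_df))] + [np.asarray(x_df[c], float) for c in names])
    if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
        raise ValueError("rank-deficient design matrix")
    feats = features.values if isinstance(features, pd.DataFrame) else np.asarray(features)
    y = _pca_reduce(feats, variance_kept)
    if y.shape[0] <= xmat.shape[1] + y.shape[1]:
        raise ValueError(
            f"too few subjects ({y.shape[0]}) for {xmat.shape[1] - 1} predictors "
            f"and {y.shape[1]} reduced dimensions"
        )
    steps: list[dict] = []
    current = list(names)
    while current:
        cols = {name: 1 + current.index(name) for name in current}
        x_cur = np.column_stack(
            [np.ones(len(x_df))] + [np.asarray(x_df[c], float) for c in current]
        )
        pvals = {}
        for name in current:
            *_, p = pillai_test(y, x_cur, [cols[name]])
            pvals[name] = p
        adj = bh_fdr(np.array([pvals[c] for c in current]))[0]
        adj_map = dict(zip(current, adj))
        steps.append({"predictors": list(current), "p": dict(pvals), "p_fdr": dict(adj_map)})
        failing = [c for c in current if adj_map[c] > alpha]
        if not failing:
            break
        worst = max(failing, key=lambda c: pvals[c])
        current.remove(worst)
    final_p = steps[-1]["p"] if current else {}
    return SelectionResult(
        retained=current, steps=steps, final_pvalues=dict(final_p), n_dims=y.shape[1]
    )


def univariate_effects(
    features: pd.DataFrame,
    design: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Per-feature partial-F test of ``target`` given the other predictors.

    Effect direction is the sign of the target's coefficient in the full
    model; p-values are BH-FDR adjusted across features.
    """
    if target not in design.columns:
        raise ValueError(f"target {target!r} not among predictors {list(design.columns)}")
    names = list(design.columns)
    x_full = np.column_stack([np.ones(len(design))] + [np.asarray(design[c], float) for c in names])
    tcol = 1 + names.index(target)
    x_red = np.delete(x_full, tcol, axis=1)
    y = features.values.astype(float)
    n = y.shape[0]
    df_full = n - x_full.shape[1]
    beta_full, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_full = ((y - x_full @ beta_full) ** 2).sum(axis=0)
    beta_red, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    rss_red = ((y - x_red @ beta_red) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / df_full)
    f = np.where(rss_full <= 0, np.inf, f)
    praw = stats.f.sf(f, 1, df_full)
    padj, _ = bh_fdr(praw, alpha)
    out = []
    for i, col in enumerate(features.columns):
        out.append(
            StatResult(
                test="partial-F",
                statistic=float(f[i]),
                p_value=float(praw[i]),
                df=(1, df_full),
                corrected_p=float(min(1.0, max(padj[i], praw[i]))),
                correction="BH-FDR",
                direction=int(np.sign(beta_full[tcol, i])),
                n=n,
                detail={"feature": col, "target": target},
            )
        )
    return out
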