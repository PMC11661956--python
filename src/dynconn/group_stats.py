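"""Group-difference and brain-behavior statistics.

Implements the automatic test-selection rule (Shapiro-Wilk normality gate,
then a variance-homogeneity gate), summary-statistic t tests, Box-Cox
transformation gated on non-normality, partial correlations with nuisance
regression, and two multiplicity corrections: Benjamini-Hochberg FDR and the
Dubey/Armitage-Parmar (DAP) effective-number-of-tests Bonferroni, which
shrinks the Bonferroni exponent toward 1 as the endpoints become correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import StatResult

__all__ = [
    "choose_and_run_test",
    "summary_stat_tests",
    "TransformResult",
    "boxcox_if_nonnormal",
    "partial_correlation",
    "dap_bonferroni",
    "bh_fdr",
    "bonferroni_fwe",
]


def _as_clean_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValueError("non-finite values in sample")
    return a


def choose_and_run_test(x=None, y=None, *, table=None, alpha_gate: float = 0.05) -> StatResult:
    """Two-group test with automatic selection, mirroring common practice.

    Continuous data: Shapiro-Wilk in each group; if either p < ``alpha_gate``
    use Mann-Whitney U, otherwise Levene's test decides between Student and
    Welch t.  Categorical data (pass a contingency ``table``): Pearson chi2
    without continuity correction.  The gating p-values are recorded in
    ``detail``.
    """
    if table is not None:
        tbl = np.asarray(table, dtype=float)
        chi2, p, dof, _ = stats.chi2_contingency(tbl, correction=False)
        return StatResult(
            test="chi2", statistic=float(chi2), p_value=float(p), df=int(dof),
            n=int(tbl.sum()), detail={"table": tbl.tolist()},
        )
    xa, ya = _as_clean_array(x), _as_clean_array(y)
    if len(xa) < 3 or len(ya) < 3:
        raise ValueError("need n >= 3 per group for continuous tests")
    if xa.std() == 0 and ya.std() == 0:
        raise ValueError("both groups constant; no test is meaningful")
    sw_x = stats.shapiro(xa).pvalue if xa.std() > 0 else 0.0
    sw_y = stats.shapiro(ya).pvalue if ya.std() > 0 else 0.0
    detail = {"shapiro_p": (float(sw_x), float(sw_y))}
    direction = int(np.sign(np.mean(xa) - np.mean(ya)))
    if min(sw_x, sw_y) < alpha_gate:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided")
        return StatResult(
            test="mannwhitney", statistic=float(res.statistic), p_value=float(res.pvalue),
            n=(len(xa), len(ya)), direction=direction, detail=detail,
        )
    lev = stats.levene(xa, ya)
    detail["levene_p"] = float(lev.pvalue)
    equal_var = lev.pvalue >= alpha_gate
    res = stats.ttest_ind(xa, ya, equal_var=equal_var)
    return StatResult(
        test="student-t" if equal_var else "welch-t",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        df=float(res.df), n=(len(xa), len(ya)), direction=direction, detail=detail,
    )


def summary_stat_tests(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    flavor: str = "student",
) -> StatResult:
    """Two-sample t test from printed group summaries (mean, SD, n)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if flavor not in ("student", "welch"):
        raise ValueError("flavor must be 'student' or 'welch'")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(flavor == "student")
    )
    if flavor == "student":
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    return StatResult(
        test=f"{flavor}-t", statistic=float(res.statistic), p_value=float(res.pvalue),
        df=df, n=(n1, n2), direction=int(np.sign(mean1 - mean2)),
    )


@dataclass
class TransformResult:
    """Outcome of the normality-gated Box-Cox transform."""

    values: np.ndarray
    lmbda: float | None  # None when the identity was applied
    shift: float
    shapiro_before: float
    shapiro_after: float


def boxcox_if_nonnormal(x, alpha_gate: float = 0.05) -> TransformResult:
    """Box-Cox transform applied only when Shapiro-Wilk rejects normality.

    Values are shifted to positivity with the (1 - min) convention when any
    value <= 0; lambda is chosen by profile maximum likelihood.
    """
    xa = _as_clean_array(x)
    if len(xa) < 8:
        raise ValueError("need n >= 8")
    if xa.std() == 0:
        raise ValueError("zero-variance sample")
    sw_before = float(stats.shapiro(xa).pvalue)
    if sw_before >= alpha_gate:
        return TransformResult(xa.copy(), None, 0.0, sw_before, sw_before)
    shift = float(1.0 - xa.min()) if xa.min() <= 0 else 0.0
    y, lmbda = stats.boxcox(xa + shift)
    sw_after = float(stats.shapiro(y).pvalue)
    return TransformResult(np.asarray(y), float(lmbda), shift, sw_before, sw_after)


def _residualize(v: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(v)), nuisance])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_correlation(x, y, nuisance, flavor: str = "pearson") -> StatResult:
    """Correlation of x and y after regressing out nuisance columns.

    For the spearman flavor, x, y and nuisance are rank-transformed first.
    The p-value uses a t distribution with n - k - 2 degrees of freedom
    (k nuisance columns).
    """
    xa, ya = _as_clean_array(x), _as_clean_array(y)
    z = np.asarray(nuisance, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, k = len(xa), z.shape[1]
    if n != len(ya) or n != z.shape[0]:
        raise ValueError("length mismatch")
    if n <= k + 2:
        raise ValueError("need n > #nuisance + 2")
    if flavor == "spearman":
        xa = stats.rankdata(xa)
        ya = stats.rankdata(ya)
        z = np.column_stack([stats.rankdata(z[:, j]) for j in range(k)])
    elif flavor != "pearson":
        raise ValueError("flavor must be 'pearson' or 'spearman'")
    rx = _residualize(xa, z)
    ry = _residualize(ya, z)
    df = n - k - 2
    if rx.std() < 1e-12 * max(np.abs(xa).max(), 1.0) or ry.std() < 1e-12 * max(np.abs(ya).max(), 1.0):
        warnings.warn("variable collinear with nuisance to machine precision")
        return StatResult(
            test=f"partial-{flavor}", statistic=0.0, p_value=1.0, df=df,
            direction=0, n=n, detail={"collinear": True, "k_nuisance": k},
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return StatResult(
        test=f"partial-{flavor}", statistic=r, p_value=p, df=df,
        direction=int(np.sign(r)), n=n, detail={"t": float(t), "k_nuisance": k},
    )


def dap_bonferroni(pvals, endpoint_corr: np.ndarray) -> np.ndarray:
    """Dubey/Armitage-Parmar correction for correlated endpoints.

    For endpoint j with mean absolute correlation r_j to the other endpoints
    (clamped to [0, 1]), the effective number of tests is m**(1 - r_j) and the
    corrected p is the Sidak form 1 - (1 - p)**m_eff, capped at 1.  With one
    endpoint the correction is the identity.
    """
    p = np.asarray(pvals, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 1:
        return p.copy()
    c = np.asarray(endpoint_corr, dtype=float)
    if c.shape != (m, m):
        raise ValueError(f"endpoint correlation matrix must be {m}x{m}")
    out = np.empty(m)
    for j in range(m):
        others = np.abs(np.delete(c[j], j))
        rbar = float(np.clip(others.mean(), 0.0, 1.0))
        m_eff = m ** (1.0 - rbar)
        out[j] = min(1.0, 1.0 - (1.0 - p[j]) ** m_eff)
    return out


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask at ``q``)."""
    p = np.asarray(pvals, dtype=float)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def bonferroni_fwe(pvals) -> np.ndarray:
    """Plain Bonferroni: corrected = min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, len(p) * p)
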