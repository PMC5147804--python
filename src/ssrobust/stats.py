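"""Statistical machinery for the comparative analyses.

Covers the group-with-covariate linear model (ANCOVA with RSA as the
covariate), two-proportion tests with an exact small-count fallback,
Holm-Bonferroni and Benjamini-Hochberg multiple-testing corrections, the
contact-regression residue subsetting used to dissect the helix-strand
robustness gap, and a logistic-regression predictor-importance comparison
(RSA versus contact density).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AncovaResult",
    "ProportionTestResult",
    "SingularDesignError",
    "ancova",
    "prop_test",
    "holm_bonferroni",
    "benjamini_hochberg",
    "subset_by_contact_regression",
    "predictor_importance",
    "wilson_ci",
]


class SingularDesignError(ValueError):
    """The model design matrix is rank deficient."""


@dataclass
class AncovaResult:
    group_levels: list
    group_coefficients: dict          # offset of each level vs the first
    covariate_slope: float
    adjusted_group_means: dict        # group means at the grand covariate mean
    f_statistic: float
    p_value: float
    df_group: int
    df_resid: int

    def __post_init__(self):
        if self.df_resid <= 0:
            raise ValueError("residual df must be positive")


@dataclass
class ProportionTestResult:
    p1: float
    p2: float
    z: Optional[float]       # None for the exact branch
    p_value: float
    ci_low: float            # 95% CI of p1 - p2
    ci_high: float
    method: str              # 'z' or 'exact'


def ancova(y: Sequence[float], groups: Sequence, covariate: Sequence[float],
           interaction: bool = False) -> AncovaResult:
    """Least-squares fit of y ~ group + covariate; F-test of the group factor.

    The default model assumes a common covariate slope across groups
    (``interaction=False``); the F statistic compares the full model
    against the covariate-only reduction.  Adjusted group means are
    evaluated at the grand mean of the covariate.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("ancova needs at least 2 groups")
    n = len(y)

    dummies = np.column_stack([(groups == lv).astype(float) for lv in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, cov])
    if interaction:
        X_full = np.column_stack(
            [X_full] + [dummies[:, k] * cov for k in range(dummies.shape[1])])
    X_red = np.column_stack([np.ones(n), cov])

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    if n <= X_full.shape[1]:
        raise ValueError("more parameters than observations")

    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()

    df_group = X_full.shape[1] - X_red.shape[1]
    df_resid = int(full.df_resid)
    rss_f, rss_r = full.ssr, red.ssr
    if rss_f <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((rss_r - rss_f) / df_group) / (rss_f / df_resid)
        p = float(scipy.stats.f.sf(f_stat, df_group, df_resid))

    coefs = dict(zip(levels[1:], full.params[1:len(levels)]))
    slope = float(full.params[len(levels)])
    cbar = float(cov.mean())
    adj = {levels[0]: float(full.params[0] + slope * cbar)}
    for lv in levels[1:]:
        adj[lv] = adj[levels[0]] + float(coefs[lv])

    return AncovaResult(levels, {k: float(v) for k, v in coefs.items()},
                        slope, adj, float(f_stat), p, df_group, df_resid)


def prop_test(k1: int, n1: int, k2: int, n2: int,
              alpha: float = 0.05) -> ProportionTestResult:
    """Two-sided comparison of two binomial proportions.

    Uses the pooled z-test; when any expected cell count under the pooled
    proportion is below 5 the test switches to Fisher's exact test (the
    conditional enumeration).  The CI on p1 - p2 is the Wald interval.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n and n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pp = (k1 + k2) / (n1 + n2)
    expected = [pp * n1, (1 - pp) * n1, pp * n2, (1 - pp) * n2]

    zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
    se_unpooled = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    ci_low = p1 - p2 - zcrit * se_unpooled
    ci_high = p1 - p2 + zcrit * se_unpooled

    if min(expected) < 5:
        _, p = scipy.stats.fisher_exact(
            [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
        return ProportionTestResult(p1, p2, None, float(p), ci_low, ci_high, "exact")

    se = np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    if se == 0:
        return ProportionTestResult(p1, p2, 0.0, 1.0, ci_low, ci_high, "z")
    z = (p1 - p2) / se
    p = 2 * scipy.stats.norm.sf(abs(z))
    return ProportionTestResult(p1, p2, float(z), float(p), ci_low, ci_high, "z")


def holm_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm rejection flags, in the original order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return adj


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def subset_by_contact_regression(residues: pd.DataFrame) -> pd.DataFrame:
    """Select the residues that undercut the class contact advantage.

    Fits per-class least-squares lines n_contacts ~ rsa for helix and
    strand residues, then keeps helix residues strictly below their class
    line and strand residues strictly above theirs.  Residues exactly on a
    line are excluded.  Input needs columns ss3, rsa, n_contacts; the
    returned frame is the selected subset.
    """
    for col in ("ss3", "rsa", "n_contacts"):
        if col not in residues.columns:
            raise ValueError(f"missing column {col!r}")
    keep_idx = []
    for cls, side in (("H", "below"), ("E", "above")):
        sub = residues[residues["ss3"] == cls]
        if len(sub) < 2 or sub["rsa"].nunique() < 2:
            raise ValueError(f"degenerate fit for class {cls}: "
                             "need >= 2 distinct RSA values")
        slope, intercept = np.polyfit(sub["rsa"], sub["n_contacts"], 1)
        fitted = intercept + slope * sub["rsa"]
        resid = sub["n_contacts"] - fitted
        # points numerically on the line count as "on", not above/below
        tol = 1e-9 * max(1.0, float(np.abs(sub["n_contacts"]).max()))
        mask = resid < -tol if side == "below" else resid > tol
        keep_idx.extend(sub.index[mask])
    return residues.loc[sorted(keep_idx)]


def predictor_importance(change: Sequence[int], rsa: Sequence[float],
                         contact_density: Sequence[float],
                         ) -> tuple[Optional[float], Optional[float]]:
    """Relative importance of RSA vs contact density for residue change.

    Fits a logistic regression change ~ rsa + contact_density (IRLS via
    statsmodels) and reports |Wald z| of each predictor rescaled so the
    larger equals 100.  Returns (None, None) when the fit is separated or
    does not converge.
    """
    y = np.asarray(change, dtype=float)
    X = sm.add_constant(np.column_stack([
        np.asarray(rsa, dtype=float),
        np.asarray(contact_density, dtype=float)]))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None, None
    if not fit.mle_retvals.get("converged", False):
        return None, None
    z = np.abs(fit.params[1:] / fit.bse[1:])
    if not np.all(np.isfinite(z)) or z.max() == 0:
        return None, None
    scaled = 100.0 * z / z.max()
    return float(scaled[0]), float(scaled[1])
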