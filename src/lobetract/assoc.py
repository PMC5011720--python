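"""Phenotypic association stage: collinearity screening, stepwise regression,
Bonferroni control, and a bootstrap-tested path model.

The structure-function association between lobar tract integrities and
attention scores is assessed twice: a manifest-variable path model in which
the attention score is regressed on all segment predictors at once, with
standardized path coefficients tested by nonparametric case-resampling
bootstrap (t = beta / bootstrap SE, two-tailed p from the t reference); and
a stepwise multiple regression (forward selection with backward removal)
with Durbin-Watson residual diagnostics.  Variance inflation factors screen
for multicollinearity before either model is interpreted, and the multiple
attention components are handled with a Bonferroni-corrected alpha.

Subjects are treated as independent observations even when they come in twin
pairs, matching the classical analysis this stage reproduces;
``bootstrap_paths`` accepts a ``cluster`` argument for pair-resampling when
twin non-independence should be respected instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "vif_screen",
    "bonferroni_alpha",
    "stepwise_regress",
    "StepwiseResult",
    "bootstrap_paths",
    "PathModelResult",
]


def vif_screen(X: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per predictor, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j on all the others.  A perfectly
    collinear predictor is reported with infinite VIF and flagged.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 predictors")
    rows = []
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]))
        r2 = sm.OLS(X[col], others).fit().rsquared
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": col, "vif": float(vif),
                     "flagged": bool(vif > threshold)})
    return pd.DataFrame(rows).set_index("predictor")


def bonferroni_alpha(base: float = 0.05, repetitions: int = 1) -> float:
    """Bonferroni-corrected alpha: base significance level / repetitions."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if not 0 < base <= 1:
        raise ValueError("base alpha must be in (0, 1]")
    return base / repetitions


@dataclass
class StepwiseResult:
    """Final stepwise model plus its selection history and diagnostics."""

    selected: list
    results: object | None  # statsmodels RegressionResults, None if empty
    history: list
    durbin_watson: float
    note: str

    def summary(self) -> str:
        if self.results is None:
            return f"stepwise regression: null model ({self.note})"
        return str(self.results.summary())


def stepwise_regress(X: pd.DataFrame, y: pd.Series | np.ndarray,
                     p_enter: float = 0.05, p_remove: float = 0.10
                     ) -> StepwiseResult:
    """Forward selection with backward removal on OLS p-values.

    At each step the candidate with the smallest entry p-value joins the
    model if p < ``p_enter``; after each entry any included predictor whose
    p-value has risen above ``p_remove`` is dropped.  Returns the final OLS
    fit (95% CIs available from it) and the Durbin-Watson statistic of its
    residuals.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(X) < X.shape[1] + 2:
        raise ValueError("need at least 2 more subjects than predictors")
    if p_remove < p_enter:
        raise ValueError("p_remove should be >= p_enter to avoid cycling")
    included: list = []
    history: list = []
    candidates = list(X.columns)
    for _ in range(4 * len(candidates) + 4):
        # forward step
        best_p, best_c = np.inf, None
        for c in candidates:
            if c in included:
                continue
            exog = sm.add_constant(X[included + [c]])
            p = sm.OLS(y, exog).fit().pvalues[c]
            if p < best_p:
                best_p, best_c = p, c
        entered = False
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            history.append(("enter", best_c, float(best_p)))
            entered = True
        # backward sweep
        removed = True
        while removed and included:
            fit = sm.OLS(y, sm.add_constant(X[included])).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                history.append(("remove", worst, float(pvals[worst])))
            else:
                removed = False
        if not entered:
            break
    if included:
        results = sm.OLS(y, sm.add_constant(X[included])).fit()
        resid = results.resid
        note = ""
    else:
        results = None
        resid = y - y.mean()
        note = "no predictor passed the entry threshold"
    return StepwiseResult(selected=list(included), results=results,
                          history=history,
                          durbin_watson=float(durbin_watson(resid)),
                          note=note)


@dataclass
class PathModelResult:
    """Standardized path coefficients with bootstrap significance."""

    table: pd.DataFrame  # index predictor; beta, se_boot, t, p
    r_squared: float
    n_obs: int
    n_boot: int
    n_redrawn: int
    seed: int | None

    def summary(self) -> str:
        lines = [f"path model: n = {self.n_obs}, R^2 = {self.r_squared:.3f}, "
                 f"{self.n_boot} bootstrap draws"]
        for name, row in self.table.iterrows():
            lines.append(f"  {name}: beta = {row['beta']:+.3f}  "
                         f"t = {row['t']:+.2f}  p = {row['p']:.4f}")
        return "\n".join(lines)


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def bootstrap_paths(X: pd.DataFrame, y: pd.Series | np.ndarray,
                    n_boot: int = 5000, seed: int | None = None,
                    cluster: np.ndarray | None = None) -> PathModelResult:
    """Manifest-variable path model with bootstrap-tested coefficients.

    The outcome is regressed on all predictors simultaneously after
    z-scoring, so the coefficients are standardized paths.  Subjects are
    resampled with replacement ``n_boot`` times; the bootstrap SD of each
    coefficient gives t = beta / SE and a two-tailed p from the t(n - k - 1)
    reference.  A degenerate resample (constant outcome or predictor) is
    redrawn and counted.  ``cluster`` (e.g. twin-pair ids) switches to
    cluster resampling so pair non-independence is respected; the default
    resamples subjects independently, matching the classical analysis.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, k = Xa.shape
    if len(ya) != n:
        raise ValueError("X and y lengths differ")
    if np.any(Xa.std(axis=0) == 0) or ya.std() == 0:
        raise ValueError("constant predictor or outcome")
    Xz, yz = _zscore(Xa), _zscore(ya)
    beta = np.linalg.lstsq(Xz, yz, rcond=None)[0]
    resid = yz - Xz @ beta
    r2 = 1.0 - resid @ resid / (yz @ yz)

    cluster_members = None
    if cluster is not None:
        cluster = np.asarray(cluster)
        if len(cluster) != n:
            raise ValueError("cluster labels must align with subjects")
        cluster_members = [np.flatnonzero(cluster == c)
                           for c in pd.unique(cluster)]

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, k))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        if cluster_members is None:
            idx = rng.integers(0, n, size=n)
        else:
            picks = rng.integers(0, len(cluster_members),
                                 size=len(cluster_members))
            idx = np.concatenate([cluster_members[j] for j in picks])
        xb, yb = Xa[idx], ya[idx]
        if yb.std() == 0 or np.any(xb.std(axis=0) == 0):
            n_redrawn += 1
            if n_redrawn > 100 * n_boot:
                raise RuntimeError("bootstrap kept drawing degenerate resamples")
            continue
        boot[b] = np.linalg.lstsq(_zscore(xb), _zscore(yb), rcond=None)[0]
        b += 1
    se = boot.std(axis=0, ddof=1)
    tvals = beta / se
    dof = max(n - k - 1, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    table = pd.DataFrame({"beta": beta, "se_boot": se, "t": tvals, "p": pvals},
                         index=list(X.columns))
    return PathModelResult(table=table, r_squared=float(r2), n_obs=n,
                           n_boot=n_boot, n_redrawn=n_redrawn, seed=seed)
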