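"""Twin variance-component (ACE) models fitted by maximum likelihood.

The classical twin design decomposes the variance of a standardized trait
into additive genetic (A), shared/common environment (C) and unique
environment (E) sources by exploiting the different genetic resemblance of
monozygotic (MZ, genetic correlation 1.0) and dizygotic (DZ, 0.5) pairs.
For a pair with phenotypes (y1, y2) the model-implied covariance is

    Var(y)       = a^2 + c^2 + e^2
    Cov(y1, y2)  = a^2 + c^2        (MZ)
                 = 0.5 a^2 + c^2    (DZ)

with a, c, e path coefficients.  :class:`UnivariateACE` maximizes the exact
per-pair bivariate-normal log-likelihood; the reduced AE / CE / E models fix
paths at zero, and nested models are compared by chi-square likelihood-ratio
tests and AIC.  Component confidence intervals are profile-likelihood
intervals on the variance shares, clipped to [0, 1].

:class:`BivariateACE` extends this to two traits via a Cholesky-equivalent
parameterisation of each component's 2x2 cross-trait covariance block
(sigma1, sigma2, r), so the component-specific cross-trait correlations
(r_g, r_c, r_e) are direct parameters and their profile CIs are ordinary
fixed-parameter profiles.  The phenotypic cross-trait correlation r_ph
decomposes exactly as

    r_ph = r_g sqrt(a1^2 a2^2) + r_c sqrt(c1^2 c2^2) + r_e sqrt(e1^2 e2^2)
         = r_ph-a + r_ph-c + r_ph-e,

the genetic / shared / unique-environmental contributions to the phenotypic
correlation (:func:`decompose_rph`).

Likelihood evaluations use per-zygosity sufficient statistics (sample mean
and scatter), so fitting cost is independent of the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

__all__ = [
    "UnivariateACE",
    "UnivariateACEResults",
    "BivariateACE",
    "BivariateACEResults",
    "ModelComparison",
    "compare_models",
    "lrt",
    "decompose_rph",
    "RphDecomposition",
    "falconer_h2",
    "residualize_traits",
    "MODEL_COMPONENTS",
]

MODEL_COMPONENTS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"),
                    "CE": ("C", "E"), "E": ("E",)}

_LOG2PI = np.log(2.0 * np.pi)


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Falconer's moment estimator of heritability, 2 (r_MZ - r_DZ)."""
    return 2.0 * (r_mz - r_dz)


def residualize_traits(data: pd.DataFrame, traits, covariates) -> pd.DataFrame:
    """Regress covariates out of twin trait columns before model fitting.

    Off by default in the model classes (the classical analysis fits raw
    standardized traits); call this first when age/sex adjustment is wanted.
    Covariate columns may be pair-level (``cov``) or twin-specific
    (``cov_twin1`` / ``cov_twin2``).  Both twins' values enter one pooled
    OLS per trait so the same adjustment applies to each twin column.
    """
    out = data.copy()
    for trait in ([traits] if isinstance(traits, str) else traits):
        cols = [f"{trait}_twin1", f"{trait}_twin2"]
        y = np.concatenate([data[c].to_numpy(float) for c in cols])
        X = [np.ones_like(y)]
        for cov in covariates:
            if cov in data.columns:
                v = data[cov].to_numpy(float)
                X.append(np.concatenate([v, v]))
            else:
                X.append(np.concatenate(
                    [data[f"{cov}_twin1"].to_numpy(float),
                     data[f"{cov}_twin2"].to_numpy(float)]))
        X = np.column_stack(X)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        n = len(data)
        out[cols[0]] = resid[:n]
        out[cols[1]] = resid[n:]
    return out


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

class _GroupStats:
    """Mean/scatter sufficient statistics of one zygosity group (n x d data)."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("group data must be 2D")
        self.n, self.d = X.shape
        self.mean = X.mean(axis=0) if self.n else np.zeros(X.shape[1])
        xc = X - self.mean
        self.scatter = xc.T @ xc / max(self.n, 1)

    def negloglik(self, sigma: np.ndarray, mu: np.ndarray) -> float:
        if self.n == 0:
            return 0.0
        try:
            cf = sla.cho_factor(sigma, lower=True, check_finite=False)
        except (sla.LinAlgError, ValueError):
            return 1e12  # finite penalty keeps quasi-Newton gradients usable
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        diff = self.mean - mu
        quad = float(diff @ sla.cho_solve(cf, diff, check_finite=False))
        tr = float(np.trace(sla.cho_solve(cf, self.scatter, check_finite=False)))
        return 0.5 * self.n * (self.d * _LOG2PI + logdet + tr + quad)


def _extract_pairs(data: pd.DataFrame, trait: str,
                   zygosity_col: str) -> tuple[np.ndarray, np.ndarray]:
    for col in (f"{trait}_twin1", f"{trait}_twin2", zygosity_col):
        if col not in data.columns:
            raise ValueError(f"twin pair table is missing column '{col}'")
    vals = data[[f"{trait}_twin1", f"{trait}_twin2"]].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("twin pair table contains missing/non-finite values")
    zyg = data[zygosity_col].astype(str).to_numpy()
    bad = set(zyg) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
    return vals[zyg == "MZ"], vals[zyg == "DZ"]


# ---------------------------------------------------------------------------
# univariate model
# ---------------------------------------------------------------------------

class UnivariateACE:
    """Univariate ACE-family twin model for one trait.

    Parameters
    ----------
    data : DataFrame with columns ``zygosity`` (MZ/DZ) and
        ``{trait}_twin1`` / ``{trait}_twin2``.
    trait : trait column prefix (default ``trait1``).
    model : one of ``ACE, AE, CE, E``.
    standardize : z-score the trait over all twins before fitting (default).
    estimate_mean : estimate a common mean jointly with the (co)variances;
        with ``False`` the mean is fixed at zero.
    """

    def __init__(self, data: pd.DataFrame, trait: str = "trait1",
                 model: str = "ACE", zygosity_col: str = "zygosity",
                 standardize: bool = True, estimate_mean: bool = True):
        if model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model '{model}'")
        self.model = model
        self.trait = trait
        self.estimate_mean = estimate_mean
        self.standardize = standardize
        mz, dz = _extract_pairs(data, trait, zygosity_col)
        if len(mz) < 2 or len(dz) < 2:
            raise ValueError("need at least 2 MZ and 2 DZ pairs")
        if standardize:
            pooled = np.concatenate([mz.ravel(), dz.ravel()])
            loc, scale = pooled.mean(), pooled.std(ddof=1)
            if scale == 0:
                raise ValueError("trait has zero variance")
            mz = (mz - loc) / scale
            dz = (dz - loc) / scale
        self._mz = _GroupStats(mz)
        self._dz = _GroupStats(dz)

    # -- likelihood ---------------------------------------------------------

    @property
    def free_components(self) -> tuple[str, ...]:
        return MODEL_COMPONENTS[self.model]

    def _negloglik_paths(self, a: float, c: float, e: float,
                         mu: float) -> float:
        v = a * a + c * c + e * e
        mvec = np.array([mu, mu])
        s_mz = np.array([[v, a * a + c * c], [a * a + c * c, v]])
        s_dz = np.array([[v, 0.5 * a * a + c * c], [0.5 * a * a + c * c, v]])
        return self._mz.negloglik(s_mz, mvec) + self._dz.negloglik(s_dz, mvec)

    def _unpack(self, theta: np.ndarray) -> tuple[float, float, float, float]:
        comps = self.free_components
        vals = {"A": 0.0, "C": 0.0, "E": 0.0}
        for i, comp in enumerate(comps):
            vals[comp] = theta[i]
        mu = theta[len(comps)] if self.estimate_mean else 0.0
        return vals["A"], vals["C"], vals["E"], mu

    def negloglik(self, theta: np.ndarray) -> float:
        return self._negloglik_paths(*self._unpack(theta))

    # -- fitting ------------------------------------------------------------

    def _starts(self, n_starts: int, seed: int) -> list[np.ndarray]:
        comps = self.free_components
        base = {"A": 0.55, "C": 0.35, "E": 0.65}
        anchors = [
            [base[c] for c in comps],
            [(0.9 if c == "A" else 0.3) for c in comps],
            [(0.9 if c == "C" else 0.3) for c in comps],
            [(0.9 if c == "E" else 0.2) for c in comps],
        ]
        rng = np.random.default_rng(seed)
        starts = [np.array(a, dtype=float) for a in anchors]
        while len(starts) < max(n_starts, len(starts)):
            starts.append(rng.uniform(0.05, 0.95, size=len(comps)))
        starts = starts[:max(n_starts, 4)]
        if self.estimate_mean:
            m0 = 0.5 * (self._mz.mean.mean() * self._mz.n
                        + self._dz.mean.mean() * self._dz.n) \
                / (self._mz.n + self._dz.n) * 2
            starts = [np.append(s, m0) for s in starts]
        return starts

    def _bounds(self) -> list[tuple[float, float]]:
        bounds = []
        for comp in self.free_components:
            lo = 1e-4 if comp == "E" else 0.0
            bounds.append((lo, 10.0))
        if self.estimate_mean:
            bounds.append((-1e3, 1e3))
        return bounds

    def fit(self, n_starts: int = 5, seed: int = 0) -> "UnivariateACEResults":
        best = None
        for x0 in self._starts(n_starts, seed):
            res = optimize.minimize(self.negloglik, x0, method="L-BFGS-B",
                                    bounds=self._bounds(),
                                    options={"ftol": 1e-12, "gtol": 1e-10,
                                             "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"ACE optimization failed: {best}")
        a, c, e, mu = self._unpack(best.x)
        k = len(self.free_components) + (1 if self.estimate_mean else 0)
        return UnivariateACEResults(model_obj=self, model=self.model,
                                    paths={"A": abs(a), "C": abs(c), "E": abs(e)},
                                    mean=mu, loglik=-float(best.fun), k_params=k,
                                    n_mz=self._mz.n, n_dz=self._dz.n,
                                    converged=bool(best.success))

    # -- profile likelihood over a variance share ---------------------------

    def _profile_negloglik(self, comp: str, share: float) -> float:
        """Max log-likelihood with comp's variance share fixed at ``share``."""
        comps = self.free_components
        if comp not in comps:
            raise ValueError(f"component {comp} is not free in model {self.model}")
        others = [c for c in comps if c != comp]
        share = min(max(share, 0.0), 1.0)

        def build(sigma_tot, t):
            vals = {"A": 0.0, "C": 0.0, "E": 0.0}
            vals[comp] = np.sqrt(share) * sigma_tot
            rest = 1.0 - share
            if len(others) == 1:
                vals[others[0]] = np.sqrt(rest) * sigma_tot
            elif len(others) == 2:
                vals[others[0]] = np.sqrt(t * rest) * sigma_tot
                vals[others[1]] = np.sqrt((1.0 - t) * rest) * sigma_tot
            # keep the pair covariance non-singular when E is pinned at the
            # share boundary; the variance-share perturbation is ~1e-10
            if "E" in comps:
                vals["E"] = max(vals["E"], 1e-5 * sigma_tot)
            return vals

        def obj(inner):
            sigma_tot = inner[0]
            t = inner[1] if len(others) == 2 else 0.0
            mu = inner[-1] if self.estimate_mean else 0.0
            vals = build(sigma_tot, t)
            return self._negloglik_paths(vals["A"], vals["C"], vals["E"], mu)

        x0, bounds = [1.0], [(1e-3, 10.0)]
        if len(others) == 2:
            x0.append(0.5)
            bounds.append((0.0, 1.0))
        if self.estimate_mean:
            x0.append(0.0)
            bounds.append((-1e3, 1e3))
        best = None
        for start in (x0, [v * 0.6 for v in x0[:1]] + x0[1:],
                      [v * 1.5 for v in x0[:1]] + x0[1:]):
            res = optimize.minimize(obj, np.asarray(start, float),
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-12, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        return float(best.fun)


@dataclass
class UnivariateACEResults:
    """ML estimates of one ACE-family fit, with profile CIs on demand."""

    model_obj: UnivariateACE
    model: str
    paths: dict
    mean: float
    loglik: float
    k_params: int
    n_mz: int
    n_dz: int
    converged: bool

    @property
    def total_variance(self) -> float:
        return sum(p * p for p in self.paths.values())

    @property
    def variance_components(self) -> dict:
        v = self.total_variance
        return {"a2": self.paths["A"] ** 2 / v,
                "c2": self.paths["C"] ** 2 / v,
                "e2": self.paths["E"] ** 2 / v}

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def profile_ci(self, component: str = "A", level: float = 0.95
                   ) -> tuple[float, float]:
        """Profile-likelihood CI for a component's variance share, in [0, 1].

        A bound that stays inside the critical deviance all the way to the
        parameter-space edge is reported at 0 or 1 (boundary solution).
        """
        comp = {"a2": "A", "c2": "C", "e2": "E"}.get(component, component)
        model = self.model_obj
        if comp not in model.free_components:
            return (0.0, 0.0)
        if model.free_components == (comp,):
            return (1.0, 1.0)  # single-component model: share fixed at 1
        crit = stats.chi2.ppf(level, df=1)
        share_hat = self.variance_components[{"A": "a2", "C": "c2",
                                              "E": "e2"}[comp]]
        ll_max = self.loglik

        def deviance(s):
            d = 2.0 * (ll_max + model._profile_negloglik(comp, s))
            return d if np.isfinite(d) else 1e6

        def solve(lo, hi):
            # deviance crosses crit between lo and hi
            return float(optimize.brentq(lambda s: deviance(s) - crit, lo, hi,
                                         xtol=1e-4))

        d0 = deviance(0.0)
        lower = 0.0 if d0 <= crit else solve(0.0, share_hat)
        d1 = deviance(1.0)
        upper = 1.0 if d1 <= crit else solve(share_hat, 1.0)
        return (min(max(lower, 0.0), 1.0), min(max(upper, 0.0), 1.0))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        vc = self.variance_components
        for comp, key in (("A", "a2"), ("C", "c2"), ("E", "e2")):
            if comp in self.model_obj.free_components:
                lo, hi = self.profile_ci(comp, level=level)
            else:
                lo = hi = 0.0
            rows.append({"component": key, "estimate": vc[key],
                         "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def summary(self, level: float = 0.95) -> str:
        vc = self.variance_components
        ci = self.conf_int(level=level)
        lines = [
            f"{self.model} twin model ({self.n_mz} MZ / {self.n_dz} DZ pairs)",
            f"  logLik = {self.loglik:.4f}   k = {self.k_params}   "
            f"AIC = {self.aic:.4f}",
        ]
        for _, row in ci.iterrows():
            lines.append(f"  {row['component']} = {row['estimate']:.3f} "
                         f"({row['ci_low']:.3f}, {row['ci_high']:.3f})")
        lines.append(f"  total variance = {self.total_variance:.3f}   "
                     f"mean = {self.mean:.3f}")
        _ = vc
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _is_nested(reduced: str, full: str) -> bool:
    return set(MODEL_COMPONENTS[reduced]) < set(MODEL_COMPONENTS[full])


def lrt(full: UnivariateACEResults, reduced: UnivariateACEResults) -> dict:
    """Chi-square likelihood-ratio test of a reduced model against a full one."""
    if not _is_nested(reduced.model, full.model):
        raise ValueError(
            f"{reduced.model} is not nested in {full.model}; "
            "use AIC for non-nested comparison")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    df = full.k_params - reduced.k_params
    return {"chi2": max(chi2, 0.0), "df": df,
            "p": float(stats.chi2.sf(max(chi2, 0.0), df))}


@dataclass
class ModelComparison:
    fits: dict
    table: pd.DataFrame
    best: str

    def __getitem__(self, model: str) -> UnivariateACEResults:
        return self.fits[model]


def compare_models(data: pd.DataFrame, trait: str = "trait1",
                   models: tuple = ("ACE", "AE", "CE", "E"),
                   alpha: float = 0.05, **kwargs) -> ModelComparison:
    """Fit an ACE-family model set and select the best parsimonious model.

    Each reduced model is tested against the full ACE model by chi-square
    difference; the selected model is the lowest-AIC model among those not
    significantly worse than ACE (at ``alpha``).
    """
    if "ACE" not in models:
        raise ValueError("the full ACE model anchors the comparison")
    fit_kw = {k: kwargs.pop(k) for k in ("n_starts", "seed") if k in kwargs}
    fits = {m: UnivariateACE(data, trait=trait, model=m, **kwargs).fit(**fit_kw)
            for m in models}
    rows = []
    for m in models:
        r = fits[m]
        row = {"model": m, "k": r.k_params, "loglik": r.loglik, "aic": r.aic,
               "a2": r.variance_components["a2"],
               "c2": r.variance_components["c2"],
               "e2": r.variance_components["e2"]}
        if m != "ACE":
            test = lrt(fits["ACE"], r)
            row.update({"chi2_vs_ACE": test["chi2"], "df": test["df"],
                        "p_vs_ACE": test["p"]})
        else:
            row.update({"chi2_vs_ACE": 0.0, "df": 0, "p_vs_ACE": 1.0})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    eligible = table[table["p_vs_ACE"] >= alpha]
    best = str(eligible["aic"].idxmin()) if len(eligible) else "ACE"
    return ModelComparison(fits=fits, table=table, best=best)


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------

def _block(s1: float, s2: float, r: float) -> np.ndarray:
    return np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])


@dataclass
class RphDecomposition:
    r_ph_a: float
    r_ph_c: float
    r_ph_e: float
    r_ph: float


def decompose_rph(r_g: float = 0.0, r_c: float = 0.0, r_e: float = 0.0,
                  a2: tuple = (0.0, 0.0), c2: tuple = (0.0, 0.0),
                  e2: tuple = (0.0, 0.0)) -> RphDecomposition:
    """Split a phenotypic correlation into genetic/shared/unique parts.

    Given the component correlations between two standardized traits and the
    per-trait variance shares,

        r_ph-a = r_g sqrt(a2_1 a2_2),  r_ph-c = r_c sqrt(c2_1 c2_2),
        r_ph-e = r_e sqrt(e2_1 e2_2),  r_ph = r_ph-a + r_ph-c + r_ph-e.

    A trait with zero heritability contributes r_ph-a = 0 whatever r_g is.
    """
    for name, shares in (("a2", a2), ("c2", c2), ("e2", e2)):
        if any(s < 0 for s in shares):
            raise ValueError(f"{name} shares must be non-negative")
    rpa = r_g * np.sqrt(a2[0] * a2[1])
    rpc = r_c * np.sqrt(c2[0] * c2[1])
    rpe = r_e * np.sqrt(e2[0] * e2[1])
    return RphDecomposition(float(rpa), float(rpc), float(rpe),
                            float(rpa + rpc + rpe))


class BivariateACE:
    """Bivariate ACE twin model (Cholesky-equivalent parameterisation).

    Each included component k in {A, C, E} contributes a cross-trait
    covariance block parameterised as (sigma1_k, sigma2_k, r_k); this is a
    reparameterisation of the 2x2 Cholesky factor, guaranteeing positive
    semidefiniteness while making the component correlations r_g, r_c, r_e
    direct parameters.
    """

    def __init__(self, data: pd.DataFrame,
                 traits: tuple = ("trait1", "trait2"), model: str = "ACE",
                 zygosity_col: str = "zygosity", standardize: bool = True,
                 estimate_means: bool = True):
        if model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model '{model}'")
        self.model = model
        self.traits = tuple(traits)
        self.estimate_means = estimate_means
        p1_mz, p1_dz = _extract_pairs(data, traits[0], zygosity_col)
        p2_mz, p2_dz = _extract_pairs(data, traits[1], zygosity_col)
        if len(p1_mz) < 2 or len(p1_dz) < 2:
            raise ValueError("need at least 2 MZ and 2 DZ pairs")

        def z(x_mz, x_dz):
            pooled = np.concatenate([x_mz.ravel(), x_dz.ravel()])
            scale = pooled.std(ddof=1)
            if scale == 0:
                raise ValueError("trait has zero variance")
            return (x_mz - pooled.mean()) / scale, (x_dz - pooled.mean()) / scale

        if standardize:
            p1_mz, p1_dz = z(p1_mz, p1_dz)
            p2_mz, p2_dz = z(p2_mz, p2_dz)
        # variable order: (t1 twin1, t2 twin1, t1 twin2, t2 twin2)
        X_mz = np.column_stack([p1_mz[:, 0], p2_mz[:, 0], p1_mz[:, 1], p2_mz[:, 1]])
        X_dz = np.column_stack([p1_dz[:, 0], p2_dz[:, 0], p1_dz[:, 1], p2_dz[:, 1]])
        self._mz = _GroupStats(X_mz)
        self._dz = _GroupStats(X_dz)

    @property
    def free_components(self) -> tuple[str, ...]:
        return MODEL_COMPONENTS[self.model]

    # theta layout: per component (s1, s2, r), then 2 means if estimated
    def _unpack(self, theta: np.ndarray) -> tuple[dict, np.ndarray]:
        blocks = {}
        i = 0
        for comp in self.free_components:
            s1, s2, r = theta[i], theta[i + 1], theta[i + 2]
            blocks[comp] = _block(s1, s2, r)
            i += 3
        mu2 = theta[i:i + 2] if self.estimate_means else np.zeros(2)
        return blocks, np.concatenate([mu2, mu2])

    def _sigma(self, blocks: dict, zygosity: str) -> np.ndarray:
        zero = np.zeros((2, 2))
        sa = blocks.get("A", zero)
        sc = blocks.get("C", zero)
        se = blocks.get("E", zero)
        within = sa + sc + se
        cross = (1.0 if zygosity == "MZ" else 0.5) * sa + sc
        return np.block([[within, cross], [cross, within]])

    def negloglik(self, theta: np.ndarray) -> float:
        blocks, mu = self._unpack(theta)
        return (self._mz.negloglik(self._sigma(blocks, "MZ"), mu)
                + self._dz.negloglik(self._sigma(blocks, "DZ"), mu))

    def _bounds(self, fixed_r: dict | None = None) -> list:
        bounds = []
        for comp in self.free_components:
            lo = 1e-3 if comp == "E" else 0.0
            bounds.append((lo, 6.0))
            bounds.append((lo, 6.0))
            if fixed_r and comp in fixed_r:
                bounds.append((fixed_r[comp], fixed_r[comp]))
            else:
                rmax = 0.999 if comp == "E" else 1.0
                bounds.append((-rmax, rmax))
        if self.estimate_means:
            bounds += [(-1e3, 1e3)] * 2
        return bounds

    def _starts(self, n_starts: int, seed: int) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        anchors = []
        for rg0 in (0.0, 0.5, -0.5):
            theta = []
            for comp in self.free_components:
                s = {"A": 0.6, "C": 0.3, "E": 0.6}[comp]
                theta += [s, s, rg0]
            anchors.append(theta)
        starts = [np.array(a, dtype=float) for a in anchors]
        while len(starts) < n_starts:
            theta = []
            for _ in self.free_components:
                theta += [rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                          rng.uniform(-0.8, 0.8)]
            starts.append(np.array(theta))
        if self.estimate_means:
            starts = [np.append(s, [0.0, 0.0]) for s in starts]
        return starts

    def _minimize(self, fixed_r: dict | None, n_starts: int,
                  seed: int) -> optimize.OptimizeResult:
        best = None
        bounds = self._bounds(fixed_r)
        for x0 in self._starts(n_starts, seed):
            if fixed_r:
                x0 = x0.copy()
                i = 0
                for comp in self.free_components:
                    if comp in fixed_r:
                        x0[i + 2] = fixed_r[comp]
                    i += 3
            res = optimize.minimize(self.negloglik, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": 1e-12, "gtol": 1e-10,
                                             "maxiter": 1000})
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self, n_starts: int = 8, seed: int = 0) -> "BivariateACEResults":
        best = self._minimize(None, n_starts, seed)
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"bivariate ACE optimization failed: {best}")
        blocks, mu = self._unpack(best.x)
        k = 3 * len(self.free_components) + (2 if self.estimate_means else 0)
        return BivariateACEResults(model_obj=self, model=self.model,
                                   blocks=blocks, means=mu[:2],
                                   loglik=-float(best.fun), k_params=k,
                                   n_mz=self._mz.n, n_dz=self._dz.n,
                                   converged=bool(best.success),
                                   _fit_seed=seed)


@dataclass
class BivariateACEResults:
    """Bivariate fit: variance shares, component correlations, decomposition."""

    model_obj: BivariateACE
    model: str
    blocks: dict
    means: np.ndarray
    loglik: float
    k_params: int
    n_mz: int
    n_dz: int
    converged: bool
    _fit_seed: int = 0

    def _within(self) -> np.ndarray:
        zero = np.zeros((2, 2))
        return sum((self.blocks.get(c, zero) for c in ("A", "C", "E")),
                   start=zero)

    @property
    def total_variance(self) -> np.ndarray:
        return np.diag(self._within())

    def shares(self, comp: str) -> np.ndarray:
        zero = np.zeros((2, 2))
        return np.diag(self.blocks.get(comp, zero)) / self.total_variance

    @property
    def a2(self) -> np.ndarray:
        return self.shares("A")

    @property
    def c2(self) -> np.ndarray:
        return self.shares("C")

    @property
    def e2(self) -> np.ndarray:
        return self.shares("E")

    def _component_r(self, comp: str) -> float:
        blk = self.blocks.get(comp)
        if blk is None:
            return 0.0
        denom = np.sqrt(blk[0, 0] * blk[1, 1])
        if denom < 1e-12:
            return float("nan")  # component absent for a trait: r unidentified
        return float(blk[0, 1] / denom)

    @property
    def r_g(self) -> float:
        return self._component_r("A")

    @property
    def r_c(self) -> float:
        return self._component_r("C")

    @property
    def r_e(self) -> float:
        return self._component_r("E")

    @property
    def r_ph(self) -> float:
        w = self._within()
        return float(w[0, 1] / np.sqrt(w[0, 0] * w[1, 1]))

    def _contribution(self, comp: str) -> float:
        blk = self.blocks.get(comp)
        if blk is None:
            return 0.0
        v = self.total_variance
        return float(blk[0, 1] / np.sqrt(v[0] * v[1]))

    @property
    def r_ph_a(self) -> float:
        return self._contribution("A")

    @property
    def r_ph_c(self) -> float:
        return self._contribution("C")

    @property
    def r_ph_e(self) -> float:
        return self._contribution("E")

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def decompose(self) -> RphDecomposition:
        return RphDecomposition(self.r_ph_a, self.r_ph_c, self.r_ph_e,
                                self.r_ph_a + self.r_ph_c + self.r_ph_e)

    def profile_ci(self, which: str = "r_g", level: float = 0.95,
                   n_starts: int = 4) -> tuple[float, float]:
        """Profile-likelihood CI for a component correlation (r_g/r_c/r_e)."""
        comp = {"r_g": "A", "r_c": "C", "r_e": "E"}[which]
        if comp not in self.model_obj.free_components:
            raise ValueError(f"{which} is not a parameter of model {self.model}")
        crit = stats.chi2.ppf(level, df=1)
        r_hat = self._component_r(comp)
        if not np.isfinite(r_hat):
            return (-1.0, 1.0)
        rmax = 0.999 if comp == "E" else 1.0

        def deviance(r):
            best = self.model_obj._minimize({comp: float(r)}, n_starts,
                                            self._fit_seed)
            d = 2.0 * (self.loglik + best.fun)
            return d if np.isfinite(d) else 1e6

        def bound(lo, hi):
            return float(optimize.brentq(lambda r: deviance(r) - crit,
                                         lo, hi, xtol=1e-3))

        d_lo = deviance(-rmax)
        lower = -1.0 if d_lo <= crit else bound(-rmax, r_hat)
        d_hi = deviance(rmax)
        upper = 1.0 if d_hi <= crit else bound(r_hat, rmax)
        return (lower, upper)

    def bootstrap_ci_rph(self, data: pd.DataFrame, n_boot: int = 200,
                         seed: int = 0, level: float = 0.95,
                         **model_kw) -> tuple[float, float]:
        """Percentile bootstrap CI for r_ph (pairs resampled within zygosity)."""
        rng = np.random.default_rng(seed)
        zyg = data["zygosity"].astype(str)
        mz_rows = data[zyg == "MZ"]
        dz_rows = data[zyg == "DZ"]
        vals = []
        for _ in range(n_boot):
            boot = pd.concat([
                mz_rows.sample(len(mz_rows), replace=True,
                               random_state=rng.integers(2 ** 31)),
                dz_rows.sample(len(dz_rows), replace=True,
                               random_state=rng.integers(2 ** 31)),
            ], ignore_index=True)
            try:
                r = BivariateACE(boot, traits=self.model_obj.traits,
                                 model=self.model, **model_kw).fit(
                                     n_starts=3, seed=0).r_ph
                vals.append(r)
            except (ValueError, RuntimeError):
                continue
        alpha = 1.0 - level
        return (float(np.quantile(vals, alpha / 2)),
                float(np.quantile(vals, 1 - alpha / 2)))

    def summary(self) -> str:
        t1, t2 = self.model_obj.traits
        lines = [
            f"Bivariate {self.model} twin model: {t1} x {t2} "
            f"({self.n_mz} MZ / {self.n_dz} DZ pairs)",
            f"  logLik = {self.loglik:.4f}   k = {self.k_params}   "
            f"AIC = {self.aic:.4f}",
            f"  a2 = ({self.a2[0]:.3f}, {self.a2[1]:.3f})   "
            f"c2 = ({self.c2[0]:.3f}, {self.c2[1]:.3f})   "
            f"e2 = ({self.e2[0]:.3f}, {self.e2[1]:.3f})",
            f"  r_ph = {self.r_ph:.3f}   r_g = {self.r_g:.3f}   "
            f"r_c = {self.r_c:.3f}   r_e = {self.r_e:.3f}",
            f"  r_ph-a = {self.r_ph_a:.3f}   r_ph-c = {self.r_ph_c:.3f}   "
            f"r_ph-e = {self.r_ph_e:.3f}",
        ]
        return "\n".join(lines)
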