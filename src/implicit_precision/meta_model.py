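"""Inverse-variance-weighted random-intercept meta-model and contrasts.

The cell (or participant-level) proportions are combined across attitude
domains with the weighted linear mixed model

    y_k = mu + beta_{measure(k)} + u_{domain(k)} + e_k,
    u_d ~ N(0, tau^2),   e_k ~ N(0, sigma^2 * v_k),

where v_k is the known relative error variance of row k (the inverse of
its meta-analytic weight) and sigma^2 a residual scale. Measure is a fixed
factor (the six tasks are exhaustive for the comparison); domain is a
random intercept (domains are a sample from a larger population of
attitude domains). tau^2 is estimated by restricted maximum likelihood via
a one-dimensional profile search over the variance ratio lambda =
tau^2/sigma^2; when the profile optimum is at lambda ~ 0 the fit reduces
to weighted least squares and is flagged as such. Estimated marginal means
per measure and Holm-corrected pairwise contrasts (z reference) mirror the
standard meta-analytic reporting of such models.

A ``fixed_scale`` mode pins sigma^2 = 1, the classical meta-regression
convention in which the supplied variances are taken as exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaDataset",
    "MetaFit",
    "fit_weighted_lmm",
    "estimated_marginal_means",
    "pairwise_contrasts",
    "holm_adjust",
]

_WLS_TAU2_FLOOR = 1e-10


@dataclass(frozen=True)
class MetaDataset:
    """Rows of (y, variance, measure, domain) ready for the meta-model."""

    y: np.ndarray
    variance: np.ndarray
    measure: np.ndarray
    domain: np.ndarray

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        y: str = "proportion",
        variance: str = "variance",
        measure: str = "measure",
        domain: str = "domain",
    ) -> "MetaDataset":
        return cls(
            y=frame[y].to_numpy(dtype=float),
            variance=frame[variance].to_numpy(dtype=float),
            measure=frame[measure].to_numpy(dtype=object),
            domain=frame[domain].to_numpy(dtype=object),
        )

    def __post_init__(self) -> None:
        n = self.y.size
        if not (self.variance.size == self.measure.size == self.domain.size == n):
            raise ValueError("all MetaDataset columns must have equal length")
        if n == 0:
            raise ValueError("empty MetaDataset")
        if np.any(self.variance <= 0):
            raise ValueError("every row variance must be positive")

    @property
    def measures(self) -> list[str]:
        return sorted(set(self.measure))

    @property
    def domains(self) -> list[str]:
        return sorted(set(self.domain))


@dataclass(frozen=True)
class MetaFit:
    coef: np.ndarray          # fixed effects: intercept + treatment dummies
    cov: np.ndarray           # covariance of the fixed effects
    coef_names: list[str]
    tau2_domain: float
    sigma2: float
    fit_method: str           # "REML" | "WLS-fallback" | "fixed-scale"
    converged: bool
    measures: list[str]
    reml_criterion: float

    def __post_init__(self) -> None:
        if self.tau2_domain < 0:
            raise ValueError("tau2 must be non-negative")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("fixed-effect covariance must be symmetric")


def _design(data: MetaDataset) -> tuple[np.ndarray, list[str], np.ndarray]:
    measures = data.measures
    n = data.y.size
    x = np.ones((n, len(measures)))
    names = ["intercept"]
    for j, m in enumerate(measures[1:], start=1):
        x[:, j] = (data.measure == m).astype(float)
        names.append(f"measure[{m}]")
    z = np.column_stack(
        [(data.domain == d).astype(float) for d in data.domains]
    )
    return x, names, z


def _check_design(data: MetaDataset) -> None:
    counts = pd.Series(data.measure).value_counts()
    empty = [m for m in data.measures if counts.get(m, 0) == 0]
    if empty:
        raise ValueError(f"measure level(s) with no rows: {empty}")


def _profiled_reml(
    lam: float,
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    v: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """-2 * restricted log-likelihood at variance ratio lam = tau2/sigma2.

    Marginal covariance up to sigma^2: W = diag(v) + lam * Z Z'. Returns
    the criterion plus the GLS coefficients, (X' W^-1 X)^-1 and sigma2_hat.
    """
    n, p = x.shape
    w = np.diag(v) + lam * z @ z.T
    # Cholesky solve; W is SPD for lam >= 0, v > 0
    c = np.linalg.cholesky(w)
    solve = lambda rhs: np.linalg.solve(c.T, np.linalg.solve(c, rhs))
    wi_x = solve(x)
    wi_y = solve(y)
    xtwx = x.T @ wi_x
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (x.T @ wi_y)
    resid = y - x @ beta
    quad = float(resid @ solve(resid))
    # floor guards the log for exactly-zero residuals (all-identical outcomes)
    sigma2 = max(quad / (n - p), 1e-30)
    logdet_w = 2.0 * float(np.sum(np.log(np.diag(c))))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    crit = logdet_w + (n - p) * np.log(sigma2) + logdet_xtwx
    return crit, beta, xtwx_inv, sigma2


def fit_weighted_lmm(
    data: MetaDataset,
    *,
    fixed_scale: bool = False,
) -> MetaFit:
    """Fit the weighted measure + (1 | domain) model by profile REML.

    The per-row variances act as known *relative* error variances; the
    residual scale sigma^2 and the domain variance tau^2 are estimated.
    The profile over lambda = tau^2/sigma^2 is searched on a log grid and
    polished with bounded Brent minimization (tolerance 1e-8); a profile
    optimum at lambda ~ 0 is reported as ``fit_method="WLS-fallback"``.
    With ``fixed_scale=True`` sigma^2 is pinned to 1 (classical
    meta-regression weighting) and tau^2 alone is profiled.
    """
    _check_design(data)
    x, names, z = _design(data)
    y, v = data.y, data.variance
    n, p = x.shape
    if n <= p:
        raise ValueError(
            f"{n} row(s) cannot identify {p} fixed effect(s) plus a residual scale"
        )

    if fixed_scale:
        def crit_fn(log_lam: float) -> float:
            lam = np.exp(log_lam)
            w = np.diag(v) + lam * z @ z.T
            c = np.linalg.cholesky(w)
            solve = lambda rhs: np.linalg.solve(c.T, np.linalg.solve(c, rhs))
            wi_x = solve(x)
            xtwx = x.T @ wi_x
            beta = np.linalg.solve(xtwx, x.T @ solve(y))
            resid = y - x @ beta
            logdet_w = 2.0 * float(np.sum(np.log(np.diag(c))))
            _, logdet_xtwx = np.linalg.slogdet(xtwx)
            return logdet_w + float(resid @ solve(resid)) + logdet_xtwx
    else:
        def crit_fn(log_lam: float) -> float:
            return _profiled_reml(np.exp(log_lam), y, x, z, v)[0]

    # coarse log-grid then bounded polish; lambda spans ~[1e-12, 1e6] x mean(v)
    scale = float(np.mean(v))
    grid = np.log(scale) + np.linspace(-28.0, 14.0, 43)
    crit_grid = [crit_fn(g) for g in grid]
    k = int(np.argmin(crit_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        crit_fn, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    lam = float(np.exp(res.x))
    crit, beta, xtwx_inv, sigma2 = _profiled_reml(lam, y, x, z, v)
    if fixed_scale:
        sigma2 = 1.0
        crit = crit_fn(res.x)
    tau2 = lam * sigma2
    if tau2 <= _WLS_TAU2_FLOOR:
        crit, beta, xtwx_inv, sigma2 = _profiled_reml(0.0, y, x, z, v)
        if fixed_scale:
            sigma2 = 1.0
        method = "WLS-fallback"
        tau2 = 0.0
    else:
        method = "fixed-scale" if fixed_scale else "REML"
    cov = sigma2 * xtwx_inv
    cov = (cov + cov.T) / 2.0
    return MetaFit(
        coef=beta,
        cov=cov,
        coef_names=names,
        tau2_domain=float(tau2),
        sigma2=float(sigma2),
        fit_method=method,
        converged=bool(res.success),
        measures=data.measures,
        reml_criterion=float(crit),
    )


def estimated_marginal_means(fit: MetaFit) -> pd.DataFrame:
    """Population-level mean per measure with its standard error.

    With a treatment-coded design and the domain intercept averaging to
    zero, measure m's EMM is intercept (+ its dummy coefficient); the SE
    comes from the fixed-effect covariance.
    """
    rows = []
    p = fit.coef.size
    for j, m in enumerate(fit.measures):
        contrast = np.zeros(p)
        contrast[0] = 1.0
        if j > 0:
            contrast[j] = 1.0
        emm = float(contrast @ fit.coef)
        se = float(np.sqrt(contrast @ fit.cov @ contrast))
        rows.append({"measure": m, "emm": emm, "se": se})
    return pd.DataFrame(rows)


def holm_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pairwise_contrasts(
    fit: MetaFit, *, alpha: float = 0.05, adjust: str = "holm"
) -> pd.DataFrame:
    """All pairwise EMM differences with Holm-adjusted z-based p-values.

    The difference (m1, m2) is EMM(m1) - EMM(m2); its SE uses the full
    fixed-effect covariance. The CI is unadjusted (reported at level
    alpha); only the p-values carry the multiplicity correction.
    """
    measures = fit.measures
    if len(measures) < 2:
        raise ValueError("contrasts need at least 2 measures")
    p = fit.coef.size
    cvecs = {}
    for j, m in enumerate(measures):
        c = np.zeros(p)
        c[0] = 1.0
        if j > 0:
            c[j] = 1.0
        cvecs[m] = c
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for m1, m2 in combinations(measures, 2):
        d = cvecs[m1] - cvecs[m2]
        diff = float(d @ fit.coef)
        se = float(np.sqrt(d @ fit.cov @ d))
        if se < 1e-12 or abs(diff) < 1e-12:
            z_val, p_val = 0.0, 1.0
        else:
            z_val = diff / se
            p_val = 2.0 * norm.sf(abs(z_val))
        rows.append(
            {
                "measure_1": m1,
                "measure_2": m2,
                "emm_difference": diff,
                "ci_lower": diff - z_crit * se,
                "ci_upper": diff + z_crit * se,
                "z": z_val,
                "p_value": p_val,
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "holm":
        table["p_holm"] = holm_adjust(table["p_value"].to_numpy())
    elif adjust == "none":
        table["p_holm"] = table["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
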