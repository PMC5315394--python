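"""Mixed unconditional logistic regression and OR reporting.

The full model regresses case status on the environment category
(reference: rural), SES quartile (reference: Q1), GCI/10 as a continuous
covariate, and the matching factors sex and birth year, with the region
as a zero-mean normal random intercept.  The marginal likelihood is
maximised with adaptive Gauss-Hermite quadrature (the Laplace
approximation is its one-node special case); confidence intervals are
Wald, exp(estimate +/- 1.96 SE).

A random intercept over only five regions is statistically fragile: when
the variance estimate collapses to the boundary the fit automatically
falls back to region fixed effects, and the ``method`` field records
which route produced the estimates.  With the variance fixed at zero the
mixed likelihood reduces exactly to ordinary logistic regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054

ENV_LEVELS = ("rural", "industrial", "intersection", "urban", "ring")
SES_LEVELS = ("Q1", "Q2", "Q3", "Q4")

__all__ = [
    "ModelSpec",
    "TermEstimate",
    "ModelFit",
    "fit_mixed_logistic",
    "crude_or",
    "or_table",
]


@dataclass
class ModelSpec:
    """Fixed and random terms of one model."""

    crop_col: str = "gci"
    include_env: bool = True
    include_ses: bool = True
    include_sex: bool = True
    include_year: bool = True
    random_region: bool = True
    #: crop-only sensitivity models drop the environment and SES terms
    crop_only: bool = False

    def covariate_columns(self) -> list[str]:
        cols = ["status", self.crop_col]
        if self.include_env and not self.crop_only:
            cols.append("env")
        if self.include_ses and not self.crop_only:
            cols.append("ses_q")
        if self.include_sex:
            cols.append("sex")
        if self.include_year:
            cols.append("birth_year")
        if self.random_region:
            cols.append("region")
        return cols


@dataclass
class TermEstimate:
    estimate: float
    se: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass
class ModelFit:
    terms: dict[str, TermEstimate]
    sigma_region: float
    method: str
    converged: bool
    n_cases: int
    n_controls: int
    loglik: float
    n_dropped: int = 0
    category_counts: dict = field(default_factory=dict)
    gci_positive: tuple[int, int] = (0, 0)

    def odds_ratio(self, term: str) -> float:
        return self.terms[term].or_


# ---------------------------------------------------------------------------
# design matrix

def _build_design(data: pd.DataFrame, spec: ModelSpec):
    cols = spec.covariate_columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    y = (sub["status"].to_numpy() == "case").astype(float)

    parts = [np.ones(len(sub))]
    names = ["intercept"]

    crop = sub[spec.crop_col].to_numpy(float) / 10.0
    parts.append(crop)
    names.append(f"{spec.crop_col}10")

    def add_dummies(col: str, levels: tuple[str, ...], reference: str, prefix: str):
        values = sub[col].to_numpy()
        present = [lv for lv in levels if (values == lv).any()]
        ref = reference if reference in present else (present[0] if present else None)
        for lv in present:
            if lv == ref:
                continue
            parts.append((values == lv).astype(float))
            names.append(f"{prefix}{lv}")

    if spec.include_env and not spec.crop_only:
        add_dummies("env", ENV_LEVELS, "rural", "env_")
    if spec.include_ses and not spec.crop_only:
        add_dummies("ses_q", SES_LEVELS, "Q1", "ses_q".lower() + "_")
    if spec.include_sex:
        parts.append((sub["sex"].to_numpy() == "M").astype(float))
        names.append("sex_male")
    if spec.include_year:
        year = sub["birth_year"].to_numpy(float)
        parts.append(year - year.mean())
        names.append("birth_year_c")

    X = np.column_stack(parts)
    groups = sub["region"].to_numpy() if spec.random_region else None
    return y, X, names, groups, sub, n_dropped


# ---------------------------------------------------------------------------
# plain logistic (Newton-Raphson), used directly and as the sigma=0 limit

def _logistic_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls_logistic(y, X, max_iter: int = 100, tol: float = 1e-12):
    beta = np.zeros(X.shape[1])
    converged = False
    H = np.eye(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        g = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    separated = bool(np.max(np.abs(beta)) > 30.0)
    cov = np.linalg.pinv(H)
    return beta, cov, _logistic_loglik(y, X @ beta), converged and not separated


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite marginal likelihood

def _aghq_negloglik(y, X, group_idx, n_groups, beta, sigma, nodes, weights):
    """Negative marginal log-likelihood of the random-intercept model.

    For each region the integrand is recentred at its posterior mode and
    rescaled by the local curvature (adaptive quadrature); with sigma
    near zero this reduces numerically to the plain logistic likelihood.
    """
    s2 = max(sigma * sigma, 1e-16)
    eta0 = X @ beta
    total = 0.0
    for j in range(n_groups):
        sel = group_idx == j
        yj, ej = y[sel], eta0[sel]
        # inner Newton for the mode of the joint log-density in b
        b = 0.0
        for _ in range(50):
            mu = expit(ej + b)
            g = float(np.sum(yj - mu)) - b / s2
            h = -float(np.sum(mu * (1.0 - mu))) - 1.0 / s2
            step = g / h
            b -= step
            if abs(step) < 1e-10:
                break
        mu = expit(ej + b)
        h = -float(np.sum(mu * (1.0 - mu))) - 1.0 / s2
        tau = 1.0 / math.sqrt(-h)
        bk = b + tau * nodes  # (K,)
        etak = ej[:, None] + bk[None, :]
        ll_k = np.sum(yj[:, None] * etak - np.logaddexp(0.0, etak), axis=0)
        ll_k -= 0.5 * bk * bk / s2
        # probabilists' Gauss-Hermite: sum_k w_k e^{z_k^2/2} g(mode + tau z_k)
        log_terms = ll_k + 0.5 * nodes * nodes + np.log(weights)
        m = log_terms.max()
        integral = m + math.log(np.sum(np.exp(log_terms - m)))
        total += integral + math.log(tau) - 0.5 * math.log(2.0 * math.pi * s2)
    return -total


def _fit_aghq(y, X, groups, n_quad: int, beta0: np.ndarray):
    labels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    nodes, weights = hermegauss(n_quad)

    def obj(theta):
        return _aghq_negloglik(
            y, X, group_idx, n_groups, theta[:-1], theta[-1], nodes, weights
        )

    x0 = np.append(beta0, 0.3)
    bounds = [(None, None)] * X.shape[1] + [(1e-6, 10.0)]
    res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})

    def covariance():
        from statsmodels.tools.numdiff import approx_hess

        hess = approx_hess(res.x, obj)
        try:
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(hess)

    return res.x[:-1], float(res.x[-1]), covariance, -float(res.fun), bool(res.success)


# ---------------------------------------------------------------------------
# public fitting API

def fit_mixed_logistic(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_quad: int = 15,
    fix_sigma: float | None = None,
    boundary_sigma: float = 0.02,
) -> ModelFit:
    """Fit the (mixed) unconditional logistic model.

    Rows with missing covariates are dropped and counted.  When the
    region variance estimate collapses below ``boundary_sigma`` the fit
    is redone with region fixed effects (method ``"region_fixed"``).
    ``fix_sigma=0`` forces the degenerate mixed model, which must and
    does agree with plain logistic regression.
    """
    spec = spec or ModelSpec()
    y, X, names, groups, sub, n_dropped = _build_design(data, spec)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both cases and controls to fit")

    beta0, cov0, ll0, conv0 = _irls_logistic(y, X)
    sigma = 0.0
    method = "logistic"
    converged = conv0
    beta, cov, ll = beta0, cov0, ll0

    n_regions = len(np.unique(groups)) if groups is not None else 0
    use_mixed = (
        spec.random_region
        and (fix_sigma is None or fix_sigma > 0)
        and n_regions >= 2
    )
    if use_mixed:
        beta_m, sigma_m, cov_fn, ll_m, ok = _fit_aghq(y, X, groups, n_quad, beta0)
        if sigma_m <= boundary_sigma:
            # variance on the boundary: region fixed effects instead
            labels = np.unique(groups)
            dummies = [(groups == lv).astype(float) for lv in labels[1:]]
            Xf = np.column_stack([X] + dummies)
            names_f = names + [f"region_{lv}" for lv in labels[1:]]
            beta, cov, ll, converged = _irls_logistic(y, Xf)
            names = names_f
            sigma, method = 0.0, "region_fixed"
            logger.info("region variance on boundary (sigma=%.4f); using fixed effects",
                        sigma_m)
        else:
            beta, cov, ll = beta_m, cov_fn()[:-1, :-1], ll_m
            sigma, method, converged = sigma_m, "aghq", ok
    elif spec.random_region and n_regions == 1 and fix_sigma is None:
        method = "logistic"  # single region: random intercept degenerate

    se = np.sqrt(np.clip(np.diag(cov)[: len(beta)], 0.0, None))
    with np.errstate(over="ignore"):  # separated terms have infinite CIs
        terms = {
            name: TermEstimate(
                estimate=float(b),
                se=float(s),
                or_=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
            )
            for name, b, s in zip(names, beta, se)
        }

    is_case = sub["status"].to_numpy() == "case"
    counts: dict = {}
    for col, levels in (("env", ENV_LEVELS), ("ses_q", SES_LEVELS), ("sex", ("F", "M"))):
        if col in sub.columns:
            vals = sub[col].to_numpy()
            for lv in levels:
                m = vals == lv
                if m.any():
                    counts[(col, lv)] = (int((m & is_case).sum()),
                                         int((m & ~is_case).sum()))
    gci_pos = sub[spec.crop_col].to_numpy(float) > 0
    return ModelFit(
        terms=terms,
        sigma_region=float(sigma),
        method=method,
        converged=bool(converged),
        n_cases=int(is_case.sum()),
        n_controls=int((~is_case).sum()),
        loglik=float(ll),
        n_dropped=n_dropped,
        category_counts=counts,
        gci_positive=(int((gci_pos & is_case).sum()), int((gci_pos & ~is_case).sum())),
    )


# ---------------------------------------------------------------------------
# crude ORs and report tables

def crude_or(a: float, b: float, c: float, d: float, haldane: bool = False):
    """Cross-product odds ratio with a Woolf 95% CI.

    Counts are (cases exposed, cases unexposed, controls exposed,
    controls unexposed).  A zero cell raises unless ``haldane`` adds 0.5
    to every cell.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell: no finite Woolf CI (set haldane=True)")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, (or_ * math.exp(-Z95 * se), or_ * math.exp(Z95 * se))


def or_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Tidy report table across subgroup fits.

    One row per (subgroup, covariate level or continuous term) with
    category counts, column percentages, OR and 95% CI; reference levels
    carry OR 1 with no interval.  The final rows per subgroup count
    subjects with GCI > 0.
    """
    rows = []
    for name, fit in fits.items():
        tot_cases = max(fit.n_cases, 1)
        tot_ctrl = max(fit.n_controls, 1)
        for (col, lv), (nc, nk) in fit.category_counts.items():
            term = f"env_{lv}" if col == "env" else (
                f"ses_q_{lv}" if col == "ses_q" else f"sex_{lv}"
            )
            key = {"env": f"env_{lv}", "ses_q": f"ses_q_{lv}", "sex": "sex_male"}[col]
            t = fit.terms.get(key) if not (col == "sex" and lv == "F") else None
            rows.append(
                {
                    "subgroup": name,
                    "term": term,
                    "n_cases": nc,
                    "pct_cases": 100.0 * nc / tot_cases,
                    "n_controls": nk,
                    "pct_controls": 100.0 * nk / tot_ctrl,
                    "or": t.or_ if t else 1.0,
                    "ci_low": t.ci_low if t else np.nan,
                    "ci_high": t.ci_high if t else np.nan,
                }
            )
        for term_name, t in fit.terms.items():
            if term_name.endswith("10") or term_name == "birth_year_c":
                rows.append(
                    {
                        "subgroup": name,
                        "term": term_name,
                        "n_cases": fit.gci_positive[0] if term_name.endswith("10") else fit.n_cases,
                        "pct_cases": 100.0 * fit.gci_positive[0] / tot_cases
                        if term_name.endswith("10") else 100.0,
                        "n_controls": fit.gci_positive[1] if term_name.endswith("10") else fit.n_controls,
                        "pct_controls": 100.0 * fit.gci_positive[1] / tot_ctrl
                        if term_name.endswith("10") else 100.0,
                        "or": t.or_,
                        "ci_low": t.ci_low,
                        "ci_high": t.ci_high,
                    }
                )
    return pd.DataFrame(rows)
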