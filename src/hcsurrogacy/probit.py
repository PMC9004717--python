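"""Univariate and bivariate probit regression by maximum likelihood.

The bivariate probit treats two binary outcomes as the signs of two latent
normal linear predictors with correlation ``rho``; the four cell
probabilities come from the bivariate normal CDF.  The log-likelihood is
maximized directly (quasi-Newton on the coefficients and ``atanh(rho)``),
with univariate probit fits as starting values, so no external bivariate
probit package is involved.

The bivariate normal CDF itself is computed from Owen's T function, which is
vectorized and accurate to ~1e-14; scipy's generic multivariate normal CDF is
used only as a cross-check in the test-suite because it is far too slow to
sit inside a likelihood loop.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .entropy import ProbabilityVector

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationError",
    "ProbitFit",
    "BivariateProbitFit",
    "bvn_cdf",
    "fit_probit",
    "fit_bivariate_probit",
    "conditional_cell_probs",
]

_CELL_FLOOR = 1e-300


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by a predictor."""


# ---------------------------------------------------------------------------
# bivariate normal CDF


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen (1956): ``Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta``
    with ``a_h = (k - rho h)/(h sqrt(1-rho^2))`` (and symmetrically for k) and
    ``beta = 1/2`` iff h and k lie on opposite sides of zero.  Vectorized;
    exact special cases at rho in {0, +/-1} and at h = k = 0.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    rho = np.clip(rho, -1.0, 1.0)
    out = np.empty(h.shape, dtype=float)

    ph, pk = ndtr(h), ndtr(k)

    m_pos = rho >= 1.0 - 1e-15
    m_neg = rho <= -1.0 + 1e-15
    out[m_pos] = np.minimum(ph, pk)[m_pos]
    out[m_neg] = np.maximum(ph + pk - 1.0, 0.0)[m_neg]

    m_ind = (np.abs(rho) < 1e-15) & ~(m_pos | m_neg)
    out[m_ind] = (ph * pk)[m_ind]

    rest = ~(m_pos | m_neg | m_ind)
    if np.any(rest):
        hr, kr, rr = h[rest], k[rest], rho[rest]
        s = np.sqrt(1.0 - rr * rr)
        both_zero = (hr == 0.0) & (kr == 0.0)
        hz = (hr == 0.0) & ~both_zero
        kz = (kr == 0.0) & ~both_zero
        gen = ~(both_zero | hz | kz)

        vals = np.empty(hr.shape, dtype=float)
        vals[both_zero] = 0.25 + np.arcsin(rr[both_zero]) / (2.0 * math.pi)
        # one argument exactly zero: Phi2(0, k, rho) = Phi(k)/2 - T(k, -rho/sqrt(1-rho^2))
        if np.any(hz):
            vals[hz] = 0.5 * ndtr(kr[hz]) - owens_t(kr[hz], -rr[hz] / s[hz])
        if np.any(kz):
            vals[kz] = 0.5 * ndtr(hr[kz]) - owens_t(hr[kz], -rr[kz] / s[kz])
        if np.any(gen):
            hg, kg, rg, sg = hr[gen], kr[gen], rr[gen], s[gen]
            ah = (kg / hg - rg) / sg
            ak = (hg / kg - rg) / sg
            beta = np.where(hg * kg < 0.0, 0.5, 0.0)
            vals[gen] = (
                0.5 * (ndtr(hg) + ndtr(kg)) - owens_t(hg, ah) - owens_t(kg, ak) - beta
            )
        out[rest] = vals
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def _bvn_pdf(h, k, rho):
    s2 = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / s2
    return np.exp(-0.5 * z) / (2.0 * math.pi * np.sqrt(s2))


# ---------------------------------------------------------------------------
# univariate probit


@dataclass(frozen=True)
class ProbitFit:
    intercept: float
    coefficients: np.ndarray
    converged: bool
    loglik: float
    se: np.ndarray = field(default=None, repr=False)  # (intercept first)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])

    def linear_predictor(self, predictors: np.ndarray) -> np.ndarray:
        predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
        return self.intercept + predictors @ self.coefficients

    def predict_proba(self, predictors: np.ndarray) -> np.ndarray:
        return ndtr(self.linear_predictor(predictors))


def _check_separation(outcome: np.ndarray, predictors: np.ndarray) -> None:
    """Raise if any single predictor column perfectly separates the outcome."""
    ones = outcome == 1
    for j in range(predictors.shape[1]):
        col = predictors[:, j]
        if col.std() == 0:
            continue
        if col[ones].min() >= col[~ones].max() or col[~ones].min() >= col[ones].max():
            raise SeparationError(
                f"predictor column {j} perfectly separates the outcome classes"
            )


def _validate_binary(name: str, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must be coded 0/1")
    y = y.astype(float)
    if y.min() == y.max():
        raise ValueError(f"{name} must contain both outcome classes")
    return y


def fit_probit(outcome: np.ndarray, predictors: np.ndarray) -> ProbitFit:
    """Maximum-likelihood probit regression (intercept added automatically).

    Thin wrapper over statsmodels' Probit with explicit separation and rank
    checks, returning a plain :class:`ProbitFit`.
    """
    y = _validate_binary("outcome", outcome)
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    if x.shape[0] != y.size:
        raise ValueError("predictor matrix and outcome length mismatch")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    _check_separation(y.astype(int), x)
    design = sm.add_constant(x, has_constant="add")
    try:
        res = sm.Probit(y, design).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:  # pragma: no cover - depends on sm version
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params)
    fitted = ndtr(design @ params)
    if fitted.min() <= 0.0 or fitted.max() >= 1.0:
        raise SeparationError("fitted probabilities hit the boundary; data are separated")
    return ProbitFit(
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        converged=bool(res.mle_retvals.get("converged", True)),
        loglik=float(res.llf),
        se=np.asarray(res.bse),
    )


# ---------------------------------------------------------------------------
# bivariate probit


@dataclass(frozen=True)
class BivariateProbitFit:
    """ML fit of two probit equations with correlated latent errors."""

    intercept_t: float
    intercept_z: float
    gamma_t: np.ndarray
    gamma_z: np.ndarray
    rho_latent: float
    converged: bool
    loglik: float
    se_beta_t: np.ndarray = field(default=None, repr=False)
    se_beta_z: np.ndarray = field(default=None, repr=False)
    se_atanh_rho: float = float("nan")
    grad_norm: float = float("nan")
    n_obs: int = 0
    rho_near_boundary: bool = False

    @property
    def beta_t(self) -> np.ndarray:
        return np.concatenate([[self.intercept_t], self.gamma_t])

    @property
    def beta_z(self) -> np.ndarray:
        return np.concatenate([[self.intercept_z], self.gamma_z])

    def linear_predictors(self, predictors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(predictors, dtype=float))
        return (
            self.intercept_t + x @ self.gamma_t,
            self.intercept_z + x @ self.gamma_z,
        )

    def rho_confint(self, level: float = 0.95) -> tuple[float, float]:
        """Wald interval for rho built on the atanh scale and mapped back."""
        from scipy.stats import norm as _norm

        eta = math.atanh(self.rho_latent)
        half = _norm.ppf(0.5 + level / 2.0) * self.se_atanh_rho
        return math.tanh(eta - half), math.tanh(eta + half)

    def to_json(self) -> str:
        doc = {
            "model": "bivariate_probit",
            "n_obs": self.n_obs,
            "converged": self.converged,
            "loglik": self.loglik,
            "grad_norm": self.grad_norm,
            "parameters": {
                "beta_T": list(self.beta_t),
                "beta_Z": list(self.beta_z),
                "rho": self.rho_latent,
            },
            "standard_errors": {
                "beta_T": list(np.asarray(self.se_beta_t)),
                "beta_Z": list(np.asarray(self.se_beta_z)),
                "atanh_rho": self.se_atanh_rho,
            },
        }
        return json.dumps(doc, indent=2)


def _cell_probs_from_lp(lp_t, lp_z, rho):
    """Cells (p11, p10, p01, p00) given the two latent linear predictors."""
    p11 = bvn_cdf(lp_t, lp_z, rho)
    pt = ndtr(lp_t)
    pz = ndtr(lp_z)
    p10 = np.clip(pt - p11, 0.0, 1.0)
    p01 = np.clip(pz - p11, 0.0, 1.0)
    p00 = np.clip(1.0 - pt - pz + p11, 0.0, 1.0)
    return p11, p10, p01, p00


def _biv_nll_and_grad(theta, design, qt, qz):
    """Mean negative log-likelihood and gradient.

    Uses the sign-flip form: the likelihood of observation i is
    ``Phi2(q_T w_T, q_Z w_Z, q_T q_Z rho)`` with q = 2y - 1.
    """
    n, p = design.shape
    beta_t = theta[:p]
    beta_z = theta[p : 2 * p]
    eta = theta[-1]
    rho = math.tanh(eta)

    w1 = qt * (design @ beta_t)
    w2 = qz * (design @ beta_z)
    r = qt * qz * rho
    lik = np.maximum(bvn_cdf(w1, w2, r), _CELL_FLOOR)
    nll = -np.log(lik).mean()

    s = math.sqrt(max(1.0 - rho * rho, 1e-12))
    phi1 = np.exp(-0.5 * w1 * w1) / math.sqrt(2.0 * math.pi)
    phi2 = np.exp(-0.5 * w2 * w2) / math.sqrt(2.0 * math.pi)
    g1 = qt * phi1 * ndtr((w2 - r * w1) / s) / lik
    g2 = qz * phi2 * ndtr((w1 - r * w2) / s) / lik
    grho = qt * qz * _bvn_pdf(w1, w2, r) / lik

    grad = np.empty(2 * p + 1)
    grad[:p] = -(design * g1[:, None]).sum(axis=0) / n
    grad[p : 2 * p] = -(design * g2[:, None]).sum(axis=0) / n
    grad[-1] = -grho.sum() / n * (1.0 - rho * rho)  # chain rule through tanh
    return nll, grad


def fit_bivariate_probit(
    outcome_t: np.ndarray,
    outcome_z: np.ndarray,
    predictors: np.ndarray | None = None,
    max_restarts: int = 3,
) -> BivariateProbitFit:
    """Fit a bivariate probit for two binary outcomes on shared predictors.

    Starting values come from the two univariate probit fits with rho = 0;
    rho is optimized on the atanh scale so the constraint |rho| < 1 is
    automatic.  Convergence requires a per-observation gradient norm below
    1e-6; up to ``max_restarts`` jittered restarts are attempted, and the best
    log-likelihood found is carried on the error if none converges.

    Predictor columns are standardized internally for optimizer conditioning
    and the estimates mapped back to the original scale.
    """
    yt = _validate_binary("outcome_T", outcome_t)
    yz = _validate_binary("outcome_Z", outcome_z)
    if yt.size != yz.size:
        raise ValueError("the two outcome vectors differ in length")
    n = yt.size
    if predictors is None:
        x = np.empty((n, 0))
    else:
        x = np.atleast_2d(np.asarray(predictors, dtype=float))
        if x.shape[0] != n:
            x = x.T
        if x.shape[0] != n:
            raise ValueError("predictor matrix and outcome length mismatch")
    k = x.shape[1]
    if k:
        if np.linalg.matrix_rank(x) < k:
            raise ValueError("predictor matrix is rank deficient")
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant predictor column; the intercept is added internally")
        xs = (x - mu) / sd
    else:
        mu = np.empty(0)
        sd = np.empty(0)
        xs = x
    design = np.column_stack([np.ones(n), xs])
    p = k + 1

    def uni_start(y):
        if k:
            fit = fit_probit(y, xs)
            return fit.params
        return np.array([float(ndtri(y.mean()))])

    start = np.concatenate([uni_start(yt), uni_start(yz), [0.0]])
    qt = 2.0 * yt - 1.0
    qz = 2.0 * yz - 1.0

    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(max_restarts + 1):
        theta0 = start if attempt == 0 else start + rng.normal(0, 0.05, start.size)
        res = optimize.minimize(
            _biv_nll_and_grad,
            theta0,
            args=(design, qt, qz),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        gnorm = float(np.linalg.norm(res.jac))
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gnorm)
        if gnorm < 1e-6:
            best = (res, gnorm)
            break
    res, gnorm = best
    converged = gnorm < 1e-6
    if not converged and gnorm > 1e-4:
        raise RuntimeError(
            f"bivariate probit failed to converge after {max_restarts} restarts "
            f"(gradient norm {gnorm:.2e}, best mean loglik {-res.fun:.6f})"
        )

    theta = res.x
    eta = float(theta[-1])
    rho = math.tanh(eta)
    near_boundary = abs(rho) > 0.999
    if near_boundary:
        logger.warning("fitted latent correlation %.4f is near the boundary", rho)

    # covariance: numerical Hessian of the total NLL in the standardized space,
    # then a linear map back to the raw predictor scale
    def total_nll(th):
        return _biv_nll_and_grad(th, design, qt, qz)[0] * n

    hess = approx_hess1(theta, total_nll)
    try:
        cov_std = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_std = np.full((theta.size, theta.size), np.nan)

    # block Jacobian of (beta_raw ; eta) wrt (beta_std ; eta)
    jac = np.eye(theta.size)
    if k:
        for block in (0, p):
            jac[block, block + 1 : block + p] = -mu / sd
            for j in range(k):
                jac[block + 1 + j, block + 1 + j] = 1.0 / sd[j]
    cov = jac @ cov_std @ jac.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    beta_t_std = theta[:p]
    beta_z_std = theta[p : 2 * p]
    if k:
        gamma_t = beta_t_std[1:] / sd
        gamma_z = beta_z_std[1:] / sd
        b0_t = beta_t_std[0] - float((beta_t_std[1:] * mu / sd).sum())
        b0_z = beta_z_std[0] - float((beta_z_std[1:] * mu / sd).sum())
    else:
        gamma_t = np.empty(0)
        gamma_z = np.empty(0)
        b0_t = float(beta_t_std[0])
        b0_z = float(beta_z_std[0])

    fit = BivariateProbitFit(
        intercept_t=b0_t,
        intercept_z=b0_z,
        gamma_t=gamma_t,
        gamma_z=gamma_z,
        rho_latent=rho,
        converged=converged,
        loglik=float(-res.fun * n),
        se_beta_t=se[:p],
        se_beta_z=se[p : 2 * p],
        se_atanh_rho=float(se[-1]),
        grad_norm=gnorm,
        n_obs=n,
        rho_near_boundary=near_boundary,
    )
    _validate_cells(fit, x)
    return fit


def _validate_cells(fit: BivariateProbitFit, predictors: np.ndarray) -> None:
    lp_t, lp_z = fit.linear_predictors(predictors) if predictors.size else (
        np.array([fit.intercept_t]),
        np.array([fit.intercept_z]),
    )
    cells = np.column_stack(_cell_probs_from_lp(lp_t, lp_z, fit.rho_latent))
    if cells.min() < 0 or np.abs(cells.sum(axis=1) - 1.0).max() > 1e-10:
        raise RuntimeError("fitted cell probabilities are inconsistent")


def conditional_cell_probs(
    fit: BivariateProbitFit, predictors_row: np.ndarray
) -> ProbabilityVector:
    """The four cell probabilities P(T=t, Z=z | S = s) at one predictor row.

    Order: (T=1,Z=1), (T=1,Z=0), (T=0,Z=1), (T=0,Z=0).  Cells sum to 1
    within 1e-10 and the margins match the univariate linear predictors by
    construction.
    """
    row = np.atleast_2d(np.asarray(predictors_row, dtype=float))
    lp_t, lp_z = fit.linear_predictors(row)
    p11, p10, p01, p00 = (
        float(np.asarray(v).reshape(-1)[0])
        for v in _cell_probs_from_lp(lp_t, lp_z, fit.rho_latent)
    )
    cells = np.array([p11, p10, p01, p00])
    cells = np.clip(cells, 0.0, 1.0)
    cells /= cells.sum()
    return ProbabilityVector(cells)
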