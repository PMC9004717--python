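"""Monte-Carlo plug-in oracle for the generalized mutual information.

Estimates I_a(T, S) from nothing but the entropy primitives and the known
densities: sample from the joint law, average ``phi_a(f(.))`` for each of the
marginal and joint densities, and combine through the non-additive rule

    I_a = HC_a(T) + HC_a(S) + (1 - a) HC_a(T) HC_a(S) - HC_a(T, S).

Standard errors come from batching: the combined statistic is recomputed on
independent batches and the SE is the batch SD over sqrt(B).  This route is
deliberately independent of the closed forms it cross-checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from hcsurrogacy import (
    GaussianPairSpec,
    ProbabilityTable2x2,
    ProbitGaussianSpec,
    hc_entropy_discrete,
    nonadditive_joint_under_independence,
    phi_alpha,
)


def _combine(h_t: float, h_s: float, h_joint: float, alpha: float) -> float:
    return nonadditive_joint_under_independence(h_t, h_s, alpha) - h_joint


def _batched(est_fn, n: int, batches: int, rng) -> tuple[float, float]:
    per_batch = n // batches
    vals = np.array([est_fn(per_batch, rng) for _ in range(batches)])
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(batches))


def mc_gaussian_mi(
    spec: GaussianPairSpec, alpha: float, n: int = 1_000_000, seed: int = 0, batches: int = 50
) -> tuple[float, float]:
    cov = np.array(
        [
            [spec.sigma_t**2, spec.rho * spec.sigma_t * spec.sigma_s],
            [spec.rho * spec.sigma_t * spec.sigma_s, spec.sigma_s**2],
        ]
    )
    mean = np.array([spec.mu_t, spec.mu_s])
    joint = stats.multivariate_normal(mean, cov)
    rng = np.random.default_rng(seed)

    def one_batch(m, rng):
        ts = rng.multivariate_normal(mean, cov, size=m)
        h_t = phi_alpha(stats.norm.pdf(ts[:, 0], spec.mu_t, spec.sigma_t), alpha).mean()
        h_s = phi_alpha(stats.norm.pdf(ts[:, 1], spec.mu_s, spec.sigma_s), alpha).mean()
        h_j = phi_alpha(joint.pdf(ts), alpha).mean()
        return _combine(h_t, h_s, h_j, alpha)

    return _batched(one_batch, n, batches, rng)


def mc_binary_mi(
    table: ProbabilityTable2x2, alpha: float, n: int = 1_000_000, seed: int = 0, batches: int = 50
) -> tuple[float, float]:
    cells = table.cells()  # order p00, p10, p01, p11; index = t + 2 s
    rng = np.random.default_rng(seed)

    def one_batch(m, rng):
        draws = rng.choice(4, size=m, p=cells)
        freq = np.bincount(draws, minlength=4) / m
        p_t = np.array([freq[0] + freq[2], freq[1] + freq[3]])
        p_s = np.array([freq[0] + freq[1], freq[2] + freq[3]])
        h_t = hc_entropy_discrete(p_t / p_t.sum(), alpha)
        h_s = hc_entropy_discrete(p_s / p_s.sum(), alpha)
        h_j = hc_entropy_discrete(freq / freq.sum(), alpha)
        return _combine(h_t, h_s, h_j, alpha)

    return _batched(one_batch, n, batches, rng)


def mc_probit_mi(
    spec: ProbitGaussianSpec, alpha: float, n: int = 1_000_000, seed: int = 0, batches: int = 50
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    mu_t = float(ndtri(spec.p1))
    denom = np.sqrt(1.0 - spec.rho**2)

    def cond_p1(s):
        return ndtr((mu_t + spec.rho * (s - spec.mu_s) / spec.sigma_s) / denom)

    def one_batch(m, rng):
        s = rng.normal(spec.mu_s, spec.sigma_s, m)
        u = rng.normal(mu_t + spec.rho * (s - spec.mu_s) / spec.sigma_s, denom, m)
        t = (u >= 0).astype(int)
        f_s = stats.norm.pdf(s, spec.mu_s, spec.sigma_s)
        q1 = cond_p1(s)
        f_joint = np.where(t == 1, q1, 1.0 - q1) * f_s
        p_hat = t.mean()
        h_t = hc_entropy_discrete([1 - p_hat, p_hat], alpha)
        h_s = phi_alpha(f_s, alpha).mean()
        h_j = phi_alpha(np.clip(f_joint, 1e-300, None), alpha).mean()
        return _combine(h_t, h_s, h_j, alpha)

    return _batched(one_batch, n, batches, rng)
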