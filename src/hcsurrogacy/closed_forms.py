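"""Closed-form generalized mutual information for three distributional families.

For entropy order ``a`` the generalized mutual information is

    I_a(T, S) = HC_a(T) + HC_a(S) + (1 - a) HC_a(T) HC_a(S) - HC_a(T, S)

which is zero exactly under independence, and the information-theoretic
measure of association (ITMA) maps it onto [0, 1):

    R_a^2 = 1 - exp(-2 I_a(T, S)).

Closed forms are provided for

* a bivariate normal pair (T, S),
* a pair of binary endpoints given by a 2x2 joint table, and
* a binary endpoint with a latent-normal (probit) link to a continuous
  Gaussian surrogate.

Notable differences from the Shannon special case (a = 1): for a != 1 the
Gaussian and probit values depend on the marginal standard deviations, not
just on the correlation, and for a < 1 the Gaussian value stays bounded as
|rho| -> 1, which allows a normalized ITMA on [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import ndtr, ndtri, owens_t, roots_hermite  # noqa: F401

from .entropy import AlphaOrder, as_order, hc_entropy_discrete, hc_entropy_gaussian

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianPairSpec",
    "ProbabilityTable2x2",
    "ProbitGaussianSpec",
    "MutualInfoResult",
    "RhoRangeError",
    "gaussian_mutual_info",
    "binary_mutual_info",
    "binary_table_from_margins_rho",
    "binary_rho_bounds",
    "binary_mi_max",
    "imath_integral",
    "imath_integral_gh",
    "probit_mutual_info",
    "probit_mi_rho_limit",
    "probit_mi_alpha2_owen",
    "itma_from_mi",
    "itma_normalize_discrete_shannon",
]


class RhoRangeError(ValueError):
    """Requested correlation is outside the feasible interval for the margins."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GaussianPairSpec:
    """Bivariate normal (T, S): means, SDs and correlation."""

    mu_t: float = 0.0
    mu_s: float = 0.0
    sigma_t: float = 1.0
    sigma_s: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_t <= 0 or self.sigma_s <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"correlation must lie in [-1, 1], got {self.rho}")


@dataclass(frozen=True)
class ProbabilityTable2x2:
    """Joint distribution of two binary endpoints; first index T, second S."""

    p00: float
    p10: float
    p01: float
    p11: float

    def __post_init__(self) -> None:
        cells = self.cells()
        if np.any(cells < 0):
            raise ValueError(f"cell probabilities must be nonnegative, got {cells}")
        if abs(cells.sum() - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities must sum to 1 within 1e-12, got {cells.sum()!r}")

    def cells(self) -> np.ndarray:
        return np.array([self.p00, self.p10, self.p01, self.p11], dtype=float)

    @property
    def margin_t(self) -> np.ndarray:
        """(P(T=0), P(T=1))"""
        return np.array([self.p00 + self.p01, self.p10 + self.p11])

    @property
    def margin_s(self) -> np.ndarray:
        """(P(S=0), P(S=1))"""
        return np.array([self.p00 + self.p10, self.p01 + self.p11])

    @property
    def rho(self) -> float:
        """Pearson correlation of the two indicators."""
        p1t, p1s = self.margin_t[1], self.margin_s[1]
        denom = math.sqrt(p1t * (1 - p1t) * p1s * (1 - p1s))
        if denom == 0:
            raise ValueError("correlation undefined for a degenerate margin")
        return (self.p11 - p1t * p1s) / denom

    def transpose(self) -> "ProbabilityTable2x2":
        return ProbabilityTable2x2(self.p00, self.p01, self.p10, self.p11)


@dataclass(frozen=True)
class ProbitGaussianSpec:
    """Binary T through a latent normal U ~ N(mu_T, 1), continuous S ~ N(mu_S, sigma_S^2).

    ``T = 1 iff U >= 0`` so the latent mean is determined by the success
    probability, ``mu_T = Phi^{-1}(p1)`` (recomputed, never stored).  ``rho``
    is the correlation between U and S.
    """

    p1: float
    mu_s: float = 0.0
    sigma_s: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p1 < 1.0:
            raise ValueError(f"success probability must lie strictly in (0, 1), got {self.p1}")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"latent correlation must lie in [-1, 1], got {self.rho}")

    @property
    def p0(self) -> float:
        return 1.0 - self.p1

    @property
    def mu_t(self) -> float:
        return float(ndtri(self.p1))


@dataclass(frozen=True)
class MutualInfoResult:
    """A generalized mutual information value with its ITMA transforms.

    ``itma = 1 - exp(-2 mi)``; ``itma_normalized`` divides by the attainable
    maximum when one exists for the family/order at hand (tagged by
    ``normalization_kind``).

    The value is zero under independence and nonnegative for the Gaussian and
    probit families at every order, and for every family at orders below 1.
    For two binary endpoints at orders above 1, however, strongly discordant
    tables can yield a genuinely *negative* generalized mutual information
    (the non-additive combination rule overshoots the joint entropy); such
    values are reported as computed, with a correspondingly negative ITMA,
    rather than masked.
    """

    alpha: float
    mi: float
    itma: float
    itma_normalized: float | None = None
    normalization_kind: str = "none"

    def __post_init__(self) -> None:
        if self.itma_normalized is not None and self.itma_normalized < self.itma - 1e-12:
            raise ValueError("normalized ITMA cannot be below the raw ITMA")


def itma_from_mi(mi: float) -> float:
    """ITMA transform ``R^2 = 1 - exp(-2 I)``; maps [0, inf] onto [0, 1]."""
    if mi < -1e-12:
        raise ValueError(f"mutual information must be nonnegative, got {mi}")
    mi = max(mi, 0.0)
    return 1.0 - math.exp(-2.0 * mi) if math.isfinite(mi) else 1.0


def itma_normalize_discrete_shannon(r2: float, h_t: float) -> float:
    """Normalize a Shannon ITMA of a discrete endpoint by its cap ``1 - e^{-2 h(T)}``."""
    if h_t <= 0:
        raise ValueError("Shannon entropy of the endpoint must be positive (non-degenerate)")
    return r2 / (1.0 - math.exp(-2.0 * h_t))


def _clamp_mi(mi: float) -> float:
    if -1e-12 < mi < 0.0:
        logger.debug("clamping tiny negative mutual information %r to 0", mi)
        return 0.0
    return mi


def _result(order: AlphaOrder, mi: float, mi_max: float | None = None, kind: str = "none"):
    mi = _clamp_mi(mi)
    itma = 1.0 - math.exp(-2.0 * mi) if math.isfinite(mi) else 1.0
    normalized = None
    if mi >= 0 and mi_max is not None and math.isfinite(mi_max) and mi_max > 0:
        normalized = itma / (1.0 - math.exp(-2.0 * mi_max))
    else:
        kind = "none"
    return MutualInfoResult(
        alpha=order.alpha,
        mi=mi,
        itma=itma,
        itma_normalized=normalized,
        normalization_kind=kind,
    )


# ---------------------------------------------------------------------------
# Gaussian pair


def gaussian_mutual_info(
    spec: GaussianPairSpec, order: float | AlphaOrder
) -> MutualInfoResult:
    """Generalized mutual information of a bivariate normal pair.

    For ``a != 1``::

        I_a = (2 pi sigma_T sigma_S)^(1-a) / (a (1-a)) * [1 - (1-rho^2)^((1-a)/2)]

    and the Shannon branch gives the textbook ``-log(1 - rho^2) / 2``.  At
    ``|rho| = 1`` the value is infinite for a >= 1 and equals the finite
    supremum ``(2 pi sigma_T sigma_S)^(1-a) / (a (1-a))`` for a < 1; that
    supremum is also what the ``a < 1`` normalized ITMA divides through.
    """
    order = as_order(order)
    rho2 = spec.rho * spec.rho

    if order.is_shannon:
        mi = math.inf if rho2 >= 1.0 else -0.5 * math.log1p(-rho2)
        return _result(order, mi)

    a = order.alpha
    pref = (2.0 * math.pi * spec.sigma_t * spec.sigma_s) ** (1.0 - a) / (a * (1.0 - a))
    if rho2 >= 1.0:
        mi = math.inf if a > 1 else pref
    else:
        mi = pref * (1.0 - (1.0 - rho2) ** ((1.0 - a) / 2.0))
    if a < 1:
        # the supremum of I_a over rho is the prefactor itself
        return _result(order, mi, mi_max=pref, kind="alpha_lt1_sup")
    return _result(order, mi)


# ---------------------------------------------------------------------------
# binary pair


def binary_mutual_info(
    table: ProbabilityTable2x2, order: float | AlphaOrder
) -> MutualInfoResult:
    """Generalized mutual information of two binary endpoints.

    ``I_a = [ (sum_t p_{t+}^a)(sum_s p_{+s}^a) - sum_{ts} p_{ts}^a ] / (1-a)``
    for a != 1; the Shannon branch is computed exactly from the discrete
    entropy decomposition ``h(T) + h(S) - h(T,S)``.  The normalized ITMA
    divides by the maximum attainable over tables with the same margins.
    """
    order = as_order(order)
    cells = table.cells()
    mt, ms = table.margin_t, table.margin_s
    if order.is_shannon:
        mi = (
            hc_entropy_discrete(mt, order)
            + hc_entropy_discrete(ms, order)
            - hc_entropy_discrete(cells, order)
        )
    else:
        a = order.alpha
        pos = cells[cells > 0]
        mi = ((mt**a).sum() * (ms**a).sum() - (pos**a).sum()) / (1.0 - a)
    mi_max = None
    if 0 < mt[1] < 1 and 0 < ms[1] < 1:
        mi_max = binary_mi_max(mt[1], ms[1], order)
    return _result(order, mi, mi_max=mi_max, kind="binary_max")


def binary_rho_bounds(p1_t: float, p1_s: float) -> tuple[float, float]:
    """Feasible interval for the indicator correlation given the two margins.

    The joint cell ``p11 = p1_T p1_S + rho * D`` (D the product of margin SDs)
    must keep all four cells in [0, 1], which yields
    ``max(-p1 q1, -p0 q0) / D <= rho <= min(p1 q0, p0 q1) / D`` in terms of the
    success margins ``p = p1_T`` and ``q = p1_S``.
    """
    for name, p in (("p1_T", p1_t), ("p1_S", p1_s)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")
    p0t, p0s = 1.0 - p1_t, 1.0 - p1_s
    d = math.sqrt(p1_t * p0t * p1_s * p0s)
    lo = max(-p1_t * p1_s, -p0t * p0s, p1_t * p0s - 1.0, p0t * p1_s - 1.0) / d
    hi = min(p1_t * p0s, p0t * p1_s, 1.0 - p1_t * p1_s, 1.0 - p0t * p0s) / d
    return lo, hi


def binary_table_from_margins_rho(
    p1_t: float, p1_s: float, rho: float
) -> ProbabilityTable2x2:
    """Reconstruct the 2x2 joint table from its margins and indicator correlation.

    Exact round-trip with :attr:`ProbabilityTable2x2.rho`.  A correlation
    outside the feasible interval raises :class:`RhoRangeError` naming the
    admissible range.
    """
    lo, hi = binary_rho_bounds(p1_t, p1_s)
    if not lo - 1e-12 <= rho <= hi + 1e-12:
        raise RhoRangeError(
            f"rho={rho} infeasible for margins p1_T={p1_t}, p1_S={p1_s}; "
            f"admissible interval is [{lo:.6f}, {hi:.6f}]"
        )
    p0t, p0s = 1.0 - p1_t, 1.0 - p1_s
    d = math.sqrt(p1_t * p0t * p1_s * p0s)
    shift = rho * d
    cells = np.array(
        [
            p0t * p0s + shift,  # p00
            p1_t * p0s - shift,  # p10
            p0t * p1_s - shift,  # p01
            p1_t * p1_s + shift,  # p11
        ]
    )
    cells = np.clip(cells, 0.0, 1.0)
    cells /= cells.sum()
    return ProbabilityTable2x2(*cells)


def binary_mi_max(p1_t: float, p1_s: float, order: float | AlphaOrder) -> float:
    """Maximum generalized mutual information over tables with the given margins.

    Equals the independence part of I_a minus the minimum of ``HC_a(T, S)``
    over the feasible correlation interval.  The joint entropy is concave in
    rho (each cell is linear in rho), so its minimum sits at one of the two
    interval endpoints; both are evaluated and the smaller taken, which also
    covers the degenerate case where the derivative sign test is exactly zero
    (e.g. symmetric margins).
    """
    order = as_order(order)
    lo, hi = binary_rho_bounds(p1_t, p1_s)
    joint_entropies = [
        hc_entropy_discrete(binary_table_from_margins_rho(p1_t, p1_s, r).cells(), order)
        for r in (lo, hi)
    ]
    h_t = hc_entropy_discrete([1.0 - p1_t, p1_t], order)
    h_s = hc_entropy_discrete([1.0 - p1_s, p1_s], order)
    a = order.alpha if not order.is_shannon else 1.0
    independent_part = h_t + h_s + (1.0 - a) * h_t * h_s
    return independent_part - min(joint_entropies)


# ---------------------------------------------------------------------------
# probit (binary T, Gaussian S)


def imath_integral(a: float, b: float, order: float | AlphaOrder) -> float:
    """The probit kernel integral ``int Phi^alpha(a + b y) phi(y) dy``.

    Evaluated by adaptive quadrature to an absolute tolerance well below
    1e-10.  (Gauss-Hermite rules, the natural first choice for this
    Gaussian-weighted integrand, lose accuracy once ``|b|`` exceeds about 2
    because the composed CDF steepens into a near-kink; see
    :func:`imath_integral_gh`, which is kept as an independent cross-check.)
    For ``b = 0`` the value is exactly ``Phi(a)^alpha``.
    """
    order = as_order(order)
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("imath_integral requires finite arguments")
    if b == 0.0:
        return float(ndtr(a) ** order.alpha)
    alpha = order.alpha

    def integrand(y):
        return float(ndtr(a + b * y)) ** alpha * math.exp(-0.5 * y * y) / math.sqrt(
            2.0 * math.pi
        )

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-13, limit=300)
    return float(val)


def imath_integral_gh(a: float, b: float, order: float | AlphaOrder, nodes: int = 128) -> float:
    """Gauss-Hermite evaluation of the same kernel (cross-check route).

    Accurate to ~1e-10 for moderate slopes (|b| <~ 2) at 128 nodes; degrades
    for steep slopes, which is why :func:`imath_integral` integrates
    adaptively instead.
    """
    alpha = as_order(order).alpha
    z, w = roots_hermite(nodes)
    vals = ndtr(a + b * math.sqrt(2.0) * z) ** alpha
    return float((w * vals).sum() / math.sqrt(math.pi))


def _probit_prefactor(sigma_s: float, a: float) -> float:
    return (2.0 * math.pi * sigma_s * sigma_s) ** ((1.0 - a) / 2.0) / (
        (1.0 - a) * math.sqrt(a)
    )


def probit_mutual_info(
    spec: ProbitGaussianSpec, order: float | AlphaOrder
) -> MutualInfoResult:
    """Generalized mutual information between a probit-linked binary T and Gaussian S.

    For ``a != 1``::

        I_a = (2 pi sigma_S^2)^((1-a)/2) / ((1-a) sqrt(a))
              * sum_t [ p_t^a - imath(a_t, b_t) ]

    with ``a_t = Phi^{-1}(p_t)/sqrt(1-rho^2)`` and
    ``b_t = (-1)^{1-t} rho / (sqrt(a) sqrt(1-rho^2))``.  The Shannon branch
    integrates the conditional Bernoulli entropy against the latent Gaussian
    (scale-free, as Shannon mutual information must be).  At ``|rho| = 1`` the
    caller is directed to :func:`probit_mi_rho_limit`.
    """
    order = as_order(order)
    if abs(spec.rho) >= 1.0:
        raise ValueError(
            "|rho| = 1 is a boundary case; use probit_mi_rho_limit for the limit value"
        )
    rho = spec.rho
    probs = (spec.p0, spec.p1)
    if order.is_shannon:
        mi = 0.0
        denom = math.sqrt(1.0 - rho * rho)
        for t, pt in enumerate(probs):
            sign = 1.0 if t == 1 else -1.0
            thr = float(ndtri(pt))

            def integrand(y, sign=sign, thr=thr):
                q = float(ndtr((thr + sign * rho * y) / denom))
                if q <= 0.0:
                    return 0.0
                return q * math.log(q) * math.exp(-0.5 * y * y) / math.sqrt(2.0 * math.pi)

            val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-13, limit=300)
            mi += val - pt * math.log(pt)
        return _result(order, mi)

    a = order.alpha
    denom = math.sqrt(1.0 - rho * rho)
    total = 0.0
    for t, pt in enumerate(probs):
        sign = 1.0 if t == 1 else -1.0
        a_t = float(ndtri(pt)) / denom
        b_t = sign * rho / (math.sqrt(a) * denom)
        total += pt**a - imath_integral(a_t, b_t, order)
    mi = _probit_prefactor(spec.sigma_s, a) * total
    return _result(order, mi)


def probit_mi_rho_limit(spec: ProbitGaussianSpec, order: float | AlphaOrder) -> float:
    """The finite ``rho -> +/-1`` limit of the probit mutual information (a != 1).

    ``I_a -> pref(a, sigma_S) * { sum_t p_t^a - Phi(sqrt(a) Phi^{-1}(p1))
    - Phi(sqrt(a) Phi^{-1}(p0)) }``; symmetric in the sign of rho.  At the
    Shannon order the mutual information diverges instead, which is reported
    as an error.
    """
    order = as_order(order)
    if order.is_shannon:
        raise ValueError("Shannon mutual information diverges at perfect latent correlation")
    a = order.alpha
    sq = math.sqrt(a)
    total = (
        spec.p0**a
        + spec.p1**a
        - float(ndtr(sq * ndtri(spec.p1)))
        - float(ndtr(sq * ndtri(spec.p0)))
    )
    return _probit_prefactor(spec.sigma_s, a) * total


def probit_mi_alpha2_owen(spec: ProbitGaussianSpec) -> float:
    """Order-2 probit mutual information in closed form through Owen's T function.

    Uses the identity ``imath^(2)(a, b) = Phi(h) - 2 T(h, 1/sqrt(1+2b^2))``
    with ``h = a / sqrt(1 + b^2)``, which collapses (via ``T(h,k) = T(-h,k)``
    and ``Phi(h1) + Phi(h0) = 1``) to

        I_2 = [1 - 4 T(Phi^{-1}(p0)/sqrt(1-rho^2/2), sqrt(1-rho^2))
               - p1^2 - p0^2] / (2 sqrt(pi) sigma_S).

    Agrees with :func:`probit_mutual_info` at order 2 to quadrature accuracy.
    """
    rho2 = spec.rho * spec.rho
    h0 = float(ndtri(spec.p0)) / math.sqrt(1.0 - rho2 / 2.0)
    t_term = float(owens_t(h0, math.sqrt(1.0 - rho2)))
    return (1.0 - 4.0 * t_term - spec.p1**2 - spec.p0**2) / (
        2.0 * math.sqrt(math.pi) * spec.sigma_s
    )


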