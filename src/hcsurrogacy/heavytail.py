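"""A heavy-tailed density with infinite Shannon but finite H-C entropy.

The density is a standard-normal core spliced to logarithmically heavy tails:

    f(x) = phi(x)                   for |x| <= c1
    f(x) = c2 / (|x| (log|x|)^2)    for |x| >  c1

The constants are pinned down by two conditions: continuity at |x| = c1 and
total probability 1.  Because the tail integral from c1 to infinity is
``c2 / log(c1)`` in closed form, the two conditions collapse to a single
scalar root-finding problem

    phi(c1) * c1 * log(c1) = 1 - Phi(c1),      c2 = (1 - Phi(c1)) log(c1).

The differential Shannon entropy of this density diverges (the tail of
``-f log f`` behaves like ``c2 / (x log x)``), while the H-C entropy of any
order alpha > 1 is finite because the density is bounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .entropy import DensitySpec

__all__ = ["HeavyTailDensity", "solve_heavy_tail_constants"]


@dataclass(frozen=True)
class HeavyTailDensity:
    """Piecewise normal-core / log-squared-tail density (see module docstring)."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 <= 1.0:
            raise ValueError("junction point c1 must exceed 1 for the tail to be integrable")
        if self.c2 <= 0:
            raise ValueError("tail constant c2 must be positive")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        core = stats.norm.pdf(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(np.maximum(ax, 1.0 + 1e-15))
            tail = self.c2 / (ax * logs * logs)
        out = np.where(ax <= self.c1, core, tail)
        return out if out.ndim else float(out)

    def tail_mass(self, m: float) -> float:
        """Exact mass of one tail beyond ``m >= c1``: ``c2 / log(m)``."""
        if m < self.c1:
            raise ValueError("tail mass defined for m >= c1")
        return self.c2 / math.log(m)

    def total_mass(self) -> float:
        """Core mass by quadrature plus the two analytic tail masses."""
        core, _ = integrate.quad(self.pdf, -self.c1, self.c1, epsabs=1e-13)
        return core + 2.0 * self.tail_mass(self.c1)

    def continuity_residual(self) -> float:
        return float(stats.norm.pdf(self.c1) - self.c2 / (self.c1 * math.log(self.c1) ** 2))

    def density_spec(self) -> DensitySpec:
        return DensitySpec(
            evaluator=self.pdf,
            support=(-math.inf, math.inf),
            bound=1.0 / math.sqrt(2.0 * math.pi),
            breakpoints=(-self.c1, self.c1),
        )

    def truncated_shannon(self, m: float) -> float:
        """The Shannon integral ``-int_{-m}^{m} f log f`` (grows without bound in m)."""

        def integrand(x):
            p = float(self.pdf(x))
            return -p * math.log(p) if p > 0 else 0.0

        parts = 0.0
        for lo, hi in [(-m, -self.c1), (-self.c1, self.c1), (self.c1, m)]:
            v, _ = integrate.quad(integrand, lo, hi, limit=400)
            parts += v
        return parts


def solve_heavy_tail_constants() -> HeavyTailDensity:
    """Solve the continuity + normalization system for (c1, c2).

    Root-finds ``g(c) = phi(c) c log(c) - (1 - Phi(c))`` on a bracketing
    interval; the root is the junction point and the tail constant follows as
    ``c2 = (1 - Phi(c1)) log(c1)``.  Both residuals are verified below 1e-10.
    """
    g = lambda c: stats.norm.pdf(c) * c * math.log(c) - stats.norm.sf(c)
    # g < 0 just above 1 (log factor vanishes) and > 0 by c = 3: a sign bracket
    c1 = optimize.brentq(g, 1.05, 3.0, xtol=1e-14, rtol=8.9e-16)
    c2 = stats.norm.sf(c1) * math.log(c1)
    density = HeavyTailDensity(c1=c1, c2=c2)
    norm_residual = abs(density.total_mass() - 1.0)
    cont_residual = abs(density.continuity_residual())
    if norm_residual > 1e-10 or cont_residual > 1e-10:
        raise RuntimeError(
            f"heavy-tail constants failed verification: normalization residual "
            f"{norm_residual:.2e}, continuity residual {cont_residual:.2e}"
        )
    return density
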