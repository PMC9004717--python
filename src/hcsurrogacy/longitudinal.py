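"""Trial-level surrogacy of a longitudinal continuous marker for a binary endpoint.

Two quantities are computed for each candidate visit-schedule ("design"):

* ``I_a(T, S | Z)`` — the generalized mutual information between the binary
  clinical endpoint T and the longitudinal surrogate vector S, evaluated
  within each treatment arm and averaged with the empirical arm weights.
  Within an arm the surrogate vector is reduced to a scalar Gaussian index
  via a probit fit (see :func:`single_index_probit_spec`), which puts the
  problem in the binary/Gaussian latent-probit family with a closed form.

* ``I_a(T, Z | S)`` — the Prentice check.  A valid surrogate renders the
  endpoint and the treatment assignment conditionally independent given the
  surrogate, so this quantity should be near zero.  It is estimated from a
  bivariate probit of (T, Z) on the surrogate vector, averaging the
  conditional 2x2 mutual information over the empirical distribution of S.

Both are reported together with their ITMA transform ``1 - exp(-2 I)``.
Permutation nulls (endpoint permuted within arm) calibrate what "near zero"
means for the Prentice measure at a given sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .closed_forms import ProbitGaussianSpec, itma_from_mi, probit_mutual_info
from .entropy import AlphaOrder, as_order
from .probit import BivariateProbitFit, fit_bivariate_probit, fit_probit

logger = logging.getLogger(__name__)

__all__ = [
    "TrialDataset",
    "DesignSubset",
    "SurrogacyReport",
    "single_index_probit_spec",
    "arm_conditional_mi",
    "prentice_conditional_mi",
    "design_sweep",
    "prentice_conditional_null",
    "prentice_permutation_null",
    "arm_mi_permutation_null",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class DesignSubset:
    """An ordered subset of the visit schedule; must start at baseline week 0."""

    visit_weeks: tuple[int, ...]

    def __init__(self, visit_weeks: Sequence[int]) -> None:
        weeks = tuple(int(w) for w in visit_weeks)
        if not weeks:
            raise ValueError("a design needs at least one visit")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"visit weeks must be strictly increasing, got {weeks}")
        if weeks[0] != 0:
            raise ValueError(f"a design must include the baseline week 0, got {weeks}")
        object.__setattr__(self, "visit_weeks", weeks)

    @property
    def label(self) -> str:
        return ", ".join(str(w) for w in self.visit_weeks)


class TrialDataset:
    """Long-format longitudinal surrogate records plus one binary endpoint per subject.

    Parameters
    ----------
    observations
        DataFrame with columns ``subject_id``, ``arm`` (0/1), ``week`` (int),
        ``surrogate`` (float); one row per subject-visit.
    endpoints
        DataFrame with columns ``subject_id`` and ``endpoint`` (0/1).
    """

    def __init__(self, observations: pd.DataFrame, endpoints: pd.DataFrame) -> None:
        obs = observations.copy()
        required = {"subject_id", "arm", "week", "surrogate"}
        if missing := required - set(obs.columns):
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if missing := {"subject_id", "endpoint"} - set(endpoints.columns):
            raise ValueError(f"endpoints missing columns {sorted(missing)}")

        if not obs["arm"].isin((0, 1)).all():
            bad = obs.loc[~obs["arm"].isin((0, 1)), "subject_id"].iloc[0]
            raise ValueError(f"arm must be 0/1; offending subject {bad!r}")
        dup = obs.duplicated(subset=["subject_id", "week"])
        if dup.any():
            row = obs.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate visit for subject {row['subject_id']!r} at week {row['week']}"
            )
        arms_per_subject = obs.groupby("subject_id")["arm"].nunique()
        if (arms_per_subject > 1).any():
            bad = arms_per_subject.idxmax()
            raise ValueError(f"subject {bad!r} appears in more than one arm")

        ep = endpoints.copy()
        if not ep["endpoint"].isin((0, 1)).all():
            bad = ep.loc[~ep["endpoint"].isin((0, 1)), "subject_id"].iloc[0]
            raise ValueError(f"endpoint must be 0/1; offending subject {bad!r}")
        if ep["subject_id"].duplicated().any():
            bad = ep.loc[ep["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate endpoint row for subject {bad!r}")
        known = set(ep["subject_id"])
        orphan = set(obs["subject_id"]) - known
        if orphan:
            raise ValueError(f"subjects without an endpoint record: {sorted(orphan)[:5]}")

        obs["week"] = obs["week"].astype(int)
        obs["arm"] = obs["arm"].astype(int)
        ep["endpoint"] = ep["endpoint"].astype(int)
        self.observations = obs.sort_values(["subject_id", "week"]).reset_index(drop=True)
        self.endpoints = ep.set_index("subject_id")["endpoint"]
        self._arm = obs.groupby("subject_id")["arm"].first()

    @property
    def schedule(self) -> tuple[int, ...]:
        return tuple(sorted(self.observations["week"].unique()))

    @property
    def n_subjects(self) -> int:
        return int(self._arm.size)

    def arm_sizes(self) -> tuple[int, int]:
        counts = self._arm.value_counts()
        return int(counts.get(0, 0)), int(counts.get(1, 0))

    def design_matrix(self, design: DesignSubset):
        """Complete-case wide extraction for a design.

        Returns ``(S, T, Z)``: surrogate matrix (n x k, columns in design
        order), endpoint vector and arm vector.  Subjects missing any design
        visit are dropped (logged).
        """
        missing = set(design.visit_weeks) - set(self.schedule)
        if missing:
            raise ValueError(
                f"design references weeks absent from the data: {sorted(missing)}"
            )
        wide = self.observations.pivot(index="subject_id", columns="week", values="surrogate")
        wide = wide[list(design.visit_weeks)]
        complete = wide.dropna()
        dropped = wide.shape[0] - complete.shape[0]
        if dropped:
            logger.info("design %s: dropped %d incomplete subjects", design.label, dropped)
        ids = complete.index
        return (
            complete.to_numpy(),
            self.endpoints.loc[ids].to_numpy(),
            self._arm.loc[ids].to_numpy(),
        )

    def with_endpoints(self, new_endpoints: pd.Series) -> "TrialDataset":
        ep = new_endpoints.rename("endpoint").rename_axis("subject_id").reset_index()
        return TrialDataset(self.observations, ep)


# ---------------------------------------------------------------------------
# single-index reduction


def single_index_probit_spec(surrogates: np.ndarray, endpoint: np.ndarray) -> ProbitGaussianSpec:
    """Reduce a surrogate vector to the latent-probit scalar family.

    Fits a probit of the endpoint on the surrogate matrix and forms the index
    ``V = gamma' S``.  A probit of the endpoint on the standardized index has
    slope ``b``; the unique single-index Gaussian latent model consistent with
    that fit has latent correlation ``rho = b / sqrt(1 + b^2)``, endpoint rate
    equal to the empirical rate, and (mu_S, sigma_S) the moments of V.
    """
    fit = fit_probit(endpoint, surrogates)
    index = np.atleast_2d(surrogates) @ fit.coefficients
    mu_v = float(index.mean())
    sd_v = float(index.std(ddof=1))
    if sd_v <= 0:
        raise ValueError("the fitted index is constant; surrogate carries no signal")
    standardized = (index - mu_v) / sd_v
    refit = fit_probit(endpoint, standardized[:, None])
    b = float(refit.coefficients[0])
    rho = b / math.sqrt(1.0 + b * b)
    return ProbitGaussianSpec(
        p1=float(np.mean(endpoint)), mu_s=mu_v, sigma_s=sd_v, rho=rho
    )


# ---------------------------------------------------------------------------
# the two conditional measures


def arm_conditional_mi(
    data: TrialDataset, design: DesignSubset, order: float | AlphaOrder
) -> float:
    """Trial-level ``I_a(T, S | Z)``: per-arm probit MI averaged over arms.

    ``I_a(T,S|Z) = I_a(T,S|Z=1) P(Z=1) + I_a(T,S|Z=0) P(Z=0)`` with the
    empirical arm frequencies as weights.
    """
    order = as_order(order)
    surr, endpoint, arm = data.design_matrix(design)
    total = 0.0
    for z in (0, 1):
        mask = arm == z
        if not mask.any():
            raise ValueError(f"arm {z} is empty for design {design.label}")
        t_arm = endpoint[mask]
        if t_arm.min() == t_arm.max():
            raise ValueError(f"endpoint is constant within arm {z}; MI undefined")
        spec = single_index_probit_spec(surr[mask], t_arm)
        mi = probit_mutual_info(spec, order).mi
        total += mi * mask.mean()
    return total


def _prentice_from_fit(
    fit: BivariateProbitFit, surrogates: np.ndarray, order: AlphaOrder
) -> float:
    lp_t, lp_z = fit.linear_predictors(surrogates)
    pt1 = ndtr(lp_t)
    pz1 = ndtr(lp_z)
    from .probit import _cell_probs_from_lp

    p11, p10, p01, p00 = _cell_probs_from_lp(lp_t, lp_z, fit.rho_latent)
    cells = np.stack([p11, p10, p01, p00])
    margins = np.stack([pt1 * pz1, pt1 * (1 - pz1), (1 - pt1) * pz1, (1 - pt1) * (1 - pz1)])
    if order.is_shannon:
        c = np.clip(cells, 1e-300, 1.0)
        m = np.clip(margins, 1e-300, 1.0)
        per_subject = (c * (np.log(c) - np.log(m))).sum(axis=0)
    else:
        a = order.alpha
        per_subject = (margins**a - cells**a).sum(axis=0) / (1.0 - a)
    return float(np.maximum(per_subject, 0.0).mean())


def prentice_conditional_mi(
    data: TrialDataset, design: DesignSubset, order: float | AlphaOrder
) -> float:
    """The Prentice measure ``I_a(T, Z | S)`` for one design.

    Fits a bivariate probit of (T, Z) on the design's surrogate vector and
    averages the conditional 2x2 mutual information

        sum_{t,z} [ p(T=t|S)^a p(Z=z|S)^a - p(T=t,Z=z|S)^a ] / (1-a)

    (Shannon form at a = 1) over the observed surrogate vectors — the
    empirical law of S plays the role of the integrating measure.
    """
    order = as_order(order)
    surr, endpoint, arm = data.design_matrix(design)
    fit = fit_bivariate_probit(endpoint, arm, surr)
    return _prentice_from_fit(fit, surr, order)


# ---------------------------------------------------------------------------
# report sweep


@dataclass
class SurrogacyReport:
    """Cross of designs x orders with both conditional measures and their ITMAs."""

    table: pd.DataFrame
    n_control: int
    n_treatment: int
    alphas: tuple[float, ...]
    failures: dict[str, str] = field(default_factory=dict)

    def wide_frame(self, measure: str = "both") -> pd.DataFrame:
        """Table-style layout: one row per design, paired (MI, ITMA) columns per order."""
        cols = {
            "ts": [("mi_ts_given_z", "itma_ts")],
            "tz": [("mi_tz_given_s", "itma_tz")],
            "both": [("mi_ts_given_z", "itma_ts"), ("mi_tz_given_s", "itma_tz")],
        }[measure]
        pieces = {}
        for mi_col, itma_col in cols:
            for alpha in self.alphas:
                sub = self.table[self.table["alpha"] == alpha].set_index("design")
                pieces[f"{mi_col}[alpha={alpha:g}]"] = sub[mi_col]
                pieces[f"{itma_col}[alpha={alpha:g}]"] = sub[itma_col]
        out = pd.DataFrame(pieces)
        out.index.name = "design"
        # preserve the sweep's design order
        order = self.table["design"].drop_duplicates().tolist()
        return out.loc[[d for d in order if d in out.index]]


def design_sweep(
    data: TrialDataset,
    designs: Sequence[DesignSubset],
    alphas: Sequence[float | AlphaOrder],
) -> SurrogacyReport:
    """Evaluate every design at every entropy order; failures are recorded, not fatal."""
    orders = [as_order(a) for a in alphas]
    rows = []
    failures: dict[str, str] = {}
    for design in designs:
        try:
            surr, endpoint, arm = data.design_matrix(design)
            fit = fit_bivariate_probit(endpoint, arm, surr)
            for order in orders:
                mi_ts = arm_conditional_mi(data, design, order)
                mi_tz = _prentice_from_fit(fit, surr, order)
                rows.append(
                    {
                        "design": design.label,
                        "alpha": order.alpha,
                        "mi_ts_given_z": mi_ts,
                        "itma_ts": itma_from_mi(mi_ts),
                        "mi_tz_given_s": mi_tz,
                        "itma_tz": itma_from_mi(mi_tz),
                    }
                )
        except Exception as exc:  # noqa: BLE001 - a single design must not kill the sweep
            logger.warning("design %s failed: %s", design.label, exc)
            failures[design.label] = str(exc)
    n0, n1 = data.arm_sizes()
    return SurrogacyReport(
        table=pd.DataFrame(rows),
        n_control=n0,
        n_treatment=n1,
        alphas=tuple(o.alpha for o in orders),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# permutation nulls


def _permute_within_arm(data: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    arm = data._arm
    endpoint = data.endpoints.copy()
    for z in (0, 1):
        ids = arm.index[arm == z]
        endpoint.loc[ids] = rng.permutation(endpoint.loc[ids].to_numpy())
    return data.with_endpoints(endpoint)


def prentice_conditional_null(
    data: TrialDataset,
    design: DesignSubset,
    order: float | AlphaOrder,
    n_resamples: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the Prentice measure under T independent of Z given S.

    The Prentice hypothesis is exactly that the endpoint's conditional law
    given the surrogate does not involve the treatment, so the calibrated
    null resamples ``T* ~ Bernoulli(phat(T=1 | S))`` from a probit of T on
    the design's surrogate vector (fit without Z) and recomputes the measure
    on ``(T*, Z, S)``.  Unlike permutation of T, this preserves the T-S
    association, whose strength inflates the sampling spread of the fitted
    latent correlation and hence the noise floor of the plug-in statistic.
    Resamples with a degenerate endpoint or a failed fit are skipped (logged).
    """
    order = as_order(order)
    rng = np.random.default_rng(seed)
    surr, endpoint, arm = data.design_matrix(design)
    null_model = fit_probit(endpoint, surr)
    p_hat = null_model.predict_proba(surr)
    out = []
    for _ in range(n_resamples):
        t_star = (rng.random(p_hat.size) < p_hat).astype(int)
        if t_star.min() == t_star.max():
            continue
        try:
            fit = fit_bivariate_probit(t_star, arm, surr)
            out.append(_prentice_from_fit(fit, surr, order))
        except (RuntimeError, ValueError) as exc:
            logger.info("null resample skipped: %s", exc)
    return np.asarray(out)


def prentice_permutation_null(
    data: TrialDataset,
    design: DesignSubset,
    order: float | AlphaOrder,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the Prentice measure under within-arm endpoint permutation.

    Permuting T within arm severs any T-S and conditional T-Z association
    while preserving the arm-wise endpoint rates, giving a calibrated
    reference for "approximately zero".  Permutations whose bivariate probit
    fit fails are skipped (rare; logged).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        permuted = _permute_within_arm(data, rng)
        try:
            out.append(prentice_conditional_mi(permuted, design, order))
        except (RuntimeError, ValueError) as exc:
            logger.info("permutation skipped: %s", exc)
    return np.asarray(out)


def arm_mi_permutation_null(
    data: TrialDataset,
    design: DesignSubset,
    order: float | AlphaOrder,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the arm-averaged ``I_a(T, S | Z)`` under permutation."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        permuted = _permute_within_arm(data, rng)
        try:
            out.append(arm_conditional_mi(permuted, design, order))
        except (RuntimeError, ValueError) as exc:
            logger.info("permutation skipped: %s", exc)
    return np.asarray(out)
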