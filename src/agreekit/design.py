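"""Sample-size planning for agreement studies on a binary scale.

Two questions are answered, both for the mean pairwise proportion of
agreement ``po`` with R observers who share a common positive rate pi:

* **CI-width mode** -- the smallest number of patients N such that the
  95% (or other level) Wald confidence interval around the anticipated
  agreement has width at most w;
* **power mode** -- the smallest N to reject H0: rho <= rho0 against the
  one-sided alternative rho = rhoA with type-I error alpha and power
  1 - beta, via  Phi( (rhoA - rho0) / SE(rhoA) - z_{1-alpha} ) >= 1 - beta.

Both need the variance of the estimator at N = 1, i.e. the variance of the
per-patient agreement statistic

    a_i = [m_i1 (m_i1 - 1) + m_i2 (m_i2 - 1)] / (R (R - 1)).

The planning model for the distribution of m_i1 is the dichotomous
latent-class model: each patient is truly positive (probability tau) or
truly negative, and the R raters classify independently with a common
error rate, so a positive patient is rated positive with probability h and
a negative one with probability 1 - h.  The two parameters (h, tau) are
pinned down exactly by the planning inputs: h solves
``h^2 + (1-h)^2 = po`` (pairwise agreement) and tau matches the marginal
positive rate pi.  Equivalently this is the unique common-correlation
model in which disjoint observer pairs are uncorrelated; the implied
pairwise kappa is kappa = 1 - (1 - po) / (2 pi (1 - pi)).

Feasibility requires po >= 1 - 2 pi (1 - pi) (otherwise no common-
correlation model with non-negative kappa has marginal pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DesignSpec",
    "DesignResult",
    "InfeasibleDesignError",
    "PlanningModel",
    "variance_model",
    "n_for_ci_width",
    "n_for_power",
    "design_table",
    "simulate_planning_model",
]


class InfeasibleDesignError(ValueError):
    """Raised when no planning model matches the requested inputs."""


@dataclass(frozen=True)
class DesignSpec:
    """Inputs for a sample-size calculation.

    ``mode='ci_width'`` uses ``target`` (expected po), ``width`` and
    ``level``; ``mode='power'`` uses ``rho0 < rhoA``, one-sided ``alpha``
    and ``power``.  ``prevalence`` is the common per-rater positive rate.
    """

    prevalence: float
    mode: str = "ci_width"
    r_range: Sequence[int] = (2,)
    coefficient: str = "po"
    target: float | None = None
    width: float = 0.10
    level: float = 0.95
    rho0: float | None = None
    rhoA: float | None = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise InfeasibleDesignError("prevalence must lie in (0, 1)")
        if any(int(r) < 2 for r in self.r_range):
            raise InfeasibleDesignError("need at least two observers")
        if self.coefficient != "po":
            raise InfeasibleDesignError(
                "sample-size planning is implemented for the proportion of agreement")
        if self.mode == "ci_width":
            if self.target is None:
                raise InfeasibleDesignError("ci_width mode needs a target agreement")
            if not 0 < self.width < 1:
                raise InfeasibleDesignError("interval width must lie in (0, 1)")
            if not 0 < self.level < 1:
                raise InfeasibleDesignError("confidence level must lie in (0, 1)")
        elif self.mode == "power":
            if self.rho0 is None or self.rhoA is None:
                raise InfeasibleDesignError("power mode needs rho0 and rhoA")
            if not self.rhoA > self.rho0:
                raise InfeasibleDesignError("need rhoA > rho0 for a one-sided test")
            if not 0 < self.alpha < 1 or not 0 < self.power < 1:
                raise InfeasibleDesignError("alpha and power must lie in (0, 1)")
        else:
            raise InfeasibleDesignError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class DesignResult:
    """Minimal patient numbers per observer count, with achieved criterion."""

    mode: str
    n_by_raters: dict
    achieved: dict

    def to_frame(self):
        import pandas as pd

        label = "achieved_width" if self.mode == "ci_width" else "achieved_power"
        return pd.DataFrame({
            "n_raters": list(self.n_by_raters),
            "min_patients": list(self.n_by_raters.values()),
            label: [self.achieved[r] for r in self.n_by_raters],
        })

    def to_markdown(self) -> str:
        df = self.to_frame()
        head = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join("---" for _ in df.columns) + "|"
        rows = ["| " + " | ".join(f"{v:g}" if isinstance(v, float) else str(v)
                                  for v in rec) + " |"
                for rec in df.itertuples(index=False)]
        return "\n".join([head, sep, *rows])


class PlanningModel:
    """Latent two-class rating model with marginal pi and pairwise
    agreement po; supplies the m_i1 distribution and Var(a) per patient."""

    def __init__(self, prevalence: float, target_po: float):
        pi = prevalence
        floor = 1 - 2 * pi * (1 - pi)
        if not floor <= target_po <= 1:
            raise InfeasibleDesignError(
                f"target agreement {target_po} is not achievable at prevalence "
                f"{pi}; the common-correlation construction needs po in "
                f"[{floor:.4f}, 1]")
        self.prevalence = pi
        self.target_po = target_po
        self.kappa = 1 - (1 - target_po) / (2 * pi * (1 - pi))
        self.accuracy = 0.5 * (1 + np.sqrt(2 * target_po - 1))
        h = self.accuracy
        self.tau = pi if h == 0.5 else (pi - (1 - h)) / (2 * h - 1)

    def pmf_mi1(self, R: int) -> np.ndarray:
        """Distribution of the number of positive ratings among R raters."""
        m = np.arange(R + 1)
        h = self.accuracy
        return (self.tau * stats.binom.pmf(m, R, h)
                + (1 - self.tau) * stats.binom.pmf(m, R, 1 - h))

    def var_po_per_patient(self, R: int) -> float:
        """Var(a_i): the variance of po-hat is this divided by N."""
        m = np.arange(R + 1)
        a = (m * (m - 1) + (R - m) * (R - m - 1)) / (R * (R - 1))
        p = self.pmf_mi1(R)
        mu = p @ a
        return float(p @ a**2 - mu**2)

    def simulate_mi1(self, R: int, N: int, rng: np.random.Generator) -> np.ndarray:
        truth = rng.random(N) < self.tau
        h = np.where(truth, self.accuracy, 1 - self.accuracy)
        return rng.binomial(R, h)


def variance_model(R: int, prevalence: float, target_po: float) -> float:
    """Per-patient variance of the agreement statistic under the planning
    model; reduces to po(1-po) for R = 2."""
    return PlanningModel(prevalence, target_po).var_po_per_patient(int(R))


def _search_up(start: int, ok) -> int:
    """Smallest integer N >= start with ok(N), assuming ok is monotone."""
    n = max(start, 4)
    while not ok(n):
        n += 1
        if n > 10**7:  # pragma: no cover
            raise InfeasibleDesignError("sample-size search did not converge")
    return n


def n_for_ci_width(spec: DesignSpec) -> DesignResult:
    """Smallest N per R with 2 z_{1-alpha/2} sqrt(Var1/N) <= width."""
    if spec.mode != "ci_width":
        raise InfeasibleDesignError("spec.mode must be 'ci_width'")
    z = stats.norm.ppf(0.5 + spec.level / 2)
    ns, achieved = {}, {}
    for R in spec.r_range:
        v1 = variance_model(R, spec.prevalence, spec.target)
        def ok(n, v1=v1):
            return 2 * z * np.sqrt(v1 / n) <= spec.width
        n = _search_up(4, ok)
        ns[int(R)] = n
        achieved[int(R)] = float(2 * z * np.sqrt(v1 / n))
    return DesignResult("ci_width", ns, achieved)


def n_for_power(spec: DesignSpec) -> DesignResult:
    """Smallest N per R with Phi(delta/SE(rhoA) - z_{1-alpha}) >= power."""
    if spec.mode != "power":
        raise InfeasibleDesignError("spec.mode must be 'power'")
    za = stats.norm.ppf(1 - spec.alpha)
    delta = spec.rhoA - spec.rho0
    ns, achieved = {}, {}
    for R in spec.r_range:
        v1 = variance_model(R, spec.prevalence, spec.rhoA)
        def ok(n, v1=v1):
            return stats.norm.cdf(delta / np.sqrt(v1 / n) - za) >= spec.power
        n = _search_up(4, ok)
        ns[int(R)] = n
        achieved[int(R)] = float(stats.norm.cdf(delta / np.sqrt(v1 / n) - za))
    return DesignResult("power", ns, achieved)


def design_table(spec: DesignSpec) -> DesignResult:
    """Minimal patient numbers across the requested observer range."""
    return n_for_ci_width(spec) if spec.mode == "ci_width" else n_for_power(spec)


def simulate_planning_model(spec: DesignSpec, R: int, N: int, n_reps: int,
                            seed: int) -> dict:
    """Monte-Carlo check of a design cell under the planning model.

    Returns the mean realized Wald CI width (and, in power mode, the
    rejection rate of the one-sided test at rho0) across replicates.
    """
    target = spec.target if spec.mode == "ci_width" else spec.rhoA
    model = PlanningModel(spec.prevalence, target)
    rng = np.random.default_rng(seed)
    z_ci = stats.norm.ppf(0.5 + spec.level / 2)
    za = stats.norm.ppf(1 - spec.alpha)
    widths, rejects = [], []
    for _ in range(n_reps):
        m1 = model.simulate_mi1(R, N, rng)
        a = (m1 * (m1 - 1) + (R - m1) * (R - m1 - 1)) / (R * (R - 1))
        po_hat = a.mean()
        se = np.sqrt(((a - po_hat) ** 2).sum() / (N * (N - 1)))
        widths.append(2 * z_ci * se)
        if spec.mode == "power" and se > 0:
            rejects.append((po_hat - spec.rho0) / se >= za)
    out = {"mean_width": float(np.mean(widths))}
    if spec.mode == "power":
        out["rejection_rate"] = float(np.mean(rejects))
    return out
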