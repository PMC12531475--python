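"""Standard errors and confidence intervals for agreement coefficients.

The workhorse is the delta method.  For a single observer pair the 2x2 cell
proportions are multinomial and every coefficient has a closed-form
large-sample variance:

* ``po``: binomial, po(1-po)/N;
* Cohen's kappa (rater-marginal chance): the Fleiss-Cohen-Everitt variance;
* Scott's pi / intraclass kappa (pooled-marginal chance): the
  Bloch-Kraemer intraclass variance;
* the G index (uniform chance): a linear map of po, variance 4 var(po);
* ppos / pneg: multinomial delta method in closed form.

For R > 2 observers the coefficients are smooth functions of per-patient
means, so their variance is estimated from per-patient influence values
(the linearization used by the irrCAC family of programs): for a statistic
f with patient contributions u_i, ``var = sum (u_i - u_bar)^2 / (N(N-1))``.
Mean-of-pairs specific agreement admits no such linearization; the
bootstrap is the only route there.

Wald intervals follow ``estimate +/- z * SE`` with bounds clamped to the
coefficient's natural range; a Yates-type continuity correction, patient
bootstrap percentile intervals and Fisher-Z intervals are provided as
alternatives for small samples and near-boundary estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import (AgreementDataError, CategoryCounts, ChanceModel, PairTable,
                   RatingsMatrix)
from . import multi as _multi
from . import pair as _pair
from .pair import UndefinedCoefficientError

__all__ = [
    "IntervalEstimate",
    "se_po_pair",
    "se_kappa_pair",
    "se_specific_pair",
    "se_multi",
    "wald_ci",
    "continuity_corrected_ci",
    "bootstrap_ci",
    "fisher_z_ci",
    "evaluate_coefficient",
]

_PROPORTION_BOUNDS = (0.0, 1.0)
_KAPPA_BOUNDS = (-1.0, 1.0)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with standard error and confidence bounds."""

    estimate: float
    se: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "wald_delta"
    clamped: bool = False

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate, "se": self.se, "lower": self.lower,
            "upper": self.upper, "level": self.level, "method": self.method,
            "clamped": self.clamped,
        }


def wald_ci(estimate: float, se: float, level: float = 0.95,
            bounds: tuple = _PROPORTION_BOUNDS,
            method: str = "wald_delta") -> IntervalEstimate:
    """Symmetric normal interval, clamped to the coefficient's range."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = estimate - z * se, estimate + z * se
    clamped = lo < bounds[0] or hi > bounds[1]
    return IntervalEstimate(estimate, se, max(lo, bounds[0]), min(hi, bounds[1]),
                            level, method, clamped)


# ---------------------------------------------------------------------------
# pair-level standard errors
# ---------------------------------------------------------------------------

def se_po_pair(t: PairTable) -> float:
    """Binomial delta-method SE of the proportion of agreement."""
    po = float(_pair.po_pair(t))
    return math.sqrt(po * (1 - po) / t.N)


def se_kappa_pair(t: PairTable, chance: ChanceModel | str) -> float:
    """Large-sample delta-method SE of the pair kappa under each chance model."""
    chance = ChanceModel.parse(chance)
    k = _pair.kappa_pair(t, chance)
    if not k.defined:
        raise UndefinedCoefficientError(f"kappa undefined: {k.reason}")
    if chance is ChanceModel.UNIFORM:
        # kappa1 = 2 po - 1 exactly
        return 2 * se_po_pair(t)
    if chance is ChanceModel.RATER_MARGINALS:
        return _se_cohen_kappa(t)
    return _se_intraclass_kappa(t)


def _se_cohen_kappa(t: PairTable) -> float:
    """Fleiss-Cohen-Everitt variance of Cohen's kappa (not assuming kappa=0)."""
    N = t.N
    p = [[float(t.p11), float(t.p12)], [float(t.p21), float(t.p22)]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    po = p[0][0] + p[1][1]
    pe = row[0] * col[0] + row[1] * col[1]
    qe = 1 - pe
    a = sum(p[i][i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(2))
    b = (1 - po) ** 2 * sum(p[i][j] * (col[i] + row[j]) ** 2
                            for i in range(2) for j in range(2) if i != j)
    c = (po * pe - 2 * pe + po) ** 2
    var = (a + b - c) / (N * qe**4)
    return math.sqrt(max(var, 0.0))


def _se_intraclass_kappa(t: PairTable) -> float:
    """Bloch-Kraemer delta variance of the intraclass (pooled-marginal) kappa."""
    N = t.N
    k = float(_pair.kappa_pair(t, ChanceModel.POOLED_MARGINALS))
    pbar = float(t.p1_dot + t.p_dot1) / 2
    qbar = 1 - pbar
    var = ((1 - k) / N) * ((1 - k) * (1 - 2 * k) + k * (2 - k) / (2 * pbar * qbar))
    return math.sqrt(max(var, 0.0))


def se_specific_pair(t: PairTable, category: str = "pos") -> float:
    """Multinomial delta-method SE of the specific agreement proportion.

    For ppos with s = p12 + p21 and D = 2 p11 + s the variance is
    ``4 p11 s (p11 + s) / (N D^4)``; pneg is symmetric in p22.
    """
    if category not in ("pos", "neg"):
        raise AgreementDataError(f"category must be 'pos' or 'neg', got {category!r}")
    coef = _pair.specific_pos(t) if category == "pos" else _pair.specific_neg(t)
    if not coef.defined:
        raise UndefinedCoefficientError(f"p{category} undefined: {coef.reason}")
    s = float(t.p12 + t.p21)
    joint = float(t.p11) if category == "pos" else float(t.p22)
    D = 2 * joint + s
    var = 4 * joint * s * (joint + s) / (t.N * D**4)
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# multi-rater standard errors (per-patient influence values)
# ---------------------------------------------------------------------------

def _agreement_stat(cc: CategoryCounts) -> np.ndarray:
    m1 = cc.mi1.astype(float)
    r = cc.Ri.astype(float)
    m2 = r - m1
    return (m1 * (m1 - 1) + m2 * (m2 - 1)) / (r * (r - 1))


def _influence_values(m: RatingsMatrix, coefficient: str,
                      chance: ChanceModel | str | None = None) -> tuple[float, np.ndarray]:
    """(estimate, per-patient influence values) for linearizable coefficients."""
    cc = CategoryCounts.from_matrix(m)
    N = cc.n_patients
    a = _agreement_stat(cc)
    po = a.mean()
    m1 = cc.mi1.astype(float)
    r = cc.Ri.astype(float)
    rbar = r.mean()
    p1 = m1.sum() / r.sum()

    if coefficient == "po":
        return po, a
    if coefficient in ("ppos", "pneg"):
        cnt = m1 if coefficient == "ppos" else r - m1
        if cnt.sum() == 0:
            raise UndefinedCoefficientError(f"{coefficient} undefined: empty category")
        u = cnt * (cnt - 1) / (r - 1)
        est = u.sum() / cnt.sum()
        return est, (u - est * cnt) / cnt.mean() + est
    if coefficient == "kappa":
        chance = ChanceModel.parse(chance)
        if chance is ChanceModel.UNIFORM:
            return 2 * po - 1, 2 * a - 1
        if chance is ChanceModel.RATER_MARGINALS:
            return _conger_influence(m, cc, a, po)
        # pooled marginals (Fleiss), variable R_i allowed
        b = (m1 * p1 + (r - m1) * (1 - p1)) / r
        pe = b.mean()
        k = (po - pe) / (1 - pe)
        dpe_dp1 = ((2 * m1 - r) / r).mean()
        p1_infl = (m1 - p1 * r) / rbar
        h = b + dpe_dp1 * p1_infl
        infl = ((a - po) - (1 - k) * (h - pe)) / (1 - pe)
        return k, infl + k
    if coefficient == "ac1":
        qe = 2 * p1 * (1 - p1)
        if qe == 1:
            raise UndefinedCoefficientError("ac1 undefined: chance disagreement is 1")
        est = (po - qe) / (1 - qe)
        dqe_dp1 = 2 * (1 - 2 * p1)
        p1_infl = (m1 - p1 * r) / rbar
        h = dqe_dp1 * p1_infl
        infl = ((a - po) - (1 - est) * h) / (1 - qe)
        return est, infl + est
    raise AgreementDataError(f"no analytic SE for coefficient {coefficient!r}")


def _conger_influence(m: RatingsMatrix, cc: CategoryCounts, a: np.ndarray,
                      po: float) -> tuple[float, np.ndarray]:
    wide = _multi._complete_wide(m)
    X = wide.to_numpy().astype(float)
    N, R = X.shape
    pr = X.mean(axis=0)
    pe = 0.0
    cross = np.zeros(N)
    for r_ in range(R):
        for s_ in range(R):
            if r_ == s_:
                continue
            pe += pr[r_] * pr[s_] + (1 - pr[r_]) * (1 - pr[s_])
            cross += X[:, r_] * pr[s_] + (1 - X[:, r_]) * (1 - pr[s_])
    pe /= R * (R - 1)
    h = 2 * cross / (R * (R - 1)) - pe  # per-patient linearization, mean pe
    k = (po - pe) / (1 - pe)
    infl = ((a - po) - (1 - k) * (h - pe)) / (1 - pe)
    return k, infl + k


def se_multi(m: RatingsMatrix, coefficient: str,
             chance: ChanceModel | str | None = None,
             approach: str = "pooled") -> float:
    """Delta-method SE of a multi-rater coefficient from influence values.

    Supports ``po``, ``kappa`` (any chance model; rater-marginal chance
    needs a complete matrix), pooled ``ppos``/``pneg`` and ``ac1``.
    Mean-of-pairs specific agreement has no analytic SE; request
    :func:`bootstrap_ci` for it.
    """
    if approach == "mean_of_pairs":
        raise AgreementDataError(
            "no analytic standard error exists for mean-of-pairs specific "
            "agreement; use bootstrap_ci")
    est, infl = _influence_values(m, coefficient, chance)
    n = len(infl)
    var = ((infl - infl.mean()) ** 2).sum() / (n * (n - 1))
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# interval constructions
# ---------------------------------------------------------------------------

def continuity_corrected_ci(t: PairTable, level: float = 0.95) -> IntervalEstimate:
    """Wald interval for the pair po widened by 1/(2N) on each side.

    The discreteness of counts makes the plain Wald interval anti-
    conservative at small N; the Yates-type 1/(2N) widening restores
    coverage and vanishes as N grows.
    """
    po = float(_pair.po_pair(t))
    se = se_po_pair(t)
    z = stats.norm.ppf(0.5 + level / 2)
    cc = 1 / (2 * t.N)
    lo, hi = po - z * se - cc, po + z * se + cc
    clamped = lo < 0 or hi > 1
    return IntervalEstimate(po, se, max(lo, 0.0), min(hi, 1.0), level,
                            "wald_delta_cc", clamped)


def fisher_z_ci(estimate: float, se: float, level: float = 0.95) -> IntervalEstimate:
    """Fisher-Z interval: symmetric on the artanh scale, back-transformed.

    Bounds stay inside (-1, 1) without clamping, which helps for
    coefficients near 1 where the Wald interval spills over the boundary.
    """
    if not -1 < estimate < 1:
        raise ValueError("Fisher-Z transform needs |estimate| < 1")
    z = stats.norm.ppf(0.5 + level / 2)
    zeta = math.atanh(estimate)
    se_z = se / (1 - estimate**2)
    return IntervalEstimate(estimate, se, math.tanh(zeta - z * se_z),
                            math.tanh(zeta + z * se_z), level, "fisher_z", False)


def evaluate_coefficient(m: RatingsMatrix, coefficient: str,
                         chance: ChanceModel | str | None = None,
                         approach: str = "pooled") -> float:
    """Point estimate of a named coefficient from a ratings matrix."""
    cc = CategoryCounts.from_matrix(m)
    if coefficient == "po":
        return float(_multi.po_multi(cc))
    if coefficient in ("ppos", "pneg"):
        return float(_multi.specific_multi(cc, coefficient[1:], approach, m))
    if coefficient == "pJ":
        return float(_multi.jaccard_multi(cc, approach, m))
    if coefficient == "kappa":
        return float(_multi.kappa_multi(m, chance))
    if coefficient == "ac1":
        return float(_multi.gwet_ac1(m))
    if coefficient == "kripp_alpha":
        return float(_multi.kripp_alpha_multi(cc))
    raise AgreementDataError(f"unknown coefficient {coefficient!r}")


def bootstrap_ci(m: RatingsMatrix, coefficient: str,
                 chance: ChanceModel | str | None = None,
                 approach: str = "pooled", B: int = 2000,
                 seed: int | None = None, level: float = 0.95) -> IntervalEstimate:
    """Percentile interval from resampling patients with replacement.

    Replicates on which the coefficient is undefined (e.g. a resample
    without positive ratings) are dropped; more than 50% undefined
    replicates aborts with an error.
    """
    if B < 200:
        raise ValueError("use at least B=200 bootstrap replicates")
    if seed is None:
        raise ValueError("bootstrap_ci requires a seed for reproducibility")
    est = evaluate_coefficient(m, coefficient, chance, approach)
    wide = m.wide()
    N = len(wide)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(B):
        idx = rng.integers(0, N, N)
        resampled = wide.iloc[idx].copy()
        resampled.index = [f"b{i}" for i in range(N)]
        mb = RatingsMatrix.from_wide(resampled)
        try:
            values.append(evaluate_coefficient(mb, coefficient, chance, approach))
        except (UndefinedCoefficientError, AgreementDataError):
            continue
    if len(values) < B / 2:
        raise AgreementDataError(
            f"coefficient undefined on {B - len(values)} of {B} bootstrap replicates")
    values = np.asarray(values)
    alpha = 1 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(est, float(values.std(ddof=1)), float(lo), float(hi),
                            level, "bootstrap_percentile", False)
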