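"""Agreement coefficients for R >= 2 observers.

Every coefficient here generalizes its two-observer counterpart by
averaging over all R(R-1)/2 observer pairs and reduces to it when R = 2.
Two generalizations exist for specific agreement:

* ``mean_of_pairs`` -- compute the pair index for every observer pair and
  average the indices (easy to interpret, but the Jaccard identity breaks
  and no analytic standard error exists);
* ``pooled`` -- average numerators and denominators over pairs separately
  and take the ratio (default; preserves pJ = ppos/(2-ppos) and admits a
  delta-method standard error).

With per-patient rating counts ``(m_i1, R_i)`` the key closed forms are

.. math::

    p_o = \\frac1N \\sum_i \\frac{m_{i1}(m_{i1}-1) + m_{i2}(m_{i2}-1)}
                               {R_i(R_i-1)},
    \\qquad
    p_{pos} = \\frac{\\sum_i m_{i1}(m_{i1}-1)/(R_i-1)}{\\sum_i m_{i1}}.

Chance-corrected versions divide out the chance agreement of the uniform,
rater-marginal (Conger/Hubert) or pooled-marginal (Fleiss) coin models;
Gwet's AC1 instead compares observed agreement to pooled-marginal chance
*disagreement*.  All point estimates are exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

from .data import (AgreementDataError, CategoryCounts, ChanceModel,
                   RatingsMatrix, crosstab)
from .pair import (Coefficient, UndefinedCoefficientError, jaccard, po_pair,
                   specific_neg, specific_pos)

__all__ = [
    "MultiEstimate",
    "po_multi",
    "specific_multi",
    "jaccard_multi",
    "chance_multi",
    "kappa_multi",
    "gwet_ac1",
    "kripp_alpha_multi",
]


@dataclass(frozen=True)
class MultiEstimate:
    """A multi-rater coefficient value (exact rational when defined)."""

    id: str
    value: Fraction | None
    approach: str | None = None
    chance: ChanceModel | None = None
    n_patients: int | None = None
    n_raters: int | str | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __float__(self) -> float:
        if self.value is None:
            raise UndefinedCoefficientError(f"{self.id} undefined: {self.reason}")
        return float(self.value)

    def round(self, ndigits: int = 2) -> float:
        return round(float(self), ndigits)


def _meta(cc: CategoryCounts) -> dict:
    R = cc.equal_R
    return {"n_patients": cc.n_patients, "n_raters": R if R is not None else "variable"}


def po_multi(cc: CategoryCounts) -> MultiEstimate:
    """Mean pairwise proportion of agreement.

    Equals the average of the observed agreement over all distinct observer
    pairs (over all jointly available pairs when R_i varies).
    """
    total = Fraction(0)
    for m1, r in zip(cc.mi1, cc.Ri):
        m1, r = int(m1), int(r)
        m2 = r - m1
        total += Fraction(m1 * (m1 - 1) + m2 * (m2 - 1), r * (r - 1))
    return MultiEstimate("po", total / cc.n_patients, **_meta(cc))


def _pair_tables(m: RatingsMatrix) -> dict:
    wide = m.wide()
    return {(a, b): crosstab(m, a, b) for a, b in combinations(wide.columns, 2)}


def specific_multi(cc: CategoryCounts, category: str = "pos",
                   approach: str = "pooled",
                   m: RatingsMatrix | None = None) -> MultiEstimate:
    """Specific agreement on the positive or negative category.

    ``pooled`` needs only the per-patient counts; ``mean_of_pairs`` needs
    the full matrix ``m`` and every pair's index to be defined.
    """
    if category not in ("pos", "neg"):
        raise AgreementDataError(f"category must be 'pos' or 'neg', got {category!r}")
    name = f"p{category}"
    if approach == "pooled":
        counts = cc.mi1 if category == "pos" else cc.mi2
        denom = int(counts.sum())
        if denom == 0:
            return MultiEstimate(name, None, approach=approach, **_meta(cc),
                                 reason=f"no {category}itive ratings at all"
                                 if category == "pos" else "no negative ratings at all")
        num = Fraction(0)
        for k, r in zip(counts, cc.Ri):
            num += Fraction(int(k) * (int(k) - 1), int(r) - 1)
        return MultiEstimate(name, num / denom, approach=approach, **_meta(cc))
    if approach != "mean_of_pairs":
        raise AgreementDataError(f"unknown approach {approach!r}")
    if m is None:
        raise AgreementDataError("approach='mean_of_pairs' needs the ratings matrix")
    fn = specific_pos if category == "pos" else specific_neg
    vals, bad = [], []
    for pair, t in _pair_tables(m).items():
        c = fn(t)
        (vals if c.defined else bad).append(c.value if c.defined else pair)
    if bad:
        return MultiEstimate(name, None, approach=approach, **_meta(cc),
                             reason=f"undefined for pairs {bad}")
    return MultiEstimate(name, sum(vals, Fraction(0)) / len(vals),
                         approach=approach, **_meta(cc))


def jaccard_multi(cc: CategoryCounts, approach: str = "pooled",
                  m: RatingsMatrix | None = None) -> MultiEstimate:
    """Multi-rater Jaccard index.

    The pooled route applies pJ = ppos/(2-ppos) to the pooled ppos, which
    equals pooling the pair-level Jaccard numerators and denominators; the
    mean-of-pairs route averages the pair Jaccards directly (the identity
    then no longer links it to the averaged ppos).
    """
    if approach == "pooled":
        pp = specific_multi(cc, "pos", "pooled")
        if not pp.defined:
            return MultiEstimate("pJ", None, approach=approach, **_meta(cc),
                                 reason=pp.reason)
        return MultiEstimate("pJ", pp.value / (2 - pp.value), approach=approach,
                             **_meta(cc))
    if approach != "mean_of_pairs":
        raise AgreementDataError(f"unknown approach {approach!r}")
    if m is None:
        raise AgreementDataError("approach='mean_of_pairs' needs the ratings matrix")
    vals, bad = [], []
    for pair, t in _pair_tables(m).items():
        c = jaccard(t)
        (vals if c.defined else bad).append(c.value if c.defined else pair)
    if bad:
        return MultiEstimate("pJ", None, approach=approach, **_meta(cc),
                             reason=f"undefined for pairs {bad}")
    return MultiEstimate("pJ", sum(vals, Fraction(0)) / len(vals),
                         approach=approach, **_meta(cc))


def _complete_wide(m: RatingsMatrix):
    wide = m.wide()
    if wide.isna().any().any():
        raise AgreementDataError(
            "rater-marginal chance needs every rater to rate every patient; "
            "use the pooled-marginal model for incomplete data")
    return wide.astype(int)


def chance_multi(m: RatingsMatrix, chance: ChanceModel | str) -> Fraction:
    """Multi-rater chance agreement under the three coin models.

    Rater-marginal chance averages, over ordered rater pairs, the product
    of the two raters' observed category proportions; pooled-marginal
    chance uses the overall proportions (ratings-weighted when R_i varies).
    """
    chance = ChanceModel.parse(chance)
    if chance is ChanceModel.UNIFORM:
        return Fraction(1, 2)
    if chance is ChanceModel.RATER_MARGINALS:
        wide = _complete_wide(m)
        N, R = wide.shape
        pos = [Fraction(int(wide[c].sum()), N) for c in wide.columns]
        total = Fraction(0)
        for r, s in combinations(range(R), 2):
            total += pos[r] * pos[s] + (1 - pos[r]) * (1 - pos[s])
        return total / (R * (R - 1) // 2)
    cc = CategoryCounts.from_matrix(m)
    n_ratings = int(cc.Ri.sum())
    p1 = Fraction(int(cc.mi1.sum()), n_ratings)
    pe = Fraction(0)
    for m1, r in zip(cc.mi1, cc.Ri):
        pe += Fraction(1, int(r)) * (int(m1) * p1 + (int(r) - int(m1)) * (1 - p1))
    return pe / cc.n_patients


def kappa_multi(m: RatingsMatrix, chance: ChanceModel | str) -> MultiEstimate:
    """Multi-rater kappa: uniform -> Randolph/kappa-BP, rater marginals ->
    Conger/Hubert, pooled marginals -> Fleiss."""
    chance = ChanceModel.parse(chance)
    cc = CategoryCounts.from_matrix(m)
    pe = chance_multi(m, chance)
    if pe == 1:
        return MultiEstimate("kappa", None, chance=chance, **_meta(cc),
                             reason="chance agreement is 1")
    po = po_multi(cc).value
    return MultiEstimate("kappa", (po - pe) / (1 - pe), chance=chance, **_meta(cc))


def gwet_ac1(m: RatingsMatrix) -> MultiEstimate:
    """Gwet's AC1: observed agreement against pooled-marginal chance
    *disagreement*, AC1 = (po - qe) / (1 - qe) with qe = 2 p1 p2."""
    cc = CategoryCounts.from_matrix(m)
    qe = 1 - chance_multi(m, ChanceModel.POOLED_MARGINALS)
    if qe == 1:
        return MultiEstimate("ac1", None, **_meta(cc),
                             reason="chance disagreement is 1")
    po = po_multi(cc).value
    return MultiEstimate("ac1", (po - qe) / (1 - qe), **_meta(cc))


def kripp_alpha_multi(cc: CategoryCounts) -> MultiEstimate:
    """Krippendorff's alpha for binary ratings with variable R_i.

    Coincidence-matrix form: observed disagreement weights each patient's
    discordant rating pairs by 1/(R_i - 1); expected disagreement counts
    category pairs sampled without replacement from all n = sum R_i ratings.
    """
    n = int(cc.Ri.sum())
    n1 = int(cc.mi1.sum())
    n2 = n - n1
    de = Fraction(2 * n1 * n2, n * (n - 1))
    if de == 0:
        return MultiEstimate("kripp_alpha", None, **_meta(cc),
                             reason="all ratings identical: no expected disagreement")
    do = Fraction(0)
    for m1, r in zip(cc.mi1, cc.Ri):
        m1, r = int(m1), int(r)
        do += Fraction(2 * m1 * (r - m1), r - 1)
    do = do / n
    return MultiEstimate("kripp_alpha", 1 - do / de, **_meta(cc))
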