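"""Two-observer agreement coefficients.

All point estimates are computed in exact rational arithmetic from the
integer cell counts of a :class:`~agreekit.data.PairTable`; callers convert
to float at the boundary.  Degenerate tables (e.g. no positive rating by
either observer) yield an explicit undefined state carrying the reason,
never a silent NaN or zero.

Implemented coefficients, for a table (n11, n12, n21, n22) with total N:

========================  =====================================================
observed agreement        po = (n11 + n22) / N
positive agreement        ppos = 2 n11 / (2 n11 + n12 + n21)   (Dice / F1)
negative agreement        pneg = 2 n22 / (2 n22 + n12 + n21)
Jaccard                   pJ = n11 / (n11 + n12 + n21) = ppos / (2 - ppos)
Goodman-Kruskal lambda    2 ppos - 1
Rogot-Goldberg            (ppos + pneg) / 2
kappa                     (po - pe) / (1 - pe), pe set by a chance model
Krippendorff alpha        1 - qo/qe with Bessel-corrected chance disagreement
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .data import ChanceModel, PairTable

__all__ = [
    "Coefficient",
    "UndefinedCoefficientError",
    "po_pair",
    "specific_pos",
    "specific_neg",
    "jaccard",
    "lambda_gk",
    "rogot_goldberg",
    "chance_agreement",
    "kappa_pair",
    "kripp_alpha_pair",
]


class UndefinedCoefficientError(ZeroDivisionError):
    """Raised when the float value of an undefined coefficient is requested."""


@dataclass(frozen=True)
class Coefficient:
    """An agreement coefficient value, possibly undefined.

    ``value`` is an exact :class:`~fractions.Fraction` when defined and
    ``None`` otherwise, with ``reason`` explaining the degeneracy.
    """

    id: str
    value: Fraction | None
    chance: ChanceModel | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __float__(self) -> float:
        if self.value is None:
            raise UndefinedCoefficientError(f"{self.id} undefined: {self.reason}")
        return float(self.value)

    def round(self, ndigits: int = 2) -> float:
        """Presentation-layer rounding; estimates stay exact internally."""
        return round(float(self), ndigits)


def po_pair(t: PairTable) -> Coefficient:
    """Proportion of agreement (simple matching coefficient)."""
    return Coefficient("po", Fraction(t.n11 + t.n22, t.N))


def specific_pos(t: PairTable) -> Coefficient:
    """Proportion of positive agreement: p11 over the mean positive marginal."""
    denom = 2 * t.n11 + t.n12 + t.n21
    if denom == 0:
        return Coefficient("ppos", None,
                           reason="no positive rating by either observer")
    return Coefficient("ppos", Fraction(2 * t.n11, denom))


def specific_neg(t: PairTable) -> Coefficient:
    denom = 2 * t.n22 + t.n12 + t.n21
    if denom == 0:
        return Coefficient("pneg", None,
                           reason="no negative rating by either observer")
    return Coefficient("pneg", Fraction(2 * t.n22, denom))


def jaccard(t: PairTable) -> Coefficient:
    """Joint positives over patients positive for at least one observer."""
    denom = t.n11 + t.n12 + t.n21
    if denom == 0:
        return Coefficient("pJ", None,
                           reason="no positive rating by either observer")
    return Coefficient("pJ", Fraction(t.n11, denom))


def lambda_gk(t: PairTable) -> Coefficient:
    ppos = specific_pos(t)
    if not ppos.defined:
        return Coefficient("lambda_gk", None, reason=ppos.reason)
    return Coefficient("lambda_gk", 2 * ppos.value - 1)


def rogot_goldberg(t: PairTable) -> Coefficient:
    """Mean of the positive and negative specific agreements."""
    ppos, pneg = specific_pos(t), specific_neg(t)
    if not (ppos.defined and pneg.defined):
        return Coefficient("rogot_goldberg", None,
                           reason=ppos.reason or pneg.reason)
    return Coefficient("rogot_goldberg", (ppos.value + pneg.value) / 2)


def chance_agreement(t: PairTable, chance: ChanceModel | str) -> Fraction:
    """Proportion of agreement expected by chance under the given model."""
    chance = ChanceModel.parse(chance)
    if chance is ChanceModel.UNIFORM:
        return Fraction(1, 2)
    if chance is ChanceModel.RATER_MARGINALS:
        return t.p1_dot * t.p_dot1 + t.p2_dot * t.p_dot2
    pbar1 = (t.p1_dot + t.p_dot1) / 2
    pbar2 = (t.p2_dot + t.p_dot2) / 2
    return pbar1**2 + pbar2**2


def kappa_pair(t: PairTable, chance: ChanceModel | str) -> Coefficient:
    """Chance-corrected agreement (po - pe) / (1 - pe).

    Uniform chance gives the G index / PABAK (= 2 po - 1), rater marginals
    Cohen's kappa, pooled marginals Scott's pi / the intraclass kappa.
    """
    chance = ChanceModel.parse(chance)
    pe = chance_agreement(t, chance)
    if pe == 1:
        return Coefficient("kappa", None, chance=chance,
                           reason="chance agreement is 1 (all mass in one category)")
    po = po_pair(t).value
    return Coefficient("kappa", (po - pe) / (1 - pe), chance=chance)


def kripp_alpha_pair(t: PairTable) -> Coefficient:
    """Krippendorff's alpha for two observers and binary ratings.

    Same chance model as Scott's pi, but the expected disagreement carries
    Bessel's correction for sampling the NR = 2N ratings without
    replacement: qe = (NR / (NR - 1)) * 2 * pbar1 * pbar2.  Equals the
    coincidence-matrix formulation of alpha and converges to Scott's pi as
    N grows.
    """
    NR = 2 * t.N
    pbar1 = (t.p1_dot + t.p_dot1) / 2
    pbar2 = 1 - pbar1
    qe = Fraction(NR, NR - 1) * 2 * pbar1 * pbar2
    if qe == 0:
        return Coefficient("kripp_alpha", None,
                           reason="all ratings in one category: no expected disagreement")
    qo = 1 - po_pair(t).value
    return Coefficient("kripp_alpha", 1 - qo / qe)
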