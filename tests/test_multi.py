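"""Multi-rater coefficients: worked example, reductions and oracles."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import agreekit as ak
from agreekit.data import AgreementDataError
from tests.conftest import (coincidence_alpha, mean_pair_coefficient,
                            pooled_pair_coefficient, random_matrix)


class TestWorkedExample:
    def test_mean_pairwise_po(self, ctg_counts):
        assert ak.po_multi(ctg_counts).value == Fraction(73, 100)

    def test_po_without_rater_e(self, ctg):
        cc = ak.CategoryCounts.from_matrix(ak.drop_rater(ctg, "E"))
        assert ak.po_multi(cc).value == Fraction(53, 60)
        assert ak.po_multi(cc).round() == 0.88

    def test_pooled_specific_agreement(self, ctg_counts):
        pp = ak.specific_multi(ctg_counts, "pos", "pooled")
        assert pp.value == Fraction(106, 160)
        assert pp.round() == 0.66
        assert ak.jaccard_multi(ctg_counts, "pooled").round() == 0.50

    def test_mean_of_pairs_specific_agreement(self, ctg, ctg_counts):
        pp = ak.specific_multi(ctg_counts, "pos", "mean_of_pairs", ctg)
        assert pp.round() == 0.69
        assert ak.jaccard_multi(ctg_counts, "mean_of_pairs", ctg).round() == 0.56

    def test_subset_ad_pooled(self, ctg):
        sub = ak.drop_rater(ctg, "E")
        cc = ak.CategoryCounts.from_matrix(sub)
        assert ak.specific_multi(cc, "pos", "pooled").value == Fraction(70, 84)
        # exact pooled Jaccard is 35/49 = 0.7143 (the identity value)
        assert ak.jaccard_multi(cc, "pooled").value == Fraction(35, 49)

    def test_chance_def2_and_def3(self, ctg):
        assert float(ak.chance_multi(ctg, "def2")) == pytest.approx(0.5135)
        assert ak.chance_multi(ctg, "def3") == Fraction(13, 25)

    @pytest.mark.parametrize("chance,val", [
        ("def1", 0.46), ("def2", 0.45), ("def3", 0.44)])
    def test_kappas_five_raters(self, ctg, chance, val):
        assert ak.kappa_multi(ctg, chance).round() == val

    @pytest.mark.parametrize("chance,val", [
        ("def1", 0.77), ("def2", 0.74), ("def3", 0.74)])
    def test_kappas_a_to_d(self, ctg, chance, val):
        # def2 exact value is 0.74499, a hair under the printed 0.75
        sub = ak.drop_rater(ctg, "E")
        assert ak.kappa_multi(sub, chance).round() == val

    def test_gwet_ac1(self, ctg):
        ac1 = ak.gwet_ac1(ctg)
        assert ac1.value == (Fraction(73, 100) - Fraction(12, 25)) / (1 - Fraction(12, 25))
        assert ac1.round() == 0.48

    def test_kripp_alpha_close_to_fleiss_kappa(self, ctg, ctg_counts):
        alpha = float(ak.kripp_alpha_multi(ctg_counts))
        k3 = float(ak.kappa_multi(ctg, "def3"))
        assert abs(alpha - k3) < 0.02


class TestReductions:
    """Every multi-rater formula must collapse to its pair version at R=2."""

    def _two_rater(self):
        wide = pd.DataFrame({"x": [1, 1, 0, 0, 1, 0, 1, 0, 0, 0],
                             "y": [1, 0, 0, 1, 1, 0, 1, 0, 1, 0]},
                            index=[f"p{i}" for i in range(10)])
        return ak.RatingsMatrix.from_wide(wide)

    def test_po_and_specific(self):
        m = self._two_rater()
        cc = ak.CategoryCounts.from_matrix(m)
        t = ak.crosstab(m, "x", "y")
        assert ak.po_multi(cc).value == ak.po_pair(t).value
        for cat, fn in [("pos", ak.specific_pos), ("neg", ak.specific_neg)]:
            for approach in ("pooled", "mean_of_pairs"):
                got = ak.specific_multi(cc, cat, approach, m)
                assert got.value == fn(t).value

    def test_kappas_and_alpha(self):
        m = self._two_rater()
        cc = ak.CategoryCounts.from_matrix(m)
        t = ak.crosstab(m, "x", "y")
        for chance in ("def1", "def2", "def3"):
            assert ak.kappa_multi(m, chance).value == ak.kappa_pair(t, chance).value
        assert ak.kripp_alpha_multi(cc).value == ak.kripp_alpha_pair(t).value

    def test_ac1_pair_reduction(self):
        m = self._two_rater()
        t = ak.crosstab(m, "x", "y")
        po = ak.po_pair(t).value
        qe = 1 - ak.chance_agreement(t, "def3")
        assert ak.gwet_ac1(m).value == (po - qe) / (1 - qe)


class TestPairwiseEnumerationOracle:
    """Count-based closed forms equal explicit averages over pair tables."""

    def test_po_equals_mean_over_pairs(self, ctg, ctg_counts):
        assert ak.po_multi(ctg_counts).value == mean_pair_coefficient(ctg, ak.po_pair)

    def test_pooled_specific_equals_pooled_pairs(self, ctg, ctg_counts):
        got = ak.specific_multi(ctg_counts, "pos", "pooled").value
        want = pooled_pair_coefficient(
            ctg, lambda t: t.p11, lambda t: (t.p1_dot + t.p_dot1) / 2)
        assert got == want

    def test_oracles_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = random_matrix(rng, n=10, r=4)
            cc = ak.CategoryCounts.from_matrix(m)
            assert ak.po_multi(cc).value == mean_pair_coefficient(m, ak.po_pair)
            pp = ak.specific_multi(cc, "pos", "pooled")
            if pp.defined:
                want = pooled_pair_coefficient(
                    m, lambda t: t.p11, lambda t: (t.p1_dot + t.p_dot1) / 2)
                assert pp.value == want
            pn = ak.specific_multi(cc, "neg", "pooled")
            if pn.defined:
                want = pooled_pair_coefficient(
                    m, lambda t: t.p22, lambda t: (t.p2_dot + t.p_dot2) / 2)
                assert pn.value == want

    def test_pooled_jaccard_identity_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            m = random_matrix(rng)
            cc = ak.CategoryCounts.from_matrix(m)
            pp = ak.specific_multi(cc, "pos", "pooled")
            pj = ak.jaccard_multi(cc, "pooled")
            if pp.defined:
                assert pj.value == pp.value / (2 - pp.value)


class TestInvariances:
    def test_rater_and_patient_permutations(self, ctg):
        wide = ctg.wide()
        perm = ak.RatingsMatrix.from_wide(
            wide[["D", "B", "E", "A", "C"]].sample(frac=1, random_state=1))
        for chance in ("def1", "def2", "def3"):
            assert (ak.kappa_multi(perm, chance).value
                    == ak.kappa_multi(ctg, chance).value)
        cc, ccp = (ak.CategoryCounts.from_matrix(x) for x in (ctg, perm))
        assert ak.po_multi(cc).value == ak.po_multi(ccp).value
        assert (ak.specific_multi(cc, "pos").value
                == ak.specific_multi(ccp, "pos").value)

    def test_dropping_discordant_rater_raises_agreement(self, ctg):
        # rater E flags twice as many positives; all coefficients rise without E
        sub = ak.drop_rater(ctg, "E")
        cc, ccs = (ak.CategoryCounts.from_matrix(x) for x in (ctg, sub))
        assert ak.po_multi(ccs).value > ak.po_multi(cc).value
        assert (ak.specific_multi(ccs, "pos").value
                > ak.specific_multi(cc, "pos").value)
        for chance in ("def1", "def2", "def3"):
            assert (ak.kappa_multi(sub, chance).value
                    > ak.kappa_multi(ctg, chance).value)

    def test_kappa_ordering_on_complete_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = random_matrix(rng, n=15, r=3)
            k1, k2, k3 = (ak.kappa_multi(m, c) for c in ("def1", "def2", "def3"))
            if k2.defined and k3.defined:
                assert k2.value >= k3.value
            marg = m.wide().mean(axis=0)
            if k1.defined and k2.defined and (
                    (marg >= 0.5).all() or (marg <= 0.5).all()):
                assert k1.value >= k2.value

    def test_all_identical_ratings(self):
        wide = pd.DataFrame(np.ones((6, 3)), index=[f"p{i}" for i in range(6)],
                            columns=list("xyz"))
        m = ak.RatingsMatrix.from_wide(wide)
        cc = ak.CategoryCounts.from_matrix(m)
        assert ak.po_multi(cc).value == 1
        assert not ak.kripp_alpha_multi(cc).defined
        assert float(ak.gwet_ac1(m)) == 1


class TestVariableRi:
    def test_po_with_missing_ratings(self):
        wide = pd.DataFrame([[1, 1, np.nan], [1, 0, 1], [0, 0, 0]],
                            index=list("abc"), columns=list("xyz"))
        cc = ak.CategoryCounts.from_matrix(ak.RatingsMatrix.from_wide(wide))
        # patient a: R=2 both agree; b: 1 of 3 pairs agree; c: all agree
        assert ak.po_multi(cc).value == Fraction(1 + Fraction(1, 3) + 1, 3)

    def test_def2_requires_complete_matrix(self):
        wide = pd.DataFrame([[1, 1, np.nan], [1, 0, 1], [0, 0, 0]],
                            index=list("abc"), columns=list("xyz"))
        m = ak.RatingsMatrix.from_wide(wide)
        with pytest.raises(AgreementDataError, match="pooled-marginal"):
            ak.chance_multi(m, "def2")

    def test_alpha_variable_ri_matches_oracle(self):
        rng = np.random.default_rng(3)
        wide = pd.DataFrame(rng.integers(0, 2, (12, 4)).astype(float),
                            index=[f"p{i}" for i in range(12)], columns=list("wxyz"))
        wide.iloc[0, 0] = np.nan
        wide.iloc[5, 2] = np.nan
        cc = ak.CategoryCounts.from_matrix(ak.RatingsMatrix.from_wide(wide))
        assert ak.kripp_alpha_multi(cc).value == coincidence_alpha(cc.mi1, cc.Ri)

    def test_alpha_converges_to_fleiss_kappa(self):
        # scale the CTG pattern frequencies up: alpha -> kappa3 as N grows
        base_m1 = [5, 5, 5, 5, 4, 3, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        diffs = []
        for factor in (1, 50):
            mi1 = np.repeat(base_m1, factor)
            cc = ak.CategoryCounts(tuple(range(len(mi1))), np.array(mi1),
                                   np.full(len(mi1), 5))
            alpha = float(ak.kripp_alpha_multi(cc))
            po = float(ak.po_multi(cc))
            p1 = mi1.sum() / (5 * len(mi1))
            pe = p1**2 + (1 - p1) ** 2
            diffs.append(abs(alpha - (po - pe) / (1 - pe)))
        assert diffs[1] < diffs[0] / 10
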