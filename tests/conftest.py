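from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

import agreekit as ak


@pytest.fixture(scope="session")
def ctg():
    """The 20 x 5 CTG worked-example matrix."""
    return ak.build_ctg_fixture()


@pytest.fixture(scope="session")
def ctg_counts(ctg):
    return ak.CategoryCounts.from_matrix(ctg)


@pytest.fixture(scope="session")
def table_ac():
    """Printed 2x2 table for obstetricians A and C."""
    return ak.PairTable(6, 0, 3, 11)


def coincidence_alpha(mi1, Ri):
    """Independent oracle: Krippendorff's alpha via the coincidence matrix.

    Builds the 2x2 coincidence matrix over ordered within-patient rating
    pairs (each weighted 1/(R_i - 1)) and applies alpha = 1 - Do/De.
    """
    mi1 = [int(x) for x in mi1]
    Ri = [int(x) for x in Ri]
    o11 = o22 = o12 = Fraction(0)
    for m1, r in zip(mi1, Ri):
        m2 = r - m1
        o11 += Fraction(m1 * (m1 - 1), r - 1)
        o22 += Fraction(m2 * (m2 - 1), r - 1)
        o12 += Fraction(m1 * m2, r - 1)  # ordered pairs: o21 == o12
    n = o11 + o22 + 2 * o12
    n1 = o11 + o12
    n2 = o22 + o12
    do = 2 * o12 / n
    de = 2 * n1 * n2 / (n * (n - 1))
    if de == 0:
        return None
    return 1 - do / de


def mean_pair_coefficient(m, fn):
    """Oracle: explicit enumeration over all R(R-1)/2 pair tables."""
    raters = m.rater_ids
    vals = [fn(ak.crosstab(m, a, b)) for a, b in combinations(raters, 2)]
    return sum((v.value for v in vals), Fraction(0)) / len(vals)


def pooled_pair_coefficient(m, num_fn, den_fn):
    """Oracle: pool pair-level numerators and denominators separately."""
    raters = m.rater_ids
    num = den = Fraction(0)
    for a, b in combinations(raters, 2):
        t = ak.crosstab(m, a, b)
        num += num_fn(t)
        den += den_fn(t)
    return num / den


def random_matrix(rng, n=12, r=4, p=0.4):
    spec = ak.SimulationSpec(n, r, p, icc=0.3, seed=int(rng.integers(2**31)))
    return ak.simulate_common_correlation(spec)
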