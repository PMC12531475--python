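"""Data structures and I/O for binary rating studies.

The atoms of the analysis are:

* :class:`PairTable` -- a 2x2 contingency table of counts for one pair of
  observers (or two occasions of the same observer),
* :class:`RatingsMatrix` -- the full patients x raters table of binary
  ratings, possibly with several assessment occasions per rater and with
  missing entries,
* :class:`CategoryCounts` -- the per-patient sufficient statistics
  ``(m_i1, R_i)`` (number of positive ratings and number of ratings) that
  drive every multi-rater formula.

Conventions: category ``1`` is the positive/abnormal result and ``0`` the
negative/normal one; missing cells are ``NA`` by default in CSV files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgreementDataError",
    "InconsistentTableError",
    "PairTable",
    "RatingsMatrix",
    "CategoryCounts",
    "ChanceModel",
    "read_wide",
    "write_wide",
    "read_long",
    "select_occasion",
    "crosstab",
    "reconstruct_pair_tables",
    "build_ctg_fixture",
    "search_rating_matrix",
    "CTG_POSITIVE_COUNTS",
    "CTG_PAIRWISE_AGREEMENT",
]


class AgreementDataError(ValueError):
    """Raised for invalid or inconsistent rating data."""


class InconsistentTableError(AgreementDataError):
    """Raised when printed summaries cannot correspond to any 2x2 table."""


@dataclass(frozen=True)
class PairTable:
    """2x2 classification table for two observers rating N objects.

    ``n11`` counts objects rated positive by both observers, ``n12``
    positive by observer 1 only, ``n21`` positive by observer 2 only and
    ``n22`` negative by both.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        cells = (self.n11, self.n12, self.n21, self.n22)
        if any(int(c) != c or c < 0 for c in cells):
            raise AgreementDataError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) <= 0:
            raise AgreementDataError("empty table: N must be positive")

    @property
    def N(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    # -- exact proportions ------------------------------------------------
    @property
    def p11(self) -> Fraction:
        return Fraction(self.n11, self.N)

    @property
    def p12(self) -> Fraction:
        return Fraction(self.n12, self.N)

    @property
    def p21(self) -> Fraction:
        return Fraction(self.n21, self.N)

    @property
    def p22(self) -> Fraction:
        return Fraction(self.n22, self.N)

    @property
    def p1_dot(self) -> Fraction:
        """Proportion rated positive by observer 1."""
        return Fraction(self.n11 + self.n12, self.N)

    @property
    def p_dot1(self) -> Fraction:
        """Proportion rated positive by observer 2."""
        return Fraction(self.n11 + self.n21, self.N)

    @property
    def p2_dot(self) -> Fraction:
        return 1 - self.p1_dot

    @property
    def p_dot2(self) -> Fraction:
        return 1 - self.p_dot1

    def swap_categories(self) -> "PairTable":
        """Relabel positive <-> negative for both observers."""
        return PairTable(self.n22, self.n21, self.n12, self.n11)

    def to_text(self) -> str:
        return f"{self.n11} {self.n12} {self.n21} {self.n22}"

    @classmethod
    def from_text(cls, text: str) -> "PairTable":
        parts = text.split()
        if len(parts) != 4:
            raise AgreementDataError(
                f"pair table text must hold four integers 'n11 n12 n21 n22', got {text!r}")
        return cls(*(int(p) for p in parts))


class ChanceModel(enum.Enum):
    """The three standard definitions of agreement expected by chance.

    * ``UNIFORM`` -- both observers toss fair coins (pe = 0.5);
    * ``RATER_MARGINALS`` -- each observer tosses a coin biased to their own
      observed positive rate (Cohen / Conger);
    * ``POOLED_MARGINALS`` -- both observers share a coin biased to the
      average positive rate (Scott / Fleiss).
    """

    UNIFORM = "def1"
    RATER_MARGINALS = "def2"
    POOLED_MARGINALS = "def3"

    @classmethod
    def parse(cls, value: "ChanceModel | str") -> "ChanceModel":
        if isinstance(value, cls):
            return value
        val = str(value).strip().lower()
        aliases = {
            "def1": cls.UNIFORM, "1": cls.UNIFORM, "uniform": cls.UNIFORM,
            "def2": cls.RATER_MARGINALS, "2": cls.RATER_MARGINALS,
            "rater_marginals": cls.RATER_MARGINALS, "cohen": cls.RATER_MARGINALS,
            "conger": cls.RATER_MARGINALS,
            "def3": cls.POOLED_MARGINALS, "3": cls.POOLED_MARGINALS,
            "pooled_marginals": cls.POOLED_MARGINALS, "scott": cls.POOLED_MARGINALS,
            "fleiss": cls.POOLED_MARGINALS,
        }
        try:
            return aliases[val]
        except KeyError:
            raise AgreementDataError(f"unknown chance model {value!r}") from None


@dataclass
class RatingsMatrix:
    """Binary ratings of patients by raters, in long form internally.

    ``frame`` has columns ``patient_id``, ``rater_id``, ``occasion``,
    ``rating`` with ratings in {0, 1}.  Missing ratings are simply absent
    rows.  ``underrated`` lists patients with fewer than two ratings on the
    primary occasion structure; they are flagged, never silently dropped.
    """

    frame: pd.DataFrame
    underrated: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"patient_id", "rater_id", "occasion", "rating"}
        missing = required - set(self.frame.columns)
        if missing:
            raise AgreementDataError(f"ratings frame lacks columns {sorted(missing)}")
        bad = ~self.frame["rating"].isin([0, 1])
        if bad.any():
            row = self.frame[bad].iloc[0]
            raise AgreementDataError(
                f"rating outside {{0,1}} for patient {row['patient_id']!r}, "
                f"rater {row['rater_id']!r}")
        dup = self.frame.duplicated(["patient_id", "rater_id", "occasion"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise AgreementDataError(
                f"duplicate rating for (patient {row['patient_id']!r}, "
                f"rater {row['rater_id']!r}, occasion {row['occasion']!r})")

    # -- basic structure --------------------------------------------------
    @property
    def patient_ids(self) -> list:
        return list(dict.fromkeys(self.frame["patient_id"]))

    @property
    def rater_ids(self) -> list:
        return list(dict.fromkeys(self.frame["rater_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @property
    def has_occasions(self) -> bool:
        per = self.frame.groupby(["patient_id", "rater_id"], sort=False).size()
        return bool((per > 1).any())

    def wide(self) -> pd.DataFrame:
        """Patients x raters table (float with NaN for missing ratings).

        Requires at most one rating per (patient, rater); use
        :func:`select_occasion` first on repeated-assessment data.
        """
        if self.has_occasions:
            raise AgreementDataError(
                "matrix has several occasions per rater; select one with select_occasion()")
        out = self.frame.pivot(index="patient_id", columns="rater_id", values="rating")
        return out.reindex(index=self.patient_ids, columns=self.rater_ids).astype(float)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "RatingsMatrix":
        """Build from a patients x raters table with NaN marking missing."""
        if wide.index.duplicated().any():
            dup = wide.index[wide.index.duplicated()][0]
            raise AgreementDataError(f"duplicate patient id {dup!r}")
        long = wide.stack().rename("rating").reset_index()
        long.columns = ["patient_id", "rater_id", "rating"]
        long["occasion"] = 1
        counts = long.groupby("patient_id", sort=False).size()
        underrated = [p for p in wide.index if counts.get(p, 0) < 2]
        m = cls(long[["patient_id", "rater_id", "occasion", "rating"]].copy(),
                underrated=underrated)
        # preserve full rater/patient sets even when some are all-missing
        m._all_patients = list(wide.index)
        m._all_raters = list(wide.columns)
        return m


@dataclass(frozen=True)
class CategoryCounts:
    """Per-patient sufficient statistics (m_i1 positives out of R_i ratings)."""

    patient_ids: tuple
    mi1: np.ndarray
    Ri: np.ndarray

    def __post_init__(self) -> None:
        mi1 = np.asarray(self.mi1)
        Ri = np.asarray(self.Ri)
        if np.any(mi1 < 0) or np.any(mi1 > Ri):
            raise AgreementDataError("need 0 <= m_i1 <= R_i for every patient")

    @property
    def mi2(self) -> np.ndarray:
        return self.Ri - self.mi1

    @property
    def n_patients(self) -> int:
        return len(self.mi1)

    @property
    def equal_R(self) -> int | None:
        """Common number of raters, or None when R_i varies."""
        uniq = np.unique(self.Ri)
        return int(uniq[0]) if len(uniq) == 1 else None

    @classmethod
    def from_matrix(cls, m: RatingsMatrix) -> "CategoryCounts":
        """Available-case counts; errors on patients with fewer than two ratings."""
        wide = m.wide()
        mi1 = wide.sum(axis=1, skipna=True).to_numpy()
        Ri = wide.notna().sum(axis=1).to_numpy()
        thin = [p for p, r in zip(wide.index, Ri) if r < 2]
        if thin:
            raise AgreementDataError(
                f"patients with fewer than two ratings cannot contribute: {thin}")
        return cls(tuple(wide.index), mi1.astype(int), Ri.astype(int))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_wide(path, *, missing: str = "NA", sep: str = ",",
              category_map: Mapping | None = None) -> RatingsMatrix:
    """Read a wide CSV: first column patient ids, remaining columns raters.

    Cells must parse to 0/1 (optionally through ``category_map``, e.g.
    ``{"normal": 0, "abnormal": 1}``) or equal the ``missing`` token.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise AgreementDataError("wide table needs a patient id column and >= 2 raters")
    ids = raw.iloc[:, 0]
    if ids.duplicated().any():
        raise AgreementDataError(f"duplicate patient id {ids[ids.duplicated()].iloc[0]!r}")
    body = raw.iloc[:, 1:]
    values = np.full(body.shape, np.nan)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            cell = cell.strip()
            if cell == missing or cell == "":
                continue
            if category_map is not None and cell in category_map:
                cell = str(category_map[cell])
            if cell not in ("0", "1"):
                raise AgreementDataError(
                    f"non-binary cell {cell!r} at patient {ids.iloc[i]!r}, rater {col!r}")
            values[i, j] = int(cell)
    wide = pd.DataFrame(values, index=list(ids), columns=list(body.columns))
    return RatingsMatrix.from_wide(wide)


def write_wide(m: RatingsMatrix, path, *, missing: str = "NA", sep: str = ",") -> None:
    """Write the single-occasion wide CSV form (inverse of :func:`read_wide`)."""
    wide = m.wide()
    out = wide.map(lambda v: missing if pd.isna(v) else str(int(v)))
    out.index.name = "patient_id"
    out.to_csv(path, sep=sep)


def read_long(path, *, sep: str = ",") -> RatingsMatrix:
    """Read a long CSV with columns patient_id, rater_id, rating [, occasion]."""
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise AgreementDataError("empty long-format file")
    needed = {"patient_id", "rater_id", "rating"}
    if not needed <= set(df.columns):
        raise AgreementDataError(f"long table needs columns {sorted(needed)}")
    if "occasion" not in df.columns:
        df["occasion"] = 1
    if not df["rating"].isin([0, 1]).all():
        bad = df[~df["rating"].isin([0, 1])].iloc[0]
        raise AgreementDataError(
            f"rating outside {{0,1}} for patient {bad['patient_id']!r}")
    return RatingsMatrix(df[["patient_id", "rater_id", "occasion", "rating"]].copy())


def select_occasion(m: RatingsMatrix, rule: str = "first",
                    seed: int | None = None) -> RatingsMatrix:
    """Keep one assessment per (patient, rater).

    ``rule='first'`` keeps the lowest occasion index; ``rule='random'``
    draws one occasion uniformly and requires ``seed`` so the selection is
    reproducible.  Under interchangeable replicate assessments the two rules
    are equal in distribution.
    """
    if rule not in ("first", "random"):
        raise AgreementDataError(f"unknown occasion rule {rule!r}")
    if rule == "random" and seed is None:
        raise AgreementDataError("rule='random' requires a seed for reproducibility")
    df = m.frame.sort_values(["patient_id", "rater_id", "occasion"], kind="stable")
    if rule == "first":
        kept = df.groupby(["patient_id", "rater_id"], sort=False).head(1)
    else:
        rng = np.random.default_rng(seed)
        pick = df.groupby(["patient_id", "rater_id"], sort=False).size().to_numpy()
        take = np.concatenate([[rng.integers(0, k)] for k in pick])
        offsets = np.concatenate([[0], np.cumsum(pick)[:-1]])
        kept = df.iloc[offsets + take]
    out = kept.copy()
    out["occasion"] = 1
    return RatingsMatrix(out.reset_index(drop=True))


def crosstab(m: RatingsMatrix, rater_a, rater_b) -> PairTable:
    """2x2 table for a rater pair, restricted to jointly rated patients."""
    wide = m.wide()
    for r in (rater_a, rater_b):
        if r not in wide.columns:
            raise AgreementDataError(f"unknown rater {r!r}")
    sub = wide[[rater_a, rater_b]]
    if rater_a == rater_b:
        sub = pd.concat([wide[rater_a], wide[rater_a]], axis=1)
    sub = sub.dropna()
    if sub.empty:
        raise AgreementDataError(f"no patient rated by both {rater_a!r} and {rater_b!r}")
    a = sub.iloc[:, 0].to_numpy().astype(int)
    b = sub.iloc[:, 1].to_numpy().astype(int)
    return PairTable(int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum()),
                     int(((a == 0) & (b == 1)).sum()), int(((a == 0) & (b == 0)).sum()))


# ---------------------------------------------------------------------------
# reconstruction from printed summaries
# ---------------------------------------------------------------------------

def reconstruct_pair_tables(marginal_positive_counts: Mapping,
                            pairwise_po: Mapping,
                            N: int) -> dict:
    """Recover each pair's 2x2 table from per-rater positive counts and
    pairwise proportions of agreement.

    For a pair (a, b) with positive counts ``na``, ``nb`` and agreement
    ``po``, the joint positive count is pinned down exactly:
    ``n11 = (N*po - N + na + nb) / 2``.  A parity failure or a value outside
    ``[max(0, na+nb-N), min(na, nb)]`` proves the printed summaries
    inconsistent.  Proportions are handled as exact rationals.
    """
    tables = {}
    for (a, b), po in pairwise_po.items():
        na, nb = marginal_positive_counts[a], marginal_positive_counts[b]
        po = Fraction(po).limit_denominator(10**6)
        num = N * po - N + na + nb
        if num.denominator != 2 and num.denominator != 1:
            raise InconsistentTableError(
                f"pair ({a},{b}): N*po - N + na + nb = {num} is not an even integer")
        n11 = num / 2
        if n11.denominator != 1:
            raise InconsistentTableError(
                f"pair ({a},{b}): implied n11 = {n11} is not an integer")
        n11 = int(n11)
        lo, hi = max(0, na + nb - N), min(na, nb)
        if not lo <= n11 <= hi:
            raise InconsistentTableError(
                f"pair ({a},{b}): implied n11 = {n11} outside feasible range [{lo},{hi}]")
        tables[(a, b)] = PairTable(n11, na - n11, nb - n11, N - na - nb + n11)
    return tables


def search_rating_matrix(marginal_positive_counts: Mapping,
                         pairwise_po: Mapping,
                         N: int) -> pd.DataFrame:
    """Find a binary patients x raters matrix consistent with printed
    per-rater positive counts and all pairwise agreement proportions.

    Solved as an integer feasibility program over the counts of each
    possible per-patient rating pattern (scipy HiGHS backend).  Rows of the
    result are ordered canonically (lexicographically decreasing pattern),
    so the output is deterministic.
    """
    from itertools import product

    from scipy.optimize import Bounds, LinearConstraint, milp

    raters = list(marginal_positive_counts)
    R = len(raters)
    tables = reconstruct_pair_tables(marginal_positive_counts, pairwise_po, N)
    patterns = list(product([0, 1], repeat=R))
    rows, lo = [], []
    rows.append(np.ones(len(patterns)))
    lo.append(N)
    for j, r in enumerate(raters):
        rows.append(np.array([p[j] for p in patterns], float))
        lo.append(marginal_positive_counts[r])
    for (a, b), t in tables.items():
        ia, ib = raters.index(a), raters.index(b)
        rows.append(np.array([p[ia] * p[ib] for p in patterns], float))
        lo.append(t.n11)
    con = LinearConstraint(np.array(rows), lo, lo)
    res = milp(c=np.zeros(len(patterns)), constraints=con,
               integrality=np.ones(len(patterns)), bounds=Bounds(0, N))
    if not res.success:  # pragma: no cover - constraints proven consistent upstream
        raise InconsistentTableError(f"no rating matrix matches the summaries: {res.message}")
    counts = np.round(res.x).astype(int)
    mat = np.array([p for p, c in zip(patterns, counts) for _ in range(c)])
    order = np.lexsort(tuple(mat[:, j] for j in range(R - 1, -1, -1)))[::-1]
    mat = mat[order]
    ids = [f"p{i + 1:02d}" for i in range(N)]
    return pd.DataFrame(mat, index=ids, columns=raters)


# ---------------------------------------------------------------------------
# the CTG worked example
# ---------------------------------------------------------------------------

#: positive ("abnormal") counts out of 20 CTGs for obstetricians A..E
CTG_POSITIVE_COUNTS = {"A": 6, "B": 6, "C": 9, "D": 7, "E": 12}

#: pairwise proportions of agreement among the five obstetricians
CTG_PAIRWISE_AGREEMENT = {
    ("A", "B"): Fraction(90, 100), ("A", "C"): Fraction(85, 100),
    ("A", "D"): Fraction(85, 100), ("A", "E"): Fraction(60, 100),
    ("B", "C"): Fraction(85, 100), ("B", "D"): Fraction(95, 100),
    ("B", "E"): Fraction(50, 100), ("C", "D"): Fraction(90, 100),
    ("C", "E"): Fraction(45, 100), ("D", "E"): Fraction(45, 100),
}


def build_ctg_fixture() -> RatingsMatrix:
    """The 20 x 5 CTG classification matrix of the worked example.

    The matrix is a committed artifact generated with
    :func:`search_rating_matrix` from the published per-rater positive
    counts and pairwise agreement proportions.  Any matrix with those
    sufficient statistics yields identical point estimates for every
    coefficient in this package; multi-rater standard errors additionally
    depend on the joint rating patterns and are therefore fixture-dependent.
    """
    from importlib import resources

    with resources.files("agreekit").joinpath("data/ctg.csv").open() as fh:
        wide = pd.read_csv(fh, index_col=0).astype(float)
    return RatingsMatrix.from_wide(wide)


def drop_rater(m: RatingsMatrix, rater) -> RatingsMatrix:
    """Matrix without one rater's column."""
    if rater not in m.rater_ids:
        raise AgreementDataError(f"unknown rater {rater!r}")
    return RatingsMatrix(m.frame[m.frame["rater_id"] != rater].reset_index(drop=True))
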