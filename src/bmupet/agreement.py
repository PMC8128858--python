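"""Inter-observer agreement statistics for four-category PET/CT readings.

Raters classify each case into one of four categories:

1. low diffuse bone-marrow uptake, no focal lesion(s)
2. low diffuse bone-marrow uptake, focal lesion(s)
3. high diffuse bone-marrow uptake, no focal lesion(s)
4. high diffuse bone-marrow uptake, focal lesion(s)

Agreement is assessed on two dichotomized views: *focal* (categories 2, 4
positive) and *diffuse* (categories 3, 4 positive).  Percentage agreement
and two-rater Cohen's kappa are computed per observer pair; kappa is
undefined when both raters give the same constant rating (expected
agreement 1), and such pairs are flagged and excluded from means rather
than coerced to 0 or 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


class KappaUndefinedError(ValueError):
    """Expected agreement is 1 (both raters constant and identical)."""


VIEWS = {"focal": (2, 4), "diffuse": (3, 4)}


@dataclass
class RatingMatrix:
    """Cases x observers matrix of categories 1–4."""

    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.ratings)
        if df.empty:
            raise ValueError("rating matrix is empty")
        if df.isna().any().any():
            raise ValueError("rating matrix contains missing values")
        vals = df.to_numpy()
        if not np.isin(vals, [1, 2, 3, 4]).all():
            bad = sorted(set(np.unique(vals)) - {1, 2, 3, 4})
            raise ValueError(f"ratings must be in {{1,2,3,4}}; found {bad}")
        self.ratings = df.astype(int)

    @classmethod
    def from_csv(cls, path, index_col: int | None = 0) -> "RatingMatrix":
        return cls(pd.read_csv(path, index_col=index_col))

    @property
    def n_cases(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_observers(self) -> int:
        return self.ratings.shape[1]

    @property
    def observers(self) -> list:
        return list(self.ratings.columns)

    def dichotomize(self, view: str) -> pd.DataFrame:
        """Boolean cases x observers matrix for the given view."""
        try:
            positive = VIEWS[view]
        except KeyError:
            raise ValueError(f"view must be one of {sorted(VIEWS)}, got {view!r}")
        return self.ratings.isin(positive)


@dataclass
class ContingencyTable2x2:
    """Counts for two raters on a yes/no question.

    Rows are rater A (No, Yes), columns rater B (No, Yes):
    ``n11`` No/No, ``n12`` No/Yes, ``n21`` Yes/No, ``n22`` Yes/Yes.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for c in (self.n11, self.n12, self.n21, self.n22):
            if c < 0:
                raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @classmethod
    def from_pair(cls, a, b) -> "ContingencyTable2x2":
        a = np.asarray(a, bool)
        b = np.asarray(b, bool)
        if a.shape != b.shape:
            raise ValueError("paired ratings must have equal length")
        return cls(
            n11=int(np.sum(~a & ~b)),
            n12=int(np.sum(~a & b)),
            n21=int(np.sum(a & ~b)),
            n22=int(np.sum(a & b)),
        )

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.n11, self.n21, self.n12, self.n22)


def percent_agreement(t: ContingencyTable2x2) -> float:
    """Observed agreement (n11 + n22) / total, as a proportion."""
    return (t.n11 + t.n22) / t.total


def cohens_kappa(t: ContingencyTable2x2) -> float:
    """Chance-corrected agreement kappa = (Po − Pe) / (1 − Pe).

    Pe is the product-of-marginals expected agreement.  When both raters
    are constant and identical (Pe = 1) kappa is undefined and
    :class:`KappaUndefinedError` is raised.
    """
    n = t.total
    po = (t.n11 + t.n22) / n
    row_no, row_yes = t.n11 + t.n12, t.n21 + t.n22
    col_no, col_yes = t.n11 + t.n21, t.n12 + t.n22
    pe = (row_no * col_no + row_yes * col_yes) / (n * n)
    if t.n11 == n or t.n22 == n:
        raise KappaUndefinedError(
            "kappa undefined: both raters constant and identical (Pe = 1)"
        )
    return (po - pe) / (1 - pe)


#: Interpretation bands for kappa, closed intervals on the printed scale.
KAPPA_BANDS = (
    (0.00, 0.20, "slight"),
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
    (0.81, 1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Conventional verbal label for a kappa value (< 0: no agreement)."""
    if kappa < 0:
        return "no agreement"
    for lo, hi, name in KAPPA_BANDS:
        if kappa <= hi:
            return name
    raise ValueError(f"kappa must be <= 1, got {kappa}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table display)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PairwiseAgreement:
    """Per-pair PA and kappa plus summary statistics.

    ``table`` has one row per unordered observer pair with columns
    ``observer_a, observer_b, pa, kappa``; kappa is NaN for pairs where it
    is undefined, and those are excluded from ``mean_kappa`` (their number
    is reported in ``n_undefined``).
    """

    table: pd.DataFrame
    mean_pa: float
    min_pa: float
    max_pa: float
    mean_kappa: float
    min_kappa: float
    max_kappa: float
    n_undefined: int


def pairwise_agreement(r: RatingMatrix, view: str) -> PairwiseAgreement:
    """PA and Cohen's kappa over all C(n, 2) observer pairs on one view."""
    if r.n_observers < 2:
        raise ValueError("need at least 2 observers")
    d = r.dichotomize(view)
    rows = []
    for a, b in itertools.combinations(r.observers, 2):
        t = ContingencyTable2x2.from_pair(d[a].to_numpy(), d[b].to_numpy())
        pa = percent_agreement(t)
        try:
            k = cohens_kappa(t)
        except KappaUndefinedError:
            k = np.nan
        rows.append((a, b, pa, k))
    table = pd.DataFrame(rows, columns=["observer_a", "observer_b", "pa", "kappa"])
    kk = table["kappa"].dropna()
    return PairwiseAgreement(
        table=table,
        mean_pa=float(table["pa"].mean()),
        min_pa=float(table["pa"].min()),
        max_pa=float(table["pa"].max()),
        mean_kappa=float(kk.mean()) if len(kk) else float("nan"),
        min_kappa=float(kk.min()) if len(kk) else float("nan"),
        max_kappa=float(kk.max()) if len(kk) else float("nan"),
        n_undefined=int(table["kappa"].isna().sum()),
    )


def majority_vote(r: RatingMatrix, view: str) -> pd.Series:
    """Per-case consensus on a view: 'positive', 'negative' or 'tie'.

    A strict majority decides; an exact split is reported as a tie rather
    than being resolved.
    """
    d = r.dichotomize(view)
    yes = d.sum(axis=1)
    no = r.n_observers - yes
    out = pd.Series(
        np.where(yes > no, "positive", np.where(no > yes, "negative", "tie")),
        index=d.index,
        name=f"majority_{view}",
    )
    return out


@dataclass
class ReferenceAgreement:
    n_agree: int
    n_disagree: int
    n_tie: int
    n_total: int
    #: n_agree / (n_agree + n_disagree); NaN when no case was decided
    proportion: float


def agreement_vs_reference(verdicts, reference) -> ReferenceAgreement:
    """Compare per-case consensus verdicts against a reference classifier.

    ``verdicts`` are 'positive'/'negative'/'tie' strings (ties counted
    separately and excluded from the proportion's denominator);
    ``reference`` is a boolean sequence.
    """
    verdicts = list(verdicts)
    reference = [bool(x) for x in reference]
    if len(verdicts) != len(reference):
        raise ValueError("verdicts and reference must have equal length")
    agree = disagree = tie = 0
    for v, ref in zip(verdicts, reference):
        if v == "tie":
            tie += 1
        elif (v == "positive") == ref:
            agree += 1
        else:
            disagree += 1
    decided = agree + disagree
    return ReferenceAgreement(
        n_agree=agree,
        n_disagree=disagree,
        n_tie=tie,
        n_total=len(verdicts),
        proportion=(agree / decided) if decided else float("nan"),
    )
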