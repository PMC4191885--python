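"""Exact-test machinery shared across the pipeline.

All enrichment decisions in this package reduce to a 2x2 contingency
table tested with Fisher's exact test.  The two-sided p-value follows the
standard point-probability convention: the sum of probabilities of every
table (with the observed margins fixed) whose hypergeometric point
probability does not exceed that of the observed table.

The implementation enumerates the hypergeometric support in exact integer
arithmetic (``math.comb``), so p-values carry no rounding error beyond the
final float division.  Counts are small in every use here (region counts,
gene-set overlaps), so exactness costs nothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "fisher_exact_2x2",
    "odds_ratio_2x2",
    "GeneSet",
    "EnrichmentResult",
    "set_overlap_enrichment",
    "term_enrichment",
]

_SIDES = ("two", "greater", "less")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Unconditioned cross-product odds ratio (a*d)/(b*c).

    Zero-cell convention: ``b*c == 0`` with ``a*d > 0`` gives ``+inf``
    (counts as > 1); ``a*d == 0`` with ``b*c > 0`` gives ``0.0``; both
    products zero gives ``nan`` (direction undefined).
    """
    ad, bc = a * d, b * c
    if bc == 0:
        if ad == 0:
            return float("nan")
        return float("inf")
    return ad / bc


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: str = "two"
) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Parameters
    ----------
    a, b, c, d
        Non-negative cell counts.  Rows and columns may mean anything;
        the test conditions on both margins.
    sided
        ``"two"`` (point-probability two-sided), ``"greater"``
        (upper tail on cell ``a``) or ``"less"`` (lower tail).

    Returns
    -------
    (p_value, odds_ratio)
        Exact p-value and the cross-product odds ratio (see
        :func:`odds_ratio_2x2` for the zero-cell convention).
    """
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}, got {sided!r}")
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative count in 2x2 table: {cells}")
    if any(int(x) != x for x in cells):
        raise ValueError(f"non-integer count in 2x2 table: {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("2x2 table needs at least one positive margin")

    r1 = a + b  # first row margin: cell a varies over the hypergeometric support
    c1 = a + c
    c2 = b + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    # exact integer numerators: N_k = C(c1, k) * C(c2, r1 - k); common
    # denominator C(n, r1)
    nums = [math.comb(c1, k) * math.comb(c2, r1 - k) for k in range(lo, hi + 1)]
    denom = math.comb(n, r1)
    n_obs = nums[a - lo]
    if sided == "two":
        p_num = sum(nk for nk in nums if nk <= n_obs)
    elif sided == "greater":
        p_num = sum(nums[a - lo :])
    else:  # less
        p_num = sum(nums[: a - lo + 1])
    return min(p_num / denom, 1.0), odds_ratio_2x2(a, b, c, d)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set drawn from a stated universe."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.members <= self.universe:
            extra = sorted(self.members - self.universe)[:5]
            raise ValueError(
                f"gene set {self.name!r} has members outside its universe "
                f"(e.g. {extra})"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a 2x2 overlap / term enrichment test."""

    set_x: str
    set_y: str
    overlap: int
    table: tuple[int, int, int, int]
    p_value: float
    odds_ratio: float
    significant: bool


def set_overlap_enrichment(
    x: GeneSet,
    y: GeneSet,
    universe=None,
    sided: str = "two",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Test whether two gene sets overlap more (or less) than chance.

    Builds the table (|X∩Y|, |X\\Y|, |Y\\X|, |U\\(X∪Y)|) over the shared
    universe and delegates to :func:`fisher_exact_2x2`.
    """
    if universe is None:
        universe = x.universe | y.universe
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    xm, ym = x.members & universe, y.members & universe
    if not (x.members <= universe and y.members <= universe):
        raise ValueError("gene-set members must be contained in the universe")
    a = len(xm & ym)
    b = len(xm - ym)
    c = len(ym - xm)
    d = len(universe) - a - b - c
    p, orat = fisher_exact_2x2(a, b, c, d, sided=sided)
    return EnrichmentResult(
        set_x=x.name,
        set_y=y.name,
        overlap=a,
        table=(a, b, c, d),
        p_value=p,
        odds_ratio=orat,
        significant=p < alpha,
    )


def term_enrichment(
    query: GeneSet,
    annotation: dict,
    universe=None,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """One-sided (upper tail) term enrichment of a query set.

    Parameters
    ----------
    query
        Gene set of interest.
    annotation
        Mapping term id -> iterable of gene ids.  Terms with an empty
        gene set are skipped with a warning.
    universe
        Background gene ids; defaults to the query's declared universe.
    correction
        ``"none"`` (raw p only) or ``"BH"`` (adds a Benjamini-Hochberg
        ``q_value`` column; the ``significant`` flag still uses raw p).

    Returns
    -------
    DataFrame sorted by ascending p, ties broken by descending odds
    ratio then lexical term id.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    if universe is None:
        universe = query.universe
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    qm = query.members & universe
    rows = []
    for term in sorted(annotation):
        members = frozenset(annotation[term]) & universe
        if not members:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        a = len(qm & members)
        b = len(qm - members)
        c = len(members - qm)
        d = len(universe) - a - b - c
        p, orat = fisher_exact_2x2(a, b, c, d, sided="greater")
        rows.append(
            {
                "term": term,
                "n_term": len(members),
                "n_query": len(qm),
                "overlap": a,
                "p_value": p,
                "odds_ratio": orat,
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term",
            "n_term",
            "n_query",
            "overlap",
            "p_value",
            "odds_ratio",
            "significant",
        ],
    )
    if df.empty:
        return df
    # deterministic order: p ascending, odds ratio descending, term id
    key = df["odds_ratio"].replace(float("inf"), np.finfo(float).max).fillna(-1.0)
    df = (
        df.assign(_or=-key)
        .sort_values(["p_value", "_or", "term"], kind="mergesort")
        .drop(columns="_or")
        .reset_index(drop=True)
    )
    if correction == "BH":
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
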