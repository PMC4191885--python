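"""Spatial expression-domain classification from ISH annotation tables.

The input is an expert-annotated in situ hybridization (ISH) table: one
row per gene, one column per anatomical sub-region, each cell a
categorical staining intensity (``Undetected``, ``Low``, ``Medium``,
``High``).  The workflow is:

1. binarize the table (``Undetected`` -> 0, any detected level -> 1);
2. derive two mutually exclusive spatial domains from a reciprocal
   marker-gene pair (the region sets where exactly one of the two
   markers is expressed — the Shh+Ptch1-/Shh-Ptch1+ construction);
3. classify every gene by a directional Fisher exact test on its 2x2
   expressed/not-expressed counts over the two domain region sets.

A gene is called an A-pattern gene when its expression is significantly
skewed toward domain A (small two-sided p, cross-product odds ratio > 1)
and it is expressed in strictly more than ``min_a`` A regions;
symmetrically for B.  Regions belonging to neither domain never enter
the contingency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .enrichment import fisher_exact_2x2

__all__ = [
    "INTENSITY_CATEGORIES",
    "read_annotation_table",
    "binarize_annotations",
    "DomainPair",
    "derive_domains",
    "ContingencyTable2x2",
    "gene_contingency",
    "PatternThresholds",
    "classify_pattern_genes",
    "write_pattern_calls",
]

logger = logging.getLogger(__name__)

#: categorical staining intensities and their binary encoding
INTENSITY_CATEGORIES = {"Undetected": 0, "Low": 1, "Medium": 1, "High": 1}

LABEL_A = "A-pattern"
LABEL_B = "B-pattern"
LABEL_NONE = "none"


def read_annotation_table(path, long_format: bool = False) -> pd.DataFrame:
    """Read a categorical ISH annotation table from TSV.

    Wide format (default): first column gene id, header row of region
    ids, cells = intensity category.  Long format: three columns
    (gene, region, intensity).
    """
    if long_format:
        long = pd.read_csv(path, sep="\t", dtype=str)
        long.columns = ["gene", "region", "intensity"]
        table = long.pivot(index="gene", columns="region", values="intensity")
    else:
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate gene ids in annotation table: {dups}")
    if table.columns.duplicated().any():
        raise ValueError("duplicate region ids in annotation table")
    return table


def binarize_annotations(table: pd.DataFrame, missing: str = "zero") -> pd.DataFrame:
    """Convert a categorical annotation table to a binary 0/1 matrix.

    ``Undetected`` maps to 0; ``Low``/``Medium``/``High`` map to 1.

    Parameters
    ----------
    missing
        ``"zero"``: empty/NaN cells become 0 and the count is logged
        (curated ISH exports are routinely incomplete);
        ``"strict"``: any missing cell is an error.
    """
    if missing not in ("zero", "strict"):
        raise ValueError(f"unknown missing-cell policy {missing!r}")
    values = table.to_numpy(dtype=object)
    out = np.zeros(values.shape, dtype=np.int8)
    n_missing = 0
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            cell = values[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                if missing == "strict":
                    raise ValueError(
                        f"missing annotation for gene {table.index[i]!r}, "
                        f"region {table.columns[j]!r} (strict policy)"
                    )
                n_missing += 1
                continue
            try:
                out[i, j] = INTENSITY_CATEGORIES[cell]
            except KeyError:
                raise ValueError(
                    f"unknown intensity category {cell!r} for gene "
                    f"{table.index[i]!r}, region {table.columns[j]!r}"
                ) from None
    if n_missing:
        logger.warning("binarize_annotations: %d missing cells set to 0", n_missing)
    return pd.DataFrame(out, index=table.index.copy(), columns=table.columns.copy())


@dataclass(frozen=True)
class DomainPair:
    """Two disjoint region sets defined by a reciprocal marker pair.

    ``domain_a``: regions where marker_a is expressed and marker_b is
    not; ``domain_b``: the reverse; ``unassigned``: regions expressing
    both or neither marker.
    """

    domain_a: tuple
    domain_b: tuple
    marker_a: str
    marker_b: str
    unassigned: tuple

    def swapped(self) -> "DomainPair":
        """The same partition with the roles of A and B exchanged."""
        return DomainPair(
            domain_a=self.domain_b,
            domain_b=self.domain_a,
            marker_a=self.marker_b,
            marker_b=self.marker_a,
            unassigned=self.unassigned,
        )


def derive_domains(matrix: pd.DataFrame, marker_a: str, marker_b: str) -> DomainPair:
    """Partition regions by the reciprocal expression of two markers."""
    for marker in (marker_a, marker_b):
        if marker not in matrix.index:
            raise KeyError(f"marker gene {marker!r} not in expression matrix")
    va = matrix.loc[marker_a].to_numpy()
    vb = matrix.loc[marker_b].to_numpy()
    regions = matrix.columns
    dom_a = tuple(regions[(va == 1) & (vb == 0)])
    dom_b = tuple(regions[(va == 0) & (vb == 1)])
    unassigned = tuple(r for r in regions if r not in dom_a and r not in dom_b)
    if not dom_a or not dom_b:
        raise ValueError(
            f"marker pair ({marker_a!r}, {marker_b!r}) leaves a domain empty "
            f"(|A|={len(dom_a)}, |B|={len(dom_b)}); classification undefined"
        )
    return DomainPair(dom_a, dom_b, marker_a, marker_b, unassigned)


class ContingencyTable2x2(NamedTuple):
    a: int  # expressed in domain-A regions
    b: int  # expressed in domain-B regions
    c: int  # not expressed in domain-A regions
    d: int  # not expressed in domain-B regions


def gene_contingency(
    matrix: pd.DataFrame, domains: DomainPair, gene: str
) -> ContingencyTable2x2:
    """Expressed/not-expressed counts of one gene over the two domains.

    Regions outside both domains are ignored.
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = matrix.loc[gene]
    a = int(row[list(domains.domain_a)].sum())
    b = int(row[list(domains.domain_b)].sum())
    return ContingencyTable2x2(a, b, len(domains.domain_a) - a, len(domains.domain_b) - b)


@dataclass(frozen=True)
class PatternThresholds:
    """Selection thresholds for pattern-gene classification.

    ``min_a``/``min_b`` are strict lower bounds ("expressed in more
    than N sub-regions" means at least N+1).
    """

    p_threshold: float = 1e-4
    min_a: int = 10
    min_b: int = 15

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_a < 0 or self.min_b < 0:
            raise ValueError("region-count minima must be >= 0")


def classify_pattern_genes(
    matrix: pd.DataFrame,
    domains: DomainPair,
    thresholds: PatternThresholds | None = None,
) -> pd.DataFrame:
    """Classify every gene of the matrix as A-pattern, B-pattern or none.

    For each gene the 2x2 table (a, b, c, d) over the two domain region
    sets is tested with the two-sided Fisher exact test; direction is
    enforced by the cross-product odds ratio and the strict per-domain
    expression minima.  Marker genes are classified like any other gene
    but flagged ``is_marker`` so reports can exclude them.

    Returns a DataFrame with columns gene, a, b, c, d, p_value,
    odds_ratio, label, is_marker (one row per gene, input order).
    """
    if thresholds is None:
        thresholds = PatternThresholds()
    n_a, n_b = len(domains.domain_a), len(domains.domain_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both domains must be non-empty")
    counts_a = matrix[list(domains.domain_a)].to_numpy().sum(axis=1)
    counts_b = matrix[list(domains.domain_b)].to_numpy().sum(axis=1)

    cache: dict[tuple[int, int], tuple[float, float]] = {}
    rows = []
    markers = {domains.marker_a, domains.marker_b}
    for gene, a, b in zip(matrix.index, counts_a, counts_b):
        a, b = int(a), int(b)
        key = (a, b)
        if key not in cache:
            cache[key] = fisher_exact_2x2(a, b, n_a - a, n_b - b, sided="two")
        p, orat = cache[key]
        if p < thresholds.p_threshold and orat > 1 and a > thresholds.min_a:
            label = LABEL_A
        elif p < thresholds.p_threshold and orat < 1 and b > thresholds.min_b:
            label = LABEL_B
        else:
            label = LABEL_NONE
        rows.append(
            {
                "gene": gene,
                "a": a,
                "b": b,
                "c": n_a - a,
                "d": n_b - b,
                "p_value": p,
                "odds_ratio": orat,
                "label": label,
                "is_marker": gene in markers,
            }
        )
    return pd.DataFrame(rows)


def write_pattern_calls(calls: pd.DataFrame, path) -> None:
    """Write pattern calls as TSV (deterministic column order)."""
    cols = ["gene", "a", "b", "c", "d", "p_value", "odds_ratio", "label", "is_marker"]
    calls.to_csv(path, sep="\t", index=False, columns=cols)
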