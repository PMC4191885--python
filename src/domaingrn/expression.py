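"""Differential-expression utilities and knockdown/ChIP integration.

Three steps live here: a pooled-variance two-sample t-test for
stimulation-style expression matrices, the standard Cuffdiff
``gene_exp.diff`` result filter (status == OK and p < 0.05), and the
classification that combines a TF-knockdown DE list with the TF's
ChIP target set.  Sign logic for knockdowns: a direct target that goes
DOWN when the TF is knocked down is activated by the TF; one that goes
UP is repressed.  Which expression column is the knockdown sample is
always explicit configuration — a silent sign flip here would invert
the whole network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "two_group_ttest_de",
    "read_sample_sheet",
    "filter_cuffdiff_table",
    "classify_knockdown_response",
    "RESPONSE_CALLS",
]

RESPONSE_CALLS = (
    "activated-direct-target",
    "repressed-direct-target",
    "indirect",
    "unaffected-target",
    "not-target",
)


def read_sample_sheet(path) -> dict:
    """Two-column TSV (sample, group) -> mapping sample -> group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def two_group_ttest_de(
    matrix: pd.DataFrame,
    groups: dict,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per gene between two sample groups.

    Parameters
    ----------
    matrix
        Genes x samples expression values (log scale assumed).
    groups
        Mapping sample id -> group label.
    equal_var
        Pooled-variance (Student) t by default; Welch when False.

    Returns a DataFrame (gene, mean_a, mean_b, statistic, p_value,
    direction, significant, degenerate, q_value).  Direction is the
    sign of ``mean_b - mean_a``; genes with zero pooled variance are
    flagged degenerate with p = 1.  The BH-adjusted ``q_value`` column
    is informational; the ``significant`` flag uses raw p.
    """
    cols_a = [s for s in matrix.columns if groups.get(s) == group_a]
    cols_b = [s for s in matrix.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(cols_a)} in {group_a!r}, "
            f"{len(cols_b)} in {group_b!r})"
        )
    xa = matrix[cols_a].to_numpy(dtype=float)
    xb = matrix[cols_b].to_numpy(dtype=float)
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise ValueError("expression matrix contains non-finite values")
    import warnings as _warnings

    with _warnings.catch_warnings():
        # constant rows trigger scipy precision warnings; they are caught
        # below and flagged degenerate
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    diff = mean_b - mean_a
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "statistic": t,
            "p_value": p,
            "direction": direction,
            "significant": p < alpha,
            "degenerate": degenerate,
            "q_value": q,
        }
    ).reset_index(drop=True)


_CUFFDIFF_REQUIRED = ("status", "p_value", "value_1", "value_2")


def filter_cuffdiff_table(
    table, knockdown_column: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the standard Cuffdiff result filter and orient directions.

    Keeps rows with ``status == "OK"`` and ``p_value`` strictly below
    ``alpha``.  ``knockdown_column`` names which expression column
    (``"value_1"`` or ``"value_2"``) is the knockdown sample; direction
    is ``down`` when the knockdown value is below the control value.

    ``table`` may be a path to a ``gene_exp.diff``-style TSV or a
    DataFrame with at least status, p_value, value_1, value_2 and a
    gene identifier column (gene, gene_id or test_id).
    """
    if knockdown_column not in ("value_1", "value_2"):
        raise ValueError("knockdown_column must be 'value_1' or 'value_2'")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    for col in _CUFFDIFF_REQUIRED:
        if col not in table.columns:
            raise ValueError(f"Cuffdiff table missing required column {col!r}")
    gene_col = next(
        (c for c in ("gene", "gene_id", "test_id") if c in table.columns), None
    )
    if gene_col is None:
        raise ValueError("Cuffdiff table missing a gene identifier column (gene/gene_id/test_id)")
    keep = (table["status"] == "OK") & (table["p_value"] < alpha)
    df = table.loc[keep].copy()
    control_column = "value_1" if knockdown_column == "value_2" else "value_2"
    kd, ctrl = df[knockdown_column].astype(float), df[control_column].astype(float)
    df["direction"] = np.where(kd < ctrl, "down", np.where(kd > ctrl, "up", "none"))
    df = df.rename(columns={gene_col: "gene"})
    cols = ["gene", "value_1", "value_2", "status", "p_value", "direction"]
    return df[cols].reset_index(drop=True)


def classify_knockdown_response(
    de: pd.DataFrame, targets, universe=None
) -> pd.DataFrame:
    """Integrate a knockdown DE list with a ChIP target set.

    Parameters
    ----------
    de
        DataFrame of differentially expressed genes with at least
        ``gene`` and ``direction`` columns (the output of
        :func:`filter_cuffdiff_table`).  If a ``significant`` column is
        present only significant rows are treated as DE.
    targets
        ChIP target gene ids of the knocked-down TF.
    universe
        Optional full gene list; targets outside the DE list produce
        ``unaffected-target`` rows, remaining universe genes
        ``not-target`` rows.

    Calls: DE & target & down -> activated-direct-target; DE & target
    & up -> repressed-direct-target; DE & non-target -> indirect;
    target & not DE -> unaffected-target; otherwise not-target.
    """
    targets = set(targets)
    if "significant" in de.columns:
        de = de[de["significant"]]
    de_dir = dict(zip(de["gene"], de["direction"]))
    rows = []
    for gene, direction in de_dir.items():
        is_target = gene in targets
        if is_target and direction == "down":
            call = "activated-direct-target"
        elif is_target and direction == "up":
            call = "repressed-direct-target"
        elif not is_target:
            call = "indirect"
        else:  # target with direction "none": no usable sign evidence
            call = "unaffected-target"
        rows.append(
            {"gene": gene, "is_chip_target": is_target, "de_direction": direction, "call": call}
        )
    for gene in sorted(targets - set(de_dir)):
        rows.append(
            {"gene": gene, "is_chip_target": True, "de_direction": "none",
             "call": "unaffected-target"}
        )
    if universe is not None:
        seen = set(de_dir) | targets
        for gene in sorted(set(universe) - seen):
            rows.append(
                {"gene": gene, "is_chip_target": False, "de_direction": "none",
                 "call": "not-target"}
            )
    return pd.DataFrame(
        rows, columns=["gene", "is_chip_target", "de_direction", "call"]
    )
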