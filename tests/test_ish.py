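"""Binarization, marker-derived domains and pattern classification."""

import math

import numpy as np
import pandas as pd
import pytest

from domaingrn.ish import (
    ContingencyTable2x2,
    DomainPair,
    PatternThresholds,
    binarize_annotations,
    classify_pattern_genes,
    derive_domains,
    gene_contingency,
    read_annotation_table,
    write_pattern_calls,
)
from domaingrn.synthetic import SyntheticIshSpec, generate_ish_matrix
from oracles import fisher_two_sided_enumeration


def test_binarize_category_mapping():
    table = pd.DataFrame(
        [["Undetected", "Low", "Medium", "High"]],
        index=["g1"],
        columns=["r1", "r2", "r3", "r4"],
    )
    out = binarize_annotations(table)
    assert out.loc["g1"].tolist() == [0, 1, 1, 1]


def test_binarize_all_undetected_is_zero_matrix():
    table = pd.DataFrame(
        [["Undetected"] * 3] * 2, index=["g1", "g2"], columns=["r1", "r2", "r3"]
    )
    assert not binarize_annotations(table).to_numpy().any()


def test_binarize_unknown_category_names_cell():
    table = pd.DataFrame([["Weak"]], index=["g1"], columns=["r1"])
    with pytest.raises(ValueError, match="'Weak'.*'g1'.*'r1'"):
        binarize_annotations(table)


def test_binarize_missing_cell_policies():
    table = pd.DataFrame([[None, "High"]], index=["g1"], columns=["r1", "r2"])
    assert binarize_annotations(table, missing="zero").loc["g1"].tolist() == [0, 1]
    with pytest.raises(ValueError, match="strict"):
        binarize_annotations(table, missing="strict")


def test_annotation_roundtrip_wide_and_long(tmp_path):
    table = pd.DataFrame(
        [["Undetected", "High"], ["Low", "Medium"]],
        index=pd.Index(["g1", "g2"], name="gene"),
        columns=["r1", "r2"],
    )
    wide = tmp_path / "wide.tsv"
    table.to_csv(wide, sep="\t")
    assert read_annotation_table(wide).equals(table)

    long = tmp_path / "long.tsv"
    table.stack().rename_axis(["gene", "region"]).rename("intensity").reset_index().to_csv(
        long, sep="\t", index=False
    )
    rt = read_annotation_table(long, long_format=True)
    assert rt.loc["g2", "r2"] == "Medium"


# --- domains ----------------------------------------------------------------


def test_derive_domains_basic_partition():
    mat = pd.DataFrame(
        {"r1": [1, 0], "r2": [1, 0], "r3": [0, 1], "r4": [0, 0]},
        index=["mA", "mB"],
    )
    dom = derive_domains(mat, "mA", "mB")
    assert set(dom.domain_a) == {"r1", "r2"}
    assert set(dom.domain_b) == {"r3"}
    assert set(dom.unassigned) == {"r4"}


def test_region_with_both_markers_is_unassigned():
    mat = pd.DataFrame({"r1": [1, 1], "r2": [1, 0], "r3": [0, 1]}, index=["mA", "mB"])
    dom = derive_domains(mat, "mA", "mB")
    assert "r1" in dom.unassigned
    assert "r1" not in dom.domain_a and "r1" not in dom.domain_b


def test_missing_marker_and_empty_domain_errors():
    mat = pd.DataFrame({"r1": [1, 1], "r2": [1, 1]}, index=["mA", "mB"])
    with pytest.raises(KeyError):
        derive_domains(mat, "mA", "nope")
    with pytest.raises(ValueError, match="empty"):
        derive_domains(mat, "mA", "mB")  # markers coincide everywhere


def test_contingency_counts(small_matrix, small_domains):
    assert gene_contingency(small_matrix, small_domains, "mA") == (3, 0, 0, 3)
    assert gene_contingency(small_matrix, small_domains, "gNone") == (0, 0, 3, 3)
    # unassigned region o1 (where gA is expressed) never enters the counts
    assert gene_contingency(small_matrix, small_domains, "gA") == (2, 0, 1, 3)
    with pytest.raises(KeyError):
        gene_contingency(small_matrix, small_domains, "missing")


def test_contingency_is_namedtuple_with_margins(small_matrix, small_domains):
    t = gene_contingency(small_matrix, small_domains, "gB")
    assert isinstance(t, ContingencyTable2x2)
    assert t.a + t.c == 3 and t.b + t.d == 3


# --- classification ---------------------------------------------------------


def _separating_matrix(n_a=20, n_b=30):
    """Markers plus one gene expressed in every A region and no B region."""
    regions = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    rows = {
        "mA": [1] * n_a + [0] * n_b,
        "mB": [0] * n_a + [1] * n_b,
        "sep": [1] * n_a + [0] * n_b,
        "zero": [0] * (n_a + n_b),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=regions)


def test_fully_separating_gene_is_a_pattern():
    mat = _separating_matrix()
    dom = derive_domains(mat, "mA", "mB")
    calls = classify_pattern_genes(mat, dom).set_index("gene")
    sep = calls.loc["sep"]
    expected_p = fisher_two_sided_enumeration(20, 0, 0, 30)
    assert expected_p == pytest.approx(1 / math.comb(50, 20), rel=1e-12)
    assert sep["label"] == "A-pattern"
    assert sep["p_value"] == pytest.approx(expected_p, abs=1e-12)
    assert sep["odds_ratio"] == math.inf


def test_all_zero_gene_is_none_with_p_one():
    mat = _separating_matrix()
    dom = derive_domains(mat, "mA", "mB")
    calls = classify_pattern_genes(mat, dom).set_index("gene")
    assert calls.loc["zero", "label"] == "none"
    assert calls.loc["zero", "p_value"] == pytest.approx(1.0)


def test_label_decided_by_oracle_p_value():
    """Gene with (a, b) = (12, 2) over 20/30: label must match the oracle."""
    mat = _separating_matrix()
    gene = [1] * 12 + [0] * 8 + [1] * 2 + [0] * 28
    mat.loc["g12"] = gene
    dom = derive_domains(mat, "mA", "mB")
    calls = classify_pattern_genes(mat, dom).set_index("gene")
    p_oracle = fisher_two_sided_enumeration(12, 2, 8, 28)
    row = calls.loc["g12"]
    assert row["p_value"] == pytest.approx(p_oracle, abs=1e-10)
    expected = (
        "A-pattern"
        if (p_oracle < 1e-4 and row["odds_ratio"] > 1 and row["a"] > 10)
        else "none"
    )
    assert row["label"] == expected


def test_swapping_domains_mirrors_calls():
    spec = SyntheticIshSpec(seed=11, n_planted_a=30, n_planted_b=60, n_background=200)
    mat, truth = generate_ish_matrix(spec)
    dom = derive_domains(mat, truth.marker_a, truth.marker_b)
    thr = PatternThresholds(min_a=10, min_b=15)
    thr_swapped = PatternThresholds(min_a=thr.min_b, min_b=thr.min_a)
    calls = classify_pattern_genes(mat, dom, thr).set_index("gene")
    mirrored = classify_pattern_genes(mat, dom.swapped(), thr_swapped).set_index("gene")
    swap = {"A-pattern": "B-pattern", "B-pattern": "A-pattern", "none": "none"}
    assert (mirrored["label"] == calls["label"].map(swap)).all()
    assert np.allclose(mirrored["p_value"], calls["p_value"], atol=1e-12)


def test_labels_mutually_exclusive_and_markers_flagged():
    mat, truth = generate_ish_matrix(SyntheticIshSpec(seed=2, n_background=100))
    dom = derive_domains(mat, truth.marker_a, truth.marker_b)
    calls = classify_pattern_genes(mat, dom)
    assert set(calls["label"]) <= {"A-pattern", "B-pattern", "none"}
    flagged = set(calls.loc[calls["is_marker"], "gene"])
    assert flagged == {truth.marker_a, truth.marker_b}


def test_strict_region_minimum_boundary():
    """a = 11 passes 'more than 10'; a = 10 does not, whatever the p-value."""
    n_a, n_b = 20, 30
    mat = _separating_matrix(n_a, n_b)
    mat.loc["g11"] = [1] * 11 + [0] * (n_a - 11) + [0] * n_b
    mat.loc["g10"] = [1] * 10 + [0] * (n_a - 10) + [0] * n_b
    dom = derive_domains(mat, "mA", "mB")
    calls = classify_pattern_genes(mat, dom).set_index("gene")
    assert calls.loc["g11", "label"] == "A-pattern"
    assert calls.loc["g10", "label"] == "none"
    assert calls.loc["g10", "p_value"] < 1e-4  # rejected by the count gate alone


def test_threshold_validation():
    with pytest.raises(ValueError):
        PatternThresholds(p_threshold=0.0)
    with pytest.raises(ValueError):
        PatternThresholds(min_a=-1)


def test_pattern_calls_tsv_roundtrip(tmp_path, small_matrix, small_domains):
    calls = classify_pattern_genes(small_matrix, small_domains)
    out = tmp_path / "calls.tsv"
    write_pattern_calls(calls, out)
    rt = pd.read_csv(out, sep="\t")
    assert list(rt["gene"]) == list(calls["gene"])
    assert list(rt["label"]) == list(calls["label"])
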