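"""Signed TF -> target regulatory network assembly and export.

Nodes are genes carrying a spatial pattern label (A-pattern, B-pattern,
or ``TF-only`` for regulators taken from external ChIP studies that are
absent from the ISH matrix).  Directed edges are created from ChIP
target sets, restricted to pattern-labeled targets.  Edge signs come
from two rules applied in strict priority order:

* R1 (knockdown evidence): a direct target down-regulated after TF
  knockdown is *activated* by the TF; one up-regulated is *repressed*.
* R2 (expression logic, only without R1 evidence): if TF and target
  carry opposite pattern labels the edge is *proposed-repression*
  (mutually exclusive spatial expression); the same label gives
  *proposed-activation*.

Everything else stays ``unsigned``.  Exports are deterministic
(Cytoscape-compatible SIF, GraphML, and a sorted edge TSV).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "SIGNS",
    "build_network",
    "infer_edge_sign",
    "export_network",
    "read_network_graphml",
    "read_tf_targets",
]

SIGNS = (
    "activation",
    "repression",
    "proposed-activation",
    "proposed-repression",
    "unsigned",
)

PATTERN_LABELS = ("A-pattern", "B-pattern")


def read_tf_targets(path) -> dict:
    """Two-column (TF, gene) TSV -> mapping TF -> set of gene ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "gene"], dtype=str)
    out: dict[str, set] = {}
    for tf, gene in zip(df["tf"], df["gene"]):
        out.setdefault(tf, set()).add(gene)
    return out


def _pattern_lookup(pattern_calls) -> dict:
    if isinstance(pattern_calls, pd.DataFrame):
        return dict(zip(pattern_calls["gene"], pattern_calls["label"]))
    return dict(pattern_calls)


def build_network(
    tf_targets: dict,
    pattern_calls,
    tf_pattern: dict | None = None,
    motif_targets: dict | None = None,
    source: str = "chip",
) -> nx.DiGraph:
    """Assemble the domain-restricted regulatory network.

    Parameters
    ----------
    tf_targets
        Mapping TF id -> iterable of ChIP target gene ids.
    pattern_calls
        Pattern-classification output (DataFrame with gene/label
        columns, or a mapping gene -> label).  Only genes labeled
        A-pattern or B-pattern are admitted as targets.
    tf_pattern
        Optional mapping TF -> pattern label; TFs not listed and not
        classified themselves are labeled ``TF-only``.
    motif_targets
        Optional second evidence layer: mapping TF -> predicted target
        gene ids from promoter-motif analysis.  Kept separable from
        ChIP evidence via the edge ``evidence`` attribute; only added
        when explicitly passed.

    TFs appear as nodes even when none of their targets is
    pattern-labeled (flagged with ``retained_targets = 0``).
    """
    labels = _pattern_lookup(pattern_calls)
    tf_pattern = dict(tf_pattern or {})
    g = nx.DiGraph()

    def node_label(gene: str) -> str:
        if gene in tf_pattern:
            return tf_pattern[gene]
        return labels.get(gene, "TF-only")

    evidence_layers = [("chip", tf_targets)]
    if motif_targets:
        evidence_layers.append(("promoter-motif", motif_targets))

    for evidence, layer in evidence_layers:
        for tf in sorted(layer):
            if tf not in g:
                g.add_node(tf, pattern=node_label(tf), is_tf=True)
            g.nodes[tf]["is_tf"] = True
            retained = 0
            for target in sorted(layer[tf]):
                if labels.get(target) not in PATTERN_LABELS:
                    continue
                retained += 1
                if target not in g:
                    g.add_node(target, pattern=labels[target], is_tf=False)
                if g.has_edge(tf, target):
                    ev = set(g.edges[tf, target]["evidence"].split(","))
                    ev.add(evidence)
                    g.edges[tf, target]["evidence"] = ",".join(sorted(ev))
                else:
                    g.add_edge(
                        tf, target, evidence=evidence, sign="unsigned", source=source
                    )
            g.nodes[tf].setdefault("retained_targets", 0)
            g.nodes[tf]["retained_targets"] += retained
    return g


def infer_edge_sign(
    network: nx.DiGraph, response_calls: dict | None = None
) -> nx.DiGraph:
    """Assign edge signs by knockdown evidence, then expression logic.

    ``response_calls`` maps TF id -> knockdown-response classification
    for that TF (the DataFrame from
    :func:`domaingrn.expression.classify_knockdown_response`, or a
    mapping gene -> call).  Returns a signed copy of the network;
    conflicting knockdown calls for one edge raise ``ValueError``.
    """
    response_calls = response_calls or {}
    g = network.copy()
    call_maps: dict[str, dict] = {}
    for tf, calls in response_calls.items():
        if isinstance(calls, pd.DataFrame):
            m: dict[str, str] = {}
            for gene, call in zip(calls["gene"], calls["call"]):
                if gene in m and m[gene] != call:
                    raise ValueError(
                        f"conflicting knockdown calls for TF {tf!r}, gene {gene!r}: "
                        f"{m[gene]!r} vs {call!r}"
                    )
                m[gene] = call
            call_maps[tf] = m
        else:
            call_maps[tf] = dict(calls)

    for tf, target, data in g.edges(data=True):
        sign = "unsigned"
        call = call_maps.get(tf, {}).get(target)
        if call == "activated-direct-target":
            sign = "activation"
        elif call == "repressed-direct-target":
            sign = "repression"
        else:  # R2: expression logic, only without knockdown evidence
            lt = g.nodes[tf].get("pattern")
            lg = g.nodes[target].get("pattern")
            if lt in PATTERN_LABELS and lg in PATTERN_LABELS:
                sign = "proposed-activation" if lt == lg else "proposed-repression"
        data["sign"] = sign
    return g


def _sorted_copy(network: nx.DiGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in sorted(network.nodes):
        g.add_node(node, **network.nodes[node])
    for u, v in sorted(network.edges):
        g.add_edge(u, v, **network.edges[u, v])
    return g


def export_network(network: nx.DiGraph, path, format: str = "edge-tsv") -> None:
    """Write the network as SIF, GraphML or a sorted edge TSV.

    All three exports are byte-deterministic for a given network (nodes
    and edges are sorted before writing).  SIF uses the edge sign as
    the relation token.
    """
    fmt = format.lower()
    g = _sorted_copy(network)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{u}\t{g.edges[u, v]['sign']}\t{v}\n")
            for node in g.nodes:
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "edge-tsv":
        rows = [
            {
                "tf": u,
                "target": v,
                "sign": g.edges[u, v]["sign"],
                "evidence": g.edges[u, v]["evidence"],
                "source": g.edges[u, v].get("source", ""),
                "tf_pattern": g.nodes[u].get("pattern", ""),
                "target_pattern": g.nodes[v].get("pattern", ""),
            }
            for u, v in g.edges
        ]
        pd.DataFrame(
            rows,
            columns=[
                "tf", "target", "sign", "evidence", "source",
                "tf_pattern", "target_pattern",
            ],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network export format {format!r}")


def read_network_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)
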