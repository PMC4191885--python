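"""Configuration-driven end-to-end runner chaining all stages.

The pipeline reads an ISH annotation table, classifies pattern genes
against the marker-derived domains, assigns ChIP peaks to target genes,
tests overlap enrichment of the targets against both pattern classes,
filters the knockdown DE table, integrates it with the targets, builds
the signed network and exports it.  Every stage output is a pure
function of (inputs, config), so re-running an identical configuration
reproduces byte-identical exports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSet, set_overlap_enrichment
from .expression import classify_knockdown_response, filter_cuffdiff_table
from .ish import (
    PatternThresholds,
    binarize_annotations,
    classify_pattern_genes,
    derive_domains,
    read_annotation_table,
    write_pattern_calls,
)
from .motifs import (
    extract_promoters,
    filter_motif_results,
    motif_set_enrichment,
    read_jaspar_pwms,
)
from .network import build_network, export_network, infer_edge_sign
from .peaks import (
    WindowRule,
    assign_targets,
    genomic_distribution_summary,
    read_gene_models,
    read_peaks,
    write_assignments,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    ish_annotations: str
    marker_a: str
    marker_b: str
    peaks: str
    peaks_format: str = "BED"
    gene_models: str = ""
    gene_models_format: str = "GTF"
    de_table: str = ""
    knockdown_column: str = "value_2"
    tf_name: str = "TF"
    tf_pattern: dict = field(default_factory=dict)
    genome_fasta: str = ""
    pwms: str = ""
    p_threshold: float = 1e-4
    min_a: int = 10
    min_b: int = 15
    upstream_bp: int = 10_000
    downstream_bp: int = 3_000
    anchor: str = "summit"
    per_gene_overrides: dict = field(default_factory=dict)
    alpha: float = 0.05
    missing_policy: str = "zero"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def thresholds(self) -> PatternThresholds:
        return PatternThresholds(self.p_threshold, self.min_a, self.min_b)

    def window_rule(self) -> WindowRule:
        return WindowRule(
            upstream_bp=self.upstream_bp,
            downstream_bp=self.downstream_bp,
            anchor=self.anchor,
            per_gene_overrides=dict(self.per_gene_overrides),
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out

        return wrapped

    return deco


@_stage("ish-patterns")
def _run_ish(config: PipelineConfig, outdir: Path):
    table = read_annotation_table(config.ish_annotations)
    matrix = binarize_annotations(table, missing=config.missing_policy)
    domains = derive_domains(matrix, config.marker_a, config.marker_b)
    calls = classify_pattern_genes(matrix, domains, config.thresholds())
    write_pattern_calls(calls, outdir / "pattern_calls.tsv")
    with open(outdir / "domain_report.txt", "w") as fh:
        fh.write(f"marker_a={domains.marker_a}\nmarker_b={domains.marker_b}\n")
        fh.write(f"n_domain_a={len(domains.domain_a)}\n")
        fh.write(f"n_domain_b={len(domains.domain_b)}\n")
        fh.write(f"n_unassigned={len(domains.unassigned)}\n")
        fh.write("domain_a=" + ",".join(domains.domain_a) + "\n")
        fh.write("domain_b=" + ",".join(domains.domain_b) + "\n")
    return matrix, domains, calls


@_stage("peak-assignment")
def _run_peaks(config: PipelineConfig, outdir: Path):
    genes = read_gene_models(config.gene_models, format=config.gene_models_format)
    peaks = read_peaks(config.peaks, format=config.peaks_format)
    assignments = assign_targets(peaks, genes, config.window_rule())
    write_assignments(assignments, outdir / "target_assignments.tsv")
    summary = genomic_distribution_summary(peaks, genes)
    pct = summary.percentages
    rows = [{"category": k, "percent": pct[k]} for k in pct]
    for cut, value in summary.cumulative_upstream.items():
        rows.append({"category": f"upstream_within_{cut}bp_cumulative", "percent": value})
    pd.DataFrame(rows).to_csv(outdir / "location_summary.tsv", sep="\t", index=False)
    return genes, peaks, assignments


@_stage("overlap-enrichment")
def _run_enrichment(config: PipelineConfig, outdir: Path, calls, target_genes):
    universe = frozenset(calls["gene"])  # genes with ISH annotations
    rows = []
    targets_annotated = frozenset(target_genes) & universe
    tf_set = GeneSet(f"{config.tf_name}-targets", targets_annotated, universe)
    for label in ("A-pattern", "B-pattern"):
        pattern_set = GeneSet(
            label, frozenset(calls.loc[calls["label"] == label, "gene"]), universe
        )
        res = set_overlap_enrichment(tf_set, pattern_set, universe, alpha=config.alpha)
        rows.append(
            {
                "set_x": res.set_x,
                "set_y": res.set_y,
                "overlap": res.overlap,
                "a": res.table[0],
                "b": res.table[1],
                "c": res.table[2],
                "d": res.table[3],
                "p_value": res.p_value,
                "odds_ratio": res.odds_ratio,
                "significant": res.significant,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "overlap_enrichment.tsv", sep="\t", index=False)
    return df


@_stage("knockdown-response")
def _run_response(config: PipelineConfig, outdir: Path, target_genes):
    de = filter_cuffdiff_table(
        config.de_table, knockdown_column=config.knockdown_column, alpha=config.alpha
    )
    calls = classify_knockdown_response(de, target_genes)
    calls.to_csv(outdir / "response_calls.tsv", sep="\t", index=False)
    return calls


@_stage("motif-enrichment")
def _run_motifs(config: PipelineConfig, outdir: Path, genes, pattern_calls):
    pwms = read_jaspar_pwms(config.pwms)
    promoters = extract_promoters(genes, config.genome_fasta)
    pattern_genes = set(
        pattern_calls.loc[pattern_calls["label"] != "none", "gene"]
    )
    fg = {g: s for g, s in promoters.items() if g in pattern_genes}
    bg = {g: s for g, s in promoters.items() if g not in pattern_genes}
    if len(fg) < 2 or len(bg) < 10:
        logger.warning("motif stage skipped: too few foreground/background promoters")
        return None
    results = motif_set_enrichment(pwms, fg, bg)
    results.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    filtered = filter_motif_results(results)
    filtered.to_csv(outdir / "motif_enrichment_filtered.tsv", sep="\t", index=False)
    return results


@_stage("network")
def _run_network(config: PipelineConfig, outdir: Path, pattern_calls, target_genes, response):
    tf_targets = {config.tf_name: set(target_genes)}
    net = build_network(tf_targets, pattern_calls, tf_pattern=dict(config.tf_pattern))
    response_calls = {config.tf_name: response} if response is not None else {}
    net = infer_edge_sign(net, response_calls)
    export_network(net, outdir / "network.sif", format="sif")
    export_network(net, outdir / "network.graphml", format="graphml")
    export_network(net, outdir / "network_edges.tsv", format="edge-tsv")
    return net


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every configured stage; returns the output directory.

    Writes pattern calls, a domain report, target assignments, the
    genomic location summary, overlap-enrichment tables, knockdown
    response calls, signed network exports (SIF/GraphML/TSV) and a run
    log recording the config hash and package version.  Stages whose
    inputs are not configured (DE table, motif analysis) are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("domaingrn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("domaingrn %s, config hash %s", __version__, config.config_hash())
        _matrix, _domains, calls = _run_ish(config, outdir)
        _genes, _peaks, assignments = _run_peaks(config, outdir)
        target_genes = sorted({t.gene_id for t in assignments})
        _run_enrichment(config, outdir, calls, target_genes)
        response = None
        if config.de_table:
            response = _run_response(config, outdir, target_genes)
        if config.pwms and config.genome_fasta:
            _run_motifs(config, outdir, _genes, calls)
        _run_network(config, outdir, calls, target_genes, response)
        logger.info("pipeline complete")
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
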