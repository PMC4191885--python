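"""ChIP-seq peak to target-gene assignment by a fixed genomic window.

A peak is assigned to a gene when its summit falls inside the gene's
target window: from ``upstream_bp`` before the transcription start site
(TSS) to ``downstream_bp`` past the transcription end in gene-oriented
coordinates.  The window is half-open, ``[TSS - upstream, gene_end +
downstream)``; the upstream boundary itself is inside.  A peak may hit
several genes (every containment is reported).  Individual genes may
carry an upstream override — the analogue of extending one promoter to
a distal binding site while leaving the global rule untouched.

Coordinates are 0-based half-open internally.  MACS ``.xls`` tables
(1-based inclusive) are converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GeneModelSet",
    "Peak",
    "PeakSet",
    "WindowRule",
    "TargetAssignment",
    "read_gene_models",
    "read_peaks",
    "write_peaks_bed",
    "assign_targets",
    "write_assignments",
    "LocationSummary",
    "genomic_distribution_summary",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic span with optional exon/CDS structure.

    ``start``/``end`` are 0-based half-open.  ``tss`` is the first
    transcribed base (``start`` on +, ``end - 1`` on -); ``tes`` the
    last (``end - 1`` on +, ``start`` on -).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = None
    cds: tuple = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")
        if self.exons:
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"gene {self.gene_id!r}: exon outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_offset(self, position: int) -> int:
        """Gene-oriented offset of a genomic position from the TSS.

        0 at the TSS, positive downstream (into and past the gene body),
        negative upstream of the promoter, on either strand.
        """
        return position - self.tss if self.strand == "+" else self.tss - position


class GeneModelSet:
    """Ordered collection of gene models, indexed by gene id."""

    def __init__(self, models):
        self._models = {}
        for m in models:
            if m.gene_id in self._models:
                raise ValueError(f"duplicate gene id {m.gene_id!r}")
            self._models[m.gene_id] = m

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    def __contains__(self, gene_id) -> bool:
        return gene_id in self._models

    def __iter__(self):
        return iter(self._models.values())

    def __len__(self) -> int:
        return len(self._models)

    @property
    def gene_ids(self):
        return list(self._models)


@dataclass(frozen=True)
class Peak:
    """A called peak; ``summit`` is an absolute genomic coordinate."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.peak_id!r}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )


class PeakSet:
    """Ordered collection of peaks."""

    def __init__(self, peaks):
        self.peaks = list(peaks)
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak ids")

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks


@dataclass(frozen=True)
class WindowRule:
    """Peak-to-gene assignment window.

    ``upstream_bp`` before the TSS to ``downstream_bp`` past the gene
    end, in gene orientation.  ``anchor`` decides what must fall inside:
    the summit (default) or any part of the peak interval.
    ``per_gene_overrides`` replaces ``upstream_bp`` for named genes.
    """

    upstream_bp: int = 10_000
    downstream_bp: int = 3_000
    anchor: str = "summit"
    per_gene_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window lengths must be non-negative")
        if self.anchor not in ("summit", "any-overlap"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if any(v < 0 for v in self.per_gene_overrides.values()):
            raise ValueError("per-gene upstream overrides must be non-negative")

    def upstream_for(self, gene_id: str) -> int:
        return self.per_gene_overrides.get(gene_id, self.upstream_bp)


@dataclass(frozen=True)
class TargetAssignment:
    peak_id: str
    gene_id: str
    relation: str  # upstream-promoter | gene-body | downstream
    distance_to_tss: int  # gene-oriented, negative = upstream


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf_attrs(s: str) -> dict:
    return dict(_GTF_ATTR.findall(s))


def read_gene_models(path, format: str = "GTF") -> GeneModelSet:
    """Read gene models from GTF or BED12.

    One model per gene id; when a gene has several transcripts the
    longest transcript wins.  Coordinates are normalized to 0-based
    half-open.
    """
    fmt = format.upper()
    if fmt == "GTF":
        return _read_gtf(path)
    if fmt == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gtf(path) -> GeneModelSet:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    best: dict[str, gffutils.Feature] = {}
    order: list[str] = []
    for tx in db.features_of_type("transcript"):
        gid = tx.attributes["gene_id"][0]
        if gid not in best:
            order.append(gid)
            best[gid] = tx
        else:
            cur = best[gid]
            if (tx.end - tx.start) > (cur.end - cur.start):
                best[gid] = tx
    models = []
    for gid in order:
        tx = best[gid]
        exons = tuple(
            sorted(
                (e.start - 1, e.end)  # GTF is 1-based inclusive
                for e in db.children(tx, featuretype="exon")
            )
        )
        cds_feats = list(db.children(tx, featuretype="CDS"))
        cds = None
        if cds_feats:
            cds = (min(c.start - 1 for c in cds_feats), max(c.end for c in cds_feats))
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=tx.seqid,
                strand=tx.strand,
                start=tx.start - 1,
                end=tx.end,
                exons=exons or None,
                cds=cds,
            )
        )
    return GeneModelSet(models)


def _read_bed12(path) -> GeneModelSet:
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount",
        "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError("BED12 reader needs at least 6 columns (chrom..strand)")
    df.columns = names[: df.shape[1]]
    best: dict[str, GeneModel] = {}
    order: list[str] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(f"malformed BED line {lineno}: {exc}") from None
        exons = cds = None
        if hasattr(row, "blockStarts") and isinstance(row.blockSizes, str):
            sizes = [int(x) for x in row.blockSizes.rstrip(",").split(",")]
            offs = [int(x) for x in row.blockStarts.rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        if hasattr(row, "thickEnd"):
            ts, te = int(row.thickStart), int(row.thickEnd)
            if ts < te:
                cds = (ts, te)
        model = GeneModel(
            gene_id=row.name, chrom=row.chrom, strand=row.strand,
            start=start, end=end, exons=exons, cds=cds,
        )
        if model.gene_id not in best:
            order.append(model.gene_id)
            best[model.gene_id] = model
        elif model.length > best[model.gene_id].length:
            best[model.gene_id] = model
    return GeneModelSet(best[g] for g in order)


def read_peaks(path, format: str = "BED") -> PeakSet:
    """Read peaks from BED (0-based) or a MACS ``.xls`` table (1-based).

    BED: columns chrom, start, end[, name, score, strand[, summit
    offset from start]].  Without a summit column the summit defaults
    to the interval midpoint ``floor((start + end) / 2)``.

    MACS xls: ``#`` comment lines, then a header with chr/start/end/
    summit/-10*log10(pvalue) columns; start is converted from 1-based
    inclusive and the summit column is an offset from the (1-based)
    peak start.
    """
    fmt = format.upper()
    if fmt == "BED":
        return _read_peaks_bed(path)
    if fmt in ("MACS-XLS", "MACS_XLS", "MACS"):
        return _read_peaks_macs(path)
    raise ValueError(f"unknown peak format {format!r}")


def _read_peaks_bed(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = row[3] if len(row) > 3 else f"peak_{i + 1}"
        score = float(row[4]) if len(row) > 4 else 0.0
        summit = start + int(row[6]) if len(row) > 6 else (start + end) // 2
        peaks.append(Peak(name, chrom, start, end, summit, score))
    return PeakSet(peaks)


def _read_peaks_macs(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chr", "start", "end", "summit"}
    if not required <= set(df.columns):
        raise ValueError(f"MACS table missing columns {sorted(required - set(df.columns))}")
    score_col = next((c for c in df.columns if "log10" in c), None)
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        start0 = int(r["start"]) - 1  # 1-based inclusive -> 0-based half-open
        end0 = int(r["end"])
        summit = start0 + int(r["summit"])
        score = float(r[score_col]) if score_col else 0.0
        peaks.append(Peak(f"macs_peak_{i + 1}", str(r["chr"]), start0, end0, summit, score))
    return PeakSet(peaks)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    """Write peaks as BED6+1 (7th column = summit offset from start)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:g}\t.\t"
                f"{p.summit - p.start}\n"
            )


def _gene_window(gene: GeneModel, rule: WindowRule) -> tuple[int, int]:
    """Genomic half-open window implied by the rule for one gene."""
    up = rule.upstream_for(gene.gene_id)
    down = rule.downstream_bp
    if gene.strand == "+":
        return gene.start - up, gene.end + down
    return gene.start - down, gene.end + up


def _relation(gene: GeneModel, summit: int) -> tuple[str, int]:
    off = gene.oriented_offset(summit)
    if off < 0:
        return "upstream-promoter", off
    if off < gene.length:
        return "gene-body", off
    return "downstream", off


def assign_targets(
    peaks: PeakSet, genes: GeneModelSet, rule: WindowRule | None = None
) -> list[TargetAssignment]:
    """Assign peaks to target genes under the window rule.

    With ``anchor="summit"`` a peak is assigned to every gene whose
    window contains its summit; with ``anchor="any-overlap"`` any
    overlap between the peak interval and the window counts.  Relation
    and distance are always computed from the summit.  Output is sorted
    by (peak id, gene id).
    """
    if rule is None:
        rule = WindowRule()
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        lo, hi = _gene_window(gene, rule)
        if hi <= lo:
            continue
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene)
    out = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        if rule.anchor == "summit":
            hits = tree[peak.summit]
        else:
            hits = tree.overlap(peak.start, peak.end)
        for iv in hits:
            gene = iv.data
            relation, dist = _relation(gene, peak.summit)
            out.append(TargetAssignment(peak.peak_id, gene.gene_id, relation, dist))
    out.sort(key=lambda t: (t.peak_id, t.gene_id))
    return out


def write_assignments(assignments, path) -> None:
    pd.DataFrame(
        [
            {
                "peak": t.peak_id,
                "gene": t.gene_id,
                "relation": t.relation,
                "distance_to_tss": t.distance_to_tss,
            }
            for t in assignments
        ],
        columns=["peak", "gene", "relation", "distance_to_tss"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LocationSummary:
    """Genomic distribution of peak summits.

    ``percentages`` maps the mutually exclusive categories (5utr, 3utr,
    exon, intron, gene-body, the three exclusive upstream distance
    bins, intergenic) to percentages that sum to 100.
    ``cumulative_upstream`` reports the nested "within <= X bp of a
    TSS" percentages over all peaks.
    """

    counts: dict
    n_peaks: int
    bins: tuple

    @property
    def percentages(self) -> dict:
        return {k: 100.0 * v / self.n_peaks for k, v in self.counts.items()}

    @property
    def cumulative_upstream(self) -> dict:
        keys = _upstream_bin_labels(self.bins)
        cum, out = 0, {}
        for cut, key in zip(self.bins, keys):
            cum += self.counts[key]
            out[cut] = 100.0 * cum / self.n_peaks
        return out


def _upstream_bin_labels(bins) -> list[str]:
    labels, prev = [], 0
    for cut in bins:
        labels.append(f"upstream_{prev}_{cut}bp")
        prev = cut
    return labels


def _gene_body_category(gene: GeneModel, summit: int) -> str:
    """Sub-classification of a summit inside a gene body."""
    if not gene.exons:
        return "gene-body"
    in_exon = any(s <= summit < e for s, e in gene.exons)
    if not in_exon:
        return "intron"
    if not gene.cds:
        return "exon"
    cs, ce = gene.cds
    if summit < cs:
        return "5utr" if gene.strand == "+" else "3utr"
    if summit >= ce:
        return "3utr" if gene.strand == "+" else "5utr"
    return "exon"


#: classification priority when a summit hits several genes
_PRECEDENCE = ["5utr", "3utr", "exon", "intron", "gene-body"]


def genomic_distribution_summary(
    peaks: PeakSet, genes: GeneModelSet, bins=(1000, 3000, 10000)
) -> LocationSummary:
    """Classify every peak summit into one genomic category.

    Precedence: 5'UTR > 3'UTR > exon > intron > unresolved gene body >
    upstream distance bins (nearest TSS, gene-oriented) > intergenic.
    Percentages are over all peaks and sum to 100; the nested upstream
    bins are additionally reported cumulatively.
    """
    bins = tuple(sorted(bins))
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    body_trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        body_trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene)
        by_chrom.setdefault(gene.chrom, []).append(gene)

    labels = _upstream_bin_labels(bins)
    counts = {k: 0 for k in _PRECEDENCE + labels + ["intergenic"]}
    max_up = bins[-1]
    for peak in peaks:
        summit = peak.summit
        cats = []
        tree = body_trees.get(peak.chrom)
        if tree is not None:
            for iv in tree[summit]:
                cats.append(_gene_body_category(iv.data, summit))
        if cats:
            cat = min(cats, key=_PRECEDENCE.index)
            counts[cat] += 1
            continue
        # nearest upstream TSS in gene orientation
        best = None
        for gene in by_chrom.get(peak.chrom, ()):
            off = gene.oriented_offset(summit)
            if -max_up <= off < 0:
                dist = -off
                if best is None or dist < best:
                    best = dist
        if best is None:
            counts["intergenic"] += 1
        else:
            for cut, label in zip(bins, labels):
                if best <= cut:
                    counts[label] += 1
                    break
    return LocationSummary(counts=counts, n_peaks=len(peaks), bins=bins)
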