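"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one of the external resources the pipeline
normally consumes — the curated ISH annotation matrix, a genome with
gene models and called ChIP peaks, a Cuffdiff-style knockdown DE table,
and promoter sequences with planted motif occurrences — and returns the
planted truth alongside, so recovery can be measured exactly.

All generators draw from independent, splittable random streams derived
from one global seed (``numpy.random.SeedSequence`` with a per-generator
stream key), so adding one generator call never perturbs the output of
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import GeneModel, GeneModelSet, Peak, PeakSet, WindowRule, _gene_window
from .motifs import PWM

__all__ = [
    "SyntheticIshSpec",
    "SyntheticTruth",
    "SyntheticGenomeSpec",
    "generate_ish_matrix",
    "generate_toy_genome_and_peaks",
    "generate_genome_fasta",
    "generate_de_table",
    "generate_promoters_with_planted_motif",
    "write_annotation_tsv",
    "write_gtf",
    "write_de_tsv",
    "write_genome_fasta",
    "write_manifest",
]

# stream keys: one per generator so streams split cleanly from one seed
_STREAM_ISH = 0
_STREAM_GENOME = 1
_STREAM_DE = 2
_STREAM_PROMOTER = 3
_STREAM_FASTA = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_a_genes: frozenset = frozenset()
    planted_b_genes: frozenset = frozenset()
    marker_a: str = ""
    marker_b: str = ""
    true_targets: dict = field(default_factory=dict)  # TF -> frozenset of gene ids
    true_signs: dict = field(default_factory=dict)  # (TF, gene) -> activation|repression

    def __post_init__(self):
        if self.planted_a_genes & self.planted_b_genes:
            raise ValueError("planted gene classes must be disjoint")
        planted = self.planted_a_genes | self.planted_b_genes
        if self.marker_a in planted or self.marker_b in planted:
            raise ValueError("markers must not be planted pattern genes")
        for (tf, gene), sign in self.true_signs.items():
            if sign not in ("activation", "repression"):
                raise ValueError(f"unknown sign {sign!r} for ({tf}, {gene})")
            if tf in self.true_targets and gene not in self.true_targets[tf]:
                raise ValueError(f"signed pair ({tf}, {gene}) not in true_targets")


@dataclass(frozen=True)
class SyntheticIshSpec:
    """Planted two-domain ISH matrix.

    Defaults mirror the real curated matrix this stands in for: a
    20-region A domain, a 30-region B domain, 28 remaining regions and
    ~2000 genes, with planted domain-restricted genes expressed in
    their home domain with probability ``p_in`` and elsewhere with
    probability ``p_out``; background genes are Bernoulli(``p_bg``)
    everywhere.
    """

    n_regions_a: int = 20
    n_regions_b: int = 30
    n_regions_other: int = 28
    n_planted_a: int = 50
    n_planted_b: int = 300
    n_background: int = 1650
    p_in: float = 0.95
    p_out: float = 0.02
    p_bg: float = 0.10
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_regions_a, self.n_regions_b, self.n_regions_other,
            self.n_planted_a, self.n_planted_b, self.n_background,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_regions_a + self.n_regions_b < 2:
            raise ValueError("need at least two domain regions")
        for p in (self.p_in, self.p_out, self.p_bg):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def generate_ish_matrix(spec: SyntheticIshSpec):
    """Binary gene x region matrix with two planted marker-defined domains.

    Returns (matrix, truth).  The two marker genes are noise-free: the
    A marker is 1 exactly on the A regions and the B marker exactly on
    the B regions, so domain derivation from the markers is exact by
    construction.
    """
    rng = _rng(spec.seed, _STREAM_ISH)
    regions = (
        [f"A{i + 1:02d}" for i in range(spec.n_regions_a)]
        + [f"B{i + 1:02d}" for i in range(spec.n_regions_b)]
        + [f"O{i + 1:02d}" for i in range(spec.n_regions_other)]
    )
    marker_a, marker_b = "markerA", "markerB"
    genes_a = [f"geneA{i + 1:04d}" for i in range(spec.n_planted_a)]
    genes_b = [f"geneB{i + 1:04d}" for i in range(spec.n_planted_b)]
    genes_bg = [f"geneN{i + 1:04d}" for i in range(spec.n_background)]
    genes = [marker_a, marker_b] + genes_a + genes_b + genes_bg

    n_regions = len(regions)
    in_a = np.zeros(n_regions, dtype=bool)
    in_a[: spec.n_regions_a] = True
    in_b = np.zeros(n_regions, dtype=bool)
    in_b[spec.n_regions_a : spec.n_regions_a + spec.n_regions_b] = True

    mat = np.zeros((len(genes), n_regions), dtype=np.int8)
    mat[0] = in_a
    mat[1] = in_b
    row = 2
    for block, home in ((genes_a, in_a), (genes_b, in_b)):
        if block:
            probs = np.where(home, spec.p_in, spec.p_out)
            mat[row : row + len(block)] = rng.random((len(block), n_regions)) < probs
            row += len(block)
    if genes_bg:
        mat[row:] = rng.random((len(genes_bg), n_regions)) < spec.p_bg

    matrix = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=regions)
    truth = SyntheticTruth(
        planted_a_genes=frozenset(genes_a),
        planted_b_genes=frozenset(genes_b),
        marker_a=marker_a,
        marker_b=marker_b,
    )
    return matrix, truth


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Toy genome layout for window-assignment tests."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 50
    min_gene_len: int = 2_000
    max_gene_len: int = 20_000
    n_peaks: int = 200
    frac_in_window: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.n_genes, self.n_peaks) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 < self.min_gene_len <= self.max_gene_len:
            raise ValueError("need 0 < min_gene_len <= max_gene_len")
        if not 0.0 <= self.frac_in_window <= 1.0:
            raise ValueError("frac_in_window must be in [0, 1]")


def generate_toy_genome_and_peaks(spec: SyntheticGenomeSpec, window: WindowRule | None = None):
    """Non-overlapping genes plus peaks planted inside/outside windows.

    Genes are laid out so that no two target windows overlap and a
    clear intergenic gap separates consecutive windows.  Exactly
    ``round(frac_in_window * n_peaks)`` peak summits are placed
    uniformly inside a randomly chosen gene's window; the remainder go
    into guaranteed-intergenic gaps (outside every window).  Truth
    records the intended peak -> gene assignments under ``window``.

    Returns (genes, peaks, truth) with ``truth.true_targets`` mapping
    the synthetic TF id ``"TF"`` to the intended target genes and the
    intended assignments retrievable from peak/gene ids (peaks planted
    in a window are named ``peak_in_<gene_id>_<k>``).
    """
    if window is None:
        window = WindowRule()
    rng = _rng(spec.seed, _STREAM_GENOME)
    gap = 2_000  # guaranteed intergenic margin between consecutive windows
    # a window can extend max(upstream, downstream) past either gene edge
    # depending on strand, so reserve that extent on both sides
    up = max([window.upstream_bp, *window.per_gene_overrides.values()])
    ext = max(up, window.downstream_bp)
    slot_overhead = 2 * ext + 2 * gap

    genes = []
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = gap + ext
        for _ in range(per_chrom[ci]):
            glen = int(rng.integers(spec.min_gene_len, spec.max_gene_len + 1))
            if cursor + glen + ext + gap > spec.chrom_length:
                raise ValueError(
                    f"chromosome {chrom} (length {spec.chrom_length}) cannot host "
                    "the requested genes without overlapping windows"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel(f"g{gi:04d}", chrom, strand, cursor, cursor + glen)
            )
            cursor += glen + slot_overhead + int(rng.integers(0, 5_000))
    gene_set = GeneModelSet(genes)

    n_in = round(spec.frac_in_window * spec.n_peaks)
    peaks = []
    intended: dict[str, str] = {}
    for k in range(n_in):
        gene = genes[int(rng.integers(len(genes)))]
        lo, hi = _gene_window(gene, window)
        summit = int(rng.integers(lo, hi))
        peaks.append(
            Peak(f"peak_in_{k + 1:05d}", gene.chrom, summit - 100, summit + 101, summit)
        )
        intended[f"peak_in_{k + 1:05d}"] = gene.gene_id

    # intergenic placements: the half-gap immediately left of each window
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        windows_by_chrom.setdefault(gene.chrom, []).append(_gene_window(gene, window))
    for k in range(spec.n_peaks - n_in):
        gene = genes[int(rng.integers(len(genes)))]
        lo, _ = _gene_window(gene, window)
        summit = int(rng.integers(lo - gap, lo - 300))
        assert all(
            not (wlo <= summit < whi) for wlo, whi in windows_by_chrom[gene.chrom]
        )
        peaks.append(
            Peak(f"peak_out_{k + 1:05d}", gene.chrom, summit - 100, summit + 101, summit)
        )
    peak_set = PeakSet(peaks)
    truth = SyntheticTruth(
        true_targets={"TF": frozenset(intended.values())},
    )
    return gene_set, peak_set, truth, intended


def generate_genome_fasta(chrom_lengths: dict, seed: int = 0) -> dict:
    """Random A/C/G/T sequences for the given chromosome lengths."""
    rng = _rng(seed, _STREAM_FASTA)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: b"".join(rng.choice(bases, size=length)).decode()
        for chrom, length in chrom_lengths.items()
    }


def generate_de_table(
    truth: SyntheticTruth,
    n_genes: int,
    frac_sig: float = 1.0,
    seed: int = 0,
    tf: str | None = None,
    dropout_frac: float = 0.0,
) -> pd.DataFrame:
    """Cuffdiff-style knockdown DE table with planted direct targets.

    ``value_1`` is the control, ``value_2`` the knockdown sample.  A
    fraction ``frac_sig`` of the TF's true targets receive p < 0.05
    with the direction dictated by the planted sign (activation means
    the target drops in the knockdown); every other gene gets a
    uniform p-value and a fold change consistent in sign with nothing.
    ``dropout_frac`` of rows are marked status NOTEST.
    """
    if not 0.0 <= frac_sig <= 1.0:
        raise ValueError("frac_sig must be in [0, 1]")
    if not 0.0 <= dropout_frac <= 1.0:
        raise ValueError("dropout_frac must be in [0, 1]")
    rng = _rng(seed, _STREAM_DE)
    if tf is None:
        if len(truth.true_targets) != 1:
            raise ValueError("tf must be named when truth has several TFs")
        tf = next(iter(truth.true_targets))
    targets = sorted(truth.true_targets.get(tf, ()))
    extra = max(0, n_genes - len(targets))
    genes = targets + [f"bg{i + 1:05d}" for i in range(extra)]

    n_sig = round(frac_sig * len(targets))
    sig = set(rng.choice(len(targets), size=n_sig, replace=False).tolist()) if n_sig else set()

    rows = []
    for i, gene in enumerate(genes):
        control = float(rng.lognormal(mean=3.0, sigma=1.0))
        is_target = i < len(targets)
        if is_target and i in sig:
            sign = truth.true_signs.get((tf, gene), "activation")
            p = float(rng.uniform(1e-8, 0.05))
            fold = rng.uniform(0.2, 0.6) if sign == "activation" else rng.uniform(1.8, 4.0)
        else:
            p = float(rng.uniform(0.0, 1.0))
            fold = float(np.exp(rng.normal(0.0, 0.05)))
        kd = control * float(fold)
        rows.append(
            {"gene": gene, "value_1": control, "value_2": kd, "status": "OK", "p_value": p}
        )
    df = pd.DataFrame(rows)
    if dropout_frac:
        n_drop = round(dropout_frac * len(df))
        drop_idx = rng.choice(len(df), size=n_drop, replace=False)
        df.loc[drop_idx, "status"] = "NOTEST"
    return df


def generate_promoters_with_planted_motif(
    pwm: PWM, n_fg: int, n_bg: int, plant_prob: float = 1.0, seed: int = 0,
    length: int = 1200,
):
    """Foreground/background promoter sets with planted consensus sites.

    All sequences are i.i.d. uniform A/C/G/T of the given length
    (default 1200 nt, the -1000..+200 promoter window).  Each
    foreground sequence receives one copy of the motif consensus at a
    uniformly chosen offset with probability ``plant_prob``.

    Returns (foreground, background) dicts of gene id -> sequence.
    """
    if not 0.0 <= plant_prob <= 1.0:
        raise ValueError("plant_prob must be in [0, 1]")
    if length < pwm.length:
        raise ValueError("promoter length shorter than motif")
    rng = _rng(seed, _STREAM_PROMOTER)
    alphabet = np.array(list("ACGT"))
    consensus = pwm.consensus

    def random_seq() -> str:
        return "".join(alphabet[rng.integers(0, 4, size=length)])

    fg = {}
    for i in range(n_fg):
        seq = random_seq()
        if rng.random() < plant_prob:
            pos = int(rng.integers(0, length - pwm.length + 1))
            seq = seq[:pos] + consensus + seq[pos + pwm.length :]
        fg[f"fg{i + 1:04d}"] = seq
    bg = {f"bg{i + 1:04d}": random_seq() for i in range(n_bg)}
    return fg, bg


# ---------------------------------------------------------------------------
# writers: the same plain-text formats the pipeline readers consume


def write_annotation_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a binary matrix as a categorical annotation TSV.

    1 becomes ``Medium`` and 0 ``Undetected`` so the file round-trips
    through the standard binarization.
    """
    cat = matrix.replace({0: "Undetected", 1: "Medium"})
    cat.to_csv(path, sep="\t", index_label="gene")


def write_gtf(genes: GeneModelSet, path, source: str = "domaingrn") -> None:
    """Write gene models as GTF (transcript + exon features, 1-based)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons or ((g.start, g.end),):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            if g.cds:
                cs, ce = g.cds
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_de_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_genome_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_manifest(path, **entries) -> None:
    """Plain-text key=value manifest recording specs and seeds."""
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")
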