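"""Promoter extraction, PWM scanning and motif enrichment.

Promoters are fixed windows around the TSS (default 1000 bp upstream to
200 bp downstream, 1200 nt total), strand-aware so position 0 is always
-1000 in gene orientation.  Each position weight matrix (PWM) is scored
against a promoter as the best log2-odds hit over both strands and all
offsets (best-single-hit statistic); enrichment of a motif in a
foreground promoter set versus a background set is summarized by a
one-sided z statistic on the mean best scores.  That z-test is an
approximation: max-score distributions are skewed, which is why the
null-calibration checks in the test-suite use a deliberately wide band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PWM",
    "read_jaspar_pwms",
    "write_jaspar_pwms",
    "extract_promoters",
    "read_promoters_fasta",
    "write_promoters_fasta",
    "pwm_max_score",
    "motif_set_enrichment",
    "filter_motif_results",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a log-odds pseudocount.

    ``matrix`` is 4 x L (rows A, C, G, T); every column must sum to 1.
    ``pseudocount`` is added to each probability (then renormalized)
    before taking log2 odds against a uniform background, so zero
    probabilities stay finite.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError(f"PWM {self.motif_id!r}: matrix must be 4 x L")
        sums = m.sum(axis=0)
        if np.any(sums == 0):
            raise ValueError(f"PWM {self.motif_id!r}: zero-sum column")
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.motif_id!r}: columns must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_counts(cls, motif_id: str, counts, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=0)
        if np.any(sums == 0):
            raise ValueError(f"PWM {motif_id!r}: zero-sum count column")
        return cls(motif_id, counts / sums, pseudocount)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds table (row 4 = N, scored as background: 0)."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=0)
        table = np.zeros((5, self.length))
        with np.errstate(divide="ignore"):  # zero prob with zero pseudocount -> -inf
            table[:4] = np.log2(p / 0.25)
        return table


def read_jaspar_pwms(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR-style count matrices into PWMs (via Biopython)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in ALPHABET], dtype=float)
        name = rec.matrix_id or rec.name
        out.append(PWM.from_counts(name, counts, pseudocount))
    return out


def write_jaspar_pwms(pwms, path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for i, base in enumerate(ALPHABET):
                row = " ".join(f"{v:6d}" for v in counts[i])
                fh.write(f"{base}  [{row} ]\n")


def extract_promoters(
    genes, genome_fasta, upstream: int = 1000, downstream: int = 200
) -> dict:
    """Extract strand-aware promoter sequences from an indexed FASTA.

    The promoter of a gene covers ``[TSS - upstream, TSS + downstream)``
    in gene orientation; minus-strand sequences are reverse-complemented
    so position 0 is ``-upstream`` relative to the TSS for every gene.
    Windows running off a contig end are truncated with a warning.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    promoters = {}
    for gene in genes:
        if gene.chrom not in fasta:
            raise KeyError(f"chromosome {gene.chrom!r} missing from genome FASTA")
        contig_len = len(fasta[gene.chrom])
        tss = gene.tss
        if gene.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream + 1, tss + upstream + 1
        clo, chi = max(lo, 0), min(hi, contig_len)
        seq = str(fasta[gene.chrom][clo:chi])
        if (clo, chi) != (lo, hi):
            warnings.warn(
                f"promoter of {gene.gene_id!r} truncated at contig edge "
                f"({chi - clo} of {hi - lo} bp)"
            )
        if gene.strand == "-":
            seq = reverse_complement(seq)
        promoters[gene.gene_id] = seq
    return promoters


def read_promoters_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters_fasta(promoters: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in promoters:
            fh.write(f">{name}\n")
            seq = promoters[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide {exc.args[0]!r} in sequence") from None


def _batch_max_scores(pwm: PWM, seqs: list[str]) -> np.ndarray:
    """Best two-strand hit per sequence; sequences must share a length."""
    L = pwm.length
    lom = pwm.log_odds()
    idx = np.stack([_encode(s) for s in seqs])
    n_win = idx.shape[1] - L + 1
    if n_win < 1:
        raise ValueError(f"sequence shorter than motif (length {L})")
    best = np.full(idx.shape[0], -np.inf)
    # reverse-complement the motif rather than each sequence
    rc = np.zeros_like(lom)
    rc[:4] = lom[[3, 2, 1, 0], ::-1][:4]
    for table in (lom, rc):
        scores = np.zeros((idx.shape[0], n_win))
        for j in range(L):
            scores += table[idx[:, j : j + n_win], j]
        np.maximum(best, scores.max(axis=1), out=best)
    return best


def pwm_max_score(pwm: PWM, sequence: str) -> float:
    """Best log2-odds hit of a PWM in one sequence, over both strands.

    N bases score 0 (background).  Raises if the sequence is shorter
    than the motif.
    """
    if len(sequence) < pwm.length:
        raise ValueError(
            f"sequence (length {len(sequence)}) shorter than motif "
            f"{pwm.motif_id!r} (length {pwm.length})"
        )
    return float(_batch_max_scores(pwm, [sequence])[0])


def motif_set_enrichment(
    pwms, foreground: dict, background: dict
) -> pd.DataFrame:
    """Per-motif enrichment of foreground vs background promoters.

    For each motif the best-hit score of every promoter is computed and
    the foreground mean is compared to the background distribution:
    ``z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg))`` with the sample
    (n-1) background standard deviation, one-sided upper-tail normal p.
    Motifs whose background scores are constant are flagged degenerate
    with p = 1.  Results are ranked by ascending p (ties by motif id).
    """
    if len(foreground) < 2:
        raise ValueError("need at least 2 foreground promoters")
    if len(background) < 10:
        raise ValueError("need at least 10 background promoters")
    fg = [foreground[k] for k in foreground]
    bg = [background[k] for k in background]
    rows = []
    for pwm in pwms:
        s_fg = _batch_max_scores(pwm, fg)
        s_bg = _batch_max_scores(pwm, bg)
        mean_fg, mean_bg = float(s_fg.mean()), float(s_bg.mean())
        sd_bg = float(s_bg.std(ddof=1))
        if sd_bg == 0.0:
            z, p, degenerate = float("nan"), 1.0, True
        else:
            z = (mean_fg - mean_bg) / (sd_bg / math.sqrt(len(fg)))
            p = float(norm.sf(z))
            degenerate = False
        rows.append(
            {
                "motif": pwm.motif_id,
                "mean_fg": mean_fg,
                "mean_bg": mean_bg,
                "sd_bg": sd_bg,
                "z": z,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["p_value", "motif"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def filter_motif_results(
    results: pd.DataFrame, p_max: float = 0.005, rank_max: int = 20
) -> pd.DataFrame:
    """Keep motifs with p strictly below ``p_max`` AND rank <= ``rank_max``."""
    if results.empty:
        return results
    keep = (results["p_value"] < p_max) & (results["rank"] <= rank_max)
    return results[keep].reset_index(drop=True)
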