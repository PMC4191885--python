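"""Independent brute-force oracles used to cross-check the package.

These deliberately take different computational routes from the
implementation (float hypergeometric enumeration vs exact integers;
all-pairs scans vs interval trees) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

#: relative tie tolerance for float point-probability comparison; distinct
#: hypergeometric probabilities at these table sizes differ by >= ~1e-4
#: relative, so any tolerance far below that is safe
TIE_REL_TOL = 1e-9


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of fixed-margin tables."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + TIE_REL_TOL)].sum())


def fisher_one_sided_enumeration(a: int, b: int, c: int, d: int, tail: str) -> float:
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    if tail == "greater":
        return float(pmf[ks >= a].sum())
    if tail == "less":
        return float(pmf[ks <= a].sum())
    raise ValueError(tail)


def assign_targets_all_pairs(peaks, genes, rule):
    """O(n*m) containment oracle for the peak-to-gene window rule."""
    pairs = set()
    for peak in peaks:
        for gene in genes:
            if gene.chrom != peak.chrom:
                continue
            off = gene.oriented_offset(peak.summit)
            up = rule.upstream_for(gene.gene_id)
            if -up <= off < gene.length + rule.downstream_bp:
                pairs.add((peak.peak_id, gene.gene_id))
    return pairs


def pooled_t_closed_form(xa, xb):
    """Hand-written pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as t_dist

    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    na, nb = len(xa), len(xb)
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = (xb.mean() - xa.mean()) / se
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def pwm_best_hit_scan(matrix, pseudocount, sequence):
    """Exhaustive best log2-odds hit over all offsets and both strands."""
    import math

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    p = matrix + pseudocount
    p = p / p.sum(axis=0)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = matrix.shape[1]

    def score(seq):
        best = -math.inf
        for off in range(len(seq) - L + 1):
            s = 0.0
            for j in range(L):
                base = seq[off + j]
                if base != "N":
                    s += math.log2(p[index[base], j] / 0.25)
            best = max(best, s)
        return best

    rc = "".join(comp[b] for b in reversed(sequence))
    return max(score(sequence), score(rc))
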