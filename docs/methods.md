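# Methods

## Problem setting

A reciprocal marker-gene pair (a secreted ligand and its receptor whose
expression domains abut without overlapping) partitions an annotated
anatomical map into two region sets. Genes whose detected expression is
strongly skewed toward one set are candidate effectors of that domain's
identity; combining them with direct-binding (ChIP-seq) and perturbation
(TF knockdown) evidence yields a signed, domain-restricted regulatory
network. This package implements that chain of inference as composable,
individually testable stages.

## Domain derivation and pattern classification

The ISH annotation table is categorical; we binarize with `Undetected`
→ 0 and any detected level (`Low`, `Medium`, `High`) → 1. Curated
exports are routinely incomplete, so the default missing-cell policy is
missing-as-zero with a logged count; a strict mode turns any missing
cell into an error. Density/pattern annotation columns are carried but
never used.

Domain A is the region set where marker A is detected and marker B is
not; domain B the reverse. Regions with both or neither marker are
**unassigned** and excluded from every contingency table: the test
universe is only |A| + |B| regions. This matches the framing of genes
"expressed exclusively" in one domain; had the original analyses used
the full region list as universe, absolute counts would differ, which
is why planted-truth recovery, not a literal count, is the acceptance
property. The same reasoning applies to the expression minima: we count
expressed regions *within* the domain.

Fisher's exact test is computed by exact integer enumeration of the
hypergeometric support (`math.comb`), with the standard two-sided
convention (sum of point probabilities ≤ the observed one). Region
counts never exceed a few dozen, so exactness is free; an independent
float enumeration oracle and scipy's implementation agree with it to
~1e−15 across the exhaustive grid of tables with margins ≤ 40 (distinct
hypergeometric point probabilities at those sizes are separated by at
least ~1e−4 relative, so float tie handling cannot flip a table).

Direction is carried by the unconditioned cross-product odds ratio
(a·d)/(b·c) with the conventions: b·c = 0 ∧ a·d > 0 → +∞ (counts as
> 1); a·d = 0 ∧ b·c > 0 → 0; both zero → undefined, label `none`.
A conditional-MLE estimator could change the magnitude but never the
direction, and only direction matters here. The selection thresholds
default to p < 1e−4 with strict minima a > 10 (A-pattern) and b > 15
(B-pattern) — "more than N" meaning ≥ N + 1. Sidedness: we use the
two-sided p and enforce direction separately via the odds ratio; at
p < 1e−4 this reproduces a one-sided selection in either reading,
because the one-sided p is at most the two-sided p and at most twice
smaller in the selected direction. Marker genes are classified like any
other gene but flagged `is_marker`.

## Peak-to-gene assignment

Windows are half-open in gene orientation: a summit at offset *o* from
the TSS (negative = upstream) is inside iff −upstream ≤ *o* <
gene_length + downstream. The upstream boundary itself is inside; the
choice of half-open downstream edge is arbitrary but fixed and tested.
Defaults are 10 kb upstream and 3 kb downstream. Per-gene upstream
overrides replace the global upstream for that gene only (the distal
promoter precedent: 17,491 bp). The default anchor is the peak summit;
an any-overlap mode exists for sensitivity analysis but relations and
distances are always reported from the summit. Multi-gene hits are all
reported — the target definition is per-gene containment, not
nearest-gene. Duplicate transcripts resolve to the longest, a common
convention isolated in one function.

The location summary classifies each summit once, with precedence
5′UTR > 3′UTR > exon > intron > unresolved gene body > upstream bins
(nearest TSS) > intergenic. UTRs require exon + CDS structure
(BED12 thick region or GTF CDS features); genes without exon structure
contribute `gene-body`. Upstream bins (0–1 kb, 1–3 kb, 3–10 kb) are
exclusive in the percentage table and additionally reported as nested
cumulative fractions. Percentages are over all peaks and must sum to
100 ± 1e−9.

## Expression response

The two-group DE test is the pooled-variance (Student) t, two-sided,
with Welch behind a flag; zero-pooled-variance genes get p = 1 and a
`degenerate` flag. No multiple-testing correction gates the default
significance calls (raw p < 0.05, matching the conventions of the data
this emulates); a Benjamini–Hochberg column is emitted for
transparency. The Cuffdiff filter keeps status = OK ∧ p < 0.05
(strict). Which expression column is the knockdown sample is explicit,
never inferred — a silent orientation flip would invert every inferred
sign. Merging of multiple knockdown replicates' tables is left to the
caller (both intersection and union are defensible; the package takes
one table at a time).

## Sign rules and network assembly

Only pattern-labeled genes are admitted as targets; TFs may come from
outside the annotated universe and are then labeled `TF-only` (allowed
as sources, never as targets). ChIP evidence builds the edge set;
promoter-motif predictions can add edges only when explicitly passed,
and stay distinguishable via the edge `evidence` attribute. Sign
priority: knockdown evidence (R1) strictly precedes expression logic
(R2); conflicting knockdown calls for one edge are an upstream data
inconsistency and raise. R2 encodes the mutual-exclusivity argument:
regulator and target expressed in opposite domains suggests repression,
shared domain suggests activation — hence the `proposed-` prefix, these
are hypotheses, not measurements. Indirect regulatory routes (a TF
acting through an intermediate) are deliberately not encoded; no
computable rule distinguishes them from direct ones at this evidence
level.

## Motif analysis

Promoters are −1000..+200 nt around the TSS (1200 nt), strand-aware and
truncated with a warning at contig edges. PWM probabilities get a
pseudocount of 0.01 (renormalized) before log₂-odds against a uniform
background; N scores 0. The per-promoter statistic is the best single
hit over both strands (Pscan-like), and set-level enrichment is
z = (x̄_fg − x̄_bg)/(s_bg/√n_fg) with the n−1 background SD and a
one-sided normal p. This z-test is a stated approximation: best-hit
scores are skewed and the background-mean uncertainty is ignored, which
inflates the null type-I rate somewhat (empirically ~0.06–0.09 at
α = 0.05 in the shipped calibration runs) — the acceptance band
[0.01, 0.10] is deliberately wide for this reason. Enrichment over sets
of orthologous promoters from several genomes is out of scope; the
statistic is unchanged per genome. Result filtering keeps p < 0.005
(strict) and rank ≤ 20.

## Synthetic data

The generators define the study conditions for every verification in
this package:

* **ISH matrix** — 20 A + 30 B + 28 other regions; 50 planted-A, 300
  planted-B, 1650 background genes plus the two noise-free markers
  (matching the scale of the curated atlas this emulates: ~2000 genes,
  78 regions, 20/30-region domains). Planted genes are Bernoulli(p_in =
  0.95) in their home domain and Bernoulli(p_out = 0.02) elsewhere;
  background genes Bernoulli(p_bg = 0.10) everywhere. Markers are
  noise-free because domains in the real workflow come from curated
  annotations, not noisy calls.
* **Toy genome** — non-overlapping genes with random strands, laid out
  so no two target windows overlap and a ≥ 2 kb intergenic margin
  separates windows; a chosen fraction of peak summits is placed
  uniformly inside randomly chosen windows, the rest in
  guaranteed-intergenic gaps. This makes intended assignments exactly
  recoverable, which is the point: the generator tests the window rule,
  not ambiguity resolution.
* **DE table** — planted direct targets receive p < 0.05 with fold
  changes whose direction encodes the planted sign (activation ⇒ down
  after knockdown); all other genes draw p ~ Uniform(0, 1), so ~5 % of
  them pass the filter and exercise the `indirect` call path.
* **Promoters** — i.i.d. uniform nucleotides, with the motif consensus
  planted at a uniform offset with a given probability.

All generators draw from splittable streams (`SeedSequence` with a
per-generator stream key) derived from one global seed, so adding one
generator call never changes another's output; equal (spec, seed) gives
byte-identical output.

What the synthetic data does **not** emulate: spatial autocorrelation
between neighbouring regions, annotation noise in the markers,
overlapping genes and shared promoters, GC/repeat structure of real
genomes, and correlated DE p-values. Passing recovery tests therefore
demonstrates correctness of the inference machinery under its own
assumptions, not performance on real atlas or sequencing data.

## Problem sizes and numerical choices

The shipped verification runs use: 20 simulated atlases (2002 × 78) for
pattern recovery; the exhaustive 2×2 grid with margins ≤ 40 (741 320
tables) for exact-test agreement; 200 genes × 1000 peaks (4 chromosomes,
6 Mb each, including two 17,491 bp overrides) for the window oracle;
50 power runs (50 fg vs 500 bg promoters) and 200 null runs for motif
calibration; 100 random matrices plus 10 × 2000 null genes for the
t-test. These sizes were chosen so the whole verification completes in
about a minute on one CPU while keeping every binomial standard error
small relative to the tolerances tested.

Tie-breaking is deterministic everywhere: enrichment tables sort by
(p, −OR, term id), motif ranks by (p, motif id), assignments by
(peak id, gene id), and all exports sort nodes and edges, so re-running
any stage on identical inputs is byte-identical.

## Known limitations

* The region universe choice (domain regions only) is a documented
  reading, not a certainty; a full-universe variant would need only a
  different `DomainPair`.
* The motif z statistic is approximate (see above); use the calibration
  numbers, not nominal p-values, when comparing motif ranks across
  studies.
* Absolute result counts from the original biological setting (pattern
  gene totals, peak/target counts, DE totals) depend on external
  curated resources and are not reproduced here; the package verifies
  the procedures, and applies unchanged to the real exports when
  available.
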