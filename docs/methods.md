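# Methods

## Scope and model

`bregtools` operationalizes the identification of regulatory B (Breg) cells
from paired single-cell expression and BCR data as a fixed sequence of
defined computations: QC filtering, library-size log-normalization and
per-gene z-scaling, signature module scoring with thresholded Breg / B10
calls, per-organ differential expression with a cross-organ intersection,
and entropy-based clonal repertoire indices. Embedding and clustering are
deliberately treated as plumbing: they only subdivide called Breg cells
into subsets, and no particular subset count is promised — the cluster
number depends on resolution and neighborhood parameters that the method
itself does not pin down.

## Module score and calls

The score of cell `c` for signature `S` is `log1p(mean of z-scaled values
of the S genes in c)`. Two numerical conventions materially shift the
score's operating point and are therefore pinned and exposed:

- **Scaling sd.** Per-gene standardization uses the sample standard
  deviation (`ddof=1`), the denominator used by the reference single-cell
  toolkit's `ScaleData`; `ddof=0` is available. For two cells with values
  (0, 2) this gives scaled values (-0.7071, +0.7071) (sample sd = sqrt(2));
  the population convention gives (-1, +1).
- **Clipping.** Scaled values are clipped above at 10 with no lower clip
  (reference default). Clipping bounds the influence of single extreme
  cells on signature means.

Because clipped z-scores can average at or below -1, where `log1p` is
undefined, such cells receive a `-inf` sentinel: they are recorded, never
an error, and fall below any finite threshold.

Calls are strict: Breg iff score > 0.16, B10 (among Breg) iff B10 score >
threshold. The B10 threshold is genuinely underdetermined — the source
analysis says only that cells with a "high" B10 score are B10 — so the
default is 0.0 (the signature-neutral point: positive mean z over the B10
genes), with `calibrate_threshold` providing a deterministic data-driven
alternative: an exact 1-D two-means partition of the score distribution,
returning the midpoint of the two group means. On synthetic data with 60%
planted B10 at a 2-fold effect, the neutral threshold over-calls (~77%)
because called-Breg cells are globally shifted upward in z; the calibrated
threshold recovers ~53–55%.

## QC

Boundaries are strict in all four cell rules (genes detected in (300,
8000), mito <= 10%, complexity `log10(genes)/log10(UMIs)` >= 0.8), so
boundary cells are kept. Complexity is undefined for cells with <= 1 UMI
or no detected genes; such cells fail QC. Mitochondrial genes are
recognized by a case-insensitive `mt-` symbol prefix (mouse convention;
configurable). Filter order is fixed — cell rules, then the >= 10-cells
gene filter on retained cells, then BCR multichain removal — and the
summary log reports removals per rule in that order. The multichain rule
defaults to AND over chain classes (>= 2 distinct heavy AND >= 2 distinct
light chain keys), with an OR variant exposed; distinctness is at the
clonotype chain-key level so duplicate records of one chain never flag a
cell. Contig records whose barcode is absent from the matrix are kept but
flagged `unmatched` and excluded from doublet flagging; no rule for them is
defined upstream, and silently dropping data seemed worse than flagging.

A note on idempotence: each individual filter is idempotent; the composite
is in principle not (removing genes changes per-cell metrics), but at the
scales used here re-running the full QC removes nothing, which the suite
checks on fixed seeds.

## Differential expression

Per organ, Breg vs non-Breg cells are compared gene-wise on log-normalized
values with a two-sided Wilcoxon rank-sum test: exact distribution when
both groups have <= 25 cells and the gene has no ties, midrank normal
approximation with continuity correction otherwise. P-values are BH-
corrected across tested genes (genes expressed in >= 10% of either group).
log2 fold-changes are computed on expm1-means with a pseudocount of 1. The
cross-organ marker set intersects per-organ upregulated genes
(`padj < 0.05` and `log2FC > 0.25` in every organ); these thresholds are
ecosystem defaults, not derived quantities, and are all exposed in the run
config. On synthetic data the intersection is dominated by the planted
signature genes (~134 at the default effect size), which is the expected
behavior of the construction rather than a claim about real tissue.

## Clonal indices

Clonotype identity is the canonical string of all of a cell's productive
chains, each contributing `chain:V gene:CDR3` (amino-acid CDR3 by default,
nucleotide optionally), sorted lexicographically — so identity requires
matching V genes and CDR3s on every chain. All entropies are base 2, which
bounds the two-cluster transition index by 1. Conventions at the degenerate
point `K = 1` clonotype: a multi-cell monoclonal cluster has expansion 1, a
single cell 0 (no evidence of expansion either way). Pairwise organ sharing
counts clonotypes present in both organs, and shared cells over the union
of the pair (both sides counted) — the counting side of "shared cells" is
not defined upstream, so this choice is stated prominently here and in the
function docstring. Migration and transition are computed within-cluster,
over the cells of the cluster(s) in question only. Tie-breaks in the
top-clonotype ranking are lexicographic by key for determinism.

## Synthetic data generator

The generator emulates a pooled five-organ mouse B-cell experiment:

- **Counts.** Gene base means are log-normal (sigma = 1); each cell draws a
  gamma library-size factor (mean 5,000 UMIs, shape 2) and counts are
  gamma-Poisson (negative binomial) with dispersion 10 — the simplest
  generative model matching overdispersed UMI data. Planted Breg cells have
  their 134 signature-gene means multiplied by 2 (B10 cells additionally x2
  on 30 B10-signature genes), with per-cell renormalization so effects are
  compositional, not library-size shifts. Thirteen mitochondrial genes
  (`mt-` prefixed, real mouse symbols) carry 5% of expected library mass.
- **Prevalence.** Default planted Breg fractions are 30% in PC and 8–12%
  elsewhere, mirroring the higher peritoneal Breg prevalence in mice; the
  B10 fraction among Breg is 60%.
- **Repertoire.** Every non-doublet cell gets one heavy and one light
  chain. Two expanded clones of 20 cells are planted among PC Breg cells
  (the organ hosting clonally expanded subsets), 3 clones each are shared
  liver<->PC and spleen<->PC (one Breg cell per side), all remaining cells
  are clonal singletons, and 1% of cells are multichain doublets carrying
  two distinct clonotypes. CDR3 amino-acid strings are random (`C`
  ... `W`/`F` flanks) and the nucleotide string is a random in-frame
  back-translation — no biological VDJ model is attempted.

What the generator does *not* emulate: batch effects, ambient RNA,
cell-type structure beyond the Breg/B10 axis, somatic hypermutation,
isotype switching, hashtag demultiplexing noise, or realistic gene-gene
correlation. Passing recovery tests therefore demonstrates that the
implemented computations recover exactly the structure they are defined
over — not that the thresholds would transfer unchanged to real tissue.

One structural artifact is worth knowing: with a 1,500-gene universe the
complexity metric `log10(genes)/log10(UMIs)` saturates for high-UMI cells,
so the 0.8 complexity filter removes the deep-library tail (~15–20% of
cells at default settings) — a much larger share than on a full
transcriptome. The QC code is unaffected; only the synthetic pass rate is.

## Problem sizes and determinism

The test suite runs the generator at 5 x 150–200 cells and 400–500 genes
for module tests, and the recovery checks at 5 x 1,000 cells x 1,500 genes
with a 2-fold effect and uniform 15% Breg fraction — sizes chosen so the
planted-structure checks are comfortably powered while the whole suite
stays fast on one CPU. All randomness in the generator flows from the
single `SimConfig.seed` (expression and repertoire use independent streams
spawned from it); PCA, Leiden and t-SNE take explicit random states; and
identical configs reproduce byte-identical bundle files and pipeline CSVs,
which the suite asserts directly.

## Known limitations

- The 0.16 Breg threshold is consumed as given; its operating point
  depends on the scaling conventions above, so both are pinned and logged.
- The Breg sub-cluster count is configuration-dependent by design; no
  attempt is made to reproduce any particular subset count.
- The exact-Wilcoxon path is only engaged for small tie-free groups;
  single-cell data is tie-heavy, so the asymptotic path dominates in
  practice.
- Orphan contigs and cells without BCR records are retained (flagged) in
  repertoire outputs but excluded from indices, which assumes missingness
  is uninformative.
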