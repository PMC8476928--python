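# bregtools

Regulatory B (Breg) cells are immunosuppressive B cells with no single
surface marker: across mouse organs they are recognized operationally, by
elevated expression of a set of immunosuppressive and IL-10-associated
genes. `bregtools` implements that operational definition for paired
single-cell RNA + B-cell-receptor (BCR) data: it scores every B cell against
a Breg gene signature, calls Breg cells by a score threshold, partitions
them into IL-10-producing **B10** and **non-B10** subsets with a second
signature, finds marker genes shared across organs, and quantifies clonal
expansion, migration and inter-cluster transition from the paired BCR
repertoire.

The package is aimed at immunologists analyzing multi-organ B-cell atlases
(spleen, liver, mesenteric lymph node, peritoneal cavity, bone marrow) from
10x-style outputs, and ships a synthetic-data generator with planted ground
truth so the whole pipeline can be exercised and validated without any
download.

## The model

**Module score.** Let `Z` be the cell x gene matrix of log-normalized
(`ln(1 + count/total x 10^4)`) then per-gene z-scaled values (sample sd,
upper-clipped at 10). For a signature `S` of gene symbols, the score of
cell `c` is

```
score(c) = log1p( mean_{g in S} Z[c, g] )
```

A cell is **Breg** iff `score > 0.16` (strict); among Breg cells, a cell is
**B10** iff its B10-signature score exceeds the B10 threshold (default 0,
the signature-neutral point; a data-driven two-means calibration is
available as `b10_threshold="auto"`).

**QC.** A cell is removed iff it has more than 8,000 or fewer than 300
detected genes, more than 10% mitochondrial counts (`mt-` prefix), or
`log10(genes)/log10(UMIs) < 0.8`; all boundaries strict. Genes expressed in
fewer than 10 retained cells are dropped. Cells carrying two or more
distinct heavy chains AND two or more distinct light chains (clonotype key
`chain:V gene:CDR3`) are removed as multichain doublets.

**Clonal indices** (Shannon entropy, base 2). For a cell cluster with
clonotype frequencies `p_i` over `K` clonotypes:
`expansion = 1 - H(p)/log2 K` (1 = monoclonal, 0 = all singletons);
`migration = sum_i w_i H(tissue distribution of clone i)` with clone-size
weights `w_i`; `transition(A, B) = sum_i w_i H(split of clone i between
clusters A and B)`, bounded by 1.

**Markers.** Per organ, Breg vs non-Breg genes are tested with a two-sided
Wilcoxon rank-sum on log-normalized values (BH-corrected); genes
significantly upregulated (`padj < 0.05`, `log2FC > 0.25`) in *every* organ
form the common marker set.

## Worked example

```python
from bregtools import (SimConfig, generate_dataset, run_qc, lognormalize,
                       zscore_scale, compute_module_score, call_breg, call_b10,
                       composition_table, assign_clonotypes, pairwise_sharing,
                       expansion_index)

cfg = SimConfig(seed=0, cells_per_organ=300, n_genes=1500)
counts, truth, contigs = generate_dataset(cfg)

filtered, report, summary = run_qc(counts, contigs)
print(summary[-1])                       # final: 1187 cells x 1500 genes

scaled = zscore_scale(lognormalize(filtered))
scores = compute_module_score(scaled, truth.breg_signature)
calls = call_breg(scores, threshold=0.16)
b10 = compute_module_score(scaled, truth.b10_signature, cells=calls.breg_barcodes)
calls = call_b10(calls, b10, threshold=0.0)

organ = truth.cells["organ"].reindex(filtered.barcodes)
print(composition_table(calls, organ)["organ_breg"].round(3))
```

```
        n_cells  n_breg  breg_fraction  nonbreg_fraction
organ
BM          245      23          0.094             0.906
PC          237      63          0.266             0.734
liver       235      33          0.140             0.860
mLN         248      27          0.109             0.891
spleen      222      32          0.144             0.856
```

The peritoneal cavity (PC) shows the highest Breg fraction — the generator
plants 30% there versus 8–12% elsewhere, and the thresholded score
recovers the gradient. The repertoire side recovers the planted clonal
structure:

```python
assign = assign_clonotypes(contigs)
breg_cells = truth.cells.index[truth.cells["is_breg"]]
shared, _ = pairwise_sharing(assign, truth.cells["organ"], scope=breg_cells)
print(shared.loc["liver", "PC"])         # 3 planted liver<->PC shared clonotypes
```

A `bregtools` console script exposes the stages (`simulate`, `qc`, `score`,
`markers`, `repertoire`, `run`) for shell use; `bregtools run --seed 0
--outdir out/` executes the whole pipeline on a default synthetic dataset
and writes every artifact (QC report, scores, composition tables, per-organ
DE + common markers, sharing matrices, clonal indices, recovery report) as
plain CSV/JSON.

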