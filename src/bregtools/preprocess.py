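"""Normalization, scaling, and (as plumbing) embedding + clustering.

``lognormalize`` is the standard library-size normalization: each count is
divided by its cell's total, multiplied by a scale factor (default 10,000),
and natural-log1p transformed. ``zscore_scale`` standardizes each gene over
cells (sample standard deviation by default) and clips values above
``clip_max`` (default 10, no lower clip) — the convention the module scores
depend on. ``embed_cluster`` wraps PCA + neighborhood-graph Leiden clustering
(and optionally a t-SNE embedding); its parameters are plumbing and are not
tied to any particular expected number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountsMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels, a 2-D embedding, and the parameters used."""

    labels: pd.Series
    embedding: pd.DataFrame | None
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def lognormalize(counts: CountsMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """value(c, g) = ln(1 + count(c, g) / total(c) * scale_factor).

    Raises on zero-total cells; those should have been removed by QC.
    """
    totals = np.asarray(counts.values.sum(axis=1)).ravel()
    if np.any(totals == 0):
        zero = counts.barcodes[totals == 0]
        raise ValueError(
            f"{len(zero)} cell(s) with zero total counts, e.g. "
            f"{zero[:5].tolist()}; remove them with QC before normalizing"
        )
    dense = counts.values.toarray().astype(float)
    dense *= (scale_factor / totals)[:, None]
    np.log1p(dense, out=dense)
    return ExpressionMatrix(dense, counts.barcodes, counts.genes)


def zscore_scale(
    norm: ExpressionMatrix, clip_max: float = 10.0, ddof: int = 1
) -> ExpressionMatrix:
    """Per-gene standardization over cells, upper-clipped at ``clip_max``.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population convention. Constant genes map to all-zero
    columns. There is no lower clip.
    """
    if norm.shape[0] < 2:
        raise ValueError("scaling requires at least 2 cells")
    X = norm.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    out = np.zeros_like(X)
    nonconst = sd > 0
    out[:, nonconst] = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    np.minimum(out, clip_max, out=out)
    return ExpressionMatrix(out, norm.barcodes, norm.genes)


def embed_cluster(
    scaled: ExpressionMatrix,
    n_hvg: int | None = None,
    n_pcs: int = 30,
    resolution: float = 0.5,
    seed: int = 0,
    embedding: str | None = "tsne",
) -> ClusterAssignment:
    """PCA + Leiden clustering on the scaled matrix, deterministic under seed.

    ``n_hvg`` optionally restricts to the genes with the highest post-clip
    variance before PCA. ``embedding`` is ``"tsne"``, ``"pca"`` (first two
    PCs) or ``None``.
    """
    import anndata as ad
    import scanpy as sc

    n_cells, n_genes = scaled.shape
    max_rank = min(n_cells, n_genes) - 1
    if n_pcs > max_rank:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the matrix rank bound {max_rank} "
            f"for a {n_cells} x {n_genes} matrix"
        )
    X = scaled.values
    genes = scaled.genes
    if n_hvg is not None and n_hvg < n_genes:
        var = X.var(axis=0)
        order = np.argsort(var, kind="stable")[::-1][:n_hvg]
        order = np.sort(order)
        X = X[:, order]
        genes = genes[order]

    adata = ad.AnnData(
        X=np.ascontiguousarray(X),
        obs=pd.DataFrame(index=scaled.barcodes.astype(str)),
        var=pd.DataFrame(index=genes.astype(str)),
    )
    sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, use_rep="X_pca", random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = pd.Series(
        adata.obs["leiden"].astype(str).to_numpy(), index=scaled.barcodes, name="cluster"
    )

    emb = None
    if embedding == "pca":
        emb = pd.DataFrame(
            adata.obsm["X_pca"][:, :2], index=scaled.barcodes, columns=["dim1", "dim2"]
        )
    elif embedding == "tsne":
        perplexity = min(30.0, max(2.0, (n_cells - 1) / 4))
        sc.tl.tsne(adata, use_rep="X_pca", random_state=seed, perplexity=perplexity)
        emb = pd.DataFrame(
            adata.obsm["X_tsne"], index=scaled.barcodes, columns=["tsne1", "tsne2"]
        )
    elif embedding is not None:
        raise ValueError(f"unknown embedding {embedding!r}")

    params = {
        "n_hvg": n_hvg,
        "n_pcs": n_pcs,
        "resolution": resolution,
        "seed": seed,
        "embedding": embedding,
        "n_clusters": int(labels.nunique()),
    }
    logger.info("clustered %d cells into %d clusters", n_cells, labels.nunique())
    return ClusterAssignment(labels=labels, embedding=emb, parameters=params)
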