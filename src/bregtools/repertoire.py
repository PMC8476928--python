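"""Clonotype assignment, pairwise-organ sharing, and clonal entropy indices.

A cell's clonotype key is built from ALL of its productive chains: each chain
contributes ``chain:v_gene:CDR3`` (amino-acid CDR3 by default, nucleotide
optionally) and the sub-keys are sorted lexicographically and joined, so two
cells share a clonotype iff their canonical keys are string-equal.

The three indices are Shannon-entropy based, in bits (base 2):

- expansion index of a cluster = 1 - H(clone frequencies) / log2(K) for K > 1
  distinct clonotypes (1 for a multi-cell monoclonal cluster, 0 for a single
  cell); 1 means monoclonal expansion, 0 all singletons.
- migration index of a cluster = sum over clonotypes of w_i * H_i where H_i is
  the entropy of clone i's tissue distribution within the cluster and w_i its
  clone-size share; bounded by log2(number of tissues).
- transition index between two clusters = the same clone-size-weighted entropy
  of each clone's split between the two clusters, over the cells of their
  union; bounded by 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .io_qc import VALID_CHAINS

logger = logging.getLogger(__name__)


def assign_clonotypes(
    contigs: pd.DataFrame, key_mode: str = "aa"
) -> pd.DataFrame:
    """Canonical clonotype key per cell, from all productive chains.

    Returns a table indexed by barcode with ``clonotype`` (the canonical key),
    ``n_chains`` and ``clone_size``. Records flagged ``unmatched`` and
    non-productive records are excluded; cells left with no chains are absent
    from the result (they are retained elsewhere in the pipeline).
    """
    if key_mode not in ("aa", "nt"):
        raise ValueError(f"key_mode must be 'aa' or 'nt', got {key_mode!r}")
    if len(contigs) == 0:
        return pd.DataFrame(columns=["clonotype", "n_chains", "clone_size"]).rename_axis("barcode")
    work = contigs
    if "unmatched" in work.columns:
        work = work[~work["unmatched"].fillna(False).astype(bool)]
    if "productive" in work.columns:
        prod = work["productive"]
        if prod.dtype == object:
            prod = prod.astype(str).str.lower().isin(("true", "t"))
        work = work[prod.astype(bool)]
    if len(work) == 0:
        return pd.DataFrame(columns=["clonotype", "n_chains", "clone_size"]).rename_axis("barcode")
    bad = set(work["chain"].astype(str)) - VALID_CHAINS
    if bad:
        raise ValueError(f"invalid chain class(es): {sorted(bad)}")
    cdr3 = work["cdr3"] if key_mode == "aa" else work["cdr3_nt"]
    sub_keys = (
        work["chain"].astype(str) + ":" + work["v_gene"].astype(str) + ":" + cdr3.astype(str)
    )
    per_cell = (
        pd.DataFrame({"barcode": work["barcode"], "sub_key": sub_keys})
        .groupby("barcode")["sub_key"]
        .agg(lambda keys: ";".join(sorted(set(keys))))
        .rename("clonotype")
    )
    n_chains = (
        pd.DataFrame({"barcode": work["barcode"], "sub_key": sub_keys})
        .groupby("barcode")["sub_key"]
        .nunique()
        .rename("n_chains")
    )
    out = pd.concat([per_cell, n_chains], axis=1)
    out["clone_size"] = out.groupby("clonotype")["clonotype"].transform("size")
    return out


def _entropy_bits(counts: Sequence[float]) -> float:
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def expansion_index(clonotypes: Sequence[str]) -> float:
    """1 - normalized Shannon entropy of clonotype frequencies in a cluster.

    ``clonotypes`` is one entry per cell. A monoclonal cluster of >= 2 cells
    scores 1 (maximal expansion); a single cell scores 0 (no evidence).
    """
    clonotypes = list(clonotypes)
    if not clonotypes:
        raise ValueError("expansion index of an empty cluster is undefined")
    sizes = Counter(clonotypes)
    k = len(sizes)
    n = len(clonotypes)
    if k == 1:
        return 1.0 if n >= 2 else 0.0
    return 1.0 - _entropy_bits(sizes.values()) / np.log2(k)


def migration_index(
    clonotypes: Sequence[str], tissues: Sequence[str]
) -> float:
    """Clone-size-weighted entropy of each clone's tissue distribution."""
    clonotypes = list(clonotypes)
    tissues = list(tissues)
    if not clonotypes:
        raise ValueError("migration index of an empty cluster is undefined")
    if len(clonotypes) != len(tissues):
        raise ValueError("clonotypes and tissues must have equal length")
    n = len(clonotypes)
    index = 0.0
    df = pd.DataFrame({"clone": clonotypes, "tissue": tissues})
    for _, grp in df.groupby("clone", sort=False):
        w = len(grp) / n
        index += w * _entropy_bits(Counter(grp["tissue"]).values())
    return index


def transition_index(
    clonotypes_a: Sequence[str], clonotypes_b: Sequence[str]
) -> float:
    """Clone-size-weighted entropy of clone splits between two clusters.

    One entry per cell of each cluster. Clones confined to one cluster
    contribute zero; a clone split evenly contributes its full weight.
    """
    a = Counter(clonotypes_a)
    b = Counter(clonotypes_b)
    n = sum(a.values()) + sum(b.values())
    if n == 0:
        raise ValueError("transition index of an empty cluster pair is undefined")
    index = 0.0
    for clone in set(a) | set(b):
        size = a.get(clone, 0) + b.get(clone, 0)
        index += size / n * _entropy_bits([a.get(clone, 0), b.get(clone, 0)])
    return index


def transition_between(
    assign: pd.DataFrame, clusters: pd.Series, cluster_a: str, cluster_b: str
) -> float:
    """Transition index between two named clusters of assigned cells."""
    if cluster_a == cluster_b:
        raise ValueError("transition index requires two distinct clusters")
    clusters = clusters.reindex(assign.index)
    clones_a = assign.loc[clusters == cluster_a, "clonotype"]
    clones_b = assign.loc[clusters == cluster_b, "clonotype"]
    return transition_index(clones_a.tolist(), clones_b.tolist())


def clonal_index_table(
    assign: pd.DataFrame,
    clusters: pd.Series,
    tissues: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster expansion/migration indices and the pairwise transition matrix.

    ``assign`` is the output of :func:`assign_clonotypes`; ``clusters`` and
    ``tissues`` label its cells (cells missing a label are dropped with a
    note). Clusters with no assigned cells are omitted.
    """
    clusters = clusters.reindex(assign.index)
    tissues = tissues.reindex(assign.index)
    keep = clusters.notna() & tissues.notna()
    if keep.sum() < len(assign):
        logger.info("%d assigned cells lack cluster/tissue labels; dropped",
                    int(len(assign) - keep.sum()))
    work = assign[keep]
    clusters = clusters[keep]
    tissues = tissues[keep]

    rows = []
    names = sorted(clusters.unique())
    for cl in names:
        mask = clusters == cl
        clones = work.loc[mask, "clonotype"].tolist()
        rows.append(
            {
                "cluster": cl,
                "n_cells": len(clones),
                "n_clonotypes": len(set(clones)),
                "expansion": expansion_index(clones),
                "migration": migration_index(clones, tissues[mask].tolist()),
            }
        )
    per_cluster = pd.DataFrame(rows).set_index("cluster")

    trans = pd.DataFrame(0.0, index=names, columns=names)
    for i, ca in enumerate(names):
        for cb in names[i + 1 :]:
            val = transition_between(work, clusters, ca, cb)
            trans.loc[ca, cb] = val
            trans.loc[cb, ca] = val
    return per_cluster, trans


def pairwise_sharing(
    assign: pd.DataFrame,
    organs: pd.Series,
    scope: pd.Index | None = None,
    organ_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared clonotype and shared cell counts between organ pairs.

    For organs (A, B): the shared-clonotype count is the number of clonotypes
    present in both; the shared-cell count is the number of scope cells in
    A or B bearing such a shared clonotype (both sides of the pair counted).
    ``scope`` restricts the cells considered (e.g. to Breg cells). Both
    matrices are symmetric; the diagonal is left at zero by convention.
    """
    work = assign if scope is None else assign.loc[assign.index.intersection(scope)]
    organs = organs.reindex(work.index)
    if organs.isna().any():
        work = work[organs.notna()]
        organs = organs.dropna()
    names = list(organ_order) if organ_order is not None else sorted(organs.unique())
    clones_by_organ = {
        o: work.loc[organs == o, "clonotype"] for o in names
    }
    clono = pd.DataFrame(0, index=names, columns=names, dtype=int)
    cells = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        set_a = set(clones_by_organ[a])
        for b in names[i + 1 :]:
            set_b = set(clones_by_organ[b])
            shared = set_a & set_b
            clono.loc[a, b] = clono.loc[b, a] = len(shared)
            n_cells = int(
                clones_by_organ[a].isin(shared).sum()
                + clones_by_organ[b].isin(shared).sum()
            )
            cells.loc[a, b] = cells.loc[b, a] = n_cells
    return clono, cells


def top_clonotypes(
    assign: pd.DataFrame,
    n: int = 10,
    organs: pd.Series | None = None,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """The ``n`` largest clonotypes, ties broken lexicographically by key.

    Optionally adds per-organ and per-cluster cell-count columns.
    """
    if len(assign) == 0:
        raise ValueError("no clonotype assignments")
    sizes = (
        assign.groupby("clonotype").size().rename("size").reset_index()
        .sort_values(["size", "clonotype"], ascending=[False, True])
        .head(n)
        .set_index("clonotype")
    )
    sizes.insert(0, "rank", range(1, len(sizes) + 1))
    for label, series in (("organ", organs), ("cluster", clusters)):
        if series is None:
            continue
        series = series.reindex(assign.index)
        ct = pd.crosstab(assign["clonotype"], series)
        ct.columns = [f"{label}_{c}" for c in ct.columns]
        sizes = sizes.join(ct, how="left")
    return sizes
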