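"""Per-organ Breg vs non-Breg differential expression and cross-organ markers.

Differential expression uses a two-sided Wilcoxon rank-sum test per gene on
log-normalized values, with Benjamini-Hochberg correction across the tested
genes. Genes are pre-filtered to those expressed in at least ``min_pct`` of
either group. The log2 fold-change is computed on expm1-means with a
pseudocount of 1 (log2((mean(expm1 x) + 1) / (mean(expm1 y) + 1))), the usual
convention for log1p-normalized single-cell data.

The cross-organ marker set is the intersection of per-organ upregulated genes
(adjusted p below ``fdr`` AND log2FC above ``min_log2fc`` in every organ).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .scoring import BregCall

logger = logging.getLogger(__name__)

# above this per-group size the normal approximation (with tie midranks and
# continuity correction) replaces the exact rank-sum distribution
EXACT_MAX_N = 25


def _ranksum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per column (gene).

    Exact distribution when both groups are small (<= 25) and a gene has no
    ties; midrank normal approximation with continuity correction otherwise.
    """
    n1, n2 = a.shape[0], b.shape[0]
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pvals = np.empty(a.shape[1])
        for j in range(a.shape[1]):
            col = np.concatenate([a[:, j], b[:, j]])
            has_ties = len(np.unique(col)) < len(col)
            method = "asymptotic" if has_ties else "exact"
            pvals[j] = stats.mannwhitneyu(
                a[:, j], b[:, j], alternative="two-sided", method=method
            ).pvalue
        return pvals
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", axis=0
    )
    return np.asarray(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def rank_genes_breg(
    norm: ExpressionMatrix,
    calls: BregCall,
    organs: pd.Series,
    organ: str,
    min_pct: float = 0.1,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Breg vs non-Breg differential expression within one organ.

    Returns a table indexed by gene with ``log2fc``, ``pval``, ``padj``,
    ``pct_breg``, ``pct_rest`` and the organ label, sorted by p-value
    (ties by gene symbol).
    """
    organs = organs.reindex(norm.barcodes)
    in_organ = (organs == organ).to_numpy()
    is_breg = calls.is_breg.reindex(norm.barcodes).fillna(False).to_numpy()
    breg_mask = in_organ & is_breg
    rest_mask = in_organ & ~is_breg
    for label, mask in (("Breg", breg_mask), ("non-Breg", rest_mask)):
        if mask.sum() == 0:
            raise ValueError(f"organ {organ}: {label} group is empty")
        if mask.sum() < min_group_size:
            raise ValueError(
                f"organ {organ}: {label} group has {int(mask.sum())} cells, "
                f"fewer than min_group_size={min_group_size}"
            )

    X_breg = norm.values[breg_mask]
    X_rest = norm.values[rest_mask]
    pct_breg = (X_breg > 0).mean(axis=0)
    pct_rest = (X_rest > 0).mean(axis=0)
    tested = (pct_breg >= min_pct) | (pct_rest >= min_pct)
    if not tested.any():
        raise ValueError(f"organ {organ}: no gene passes the min_pct filter")

    a = X_breg[:, tested]
    b = X_rest[:, tested]
    pvals = _ranksum_pvalues(a, b)
    padj = bh_adjust(pvals)
    mean_breg = np.expm1(a).mean(axis=0)
    mean_rest = np.expm1(b).mean(axis=0)
    log2fc = np.log2(mean_breg + 1.0) - np.log2(mean_rest + 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pval": pvals,
            "padj": padj,
            "pct_breg": pct_breg[tested],
            "pct_rest": pct_rest[tested],
            "organ": organ,
        },
        index=norm.genes[tested],
    )
    table = table.sort_values(["pval", "log2fc"], ascending=[True, False])
    logger.info(
        "DE %s: %d Breg vs %d non-Breg cells, %d genes tested",
        organ, a.shape[0], b.shape[0], int(tested.sum()),
    )
    return table


def upregulated_set(
    table: pd.DataFrame, fdr: float = 0.05, min_log2fc: float = 0.25
) -> set[str]:
    """Genes significantly upregulated in Breg cells in one organ table."""
    mask = (table["padj"] < fdr) & (table["log2fc"] > min_log2fc)
    return set(table.index[mask])


def intersect_common_markers(
    tables: Mapping[str, pd.DataFrame],
    fdr: float = 0.05,
    min_log2fc: float = 0.25,
) -> tuple[list[str], dict[str, set[str]], dict]:
    """Genes upregulated in Breg cells in EVERY organ.

    Returns the sorted common gene list, the per-organ upregulated sets, and
    a summary (per-organ set sizes, all pairwise intersection sizes, and the
    full intersection size) sufficient to rebuild a Venn diagram.
    """
    if not tables:
        raise ValueError("no DE tables given")
    per_organ = {
        organ: upregulated_set(tab, fdr=fdr, min_log2fc=min_log2fc)
        for organ, tab in tables.items()
    }
    organs = sorted(per_organ)
    common: set[str] = set.intersection(*per_organ.values())
    summary = {
        "organs": organs,
        "set_sizes": {o: len(per_organ[o]) for o in organs},
        "pairwise_intersections": {
            f"{a}&{b}": len(per_organ[a] & per_organ[b])
            for i, a in enumerate(organs)
            for b in organs[i + 1 :]
        },
        "common_size": len(common),
        "fdr": fdr,
        "min_log2fc": min_log2fc,
    }
    return sorted(common), per_organ, summary
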