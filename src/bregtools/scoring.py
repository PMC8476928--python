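"""Module scoring of gene signatures and the Breg / B10 calls.

The module score of a cell for a signature is ``log1p(m)`` where ``m`` is the
mean of the cell's z-scaled expression values over the signature genes present
in the matrix. Cells whose mean falls at or below -1 (possible on clipped
z-scores, where log1p is undefined) receive a -inf sentinel and are therefore
below any finite threshold.

Cells with a Breg-signature score strictly greater than the Breg threshold
(default 0.16) are called Breg; among Breg cells, those with a B10-signature
score strictly greater than the B10 threshold (default 0.0, the
signature-neutral point) are called B10, the rest non-B10 Breg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-cell module scores for one signature."""

    scores: pd.Series
    signature: str
    n_genes_used: int
    genes_used: tuple[str, ...] = ()


@dataclass
class BregCall:
    """Per-cell Breg and (for Breg cells only) B10 flags."""

    is_breg: pd.Series
    is_b10: pd.Series | None = None
    breg_threshold: float = 0.16
    b10_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.is_b10 is not None:
            bad = self.is_b10.fillna(False).astype(bool) & ~self.is_breg
            if bad.any():
                raise ValueError("is_b10 implies is_breg; call violates this")

    @property
    def breg_barcodes(self) -> pd.Index:
        return self.is_breg.index[self.is_breg]


def compute_module_score(
    scaled: ExpressionMatrix,
    signature: GeneSignature,
    cells: Sequence[str] | pd.Index | None = None,
) -> ScoreVector:
    """Score each cell: log1p of the mean scaled value over signature genes.

    Signature genes absent from the matrix are dropped with a warning and
    reflected in ``n_genes_used``; a signature with no genes present raises.
    Means <= -1 map to a -inf sentinel.
    """
    present = [g for g in signature.genes if g in scaled.genes]
    missing = [g for g in signature.genes if g not in scaled.genes]
    if not present:
        raise ValueError(
            f"no gene of signature '{signature.name}' is present in the matrix"
        )
    if missing:
        logger.warning(
            "signature '%s': %d of %d genes missing from matrix (e.g. %s)",
            signature.name, len(missing), len(signature), missing[:5],
        )
    sub = scaled.subset(barcodes=cells, genes=present)
    m = sub.values.mean(axis=1)
    scores = np.full(m.shape, -np.inf)
    ok = m > -1.0
    scores[ok] = np.log1p(m[ok])
    if not ok.all():
        logger.warning(
            "signature '%s': %d cell(s) with mean scaled value <= -1 mapped "
            "to -inf sentinel", signature.name, int((~ok).sum()),
        )
    return ScoreVector(
        scores=pd.Series(scores, index=sub.barcodes, name=f"{signature.name}_score"),
        signature=signature.name,
        n_genes_used=len(present),
        genes_used=tuple(present),
    )


def call_breg(scores: ScoreVector, threshold: float = 0.16) -> BregCall:
    """Call cells Breg iff their score is strictly greater than ``threshold``."""
    is_breg = scores.scores > threshold
    is_breg.name = "is_breg"
    return BregCall(is_breg=is_breg, breg_threshold=threshold)


def call_b10(
    call: BregCall, b10_scores: ScoreVector, threshold: float = 0.0
) -> BregCall:
    """Partition Breg cells into B10 (score strictly above threshold) and non-B10.

    ``b10_scores`` must be computed on Breg cells only; scoring non-Breg cells
    for B10 is an error.
    """
    breg = set(call.breg_barcodes)
    extra = [bc for bc in b10_scores.scores.index if bc not in breg]
    if extra:
        raise ValueError(
            f"B10 scores supplied for {len(extra)} non-Breg cell(s), "
            f"e.g. {extra[:5]}"
        )
    is_b10 = pd.Series(pd.NA, index=call.is_breg.index, dtype="boolean", name="is_b10")
    is_b10.loc[b10_scores.scores.index] = (b10_scores.scores > threshold).to_numpy()
    return BregCall(
        is_breg=call.is_breg,
        is_b10=is_b10,
        breg_threshold=call.breg_threshold,
        b10_threshold=threshold,
    )


def calibrate_threshold(scores: ScoreVector | pd.Series) -> float:
    """Data-driven score threshold: midpoint of a two-means split.

    Intended for the B10 cut, where only a "high score" is specified: the
    finite scores are partitioned into two groups by 1-D k-means (k=2) and
    the midpoint of the two centers is returned. Deterministic.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    vals = np.sort(np.asarray(s[np.isfinite(s)], dtype=float))
    if len(vals) < 2 or vals[0] == vals[-1]:
        raise ValueError("cannot calibrate a threshold on <2 distinct scores")
    # exact 1-D 2-means: scan all split points for minimal within-group SSE
    csum = np.cumsum(vals)
    csq = np.cumsum(vals**2)
    n = len(vals)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):
        sse_l = csq[i - 1] - csum[i - 1] ** 2 / i
        sse_r = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        if sse_l + sse_r < best_sse:
            best_sse, best_i = sse_l + sse_r, i
    lo_mean = csum[best_i - 1] / best_i
    hi_mean = (csum[-1] - csum[best_i - 1]) / (n - best_i)
    return float((lo_mean + hi_mean) / 2)


def composition_table(
    calls: BregCall,
    organs: pd.Series,
    clusters: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Proportion tables: Breg per organ, and per-cluster organ / B10 splits.

    Each proportion block sums to 1 across its columns. Organs with zero
    cells are omitted with a logged note. ``clusters`` labels the Breg cells
    (the sub-clustering of called Breg cells).
    """
    organs = organs.reindex(calls.is_breg.index)
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for organ, group in calls.is_breg.groupby(organs, sort=True):
        n = len(group)
        if n == 0:
            logger.info("organ %s has zero cells; omitted", organ)
            continue
        n_breg = int(group.sum())
        rows.append(
            {
                "organ": organ,
                "n_cells": n,
                "n_breg": n_breg,
                "breg_fraction": n_breg / n,
                "nonbreg_fraction": (n - n_breg) / n,
            }
        )
    tables["organ_breg"] = pd.DataFrame(rows).set_index("organ")

    if clusters is not None:
        cluster_organ = (
            pd.crosstab(clusters, organs.reindex(clusters.index), normalize="index")
            .rename_axis(index="cluster", columns="organ")
            .sort_index()
        )
        tables["cluster_organ"] = cluster_organ
        if calls.is_b10 is not None:
            b10 = calls.is_b10.reindex(clusters.index).astype(bool)
            rows = []
            for cl, grp in b10.groupby(clusters, sort=True):
                n = len(grp)
                n_b10 = int(grp.sum())
                rows.append(
                    {
                        "cluster": cl,
                        "n_cells": n,
                        "b10_fraction": n_b10 / n,
                        "non_b10_fraction": (n - n_b10) / n,
                    }
                )
            tables["cluster_b10"] = pd.DataFrame(rows).set_index("cluster")
    return tables
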