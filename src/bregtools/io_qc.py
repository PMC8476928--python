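"""Reading of 10x-style bundles and the cell / gene / BCR quality filters.

Filter semantics use strict inequalities at every boundary: a cell is removed
iff it has *more than* ``max_genes`` or *less than* ``min_genes`` detected
genes, *more than* ``max_pct_mito`` percent mitochondrial counts, or a
genes-per-UMI complexity *less than* ``min_complexity``. Genes are kept when
expressed (count > 0) in at least ``min_cells_per_gene`` cells. Cells carrying
two or more distinct heavy chains AND two or more distinct light chains are
removed as multichain doublets (an OR-over-chain-classes variant is provided).

Filter order is fixed: cell filters first, then the gene filter on the
retained cells, then BCR-based doublet removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountsMatrix

logger = logging.getLogger(__name__)

VALID_CHAINS = {"IGH", "IGK", "IGL"}
LIGHT_CHAINS = {"IGK", "IGL"}


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs (all boundaries strict)."""

    min_genes: int = 300
    max_genes: int = 8000
    max_pct_mito: float = 10.0
    min_complexity: float = 0.8
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if min(self.min_genes, self.max_genes, self.max_pct_mito,
               self.min_complexity, self.min_cells_per_gene) <= 0:
            raise ValueError("all QC thresholds must be positive")


def read_tenx_bundle(
    directory: str | Path,
) -> tuple[CountsMatrix, pd.Series, pd.DataFrame]:
    """Read matrix.mtx + barcodes.tsv + features.tsv + metadata + contigs.

    Returns the cell-by-gene counts, the per-cell organ labels (aligned to the
    matrix barcodes), and the contig table with an ``unmatched`` flag on
    records whose barcode is absent from the matrix (such orphans are kept in
    repertoire outputs but never used for doublet flagging).
    """
    directory = Path(directory)
    try:
        mat = spio.mmread(str(directory / "matrix.mtx"))
    except ValueError as exc:
        raise ValueError(f"malformed matrix.mtx in {directory}: {exc}") from exc

    barcodes = pd.Index(
        [l.strip() for l in (directory / "barcodes.tsv").read_text().splitlines() if l.strip()],
        name="barcode",
    )
    feats = pd.read_csv(directory / "features.tsv", sep="\t", header=None, dtype=str)
    symbols = pd.Index(feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0],
                       name="gene")
    if symbols.has_duplicates:
        dups = symbols[symbols.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene symbol(s) in features.tsv: {dups[:10]}")

    # 10x convention: features as rows, cells as columns
    counts = CountsMatrix(sparse.csr_matrix(mat.T), barcodes, symbols)

    meta = pd.read_csv(directory / "cell_metadata.csv", dtype=str)
    missing = pd.Index(meta["barcode"]).difference(barcodes)
    if len(missing):
        raise ValueError(
            f"{len(missing)} cell(s) present in cell_metadata.csv but absent "
            f"from the matrix, e.g. {missing[:5].tolist()}"
        )
    organ = meta.set_index("barcode")["organ"].reindex(barcodes)
    if organ.isna().any():
        logger.warning(
            "%d matrix cells have no organ label in cell_metadata.csv",
            int(organ.isna().sum()),
        )

    contig_path = directory / "contigs.csv"
    if contig_path.exists():
        contigs = pd.read_csv(contig_path)
        if len(contigs) == 0:
            contigs = pd.read_csv(contig_path, dtype=str)
    else:
        contigs = pd.DataFrame(columns=["barcode", "chain", "v_gene", "cdr3", "cdr3_nt"])
    if len(contigs):
        contigs["unmatched"] = ~contigs["barcode"].isin(barcodes)
        n_orphan = int(contigs["unmatched"].sum())
        if n_orphan:
            logger.warning("%d contig record(s) with barcode not in matrix", n_orphan)
    else:
        contigs["unmatched"] = pd.Series(dtype=bool)
    return counts, organ, contigs


def compute_cell_metrics(
    counts: CountsMatrix, mito_prefix: str = "mt-"
) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total UMIs, mito %, complexity.

    ``complexity`` is log10(n_genes)/log10(n_umi), the genes-per-UMI measure;
    it is undefined (NaN) for cells with n_umi <= 1 or no detected genes, and
    such cells fail the complexity filter.
    """
    X = counts.values
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_mask = np.asarray(counts.genes.str.lower().str.startswith(mito_prefix.lower()))
    mito_counts = (
        np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any()
        else np.zeros(len(n_umi))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_counts / np.maximum(n_umi, 1), 0.0)
        complexity = np.where(
            (n_umi > 1) & (n_genes > 0),
            np.log10(np.maximum(n_genes, 1)) / np.log10(np.maximum(n_umi, 2)),
            np.nan,
        )
    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "n_umi": n_umi.astype(int),
            "pct_mito": pct_mito,
            "complexity": complexity,
        },
        index=counts.barcodes,
    )


def apply_cell_filters(
    metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the cell-level filters; boundary values are kept.

    Returns the kept barcodes and a per-cell report carrying every removal
    reason that applies (``low_n_genes``, ``high_n_genes``, ``high_pct_mito``,
    ``low_complexity``) plus the ``kept`` flag. Cells whose complexity is
    undefined fail the complexity rule.
    """
    t = thresholds
    report = metrics.copy()
    report["low_n_genes"] = metrics["n_genes"] < t.min_genes
    report["high_n_genes"] = metrics["n_genes"] > t.max_genes
    report["high_pct_mito"] = metrics["pct_mito"] > t.max_pct_mito
    report["low_complexity"] = ~(metrics["complexity"] >= t.min_complexity)
    reasons = ["low_n_genes", "high_n_genes", "high_pct_mito", "low_complexity"]
    report["kept"] = ~report[reasons].any(axis=1)
    kept = report.index[report["kept"]]
    return kept, report


def apply_gene_filter(counts: CountsMatrix, min_cells: int = 10) -> pd.Index:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells.

    Intended to run after cell filtering, on the retained cells.
    """
    cells_per_gene = counts.values.getnnz(axis=0)
    return counts.genes[cells_per_gene >= min_cells]


def _chain_keys(contigs: pd.DataFrame, key_mode: str = "aa") -> pd.Series:
    cdr3 = contigs["cdr3"] if key_mode == "aa" else contigs["cdr3_nt"]
    return contigs["chain"].astype(str) + ":" + contigs["v_gene"].astype(str) + ":" + cdr3.astype(str)


def flag_multichain_cells(
    contigs: pd.DataFrame, mode: str = "and", key_mode: str = "aa"
) -> pd.Index:
    """Barcodes to remove as multichain (multi-clonotype) doublets.

    Under the default ``and`` rule a cell is flagged iff it carries >= 2
    distinct heavy-chain keys AND >= 2 distinct light-chain keys (key =
    chain:v_gene:CDR3); under ``or`` either condition alone suffices.
    Distinctness is at the chain-key level, so duplicated records of the same
    chain never flag a cell. Cells with no contig records are never flagged,
    and records marked ``unmatched`` are ignored.
    """
    if mode not in ("and", "or"):
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    if len(contigs) == 0:
        return pd.Index([], name="barcode")
    work = contigs
    if "unmatched" in work.columns:
        work = work[~work["unmatched"].fillna(False).astype(bool)]
    bad = set(work["chain"].astype(str)) - VALID_CHAINS
    if bad:
        raise ValueError(f"invalid chain class(es): {sorted(bad)} (expected IGH/IGK/IGL)")
    keys = _chain_keys(work, key_mode)
    per_cell = pd.DataFrame(
        {
            "barcode": work["barcode"],
            "heavy": work["chain"].eq("IGH"),
            "key": keys,
        }
    )
    n_heavy = per_cell[per_cell["heavy"]].groupby("barcode")["key"].nunique()
    n_light = per_cell[~per_cell["heavy"]].groupby("barcode")["key"].nunique()
    all_bc = per_cell["barcode"].unique()
    n_heavy = n_heavy.reindex(all_bc, fill_value=0)
    n_light = n_light.reindex(all_bc, fill_value=0)
    if mode == "and":
        flagged = (n_heavy >= 2) & (n_light >= 2)
    else:
        flagged = (n_heavy >= 2) | (n_light >= 2)
    return pd.Index(sorted(n_heavy.index[flagged]), name="barcode")


def run_qc(
    counts: CountsMatrix,
    contigs: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = "mt-",
    multichain_mode: str = "and",
) -> tuple[CountsMatrix, pd.DataFrame, list[str]]:
    """Full QC pass in the fixed order: cells, then genes, then BCR doublets.

    Returns the filtered matrix, the per-cell QC report (metrics, reason
    flags, ``multichain`` flag, final ``kept``), and a human-readable summary
    log of removals per rule in application order.
    """
    metrics = compute_cell_metrics(counts, mito_prefix=mito_prefix)
    kept_cells, report = apply_cell_filters(metrics, thresholds)
    summary = [f"input cells: {counts.n_cells}; input genes: {counts.n_genes}"]
    for reason in ("low_n_genes", "high_n_genes", "high_pct_mito", "low_complexity"):
        summary.append(f"cells flagged {reason}: {int(report[reason].sum())}")
    summary.append(f"cells kept after cell filters: {len(kept_cells)}")

    filtered = counts.subset(barcodes=kept_cells)
    kept_genes = apply_gene_filter(filtered, thresholds.min_cells_per_gene)
    summary.append(
        f"genes removed (< {thresholds.min_cells_per_gene} cells): "
        f"{filtered.n_genes - len(kept_genes)}; genes kept: {len(kept_genes)}"
    )
    filtered = filtered.subset(genes=kept_genes)

    report["multichain"] = False
    if contigs is not None and len(contigs):
        flagged = flag_multichain_cells(contigs, mode=multichain_mode)
        report.loc[report.index.intersection(flagged), "multichain"] = True
        remove = filtered.barcodes.intersection(flagged)
        summary.append(f"multichain doublet cells removed: {len(remove)}")
        filtered = filtered.subset(
            barcodes=filtered.barcodes.difference(remove, sort=False)
        )
    report["kept"] = report["kept"] & ~report["multichain"]
    summary.append(
        f"final: {filtered.n_cells} cells x {filtered.n_genes} genes"
    )
    for line in summary:
        logger.info(line)
    return filtered, report, summary
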