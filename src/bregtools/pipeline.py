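"""End-to-end orchestration: simulate/read -> QC -> normalize -> score ->
markers -> repertoire, as one configured, logged, reproducible run.

Every stage writes plain CSV/TSV/JSON artifacts into the output directory and
the effective configuration is echoed verbatim to ``config_echo.yaml`` so a
run is fully reconstructible. With synthetic input (a :class:`SimConfig`) the
generated bundle is first written to ``<outdir>/input/`` and read back through
the same reader used for external bundles, and a recovery report comparing
calls to the planted truth is produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_qc, markers, preprocess, repertoire, scoring
from .containers import CountsMatrix, GeneSignature
from .io_qc import QCThresholds
from .simulate import SimConfig, generate_dataset, read_truth, write_tenx_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run."""

    outdir: str
    sim: SimConfig | None = None
    input_dir: str | None = None
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    mito_prefix: str = "mt-"
    multichain_mode: str = "and"
    scale_factor: float = 10_000.0
    clip_max: float = 10.0
    scale_ddof: int = 1
    breg_signature: str | None = None
    b10_signature: str | None = None
    breg_threshold: float = 0.16
    # a float, or "auto" for a two-means split of the B10 score distribution
    b10_threshold: float | str = 0.0
    n_pcs: int = 30
    resolution: float = 0.5
    embedding: str | None = "tsne"
    de_fdr: float = 0.05
    de_min_log2fc: float = 0.25
    de_min_pct: float = 0.1
    de_min_group_size: int = 3
    key_mode: str = "aa"

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim / input_dir must be set")
        if self.input_dir is not None and self.breg_signature is None:
            raise ValueError(
                "breg_signature path is required when reading an external bundle"
            )
        if self.input_dir is not None and self.b10_signature is None:
            raise ValueError(
                "b10_signature path is required when reading an external bundle"
            )
        if self.sim is not None:
            self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["organs"] = list(self.sim.organs)
            d["sim"]["shared_clone_pairs"] = [
                list(p) for p in self.sim.shared_clone_pairs
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig(**d["sim"])
        if d.get("qc") is not None and not isinstance(d["qc"], QCThresholds):
            d["qc"] = QCThresholds(**d["qc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _setup_run_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("bregtools")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of key results and artifact paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    t0 = time.time()
    results: dict = {"outdir": str(outdir)}
    try:
        with open(outdir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        # ---- input ----------------------------------------------------
        truth = None
        if config.sim is not None:
            logger.info("stage simulate: generating synthetic bundle")
            counts0, truth, contigs0 = generate_dataset(config.sim)
            bundle_dir = outdir / "input"
            write_tenx_bundle(counts0, truth, contigs0, bundle_dir)
            breg_sig_path = bundle_dir / "breg_signature.txt"
            b10_sig_path = bundle_dir / "b10_signature.txt"
        else:
            bundle_dir = Path(config.input_dir)
            breg_sig_path = Path(config.breg_signature)
            b10_sig_path = Path(config.b10_signature)
            truth_path = bundle_dir / "truth.csv"
            if truth_path.exists():
                truth = read_truth(bundle_dir)
        counts, organ, contigs = io_qc.read_tenx_bundle(bundle_dir)
        breg_sig = GeneSignature.from_file(breg_sig_path, "breg_signature")
        b10_sig = GeneSignature.from_file(b10_sig_path, "b10_signature")

        # ---- QC -------------------------------------------------------
        logger.info("stage qc: %d cells x %d genes in", counts.n_cells, counts.n_genes)
        filtered, qc_report, summary = io_qc.run_qc(
            counts,
            contigs,
            thresholds=config.qc,
            mito_prefix=config.mito_prefix,
            multichain_mode=config.multichain_mode,
        )
        qc_report.rename_axis("barcode").to_csv(outdir / "qc_report.csv")
        (outdir / "filter_summary.txt").write_text("\n".join(summary) + "\n")
        organ = organ.reindex(filtered.barcodes)
        results["n_cells_postqc"] = filtered.n_cells
        results["n_genes_postqc"] = filtered.n_genes

        # ---- normalize / scale ---------------------------------------
        logger.info("stage preprocess: normalize + scale")
        norm = preprocess.lognormalize(filtered, scale_factor=config.scale_factor)
        scaled = preprocess.zscore_scale(
            norm, clip_max=config.clip_max, ddof=config.scale_ddof
        )

        # ---- scoring --------------------------------------------------
        logger.info("stage score: Breg + B10 module scores")
        breg_scores = scoring.compute_module_score(scaled, breg_sig)
        calls = scoring.call_breg(breg_scores, threshold=config.breg_threshold)
        b10_scores = scoring.compute_module_score(
            scaled, b10_sig, cells=calls.breg_barcodes
        )
        if config.b10_threshold == "auto":
            b10_threshold = scoring.calibrate_threshold(b10_scores)
            logger.info("calibrated B10 threshold: %.4f", b10_threshold)
        else:
            b10_threshold = float(config.b10_threshold)
        calls = scoring.call_b10(calls, b10_scores, threshold=b10_threshold)
        results["b10_threshold"] = b10_threshold
        score_df = pd.DataFrame(
            {
                "breg_score": breg_scores.scores,
                "is_breg": calls.is_breg,
                "b10_score": b10_scores.scores.reindex(calls.is_breg.index),
                "is_b10": calls.is_b10,
                "organ": organ,
            }
        )
        score_df.rename_axis("barcode").to_csv(outdir / "scores.csv")
        results["n_breg"] = int(calls.is_breg.sum())
        n_b10 = int(calls.is_b10.fillna(False).sum())
        results["n_b10"] = n_b10
        results["b10_fraction_of_breg"] = (
            n_b10 / results["n_breg"] if results["n_breg"] else float("nan")
        )

        # ---- Breg sub-clustering -------------------------------------
        clusters = None
        n_breg = results["n_breg"]
        if n_breg >= 20:
            logger.info("stage cluster: subdividing %d Breg cells", n_breg)
            breg_scaled = scaled.subset(barcodes=calls.breg_barcodes)
            n_pcs = min(config.n_pcs, min(breg_scaled.shape) - 1)
            assign = preprocess.embed_cluster(
                breg_scaled,
                n_pcs=n_pcs,
                resolution=config.resolution,
                seed=config.seed,
                embedding=config.embedding,
            )
            clusters = assign.labels
            out = pd.DataFrame({"cluster": clusters})
            if assign.embedding is not None:
                out = out.join(assign.embedding)
            out.rename_axis("barcode").to_csv(outdir / "breg_clusters.csv")
            results["n_breg_clusters"] = assign.n_clusters
        else:
            logger.info("too few Breg cells (%d) for sub-clustering; skipped", n_breg)

        # ---- composition ---------------------------------------------
        tables = scoring.composition_table(calls, organ, clusters=clusters)
        for name, tab in tables.items():
            tab.to_csv(outdir / f"composition_{name}.csv")
        results["composition"] = {k: str(outdir / f"composition_{k}.csv") for k in tables}

        # ---- markers --------------------------------------------------
        logger.info("stage markers: per-organ DE + intersection")
        de_tables: dict[str, pd.DataFrame] = {}
        for org in sorted(organ.dropna().unique()):
            mask = organ == org
            n_breg_org = int(calls.is_breg[mask].sum())
            n_rest_org = int((~calls.is_breg[mask]).sum())
            if min(n_breg_org, n_rest_org) < config.de_min_group_size:
                logger.info(
                    "organ %s skipped for DE (%d Breg / %d non-Breg cells)",
                    org, n_breg_org, n_rest_org,
                )
                continue
            tab = markers.rank_genes_breg(
                norm, calls, organ, org,
                min_pct=config.de_min_pct,
                min_group_size=config.de_min_group_size,
            )
            tab.rename_axis("gene").to_csv(outdir / f"deg_{org}.csv")
            de_tables[org] = tab
        if len(de_tables) >= 1:
            common, per_organ, venn = markers.intersect_common_markers(
                de_tables, fdr=config.de_fdr, min_log2fc=config.de_min_log2fc
            )
            (outdir / "common_markers.txt").write_text("\n".join(common) + "\n")
            with open(outdir / "venn_summary.json", "w") as fh:
                json.dump(venn, fh, indent=2, sort_keys=True)
            results["n_common_markers"] = len(common)

        # ---- repertoire ----------------------------------------------
        logger.info("stage repertoire: clonotypes + sharing + indices")
        assign = repertoire.assign_clonotypes(contigs, key_mode=config.key_mode)
        assign_kept = assign.loc[assign.index.intersection(filtered.barcodes)]
        assign_kept.rename_axis("barcode").to_csv(outdir / "clonotypes.csv")
        if len(assign_kept):
            breg_scope = calls.breg_barcodes
            clono_m, cell_m = repertoire.pairwise_sharing(
                assign_kept, organ, scope=breg_scope
            )
            clono_m.rename_axis("organ").to_csv(outdir / "sharing_clonotypes.csv")
            cell_m.rename_axis("organ").to_csv(outdir / "sharing_cells.csv")
            top = repertoire.top_clonotypes(
                assign_kept, n=10, organs=organ, clusters=clusters
            )
            top.rename_axis("clonotype").to_csv(outdir / "top_clonotypes.csv")
            if clusters is not None:
                cl_scope = assign_kept.index.intersection(clusters.index)
                if len(cl_scope):
                    per_cluster, trans = repertoire.clonal_index_table(
                        assign_kept.loc[cl_scope], clusters, organ
                    )
                    per_cluster.to_csv(outdir / "clonal_indices.csv")
                    trans.rename_axis("cluster").to_csv(outdir / "transition_matrix.csv")

        # ---- recovery vs truth ---------------------------------------
        if truth is not None:
            results["recovery"] = _recovery_report(
                outdir, truth, calls, breg_scores, contigs, assign, organ,
                multichain_mode=config.multichain_mode,
            )
        results["runtime_s"] = round(time.time() - t0, 2)
        logger.info("pipeline finished in %.1f s", results["runtime_s"])
        return results
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        handler.close()
        logging.getLogger("bregtools").removeHandler(handler)


def _recovery_report(
    outdir: Path,
    truth,
    calls: scoring.BregCall,
    breg_scores: scoring.ScoreVector,
    contigs: pd.DataFrame,
    assign: pd.DataFrame,
    organ: pd.Series,
    multichain_mode: str = "and",
) -> dict:
    """Compare calls against the planted truth; written to recovery_report.json."""
    from sklearn.metrics import roc_auc_score

    report: dict = {}
    scored = breg_scores.scores.copy()
    y_true = truth.cells["is_breg"].reindex(scored.index)
    # -inf sentinels rank below every finite score
    finite = scored[np.isfinite(scored)]
    floor = (finite.min() if len(finite) else 0.0) - 1.0
    scored = scored.replace(-np.inf, floor)
    if y_true.nunique() == 2:
        report["breg_score_auroc"] = float(roc_auc_score(y_true, scored))
    called = calls.is_breg
    tp = int((called & y_true).sum())
    report["breg_call_precision"] = tp / max(int(called.sum()), 1)
    report["breg_call_recall"] = tp / max(int(y_true.sum()), 1)

    true_b10 = truth.cells["is_b10"]
    true_breg_called = called[called].index
    if calls.is_b10 is not None and len(true_breg_called):
        called_b10 = calls.is_b10.fillna(False)
        both = called_b10 & true_b10.reindex(called_b10.index)
        report["b10_recall_among_breg"] = float(
            both.sum() / max(int(true_b10.reindex(called_b10.index).sum()), 1)
        )
        report["b10_fraction_called"] = float(
            called_b10.sum() / max(int(called.sum()), 1)
        )
        report["b10_fraction_true"] = float(
            truth.cells.loc[truth.cells["is_breg"], "is_b10"].mean()
        )

    # doublet recovery on the full contig table
    flagged = set(io_qc.flag_multichain_cells(contigs, mode=multichain_mode))
    planted = set(truth.cells.index[truth.cells["is_multichain_doublet"]])
    report["doublets_planted"] = len(planted)
    report["doublets_flagged"] = len(flagged)
    report["doublets_exact_match"] = flagged == planted

    # sharing recovery on truth labels (pre-QC, planted Breg scope)
    truth_organ = truth.cells["organ"]
    truth_breg = truth.cells.index[truth.cells["is_breg"]]
    clono_m, _ = repertoire.pairwise_sharing(assign, truth_organ, scope=truth_breg)
    report["sharing_truth_scope"] = {
        f"{a}&{b}": int(clono_m.loc[a, b])
        for i, a in enumerate(clono_m.index)
        for b in clono_m.columns[i + 1 :]
        if clono_m.loc[a, b] > 0
    }
    if len(assign):
        report["largest_clone_size"] = int(
            assign.groupby("clonotype").size().max()
        )
    with open(outdir / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
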