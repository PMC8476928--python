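"""Synthetic multi-organ paired expression + BCR data with planted ground truth.

The generator emulates the structure of a pooled mouse B-cell experiment: five
organs (spleen, liver, mLN, PC, BM), a minority regulatory-B (Breg) population
with elevated expression of a signature gene set, a B10 sub-population within
the Breg cells with a second elevated gene set, mitochondrial genes (``mt-``
prefix, mouse convention), overdispersed UMI counts with per-cell library-size
variation, multichain doublet cells, and a paired-chain BCR repertoire with
clonally expanded and organ-shared clonotypes.

Counts follow a negative-binomial model: gene base means are drawn
log-normally, each cell gets a gamma-distributed library-size factor, and
counts are sampled as a gamma-Poisson mixture with a common dispersion. Planted
Breg cells have their signature-gene means multiplied by ``signature_effect``
(B10 cells additionally by ``b10_effect``); per-cell gene probabilities are
renormalized so effects shift composition, not library size.

All randomness is driven by the single ``seed`` field; identical configs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountsMatrix, GeneSignature

DEFAULT_ORGANS = ("spleen", "liver", "mLN", "PC", "BM")

# Higher Breg prevalence in the peritoneal cavity, the organ where regulatory
# B cells are most frequent in mice.
DEFAULT_BREG_FRACTIONS = {
    "spleen": 0.12,
    "liver": 0.12,
    "mLN": 0.10,
    "PC": 0.30,
    "BM": 0.08,
}

MOUSE_MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

HEAVY_V_GENES = (
    "Ighv11-2", "Ighv1-55", "Ighv1-72", "Ighv5-6", "Ighv9-3", "Ighv2-2",
    "Ighv14-3", "Ighv3-6", "Ighv6-3", "Ighv8-8",
)
KAPPA_V_GENES = (
    "Igkv14-126", "Igkv12-89", "Igkv4-55", "Igkv6-15", "Igkv1-117",
    "Igkv10-96", "Igkv3-2", "Igkv8-30",
)
LAMBDA_V_GENES = ("Iglv1", "Iglv2", "Iglv3")
HEAVY_J_GENES = ("Ighj1", "Ighj2", "Ighj3", "Ighj4")
KAPPA_J_GENES = ("Igkj1", "Igkj2", "Igkj4", "Igkj5")
LAMBDA_J_GENES = ("Iglj1", "Iglj2")

_AA_ALPHABET = "ARNDQEGHILKMFPSTWYV"
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"), "E": ("GAA", "GAG"), "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "K": ("AAA", "AAG"),
    "M": ("ATG",), "F": ("TTT", "TTC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "W": ("TGG",),
    "Y": ("TAT", "TAC"), "V": ("GTT", "GTC", "GTA", "GTG"),
}

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic multi-organ dataset.

    Defaults mirror a realistic pooled B-cell run: 5 organs x 1,000 cells,
    1,500 genes, mean library of 5,000 UMIs with gamma-distributed size
    factors, NB dispersion (inverse overdispersion) of 10, a 134-gene Breg
    signature doubled in planted Breg cells, and ~60% B10 among Breg.
    """

    seed: int = 0
    organs: tuple[str, ...] = DEFAULT_ORGANS
    cells_per_organ: int = 1000
    n_genes: int = 1500
    n_mito_genes: int = 13
    n_signature_genes: int = 134
    n_b10_signature_genes: int = 30
    breg_fraction_per_organ: Mapping[str, float] | None = None
    b10_fraction_of_breg: float = 0.6
    signature_effect: float = 2.0
    b10_effect: float = 2.0
    library_size_mean: float = 5000.0
    library_size_shape: float = 2.0
    nb_dispersion: float = 10.0
    mito_fraction: float = 0.05
    doublet_multichain_rate: float = 0.01
    n_clonotypes: int | None = None
    expanded_clone_count: int = 2
    expanded_clone_size: int = 20
    expanded_clone_organ: str = "PC"
    shared_clone_pairs: tuple[tuple[str, str, int], ...] = (
        ("liver", "PC", 3),
        ("spleen", "PC", 3),
    )

    def __post_init__(self) -> None:
        self.organs = tuple(self.organs)
        if self.breg_fraction_per_organ is None:
            self.breg_fraction_per_organ = {
                o: DEFAULT_BREG_FRACTIONS.get(o, 0.10) for o in self.organs
            }
        else:
            self.breg_fraction_per_organ = dict(self.breg_fraction_per_organ)
        self.shared_clone_pairs = tuple(
            (a, b, int(n)) for a, b, n in self.shared_clone_pairs
        )

    def validate(self) -> None:
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("organ names must be unique")
        if self.cells_per_organ <= 0 or self.n_genes <= 0:
            raise ValueError("cells_per_organ and n_genes must be positive")
        reserved = self.n_signature_genes + self.n_b10_signature_genes + self.n_mito_genes
        if self.n_genes < reserved:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the "
                f"{reserved} genes required for the signature "
                f"({self.n_signature_genes}), B10 signature "
                f"({self.n_b10_signature_genes}) and mito ({self.n_mito_genes}) "
                f"sets: deficit of {reserved - self.n_genes} genes"
            )
        for organ, frac in self.breg_fraction_per_organ.items():
            if organ not in self.organs:
                raise ValueError(f"breg fraction given for unknown organ '{organ}'")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"breg fraction for {organ} outside [0,1]: {frac}")
        for frac_name in ("b10_fraction_of_breg", "doublet_multichain_rate", "mito_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} outside [0,1]: {v}")
        if self.signature_effect < 1.0 or self.b10_effect < 1.0:
            raise ValueError("signature_effect and b10_effect must be >= 1")
        for pos_name in ("library_size_mean", "library_size_shape", "nb_dispersion"):
            if getattr(self, pos_name) <= 0:
                raise ValueError(f"{pos_name} must be positive")
        for a, b, n in self.shared_clone_pairs:
            if a == b:
                raise ValueError(f"shared clone pair has identical organs: {a}")
            for o in (a, b):
                if o not in self.organs:
                    raise ValueError(f"shared clone pair names unknown organ '{o}'")
            if n < 0:
                raise ValueError("shared clone count must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.cells_per_organ * len(self.organs)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic data.

    ``cells`` is indexed by barcode with columns ``organ``, ``is_breg``,
    ``is_b10``, ``clonotype_id`` (primary clone; missing for cells without a
    repertoire), ``is_multichain_doublet``. ``genes`` is indexed by gene symbol
    with boolean columns ``is_signature``, ``is_b10_signature``, ``is_mito``.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    library_size: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        b10_not_breg = self.cells["is_b10"] & ~self.cells["is_breg"]
        if b10_not_breg.any():
            raise ValueError("is_b10 implies is_breg; truth table violates this")

    @property
    def breg_signature(self) -> GeneSignature:
        return GeneSignature(
            "breg_signature", tuple(self.genes.index[self.genes["is_signature"]])
        )

    @property
    def b10_signature(self) -> GeneSignature:
        return GeneSignature(
            "b10_signature", tuple(self.genes.index[self.genes["is_b10_signature"]])
        )


def _gene_names(config: SimConfig) -> tuple[pd.Index, pd.DataFrame]:
    names: list[str] = []
    names += [f"BregSig{i + 1:03d}" for i in range(config.n_signature_genes)]
    names += [f"B10Sig{i + 1:02d}" for i in range(config.n_b10_signature_genes)]
    mito = list(MOUSE_MITO_GENES[: config.n_mito_genes])
    mito += [f"mt-G{i + 1}" for i in range(len(mito), config.n_mito_genes)]
    names += mito
    n_bg = config.n_genes - len(names)
    names += [f"Gene{i + 1:04d}" for i in range(n_bg)]
    genes = pd.Index(names, name="gene")
    flags = pd.DataFrame(
        {
            "is_signature": [n.startswith("BregSig") for n in names],
            "is_b10_signature": [n.startswith("B10Sig") for n in names],
            "is_mito": [n.lower().startswith("mt-") for n in names],
        },
        index=genes,
    )
    return genes, flags


def _barcodes(rng: np.random.Generator, n: int) -> pd.Index:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(bases[rng.integers(0, 4, 16)]) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return pd.Index(out, name="barcode")


def generate_expression(config: SimConfig) -> tuple[CountsMatrix, SyntheticTruth]:
    """Draw the count matrix and the planted per-cell / per-gene truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes, gene_flags = _gene_names(config)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    mito_mask = gene_flags["is_mito"].to_numpy()
    if mito_mask.any() and config.mito_fraction > 0:
        # rescale mito mass so its expected share of the library is mito_fraction
        non_mito_mass = base[~mito_mask].sum()
        target = config.mito_fraction / (1 - config.mito_fraction) * non_mito_mass
        base[mito_mask] *= target / base[mito_mask].sum()

    n_cells = config.n_cells
    barcodes = _barcodes(rng, n_cells)
    organ = np.repeat(config.organs, config.cells_per_organ)

    is_breg = np.zeros(n_cells, dtype=bool)
    is_b10 = np.zeros(n_cells, dtype=bool)
    for i, o in enumerate(config.organs):
        lo = i * config.cells_per_organ
        idx = lo + rng.permutation(config.cells_per_organ)
        n_breg = int(round(config.breg_fraction_per_organ[o] * config.cells_per_organ))
        breg_idx = idx[:n_breg]
        is_breg[breg_idx] = True
        n_b10 = int(round(config.b10_fraction_of_breg * n_breg))
        is_b10[breg_idx[:n_b10]] = True

    n_doublets = int(round(config.doublet_multichain_rate * n_cells))
    is_doublet = np.zeros(n_cells, dtype=bool)
    if n_doublets:
        is_doublet[rng.choice(n_cells, size=n_doublets, replace=False)] = True

    lib = rng.gamma(
        shape=config.library_size_shape,
        scale=config.library_size_mean / config.library_size_shape,
        size=n_cells,
    )

    sig_mask = gene_flags["is_signature"].to_numpy()
    b10_mask = gene_flags["is_b10_signature"].to_numpy()
    # three expression profiles: background, Breg, B10 (Breg + B10 boost)
    profiles = {}
    for key, (boost_sig, boost_b10) in {
        "bg": (1.0, 1.0),
        "breg": (config.signature_effect, 1.0),
        "b10": (config.signature_effect, config.b10_effect),
    }.items():
        mean = base.copy()
        mean[sig_mask] *= boost_sig
        mean[b10_mask] *= boost_b10
        profiles[key] = mean / mean.sum()

    cell_profile = np.empty((n_cells, config.n_genes))
    cell_profile[:] = profiles["bg"]
    cell_profile[is_breg & ~is_b10] = profiles["breg"]
    cell_profile[is_b10] = profiles["b10"]

    mu = cell_profile * lib[:, None]
    r = config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int32)

    matrix = CountsMatrix(sparse.csr_matrix(counts), barcodes, genes)
    cells = pd.DataFrame(
        {
            "organ": organ,
            "is_breg": is_breg,
            "is_b10": is_b10,
            "clonotype_id": pd.Series([pd.NA] * n_cells, index=barcodes, dtype="string"),
            "is_multichain_doublet": is_doublet,
        },
        index=barcodes,
    )
    truth = SyntheticTruth(
        cells=cells, genes=gene_flags, library_size=pd.Series(lib, index=barcodes)
    )
    return matrix, truth


def _random_cdr3(rng: np.random.Generator) -> tuple[str, str]:
    length = int(rng.integers(8, 17))
    middle = "".join(rng.choice(list(_AA_ALPHABET), size=length - 2))
    aa = "C" + middle + ("W" if rng.random() < 0.5 else "F")
    nt = "".join(_CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in aa)
    return aa, nt


def _make_clonotype(rng: np.random.Generator, used_keys: set[str]) -> dict:
    """Draw a unique paired heavy+light chain definition."""
    while True:
        hv = HEAVY_V_GENES[rng.integers(0, len(HEAVY_V_GENES))]
        hj = HEAVY_J_GENES[rng.integers(0, len(HEAVY_J_GENES))]
        h_aa, h_nt = _random_cdr3(rng)
        light_chain = "IGK" if rng.random() < 0.95 else "IGL"
        if light_chain == "IGK":
            lv = KAPPA_V_GENES[rng.integers(0, len(KAPPA_V_GENES))]
            lj = KAPPA_J_GENES[rng.integers(0, len(KAPPA_J_GENES))]
        else:
            lv = LAMBDA_V_GENES[rng.integers(0, len(LAMBDA_V_GENES))]
            lj = LAMBDA_J_GENES[rng.integers(0, len(LAMBDA_J_GENES))]
        l_aa, l_nt = _random_cdr3(rng)
        key = f"IGH:{hv}:{h_aa};{light_chain}:{lv}:{l_aa}"
        if key not in used_keys:
            used_keys.add(key)
            return {
                "heavy": ("IGH", hv, hj, h_aa, h_nt),
                "light": (light_chain, lv, lj, l_aa, l_nt),
            }


def generate_repertoire(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Emit a 10x-style contig table with planted clonal structure.

    Every non-doublet cell receives one heavy + one light chain. Expanded
    clones are concentrated among planted Breg cells of ``expanded_clone_organ``;
    each shared clone places one cell in each organ of its pair; all remaining
    cells are clonal singletons; doublet cells carry two distinct clonotypes
    (2 heavy + 2 light chains). The primary clonotype id of every cell is
    recorded back into ``truth.cells``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    cells = truth.cells
    n_cells = len(cells)

    is_doublet = cells["is_multichain_doublet"].to_numpy()
    organ = cells["organ"].to_numpy()
    is_breg = cells["is_breg"].to_numpy()

    assigned = np.zeros(n_cells, dtype=bool)
    clone_of_cell = np.full(n_cells, -1, dtype=int)

    used_keys: set[str] = set()
    clonotypes: list[dict] = []

    def new_clone() -> int:
        clonotypes.append(_make_clonotype(rng, used_keys))
        return len(clonotypes) - 1

    def draw_cells(pool: np.ndarray, k: int, what: str) -> np.ndarray:
        avail = np.flatnonzero(pool & ~assigned & ~is_doublet)
        if len(avail) < k:
            raise ValueError(
                f"requested {what} needs {k} cells but only {len(avail)} "
                f"unassigned cells are available"
            )
        chosen = rng.choice(avail, size=k, replace=False)
        assigned[chosen] = True
        return chosen

    # expanded clones in the designated organ's Breg cells
    exp_pool = (organ == config.expanded_clone_organ) & is_breg
    for _ in range(config.expanded_clone_count):
        cid = new_clone()
        chosen = draw_cells(
            exp_pool, config.expanded_clone_size,
            f"expanded clone in {config.expanded_clone_organ}",
        )
        clone_of_cell[chosen] = cid

    # organ-shared clones: one Breg cell in each organ of the pair
    for org_a, org_b, n_shared in config.shared_clone_pairs:
        for _ in range(n_shared):
            cid = new_clone()
            for org in (org_a, org_b):
                chosen = draw_cells(
                    (organ == org) & is_breg, 1, f"shared clone in {org}"
                )
                clone_of_cell[chosen] = cid

    # remaining non-doublet cells: singleton clones, in cell order
    for i in np.flatnonzero(~assigned & ~is_doublet):
        clone_of_cell[i] = new_clone()

    # doublet cells: two fresh distinct clonotypes each
    secondary_of_cell: dict[int, int] = {}
    for i in np.flatnonzero(is_doublet):
        clone_of_cell[i] = new_clone()
        secondary_of_cell[i] = new_clone()

    n_special = (
        config.expanded_clone_count
        + sum(n for _, _, n in config.shared_clone_pairs)
    )
    if config.n_clonotypes is not None and config.n_clonotypes < len(clonotypes):
        raise ValueError(
            f"n_clonotypes={config.n_clonotypes} too small: "
            f"{len(clonotypes)} clonotypes needed to cover every cell "
            f"({n_special} expanded/shared plus singletons and doublet extras)"
        )

    rows: list[dict] = []

    def add_chains(cell_idx: int, clone_idx: int, contig_offset: int) -> int:
        bc = cells.index[cell_idx]
        clone = clonotypes[clone_idx]
        for part in ("heavy", "light"):
            chain, v, j, aa, nt = clone[part]
            rows.append(
                {
                    "barcode": bc,
                    "is_cell": True,
                    "contig_id": f"{bc}_contig_{contig_offset}",
                    "high_confidence": True,
                    "length": 380 + len(nt),
                    "chain": chain,
                    "v_gene": v,
                    "d_gene": "IGHD2-4" if chain == "IGH" else "None",
                    "j_gene": j,
                    "c_gene": "IGHM" if chain == "IGH" else chain + "C",
                    "full_length": True,
                    "productive": True,
                    "cdr3": aa,
                    "cdr3_nt": nt,
                    "reads": int(rng.integers(500, 5000)),
                    "umis": int(rng.integers(2, 40)),
                    "raw_clonotype_id": f"clonotype{clone_idx + 1}",
                }
            )
            contig_offset += 1
        return contig_offset

    for i in range(n_cells):
        off = add_chains(i, clone_of_cell[i], 1)
        if i in secondary_of_cell:
            add_chains(i, secondary_of_cell[i], off)

    contigs = pd.DataFrame(rows, columns=CONTIG_COLUMNS)
    truth.cells["clonotype_id"] = pd.array(
        [f"clonotype{c + 1}" for c in clone_of_cell], dtype="string"
    )
    return contigs


def generate_dataset(
    config: SimConfig,
) -> tuple[CountsMatrix, SyntheticTruth, pd.DataFrame]:
    """Convenience wrapper: expression then repertoire under one config."""
    counts, truth = generate_expression(config)
    contigs = generate_repertoire(config, truth)
    return counts, truth, contigs


def write_tenx_bundle(
    counts: CountsMatrix,
    truth: SyntheticTruth | None,
    contigs: pd.DataFrame | None,
    directory: str | Path,
    organ: pd.Series | None = None,
) -> dict[str, Path]:
    """Write a 10x-style bundle: MTX + barcodes/features, metadata, contigs.

    The matrix is written feature-major (genes as rows, cells as columns, 10x
    convention). When ``truth`` is given, per-cell and per-gene truth tables
    and the two signature gene lists are written alongside; the organ column
    is taken from truth unless ``organ`` is passed explicitly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = directory / "matrix.mtx"
    spio.mmwrite(str(paths["matrix"]), counts.values.T.tocoo())

    paths["barcodes"] = directory / "barcodes.tsv"
    paths["barcodes"].write_text("\n".join(counts.barcodes) + "\n")

    paths["features"] = directory / "features.tsv"
    with paths["features"].open("w") as fh:
        for i, g in enumerate(counts.genes):
            fh.write(f"SYNG{i + 1:07d}\t{g}\tGene Expression\n")

    if organ is None and truth is not None:
        organ = truth.cells["organ"]
    if organ is None:
        organ = pd.Series("unknown", index=counts.barcodes)
    paths["cell_metadata"] = directory / "cell_metadata.csv"
    meta = pd.DataFrame({"barcode": counts.barcodes, "organ": organ.reindex(counts.barcodes).values})
    meta.to_csv(paths["cell_metadata"], index=False)

    paths["contigs"] = directory / "contigs.csv"
    if contigs is None or len(contigs) == 0:
        pd.DataFrame(columns=CONTIG_COLUMNS).to_csv(paths["contigs"], index=False)
    else:
        contigs.to_csv(paths["contigs"], index=False)

    if truth is not None:
        paths["truth"] = directory / "truth.csv"
        truth.cells.rename_axis("barcode").to_csv(paths["truth"])
        paths["truth_genes"] = directory / "truth_genes.csv"
        truth.genes.rename_axis("gene").to_csv(paths["truth_genes"])
        paths["breg_signature"] = directory / "breg_signature.txt"
        truth.breg_signature.to_file(paths["breg_signature"])
        paths["b10_signature"] = directory / "b10_signature.txt"
        truth.b10_signature.to_file(paths["b10_signature"])
    return paths


def read_truth(directory: str | Path) -> SyntheticTruth:
    """Read back the truth tables written by :func:`write_tenx_bundle`."""
    directory = Path(directory)
    cells = pd.read_csv(directory / "truth.csv", index_col="barcode")
    for col in ("is_breg", "is_b10", "is_multichain_doublet"):
        cells[col] = cells[col].astype(bool)
    cells["clonotype_id"] = cells["clonotype_id"].astype("string")
    genes = pd.read_csv(directory / "truth_genes.csv", index_col="gene")
    for col in genes.columns:
        genes[col] = genes[col].astype(bool)
    return SyntheticTruth(cells=cells, genes=genes)
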