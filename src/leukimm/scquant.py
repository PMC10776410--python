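"""Single-cell quantification: QC filtering, module scores, quantile bins,
and per-gene differential expression.

The container is a genes x cells integer count matrix with a cell-metadata
table.  QC keeps cells inside fixed bounds on the mitochondrial and ribosomal
UMI fractions, detected genes, housekeeping-gene fraction and read depth
(bounds inclusive for keeping; cells are excluded only on strict violations).
Module scores follow the binned-control scheme of Tirosh et al.: the mean
log-normalized expression of a gene set minus the mean of control genes drawn
from matching average-expression bins.  Differential expression is a per-gene
Welch t-test on log-normalized expression with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import stats as sps

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "ScoreConfig",
    "GENE_SETS",
    "HOUSEKEEPING_GENES",
    "qc_filter",
    "log_normalize",
    "module_score",
    "quantile_bins",
    "de_test",
]

# ---------------------------------------------------------------------------
# Gene-set registry
#
# The named sets used for per-cell signature scores.  The BCR-ABL1 program
# stores the published symbols verbatim, including several that match no
# current HGNC symbol (e.g. ANZA2, RXCFP1, PTPBP3, LOP2); they are kept as
# printed rather than silently corrected, and an alias map can be supplied to
# `module_score` callers by renaming matrix genes beforehand.

GENE_SETS: dict[str, tuple[str, ...]] = {
    "cytotoxicity": ("IFNG", "GZMA", "GZMB", "GZMM", "GZMH", "PRF1", "GNLY"),
    "exhaustion": ("CTLA4", "LAG3", "PDCD1", "HAVCR2", "TIGIT"),
    "hla_class_1": ("HLA-A", "HLA-B", "HLA-C"),
    "hla_class_2": (
        "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB", "HLA-DPB1", "HLA-DPA1",
        "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DQB2", "HLA-DRA", "HLA-DRB1",
        "HLA-DRB5",
    ),
    "bcr_abl1": (
        # previously implicated in CML
        "CD33", "CD69", "SELL", "CXCR4", "CDC42", "MMRN1", "ANZA2", "CDK6",
        "GAS2", "IFITM1", "CTNNB1", "NFKBIA", "FOS", "NCF4", "MGST2", "TIMP1",
        "EZH2",
        # novel candidates
        "LGALS1", "RXCFP1", "AREG", "RAB31", "PRSS21", "TUBB6", "YBX1", "CKS2",
        "PTPBP3", "PSIP1", "CDCA7", "MT2A", "FHL1", "LAMTOR2", "S100A10",
        "LAPTM4B", "DCTPP1", "STON2", "SRSF2", "HAT1", "LOP2", "PCDH9",
    ),
    "pr1": ("PRTN3", "ELANE"),
}

#: default housekeeping panel for the QC housekeeping-fraction criterion;
#: configurable via QCThresholds.housekeeping_genes
HOUSEKEEPING_GENES: tuple[str, ...] = (
    "ACTB", "GAPDH", "B2M", "HPRT1", "PPIA", "PGK1", "TBP", "UBC", "YWHAZ",
    "SDHA", "HMBS", "GUSB", "TUBB", "EEF1A1", "PTMA", "TMSB4X", "UBB",
    "NACA", "FAU", "EIF1",
)


@dataclass
class CountMatrix:
    """Genes x cells integer UMI counts with cell metadata.

    `cell_meta` is indexed by barcode and typically carries sample_id, group
    and cluster columns.
    """

    X: np.ndarray  # genes x cells
    gene_names: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if self.X.shape[0] != len(self.gene_names):
            raise ValueError("gene_names length must match matrix rows")
        if self.X.shape[1] != len(self.cell_meta):
            raise ValueError("cell_meta length must match matrix columns")
        if np.any(self.X < 0):
            raise ValueError("counts must be non-negative")
        upper = [g.upper() for g in self.gene_names]
        if len(set(upper)) != len(upper):
            raise ValueError("gene names must be unique after case-normalization")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return list(self.cell_meta.index)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            X=self.X[:, idx],
            gene_names=list(self.gene_names),
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=np.asarray(self.X.T, dtype=np.float32),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        return adata

    # -- text I/O ---------------------------------------------------------

    def write_dense_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, index=self.gene_names, columns=self.barcodes)
        df.to_csv(path, sep="\t")

    @classmethod
    def read_dense_tsv(
        cls, path: str | Path, cell_meta: Optional[pd.DataFrame] = None
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = (
            cell_meta.loc[df.columns]
            if cell_meta is not None
            else pd.DataFrame(index=df.columns)
        )
        return cls(df.to_numpy(dtype=np.int64), list(df.index), meta)

    def write_mtx(self, prefix: str | Path) -> None:
        """Write an MTX triplet (matrix.mtx, genes.tsv, barcodes.tsv)."""
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        prefix = Path(prefix)
        prefix.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix / "matrix.mtx"), coo_matrix(self.X))
        pd.Series(self.gene_names).to_csv(
            prefix / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.barcodes).to_csv(
            prefix / "barcodes.tsv", sep="\t", index=False, header=False
        )
        self.cell_meta.to_csv(prefix / "cell_meta.csv")

    @classmethod
    def read_mtx(cls, prefix: str | Path) -> "CountMatrix":
        from scipy.io import mmread

        prefix = Path(prefix)
        X = np.asarray(mmread(str(prefix / "matrix.mtx")).todense(), dtype=np.int64)
        genes = pd.read_csv(prefix / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(prefix / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        meta_path = prefix / "cell_meta.csv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, index_col=0)
            meta = meta.loc[barcodes]
        else:
            meta = pd.DataFrame(index=pd.Index(barcodes))
        return cls(X, genes, meta)


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell QC bounds. Cells are kept when inside all closed intervals."""

    mito_max: float = 0.15
    ribo_max: float = 0.50
    genes_min: int = 100
    genes_max: int = 4500
    hk_min: float = 0.25
    hk_max: float = 0.60
    depth_min: int = 500
    depth_max: int = 30_000
    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_GENES

    def __post_init__(self):
        for lo, hi, name in [
            (self.genes_min, self.genes_max, "genes"),
            (self.hk_min, self.hk_max, "hk"),
            (self.depth_min, self.depth_max, "depth"),
        ]:
            if lo >= hi:
                raise ValueError(f"{name}: min must be < max")


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    n_removed: int
    removed_per_criterion: dict


@dataclass(frozen=True)
class ScoreConfig:
    """Binned-control module-score settings (Tirosh-style)."""

    n_bins: int = 25
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


# ---------------------------------------------------------------------------
# Operations


def qc_filter(m: CountMatrix, t: QCThresholds = QCThresholds()) -> tuple[CountMatrix, QCReport]:
    """Remove cells outside the QC bounds; report removals per criterion.

    Mitochondrial genes are identified by the prefix 'MT-', ribosomal genes by
    'RPS'/'RPL' (case-insensitive).  Boundaries are inclusive for keeping: a
    cell at exactly depth_max is retained, one read above is removed.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty count matrix")
    genes_up = [g.upper() for g in m.gene_names]
    mito = np.array([g.startswith("MT-") for g in genes_up])
    ribo = np.array([g.startswith(("RPS", "RPL")) for g in genes_up])
    hk_set = {g.upper() for g in t.housekeeping_genes}
    hk = np.array([g in hk_set for g in genes_up])

    depth = m.X.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(depth > 0, m.X[mito].sum(axis=0) / depth, 0.0)
        ribo_frac = np.where(depth > 0, m.X[ribo].sum(axis=0) / depth, 0.0)
        hk_frac = np.where(depth > 0, m.X[hk].sum(axis=0) / depth, 0.0)
    n_genes_detected = (m.X > 0).sum(axis=0)

    fails = {
        "mito": mito_frac > t.mito_max,
        "ribo": ribo_frac > t.ribo_max,
        "genes_low": n_genes_detected < t.genes_min,
        "genes_high": n_genes_detected > t.genes_max,
        "hk_low": hk_frac < t.hk_min,
        "hk_high": hk_frac > t.hk_max,
        "depth_low": depth < t.depth_min,
        "depth_high": depth > t.depth_max,
    }
    any_fail = np.logical_or.reduce(list(fails.values()))
    kept = m.subset_cells(~any_fail)
    report = QCReport(
        n_input=m.n_cells,
        n_kept=int((~any_fail).sum()),
        n_removed=int(any_fail.sum()),
        removed_per_criterion={k: int(v.sum()) for k, v in fails.items()},
    )
    return kept, report


def log_normalize(m: CountMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Log-normalized expression: counts scaled to `target_sum` per cell, log1p.

    Returns a genes x cells float array.
    """
    depth = m.X.sum(axis=0).astype(float)
    depth[depth == 0] = 1.0
    return np.log1p(m.X / depth[None, :] * target_sum)


def module_score(
    m: CountMatrix,
    gene_set: Sequence[str],
    cfg: ScoreConfig = ScoreConfig(),
) -> np.ndarray:
    """Per-cell module score for a gene set, with expression-matched controls.

    On log-normalized expression the score is the mean over set genes minus
    the mean over control genes; controls are drawn per set gene from the same
    average-expression bin (`cfg.n_bins` bins, `cfg.n_ctrl_per_gene` controls
    per gene).  Genes absent from the matrix are dropped with a warning;
    at least one set gene must be present.
    """
    present = [g for g in gene_set if g in set(m.gene_names)]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if len(present) < len(gene_set):
        warnings.warn(
            f"{len(gene_set) - len(present)} gene(s) of the set absent from the "
            "matrix; scoring the remaining subset"
        )
    adata = m.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.tl.score_genes(
        adata,
        gene_list=present,
        ctrl_size=cfg.n_ctrl_per_gene,
        n_bins=cfg.n_bins,
        random_state=cfg.seed,
        score_name="_score",
    )
    return adata.obs["_score"].to_numpy(dtype=float)


def quantile_bins(scores: Sequence[float], q: int = 5) -> np.ndarray:
    """Equal-count rank bins labelled 1..q (ties broken by stable input order).

    Degenerate case: if every score is identical, all cells land in bin 1.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return np.array([], dtype=int)
    if np.all(scores == scores[0]):
        return np.ones(n, dtype=int)
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * q // n + 1
    return labels


def de_test(
    m: CountMatrix,
    group_a: Sequence,
    group_b: Sequence,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two cell groups on log-normalized expression.

    `group_a`/`group_b` are barcode lists or integer cell indices; the groups
    must be disjoint with at least two cells each.  Returns a gene-indexed
    table with mean_A, mean_B, log2FC (pseudocount 1e-9), pct_exp_A, pct_exp_B,
    p_raw and Bonferroni-adjusted p_adj.
    """

    def _resolve(group):
        arr = np.asarray(group)
        if arr.dtype.kind in "iu":
            return arr.astype(int)
        pos = {b: i for i, b in enumerate(m.barcodes)}
        return np.array([pos[b] for b in group], dtype=int)

    ia, ib = _resolve(group_a), _resolve(group_b)
    if len(set(ia) & set(ib)) > 0:
        raise ValueError("groups overlap")
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 cells")

    logX = log_normalize(m)
    A, B = logX[:, ia], logX[:, ib]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    # zero variance in both groups: t is 0/0; define p from the mean difference
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    eps = 1e-9
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    p_adj = np.minimum(p * len(p), 1.0)
    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "pct_exp_A": (m.X[:, ia] > 0).mean(axis=1),
            "pct_exp_B": (m.X[:, ib] > 0).mean(axis=1),
            "p_raw": p,
            "p_adj": p_adj,
        },
        index=pd.Index(m.gene_names, name="gene"),
    )
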