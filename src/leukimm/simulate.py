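"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* ``make_repertoire`` — a power-law (Zipf) clone-size TCRbeta repertoire with
  a planted family of motif-sharing "antigen-specific" CDR3s.  Clone read
  counts follow rank^(-zipf_exponent), renormalized to the requested total by
  largest-remainder rounding; planted CDR3s carry a short core motif near the
  junction midpoint (with optional positional jitter and per-residue
  mutation), all sequences keep the conserved C...F junction flanks.
* ``make_cell_matrix`` — a negative-binomial genes x cells count matrix with
  lognormal gene baselines, planted cluster-specific expression programs and
  planted ligand-receptor co-expression.
* ``make_hto_matrix`` — Poisson hashtag-count mixtures with known
  singlet/doublet/negative truth.

The generators emulate only the statistical structure the pipeline assumes
(no V(D)J recombination model, no germline database, uniform amino-acid
background); all take explicit integer seeds and are deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .htodemux import HTOMatrix
from .repertoire import Clonotype, Repertoire
from .scquant import CountMatrix

__all__ = [
    "AMINO_ACIDS",
    "RepertoireSimConfig",
    "CellSimConfig",
    "make_repertoire",
    "make_cell_matrix",
    "make_hto_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RepertoireSimConfig:
    """Settings for a planted-motif repertoire simulation."""

    n_clones: int = 1000
    total_reads: int = 40_000
    zipf_exponent: float = 1.3
    cdr3_length_range: tuple[int, int] = (11, 17)
    n_specific: int = 0
    motif_core: str = "QRGS"
    core_position_jitter: int = 1
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        if self.total_reads < self.n_clones:
            raise ValueError("total_reads must be >= n_clones")
        if self.zipf_exponent <= 1:
            raise ValueError("zipf_exponent must be > 1")
        lo, hi = self.cdr3_length_range
        if not (8 <= lo <= hi <= 25):
            raise ValueError("cdr3_length_range must lie within [8, 25] with lo <= hi")
        if self.n_specific < 0 or self.n_specific > self.n_clones:
            raise ValueError("need 0 <= n_specific <= n_clones")
        if not (3 <= len(self.motif_core) <= 5):
            raise ValueError("motif_core length must be 3-5")
        if set(self.motif_core) - set(AMINO_ACIDS):
            raise ValueError("motif_core must use the 20 standard amino acids")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.core_position_jitter < 0:
            raise ValueError("core_position_jitter must be non-negative")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to `weights`, summing exactly to `total`."""
    target = weights / weights.sum() * total
    counts = np.floor(target).astype(np.int64)
    short = total - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _zipf_counts(n_clones: int, total_reads: int, exponent: float) -> np.ndarray:
    """Zipf clone sizes renormalized to `total_reads`, each clone >= 1 read."""
    ranks = np.arange(1, n_clones + 1, dtype=float)
    counts = _largest_remainder(ranks**-exponent, total_reads)
    # keep every clone observed: move reads from the head to zero-count tail
    deficit = int(np.sum(counts == 0))
    if deficit > 0:
        counts[counts == 0] = 1
        head = np.argsort(-counts, kind="stable")
        i = 0
        while deficit > 0:
            take = min(deficit, int(counts[head[i]] - 1))
            counts[head[i]] -= take
            deficit -= take
            i += 1
    return counts


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, 20, size=length - 2)
    return "C" + "".join(AMINO_ACIDS[i] for i in body) + "F"


def _plant_motif(rng: np.random.Generator, seq: str, cfg: RepertoireSimConfig) -> str:
    core = list(cfg.motif_core)
    L, k = len(seq), len(core)
    if cfg.mutation_rate > 0:
        for i in range(k):
            if rng.random() < cfg.mutation_rate:
                core[i] = AMINO_ACIDS[
                    (AMINO_ACIDS.index(core[i]) + 1 + rng.integers(0, 19)) % 20
                ]
    center = (L - k) // 2
    offset = int(rng.integers(-cfg.core_position_jitter, cfg.core_position_jitter + 1))
    start = int(np.clip(center + offset, 1, L - 1 - k))
    return seq[:start] + "".join(core) + seq[start + k :]


def make_repertoire(
    config: RepertoireSimConfig,
) -> tuple[Repertoire, np.ndarray]:
    """Simulate a repertoire with `n_specific` planted motif-bearing clones.

    Returns the repertoire (clones ordered by descending Zipf rank, planted
    clones at seed-determined random ranks) and a boolean specificity-label
    vector aligned with the clonotype order.  Background CDR3s are rejected if
    they contain the motif core verbatim, so at mutation_rate 0 the planted
    labels coincide exactly with the motif substring test.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    counts = _zipf_counts(cfg.n_clones, cfg.total_reads, cfg.zipf_exponent)
    labels = np.zeros(cfg.n_clones, dtype=bool)
    labels[rng.choice(cfg.n_clones, size=cfg.n_specific, replace=False)] = True

    lo, hi = cfg.cdr3_length_range
    seen: set[str] = set()
    clonotypes = []
    for i in range(cfg.n_clones):
        for _ in range(2000):
            L = int(rng.integers(lo, hi + 1))
            seq = _random_cdr3(rng, L)
            if cfg.motif_core in seq:
                continue  # keep background clean of the planted motif
            if labels[i]:
                seq = _plant_motif(rng, seq, cfg)
            if seq not in seen:
                seen.add(seq)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to generate a unique CDR3")
        clonotypes.append(Clonotype(cdr3_aa=seq, count=int(counts[i])))

    rep = Repertoire(sample_id=f"sim{cfg.seed}", clonotypes=clonotypes)
    rep.recompute_frequencies()
    return rep, labels


# ---------------------------------------------------------------------------
# Single-cell counts


@dataclass(frozen=True)
class CellSimConfig:
    """Settings for negative-binomial count-matrix and HTO simulations.

    ``program_specs`` entries are (gene-set, target cluster, log2 effect):
    each program gene's negative-binomial mean is multiplied by 2^effect in
    its target cluster.  ``lr_plants`` entries are (ligand, receptor,
    cluster A, cluster B, log2 effect): the ligand mean is boosted in cluster
    A and the receptor mean in cluster B.
    """

    clusters: tuple[tuple[str, int], ...] = (("A", 300), ("B", 300))
    n_genes: int = 500
    program_specs: tuple[tuple[tuple[str, ...], str, float], ...] = ()
    nb_dispersion: float = 2.0
    lr_plants: tuple[tuple[str, str, str, str, float], ...] = ()
    doublet_rate: float = 0.08
    n_tags: int = 4
    mu_signal: float = 200.0
    mu_background: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if any(n < 1 for _, n in self.clusters):
            raise ValueError("cluster sizes must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.n_tags < 2:
            raise ValueError("need at least 2 tags")
        if not (self.mu_signal > self.mu_background > 0):
            raise ValueError("need mu_signal > mu_background > 0")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def n_cells(self) -> int:
        return sum(n for _, n in self.clusters)


def make_cell_matrix(config: CellSimConfig) -> tuple[CountMatrix, np.ndarray]:
    """Simulate a genes x cells NB count matrix with planted programs.

    Gene baselines are lognormal; counts are negative binomial with size
    parameter ``nb_dispersion`` (variance mu + mu^2/size).  Returns the matrix
    (cell metadata carries the cluster assignment) and the truth cluster-label
    vector.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    gene_idx = {g: i for i, g in enumerate(genes)}
    cluster_names = [name for name, _ in cfg.clusters]

    for spec_genes, target, eff in cfg.program_specs:
        unknown = [g for g in spec_genes if g not in gene_idx]
        if unknown:
            raise ValueError(f"unknown gene(s) in program_specs: {unknown}")
        if target not in cluster_names:
            raise ValueError(f"unknown cluster in program_specs: {target!r}")
    for lig, rec, ca, cb, eff in cfg.lr_plants:
        for g in (lig, rec):
            if g not in gene_idx:
                raise ValueError(f"unknown gene in lr_plants: {g!r}")
        for c in (ca, cb):
            if c not in cluster_names:
                raise ValueError(f"unknown cluster in lr_plants: {c!r}")

    baseline = rng.lognormal(mean=np.log(0.3), sigma=1.0, size=cfg.n_genes)
    # per-cluster mean matrix (genes x clusters)
    mu = np.repeat(baseline[:, None], len(cfg.clusters), axis=1)
    for spec_genes, target, eff in cfg.program_specs:
        idx = [gene_idx[g] for g in spec_genes]
        mu[idx, cluster_names.index(target)] *= 2.0**eff
    for lig, rec, ca, cb, eff in cfg.lr_plants:
        mu[gene_idx[lig], cluster_names.index(ca)] *= 2.0**eff
        mu[gene_idx[rec], cluster_names.index(cb)] *= 2.0**eff

    r = cfg.nb_dispersion
    blocks, labels = [], []
    for c, (name, n_cells) in enumerate(cfg.clusters):
        m = mu[:, c][:, None]
        p = r / (r + m)
        blocks.append(rng.negative_binomial(r, p, size=(cfg.n_genes, n_cells)))
        labels.extend([name] * n_cells)
    X = np.concatenate(blocks, axis=1)
    labels = np.array(labels, dtype=object)
    barcodes = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    meta = pd.DataFrame(
        {"sample_id": "sim", "group": "sim", "cluster": labels},
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(X, genes, meta), labels


def make_hto_matrix(config: CellSimConfig) -> tuple[HTOMatrix, pd.DataFrame]:
    """Simulate hashtag counts with known singlet/doublet truth.

    Each singlet carries one tag at Poisson(mu_signal) and the others at
    Poisson(mu_background); a ``doublet_rate`` fraction of cells carries two
    distinct signal tags.  Returns the tags x cells matrix and a
    barcode-indexed truth table with columns `call` and `tag`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    tags = [f"HTO{t + 1}" for t in range(cfg.n_tags)]
    n_doublet = int(round(cfg.doublet_rate * n))
    is_doublet = np.zeros(n, dtype=bool)
    is_doublet[rng.choice(n, size=n_doublet, replace=False)] = True

    X = rng.poisson(cfg.mu_background, size=(cfg.n_tags, n))
    truth_call = np.empty(n, dtype=object)
    truth_tag = np.empty(n, dtype=object)
    for i in range(n):
        if is_doublet[i]:
            t1, t2 = rng.choice(cfg.n_tags, size=2, replace=False)
            X[t1, i] = rng.poisson(cfg.mu_signal)
            X[t2, i] = rng.poisson(cfg.mu_signal)
            truth_call[i] = "doublet"
            truth_tag[i] = None
        else:
            t1 = int(rng.integers(0, cfg.n_tags))
            X[t1, i] = rng.poisson(cfg.mu_signal)
            truth_call[i] = "singlet"
            truth_tag[i] = tags[t1]

    barcodes = [f"cell{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {"call": truth_call, "tag": truth_tag},
        index=pd.Index(barcodes, name="barcode"),
    )
    return HTOMatrix(X, tags, barcodes), truth
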