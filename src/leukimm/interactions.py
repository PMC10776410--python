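"""Permutation testing of ligand-receptor interactions between cell clusters.

The interaction score of a (ligand, receptor) pair for an ordered cluster
pair (source, target) is the average of the mean log-normalized ligand
expression in the source cluster and the mean receptor expression in the
target cluster.  Significance comes from a cluster-label permutation null
with the add-one estimator p = (1 + #{permuted score >= observed}) /
(n_perm + 1); a pair is only considered expressed when each gene is detected
in more than `min_frac` of its cluster's cells, otherwise p = 1.  Clusters
are subsampled to equal sizes first so no cluster dominates the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scquant import CountMatrix, log_normalize

__all__ = [
    "LRPair",
    "read_lr_pairs",
    "subsample_equal",
    "score_interactions",
    "count_significant",
]


@dataclass(frozen=True)
class LRPair:
    """A simple single-subunit ligand-receptor pair."""

    ligand: str
    receptor: str
    pair_id: str = ""

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("both genes must be named")
        if not self.pair_id:
            object.__setattr__(self, "pair_id", f"{self.ligand}_{self.receptor}")


def read_lr_pairs(path: str | Path) -> list[LRPair]:
    """Read a ligand-receptor pair list from TSV (columns: ligand, receptor)."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair list needs 'ligand' and 'receptor' columns")
    return [LRPair(str(r.ligand), str(r.receptor)) for r in df.itertuples()]


def subsample_equal(
    m: CountMatrix, n_per_cluster: int, seed: int = 0, cluster_col: str = "cluster"
) -> CountMatrix:
    """Subsample every cluster to exactly `n_per_cluster` cells.

    Cells are drawn without replacement; clusters smaller than
    `n_per_cluster` are dropped with a warning.
    """
    if cluster_col not in m.cell_meta.columns:
        raise ValueError(f"cell metadata lacks {cluster_col!r} column")
    rng = np.random.default_rng(seed)
    labels = m.cell_meta[cluster_col].to_numpy()
    keep_idx = []
    for name in pd.unique(labels):
        idx = np.flatnonzero(labels == name)
        if len(idx) < n_per_cluster:
            warnings.warn(
                f"cluster {name!r} has {len(idx)} < {n_per_cluster} cells; dropped"
            )
            continue
        keep_idx.append(rng.choice(idx, size=n_per_cluster, replace=False))
    if not keep_idx:
        raise ValueError("no cluster large enough to retain")
    return m.subset_cells(np.sort(np.concatenate(keep_idx)))


def score_interactions(
    m: CountMatrix,
    clusters: Optional[Sequence] = None,
    pairs: Sequence[LRPair] = (),
    n_perm: int = 1000,
    min_frac: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (pair, ordered cluster pair) against a permutation null.

    `clusters` is a per-cell label vector (defaults to the matrix's
    cluster metadata).  Returns a table with columns pair_id, ligand,
    receptor, source, target, mean_score, p_value, expressed; non-expressed
    combinations and pairs with unknown genes are flagged and given p = 1.
    """
    if clusters is None:
        clusters = m.cell_meta["cluster"].to_numpy()
    clusters = np.asarray(clusters)
    names = list(pd.unique(clusters))
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    if len(clusters) != m.n_cells:
        raise ValueError("cluster labels must match the number of cells")

    gene_pos = {g: i for i, g in enumerate(m.gene_names)}
    known, unknown = [], []
    for p in pairs:
        (known if p.ligand in gene_pos and p.receptor in gene_pos else unknown).append(p)
    if unknown:
        warnings.warn(
            f"{len(unknown)} pair(s) with unknown gene(s) skipped: "
            f"{[p.pair_id for p in unknown]}"
        )

    used_genes = sorted({g for p in known for g in (p.ligand, p.receptor)})
    gidx = np.array([gene_pos[g] for g in used_genes], dtype=int)
    sub_pos = {g: i for i, g in enumerate(used_genes)}

    logX = log_normalize(m)[gidx]  # used genes x cells
    detected = m.X[gidx] > 0
    onehot = np.stack([(clusters == nm) for nm in names]).astype(float)
    sizes = onehot.sum(axis=1)
    cl_mean = (onehot @ logX.T) / sizes[:, None]  # clusters x used genes
    cl_frac = (onehot @ detected.T) / sizes[:, None]

    # permutation null: cluster-label permutations shared across pairs
    rng = np.random.default_rng(seed)
    n_cells = m.n_cells
    perm_means = np.empty((n_perm, len(names), len(used_genes)))
    for it in range(n_perm):
        perm = rng.permutation(n_cells)
        perm_onehot = onehot[:, perm]
        perm_means[it] = (perm_onehot @ logX.T) / sizes[:, None]

    rows = []
    for p in known:
        li, ri = sub_pos[p.ligand], sub_pos[p.receptor]
        for si, source in enumerate(names):
            for ti, target in enumerate(names):
                obs = 0.5 * (cl_mean[si, li] + cl_mean[ti, ri])
                expressed = bool(
                    cl_frac[si, li] > min_frac and cl_frac[ti, ri] > min_frac
                )
                if expressed:
                    null = 0.5 * (perm_means[:, si, li] + perm_means[:, ti, ri])
                    pval = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
                else:
                    pval = 1.0
                rows.append(
                    {
                        "pair_id": p.pair_id,
                        "ligand": p.ligand,
                        "receptor": p.receptor,
                        "source": source,
                        "target": target,
                        "mean_score": float(obs),
                        "p_value": float(pval),
                        "expressed": expressed,
                    }
                )
    for p in unknown:
        rows.append(
            {
                "pair_id": p.pair_id,
                "ligand": p.ligand,
                "receptor": p.receptor,
                "source": None,
                "target": None,
                "mean_score": float("nan"),
                "p_value": 1.0,
                "expressed": False,
            }
        )
    return pd.DataFrame(rows)


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Count significant expressed interactions per ordered cluster pair."""
    sig = results[results["expressed"] & (results["p_value"] < alpha)]
    sources = [s for s in pd.unique(results["source"].dropna())]
    table = pd.DataFrame(0, index=sources, columns=sources, dtype=int)
    for (src, tgt), grp in sig.groupby(["source", "target"]):
        table.loc[src, tgt] = len(grp)
    table.index.name = "source"
    table.columns.name = "target"
    return table
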