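"""Group-comparison statistics: rank tests, Fisher's exact test, multiplicity
adjustment, log2 fold-change of medians, differential abundance and
enrichment odds ratios.

Conventions: the Mann-Whitney test is exact (full distribution of U) for
tie-free samples with fewer than 50 observations per group — the convention
of R's wilcox.test — and uses the tie- and continuity-corrected normal
approximation otherwise;
p-values across cell types are Benjamini-Hochberg adjusted; effect sizes are
log2 ratios of group medians; odds ratios use the Haldane 0.5 correction
when any table cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "kruskal_wallis",
    "fisher_exact",
    "adjust_pvalues",
    "log2fc_of_medians",
    "differential_abundance",
    "cluster_enrichment_or",
]


@dataclass(frozen=True)
class GroupComparison:
    """One group-vs-group test result."""

    statistic_name: str
    statistic: float
    p_raw: float
    p_adj: float
    adjust_method: str
    log2fc_medians: float


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact when both samples have fewer than 50 tie-free observations (the
    convention of R's wilcox.test); otherwise the normal approximation with
    tie and continuity corrections.  Returns (U of the first sample,
    two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(a), len(b)) < 50 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all observations identical: no evidence by convention
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums hypergeometric probabilities of tables at most as probable as the
    observed one.  The odds ratio is the sample estimate ad/bc, with the
    Haldane 0.5 correction applied to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b, c, d = t.ravel()
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p)


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg step-up or Bonferroni."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    key = method.lower().replace("-", "_")
    if key in ("bh", "fdr_bh", "benjamini_hochberg"):
        return multipletests(p, method="fdr_bh")[1]
    if key == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    raise ValueError(f"unknown adjustment method: {method!r}")


def log2fc_of_medians(a, b) -> float:
    """log2(median(a) / median(b)); scalars are treated as their own median.

    Non-positive medians yield signed infinity (or NaN for 0/0) with a
    warning rather than an exception.
    """
    ma = float(np.median(np.asarray(a, dtype=float)))
    mb = float(np.median(np.asarray(b, dtype=float)))
    if ma <= 0 or mb <= 0:
        warnings.warn(f"non-positive median ({ma}, {mb}); log2FC is degenerate")
        if ma > 0 and mb == 0:
            return float("inf")
        if ma == 0 and mb > 0:
            return float("-inf")
        return float("nan")
    return float(np.log2(ma / mb))


def differential_abundance(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    group_col: str = "group",
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential abundance of cell-type proportions between two sample groups.

    `table` has one row per sample, a `group` column and one numeric column
    per cell type (per-sample proportions).  Each cell type is tested with a
    two-sided Mann-Whitney test on the per-sample proportions, BH-adjusted
    across cell types; the effect size is the log2 fold-change of group
    medians.  A cell type is flagged when |log2FC| > `lfc_threshold` and
    p_adj < `alpha`.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing {group_col!r} column")
    cell_types = [c for c in table.columns if c != group_col and c != "sample_id"]
    in_a = table[table[group_col] == group_a]
    in_b = table[table[group_col] == group_b]
    if len(in_a) < 2 or len(in_b) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for ct in cell_types:
        a, b = in_a[ct].to_numpy(float), in_b[ct].to_numpy(float)
        u, p = mann_whitney(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lfc = log2fc_of_medians(a, b)
        rows.append({"cell_type": ct, "U": u, "p_raw": p, "log2fc_medians": lfc})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), "BH")
    out["flagged"] = (np.abs(out["log2fc_medians"]) > lfc_threshold) & (
        out["p_adj"] < alpha
    )
    return out


def cluster_enrichment_or(
    in_cluster_special: int,
    in_cluster_other: int,
    out_cluster_special: int,
    out_cluster_other: int,
) -> float:
    """Enrichment odds ratio of a special cell population in a cluster.

    OR = (a/b) / (c/d) for counts (a, b) inside and (c, d) outside the
    cluster, with the Haldane 0.5 correction on every cell when any is zero.
    """
    cells = [in_cluster_special, in_cluster_other, out_cluster_special, out_cluster_other]
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a / b) / (c / d))
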