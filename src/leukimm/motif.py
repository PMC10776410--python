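"""Motif-based grouping of antigen-sorted CDR3beta sequences.

Antigen-sorted TCRs that recognize the same peptide often share short local
amino-acid motifs.  This module finds k-mers enriched in a positive set
relative to a large reference repertoire (one-sided Fisher exact test per
k-mer, Benjamini-Hochberg adjusted, with a fold-change floor), links TCRs
that share an enriched motif or are globally similar (equal length, small
Hamming distance), and selects the TCRs in similarity components that are
large enough and span enough subjects — the shared-motif subset used as
classifier positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .repertoire import Repertoire

__all__ = [
    "MotifConfig",
    "MotifGroup",
    "extract_kmers",
    "enrich_motifs",
    "build_similarity_network",
    "select_shared",
]


@dataclass(frozen=True)
class MotifConfig:
    """Settings for motif enrichment and similarity grouping.

    `trim` removes conserved junction flanks (start, end residues) before
    k-mer extraction; `min_fold` and `alpha` gate motif enrichment;
    `hamming_max` sets the global-similarity edge rule; components must reach
    `min_group_size` members from `min_subjects` subjects to be selected.
    """

    k_values: tuple[int, ...] = (3, 4)
    trim: tuple[int, int] = (3, 2)
    min_fold: float = 10.0
    alpha: float = 0.05
    hamming_max: int = 1
    min_group_size: int = 3
    min_subjects: int = 2

    def __post_init__(self):
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.hamming_max < 0:
            raise ValueError("hamming_max must be non-negative")


@dataclass
class MotifGroup:
    """A k-mer motif enriched in the positive set, with its member TCRs."""

    motif: str
    members: set[str]
    subjects: set[str]
    fold: float
    p_raw: float
    p_adj: float


def extract_kmers(cdr3_aa: str, k: int, trim: tuple[int, int] = (3, 2)) -> set[str]:
    """All contiguous k-mers of the flank-trimmed CDR3 (empty if too short)."""
    start, end = trim
    core = cdr3_aa[start : len(cdr3_aa) - end if end else len(cdr3_aa)]
    if len(core) < k:
        return set()
    return {core[i : i + k] for i in range(len(core) - k + 1)}


def _as_table(positives) -> pd.DataFrame:
    """Normalize positives input to a (cdr3_aa, subject_id) DataFrame."""
    if isinstance(positives, pd.DataFrame):
        if not {"cdr3_aa", "subject_id"} <= set(positives.columns):
            raise ValueError("positives table needs cdr3_aa and subject_id columns")
        return positives[["cdr3_aa", "subject_id"]].copy()
    rows = list(positives)
    if rows and isinstance(rows[0], str):
        return pd.DataFrame({"cdr3_aa": rows, "subject_id": "s0"})
    return pd.DataFrame(rows, columns=["cdr3_aa", "subject_id"])


def enrich_motifs(
    positives,
    reference: Repertoire,
    config: MotifConfig = MotifConfig(),
) -> list[MotifGroup]:
    """K-mers enriched in the positive TCR set relative to a reference repertoire.

    For each k-mer of the trimmed positives, presence counts (number of
    sequences containing it) in positives vs reference clonotypes form a 2x2
    table tested with a one-sided Fisher exact test; p-values are BH-adjusted
    over all tested k-mers.  Fold = positive presence rate over reference
    presence rate (0.5 pseudocount when the reference count is zero).  A group
    is kept when fold >= min_fold, p_adj < alpha, and its member and subject
    counts reach the configured minima.  A CDR3 may belong to several groups.
    """
    pos = _as_table(positives)
    if len(pos) == 0:
        raise ValueError("empty positive set")
    if len(reference) == 0:
        raise ValueError("empty reference repertoire")

    pos_seqs = pos["cdr3_aa"].tolist()
    ref_seqs = reference.cdr3s()
    n_pos, n_ref = len(pos_seqs), len(ref_seqs)

    def presence(seqs: Sequence[str]) -> dict[str, set[int]]:
        found: dict[str, set[int]] = {}
        for i, s in enumerate(seqs):
            for k in config.k_values:
                for km in extract_kmers(s, k, config.trim):
                    found.setdefault(km, set()).add(i)
        return found

    pos_hits = presence(pos_seqs)
    ref_hits = presence(ref_seqs)

    kmers = sorted(pos_hits)
    p_raw = np.empty(len(kmers))
    folds = np.empty(len(kmers))
    for i, km in enumerate(kmers):
        a = len(pos_hits[km])
        b = len(ref_hits.get(km, ()))
        table = [[a, n_pos - a], [b, n_ref - b]]
        _, p = _scipy_fisher(table, alternative="greater")
        p_raw[i] = p
        ref_rate = (b if b > 0 else 0.5) / n_ref
        folds[i] = (a / n_pos) / ref_rate
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if len(kmers) else np.array([])

    subj = pos["subject_id"].tolist()
    groups = []
    for i, km in enumerate(kmers):
        if folds[i] < config.min_fold or p_adj[i] >= config.alpha:
            continue
        members = {pos_seqs[j] for j in pos_hits[km]}
        subjects = {subj[j] for j in pos_hits[km]}
        if len(members) < config.min_group_size or len(subjects) < config.min_subjects:
            continue
        groups.append(
            MotifGroup(
                motif=km,
                members=members,
                subjects=subjects,
                fold=float(folds[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
            )
        )
    groups.sort(key=lambda g: (g.p_adj, g.p_raw, g.motif))
    return groups


def _hamming_edges(seqs: list[str], hamming_max: int) -> Iterable[tuple[str, str]]:
    """Pairs of equal-length sequences within the Hamming radius."""
    if hamming_max < 0:
        return
    by_len: dict[int, list[str]] = {}
    for s in set(seqs):
        by_len.setdefault(len(s), []).append(s)
    for L, bucket in by_len.items():
        if len(bucket) < 2:
            continue
        bucket = sorted(bucket)
        arr = np.frombuffer("".join(bucket).encode(), dtype=np.uint8).reshape(
            len(bucket), L
        )
        for i in range(len(bucket)):
            d = np.sum(arr[i + 1 :] != arr[i], axis=1)
            for j in np.flatnonzero(d <= hamming_max):
                yield bucket[i], bucket[i + 1 + j]


def build_similarity_network(
    tcrs, groups: list[MotifGroup], config: MotifConfig = MotifConfig()
) -> nx.Graph:
    """TCR similarity graph: nodes are unique CDR3beta sequences.

    An edge joins two TCRs when they are members of one enriched motif group,
    or when they have equal length and Hamming distance <= hamming_max.
    Node attribute `subjects` carries the set of subject ids observed for
    that sequence.
    """
    tab = _as_table(tcrs)
    g = nx.Graph()
    subj_map: dict[str, set[str]] = {}
    for s, sub in zip(tab["cdr3_aa"], tab["subject_id"]):
        subj_map.setdefault(s, set()).add(str(sub))
    for s, subs in subj_map.items():
        g.add_node(s, subjects=subs)
    nodes = set(g.nodes)
    for grp in groups:
        members = sorted(grp.members & nodes)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j], kind="motif")
    for u, v in _hamming_edges(sorted(nodes), config.hamming_max):
        g.add_edge(u, v, kind="hamming")
    return g


def select_shared(
    tcrs, graph: nx.Graph, config: MotifConfig = MotifConfig()
) -> set[str]:
    """TCRs in similarity components with enough members and subjects.

    A component is selected when it has >= min_group_size member sequences
    spanning >= min_subjects subjects; the returned set is the union of the
    selected components' members.
    """
    selected: set[str] = set()
    for comp in nx.connected_components(graph):
        if len(comp) < config.min_group_size:
            continue
        subjects = set()
        for node in comp:
            subjects |= graph.nodes[node].get("subjects", set())
        if len(subjects) >= config.min_subjects:
            selected |= comp
    return selected


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export the similarity graph as an edge-list TSV (cdr3_a, cdr3_b, kind)."""
    rows = [
        {"cdr3_a": u, "cdr3_b": v, "kind": d.get("kind", "")}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["cdr3_a", "cdr3_b", "kind"]).to_csv(
        path, sep="\t", index=False
    )
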