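"""TCRbeta clonotype tables: reading, productive filtering, subsampling,
and diversity statistics.

A repertoire is a sample's table of clonotypes (unique CDR3beta rearrangements
with read counts).  Frequencies p_i = count_i / total feed every diversity
index: Shannon-Wiener H = -sum p_i ln p_i, its normalization H / ln(richness),
clonality = 1 - H / ln(richness), Simpson = sum p_i^2 and its inverse.
Depth normalization subsamples reads without replacement (multivariate
hypergeometric), the read-resampling semantics of repertoire toolchains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "Repertoire",
    "DiversityStats",
    "read_clonotype_table",
    "write_clonotype_table",
    "filter_productive",
    "subsample_reads",
    "diversity_stats",
]

#: symbols marking a non-productive junction: stop codon, frame shift
_NONPRODUCTIVE_CHARS = set("*_~")


@dataclass
class Clonotype:
    """One unique TCRbeta rearrangement with its read count."""

    cdr3_aa: str
    count: int
    frequency: float = 0.0
    cdr3_nt: Optional[str] = None
    v_gene: Optional[str] = None
    d_gene: Optional[str] = None
    j_gene: Optional[str] = None
    subject_id: Optional[str] = None


@dataclass
class Repertoire:
    """A sample's ordered collection of clonotypes."""

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    tissue: str = "other"  # {PB, BM, other}
    groups: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    def __len__(self) -> int:
        return len(self.clonotypes)

    def recompute_frequencies(self) -> "Repertoire":
        total = self.total_reads
        for c in self.clonotypes:
            c.frequency = c.count / total if total > 0 else 0.0
        return self

    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clonotypes], dtype=float)

    def cdr3s(self) -> list[str]:
        return [c.cdr3_aa for c in self.clonotypes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [c.count for c in self.clonotypes],
                "freq": [c.frequency for c in self.clonotypes],
                "cdr3nt": [c.cdr3_nt or "" for c in self.clonotypes],
                "cdr3aa": [c.cdr3_aa for c in self.clonotypes],
                "v": [c.v_gene or "." for c in self.clonotypes],
                "d": [c.d_gene or "." for c in self.clonotypes],
                "j": [c.j_gene or "." for c in self.clonotypes],
            }
        )


@dataclass(frozen=True)
class DiversityStats:
    richness: int
    shannon: float
    normalized_shannon: float
    simpson: float
    inverse_simpson: float
    clonality: float


# ---------------------------------------------------------------------------
# I/O

_AIRR_COLS = {"junction_aa", "duplicate_count"}
_IMMUNOSEQ_AA = "aminoAcid"
_IMMUNOSEQ_COUNTS = ["count (templates/reads)", "count (reads)", "templates", "count"]
_VDJTOOLS_COLS = {"count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"}


def _detect_dialect(cols: set[str]) -> str:
    if _AIRR_COLS <= cols:
        return "airr"
    if _IMMUNOSEQ_AA in cols and any(c in cols for c in _IMMUNOSEQ_COUNTS):
        return "immunoseq"
    if {"count", "cdr3aa"} <= cols:
        return "vdjtools"
    raise ValueError(
        "unrecognized clonotype table header; need AIRR (junction_aa, "
        "duplicate_count), immunoSEQ (aminoAcid, count), or VDJtools "
        "(count, cdr3aa) columns"
    )


def read_clonotype_table(
    path: str | Path, dialect: str = "auto", sample_id: Optional[str] = None
) -> Repertoire:
    """Read a TCRbeta clonotype table in AIRR, immunoSEQ or VDJtools dialect.

    Frequencies are always recomputed from the counts.  With
    ``dialect='auto'`` the dialect is detected from required header columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty clonotype table: {path}")
    cols = set(df.columns)
    if dialect == "auto":
        dialect = _detect_dialect(cols)

    if dialect == "airr":
        if "junction_aa" not in cols:
            raise ValueError("missing amino-acid junction column 'junction_aa'")
        if "duplicate_count" not in cols:
            raise ValueError("missing count column 'duplicate_count'")
        aa = df["junction_aa"]
        count = df["duplicate_count"]
        nt = df.get("junction")
        v, d, j = df.get("v_call"), df.get("d_call"), df.get("j_call")
    elif dialect == "immunoseq":
        if _IMMUNOSEQ_AA not in cols:
            raise ValueError("missing amino-acid junction column 'aminoAcid'")
        count_col = next((c for c in _IMMUNOSEQ_COUNTS if c in cols), None)
        if count_col is None:
            raise ValueError("missing count column")
        aa = df[_IMMUNOSEQ_AA]
        count = df[count_col]
        nt = df.get("nucleotide")
        v, d, j = df.get("vGeneName"), df.get("dGeneName"), df.get("jGeneName")
    elif dialect == "vdjtools":
        if "cdr3aa" not in cols:
            raise ValueError("missing amino-acid junction column 'cdr3aa'")
        if "count" not in cols:
            raise ValueError("missing count column")
        aa = df["cdr3aa"]
        count = df["count"]
        nt = df.get("cdr3nt")
        v, d, j = df.get("v"), df.get("d"), df.get("j")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    def _opt(series, i):
        if series is None:
            return None
        val = series.iloc[i]
        if pd.isna(val) or val in (".", ""):
            return None
        return str(val)

    clonotypes = [
        Clonotype(
            cdr3_aa="" if pd.isna(aa.iloc[i]) else str(aa.iloc[i]),
            count=int(count.iloc[i]),
            cdr3_nt=_opt(nt, i),
            v_gene=_opt(v, i),
            d_gene=_opt(d, i),
            j_gene=_opt(j, i),
        )
        for i in range(len(df))
    ]
    rep = Repertoire(sample_id=sample_id or path.stem, clonotypes=clonotypes)
    return rep.recompute_frequencies()


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as a VDJtools-style TSV (count freq cdr3nt cdr3aa v d j)."""
    rep.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations


def filter_productive(rep: Repertoire) -> Repertoire:
    """Drop non-productive clonotypes and renormalize frequencies.

    A clonotype is non-productive if its CDR3 amino-acid string is empty,
    contains a stop symbol ('*') or frame-shift marker ('_' or '~'), or its
    nucleotide junction (when present) has a length not divisible by 3.
    """
    kept = []
    for c in rep.clonotypes:
        if not c.cdr3_aa:
            continue
        if _NONPRODUCTIVE_CHARS & set(c.cdr3_aa):
            continue
        if c.cdr3_nt is not None and len(c.cdr3_nt) % 3 != 0:
            continue
        kept.append(replace(c))
    out = Repertoire(
        sample_id=rep.sample_id, clonotypes=kept, tissue=rep.tissue, groups=dict(rep.groups)
    )
    return out.recompute_frequencies()


def subsample_reads(rep: Repertoire, depth: int = 40_000, seed: int = 0) -> Repertoire:
    """Subsample a repertoire to `depth` reads without replacement.

    Counts are drawn from the multivariate hypergeometric distribution over
    the observed reads; clonotypes drawn to zero are dropped.  A repertoire at
    exactly `depth` reads is returned unchanged (up to a copy).
    """
    total = rep.total_reads
    if depth <= 0:
        raise ValueError("depth must be positive")
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total reads {total}")
    counts = rep.counts()
    if depth == total:
        new_counts = counts
    else:
        rng = np.random.default_rng(seed)
        new_counts = rng.multivariate_hypergeometric(counts, depth)
    kept = [
        replace(c, count=int(k))
        for c, k in zip(rep.clonotypes, new_counts)
        if k > 0
    ]
    out = Repertoire(
        sample_id=rep.sample_id, clonotypes=kept, tissue=rep.tissue, groups=dict(rep.groups)
    )
    return out.recompute_frequencies()


def diversity_stats(rep: Repertoire) -> DiversityStats:
    """Diversity indices of a repertoire's clone-frequency distribution.

    For a single-clone repertoire the normalized Shannon index is defined as 0
    (so clonality = 1), resolving the ln(1) = 0 degeneracy.
    """
    if len(rep) == 0:
        raise ValueError("empty repertoire")
    p = rep.frequencies()
    p = p[p > 0]
    richness = len(rep)
    shannon = float(-np.sum(p * np.log(p)))
    if richness > 1:
        normalized = shannon / math.log(richness)
    else:
        normalized = 0.0
    simpson = float(np.sum(p**2))
    return DiversityStats(
        richness=richness,
        shannon=shannon,
        normalized_shannon=normalized,
        simpson=simpson,
        inverse_simpson=1.0 / simpson,
        clonality=1.0 - normalized,
    )
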