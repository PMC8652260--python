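"""Element-to-gene assignment by closest TSS, RPKM normalization, and the
rank-based group comparisons used throughout the analysis."""

from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "ExpressionTable",
    "assign_nearest_tss",
    "TSSIndex",
    "compute_rpkm",
    "rank_sum_compare",
    "signed_rank_test",
    "read_gene_table",
    "read_gtf_genes",
    "read_counts",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: length must be positive")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on '+', ``end - 1`` on '-'."""
        return self.start if self.strand == "+" else self.end - 1


class TSSIndex:
    """Per-chromosome sorted TSS index for fast nearest-gene queries.

    Ties in distance resolve to the lexicographically smallest gene_id.
    """

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        if not genes:
            raise ValueError("gene list must be non-empty")
        self._by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for entries in self._by_chrom.values():
            entries.sort()

    def nearest(self, chrom: str, pos: int) -> Optional[str]:
        entries = self._by_chrom.get(chrom)
        if not entries:
            return None
        i = bisect_left(entries, (pos, ""))
        # candidates flanking the insertion point; scan outward over ties
        best: tuple[int, str] | None = None
        for j in range(max(0, i - 1), min(len(entries), i + 1) + 1):
            if j >= len(entries):
                continue
            tss, gid = entries[j]
            cand = (abs(pos - tss), gid)
            if best is None or cand < best:
                best = cand
        # equal-distance genes may sit further in the sorted order; check
        # every entry at the winning distance
        assert best is not None
        d = best[0]
        lo = bisect_left(entries, (pos - d, ""))
        hi = bisect_left(entries, (pos + d + 1, ""))
        for tss, gid in entries[lo:hi]:
            if abs(pos - tss) == d and gid < best[1]:
                best = (d, gid)
        return best[1]


def assign_nearest_tss(
    element: GenomicInterval, genes: Sequence[GeneModel] | TSSIndex
) -> Optional[str]:
    """Gene id with the TSS closest to the element midpoint, or None when
    no gene lies on the element's chromosome (recorded, not fatal)."""
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    return index.nearest(element.chrom, element.midpoint)


@dataclass
class ExpressionTable:
    """Per-gene raw counts and RPKM values.

    rpkm = count * 1e9 / (library_size * length)
    """

    table: pd.DataFrame  # index gene_id; columns: count, length, rpkm
    library_size: int

    def rpkm(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "rpkm"])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index


def compute_rpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_size: int,
) -> ExpressionTable:
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rows = []
    for gid, count in counts.items():
        if gid not in lengths:
            raise KeyError(f"no length for gene {gid}")
        length = lengths[gid]
        if length <= 0:
            raise ValueError(f"gene {gid}: non-positive length {length}")
        if count < 0:
            raise ValueError(f"gene {gid}: negative count {count}")
        rows.append((gid, count, length, count * 1e9 / (library_size * length)))
    df = pd.DataFrame(rows, columns=["gene_id", "count", "length", "rpkm"])
    df = df.set_index("gene_id")
    return ExpressionTable(table=df, library_size=library_size)


# ---------------------------------------------------------------------------
# Rank tests


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank splits.

    Uses midranks, so ties are handled exactly. Returns (U_a, p).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([
        sum(combo) - n1 * (n1 + 1) / 2
        for combo in itertools.combinations(ranks, n1)
    ])
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return float(u_obs), float(min(1.0, 2 * min(p_le, p_ge)))


def rank_sum_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 8 observations; otherwise the
    tie-corrected normal approximation. Returns (U statistic of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= 8 and b.size <= 8:
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (all-zero -> p = 1). Exact enumeration of
    all sign assignments for n <= 15 non-zero pairs, normal approximation
    beyond.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired groups must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    if n <= 15:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
        ws = (signs * ranks).sum(axis=1)
        p_le = np.mean(ws <= w_obs + 1e-12)
        p_ge = np.mean(ws >= w_obs - 1e-12)
        return float(min(1.0, 2 * min(p_le, p_ge)))
    return float(stats.wilcoxon(d, alternative="two-sided", method="approx").pvalue)


# ---------------------------------------------------------------------------
# Readers


def read_gene_table(path) -> list[GeneModel]:
    """6-column TSV: gene_id, chrom, strand, start, end, length."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, chrom, strand, start, end, length = line.split("\t")
            genes.append(GeneModel(gid, chrom, strand, int(start), int(end), int(length)))
    return genes


def read_gtf_genes(path) -> list[GeneModel]:
    """Gene records from a GTF; 1-based inclusive coordinates converted to
    0-based half-open. Gene length = annotated span."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = cols[:9]
            gid = None
            for field in attrs.split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gid = field.split(" ", 1)[1].strip('"')
                    break
            if gid is None:
                raise ValueError(f"GTF gene record without gene_id: {line!r}")
            start0, end0 = int(start) - 1, int(end)
            genes.append(GeneModel(gid, chrom, strand, start0, end0, end0 - start0))
    return genes


def read_counts(path) -> dict[str, int]:
    """2-column TSV: gene_id, count."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, c = line.split("\t")
            counts[gid] = int(c)
    return counts
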