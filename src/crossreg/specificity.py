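"""Cross-tissue specificity: width unification and single-linkage grouping
of elements across a tissue panel."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_intervals import GenomicInterval, PeakSet
from .gene_assoc import signed_rank_test

__all__ = [
    "SpecificityResult",
    "unify_width",
    "classify_specific",
    "paired_fraction_test",
]

DEFAULT_UNIFY_WIDTH = 2_000


@dataclass
class SpecificityResult:
    per_tissue: pd.DataFrame  # columns: tissue, n_total, n_specific, fraction
    labels: dict[str, list[bool]]  # per tissue, specific flag per element
    merge_distance: int
    n_truncated: int = 0

    def fraction(self, tissue: str) -> float:
        row = self.per_tissue.set_index("tissue").loc[tissue]
        return float(row["fraction"])


def unify_width(
    elements: PeakSet,
    width: int = DEFAULT_UNIFY_WIDTH,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PeakSet:
    """Replace every element by a fixed-width window on its midpoint.

    The window is [mid - width//2, mid + width - width//2), truncated at
    chromosome bounds (truncation count is recorded on the result as
    ``n_truncated``). Elements on chromosomes absent from ``chrom_sizes``
    are an error.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    chrom_sizes = chrom_sizes or {}
    out = []
    n_truncated = 0
    for iv in elements:
        if chrom_sizes and iv.chrom not in chrom_sizes:
            raise KeyError(f"element on unknown chromosome {iv.chrom!r}")
        mid = iv.midpoint
        start = mid - width // 2
        end = start + width
        if start < 0:
            start, n_truncated = 0, n_truncated + 1
        limit = chrom_sizes.get(iv.chrom)
        if limit is not None and end > limit:
            end, n_truncated = limit, n_truncated + 1
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand, iv.name, iv.signal))
    res = PeakSet(out, sample_label=elements.sample_label,
                  library_size=elements.library_size)
    res.n_truncated = n_truncated  # type: ignore[attr-defined]
    return res


def classify_specific(
    panel: Mapping[str, PeakSet], merge_distance: int
) -> SpecificityResult:
    """Label every element tissue-specific or shared across a panel.

    All tissues' elements are pooled and grouped by single linkage: two
    elements link iff they share a chromosome and their midpoints differ by
    at most ``merge_distance`` bp. An element is tissue-specific iff its
    group contains elements of exactly one tissue.
    """
    if len(panel) < 2:
        raise ValueError("specificity needs at least 2 tissues")
    if merge_distance < 0:
        raise ValueError("merge_distance must be non-negative")

    records = []  # (chrom, midpoint, tissue, index-within-tissue)
    for tissue, peaks in panel.items():
        for i, iv in enumerate(peaks):
            records.append((iv.chrom, iv.midpoint, tissue, i))
    records.sort(key=lambda r: (r[0], r[1]))

    # single linkage on 1D midpoints == chaining sorted neighbours
    labels = {tissue: [False] * len(peaks) for tissue, peaks in panel.items()}
    group: list[tuple[str, int, str, int]] = []

    def flush(group):
        tissues = {r[2] for r in group}
        if len(tissues) == 1:
            for _, _, tissue, i in group:
                labels[tissue][i] = True

    for rec in records:
        if group and rec[0] == group[-1][0] and rec[1] - group[-1][1] <= merge_distance:
            group.append(rec)
        else:
            if group:
                flush(group)
            group = [rec]
    if group:
        flush(group)

    rows = []
    for tissue, peaks in sorted(panel.items()):
        n_total = len(peaks)
        n_specific = sum(labels[tissue])
        frac = n_specific / n_total if n_total else float("nan")
        rows.append((tissue, n_total, n_specific, frac))
    df = pd.DataFrame(rows, columns=["tissue", "n_total", "n_specific", "fraction"])
    return SpecificityResult(per_tissue=df, labels=labels, merge_distance=merge_distance)


def paired_fraction_test(
    fractions_class1: Sequence[float], fractions_class2: Sequence[float]
) -> float:
    """Two-sided paired Wilcoxon signed-rank test on per-tissue fractions."""
    if len(fractions_class1) != len(fractions_class2):
        raise ValueError("paired fraction lists must have equal length")
    if len(fractions_class1) < 2:
        raise ValueError("need at least 2 tissue pairs")
    return signed_rank_test(fractions_class1, fractions_class2)
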