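"""Genomic interval data model, BED-like I/O and peak-level filters.

Coordinates are 0-based half-open (BED convention) throughout the package;
readers for 1-based formats convert at the boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "FragmentSet",
    "reciprocal_overlap_filter",
    "top_n_by_signal",
    "merge_within",
    "quantify_rpm",
    "read_bed",
    "write_bed",
    "read_manifest",
    "read_fragments",
    "read_chrom_sizes",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` with optional signal."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    signal: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")
        if self.signal is not None and self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """An ordered, coordinate-sorted collection of peaks from one sample.

    Duplicate ``(chrom, start, end)`` triples are rejected; iteration order
    is always (chrom, start, end) ascending so all downstream outputs are
    deterministic.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        sample_label: str = "",
        library_size: Optional[int] = None,
    ) -> None:
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        seen = set()
        for iv in ivs:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                raise ValueError(f"duplicate peak {key} in sample {sample_label!r}")
            seen.add(key)
        if library_size is not None and library_size <= 0:
            raise ValueError("library_size must be positive")
        self.intervals: list[GenomicInterval] = ivs
        self.sample_label = sample_label
        self.library_size = library_size

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    @classmethod
    def from_bed(cls, path, sample_label: str = "", library_size: Optional[int] = None) -> "PeakSet":
        return cls(read_bed(path), sample_label=sample_label, library_size=library_size)

    def to_bed(self, path) -> None:
        write_bed(path, self.intervals)


class FragmentSet:
    """Aligned fragment intervals plus the library size of their sample.

    ``library_size`` is the total mapped reads of the originating library;
    the stored fragments may be a subsample, so no consistency between the
    two is required beyond ``library_size > 0``.
    """

    def __init__(self, fragments: Iterable[GenomicInterval], library_size: int) -> None:
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        frags = sorted(fragments, key=GenomicInterval.sort_key)
        self.fragments: list[GenomicInterval] = frags
        self.library_size = int(library_size)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for f in frags:
            self._starts.setdefault(f.chrom, []).append(f.start)  # type: ignore[attr-defined]
            self._ends.setdefault(f.chrom, []).append(f.end)  # type: ignore[attr-defined]
        self._starts = {c: np.asarray(v, dtype=np.int64) for c, v in self._starts.items()}
        self._ends = {c: np.asarray(v, dtype=np.int64) for c, v in self._ends.items()}

    def __len__(self) -> int:
        return len(self.fragments)

    def count_overlapping(self, region: GenomicInterval) -> int:
        """Fragments overlapping ``region`` by >= 1 bp."""
        starts = self._starts.get(region.chrom)
        if starts is None:
            return 0
        ends = self._ends[region.chrom]
        return int(np.count_nonzero((starts < region.end) & (ends > region.start)))


def reciprocal_overlap_filter(
    a: PeakSet, b: PeakSet, min_fraction: float = 0.5
) -> PeakSet:
    """Keep peaks of ``a`` reciprocally overlapped by some peak of ``b``.

    A peak of ``a`` passes when a single contiguous intersection with one
    peak of ``b`` covers at least ``min_fraction`` of *both* peak widths
    (the comparison is >=, so the exact boundary passes). Coordinates of
    ``a`` are kept; overlaps are never summed across several ``b`` peaks.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}

    kept = []
    for pa in a:
        candidates = by_chrom.get(pa.chrom, [])
        if not candidates:
            continue
        # b is sorted by start; only peaks with start < pa.end can overlap
        hi = bisect.bisect_left(starts[pa.chrom], pa.end)
        for pb in candidates[:hi]:
            ov = pa.overlap(pb)
            if ov >= min_fraction * pa.width and ov >= min_fraction * pb.width:
                kept.append(pa)
                break
    return PeakSet(kept, sample_label=a.sample_label, library_size=a.library_size)


def top_n_by_signal(peaks: PeakSet, n: int = 20_000) -> PeakSet:
    """The ``n`` peaks with highest signal, re-sorted by coordinate.

    Ties at rank ``n`` are broken by (chrom, start, end) ascending so that
    exactly ``min(n, len(peaks))`` peaks are returned.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    for iv in peaks:
        if iv.signal is None:
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} lacks a signal value"
            )
    ranked = sorted(peaks, key=lambda iv: (-iv.signal, iv.chrom, iv.start, iv.end))
    return PeakSet(
        ranked[:n], sample_label=peaks.sample_label, library_size=peaks.library_size
    )


def _merge_runs(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[tuple[str, int, int, list[int]]]:
    """Transitive closure of merging; returns (chrom, start, end, member idx)."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i].sort_key())
    runs: list[tuple[str, int, int, list[int]]] = []
    for i in order:
        iv = intervals[i]
        if runs and runs[-1][0] == iv.chrom and iv.start - runs[-1][2] <= max_gap:
            chrom, start, end, members = runs[-1]
            runs[-1] = (chrom, start, max(end, iv.end), members + [i])
        else:
            runs.append((iv.chrom, iv.start, iv.end, [i]))
    return runs


def merge_within(intervals: PeakSet, max_gap: int) -> PeakSet:
    """Merge intervals whose inter-interval gap is <= ``max_gap`` bp.

    ``max_gap = 0`` merges touching or overlapping intervals only. The
    merged peak's ``name`` records the constituent count; the returned
    PeakSet also carries a ``constituents`` attribute with the member
    indices of each merged region (input coordinate-sort order).
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    runs = _merge_runs(list(intervals), max_gap)
    merged = [
        GenomicInterval(chrom, start, end, name=f"n={len(members)}")
        for chrom, start, end, members in runs
    ]
    out = PeakSet(merged, sample_label=intervals.sample_label,
                  library_size=intervals.library_size)
    out.constituents = [members for _, _, _, members in runs]  # type: ignore[attr-defined]
    return out


def quantify_rpm(region: GenomicInterval, reads: FragmentSet) -> float:
    """Reads-per-million signal of ``region``: overlapping-fragment count
    (>= 1 bp counts) scaled by the library size."""
    if reads.library_size <= 0:
        raise ValueError("library_size must be positive")
    return reads.count_overlapping(region) * 1e6 / reads.library_size


# ---------------------------------------------------------------------------
# I/O


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; narrowPeak accepted (signalValue column -> signal).

    For 5+ column BED without a narrowPeak signalValue, the score column is
    used as the signal.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in _STRANDS else "."
            signal: Optional[float] = None
            if len(cols) > 6:  # narrowPeak: col 7 is signalValue
                signal = float(cols[6])
            elif len(cols) > 4 and cols[4] != ".":
                signal = float(cols[4])
            out.append(GenomicInterval(chrom, start, end, strand, name, signal))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.signal is None else f"{iv.signal:g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_manifest(path) -> dict[str, tuple[str, int]]:
    """Sidecar manifest mapping sample_label -> (path, library_size)."""
    out: dict[str, tuple[str, int]] = {}
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, p, size = line.split("\t")
            p = str((base / p)) if not Path(p).is_absolute() else p
            out[label] = (p, int(size))
    return out


def read_fragments(path, library_size: int) -> FragmentSet:
    return FragmentSet(read_bed(path), library_size=library_size)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
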