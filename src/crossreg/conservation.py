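"""Cross-species conservation: UCSC chain parsing, interval liftover with a
minimum-match filter, three-way orthologous-overlap classification, and
per-element conservation-score aggregation."""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO

from .core_intervals import GenomicInterval, PeakSet

__all__ = [
    "ChainAlignment",
    "ChainParseError",
    "LiftStatus",
    "LiftResult",
    "ConservationTrack",
    "parse_chain",
    "write_chain",
    "liftover",
    "classify_functionally_conserved",
    "ConservedCounts",
    "mean_conservation_score",
    "read_wig",
    "read_bedgraph",
]

DEFAULT_MIN_MATCH = 0.2


class ChainParseError(ValueError):
    pass


@dataclass
class ChainAlignment:
    """One pairwise-alignment chain: gapped collinear blocks mapping a
    target genome interval onto a query genome interval.

    ``blocks`` is a list of (size, dt, dq); the final block has dt = dq = 0.
    All coordinates follow the chain convention: strand-relative, with
    minus-strand positions reflected against the sequence size.
    """

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[tuple[int, int, int]]

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if sizes + dts != self.t_end - self.t_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sizes + dt = {sizes + dts} "
                f"!= tEnd - tStart = {self.t_end - self.t_start}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sizes + dq = {sizes + dqs} "
                f"!= qEnd - qStart = {self.q_end - self.q_start}"
            )
        for size, dt, dq in self.blocks:
            if size <= 0 or dt < 0 or dq < 0:
                raise ChainParseError(
                    f"chain {self.chain_id}: invalid block ({size}, {dt}, {dq})"
                )


def parse_chain(stream: TextIO | str | Path) -> list[ChainAlignment]:
    """Parse UCSC chain format; both block-arithmetic invariants are
    verified for every chain."""
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_chain(fh)
    chains: list[ChainAlignment] = []
    current: Optional[ChainAlignment] = None
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            if current is not None:
                _finish_chain(current)
                chains.append(current)
            fields = line.split()
            if len(fields) not in (12, 13):
                raise ChainParseError(f"line {lineno}: malformed chain header")
            current = ChainAlignment(
                score=int(fields[1]),
                t_name=fields[2], t_size=int(fields[3]), t_strand=fields[4],
                t_start=int(fields[5]), t_end=int(fields[6]),
                q_name=fields[7], q_size=int(fields[8]), q_strand=fields[9],
                q_start=int(fields[10]), q_end=int(fields[11]),
                chain_id=fields[12] if len(fields) == 13 else str(len(chains) + 1),
                blocks=[],
            )
        else:
            if current is None:
                raise ChainParseError(f"line {lineno}: block outside a chain")
            parts = line.split()
            try:
                if len(parts) == 3:
                    current.blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    current.blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError
            except ValueError:
                raise ChainParseError(
                    f"chain {current.chain_id}, line {lineno}: malformed block {line!r}"
                ) from None
    if current is not None:
        _finish_chain(current)
        chains.append(current)
    return chains


def _finish_chain(chain: ChainAlignment) -> None:
    if not chain.blocks:
        raise ChainParseError(f"chain {chain.chain_id}: no alignment blocks")
    chain.validate()


def write_chain(path, chains: Iterable[ChainAlignment]) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")


class LiftStatus(str, Enum):
    MAPPED = "mapped"
    UNMAPPED_NO_CHAIN = "unmapped_no_chain"
    UNMAPPED_LOW_MATCH = "unmapped_low_match"
    AMBIGUOUS = "ambiguous_multiple_chains"


@dataclass
class LiftResult:
    status: LiftStatus
    mapped_interval: Optional[GenomicInterval]
    match_fraction: float

    @property
    def is_mapped(self) -> bool:
        return self.status is LiftStatus.MAPPED


def _map_through_chain(
    interval: GenomicInterval, chain: ChainAlignment
) -> tuple[int, Optional[tuple[int, int]]]:
    """Bases of ``interval`` inside aligned blocks and the spanned query
    genome interval (min..max of mapped bases, strand-reflected for '-')."""
    t_pos, q_pos = chain.t_start, chain.q_start
    mappable = 0
    q_lo: Optional[int] = None
    q_hi: Optional[int] = None
    for size, dt, dq in chain.blocks:
        o1 = max(interval.start, t_pos)
        o2 = min(interval.end, t_pos + size)
        if o2 > o1:
            mappable += o2 - o1
            a = q_pos + (o1 - t_pos)
            b = q_pos + (o2 - t_pos)
            if chain.q_strand == "-":
                a, b = chain.q_size - b, chain.q_size - a
            q_lo = a if q_lo is None else min(q_lo, a)
            q_hi = b if q_hi is None else max(q_hi, b)
        t_pos += size + dt
        q_pos += size + dq
        if t_pos >= interval.end:
            break
    span = (q_lo, q_hi) if q_lo is not None else None
    return mappable, span


def liftover(
    interval: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_match: float = DEFAULT_MIN_MATCH,
) -> LiftResult:
    """Map one interval through pairwise-alignment chains.

    The match fraction is the share of the interval's bases lying inside
    aligned blocks of a chain. Chains are tried in descending score; the
    result spans min..max of the block-mapped query coordinates. An
    interval passing ``min_match`` on two chains whose query spans do not
    overlap is rejected as ambiguous rather than duplicated.
    """
    if not (0 < min_match <= 1):
        raise ValueError(f"min_match must be in (0, 1], got {min_match}")
    candidates = [
        c for c in chains
        if c.t_name == interval.chrom
        and c.t_start < interval.end and c.t_end > interval.start
    ]
    if not candidates:
        return LiftResult(LiftStatus.UNMAPPED_NO_CHAIN, None, 0.0)
    candidates.sort(key=lambda c: -c.score)

    passing: list[tuple[ChainAlignment, float, tuple[int, int]]] = []
    best_fraction = 0.0
    for chain in candidates:
        mappable, span = _map_through_chain(interval, chain)
        fraction = mappable / interval.width
        best_fraction = max(best_fraction, fraction)
        if span is not None and fraction >= min_match:
            passing.append((chain, fraction, span))
    if not passing:
        return LiftResult(LiftStatus.UNMAPPED_LOW_MATCH, None, best_fraction)
    if len(passing) > 1:
        top = passing[0]
        for other in passing[1:]:
            disjoint = (
                other[0].q_name != top[0].q_name
                or other[2][1] <= top[2][0]
                or other[2][0] >= top[2][1]
            )
            if disjoint:
                return LiftResult(LiftStatus.AMBIGUOUS, None, top[1])
    chain, fraction, (lo, hi) = passing[0]
    mapped = GenomicInterval(
        chain.q_name, lo, hi, strand=interval.strand,
        name=interval.name, signal=interval.signal,
    )
    return LiftResult(LiftStatus.MAPPED, mapped, fraction)


# ---------------------------------------------------------------------------
# Three-way functional conservation


@dataclass
class ConservedCounts:
    n_conserved: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_conserved / self.n_total if self.n_total else float("nan")


def _links(a: GenomicInterval, b: GenomicInterval, merge_distance: int) -> bool:
    if a.chrom != b.chrom:
        return False
    if merge_distance == 0:
        return a.overlap(b) >= 1
    return abs(a.midpoint - b.midpoint) <= merge_distance


def classify_functionally_conserved(
    focal_lifted: PeakSet,
    reference_elements: PeakSet,
    other_lifted: PeakSet,
    merge_distance: int = 0,
    n_unmapped: int = 0,
) -> tuple[list[bool], ConservedCounts]:
    """Label focal-species elements functionally conserved.

    All three sets must already be in the reference coordinate frame. An
    element is conserved iff it links (interval overlap when
    ``merge_distance`` is 0, midpoint distance otherwise) to at least one
    reference element AND at least one other-species element. Elements that
    failed liftover are not in ``focal_lifted`` but still belong in the
    denominator; pass their count as ``n_unmapped``.
    """
    if len(focal_lifted) and len(reference_elements):
        if not (focal_lifted.chroms() & reference_elements.chroms()):
            raise ValueError(
                "no shared chromosome names between lifted and reference "
                "elements: coordinate frames probably differ"
            )
    labels = []
    ref_list = list(reference_elements)
    other_list = list(other_lifted)
    for iv in focal_lifted:
        in_ref = any(_links(iv, r, merge_distance) for r in ref_list)
        in_other = in_ref and any(_links(iv, o, merge_distance) for o in other_list)
        labels.append(in_ref and in_other)
    counts = ConservedCounts(
        n_conserved=sum(labels), n_total=len(focal_lifted) + n_unmapped
    )
    return labels, counts


# ---------------------------------------------------------------------------
# Conservation-score tracks


class ConservationTrack:
    """Sparse per-base scores in [0, 1]; bases without data are distinct
    from score 0."""

    def __init__(self, segments: Mapping[str, Sequence[tuple[int, int, float]]]) -> None:
        self._segments: dict[str, list[tuple[int, int, float]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, segs in segments.items():
            segs = sorted(segs)
            for start, end, value in segs:
                if not (0.0 <= value <= 1.0):
                    raise ValueError(f"score {value} outside [0, 1]")
                if end <= start:
                    raise ValueError(f"empty segment [{start}, {end})")
            self._segments[chrom] = list(segs)
            self._starts[chrom] = [s for s, _, _ in segs]

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        return self._segments.get(chrom, [])


def mean_conservation_score(
    interval: GenomicInterval, track: ConservationTrack
) -> tuple[Optional[float], float]:
    """(mean score over bases with data, fraction of bases covered).

    The mean is ``None`` — undefined, distinct from 0 — when no base of the
    interval has data.
    """
    segs = track.segments(interval.chrom)
    starts = track._starts.get(interval.chrom, [])
    i = bisect_left(starts, interval.start)
    if i > 0:
        i -= 1
    total = 0.0
    covered = 0
    for start, end, value in segs[i:]:
        if start >= interval.end:
            break
        o1, o2 = max(start, interval.start), min(end, interval.end)
        if o2 > o1:
            covered += o2 - o1
            total += value * (o2 - o1)
    if covered == 0:
        return None, 0.0
    return total / covered, covered / interval.width


def read_wig(path) -> ConservationTrack:
    """fixedStep WIG reader (1-based starts converted to 0-based)."""
    segments: dict[str, list[tuple[int, int, float]]] = {}
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                chrom = params["chrom"]
                pos = int(params["start"]) - 1
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                segments.setdefault(chrom, [])
            elif line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep is not supported")
            else:
                if chrom is None:
                    raise ValueError(f"{path}:{lineno}: value before fixedStep header")
                segments[chrom].append((pos, pos + span, float(line)))
                pos += step
    return ConservationTrack(segments)


def read_bedgraph(path) -> ConservationTrack:
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            segments.setdefault(chrom, []).append((int(start), int(end), float(value)))
    return ConservationTrack(segments)
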