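"""Broad-domain calling: the top 5% broadest H3K4me3 peaks, plus the
per-bp input-normalized peak intensity used to characterize them."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_intervals import FragmentSet, GenomicInterval, PeakSet, quantify_rpm

__all__ = ["BDCallResult", "call_broad_domains", "peak_intensity"]

DEFAULT_BD_FRACTION = 0.05


@dataclass
class BDCallResult:
    broad: PeakSet
    narrow: PeakSet
    width_threshold: int  # smallest broad-domain width
    fraction: float


def call_broad_domains(peaks: PeakSet, fraction: float = DEFAULT_BD_FRACTION) -> BDCallResult:
    """Partition peaks into broad domains (top ``fraction`` by width) and
    narrow domains.

    k = ceil(fraction * N), which guarantees at least one broad domain for
    any non-empty input. Ties at the boundary width are broken by
    (chrom, start, end) ascending so exactly k peaks are broad.
    """
    n = len(peaks)
    if n == 0:
        raise ValueError("cannot call broad domains on an empty peak set")
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    k = math.ceil(fraction * n)
    ranked = sorted(peaks, key=lambda iv: (-iv.width, iv.chrom, iv.start, iv.end))
    broad = ranked[:k]
    narrow = ranked[k:]
    return BDCallResult(
        broad=PeakSet(broad, sample_label=peaks.sample_label,
                      library_size=peaks.library_size),
        narrow=PeakSet(narrow, sample_label=peaks.sample_label,
                       library_size=peaks.library_size),
        width_threshold=min(iv.width for iv in broad),
        fraction=fraction,
    )


def peak_intensity(
    peak: GenomicInterval, chip: FragmentSet, control: FragmentSet
) -> float:
    """Input-normalized tags per base pair of peak.

    max(chip_rpm - input_rpm, 0) / width: the same rpm-subtraction
    convention used for enhancer scoring, further normalized to breadth.
    """
    if peak.width <= 0:
        raise ValueError("peak width must be positive")
    net = max(quantify_rpm(peak, chip) - quantify_rpm(peak, control), 0.0)
    return net / peak.width
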