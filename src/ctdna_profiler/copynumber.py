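"""Focal copy-number calling from segmented log2 ratios.

Gene-level calls are made *differentially* against flanking control
regions, defined as 3-8 Mb upstream of the gene start and 3-8 Mb
downstream of the gene end.  A focal amplification is called when the
median log2-ratio over the gene exceeds the control median by >= 0.5; a
focal deletion when the control exceeds the gene by >= 0.3.  Homozygous
deletions are an *absolute* call: gene median log2 <= -1 (at appreciable
tumor fraction, both copies lost).  Medians are taken over the underlying
bins, i.e. segments are weighted by the number of their bins whose
midpoints fall inside the queried window.

Heterozygous-SNP allele ratios (BAF) provide orthogonal support: under an
allelic imbalance at tumor fraction ``tf`` the major-allele ratio deviates
from 1/2 by a predictable amount (one-copy loss: 1/(2-tf); one-copy gain:
(1+tf)/(2+tf)).  A call is BAF-supported when the mean folded deviation
|ratio - 1/2| reaches at least half the expected deviation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .panel import CHROM_LENGTHS, gene_interval


class CopyNumberError(ValueError):
    pass


class CNStatus(enum.Enum):
    AMP = "AMP"
    DEL = "DEL"
    HOMDEL = "HOMDEL"
    NEUTRAL = "NEUTRAL"
    NOCALL = "NOCALL"


@dataclass(frozen=True)
class Segment:
    """One copy-number segment; interval is 0-based half-open."""

    chrom: str
    start: int
    end: int
    log2: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CopyNumberError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.n_bins < 1:
            raise CopyNumberError("segment must contain at least one bin")


@dataclass(frozen=True)
class SnpBaf:
    """Plasma allele ratio (alt/total) of a heterozygous germline SNP."""

    position: int
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise CopyNumberError(f"allele ratio {self.ratio} outside [0, 1]")


@dataclass(frozen=True)
class CNThresholds:
    amp_diff: float = 0.5
    del_diff: float = 0.3
    homdel_log2: float = -1.0
    control_near: int = 3_000_000
    control_far: int = 8_000_000
    min_control_bins: int = 10
    min_snps: int = 3


@dataclass(frozen=True)
class GeneCNCall:
    gene: str
    status: CNStatus
    gene_log2: float | None
    control_log2: float | None
    baf_supported: bool | None = None


def _bins_in_window(seg: Segment, win_start: int, win_end: int) -> int:
    """Number of the segment's bins that overlap [win_start, win_end).

    Bins partition the segment evenly: bin i spans
    [start + i*w, start + (i+1)*w) with w = (end - start) / n_bins.
    Computed in exact integer arithmetic (overlap conditions are scaled by
    n_bins), so small windows inside one large segment still count bins.
    """
    if win_end <= seg.start or win_start >= seg.end:
        return 0
    span = seg.end - seg.start
    a = (max(win_start, seg.start) - seg.start) * seg.n_bins
    b = (min(win_end, seg.end) - seg.start) * seg.n_bins
    lo = a // span            # first bin with end > a
    hi = -(-b // span)        # one past the last bin with start < b
    return max(min(hi, seg.n_bins) - max(lo, 0), 0)


def _weighted_median(values_counts: Sequence[tuple[float, int]]) -> float | None:
    """Median of the multiset in which each value is repeated ``count`` times
    (even total -> mean of the two middle elements, as for a plain median)."""
    pairs = sorted((v, c) for v, c in values_counts if c > 0)
    total = sum(c for _, c in pairs)
    if total == 0:
        return None
    lo_idx = (total - 1) // 2
    hi_idx = total // 2
    lo_val = hi_val = None
    cum = 0
    for v, c in pairs:
        if lo_val is None and cum + c > lo_idx:
            lo_val = v
        if cum + c > hi_idx:
            hi_val = v
            break
        cum += c
    return (lo_val + hi_val) / 2.0


def _window_median(
    segments: Iterable[Segment], windows: Sequence[tuple[int, int]]
) -> tuple[float | None, int]:
    pairs: list[tuple[float, int]] = []
    for seg in segments:
        n = sum(_bins_in_window(seg, a, b) for a, b in windows)
        if n:
            pairs.append((seg.log2, n))
    total = sum(c for _, c in pairs)
    return _weighted_median(pairs), total


def control_region_log2(
    segments: Sequence[Segment],
    gene: tuple[str, int, int],
    thresholds: CNThresholds = CNThresholds(),
    chrom_lengths: dict[str, int] | None = None,
) -> float | None:
    """Bin-weighted median log2 over the pooled flanking control windows
    [start-8Mb, start-3Mb) and [end+3Mb, end+8Mb), clipped to the
    chromosome; ``None`` when fewer than ``min_control_bins`` bins overlap."""
    chrom, start, end = gene
    lengths = chrom_lengths if chrom_lengths is not None else CHROM_LENGTHS
    chrom_len = lengths.get(chrom)
    if chrom_len is None:
        raise CopyNumberError(f"unknown chromosome {chrom!r}")
    if start < 0 or end > chrom_len or start >= end:
        raise CopyNumberError(f"gene interval {gene} off chromosome range")
    windows = []
    up = (max(start - thresholds.control_far, 0), max(start - thresholds.control_near, 0))
    down = (min(end + thresholds.control_near, chrom_len), min(end + thresholds.control_far, chrom_len))
    for a, b in (up, down):
        if a < b:
            windows.append((a, b))
    on_chrom = [s for s in segments if s.chrom == chrom]
    median, n_bins = _window_median(on_chrom, windows)
    if n_bins < thresholds.min_control_bins:
        return None
    return median


def gene_log2(
    segments: Sequence[Segment],
    gene: tuple[str, int, int],
) -> float | None:
    """Bin-weighted median log2 over the gene interval itself."""
    chrom, start, end = gene
    on_chrom = [s for s in segments if s.chrom == chrom]
    median, n_bins = _window_median(on_chrom, [(start, end)])
    return median if n_bins > 0 else None


def call_focal(
    gene: str,
    segments: Sequence[Segment],
    snps: Sequence[SnpBaf] = (),
    tf: float = 0.0,
    thresholds: CNThresholds = CNThresholds(),
    interval: tuple[str, int, int] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> GeneCNCall:
    """Call the gene's focal copy-number status against its flanking controls.

    HOMDEL (absolute rule) takes precedence over DEL when both fire;
    NOCALL when the gene or its control regions lack bin coverage.
    ``snps`` should be the heterozygous SNPs within the gene region.
    """
    iv = interval if interval is not None else gene_interval(gene)
    g = gene_log2(segments, iv)
    c = control_region_log2(segments, iv, thresholds, chrom_lengths)
    if g is None or c is None:
        return GeneCNCall(gene, CNStatus.NOCALL, g, c)
    if g - c >= thresholds.amp_diff:
        status = CNStatus.AMP
    elif c - g >= thresholds.del_diff:
        status = CNStatus.HOMDEL if g <= thresholds.homdel_log2 else CNStatus.DEL
    elif g <= thresholds.homdel_log2:
        status = CNStatus.HOMDEL
    else:
        status = CNStatus.NEUTRAL
    baf = None
    if status in (CNStatus.AMP, CNStatus.DEL, CNStatus.HOMDEL):
        baf = baf_support(snps, status, tf, thresholds)
    return GeneCNCall(gene, status, g, c, baf)


def expected_baf_deviation(status: CNStatus, tf: float) -> float:
    """Expected |major-allele ratio - 1/2| under the cfDNA mixture model.

    One-copy loss: major ratio 1/(2-tf); one-copy gain (3 total copies):
    (1+tf)/(2+tf).  Homozygous deletion removes tumor signal entirely, so
    the loss expectation is used as a conservative stand-in.
    """
    if status in (CNStatus.DEL, CNStatus.HOMDEL):
        return 1.0 / (2.0 - tf) - 0.5
    if status is CNStatus.AMP:
        return (1.0 + tf) / (2.0 + tf) - 0.5
    return 0.0


def baf_support(
    snps: Sequence[SnpBaf],
    status: CNStatus,
    tf: float,
    thresholds: CNThresholds = CNThresholds(),
) -> bool | None:
    """True when the mean folded BAF deviation reaches half the expected
    deviation for the called state at ``tf``; ``None`` with fewer than
    ``min_snps`` informative SNPs."""
    if len(snps) < thresholds.min_snps:
        return None
    expected = expected_baf_deviation(status, tf)
    if expected <= 0.0:
        return False
    mean_dev = sum(abs(s.ratio - 0.5) for s in snps) / len(snps)
    return mean_dev >= 0.5 * expected


def assess_loh(
    gene: str,
    snps: Sequence[SnpBaf],
    tf: float,
    call: GeneCNCall | None = None,
    thresholds: CNThresholds = CNThresholds(),
) -> bool:
    """Loss of heterozygosity at a gene locus: a focal deletion call, or a
    BAF deviation consistent with one-copy loss at ``tf`` (which also covers
    copy-neutral LOH)."""
    if call is not None and call.status in (CNStatus.DEL, CNStatus.HOMDEL):
        return True
    supported = baf_support(snps, CNStatus.DEL, tf, thresholds)
    return bool(supported)
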