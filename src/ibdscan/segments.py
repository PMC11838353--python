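"""IBD segment input and the IBD rate track.

The scan statistic at focal position m is the IBD rate: the fraction of
eligible haplotype pairs that share a detected identity-by-descent segment
(at least ``min_cm`` long) overlapping m.  Segments arrive as the
tab-separated 8-column output of detectors in the hap-ibd / ibd-ends
family: sample1, hap1, sample2, hap2, chrom, start bp, end bp, cM length.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .maps import GeneticMap, ScanGrid

__all__ = [
    "IBDSegment",
    "SampleInfo",
    "RateTrack",
    "SegmentParseError",
    "read_ibd_segments",
    "pair_count",
    "compute_ibd_rates",
]

logger = logging.getLogger(__name__)


class SegmentParseError(ValueError):
    """Raised for malformed rows in a segment file."""


@dataclass(frozen=True)
class IBDSegment:
    """One detected IBD segment between two haplotypes."""

    chrom: str
    id_a: str          # sample id + haplotype index, e.g. "s12.1"
    id_b: str
    start_bp: float
    end_bp: float
    length_cm: float

    @property
    def within_individual(self) -> bool:
        """True for homozygosity-by-descent: both haplotypes of one sample."""
        return self.id_a.rsplit(".", 1)[0] == self.id_b.rsplit(".", 1)[0]


@dataclass(frozen=True)
class SampleInfo:
    """Sample size and ploidy, which together fix the pair count f(n)."""

    n: int
    ploidy: str = "diploid"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 individuals")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")


def pair_count(info: SampleInfo) -> int:
    """Number of eligible haplotype pairs f(n).

    Diploids: ``2n(2n-1)/2 - 2n`` — all unordered pairs among the 2n
    haplotypes minus the within-individual pairs.  Haploids: ``n**2``.
    """
    n = info.n
    if info.ploidy == "diploid":
        return (2 * n * (2 * n - 1)) // 2 - 2 * n
    return n * n


@dataclass
class RateTrack:
    """IBD rates on a scan grid.

    ``rates[m]`` is the number of retained segments covering grid point m
    divided by the pair count ``f_n``.
    """

    grid: ScanGrid
    rates: np.ndarray
    min_cm: float
    f_n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom_ids,
                "cm": self.grid.cm,
                "bp": self.grid.bp,
                "rate": self.rates,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _open_text(path):
    with open(path, "rb") as raw:
        head = raw.read(2)
    if head == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return io.open(path, "rt")


def read_ibd_segments(path, min_cm: float = 0.0) -> Iterator[IBDSegment]:
    """Stream IBD segments from an 8-column seg file, filtered by length.

    Yields only segments with ``length_cm >= min_cm`` (boundary inclusive).
    Within-individual pairs are retained here and flagged via
    :attr:`IBDSegment.within_individual`; rate computation decides whether
    to count them.  Gzip-compressed input is detected automatically.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                parts = line.split()
            if len(parts) < 8:
                raise SegmentParseError(f"{path}:{lineno}: expected 8 columns")
            try:
                s1, h1, s2, h2, chrom = parts[0], parts[1], parts[2], parts[3], parts[4]
                start_bp, end_bp = float(parts[5]), float(parts[6])
                length_cm = float(parts[7])
            except ValueError as exc:
                raise SegmentParseError(f"{path}:{lineno}: cannot parse row") from exc
            if end_bp <= start_bp:
                raise SegmentParseError(
                    f"{path}:{lineno}: non-positive physical span"
                )
            if length_cm < min_cm:
                continue
            yield IBDSegment(
                chrom=chrom,
                id_a=f"{s1}.{h1}",
                id_b=f"{s2}.{h2}",
                start_bp=start_bp,
                end_bp=end_bp,
                length_cm=length_cm,
            )


def compute_ibd_rates(
    segments: Iterable[IBDSegment],
    grid: ScanGrid,
    gmap: GeneticMap,
    info: SampleInfo,
    min_cm: float = 0.0,
) -> RateTrack:
    """Count segment coverage at every grid point and divide by f(n).

    A segment covers focal position p iff its genetic span contains p as a
    closed interval (start_cM <= p <= end_cM), endpoints obtained by linear
    interpolation of the segment's physical bounds.  Implemented with a
    difference array: each segment contributes +1 at its first covered grid
    index and -1 past its last, then a cumulative sum gives per-point
    counts in O(segments + M).

    Segments shorter than ``min_cm``, within-individual pairs (diploid
    data), and segments on chromosomes absent from the grid are excluded;
    the last are counted and logged.
    """
    counts = np.zeros(grid.M + 1, dtype=np.int64)
    delta = grid.delta_cm
    skipped_chrom = 0
    exclude_self = info.ploidy == "diploid"
    for seg in segments:
        if seg.length_cm < min_cm:
            continue
        if exclude_self and seg.within_individual:
            continue
        if seg.chrom not in grid.offsets:
            skipped_chrom += 1
            continue
        bp, _cm = gmap.tables[seg.chrom]
        lo_bp, hi_bp = bp[0], bp[-1]
        start_cm = gmap.interpolate(seg.chrom, min(max(seg.start_bp, lo_bp), hi_bp))
        end_cm = gmap.interpolate(seg.chrom, min(max(seg.end_bp, lo_bp), hi_bp))
        a, b = grid.offsets[seg.chrom]
        grid0 = grid.cm[a]
        # closed-interval coverage; 1e-9 cM tolerance absorbs float error
        # so segment ends landing exactly on a grid point are included
        i0 = int(np.ceil((start_cm - grid0) / delta - 1e-9))
        i1 = int(np.floor((end_cm - grid0) / delta + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, (b - a) - 1)
        if i0 > i1:
            continue
        counts[a + i0] += 1
        counts[a + i1 + 1] -= 1
    if skipped_chrom:
        logger.warning(
            "skipped %d segments on chromosomes absent from the grid", skipped_chrom
        )
    coverage = np.cumsum(counts[:-1])
    f_n = pair_count(info)
    rates = coverage / f_n
    if grid.M and np.any(rates == 0):
        frac = float(np.mean(rates == 0))
        if frac > 0.05:
            logger.warning(
                "%.1f%% of grid points have zero IBD rate; the sample may be "
                "too small to observe segments >= %.1f cM — review the scan "
                "plots to assess whether rates are truncated at zero",
                100 * frac,
                min_cm,
            )
    return RateTrack(grid=grid, rates=rates, min_cm=min_cm, f_n=f_n)
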