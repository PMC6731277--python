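"""FRiP computation and FRiP-ratio rescaling of coverage tracks.

To compare ChIP coverage across experiments with different signal-to-noise,
each track is rescaled by the ratio of the best FRiP (fraction of reads in
peaks) in the batch to its own FRiP:

    C*_chr,i(D) = C_chr,i(D) * max_D(FRIP) / FRIP_D

so the track with the highest FRiP is unchanged and weaker tracks are scaled
up. Coverage is held per chromosome in RPM units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import GenomicInterval


@dataclass
class PeakSet:
    """Sorted, merged (non-overlapping) peak intervals."""

    intervals: list[GenomicInterval]

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_end:  # touching intervals merge too
                    cur_end = max(cur_end, iv.end)
                else:
                    merged.append(GenomicInterval(chrom, cur_start, cur_end))
                    cur_start, cur_end = iv.start, iv.end
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
        return cls(merged)


def compute_frip(reads: Sequence[GenomicInterval], peaks: PeakSet) -> float:
    """Fraction of reads overlapping (>=1 base) any merged peak."""
    if not reads:
        raise ValueError("need at least one read")
    if not peaks.intervals:
        return 0.0
    trees: dict[str, IntervalTree] = {}
    for iv in peaks.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    hits = sum(
        1 for r in reads
        if (t := trees.get(r.chrom)) is not None and t.overlap(r.start, r.end))
    return hits / len(reads)


@dataclass
class CoverageTrack:
    """Per-chromosome RPM coverage arrays with the dataset's FRiP."""

    dataset_id: str
    coverage: dict[str, np.ndarray]
    frip: float

    def __post_init__(self) -> None:
        if not 0.0 < self.frip <= 1.0:
            raise ValueError(f"FRiP must be in (0,1], got {self.frip}")
        for chrom, arr in self.coverage.items():
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")


def rpm(raw_counts: dict[str, np.ndarray], total_mapped_reads: int) -> dict[str, np.ndarray]:
    """Scale raw per-base read counts to reads-per-million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return {c: arr.astype(float) * 1e6 / total_mapped_reads
            for c, arr in raw_counts.items()}


def rescale_coverage(tracks: Sequence[CoverageTrack]) -> list[CoverageTrack]:
    """Apply the FRiP-ratio rescaling; the max-FRiP track is returned unchanged.

    Scale factors are always >= 1; multiplying a rescaled track by
    FRIP_D / max(FRIP) recovers the input exactly.
    """
    if not tracks:
        raise ValueError("need at least one track")
    max_frip = max(t.frip for t in tracks)
    out = []
    for t in tracks:
        factor = max_frip / t.frip
        out.append(CoverageTrack(
            t.dataset_id, {c: arr * factor for c, arr in t.coverage.items()}, t.frip))
    return out


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.dataset_id}"\n')
        for chrom in sorted(track.coverage):
            arr = track.coverage[chrom]
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, dataset_id: str, frip: float,
                  chrom_sizes: dict[str, int]) -> CoverageTrack:
    coverage = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split("\t")
            coverage[chrom][int(start):int(end)] = float(value)
    return CoverageTrack(dataset_id, coverage, frip)
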