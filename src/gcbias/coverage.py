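"""Per-base read-coverage tracks and coverage diagnostics.

Coverage counts read bodies (not whole fragments): a base's depth is
the number of reads whose aligned span covers it.  Tracks come either
from a simulator truth-placement file — read spans derived from the
fragment ends and the read length — or from SAM/BAM alignments, where
every reported alignment contributes by default (multi-hit reads count
at every locus) and soft-clipped segments are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeSequence
from .simulate import FragmentRecord

__all__ = [
    "CoverageTrack",
    "ZeroCoverageReport",
    "DepthHistogram",
    "coverage_from_truth",
    "coverage_from_alignments",
    "zero_coverage_regions",
    "depth_distribution_at_loci",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    seq_name: str
    depth: np.ndarray  # one non-negative integer per base

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def length(self) -> int:
        return len(self.depth)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


@dataclass(frozen=True)
class ZeroCoverageReport:
    regions: list[tuple[int, int]]  # maximal zero runs, 0-based half-open

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_bases(self) -> int:
        return sum(e - s for s, e in self.regions)


@dataclass(frozen=True)
class DepthHistogram:
    edges: np.ndarray  # integer depth bin edges, len = n_bins + 1
    counts: np.ndarray
    n_bases: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_bases


def _read_spans(frag: FragmentRecord, read_length: int) -> list[tuple[int, int]]:
    """Spans of the two reads cut from a fragment's ends."""
    rl = min(read_length, frag.length)
    return [(frag.start, frag.start + rl), (frag.end - rl, frag.end)]


def coverage_from_truth(
    truth: list[FragmentRecord],
    read_length: int,
    genome: GenomeSequence | int,
    seq_name: str | None = None,
) -> CoverageTrack:
    """Depth per base from simulator truth placements.

    Each fragment contributes its two reads; with inserts shorter than
    twice the read length the reads overlap mid-fragment and those
    bases count twice.  Wrapped (circular) placements with
    ``end > length`` are split at the origin.
    """
    if isinstance(genome, GenomeSequence):
        length = genome.length
        seq_name = seq_name or genome.name
    else:
        length = int(genome)
        seq_name = seq_name or (truth[0].seq_name if truth else "seq")
    diff = np.zeros(length + 1, dtype=np.int64)
    for frag in truth:
        if frag.start < 0 or frag.end <= frag.start or frag.end > 2 * length:
            raise ValueError(f"truth record out of bounds: {frag}")
        if frag.end > length and frag.start >= length:
            raise ValueError(f"truth record out of bounds: {frag}")
        for s, e in _read_spans(frag, read_length):
            if e <= length:
                diff[s] += 1
                diff[e] -= 1
            else:  # circular wrap
                diff[s % length] += 1
                diff[length] -= 1
                diff[0] += 1
                diff[e - length] -= 1
    return CoverageTrack(seq_name=seq_name, depth=np.cumsum(diff[:-1]))


def coverage_from_alignments(
    path: str | Path,
    include_multihits: bool = True,
) -> dict[str, CoverageTrack]:
    """Depth per reference base from a SAM/BAM file.

    Every mapped alignment record contributes its aligned blocks
    (soft clips, insertions and skips excluded).  With
    ``include_multihits`` (default, matching an aligner configured to
    report all hits) secondary alignments count too; switch it off for
    primary-only pileups.
    """
    with pysam.AlignmentFile(str(path), check_sq=True) as af:
        if af.nreferences == 0:
            raise ValueError(f"{path}: no reference sequences in header")
        diffs = {
            name: np.zeros(length + 1, dtype=np.int64)
            for name, length in zip(af.references, af.lengths)
        }
        any_mapped = False
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if not include_multihits and (aln.is_secondary or aln.is_supplementary):
                continue
            any_mapped = True
            diff = diffs[aln.reference_name]
            for s, e in aln.get_blocks():
                diff[s] += 1
                diff[e] -= 1
    if not any_mapped:
        raise ValueError(f"{path}: no mapped alignments")
    return {
        name: CoverageTrack(seq_name=name, depth=np.cumsum(diff[:-1]))
        for name, diff in diffs.items()
    }


def zero_coverage_regions(track: CoverageTrack) -> ZeroCoverageReport:
    """Maximal runs of zero depth, their count and total length."""
    is_zero = np.concatenate([[0], (track.depth == 0).astype(np.int8), [0]])
    changes = np.flatnonzero(np.diff(is_zero))
    starts, ends = changes[0::2], changes[1::2]
    return ZeroCoverageReport(regions=list(zip(starts.tolist(), ends.tolist())))


def depth_distribution_at_loci(
    track: CoverageTrack,
    loci: list[tuple[int, int]] | None = None,
    bin_width: int = 1,
) -> DepthHistogram:
    """Histogram of depth values at the selected bases.

    ``loci`` is a list of 0-based half-open intervals; None means the
    whole sequence (the background distribution).
    """
    if loci is None:
        values = track.depth
    else:
        if len(loci) == 0:
            raise ValueError("empty loci set")
        parts = []
        for s, e in loci:
            if s < 0 or e > track.length or e <= s:
                raise ValueError(f"locus ({s}, {e}) out of bounds")
            parts.append(track.depth[s:e])
        values = np.concatenate(parts)
    if bin_width < 1:
        raise ValueError("bin_width must be a positive integer")
    top = int(values.max()) + 1 if len(values) else 1
    n_bins = int(np.ceil(top / bin_width))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return DepthHistogram(edges=edges, counts=counts, n_bases=len(values))


# ---------------------------------------------------------------------------
# plain-text interval I/O


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return list(df.itertuples(index=False, name=None))


def write_bed(intervals, path: str | Path, chrom: str | None = None) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if len(iv) == 2:
                fh.write(f"{chrom}\t{iv[0]}\t{iv[1]}\n")
            else:
                fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-compressed per-base depth in bedGraph format."""
    d = track.depth
    boundaries = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(d)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.seq_name}\t{s}\t{e}\t{d[s]}\n")
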