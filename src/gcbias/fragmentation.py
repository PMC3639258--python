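"""Genome-breaking analysis: the "shear" effect of repeats and extreme GC.

To compare how much repeats versus GC bias limit achievable assembly
contiguity, the genome is broken into pieces by removing a set of
intervals — repeat annotations, or the k windows of most extreme GC
content — and the N50 of the remaining pieces is reported.  Sweeping k
yields a contiguity-decay curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GCProfile, GenomeSequence, window_gc_profile

__all__ = [
    "BreakReport",
    "n50",
    "merge_intervals",
    "break_by_intervals",
    "extreme_gc_windows",
    "gc_break_curve",
]


@dataclass(frozen=True)
class BreakReport:
    genome_length: int
    removed_intervals: list[tuple[int, int]]  # merged, sorted, disjoint
    piece_lengths: list[int]

    @property
    def n_pieces(self) -> int:
        return len(self.piece_lengths)

    @property
    def removed_bases(self) -> int:
        return sum(e - s for s, e in self.removed_intervals)

    @property
    def n50(self) -> int:
        return n50(self.piece_lengths) if self.piece_lengths else 0


def n50(lengths) -> int:
    """Largest L such that pieces of length >= L hold at least half the bases."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("all lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and disjoint."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def break_by_intervals(genome_length: int, intervals) -> BreakReport:
    """Remove intervals from [0, genome_length) and report the pieces.

    Overlapping intervals are merged first; zero-length gaps are
    dropped.  Base conservation holds exactly:
    sum(pieces) + removed_bases == genome_length.
    """
    merged = merge_intervals(intervals)
    if merged and (merged[0][0] < 0 or merged[-1][1] > genome_length):
        raise ValueError("interval out of genome bounds")
    pieces = []
    prev = 0
    for s, e in merged:
        if s > prev:
            pieces.append(s - prev)
        prev = e
    if genome_length > prev:
        pieces.append(genome_length - prev)
    return BreakReport(
        genome_length=genome_length, removed_intervals=merged, piece_lengths=pieces
    )


def extreme_gc_windows(
    profile: GCProfile, k: int, direction: str = "highest"
) -> list[tuple[int, int]]:
    """The k windows of most extreme GC, as (start, end) intervals.

    ``direction`` is "highest" or "lowest".  Ties at rank k break by
    leftmost start coordinate, making the selection deterministic.
    """
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    n = len(profile.gc)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available windows")
    if k == 0:
        return []
    key = -profile.gc if direction == "highest" else profile.gc
    order = np.lexsort((profile.starts, key))  # extreme first, then leftmost
    sel = np.sort(profile.starts[order[:k]])
    w = profile.grid.window_size
    return [(int(s), int(s + w)) for s in sel]


def gc_break_curve(
    genome: GenomeSequence,
    window_size: int,
    k_grid=range(25, 501, 25),
    direction: str = "highest",
    repeats=None,
    merge: bool = True,
) -> list[dict]:
    """N50 decay as increasingly many extreme-GC windows are removed.

    For each k in ``k_grid`` the top-k windows (by GC, in the stated
    direction) are removed — after first removing ``repeats`` intervals
    when given, to measure the GC effect on top of the repeat effect —
    and the N50 of the remaining pieces recorded.  With ``merge``
    False, overlapping selected windows are still unioned for breaking
    (they must be, to define pieces) but ``removed_bases`` counts each
    window separately.
    """
    profile = window_gc_profile(genome, window_size)
    rows = []
    base = list(repeats) if repeats else []
    for k in k_grid:
        windows = extreme_gc_windows(profile, k, direction)
        report = break_by_intervals(genome.length, base + windows)
        removed = report.removed_bases
        if not merge:
            removed = sum(e - s for s, e in base + windows)
        rows.append(
            {
                "k": int(k),
                "n50": report.n50,
                "n_pieces": report.n_pieces,
                "removed_bases": int(removed),
            }
        )
    return rows
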