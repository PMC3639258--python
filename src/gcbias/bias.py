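"""Estimation of the degree of GC bias from read coverage.

The statistic: scan each reference sequence with a sliding window of
size equal to the mean fragment length (step = half the window); in
each window take the GC fraction and the mean read depth; normalize
depths by the mean of the per-window means; discard windows whose
normalized coverage exceeds 2 (likely collapsed repeats); fit the
remaining (gc, normalized coverage) points by ordinary least squares.
The fitted slope — in normalized-coverage units per unit GC fraction —
is the degree of GC bias.  The same machinery runs reference-free by
substituting assembled contigs for the reference; contigs shorter than
the window are skipped and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from .coverage import CoverageTrack
from .genome import GenomeSequence, window_gc_profile

__all__ = [
    "WindowObservation",
    "BiasEstimate",
    "estimate_fragment_length",
    "collect_observations",
    "filter_repeat_like",
    "fit_slope",
    "estimate_bias",
]


@dataclass(frozen=True)
class WindowObservation:
    """One scatter point: a window's GC fraction and normalized coverage."""

    seq_name: str
    start: int
    end: int
    gc: float
    mean_cov: float
    norm_cov: float


@dataclass(frozen=True)
class BiasEstimate:
    slope: float
    intercept: float
    r_squared: float
    window_size: int
    n_windows_total: int
    n_windows_filtered: int  # removed as likely repeats (norm_cov > 2)
    n_windows_skipped: int  # ambiguous windows / short contigs

    @property
    def n_windows_used(self) -> int:
        return self.n_windows_total - self.n_windows_filtered - self.n_windows_skipped

    @property
    def slope_per_10pct_gc(self) -> float:
        return self.slope / 10.0


def estimate_fragment_length(
    path: str | Path, fallback: int | None = None
) -> int:
    """Mean absolute template length over properly paired alignments.

    Each pair is counted once (the mate with positive template length).
    Falls back to ``fallback`` (e.g. 200 bp for single-end data) when
    the file has no proper pairs.
    """
    total = 0
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_proper_pair and aln.template_length > 0:
                total += aln.template_length
                n += 1
    if n == 0:
        if fallback is not None:
            return int(fallback)
        raise ValueError(
            f"{path}: no properly paired alignments and no fallback window given"
        )
    return int(round(total / n))


def collect_observations(
    genome: GenomeSequence,
    track: CoverageTrack,
    window_size: int,
    step: int | None = None,
) -> list[WindowObservation]:
    """Windowed (GC, coverage) observations for one sequence.

    ``norm_cov`` is normalized by the mean of the per-window mean
    depths of this call; when pooling several sequences use
    :func:`estimate_bias`, which normalizes globally.
    """
    obs = _raw_observations(genome, track, window_size, step)
    return _normalize(obs)


def _raw_observations(
    genome: GenomeSequence,
    track: CoverageTrack,
    window_size: int,
    step: int | None = None,
) -> list[WindowObservation]:
    if track.length != genome.length:
        raise ValueError(
            f"coverage track length {track.length} != genome length {genome.length}"
        )
    profile = window_gc_profile(genome, window_size, step)
    cov_cum = np.concatenate([[0], np.cumsum(track.depth)])
    starts = profile.starts
    ends = profile.ends
    mean_cov = (cov_cum[ends] - cov_cum[starts]) / window_size
    return [
        WindowObservation(
            seq_name=genome.name,
            start=int(s),
            end=int(e),
            gc=float(g),
            mean_cov=float(c),
            norm_cov=np.nan,
        )
        for s, e, g, c in zip(starts, ends, profile.gc, mean_cov)
    ]


def _normalize(obs: list[WindowObservation]) -> list[WindowObservation]:
    if not obs:
        return []
    mean_of_means = float(np.mean([o.mean_cov for o in obs]))
    if mean_of_means == 0:
        raise ValueError("all windows have zero coverage; cannot normalize")
    return [
        WindowObservation(
            o.seq_name, o.start, o.end, o.gc, o.mean_cov, o.mean_cov / mean_of_means
        )
        for o in obs
    ]


def filter_repeat_like(
    observations: list[WindowObservation],
) -> tuple[list[WindowObservation], list[WindowObservation]]:
    """Split observations into (kept, removed) by the repeat rule.

    Removed are exactly the windows whose normalized coverage is more
    than twice the mean; a window at exactly 2.0 is kept.
    """
    removed = [o for o in observations if o.norm_cov > 2.0]
    kept = [o for o in observations if not o.norm_cov > 2.0]
    if observations and not kept:
        raise ValueError("repeat filter removed every window; fit degenerate")
    return kept, removed


def fit_slope(
    observations: list[WindowObservation],
    window_size: int = 0,
    n_filtered: int = 0,
    n_skipped: int = 0,
) -> BiasEstimate:
    """Ordinary least squares of normalized coverage on GC fraction."""
    if len(observations) < 3:
        raise ValueError("need at least 3 observations to fit")
    gc = np.array([o.gc for o in observations])
    cov = np.array([o.norm_cov for o in observations])
    if len(np.unique(gc)) < 2:
        raise ValueError("degenerate GC spread; slope undefined")
    res = stats.linregress(gc, cov)
    return BiasEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        window_size=window_size,
        n_windows_total=len(observations) + n_filtered + n_skipped,
        n_windows_filtered=n_filtered,
        n_windows_skipped=n_skipped,
    )


def estimate_bias(
    genomes: GenomeSequence | list[GenomeSequence],
    tracks: CoverageTrack | dict[str, CoverageTrack],
    window_size: int,
    step: int | None = None,
) -> tuple[BiasEstimate, list[WindowObservation]]:
    """End-to-end degree-of-GC-bias estimate over one or more sequences.

    ``genomes`` may be a reference chromosome or assembled contigs
    (reference-free mode); ``tracks`` maps sequence name to its
    coverage.  Sequences shorter than the window are skipped and
    counted.  Normalization uses the mean over all windows of all
    sequences, so the slope is comparable across runs.

    Returns the estimate together with the (normalized, unfiltered)
    window observations for scatter output.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.seq_name: tracks}
    raw: list[WindowObservation] = []
    n_skipped = 0
    for genome in genomes:
        if genome.length < window_size:
            n_skipped += 1
            continue
        if genome.name not in tracks:
            raise ValueError(f"no coverage track for sequence {genome.name!r}")
        seq_obs = _raw_observations(genome, tracks[genome.name], window_size, step)
        n_skipped += window_gc_profile(genome, window_size, step).n_skipped
        raw.extend(seq_obs)
    if not raw:
        raise ValueError("no usable windows (all sequences shorter than the window?)")
    obs = _normalize(raw)
    kept, removed = filter_repeat_like(obs)
    estimate = fit_slope(
        kept, window_size=window_size, n_filtered=len(removed), n_skipped=n_skipped
    )
    return estimate, obs
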