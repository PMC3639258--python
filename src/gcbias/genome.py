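"""Genome ingestion and windowed GC-content statistics.

GC content of a region is the fraction of G and C among its unambiguous
(A/C/G/T) bases.  All coordinates are 0-based half-open.  Sliding-window
profiles use a step of half the window by default, dropping any trailing
partial window, and skip windows in which more than half of the bases are
ambiguous (IUPAC codes other than A/C/G/T).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

_IUPAC = set("ACGTURYSWKMBDHVN")

__all__ = [
    "GenomeSequence",
    "WindowGrid",
    "GCProfile",
    "read_fasta",
    "reverse_complement",
    "gc_fraction",
    "window_gc_profile",
    "gc_summary",
    "gc_histogram",
]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence, upper-cased on construction."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        object.__setattr__(self, "bases", self.bases.upper())

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def byte_view(self) -> np.ndarray:
        """The sequence as a uint8 array of ASCII codes (no copy of slices)."""
        return np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window start coordinates over one sequence."""

    window_size: int
    step: int
    starts: np.ndarray  # 0-based, strictly increasing

    @classmethod
    def for_length(cls, length: int, window_size: int, step: int | None = None) -> "WindowGrid":
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        if step is None:
            step = max(1, window_size // 2)
        if step < 1:
            raise ValueError("step must be >= 1")
        if window_size > length:
            raise ValueError(
                f"window_size {window_size} exceeds sequence length {length}"
            )
        starts = np.arange(0, length - window_size + 1, step, dtype=np.int64)
        return cls(window_size=window_size, step=step, starts=starts)

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class GCProfile:
    """Windowed GC fractions for one sequence.

    ``gc`` holds one value per *retained* window, aligned with
    ``starts``; ``n_skipped`` counts windows dropped because more than
    half of their bases were ambiguous, so
    ``len(gc) + n_skipped == len(grid.starts)``.
    """

    seq_name: str
    grid: WindowGrid
    gc: np.ndarray
    starts: np.ndarray
    n_skipped: int = 0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.grid.window_size


def reverse_complement(bases: str) -> str:
    return bases.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def read_fasta(path: str | Path | io.TextIOBase) -> list[GenomeSequence]:
    """Read all records of a FASTA file, preserving order.

    Raises ``ValueError`` on an empty file, an empty record name, or
    characters outside the IUPAC nucleotide alphabet (the offending
    record is named in the message).
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path!r}")
    out = []
    for rec in records:
        bases = str(rec.seq).upper()
        bad = set(bases) - _IUPAC
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        out.append(GenomeSequence(name=rec.id, bases=bases))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, s.length, width):
                fh.write(s.bases[i : i + width] + "\n")


def gc_fraction(bases: str) -> float:
    """GC fraction of a sequence; ambiguous bases are excluded entirely.

    Raises ``ValueError`` when no unambiguous base is present.
    """
    b = bases.upper()
    gc = b.count("G") + b.count("C")
    at = b.count("A") + b.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous (A/C/G/T) base")
    return gc / (gc + at)


def _indicator_cumsums(seq: GenomeSequence) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative counts of GC bases and of unambiguous bases.

    Returns arrays of length ``len(seq)+1`` so that the count over
    ``[i, j)`` is ``cum[j] - cum[i]``.
    """
    b = seq.byte_view()
    is_gc = (b == ord("G")) | (b == ord("C"))
    is_acgt = is_gc | (b == ord("A")) | (b == ord("T"))
    gc_cum = np.zeros(len(b) + 1, dtype=np.int64)
    acgt_cum = np.zeros(len(b) + 1, dtype=np.int64)
    np.cumsum(is_gc, out=gc_cum[1:])
    np.cumsum(is_acgt, out=acgt_cum[1:])
    return gc_cum, acgt_cum


def window_gc_profile(
    seq: GenomeSequence, window_size: int, step: int | None = None
) -> GCProfile:
    """GC fraction in every sliding window of ``seq``.

    Windows whose unambiguous-base count falls at or below half the
    window size are skipped and tallied in ``n_skipped``.
    """
    try:
        grid = WindowGrid.for_length(seq.length, window_size, step)
    except ValueError as exc:
        raise ValueError(f"sequence {seq.name!r}: {exc}") from exc
    gc_cum, acgt_cum = _indicator_cumsums(seq)
    starts = grid.starts
    ends = starts + window_size
    gc_counts = gc_cum[ends] - gc_cum[starts]
    acgt_counts = acgt_cum[ends] - acgt_cum[starts]
    keep = acgt_counts > window_size // 2
    gc = gc_counts[keep] / acgt_counts[keep]
    return GCProfile(
        seq_name=seq.name,
        grid=grid,
        gc=gc,
        starts=starts[keep],
        n_skipped=int((~keep).sum()),
    )


def gc_summary(seq: GenomeSequence, window_size: int = 180) -> dict:
    """Whole-sequence mean GC and windowed GC standard deviation.

    The standard deviation is taken over sliding windows of
    ``window_size`` with step ``window_size // 2``.  Fractions and
    percents (one decimal, for report parity) are both returned.
    """
    profile = window_gc_profile(seq, window_size)
    mean = gc_fraction(seq.bases)
    sd = float(np.std(profile.gc))
    return {
        "mean_gc": mean,
        "sd_gc": sd,
        "mean_gc_percent": round(mean * 100, 1),
        "sd_gc_percent": round(sd * 100, 1),
        "n_windows": len(profile.gc),
        "n_skipped": profile.n_skipped,
        "window_size": window_size,
    }


def gc_histogram(profile: GCProfile, bin_width: float = 0.01) -> list[tuple[float, int]]:
    """Histogram of windowed GC fractions over bins covering [0, 1].

    Returns ``(bin_left_edge, count)`` pairs; counts sum to the number
    of retained windows.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(profile.gc) == 0:
        raise ValueError("profile has no retained windows")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(profile.gc, bins=edges)
    return [(float(edges[i]), int(counts[i])) for i in range(n_bins)]
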