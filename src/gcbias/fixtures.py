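"""Synthetic genomes and FASTQ files with controllable GC composition.

Real bacterial and plant chromosomes enter the bias analyses only
through their windowed GC-content distribution, so block-i.i.d.
synthetic genomes — contiguous blocks whose bases are drawn i.i.d.
with a per-block P(G or C) — are sufficient test substrates.  Presets
emulate the qualitative shapes seen in real genomes: a left-skewed
distribution (an E. coli-like low-GC tail), a right-skewed wide one
(O. sativa-like), and a symmetric control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GenomeSequence

__all__ = ["CompositionSpec", "synth_genome", "synth_fastq", "skewed_genome", "blocky_genome"]

PRESETS = {
    # (block_length, sampler description) — see skewed_genome
    "ecoli-like": dict(block_length=2000, base_gc=0.52, tail_scale=0.05, tail_sign=-1),
    "osativa-like": dict(block_length=2000, base_gc=0.38, tail_scale=0.09, tail_sign=+1),
    "symmetric": dict(block_length=2000, base_gc=0.50, normal_sd=0.05),
}

_BASES_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASES_AT = np.frombuffer(b"AT", dtype=np.uint8)


@dataclass(frozen=True)
class CompositionSpec:
    """Block layout of a synthetic genome: (length, target GC) per block."""

    blocks: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        for length, gc in self.blocks:
            if length <= 0:
                raise ValueError("block lengths must be positive")
            if not 0.0 <= gc <= 1.0:
                raise ValueError("block GC targets must lie in [0, 1]")

    @property
    def total_length(self) -> int:
        return sum(l for l, _ in self.blocks)


def synth_genome(
    spec: CompositionSpec, seed: int = 0, name: str = "synthetic"
) -> GenomeSequence:
    """Draw a genome from a composition spec; deterministic under seed.

    Within each block, bases are i.i.d. with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1-gc)/2.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for length, gc in spec.blocks:
        is_gc = rng.random(length) < gc
        which = rng.integers(0, 2, length)
        arr = np.where(is_gc, _BASES_GC[which], _BASES_AT[which])
        parts.append(arr.astype(np.uint8))
    bases = np.concatenate(parts).tobytes().decode("ascii")
    return GenomeSequence(name=name, bases=bases)


def blocky_genome(
    total_length: int,
    block_length: int,
    gc_sampler,
    seed: int = 0,
    name: str = "synthetic",
) -> GenomeSequence:
    """Genome of fixed-length blocks with GC targets from ``gc_sampler(rng, n)``."""
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(total_length / block_length))
    targets = np.clip(gc_sampler(rng, n_blocks), 0.0, 1.0)
    blocks = []
    remaining = total_length
    for t in targets:
        l = min(block_length, remaining)
        blocks.append((l, float(t)))
        remaining -= l
        if remaining == 0:
            break
    spec = CompositionSpec(blocks=tuple(blocks))
    # derive the base-level stream from the same seed, one spawn later
    return synth_genome(spec, seed=np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31), name=name)


def skewed_genome(
    preset: str, total_length: int = 1_000_000, seed: int = 0
) -> GenomeSequence:
    """A preset synthetic genome with a skewed windowed-GC distribution.

    Presets:

    - ``ecoli-like`` — left-skewed: block GC = 0.52 minus an
      Exponential(0.05) tail, clipped at 0.15, so regions of extremely
      low GC exist but high-GC outliers do not.
    - ``osativa-like`` — right-skewed and wider: 0.38 plus an
      Exponential(0.09) tail, clipped at 0.9.
    - ``symmetric`` — block GC ~ Normal(0.5, 0.05) clipped to
      [0.2, 0.8]; windowed GC sd about 6% at a 180-bp window.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]

    if "normal_sd" in p:
        def sampler(rng, n):
            return np.clip(rng.normal(p["base_gc"], p["normal_sd"], n), 0.2, 0.8)
    else:
        def sampler(rng, n):
            tail = rng.exponential(p["tail_scale"], n)
            lo, hi = (0.15, 0.8) if p["tail_sign"] < 0 else (0.1, 0.9)
            return np.clip(p["base_gc"] + p["tail_sign"] * tail, lo, hi)

    return blocky_genome(
        total_length, p["block_length"], sampler, seed=seed, name=f"{preset}-{seed}"
    )


def synth_fastq(
    n_reads: int,
    read_length: int,
    per_cycle_q,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Write a FASTQ with random bases and exactly the given quality ramp."""
    q = np.asarray(per_cycle_q, dtype=float)
    if len(q) != read_length:
        raise ValueError("per_cycle_q must have one value per cycle")
    if np.any((q < 0) | (q > 41)):
        raise ValueError("quality values must lie in [0, 41]")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    qual = "".join(chr(33 + int(round(v))) for v in q)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for i in range(n_reads):
            bases = alphabet[rng.integers(0, 4, read_length)].tobytes().decode("ascii")
            fh.write(f"@synth_{i}\n{bases}\n+\n{qual}\n")
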