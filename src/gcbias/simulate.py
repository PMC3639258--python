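"""Illumina-like paired-end read simulation under a linear GC-bias model.

A sequencing library is modelled as a stream of genomic fragments whose
insert lengths follow a rounded Normal distribution.  Each candidate
fragment F is retained by acceptance–rejection with probability

    P(F) = C * max(0, 1 + s * (GC(F) - GC_m))

where GC(F) is the fragment's GC fraction, GC_m is the mean GC fraction
over all possible fragments of the nominal insert length, s is the
degree of GC bias (slope), and C normalizes the maximal weight to 1 so
the expression is a valid probability.  C cancels out of every
coverage-normalized quantity downstream.  s > 0 over-covers GC-rich
regions, s < 0 under-covers them; weights that would go negative are
clamped to zero, so a strong bias can deplete extreme-GC regions
entirely.

Reads of a fixed length are cut from the two ends of each kept fragment
(FR orientation for paired-end, RF for mate-pair), position-dependent
substitution errors are drawn from a per-cycle error profile, and an
optional GC-independent background fluctuation field modulates the
acceptance probability tile by tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .genome import GenomeSequence, reverse_complement

__all__ = [
    "GCBiasModel",
    "InsertLengthModel",
    "ErrorProfile",
    "FluctuationModel",
    "FragmentRecord",
    "SimConfig",
    "compute_gc_mean",
    "acceptance_probability",
    "simulate_fragments",
    "fragment_to_reads",
    "apply_errors",
    "learn_error_profile",
    "simulate_library",
    "simulate_mp_library",
    "read_truth",
]

_BATCH = 16384
_MAX_EMPTY_BATCHES = 1000


# ---------------------------------------------------------------------------
# model components


def _fragment_gc_array(genome: GenomeSequence, fragment_length: int) -> np.ndarray:
    """GC fraction of the fragment starting at every base position.

    Only fragments fully inside the sequence and free of ambiguous bases
    are represented; positions violating either condition yield NaN.
    """
    if fragment_length > genome.length:
        raise ValueError(
            f"fragment length {fragment_length} exceeds genome "
            f"{genome.name!r} length {genome.length}"
        )
    b = genome.byte_view()
    is_gc = ((b == ord("G")) | (b == ord("C"))).astype(np.int64)
    is_acgt = is_gc | ((b == ord("A")) | (b == ord("T"))).astype(np.int64)
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    acgt_cum = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(0, genome.length - fragment_length + 1)
    ends = starts + fragment_length
    gc = (gc_cum[ends] - gc_cum[starts]).astype(float)
    clean = (acgt_cum[ends] - acgt_cum[starts]) == fragment_length
    out = np.full(len(starts), np.nan)
    out[clean] = gc[clean] / fragment_length
    return out


def compute_gc_mean(genome: GenomeSequence, fragment_length: int) -> float:
    """Mean GC fraction over all possible fragments of ``fragment_length``.

    Fragments are anchored at every base position that leaves the
    fragment fully inside the sequence; fragments containing ambiguous
    bases are excluded from the mean.
    """
    gc = _fragment_gc_array(genome, fragment_length)
    if np.all(np.isnan(gc)):
        raise ValueError(f"genome {genome.name!r} has no unambiguous fragment")
    return float(np.nanmean(gc))


@dataclass(frozen=True)
class GCBiasModel:
    """Linear GC-bias acceptance model: C * max(0, 1 + s*(gc - gc_mean))."""

    slope_s: float
    gc_mean: float
    normalizer_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_mean <= 1.0:
            raise ValueError("gc_mean must lie in [0, 1]")
        if self.normalizer_c <= 0:
            raise ValueError("normalizer_c must be positive")

    @classmethod
    def from_genome(
        cls, genome: GenomeSequence, slope: float, fragment_length: int
    ) -> "GCBiasModel":
        """Fit GC_m to the genome and choose C = 1 / max weight.

        The maximum is taken over the GC fractions of the genome's own
        fragments, so acceptance probabilities lie in (0, 1].
        """
        gc = _fragment_gc_array(genome, fragment_length)
        gc = gc[~np.isnan(gc)]
        if len(gc) == 0:
            raise ValueError(f"genome {genome.name!r} has no unambiguous fragment")
        gc_mean = float(gc.mean())
        weights = np.maximum(0.0, 1.0 + slope * (gc - gc_mean))
        w_max = float(weights.max())
        if w_max == 0.0:
            raise ValueError("acceptance weight is zero everywhere; model degenerate")
        return cls(slope_s=slope, gc_mean=gc_mean, normalizer_c=1.0 / w_max)

    def weight(self, fragment_gc):
        return np.maximum(0.0, 1.0 + self.slope_s * (np.asarray(fragment_gc) - self.gc_mean))

    def acceptance_probability(self, fragment_gc):
        return np.minimum(1.0, self.normalizer_c * self.weight(fragment_gc))


def acceptance_probability(fragment_gc, model: GCBiasModel):
    """C * max(0, 1 + s*(gc - gc_mean)), capped at 1."""
    return model.acceptance_probability(fragment_gc)


@dataclass(frozen=True)
class InsertLengthModel:
    """Rounded-Normal insert length distribution with a hard floor."""

    mean: float = 180.0
    sd: float = 10.0
    min_len: int = 30

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.min_len < 1:
            raise ValueError("min_len must be positive")


@dataclass(frozen=True)
class FluctuationModel:
    """GC-independent background coverage fluctuation.

    The genome is tiled at ``tile_size``; each tile receives a
    multiplier drawn once from Normal(1, sd_depth / target_coverage),
    floored at zero, which scales the fragment acceptance probability.
    ``sd_depth`` is in depth units (the paper-style settings are 10 or
    20 at 100X).
    """

    sd_depth: float
    tile_size: int = 180

    def __post_init__(self) -> None:
        if self.sd_depth < 0:
            raise ValueError("sd_depth must be non-negative")
        if self.tile_size < 1:
            raise ValueError("tile_size must be positive")


@dataclass(frozen=True)
class FragmentRecord:
    seq_name: str
    start: int
    end: int
    gc: float
    kept: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ErrorProfile:
    """Per-cycle substitution error rates and the matching quality string."""

    per_cycle_rate: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.per_cycle_rate, dtype=float)
        if rates.ndim != 1 or len(rates) == 0:
            raise ValueError("per_cycle_rate must be a non-empty 1-D array")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("error rates must lie in [0, 1]")
        object.__setattr__(self, "per_cycle_rate", rates)

    @property
    def read_length(self) -> int:
        return len(self.per_cycle_rate)

    @classmethod
    def constant(cls, read_length: int, q: float) -> "ErrorProfile":
        return cls(np.full(read_length, 10.0 ** (-q / 10.0)))

    def quality_string(self, length: int | None = None) -> str:
        """Sanger Phred+33 qualities encoding the per-cycle rates, capped at Q41."""
        rates = self.per_cycle_rate[: length or self.read_length]
        with np.errstate(divide="ignore"):
            q = np.where(rates > 0, -10.0 * np.log10(np.maximum(rates, 1e-12)), 41.0)
        q = np.clip(np.rint(q), 0, 41).astype(int)
        return "".join(chr(33 + v) for v in q)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cycle\terror_rate\n")
            for i, r in enumerate(self.per_cycle_rate, start=1):
                fh.write(f"{i}\t{r:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ErrorProfile":
        rates = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(("cycle", "#")) or not line.strip():
                    continue
                rates.append(float(line.split("\t")[1]))
        return cls(np.array(rates))


def learn_error_profile(fastq_path: str | Path) -> ErrorProfile:
    """Estimate per-cycle error rates from FASTQ quality strings.

    rate[i] is the mean of 10^(-Q_i/10) over all reads long enough to
    have cycle i; a warning is issued when read lengths vary.
    """
    sums: np.ndarray | None = None
    counts: np.ndarray | None = None
    lengths = set()
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=float)
        lengths.add(len(quals))
        if sums is None or len(quals) > len(sums):
            new_sums = np.zeros(len(quals))
            new_counts = np.zeros(len(quals))
            if sums is not None:
                new_sums[: len(sums)] = sums
                new_counts[: len(counts)] = counts
            sums, counts = new_sums, new_counts
        sums[: len(quals)] += 10.0 ** (-quals / 10.0)
        counts[: len(quals)] += 1
    if sums is None:
        raise ValueError(f"no FASTQ records found in {fastq_path!r}")
    if len(lengths) > 1:
        warnings.warn(
            f"variable read lengths {sorted(lengths)} in {fastq_path!r}; "
            "each cycle averaged over the reads that reach it",
            stacklevel=2,
        )
    return ErrorProfile(sums / counts)


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated library."""

    slope: float = 0.0
    target_coverage: float = 50.0
    read_length: int = 100
    insert: InsertLengthModel = field(default_factory=InsertLengthModel)
    errors: ErrorProfile | None = None
    fluctuation: FluctuationModel | None = None
    seed: int = 0
    library_type: str = "PE"  # PE = FR orientation, MP = RF
    circular: bool = False

    def __post_init__(self) -> None:
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.library_type not in ("PE", "MP"):
            raise ValueError("library_type must be 'PE' or 'MP'")


# ---------------------------------------------------------------------------
# fragment generation


def simulate_fragments(
    genome: GenomeSequence,
    config: SimConfig,
    model: GCBiasModel | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[FragmentRecord]:
    """Stream accepted fragments until the fold-coverage target is met.

    Starts are uniform over the sequence, lengths rounded Normal draws;
    proposals that run off the end (linear mode), fall below the length
    floor, or contain ambiguous bases are resampled.  Each survivor is
    kept with probability ``acceptance_probability(gc)``, times the
    local background-fluctuation multiplier if one is configured.
    Emission stops once total read bases (two reads per fragment, each
    truncated to the fragment when shorter than the read length) reach
    ``target_coverage * genome.length``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nominal = int(round(config.insert.mean))
    if model is None:
        model = GCBiasModel.from_genome(genome, config.slope, nominal)

    L = genome.length
    b = genome.byte_view()
    is_gc = ((b == ord("G")) | (b == ord("C"))).astype(np.int64)
    is_acgt = is_gc | ((b == ord("A")) | (b == ord("T"))).astype(np.int64)
    if config.circular:
        # doubled-genome cumsums let wrapped fragments be scored directly
        is_gc = np.concatenate([is_gc, is_gc])
        is_acgt = np.concatenate([is_acgt, is_acgt])
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    acgt_cum = np.concatenate([[0], np.cumsum(is_acgt)])

    mult = None
    if config.fluctuation is not None:
        f = config.fluctuation
        n_tiles = int(np.ceil(L / f.tile_size))
        mult = np.maximum(
            0.0, rng.normal(1.0, f.sd_depth / config.target_coverage, n_tiles)
        )

    target_bases = config.target_coverage * L
    emitted = 0.0
    empty_batches = 0
    while emitted < target_bases:
        starts = rng.integers(0, L, _BATCH)
        lens = np.rint(rng.normal(config.insert.mean, config.insert.sd, _BATCH)).astype(
            np.int64
        )
        u = rng.random(_BATCH)
        ok = lens >= config.insert.min_len
        if not config.circular:
            ok &= starts + lens <= L
        ends = starts + lens
        ends_c = np.minimum(ends, len(gc_cum) - 1)  # safe index for invalid rows
        clean = (acgt_cum[ends_c] - acgt_cum[starts]) == lens
        ok &= clean
        gc = np.where(
            ok, (gc_cum[ends_c] - gc_cum[starts]) / np.maximum(lens, 1), 0.0
        )
        p = model.acceptance_probability(gc)
        if mult is not None:
            p = np.minimum(1.0, p * mult[starts // config.fluctuation.tile_size])
        accept = ok & (u < p)
        idx = np.flatnonzero(accept)
        if len(idx) == 0:
            empty_batches += 1
            if empty_batches >= _MAX_EMPTY_BATCHES:
                raise RuntimeError(
                    "no fragment accepted in "
                    f"{_MAX_EMPTY_BATCHES} batches; acceptance weight may be "
                    "(near-)zero everywhere"
                )
            continue
        empty_batches = 0
        for i in idx:
            frag = FragmentRecord(
                seq_name=genome.name,
                start=int(starts[i]),
                end=int(ends[i]),
                gc=float(gc[i]),
                kept=True,
            )
            yield frag
            emitted += 2 * min(config.read_length, frag.length)
            if emitted >= target_bases:
                return


def _fragment_bases(genome: GenomeSequence, frag: FragmentRecord) -> str:
    if frag.end <= genome.length:
        return genome.bases[frag.start : frag.end]
    # circular wrap-around
    return genome.bases[frag.start :] + genome.bases[: frag.end - genome.length]


def fragment_to_reads(
    frag: FragmentRecord, genome: GenomeSequence, config: SimConfig
) -> tuple[str, str]:
    """Cut the two reads from a fragment's ends.

    PE libraries are FR: read 1 is the fragment's first ``read_length``
    bases on the forward strand, read 2 the reverse complement of its
    last ``read_length`` bases.  MP libraries are RF (both reads
    flipped).  Fragments shorter than the read length yield truncated
    reads covering the whole fragment.
    """
    bases = _fragment_bases(genome, frag)
    rl = min(config.read_length, len(bases))
    r1 = bases[:rl]
    r2 = reverse_complement(bases[-rl:])
    if config.library_type == "MP":
        r1, r2 = reverse_complement(r1), reverse_complement(r2)
    return r1, r2


_BASE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_INDEX[_c] = _i


def apply_errors(read: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Substitute bases cycle by cycle with the profile's error rates.

    An erroneous base is replaced by one of the three other nucleotides
    uniformly; positions holding ambiguous codes are left untouched.
    """
    n = len(read)
    if profile.read_length < n:
        raise ValueError("error profile shorter than read")
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(n) < profile.per_cycle_rate[:n]
    hit &= _BASE_INDEX[arr] >= 0
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, n_hit)
        arr[hit] = _BASE_ORDER[(_BASE_INDEX[arr[hit]] + shift) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# library-level drivers


def _perfect_quality(length: int) -> str:
    return chr(33 + 41) * length


def read_truth(path: str | Path) -> list[FragmentRecord]:
    """Load a truth-placement track written by :func:`simulate_library`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seq, start, end, gc, _pair = line.rstrip("\n").split("\t")
            out.append(
                FragmentRecord(seq_name=seq, start=int(start), end=int(end), gc=float(gc))
            )
    return out


def simulate_library(
    genomes: GenomeSequence | list[GenomeSequence],
    config: SimConfig,
    out_prefix: str | Path | None = None,
) -> dict:
    """Simulate a full library; write paired FASTQ and a truth track.

    Multi-record genomes are simulated per record, each to the target
    fold coverage.  With ``out_prefix`` None nothing is written and the
    read pairs are returned in memory (intended for small inputs).
    Byte-identical outputs are guaranteed for identical config + seed:
    all randomness flows from ``config.seed`` through per-purpose
    spawned streams.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(2 * len(genomes))

    pairs_out = []
    n_pairs = 0
    read_bases = 0
    fh1 = fh2 = fht = None
    if out_prefix is not None:
        out_prefix = str(out_prefix)
        fh1 = open(out_prefix + "_1.fastq", "w")
        fh2 = open(out_prefix + "_2.fastq", "w")
        fht = open(out_prefix + ".truth.tsv", "w")
        fht.write(f"# seed={config.seed} slope={config.slope} "
                  f"coverage={config.target_coverage} library={config.library_type}\n")
        fht.write("#seq\tfrag_start\tfrag_end\tgc\tpair_id\n")
    try:
        for gi, genome in enumerate(genomes):
            rng_frag = np.random.default_rng(streams[2 * gi])
            rng_err = np.random.default_rng(streams[2 * gi + 1])
            model = GCBiasModel.from_genome(
                genome, config.slope, int(round(config.insert.mean))
            )
            for frag in simulate_fragments(genome, config, model=model, rng=rng_frag):
                r1, r2 = fragment_to_reads(frag, genome, config)
                if config.errors is not None:
                    r1 = apply_errors(r1, config.errors, rng_err)
                    r2 = apply_errors(r2, config.errors, rng_err)
                    q1 = config.errors.quality_string(len(r1))
                    q2 = config.errors.quality_string(len(r2))
                else:
                    q1 = _perfect_quality(len(r1))
                    q2 = _perfect_quality(len(r2))
                name = f"sim|{frag.seq_name}|{frag.start}|{frag.end}|{n_pairs}"
                if fh1 is not None:
                    fh1.write(f"@{name}/1\n{r1}\n+\n{q1}\n")
                    fh2.write(f"@{name}/2\n{r2}\n+\n{q2}\n")
                    fht.write(
                        f"{frag.seq_name}\t{frag.start}\t{frag.end}"
                        f"\t{frag.gc:.6f}\t{n_pairs}\n"
                    )
                else:
                    pairs_out.append((name, r1, q1, r2, q2, frag))
                n_pairs += 1
                read_bases += len(r1) + len(r2)
    finally:
        for fh in (fh1, fh2, fht):
            if fh is not None:
                fh.close()
    summary = {
        "n_pairs": n_pairs,
        "read_bases": read_bases,
        "seed": config.seed,
        "slope": config.slope,
        "library_type": config.library_type,
    }
    if out_prefix is not None:
        summary["fastq_1"] = out_prefix + "_1.fastq"
        summary["fastq_2"] = out_prefix + "_2.fastq"
        summary["truth"] = out_prefix + ".truth.tsv"
    else:
        summary["pairs"] = pairs_out
    return summary


def simulate_mp_library(
    genomes: GenomeSequence | list[GenomeSequence],
    coverage: float = 1.0,
    insert_mean: float = 3500.0,
    insert_sd: float = 500.0,
    read_length: int = 100,
    seed: int = 0,
    out_prefix: str | Path | None = None,
) -> dict:
    """Mate-pair library: long inserts, RF orientation, no GC bias."""
    config = SimConfig(
        slope=0.0,
        target_coverage=coverage,
        read_length=read_length,
        insert=InsertLengthModel(mean=insert_mean, sd=insert_sd),
        seed=seed,
        library_type="MP",
    )
    return simulate_library(genomes, config, out_prefix=out_prefix)
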