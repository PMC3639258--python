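"""Read simulation under the linear GC-bias acceptance model."""

import numpy as np
import pytest

from gcbias import (
    ErrorProfile,
    GCBiasModel,
    GenomeSequence,
    InsertLengthModel,
    SimConfig,
    acceptance_probability,
    apply_errors,
    compute_gc_mean,
    fragment_to_reads,
    learn_error_profile,
    read_truth,
    reverse_complement,
    simulate_fragments,
    simulate_library,
    simulate_mp_library,
    synth_fastq,
)
from gcbias.simulate import FragmentRecord


class TestGCMean:
    def test_homopolymer(self):
        assert compute_gc_mean(GenomeSequence("s", "A" * 500), 100) == 0.0

    def test_alternating(self):
        assert compute_gc_mean(GenomeSequence("s", "ACGT" * 100), 4) == pytest.approx(0.5)

    def test_matches_enumeration(self, toy_genome):
        L = 180
        brute = np.mean(
            [
                (lambda f: (f.count("G") + f.count("C")) / L)(
                    toy_genome.bases[i : i + L]
                )
                for i in range(toy_genome.length - L + 1)
            ]
        )
        assert compute_gc_mean(toy_genome, L) == pytest.approx(brute)

    def test_too_long_fragment_rejected(self):
        with pytest.raises(ValueError):
            compute_gc_mean(GenomeSequence("s", "ACGT"), 10)


class TestAcceptanceProbability:
    def test_at_mean_gc_returns_normalizer(self):
        m = GCBiasModel(slope_s=5.0, gc_mean=0.5, normalizer_c=0.4)
        assert acceptance_probability(0.5, m) == pytest.approx(0.4)

    def test_zero_slope_is_flat(self):
        m = GCBiasModel(slope_s=0.0, gc_mean=0.5, normalizer_c=0.7)
        gc = np.linspace(0, 1, 11)
        assert np.allclose(acceptance_probability(gc, m), 0.7)

    def test_negative_weight_clamped_to_zero(self):
        m = GCBiasModel(slope_s=-3.77, gc_mean=0.5, normalizer_c=1.0)
        assert acceptance_probability(0.8, m) == 0.0  # 1 - 3.77*0.3 < 0

    def test_capped_at_one(self):
        m = GCBiasModel(slope_s=9.0, gc_mean=0.2, normalizer_c=1.0)
        assert acceptance_probability(0.9, m) == 1.0

    def test_from_genome_max_weight_is_one(self, toy_genome):
        m = GCBiasModel.from_genome(toy_genome, 3.8, 180)
        from gcbias.simulate import _fragment_gc_array

        gc = _fragment_gc_array(toy_genome, 180)
        p = m.acceptance_probability(gc[~np.isnan(gc)])
        assert p.max() == pytest.approx(1.0)
        assert np.all(p >= 0)


class TestFragmentStream:
    def test_stopping_rule_bounds(self, flat_genome):
        cfg = SimConfig(slope=0.0, target_coverage=3.0, seed=5)
        frags = list(simulate_fragments(flat_genome, cfg))
        bases = sum(2 * min(cfg.read_length, f.length) for f in frags)
        target = cfg.target_coverage * flat_genome.length
        assert target <= bases < target + 2 * cfg.read_length

    def test_fragments_inside_sequence_with_correct_gc(self, toy_genome):
        cfg = SimConfig(slope=2.0, target_coverage=2.0, seed=1)
        for f in simulate_fragments(toy_genome, cfg):
            assert 0 <= f.start < f.end <= toy_genome.length
            piece = toy_genome.bases[f.start : f.end]
            assert f.gc == pytest.approx(
                (piece.count("G") + piece.count("C")) / len(piece)
            )

    def test_unbiased_coverage_is_uniform(self, flat_genome):
        # slope 0: normalized per-window depth should hug 1
        from gcbias import coverage_from_truth, collect_observations

        cfg = SimConfig(slope=0.0, target_coverage=20.0, seed=2)
        frags = list(simulate_fragments(flat_genome, cfg))
        track = coverage_from_truth(frags, cfg.read_length, flat_genome)
        obs = collect_observations(flat_genome, track, 1000, 1000)
        norm = np.array([o.norm_cov for o in obs])
        # depth per window-base ~ Poisson(20); window mean has sd ~ sqrt(20*540)/1000... loose bound
        assert np.abs(norm - 1).max() < 0.5
        assert np.std(norm) < 0.1

    def test_degenerate_model_aborts(self):
        genome = GenomeSequence("flat", "ACGT" * 2500)
        # every fragment has gc ~ 0.5, so this hand-built model clamps the
        # acceptance weight to zero everywhere
        model = GCBiasModel(slope_s=-10.0, gc_mean=0.0, normalizer_c=1.0)
        cfg = SimConfig(slope=-10.0, target_coverage=1.0, seed=0)
        with pytest.raises(RuntimeError, match="no fragment accepted"):
            list(simulate_fragments(genome, cfg, model=model))

    def test_circular_mode_wraps_fragments(self):
        genome = GenomeSequence("circ", "ACGT" * 500)
        cfg = SimConfig(slope=0.0, target_coverage=5.0, seed=3, circular=True)
        frags = list(simulate_fragments(genome, cfg))
        assert any(f.end > genome.length for f in frags)
        for f in frags:
            assert f.start < genome.length


class TestReads:
    def test_pe_reads_overlap_in_fragment_middle(self):
        genome = GenomeSequence("g", "ACGTA" * 100)
        frag = FragmentRecord("g", 0, 180, 0.4)
        cfg = SimConfig(slope=0, target_coverage=1, read_length=100)
        r1, r2 = fragment_to_reads(frag, genome, cfg)
        assert r1 == genome.bases[:100]
        assert r2 == reverse_complement(genome.bases[80:180])

    def test_fragment_reconstruction_round_trip(self, toy_genome, rng):
        cfg = SimConfig(slope=0, target_coverage=1, read_length=100)
        for _ in range(20):
            start = int(rng.integers(0, toy_genome.length - 180))
            frag = FragmentRecord(toy_genome.name, start, start + 180, 0.5)
            r1, r2 = fragment_to_reads(frag, toy_genome, cfg)
            rebuilt = r1 + reverse_complement(r2)[100 - (180 - 100) :]
            assert rebuilt == toy_genome.bases[start : start + 180]

    def test_palindromic_fragment_gives_equal_reads(self):
        half = "ACGTTGCA" * 10
        bases = half + reverse_complement(half)
        genome = GenomeSequence("p", bases)
        frag = FragmentRecord("p", 0, len(bases), 0.5)
        cfg = SimConfig(slope=0, target_coverage=1, read_length=40)
        r1, r2 = fragment_to_reads(frag, genome, cfg)
        assert r1 == r2

    def test_short_fragment_truncates_reads(self):
        genome = GenomeSequence("g", "ACGT" * 50)
        frag = FragmentRecord("g", 0, 60, 0.5)
        cfg = SimConfig(slope=0, target_coverage=1, read_length=100)
        r1, r2 = fragment_to_reads(frag, genome, cfg)
        assert len(r1) == len(r2) == 60

    def test_mp_orientation_is_reverse_of_pe(self, toy_genome):
        frag = FragmentRecord(toy_genome.name, 100, 600, 0.5)
        pe = SimConfig(slope=0, target_coverage=1, read_length=50, library_type="PE")
        mp = SimConfig(slope=0, target_coverage=1, read_length=50, library_type="MP")
        pe1, pe2 = fragment_to_reads(frag, toy_genome, pe)
        mp1, mp2 = fragment_to_reads(frag, toy_genome, mp)
        assert mp1 == reverse_complement(pe1)
        assert mp2 == reverse_complement(pe2)


class TestErrors:
    def test_zero_rate_leaves_read_unchanged(self, rng):
        prof = ErrorProfile(np.zeros(50))
        assert apply_errors("ACGT" * 10, prof, rng) == "ACGT" * 10

    def test_rate_one_changes_every_base(self, rng):
        read = "ACGT" * 25
        prof = ErrorProfile(np.ones(100))
        mutated = apply_errors(read, prof, rng)
        assert all(a != b for a, b in zip(read, mutated))

    def test_error_count_matches_binomial(self, rng):
        read = "A" * 100
        prof = ErrorProfile(np.full(100, 0.01))
        mismatches = 0
        for _ in range(1000):  # 1e5 read bases total
            mutated = apply_errors(read, prof, rng)
            mismatches += sum(a != b for a, b in zip(read, mutated))
        assert abs(mismatches - 1000) < 5 * np.sqrt(1000 * 0.99)

    def test_quality_string_encodes_rates(self):
        prof = ErrorProfile(np.array([0.01, 0.1, 0.0]))
        assert prof.quality_string() == chr(33 + 20) + chr(33 + 10) + chr(33 + 41)

    def test_profile_tsv_round_trip(self, tmp_path):
        prof = ErrorProfile(np.array([0.001, 0.02, 0.3]))
        p = tmp_path / "prof.tsv"
        prof.to_tsv(p)
        back = ErrorProfile.from_tsv(p)
        assert np.allclose(back.per_cycle_rate, prof.per_cycle_rate)


class TestLearnErrorProfile:
    def test_constant_q20(self, tmp_path):
        p = tmp_path / "r.fastq"
        synth_fastq(50, 10, np.full(10, 20.0), p, seed=0)
        prof = learn_error_profile(p)
        assert np.allclose(prof.per_cycle_rate, 0.01)

    def test_per_cycle_ramp(self, tmp_path):
        p = tmp_path / "r.fastq"
        synth_fastq(10, 2, [30.0, 10.0], p, seed=0)
        prof = learn_error_profile(p)
        assert np.allclose(prof.per_cycle_rate, [0.001, 0.1])

    def test_known_mixture_matches_hand_mean(self, tmp_path):
        # half the reads Q20, half Q30 -> rate = (0.01 + 0.001)/2 per cycle
        p = tmp_path / "r.fastq"
        with open(p, "w") as fh:
            for i in range(10):
                q = 20 if i % 2 == 0 else 30
                fh.write(f"@r{i}\nACGTA\n+\n{chr(33+q)*5}\n")
        prof = learn_error_profile(p)
        assert np.allclose(prof.per_cycle_rate, 0.0055)

    def test_empty_fastq_rejected(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        with pytest.raises(ValueError):
            learn_error_profile(p)

    def test_variable_lengths_warn(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@a\nACGT\n+\nIIII\n@b\nAC\n+\nII\n")
        with pytest.warns(UserWarning, match="variable read lengths"):
            learn_error_profile(p)


class TestLibrary:
    def test_deterministic_byte_identical_outputs(self, toy_genome, tmp_path):
        cfg = SimConfig(slope=1.5, target_coverage=2.0, seed=99,
                        errors=ErrorProfile.constant(100, 25))
        simulate_library(toy_genome, cfg, out_prefix=tmp_path / "a")
        simulate_library(toy_genome, cfg, out_prefix=tmp_path / "b")
        for suffix in ("_1.fastq", "_2.fastq", ".truth.tsv"):
            a = (tmp_path / ("a" + suffix)).read_bytes()
            b = (tmp_path / ("b" + suffix)).read_bytes()
            assert a == b

    def test_truth_track_round_trip(self, toy_genome, tmp_path):
        cfg = SimConfig(slope=0.0, target_coverage=1.0, seed=4)
        summary = simulate_library(toy_genome, cfg, out_prefix=tmp_path / "lib")
        truth = read_truth(summary["truth"])
        assert len(truth) == summary["n_pairs"]
        assert all(t.seq_name == toy_genome.name for t in truth)

    def test_read_names_encode_placement(self, toy_genome):
        cfg = SimConfig(slope=0.0, target_coverage=0.5, seed=4)
        summary = simulate_library(toy_genome, cfg)
        name, r1, _, _, _, frag = summary["pairs"][0]
        _, seq_name, start, end, _ = name.split("|")
        assert (seq_name, int(start), int(end)) == (frag.seq_name, frag.start, frag.end)
        assert r1 == toy_genome.bases[frag.start : frag.start + 100]


class TestMatePair:
    def test_pair_count_matches_coverage(self):
        genome = GenomeSequence("big", "ACGT" * 250_000)  # 1 Mb, uniform 50% GC
        summary = simulate_mp_library(genome, coverage=1.0, seed=8)
        assert summary["n_pairs"] == pytest.approx(5000, abs=1)  # 1e6 / (2*100)

    def test_insert_length_clt_bound(self, tmp_path):
        genome = GenomeSequence("big", "ACGT" * 250_000)
        summary = simulate_mp_library(
            genome, coverage=1.0, seed=8, out_prefix=tmp_path / "mp"
        )
        truth = read_truth(summary["truth"])
        lengths = np.array([t.length for t in truth])
        assert abs(lengths.mean() - 3500) < 3 * 500 / np.sqrt(len(lengths))
        assert summary["library_type"] == "MP"
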