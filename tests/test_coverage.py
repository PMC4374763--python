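"""Coverage profiles, NPKM normalisation and signal-to-noise statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prophagekit import (CoverageProfile, Genome, GenomeError, GenomicRegion,
                         call_active_regions, coverage_from_sam, npkm,
                         profile_from_intervals, signal_to_noise,
                         signal_to_noise_from_values, windowed_npkm)


def _sam(tmp_path, genome, records):
    lines = ["@HD\tVN:1.6\tSO:unsorted",
             f"@SQ\tSN:{genome.id}\tLN:{genome.length}"]
    lines += records
    p = tmp_path / "reads.sam"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def kb_genome():
    return Genome("g1", "ACGT" * 250)  # 1,000 bp


class TestCoverageFromSam:
    def test_two_full_reads(self, tmp_path, kb_genome):
        seq = kb_genome.sequence[:100]
        sam = _sam(tmp_path, kb_genome, [
            f"r1\t0\tg1\t1\t60\t100M\t*\t0\t0\t{seq}\t*",
            f"r2\t0\tg1\t201\t60\t100M\t*\t0\t0\t{seq}\t*",
        ])
        prof = coverage_from_sam(sam, kb_genome)
        assert prof.total_aligned_nt == 200
        assert prof.depth.mean() == pytest.approx(0.2)
        assert (prof.n_mapped_reads, prof.n_unmapped_reads) == (2, 0)

    def test_unmapped_read_only(self, tmp_path, kb_genome):
        sam = _sam(tmp_path, kb_genome,
                   ["r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*"])
        prof = coverage_from_sam(sam, kb_genome)
        assert prof.depth.sum() == 0
        assert prof.n_unmapped_reads == 1

    def test_secondary_alignment_counted_once(self, tmp_path, kb_genome):
        seq = kb_genome.sequence[:50]
        sam = _sam(tmp_path, kb_genome, [
            f"r1\t0\tg1\t1\t60\t50M\t*\t0\t0\t{seq}\t*",
            f"r1\t256\tg1\t501\t60\t50M\t*\t0\t0\t{seq}\t*",  # secondary
        ])
        prof = coverage_from_sam(sam, kb_genome)
        assert prof.total_aligned_nt == 50
        assert prof.depth[500:550].sum() == 0

    def test_mapq_zero_multimapper_excluded_from_depth(self, tmp_path,
                                                       kb_genome):
        seq = kb_genome.sequence[:50]
        sam = _sam(tmp_path, kb_genome,
                   [f"r1\t0\tg1\t1\t0\t50M\t*\t0\t0\t{seq}\t*"])
        prof = coverage_from_sam(sam, kb_genome)
        assert prof.total_aligned_nt == 0
        assert prof.n_mapped_reads == 1

    def test_insertions_and_clips_do_not_consume_reference(self, tmp_path,
                                                           kb_genome):
        # 10S40M5I45M: 85 reference positions consumed
        seq = "A" * 100
        sam = _sam(tmp_path, kb_genome,
                   [f"r1\t0\tg1\t11\t60\t10S40M5I45M\t*\t0\t0\t{seq}\t*"])
        prof = coverage_from_sam(sam, kb_genome)
        assert prof.total_aligned_nt == 85
        assert prof.depth[10:95].sum() == 85

    def test_header_mismatch_rejected(self, tmp_path, kb_genome):
        other = Genome("other", "ACGT" * 250)
        sam = _sam(tmp_path, other, [])
        with pytest.raises(GenomeError, match="not among"):
            coverage_from_sam(sam, kb_genome)
        short = Genome("g1", "ACGT" * 10)
        sam2 = _sam(tmp_path, short, [])
        with pytest.raises(GenomeError, match="length"):
            coverage_from_sam(sam2, kb_genome)


def _uniform_profile(length=10_000, depth=3):
    return CoverageProfile(genome_id="g", depth=np.full(length, depth,
                                                        dtype=np.int64),
                           total_aligned_nt=length * depth,
                           n_mapped_reads=0, n_unmapped_reads=0)


class TestNpkm:
    def test_worked_example(self):
        # 10-kb genome, 1-kb region holding 2,000 of 10,000 aligned nt:
        # (2000 / 1) / (10000 / 1e6) = 200,000
        depth = np.zeros(10_000, dtype=np.int64)
        depth[:1000] = 2
        depth[1000:9000] = 1
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        assert prof.total_aligned_nt == 10_000
        region = GenomicRegion("r", 1, 1000)
        assert npkm(prof, region) == pytest.approx(200_000.0)

    def test_uniform_depth_is_region_independent(self):
        prof = _uniform_profile()
        values = [npkm(prof, GenomicRegion("r", s, e))
                  for s, e in [(1, 1000), (2001, 2500), (5000, 9999)]]
        assert values[0] == pytest.approx(values[1])
        assert values[1] == pytest.approx(values[2])

    def test_zero_coverage_region(self):
        depth = np.zeros(5000, dtype=np.int64)
        depth[:100] = 5
        prof = CoverageProfile("g", depth, 500, 0, 0)
        assert npkm(prof, GenomicRegion("r", 2001, 3000)) == 0.0

    def test_zero_total_rejected(self):
        prof = CoverageProfile("g", np.zeros(100, dtype=np.int64), 0, 0, 0)
        with pytest.raises(GenomeError):
            npkm(prof, GenomicRegion("r", 1, 10))


class TestWindowedNpkm:
    def test_tiling_arithmetic(self):
        prof = _uniform_profile(length=3500)
        track = windowed_npkm(prof, window=1000)
        sizes = [r.span for r, _ in track.values]
        assert sizes == [1000, 1000, 1000, 500]
        starts = [r.start for r, _ in track.values]
        assert starts == [1, 1001, 2001, 3001]

    def test_concentrated_reads_mark_unique_maximum(self):
        depth = np.zeros(10_000, dtype=np.int64)
        depth[4200:4700] = 10
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        track = windowed_npkm(prof, window=1000)
        values = [v for _, v in track.values]
        assert np.argmax(values) == 4  # window 4001..5000
        assert values.count(max(values)) == 1

    @pytest.mark.parametrize("length,window", [(3500, 1000), (10_000, 1000),
                                               (9_999, 250)])
    def test_length_weighted_sum_is_1e6(self, length, window):
        rng = np.random.default_rng(length)
        depth = rng.integers(0, 20, size=length).astype(np.int64)
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        track = windowed_npkm(prof, window=window)
        total = sum(v * (r.span / 1000.0) for r, v in track.values)
        assert total == pytest.approx(1e6, rel=1e-9)

    def test_small_window_rejected(self):
        with pytest.raises(GenomeError):
            windowed_npkm(_uniform_profile(), window=50)


class TestSignalToNoise:
    @pytest.mark.parametrize("signal,noise,ratio,noise_pct", [
        # the six published average-coverage pairs and their statistics
        (82.7, 31.5, 2.6, 38.1),
        (187.0, 79.7, 2.3, 42.6),
        (1447.2, 27.2, 53.2, 1.9),
        (1671.8, 68.3, 24.5, 4.1),
        (44.9, 1.4, 32.1, 3.1),
        (664.6, 5.4, 123.1, 0.8),
    ])
    def test_published_arithmetic(self, signal, noise, ratio, noise_pct):
        rep = signal_to_noise_from_values(signal, noise)
        assert round(rep.ratio, 1) == ratio
        assert round(rep.noise_pct, 1) == noise_pct

    def test_uniform_coverage_ratio_one(self):
        prof = _uniform_profile()
        rep = signal_to_noise(prof, [GenomicRegion("r", 1001, 3000)])
        assert rep.ratio == pytest.approx(1.0)
        assert rep.noise_pct == pytest.approx(100.0)

    def test_profile_based_matches_hand_count(self):
        depth = np.zeros(1000, dtype=np.int64)
        depth[100:200] = 4   # inside the region
        depth[500:600] = 1   # outside
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        rep = signal_to_noise(prof, [GenomicRegion("r", 101, 200)])
        assert rep.signal == pytest.approx(4.0)
        assert rep.noise == pytest.approx(100 / 900)
        assert rep.ratio == pytest.approx(36.0)

    def test_overlapping_regions_merged_before_masking(self):
        prof = _uniform_profile(length=1000)
        overlapping = [GenomicRegion("a", 1, 300), GenomicRegion("b", 200, 400)]
        rep = signal_to_noise(prof, overlapping)
        assert rep.ratio == pytest.approx(1.0)

    def test_zero_noise_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            rep = signal_to_noise_from_values(10.0, 0.0)
        assert math.isinf(rep.ratio)

    def test_zero_signal_rejected(self):
        with pytest.raises(GenomeError):
            signal_to_noise_from_values(0.0, 5.0)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_noise_pct_times_ratio_is_100(self, signal, noise):
        rep = signal_to_noise_from_values(signal, noise)
        assert rep.noise_pct * rep.ratio == pytest.approx(100.0, rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        depth = rng.integers(0, 30, size=5000).astype(np.int64)
        regions = [GenomicRegion("r", 1001, 2000)]
        p1 = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        p7 = CoverageProfile("g", depth * 7, int(depth.sum()) * 7, 0, 0)
        r1, r7 = signal_to_noise(p1, regions), signal_to_noise(p7, regions)
        assert r1.ratio == pytest.approx(r7.ratio)
        assert r1.noise_pct == pytest.approx(r7.noise_pct)
        assert npkm(p1, regions[0]) == pytest.approx(npkm(p7, regions[0]))


class TestCallActiveRegions:
    def test_enriched_region_called_active(self):
        depth = np.ones(100_000, dtype=np.int64)
        depth[40_000:60_000] = 50
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        regions = [GenomicRegion("hot", 40_001, 60_000),
                   GenomicRegion("cold", 10_001, 20_000)]
        calls = call_active_regions(prof, regions)
        by_label = {c.region.label: c for c in calls}
        assert by_label["hot"].active
        assert by_label["hot"].mode_flag == "specific"
        assert not by_label["cold"].active

    def test_empty_profile_calls_nothing_active(self):
        prof = CoverageProfile("g", np.zeros(50_000, dtype=np.int64), 0, 0, 0)
        calls = call_active_regions(prof, [GenomicRegion("r", 1, 10_000)])
        assert not any(c.active for c in calls)

    def test_noisy_genome_sets_random_packaging_flag(self):
        rng = np.random.default_rng(10)
        depth = rng.poisson(10, size=100_000).astype(np.int64)
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        calls = call_active_regions(prof, [GenomicRegion("r", 1, 20_000)])
        assert all(c.mode_flag == "random_packaging_suspected" for c in calls)
        assert not any(c.active for c in calls)

    def test_all_coverage_inside_region_gives_infinite_enrichment(self):
        depth = np.zeros(50_000, dtype=np.int64)
        depth[10_000:20_000] = 8
        prof = CoverageProfile("g", depth, int(depth.sum()), 0, 0)
        (call,) = call_active_regions(prof, [GenomicRegion("r", 10_001, 20_000)])
        assert call.active and math.isinf(call.enrichment)


class TestProfileFromIntervals:
    def test_matches_sam_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        genome = Genome("g1", "".join(rng.choice(list("ACGT"), size=2_000)))
        starts = rng.integers(1, 1_901, size=50)
        ends = starts + 99
        prof_direct = profile_from_intervals("g1", 2_000, starts, ends)
        records = []
        for i, s in enumerate(starts):
            seq = genome.sequence[s - 1 : s + 99]
            records.append(f"r{i}\t0\tg1\t{s}\t60\t100M\t*\t0\t0\t{seq}\t*")
        prof_sam = coverage_from_sam(_sam(tmp_path, genome, records), genome)
        assert np.array_equal(prof_direct.depth, prof_sam.depth)
        assert prof_direct.total_aligned_nt == prof_sam.total_aligned_nt == 5_000
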