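"""Mapper soundness, rotated-reference rescue, coverage and windowing."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

from mtload import (
    CircularReference,
    ReadSet,
    ReadSimParams,
    build_pileup,
    coverage,
    generate_reference,
    map_reads,
    merge_highest_coverage,
    rotate_reference,
    simulate_reads,
    sliding_window,
)
from mtload.coverage import CoverageProfile
from mtload.reference import decode_bases


def readset_from_codes(rows, ids=None):
    rows = np.asarray(rows, dtype=np.uint8)
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return ReadSet(ids=ids, codes=rows, read_length=rows.shape[1])


def circular_window(ref, start, length):
    return ref.codes[(start + np.arange(length)) % ref.length]


class TestMapper:
    def test_error_free_interior_reads_map_to_truth(self, small_ref, clean_readset):
        reads, truth = clean_readset
        alignments = {a.read_index: a for a in map_reads(reads, small_ref)}
        rl = reads.read_length
        interior = truth.start + rl <= small_ref.length
        for i in np.flatnonzero(interior):
            assert i in alignments, f"interior read {i} unmapped"
            a = alignments[i]
            assert a.start == truth.start[i]
            assert a.is_reverse == truth.strand[i]
            assert a.n_mismatches == 0

    def test_origin_spanning_reads_unmapped_then_rescued(self, small_ref, clean_readset):
        reads, truth = clean_readset
        rl = reads.read_length
        wrapping = set(np.flatnonzero(truth.start + rl > small_ref.length))
        assert wrapping
        mapped_orig = {a.read_index for a in map_reads(reads, small_ref)}
        assert not (wrapping & mapped_orig)
        rot = rotate_reference(small_ref)
        mapped_rot = {
            a.read_index: a for a in map_reads(reads, rot, ref_version="rotated")
        }
        for i in wrapping:
            assert i in mapped_rot
            a = mapped_rot[i]
            assert small_ref.to_original(a.start) == truth.start[i]

    def test_constructed_junction_read(self, small_ref):
        # read spanning the linear origin: last 50 bases + first 50 bases
        L = small_ref.length
        reads = readset_from_codes([circular_window(small_ref, L - 50, 100)])
        assert map_reads(reads, small_ref) == []
        rot = rotate_reference(small_ref)
        aln = map_reads(reads, rot, ref_version="rotated")
        assert len(aln) == 1
        assert small_ref.to_original(aln[0].start) == L - 50

    def test_mismatch_threshold(self, small_ref):
        codes = circular_window(small_ref, 300, 100).copy()
        for k in range(6):  # max_mismatches + 1 substitutions
            codes[10 * k] = (codes[10 * k] + 1) % 4
        assert map_reads(readset_from_codes([codes]), small_ref) == []
        codes5 = circular_window(small_ref, 300, 100).copy()
        for k in range(5):
            codes5[10 * k] = (codes5[10 * k] + 1) % 4
        aln = map_reads(readset_from_codes([codes5]), small_ref)
        assert len(aln) == 1 and aln[0].n_mismatches == 5

    def test_ambiguous_placement_is_unmapped(self):
        # reference with an exact 120 bp tandem repeat: a read inside the
        # repeat has two equally good placements -> tie -> unmapped
        rng = np.random.default_rng(42)
        unit = rng.integers(0, 4, 120, dtype=np.uint8)
        fill = rng.integers(0, 4, 1000, dtype=np.uint8)
        seq = decode_bases(np.concatenate([unit, unit, fill]))
        ref = CircularReference(name="rep", sequence=seq, ncr_span=(0, len(seq)))
        read = readset_from_codes([unit[:100]])
        assert map_reads(read, ref) == []

    def test_reverse_strand_read_maps(self, small_ref):
        from mtload.reference import reverse_complement_codes

        window = circular_window(small_ref, 500, 100)
        read = readset_from_codes([reverse_complement_codes(window)])
        aln = map_reads(read, small_ref)
        assert len(aln) == 1
        assert aln[0].start == 500 and aln[0].is_reverse
        assert np.array_equal(aln[0].observed, window)

    def test_duplicate_read_ids_rejected(self, small_ref):
        rows = [circular_window(small_ref, 10, 100)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            map_reads(readset_from_codes(rows, ids=["a", "a"]), small_ref)

    def test_seed_longer_than_read_rejected(self, small_ref):
        read = readset_from_codes([circular_window(small_ref, 10, 40)])
        with pytest.raises(ValueError):
            map_reads(read, small_ref, seed_kmer_length=50)


class TestCoverage:
    def test_no_alignments_gives_zero_profile(self, small_ref):
        prof = coverage([], small_ref, "original")
        assert prof.total_bases == 0
        assert (prof.depth == 0).all()

    def test_single_read_covers_read_length_positions(self, small_ref):
        aln = map_reads(
            readset_from_codes([circular_window(small_ref, 250, 100)]), small_ref
        )
        prof = coverage(aln, small_ref, "original")
        assert (prof.depth == 1).sum() == 100
        assert prof.depth[250:350].sum() == 100

    def test_depth_conservation(self, small_ref, clean_readset):
        reads, _ = clean_readset
        aln = map_reads(reads, small_ref)
        prof = coverage(aln, small_ref, "original")
        assert prof.total_bases == len(aln) * reads.read_length

    def test_oracle_equivalence_interval_overlap(self, small_ref):
        # brute-force per-position interval counting on <= 100 reads
        params = ReadSimParams(seed=13, mean_depth=5, error_rate=0.0)
        reads, _ = simulate_reads(small_ref, params)
        aln = map_reads(reads, small_ref)
        assert len(aln) <= 100
        prof = coverage(aln, small_ref, "original")
        brute = np.zeros(small_ref.length, dtype=int)
        for a in aln:
            for p in range(a.start, a.start + reads.read_length):
                brute[p] += 1
        assert np.array_equal(prof.depth, brute)

    def test_rotated_profile_back_translated(self, small_ref):
        L = small_ref.length
        reads = readset_from_codes([circular_window(small_ref, L - 50, 100)])
        rot = rotate_reference(small_ref)
        aln = map_reads(reads, rot, ref_version="rotated")
        prof = coverage(aln, small_ref, "rotated")
        assert prof.depth[L - 50 :].sum() == 50
        assert prof.depth[:50].sum() == 50

    def test_version_mismatch_rejected(self, small_ref):
        aln = map_reads(
            readset_from_codes([circular_window(small_ref, 10, 100)]), small_ref
        )
        with pytest.raises(ValueError):
            coverage(aln, small_ref, "rotated")


class TestMerge:
    def test_zero_rotated_keeps_original(self, small_ref, clean_readset):
        reads, _ = clean_readset
        aln = map_reads(reads, small_ref)
        prof = coverage(aln, small_ref, "original")
        pile = build_pileup(aln, small_ref, "original")
        empty_prof = coverage([], small_ref, "rotated")
        empty_pile = build_pileup([], small_ref, "rotated")
        merged_prof, merged_pile = merge_highest_coverage(
            prof, empty_prof, pile, empty_pile
        )
        assert np.array_equal(merged_prof.depth, prof.depth)
        assert np.array_equal(merged_pile.counts, pile.counts)

    def test_merged_depth_is_elementwise_max(self, small_ref, clean_readset):
        reads, _ = clean_readset
        rot = rotate_reference(small_ref)
        aln_o = map_reads(reads, small_ref)
        aln_r = map_reads(reads, rot, ref_version="rotated")
        prof_o = coverage(aln_o, small_ref, "original")
        prof_r = coverage(aln_r, small_ref, "rotated")
        merged, _ = merge_highest_coverage(
            prof_o,
            prof_r,
            build_pileup(aln_o, small_ref, "original"),
            build_pileup(aln_r, small_ref, "rotated"),
        )
        assert np.array_equal(merged.depth, np.maximum(prof_o.depth, prof_r.depth))

    def test_junction_positions_take_rotated_columns(self, small_ref):
        L = small_ref.length
        reads = readset_from_codes(
            [circular_window(small_ref, L - 50, 100), circular_window(small_ref, 400, 100)]
        )
        rot = rotate_reference(small_ref)
        aln_o = map_reads(reads, small_ref)
        aln_r = map_reads(reads, rot, ref_version="rotated")
        _, merged = merge_highest_coverage(
            coverage(aln_o, small_ref, "original"),
            coverage(aln_r, small_ref, "rotated"),
            build_pileup(aln_o, small_ref, "original"),
            build_pileup(aln_r, small_ref, "rotated"),
        )
        # junction read only exists in the rotated version; interior read in both
        assert merged.depth[:50].sum() == 50
        assert merged.depth[400:500].sum() == 100

    def test_length_mismatch_rejected(self, small_ref):
        a = CoverageProfile(np.zeros(10, int), "original")
        b = CoverageProfile(np.zeros(11, int), "rotated")
        with pytest.raises(ValueError):
            merge_highest_coverage(a, b, None, None)


class TestSlidingWindow:
    def test_constant_profile_normalises_to_one(self):
        prof = CoverageProfile(np.full(500, 7), "merged")
        w = sliding_window(prof, 50)
        assert np.allclose(w.values, 1.0)

    def test_spike_matches_brute_force_toy(self):
        depth = np.zeros(50, dtype=int)
        depth[20] = 10
        prof = CoverageProfile(depth, "merged")
        w = sliding_window(prof, 10)
        brute = np.empty(50)
        for p in range(50):
            # centred circular window (even size: centre half-left)
            idx = (np.arange(p - 10 // 2, p + 10 - 10 // 2) - 0) % 50
            brute[p] = depth[idx].mean()
        brute /= brute.max()
        assert np.allclose(w.values, brute)

    def test_max_is_exactly_one(self, small_ref, clean_readset):
        reads, _ = clean_readset
        aln = map_reads(reads, small_ref)
        w = sliding_window(coverage(aln, small_ref, "original"), 200)
        assert w.values.max() == 1.0
        assert (w.values >= 0).all()

    def test_window_bounds_checked(self):
        prof = CoverageProfile(np.ones(100, int), "merged")
        with pytest.raises(ValueError):
            sliding_window(prof, 0)
        with pytest.raises(ValueError):
            sliding_window(prof, 101)


def null_flatness_expectation(L, read_length, fragment_mean, fragment_sd,
                              depth, window, seed, n_rep=15):
    """Monte-Carlo expectation of (max-min)/mean of windowed coverage under
    ideal circular sampling (no mapping): the binomial-sampling yardstick."""
    rng = np.random.default_rng(seed)
    nfrag = int(round(depth * L / (2 * read_length)))
    vals = []
    for _ in range(n_rep):
        starts = rng.integers(0, L, nfrag)
        lens = np.maximum(
            np.rint(rng.normal(fragment_mean, fragment_sd, nfrag)).astype(int),
            read_length,
        )
        cov = np.zeros(L)
        for s0 in (starts, (starts + lens - read_length) % L):
            cnt = np.bincount(s0, minlength=L).astype(float)
            cov += uniform_filter1d(cnt, read_length, mode="wrap") * read_length
        sm = uniform_filter1d(cov, window, mode="wrap")
        vals.append((sm.max() - sm.min()) / sm.mean())
    return float(np.mean(vals))


@pytest.fixture(scope="module")
def rescue_profiles(mt_ref):
    """Depth-200 error-free simulation mapped with and without rescue."""
    params = ReadSimParams(seed=0, mean_depth=200, error_rate=0.0)
    reads, _ = simulate_reads(mt_ref, params)
    rot = rotate_reference(mt_ref)
    aln_o = map_reads(reads, mt_ref)
    aln_r = map_reads(reads, rot, ref_version="rotated")
    prof_o = coverage(aln_o, mt_ref, "original")
    prof_r = coverage(aln_r, mt_ref, "rotated")
    merged, _ = merge_highest_coverage(
        prof_o,
        prof_r,
        build_pileup(aln_o, mt_ref, "original"),
        build_pileup(aln_r, mt_ref, "rotated"),
    )
    return reads, prof_o, merged


class TestRescueProperty:
    """The rotation rescue removes the origin coverage trough."""

    def test_original_only_has_origin_trough(self, rescue_profiles):
        reads, prof_o, _ = rescue_profiles
        rl = reads.read_length
        mean_depth = prof_o.depth.mean()
        near_origin = min(prof_o.depth[:rl].min(), prof_o.depth[-rl:].min())
        assert near_origin < 0.5 * mean_depth

    def test_merged_profile_is_flat(self, mt_ref, rescue_profiles):
        _, _, merged = rescue_profiles
        smoothed = uniform_filter1d(merged.depth.astype(float), 2000, mode="wrap")
        observed = (smoothed.max() - smoothed.min()) / smoothed.mean()
        expected = null_flatness_expectation(
            mt_ref.length, 100, 200.0, 20.0, depth=200, window=2000, seed=99
        )
        assert observed < 3 * expected
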