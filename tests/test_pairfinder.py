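"""Core scan: AAY motif counting, seeding, alignment, pair calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgrfinder.pairfinder import (
    ScanParams,
    align_segments,
    call_tr_vr,
    count_aay,
    find_seed_matches,
    passes_aay_filter,
    profile_substitutions,
    scan_sequence,
)
from dgrfinder.seqio import Interval, SequenceRecord
from dgrfinder.simulate import SimParams, generate_dgr_contig

from conftest import INTERIOR_A, INTERIOR_G, TEMPLATE_60, make_pair_record, mutate_at, random_bases

PARAMS = ScanParams()


class TestCountAay:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AACAATAAC", 3),
            ("GGGGGGGGG", 0),
            ("AAAC", 1),  # only offset 1 forms AAC
            ("", 0),
            ("AAACC", 1),
            ("AAAAT", 1),  # only offset 2 forms AAT
            ("AACAACAA", 2),
        ],
    )
    def test_known_counts(self, window, expected):
        assert count_aay(window) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_matches_brute_force_enumeration(self, window):
        brute = sum(
            window[i : i + 3] in ("AAC", "AAT") for i in range(len(window))
        )
        assert count_aay(window) == brute


class TestAayFilter:
    def test_aay_rich_window_passes(self):
        assert passes_aay_filter("AAC" * 20, PARAMS)

    def test_single_aay_fails(self):
        assert not passes_aay_filter("AAC" + "G" * 57, PARAMS)

    def test_exactly_three_is_inclusive(self):
        window = "AACAATAAC" + "G" * 51
        assert count_aay(window) == 3
        assert passes_aay_filter(window, PARAMS)


class TestFindSeedMatches:
    def test_planted_duplication_found(self):
        bg = random_bases(1000, seed=11)
        dup = random_bases(80, seed=12)
        seq = bg[:100] + dup + bg[180:500] + dup + bg[580:]
        rec = SequenceRecord("dup", seq)
        seeds = find_seed_matches(rec, PARAMS)
        covering = [
            s
            for s in seeds
            if s.length >= 80
            and s.copy_a.start <= 101 <= s.copy_a.end
            and s.copy_b.start <= 501 <= s.copy_b.end
        ]
        assert covering

    def test_random_sequence_yields_no_seeds(self):
        rec = SequenceRecord("rand", random_bases(1000, seed=13))
        assert find_seed_matches(rec, PARAMS) == []
        assert find_seed_matches(rec, PARAMS.without_speedups()) == []

    def test_self_is_not_a_seed(self):
        rec = SequenceRecord("self", random_bases(300, seed=14))
        assert find_seed_matches(rec, PARAMS) == []

    def test_inverted_repeat_found_on_minus_strand(self):
        from Bio.Seq import reverse_complement

        bg = random_bases(1000, seed=15)
        dup = random_bases(80, seed=16)
        seq = bg[:100] + dup + bg[180:500] + reverse_complement(dup) + bg[580:]
        rec = SequenceRecord("inv", seq)
        seeds = find_seed_matches(rec, PARAMS)
        minus = [s for s in seeds if s.copy_b.strand == "-"]
        assert minus
        assert minus[0].copy_a.start < minus[0].copy_b.start

    def test_restrict_to_keeps_only_contained_seeds(self):
        bg = random_bases(2000, seed=17)
        dup = random_bases(80, seed=18)
        seq = bg[:100] + dup + bg[180:1500] + dup + bg[1580:]
        rec = SequenceRecord("dup2", seq)
        everywhere = find_seed_matches(rec, PARAMS)
        assert everywhere
        nowhere = find_seed_matches(
            rec, PARAMS, restrict_to=[Interval("dup2", 700, 900)]
        )
        assert nowhere == []

    def test_seed_invariants(self):
        rec, truth, _ = generate_dgr_contig(
            SimParams(seed=3, contig_len=6000, include_rt=False)
        )
        for s in find_seed_matches(rec, PARAMS):
            assert s.length >= PARAMS.seed_min_len
            assert s.identity >= PARAMS.seed_min_identity
            assert not s.copy_a.overlaps(s.copy_b)
            assert s.copy_a.length() == s.copy_b.length()


class TestAlignSegments:
    def test_identical_segments_align_without_substitutions(self):
        rec, a, b = make_pair_record(TEMPLATE_60, TEMPLATE_60)
        aln = align_segments(
            rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS
        )
        kinds = [c[4] for c in aln.columns]
        assert kinds == ["match"] * 60
        assert (aln.copy_a.start, aln.copy_a.end) == a
        assert (aln.copy_b.start, aln.copy_b.end) == b

    def test_seven_substitutions_counted_exactly(self):
        vr = mutate_at(TEMPLATE_60, INTERIOR_A[:7])
        rec, a, b = make_pair_record(TEMPLATE_60, vr)
        aln = align_segments(rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS)
        kinds = [c[4] for c in aln.columns]
        assert kinds.count("substitution") == 7
        assert kinds.count("insertion_a") + kinds.count("insertion_b") == 0

    def test_two_bp_deletion_produces_two_indel_columns(self):
        vr = TEMPLATE_60[:30] + TEMPLATE_60[32:]
        rec, a, b = make_pair_record(TEMPLATE_60, vr)
        aln = align_segments(rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS)
        profile = profile_substitutions(aln)
        assert profile.indel_columns == 2
        assert profile.total_subs == 0
        # degapped aligned strings reproduce the copies
        assert aln.aligned_a.replace("-", "") == TEMPLATE_60
        assert aln.aligned_b.replace("-", "") == vr

    def test_degenerate_interval_rejected(self):
        rec, a, b = make_pair_record(TEMPLATE_60, TEMPLATE_60)
        with pytest.raises(ValueError):
            align_segments(
                rec, Interval(rec.id, 5, 10), Interval(rec.id, 8, 20), PARAMS
            )


class TestProfileSubstitutions:
    def _profile(self, tr, vr):
        rec, a, b = make_pair_record(tr, vr)
        aln = align_segments(rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS)
        return profile_substitutions(aln)

    def test_adenine_specific_substitutions(self):
        p = self._profile(TEMPLATE_60, mutate_at(TEMPLATE_60, INTERIOR_A[:7]))
        assert (p.total_subs, p.subs_at_A_in_a, p.subs_at_A_in_b) == (7, 7, 0)

    def test_identical_copies_profile_is_zero(self):
        p = self._profile(TEMPLATE_60, TEMPLATE_60)
        assert (p.total_subs, p.subs_at_A_in_a, p.subs_at_A_in_b, p.indel_columns) == (0, 0, 0, 0)

    def test_non_adenine_substitution_not_counted_at_A(self):
        c_pos = TEMPLATE_60.index("C")
        vr = mutate_at(TEMPLATE_60, [c_pos], base_map={"C": "T"})
        p = self._profile(TEMPLATE_60, vr)
        assert p.total_subs == 1
        assert p.subs_at_A_in_a == 0
        assert p.subs_at_A_in_b == 0
        assert p.subs_at_T_in_b == 1  # the T lands in the other copy


class TestCallTrVr:
    def _call(self, tr, vr):
        rec, a, b = make_pair_record(tr, vr)
        aln = align_segments(rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS)
        return call_tr_vr(rec, aln, profile_substitutions(aln), PARAMS), a, b

    def test_seven_adenine_substitutions_on_sixty_bp_is_called(self):
        pair, a, b = self._call(TEMPLATE_60, mutate_at(TEMPLATE_60, INTERIOR_A[:7]))
        assert pair is not None
        assert (pair.tr.start, pair.tr.end) == a
        assert pair.a_subs == 7
        assert pair.non_a_frac == 0.0

    def test_six_adenine_substitutions_is_below_threshold(self):
        pair, _, _ = self._call(TEMPLATE_60, mutate_at(TEMPLATE_60, INTERIOR_A[:6]))
        assert pair is None

    def test_non_a_fraction_exactly_thirty_percent_fails(self):
        # 7 A substitutions + 3 non-A substitutions = 10 total, 0.30 non-A
        vr = mutate_at(TEMPLATE_60, INTERIOR_A[:7] + INTERIOR_G[:3])
        pair, _, _ = self._call(TEMPLATE_60, vr)
        assert pair is None

    def test_template_is_the_adenine_bearing_copy(self):
        vr = mutate_at(TEMPLATE_60, INTERIOR_A[:8])
        # place the variable copy FIRST: the template must still be called
        # on the adenine-bearing (second) copy
        rec, a, b = make_pair_record(vr, TEMPLATE_60)
        aln = align_segments(rec, Interval(rec.id, *a), Interval(rec.id, *b), PARAMS)
        pair = call_tr_vr(rec, aln, profile_substitutions(aln), PARAMS)
        assert pair is not None
        assert (pair.tr.start, pair.tr.end) == b
        assert (pair.vr.start, pair.vr.end) == a


class TestScanSequence:
    def test_simulated_implant_recovered_with_exact_profile(self, sim_contig):
        rec, truth, _ = sim_contig
        pairs = scan_sequence(rec)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.tr.overlap_length(truth.tr) / truth.tr.length() >= 0.9
        assert p.vr.overlap_length(truth.vr) / truth.vr.length() >= 0.9
        assert p.a_subs >= PARAMS.min_a_subs

    def test_random_contig_reports_nothing(self):
        rec = SequenceRecord("rand50", random_bases(50_000, seed=77))
        assert scan_sequence(rec) == []

    def test_reported_pairs_satisfy_all_invariants(self):
        for seed in (4, 5, 6):
            rec, truth, _ = generate_dgr_contig(SimParams(seed=seed))
            for p in scan_sequence(rec):
                assert p.tr.length() >= PARAMS.min_pair_len
                assert p.a_subs >= PARAMS.min_a_subs
                assert p.non_a_frac < PARAMS.max_non_a_frac
                assert not p.tr.overlaps(p.vr)

    def test_raising_min_a_subs_never_increases_pair_count(self):
        rec, _, _ = generate_dgr_contig(SimParams(seed=7))
        counts = []
        for min_a in (7, 8, 9, 10, 12):
            params = ScanParams(min_a_subs=min_a)
            counts.append(len(scan_sequence(rec, params)))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 1 and counts[-1] == 0

    def test_reported_trs_are_disjoint_and_sorted(self):
        rec, _, _ = generate_dgr_contig(SimParams(seed=8))
        pairs = scan_sequence(rec)
        starts = [p.tr.start for p in pairs]
        assert starts == sorted(starts)
        for i, p in enumerate(pairs):
            for q in pairs[i + 1 :]:
                assert not p.tr.overlaps(q.tr)

    def test_exhaustive_mode_agrees_with_fast_path(self):
        rec, _, _ = generate_dgr_contig(
            SimParams(seed=9, contig_len=5000, include_rt=False, include_target=False)
        )
        fast = [(p.tr.start, p.tr.end) for p in scan_sequence(rec)]
        slow = [(p.tr.start, p.tr.end) for p in scan_sequence(rec, PARAMS.without_speedups())]
        assert len(fast) == len(slow) == 1
        assert abs(fast[0][0] - slow[0][0]) <= 5
        assert abs(fast[0][1] - slow[0][1]) <= 5

    def test_strand_symmetry_mirrors_coordinates(self):
        from Bio.Seq import reverse_complement

        rec, _, _ = generate_dgr_contig(SimParams(seed=10))
        L = len(rec.seq)
        rc = SequenceRecord(rec.id, reverse_complement(rec.seq))
        fwd = sorted((p.tr.start, p.tr.end) for p in scan_sequence(rec))
        mirrored = sorted(
            (L - p.tr.end + 1, L - p.tr.start + 1) for p in scan_sequence(rc)
        )
        assert fwd == mirrored
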