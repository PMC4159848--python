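"""System assembly: target-gene calls, completeness labels, clustering."""

from dataclasses import replace

import numpy as np
import pytest

from dgrfinder.homology import ReferenceTRHit, find_rt_hits, find_reference_tr_hits
from dgrfinder.pairfinder import ScanParams, scan_sequence
from dgrfinder.seqio import GeneModel, Interval, ProteinRecord, SequenceRecord
from dgrfinder.simulate import (
    SimParams,
    bundled_rt_cds,
    bundled_rt_protein,
    generate_dgr_contig,
    make_tr,
    mutate_tr_to_vr,
)
from dgrfinder.systems import (
    assemble_systems,
    attach_vr_to_reference_tr,
    call_target_genes,
    cluster_by_identity,
    find_orfs,
)

from conftest import random_bases

INTERNAL = replace(ScanParams(), aligner="internal")


def _pair_on(rec):
    pairs = scan_sequence(rec)
    assert pairs
    return pairs[0]


class TestCallTargetGenes:
    def _pair_with_vr(self, vr_start, vr_end):
        """A minimal pair stand-in; target calling reads only the VR."""
        from types import SimpleNamespace

        return SimpleNamespace(vr=Interval("c", vr_start, vr_end))

    def test_vr_in_cterm_buffer_is_called(self):
        pair = self._pair_with_vr(2050, 2170)
        gene = GeneModel("g", Interval(pair.vr.seq_id, 1000, 2200, "+"))
        calls = call_target_genes(pair, [gene])
        assert len(calls) == 1
        assert calls[0].cterm_offset == 30

    def test_vr_far_from_stop_not_called(self):
        pair = self._pair_with_vr(1400, 1520)
        gene = GeneModel("g", Interval(pair.vr.seq_id, 1000, 2200, "+"))
        assert call_target_genes(pair, [gene]) == []

    def test_minus_strand_stop_end_is_left_coordinate(self):
        pair = self._pair_with_vr(1000, 1110)
        gene = GeneModel("g", Interval(pair.vr.seq_id, 1000, 2200, "-"))
        calls = call_target_genes(pair, [gene])
        assert len(calls) == 1
        assert calls[0].cterm_offset == 0

    def test_vr_overhang_past_stop_within_buffer_is_called(self):
        pair = self._pair_with_vr(2150, 2260)
        gene = GeneModel("g", Interval(pair.vr.seq_id, 1000, 2200, "+"))
        calls = call_target_genes(pair, [gene])
        assert len(calls) == 1
        assert calls[0].cterm_offset == -60


class TestAssembleSystems:
    def test_complete_system(self, sim_contig):
        rec, truth, genes = sim_contig
        refs = [ProteinRecord("rt_ref", bundled_rt_protein())]
        rt_hits = find_rt_hits(rec, refs, INTERNAL)
        pairs = scan_sequence(rec)
        systems = assemble_systems(rec, pairs, rt_hits, (), genes)
        assert len(systems) == 1
        assert systems[0].completeness == "complete"
        assert systems[0].rt is not None
        assert len(systems[0].targets) == 1

    def test_no_rt_label(self, sim_contig_no_rt):
        rec, truth, genes = sim_contig_no_rt
        systems = assemble_systems(rec, scan_sequence(rec), (), (), genes)
        assert [s.completeness for s in systems] == ["no_rt"]

    def test_rt_without_target_is_no_vr(self, sim_contig):
        rec, truth, genes = sim_contig
        refs = [ProteinRecord("rt_ref", bundled_rt_protein())]
        rt_hits = find_rt_hits(rec, refs, INTERNAL)
        systems = assemble_systems(rec, scan_sequence(rec), rt_hits, (), [])
        assert [s.completeness for s in systems] == ["no_vr"]

    def test_two_pairs_share_one_rt_core(self):
        # one RT flanked by two independent TR-VR pairs within 10 kbp
        rng_seed = 55
        bg = random_bases(30_000, seed=rng_seed)
        tr1 = make_tr(110, seed=61)
        vr1, _ = mutate_tr_to_vr(tr1, 9, 0, seed=62)
        tr2 = make_tr(110, seed=63)
        vr2, _ = mutate_tr_to_vr(tr2, 9, 0, seed=64)
        rt = bundled_rt_cds()
        seq = (
            bg[:2000] + tr1 + bg[2110:3500] + vr1
            + bg[3610:8000] + rt
            + bg[8000 + len(rt):12_000] + tr2 + bg[12_110:13_500] + vr2
            + bg[13_610:]
        )
        rec = SequenceRecord("multi", seq)
        refs = [ProteinRecord("rt_ref", bundled_rt_protein())]
        rt_hits = find_rt_hits(rec, refs, INTERNAL)
        pairs = scan_sequence(rec)
        assert len(rt_hits) == 1 and len(pairs) == 2
        systems = assemble_systems(rec, pairs, rt_hits, (), [])
        assert len(systems) == 1
        assert len(systems[0].pairs) == 2
        assert systems[0].rt is not None

    def test_unpaired_reference_hit_becomes_tr_only(self):
        rec = SequenceRecord("lone", random_bases(5000, seed=71))
        hit = ReferenceTRHit(Interval("lone", 1000, 1110), "ref", 0.95, 111)
        systems = assemble_systems(rec, [], (), [hit], [])
        assert [s.completeness for s in systems] == ["tr_only"]
        assert systems[0].system_id == "lone:DGR1"


class TestAttachVrToReferenceTr:
    def _contig_with_copies(self, n_a_subs):
        tr = make_tr(110, seed=81)
        vr, _ = mutate_tr_to_vr(tr, n_a_subs, 0, seed=82)
        bg = random_bases(8000, seed=83)
        seq = bg[:2000] + tr + bg[2110:5000] + vr + bg[5110:]
        rec = SequenceRecord("attach", seq)
        hit = ReferenceTRHit(Interval("attach", 2001, 2110), "ref", 1.0, 110)
        return rec, hit

    def test_diverged_second_copy_recovered(self):
        rec, hit = self._contig_with_copies(8)
        pair = attach_vr_to_reference_tr(rec, hit, INTERNAL)
        assert pair is not None
        assert pair.a_subs == 8
        # the adenine-bearing copy (the reference hit) is the template
        assert pair.tr.overlap_length(hit.location) / hit.location.length() >= 0.9

    def test_no_second_copy_returns_none(self):
        rec = SequenceRecord("only", random_bases(6000, seed=84))
        tr = make_tr(110, seed=85)
        rec = SequenceRecord("only", rec.seq[:2000] + tr + rec.seq[2110:])
        hit = ReferenceTRHit(Interval("only", 2001, 2110), "ref", 1.0, 110)
        assert attach_vr_to_reference_tr(rec, hit, INTERNAL) is None

    def test_exact_duplicate_fails_substitution_threshold(self):
        rec, hit = self._contig_with_copies(0)
        assert attach_vr_to_reference_tr(rec, hit, INTERNAL) is None


class TestClusterByIdentity:
    AA = "ACDEFGHIKLMNPQRSTVWY"

    def _random_protein(self, n, rng):
        return "".join(self.AA[i] for i in rng.integers(0, 20, size=n))

    def _mutated(self, seq, frac, rng):
        out = list(seq)
        for i in rng.choice(len(seq), size=max(1, int(len(seq) * frac)), replace=False):
            out[i] = self.AA[rng.integers(20)]
        return "".join(out)

    def test_identical_plus_unrelated_gives_two_clusters(self):
        rng = np.random.default_rng(91)
        a = self._random_protein(200, rng)
        b = self._random_protein(200, rng)
        clusters = cluster_by_identity(
            [ProteinRecord("a1", a), ProteinRecord("a2", a), ProteinRecord("b", b)],
            0.90,
        )
        assert len(clusters) == 2

    def test_five_percent_mutated_copy_joins_at_ninety(self):
        rng = np.random.default_rng(92)
        a = self._random_protein(300, rng)
        clusters = cluster_by_identity(
            [ProteinRecord("a", a), ProteinRecord("a5", self._mutated(a, 0.05, rng))],
            0.90,
        )
        assert len(clusters) == 1

    def test_empty_input_empty_output(self):
        assert cluster_by_identity([], 0.9) == []

    def test_every_id_in_exactly_one_cluster_and_monotone_in_threshold(self):
        rng = np.random.default_rng(93)
        base = [self._random_protein(150, rng) for _ in range(3)]
        seqs = []
        for i, b in enumerate(base):
            seqs.append(ProteinRecord(f"s{i}", b))
            seqs.append(ProteinRecord(f"s{i}m", self._mutated(b, 0.08, rng)))
        sizes = []
        for thr in (0.80, 0.90, 0.99):
            clusters = cluster_by_identity(seqs, thr)
            ids = [i for c in clusters for i in c]
            assert sorted(ids) == sorted(s.id for s in seqs)
            sizes.append(len(clusters))
        assert sizes == sorted(sizes)

    def test_nucleotide_sequences_cluster_too(self):
        tr = make_tr(120, seed=94)
        vr, _ = mutate_tr_to_vr(tr, 8, 0, seed=95)
        clusters = cluster_by_identity(
            [SequenceRecord("tr", tr), SequenceRecord("vr", vr)], 0.90
        )
        assert len(clusters) == 1


class TestFindOrfs:
    def test_implanted_rt_orf_found_on_plus_strand(self, sim_contig):
        rec, truth, _ = sim_contig
        orfs = find_orfs(rec)
        hits = [
            o
            for o in orfs
            if o.location.start == truth.rt.start and o.location.end == truth.rt.end
        ]
        assert hits and hits[0].location.strand == "+"
        assert hits[0].product == "orf_prediction"
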