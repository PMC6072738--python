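"""V/J extraction, dereplication, clustering and allele calling."""

from __future__ import annotations

import random

import pytest

from tcrprof.preprocess import SequenceRead
from tcrprof.segments import (
    AlleleCluster,
    DiscoveryConfig,
    SegmentVariant,
    call_alleles,
    dereplicate,
    discover_segments,
    extract_vj,
    frequency_filter,
    greedy_identity_cluster,
    identity,
    nearest_reference,
    split_high_frequency_members,
)
from tcrprof import simulate as sim


def read_of(seq):
    return SequenceRead(id="r", seq=seq, qual=(40,) * len(seq))


@pytest.fixture(scope="module")
def planted_read(germline_module):
    germline, truth = germline_module
    c = truth.clonotypes[0]
    seq = c.seq + germline.constant_head
    return germline, c, read_of(seq), len(c.seq)


@pytest.fixture(scope="module")
def germline_module():
    germline = sim.simulate_germline(n_v=3, n_j=2, seed=5)
    cfg = sim.SimulationConfig(n_clonotypes=20, per_base_error=0.0, seed=5)
    truth = sim.recombine(germline, cfg)
    return germline, truth


class TestExtractVj:
    def test_planted_segments_recovered_exactly(
        self, planted_read, v_pattern, j_pattern
    ):
        germline, c, read, anchor = planted_read
        res = extract_vj(read, v_pattern, j_pattern, anchor=anchor)
        assert not isinstance(res, str)
        assert res.v_seq == germline.v_segment(c.v_index)
        assert res.j_seq == germline.j_segment(c.j_index)
        start, end = res.cdr3_span
        assert read.seq[start:end] == c.cdr3_nt

    def test_single_base_deletion_disrupts_frame(
        self, planted_read, v_pattern, j_pattern
    ):
        germline, c, read, anchor = planted_read
        # delete one base inside the V region, upstream of the Cys
        mutated = read.seq[:50] + read.seq[51:]
        res = extract_vj(read_of(mutated), v_pattern, j_pattern,
                         anchor=anchor - 1)
        assert isinstance(res, str)

    def test_planted_inframe_stop_rejected_as_ptc(
        self, germline_module, v_pattern, j_pattern
    ):
        germline, truth = germline_module
        # need a CDR3 long enough that the stop lands strictly between the
        # V pattern's trailing residue and the J pattern's leading x(4)
        c = next(x for x in truth.clonotypes if len(x.cdr3_nt) >= 27)
        seq = c.seq + germline.constant_head
        start = seq.find(c.cdr3_nt)
        assert start > 0
        pos = start + 6  # third CDR3 codon, in frame with the Cys
        mutated = seq[:pos] + "TAG" + seq[pos + 3:]
        res = extract_vj(read_of(mutated), v_pattern, j_pattern,
                         anchor=len(c.seq))
        assert res == "ptc"

    def test_patternless_read_rejected(self, v_pattern, j_pattern):
        res = extract_vj(read_of("ACGT" * 40), v_pattern, j_pattern)
        assert res == "no_v_pattern"


class TestDereplicate:
    def test_depth_and_frequency(self):
        variants = dereplicate(["A", "A", "B"])
        assert [(v.seq, v.depth) for v in variants] == [("A", 2), ("B", 1)]
        assert variants[0].frequency == pytest.approx(2 / 3)
        assert sum(v.depth for v in variants) == 3

    def test_all_distinct(self):
        variants = dereplicate([f"S{i}" for i in range(7)])
        assert len(variants) == 7
        assert all(v.depth == 1 for v in variants)

    def test_depth_order_tracks_sampling_probability(self):
        rng = random.Random(0)
        pool = rng.choices(["AAA", "CCC", "GGG"], weights=[.7, .2, .1],
                           k=10_000)
        variants = dereplicate(pool)
        assert [v.seq for v in variants] == ["AAA", "CCC", "GGG"]


class TestFrequencyFilter:
    def test_boundary_is_inclusive(self):
        total = 1_000_000
        variants = [
            SegmentVariant("KEEP", 100, 100 / total),
            SegmentVariant("DROP", 99, 99 / total),
        ]
        kept = frequency_filter(variants, 0.0001)
        assert [v.seq for v in kept] == ["KEEP"]

    def test_threshold_above_all_empties(self):
        variants = dereplicate(["A", "B"])
        assert frequency_filter(variants, 0.9) == []

    def test_survivors_meet_depth_floor(self):
        # brute-force check of the depth implied by the frequency bound
        rng = random.Random(2)
        pool = [f"S{rng.randint(0, 30)}" for _ in range(2000)]
        variants = dereplicate(pool)
        kept = frequency_filter(variants, 0.02)
        assert all(v.depth >= 0.02 * 2000 for v in kept)


def brute_force_greedy(seqs_by_depth, threshold):
    """Independent re-implementation of the greedy rule (oracle)."""
    reps: list[str] = []
    assignment = {}
    for seq in seqs_by_depth:
        for rep in reps:
            if identity(seq, rep) >= threshold:
                assignment[seq] = rep
                break
        else:
            reps.append(seq)
            assignment[seq] = seq
    return assignment


class TestClustering:
    def sub(self, seq, k, rng):
        pos = rng.sample(range(len(seq)), k)
        out = list(seq)
        for p in pos:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)

    def test_hand_example_hamming_identities(self):
        rng = random.Random(4)
        s1 = "".join(rng.choice("ACGT") for _ in range(20))
        s2 = self.sub(s1, 1, rng)   # 19/20 = 95%
        s3 = self.sub(s1, 3, rng)   # 17/20 = 85%
        variants = [SegmentVariant(s1, 100, .625),
                    SegmentVariant(s2, 50, .3125),
                    SegmentVariant(s3, 10, .0625)]
        clusters = greedy_identity_cluster(variants, 0.95)
        members = sorted(tuple(sorted(m.seq for m in c.members))
                         for c in clusters)
        assert members == sorted([tuple(sorted([s1, s2])), (s3,)])

    def test_singleton_and_degenerate_threshold(self):
        v = dereplicate(["ACGT"])
        assert len(greedy_identity_cluster(v, 0.95)) == 1
        many = dereplicate(["AAAA", "CCCC", "GGGG", "TTTT"])
        assert len(greedy_identity_cluster(many, 0.0)) == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_brute_force_on_toy_sets(self, trial):
        rng = random.Random(trial)
        base = "".join(rng.choice("ACGT") for _ in range(30))
        seqs = [base] + [
            self.sub(base, rng.randint(1, 6), rng)
            for _ in range(rng.randint(2, 9))
        ]
        seqs = list(dict.fromkeys(seqs))
        depths = sorted(rng.sample(range(1, 200), len(seqs)), reverse=True)
        total = sum(depths)
        variants = [SegmentVariant(s, d, d / total)
                    for s, d in zip(seqs, depths)]
        threshold = rng.choice([0.85, 0.9, 0.95])
        clusters = greedy_identity_cluster(variants, threshold)
        oracle = brute_force_greedy([v.seq for v in variants], threshold)
        ours = {m.seq: c.representative.seq
                for c in clusters for m in c.members}
        assert ours == oracle
        for c in clusters:
            for m in c.members:
                assert identity(m.seq, c.representative.seq) >= threshold

    def test_depth_conservation_through_clustering(self):
        rng = random.Random(9)
        variants = dereplicate(
            [rng.choice(["AAAA", "AAAT", "CCCC"]) for _ in range(500)])
        clusters = greedy_identity_cluster(variants, 0.9)
        assert sum(c.total_depth for c in clusters) == 500


class TestSplitRule:
    def cluster(self, depths):
        total = sum(depths)
        members = [SegmentVariant(f"S{i}", d, d / total)
                   for i, d in enumerate(depths)]
        return AlleleCluster(representative=members[0], members=members)

    def test_member_above_twenty_percent_splits(self):
        out = split_high_frequency_members([self.cluster([100, 30])], 0.20)
        assert len(out) == 2  # 30/130 = 23.1% > 20%

    def test_member_below_threshold_stays(self):
        out = split_high_frequency_members([self.cluster([100, 20])], 0.20)
        assert len(out) == 1  # 20/120 = 16.7%

    def test_singleton_unchanged(self):
        out = split_high_frequency_members([self.cluster([100])], 0.20)
        assert len(out) == 1

    def test_reaches_fixed_point(self):
        # {100, 40, 35}: both minors exceed 20% in turn
        out = split_high_frequency_members([self.cluster([100, 40, 35])], 0.2)
        again = split_high_frequency_members(out, 0.2)
        assert len(out) == len(again) == 3
        depth_sets = sorted(c.total_depth for c in out)
        assert depth_sets == [35, 40, 100]


class TestCallAlleles:
    def test_representatives_become_alleles(self):
        rng = random.Random(4)
        s1 = "".join(rng.choice("ACGT") for _ in range(20))
        clusters = [
            AlleleCluster(SegmentVariant(s1, 100, 0.9),
                          [SegmentVariant(s1, 100, 0.9)], "V"),
            AlleleCluster(SegmentVariant("ACGT" * 5, 10, 0.1),
                          [SegmentVariant("ACGT" * 5, 10, 0.1)], "V"),
        ]
        alleles = call_alleles(clusters)
        assert [s for _, s in alleles] == [s1, "ACGT" * 5]
        assert [n for n, _ in alleles] == ["V001", "V002"]

    def test_empty_cluster_list(self):
        assert call_alleles([]) == []

    def test_error_free_simulation_recovers_planted_alleles(
        self, germline_module, v_pattern, j_pattern
    ):
        germline, truth = germline_module
        # expand clonotypes into error-free "reads", extract, discover
        extractions = []
        for c in truth.clonotypes:
            read = read_of(c.seq + germline.constant_head)
            for _ in range(5):
                res = extract_vj(read, v_pattern, j_pattern,
                                 anchor=len(c.seq))
                assert not isinstance(res, str)
                extractions.append(res)
        va, ja, _, _ = discover_segments(
            extractions,
            DiscoveryConfig(v_min_freq=0.01, j_min_freq=0.01),
        )
        assert {s for _, s in va} == {
            germline.v_segment(i) for i in range(len(germline.v_alleles))}
        assert {s for _, s in ja} == {
            germline.j_segment(i) for i in range(len(germline.j_alleles))}


class TestNearestReference:
    REFS = [("TRBV1", "ACGTACGTACGTACGTACGT"),
            ("TRBV2", "TTTTACGTACGTACGTAAAA")]

    def test_identical_hit(self):
        name, ident = nearest_reference(self.REFS[0][1], self.REFS)
        assert (name, ident) == ("TRBV1", 1.0)

    def test_single_substitution_identity(self):
        query = "ACGTACGTACGTACGTACGA"
        name, ident = nearest_reference(query, self.REFS)
        assert name == "TRBV1"
        assert ident == pytest.approx(0.95)

    def test_tie_breaks_lexicographically(self):
        refs = [("B", "AAAA"), ("A", "AAAA")]
        name, ident = nearest_reference("AAAA", refs)
        assert (name, ident) == ("A", 1.0)

    def test_empty_refs_error(self):
        with pytest.raises(ValueError):
            nearest_reference("ACGT", [])
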