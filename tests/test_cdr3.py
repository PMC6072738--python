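"""Annotation, CDR3 boundary location and functionality filtering."""

from __future__ import annotations

import pytest

from tcrprof.cdr3 import (
    Annotation,
    AnnotationConfig,
    Cdr3Span,
    SegmentHit,
    annotate_segments,
    extract_cdr3_records,
    filter_cdr3,
    locate_cdr3,
)
from tcrprof.preprocess import SequenceRead, revcomp


def read_of(seq, **kw):
    return SequenceRead(id="r", seq=seq, qual=(40,) * len(seq), **kw)


@pytest.mark.parametrize("backend", ["infix", "local"])
class TestAnnotate:
    def test_exact_copy_is_assigned_at_full_identity(
        self, germline_refs, backend
    ):
        v_refs, j_refs = germline_refs
        name, ref = v_refs[1]
        ann = annotate_segments(
            read_of("ACGTAC" + ref + "GGATCC"), v_refs, j_refs,
            AnnotationConfig(aligner_backend=backend))
        assert ann.v_allele == name
        assert ann.v.identity == pytest.approx(1.0)

    def test_two_mismatches_over_long_segment_still_assigned(
        self, germline_refs, backend
    ):
        v_refs, j_refs = germline_refs
        name, ref = v_refs[0]
        mutated = list(ref)
        mutated[10] = "A" if ref[10] != "A" else "C"
        mutated[40] = "A" if ref[40] != "A" else "C"
        ann = annotate_segments(
            read_of("".join(mutated)), v_refs, j_refs,
            AnnotationConfig(aligner_backend=backend))
        assert ann.v_allele == name
        assert ann.v.identity > 0.99 - 2 / len(ref)

    def test_below_identity_threshold_unassigned(self, germline_refs, backend):
        v_refs, j_refs = germline_refs
        _, ref = j_refs[0]
        # mutate ~1 in 5 positions: identity ~80% < 90%
        mutated = "".join(
            ("A" if b != "A" else "C") if i % 5 == 0 else b
            for i, b in enumerate(ref)
        )
        ann = annotate_segments(read_of(mutated + "GG" * 10), [], j_refs,
                                AnnotationConfig(aligner_backend=backend))
        assert ann.j_allele == "unassigned"

    def test_identity_symmetric_under_reorientation(
        self, germline_refs, backend
    ):
        v_refs, j_refs = germline_refs
        _, ref = v_refs[0]
        seq = "ACGTAC" + ref + "GGATCC"
        cfg = AnnotationConfig(aligner_backend=backend)
        fwd = annotate_segments(read_of(seq), v_refs, j_refs, cfg)
        rev = annotate_segments(
            read_of(revcomp(seq)).reverse_complement(), v_refs, j_refs, cfg)
        assert fwd.v.identity == pytest.approx(rev.v.identity)


class TestLocateCdr3:
    def test_full_length_mode_hand_example(self):
        # layout: prefix | CDR3 "TGTGCCAGCAGTTTT" | J starting at its Gly
        prefix = "AAACCC"
        cdr3 = "TGTGCCAGCAGTTTT"
        j_tail = "GGCCAAGGCACCAGACTCACAGTT"
        seq = prefix + cdr3 + j_tail
        j_hit = SegmentHit(name="J001", identity=1.0, score=0,
                           read_start=len(prefix) + len(cdr3),
                           read_end=len(seq), ref_start=0)
        ann = Annotation(v=None, j=j_hit)
        span = locate_cdr3(read_of(seq), ann, anchor=None, mode="full")
        assert isinstance(span, Cdr3Span)
        assert seq[span.start:span.end] == cdr3

    def test_umi_mode_fixed_offset_ignores_j(self):
        cdr3 = "TGTGCCAGCAGTTTT"
        tail = "G" * 31
        seq = "AAA" + cdr3 + tail + "TGCTCAGATCCT"
        anchor = seq.find("TGCTCAGATCCT")
        span = locate_cdr3(read_of(seq), None, anchor=anchor, mode="umi")
        assert isinstance(span, Cdr3Span)
        assert span.end == anchor - 31
        assert seq[span.start:span.end] == cdr3

    def test_no_cys_motif_fails(self):
        seq = "AAACCCGGG" + "G" * 31
        span = locate_cdr3(read_of(seq), None, anchor=len(seq), mode="umi")
        assert span == "no_cys_motif"

    def test_last_cys_occurrence_wins(self):
        # two valid Cys contexts; the downstream one starts the CDR3
        cdr3 = "TGTGCCAGCAGTTTT"
        seq = "TGTGCA" + "AAA" + cdr3 + "G" * 31
        span = locate_cdr3(read_of(seq), None, anchor=len(seq), mode="umi")
        assert isinstance(span, Cdr3Span)
        assert seq[span.start:span.end] == cdr3

    def test_motif_crossing_junction_is_ignored(self):
        cdr3 = "TGTGCCAGCAGTTTT"
        decoy_left, decoy_right = "TGT", "GCAGA"  # TGTGC spans the joint
        seq = cdr3[:6] + decoy_left + decoy_right + cdr3[6:] + "G" * 31
        junction = 6 + len(decoy_left)
        span = locate_cdr3(
            read_of(seq, junction=junction), None, anchor=len(seq),
            mode="umi")
        # the decoy motif crossing the junction must not set the boundary
        if isinstance(span, Cdr3Span):
            assert not (span.start < junction < span.start + 5)

    def test_inverted_boundaries_fail(self):
        seq = "TGTGCC" + "G" * 4
        span = locate_cdr3(read_of(seq), None, anchor=5, mode="umi")
        assert span == "inverted"


class TestFilterCdr3:
    CASES = [
        ("TGTGCCAGCAGTTT", "too_short"),            # 14 nt
        ("TGTGCCAGCAGTTTT", "pass"),                # 15 nt in frame
        ("TGTGCCAGCAGTTTTG", "frameshift"),         # 16 nt
        ("TGTGCCAGCAGTGGCGGGAGCAGTTCAGGGAGCAGTTCAGGGAGCAGTTCATTT",
         "pass"),                                   # 54 nt inclusive
        ("TGTTAGGCCGGGTTT", "ptc"),                 # in-frame TAG
        ("TGT" * 19, "too_long"),                   # 57 nt
    ]

    @pytest.mark.parametrize("cdr3,verdict", CASES)
    def test_rejection_pattern(self, cdr3, verdict):
        assert filter_cdr3(cdr3) == verdict


class TestExtractRecords:
    def test_error_free_simulation_matches_truth_multiset(
        self, small_simulation, germline_refs, germline
    ):
        cfg, truth, replicates = small_simulation
        v_refs, j_refs = germline_refs
        reads = replicates[0]
        anchored = []
        for r in reads:
            pos = r.seq.rfind("TGCTCAGATCCT")
            assert pos >= 0
            anchored.append((r, pos))
        records, rejections = extract_cdr3_records(
            anchored, v_refs, j_refs, umi_len=12, mode="umi")
        assert sum(rejections.values()) == 0
        truth_by_id = {c.id: c for c in truth.clonotypes}
        read_truth = {rt.read_id: rt for rt in truth.reads}
        for rec in records:
            t = truth_by_id[read_truth[rec.read_id].clonotype_id]
            assert rec.cdr3_nt == t.cdr3_nt
            assert rec.umi == read_truth[rec.read_id].umi
            assert rec.v_allele == f"V{t.v_index + 1:03d}"
            assert rec.j_allele == f"J{t.j_index + 1:03d}"

    def test_empty_input(self, germline_refs):
        v_refs, j_refs = germline_refs
        records, rejections = extract_cdr3_records([], v_refs, j_refs)
        assert records == [] and sum(rejections.values()) == 0

    def test_full_and_umi_modes_agree_when_tail_is_offset_long(
        self, small_simulation, germline_refs
    ):
        # germline J tails are exactly 31 nt, so the fixed-offset boundary
        # and the J-reference boundary must coincide
        cfg, truth, replicates = small_simulation
        v_refs, j_refs = germline_refs
        taken = 0
        for r in replicates[0][:40]:
            pos = r.seq.rfind("TGCTCAGATCCT")
            payload = SequenceRead(id=r.id, seq=r.seq[12:], qual=r.qual[12:])
            umi_span = locate_cdr3(payload, None, anchor=pos - 12, mode="umi")
            ann = annotate_segments(payload, v_refs, j_refs)
            full_span = locate_cdr3(payload, ann, anchor=None, mode="full")
            assert isinstance(umi_span, Cdr3Span)
            assert isinstance(full_span, Cdr3Span)
            assert (umi_span.start, umi_span.end) == (
                full_span.start, full_span.end)
            taken += 1
        assert taken == 40
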