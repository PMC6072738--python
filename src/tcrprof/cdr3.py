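"""CDR3 clonotype extraction: annotation, boundary location, filtering.

Reads are annotated by local alignment against the discovered V/J allele
references (>90% identity contract); the CDR3 is delimited by the
conserved-Cys nucleotide motif ``TG[TC]`` followed by ``[GA][CG]`` on the
V side and, on the J side, either the conserved-Gly codon of the J
reference (full-length mode) or a fixed offset upstream of the
constant-region anchor (short-read/UMI mode). Extracted CDR3s are filtered
for functionality: 15-54 nt, a codon multiple, and stop-free.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from Bio import Align

from tcrprof.motif import translate
from tcrprof.preprocess import SequenceRead

#: Conserved-Cys context: the Cys codon TG[TC] immediately followed by the
#: [GA][CG] start of the next CDR3 codon.
CYS_MOTIF = re.compile(r"TG[TC](?=[GA][CG])")


@dataclass
class AnnotationConfig:
    """Thresholds of the annotation and CDR3-filtering stage.

    min_identity:
        a segment is annotated only when locally aligned at strictly more
        than this identity to some reference (default 0.90).
    cdr3_min_nt / cdr3_max_nt:
        inclusive functional CDR3 length bounds (default 15-54 nt,
        i.e. 5-18 residues).
    constant_offset_nt:
        in short-read/UMI mode the CDR3 3' boundary is fixed this many nt
        upstream of the constant-region anchor (default 31).
    """

    min_identity: float = 0.90
    top_k: int = 2
    cdr3_min_nt: int = 15
    cdr3_max_nt: int = 54
    constant_offset_nt: int = 31
    aligner_backend: Literal["infix", "local"] = "infix"
    match_score: float = 2.0
    mismatch_score: float = -3.0
    open_gap_score: float = -5.0
    extend_gap_score: float = -2.0

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0,1]")
        if self.cdr3_min_nt > self.cdr3_max_nt:
            raise ValueError("cdr3_min_nt must be <= cdr3_max_nt")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = self.open_gap_score
        aligner.extend_gap_score = self.extend_gap_score
        return aligner


@dataclass(frozen=True)
class SegmentHit:
    """One local-alignment hit of a reference segment on a read."""

    name: str
    identity: float
    score: float
    read_start: int
    read_end: int
    ref_start: int  # reference coordinate aligned at read_start

    @property
    def ref_origin_on_read(self) -> int:
        """Read coordinate corresponding to reference position 0."""
        return self.read_start - self.ref_start


@dataclass(frozen=True)
class Annotation:
    v: Optional[SegmentHit]
    j: Optional[SegmentHit]
    v_candidates: tuple[SegmentHit, ...] = ()
    j_candidates: tuple[SegmentHit, ...] = ()

    @property
    def v_allele(self) -> str:
        return self.v.name if self.v else "unassigned"

    @property
    def j_allele(self) -> str:
        return self.j.name if self.j else "unassigned"


@dataclass(frozen=True)
class Cdr3Record:
    """One extracted CDR3 with its annotation and provenance."""

    cdr3_nt: str
    cdr3_aa: str
    v_allele: str
    j_allele: str
    read_id: str
    umi: Optional[str] = None


Cdr3Filter = Literal["pass", "too_short", "too_long", "frameshift", "ptc"]


def _align_hits(
    read_seq: str,
    refs: Sequence[tuple[str, str]],
    cfg: AnnotationConfig,
) -> list[SegmentHit]:
    """Align every reference locally against the read; rank by score.

    Ranking uses the alignment score (edit distance for the infix
    backend), never identity alone: a local alignment of the wrong
    reference can reach 100% identity over a trivially short stretch.
    Identity over the aligned columns is then the annotation threshold.
    """
    if cfg.aligner_backend == "infix":
        return _align_hits_infix(read_seq, refs)
    return _align_hits_local(read_seq, refs, cfg)


def _align_hits_infix(
    read_seq: str, refs: Sequence[tuple[str, str]]
) -> list[SegmentHit]:
    import edlib

    hits: list[SegmentHit] = []
    for name, ref in refs:
        res = edlib.align(ref, read_seq, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        cigar = res["cigar"]
        columns = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                columns += int(num)
                num = ""
        if columns == 0:
            continue
        ident = (columns - res["editDistance"]) / columns
        start, last = res["locations"][0]
        hits.append(
            SegmentHit(name=name, identity=ident, score=-res["editDistance"],
                       read_start=int(start), read_end=int(last) + 1,
                       ref_start=0)
        )
    hits.sort(key=lambda h: (-h.score, -h.identity, h.name))
    return hits


def _align_hits_local(
    read_seq: str, refs: Sequence[tuple[str, str]], cfg: AnnotationConfig
) -> list[SegmentHit]:
    aligner = cfg.aligner()
    hits: list[SegmentHit] = []
    for name, ref in refs:
        alignments = aligner.align(read_seq, ref)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        if columns == 0:
            continue
        ident = counts.identities / columns
        read_start = int(aln.aligned[0][0][0])
        read_end = int(aln.aligned[0][-1][1])
        ref_start = int(aln.aligned[1][0][0])
        hits.append(SegmentHit(name=name, identity=ident,
                               score=float(aln.score),
                               read_start=read_start, read_end=read_end,
                               ref_start=ref_start))
    hits.sort(key=lambda h: (-h.score, -h.identity, h.name))
    return hits


def annotate_segments(
    read: SequenceRead,
    v_refs: Sequence[tuple[str, str]],
    j_refs: Sequence[tuple[str, str]],
    cfg: Optional[AnnotationConfig] = None,
) -> Annotation:
    """Annotate a read's V and J segments by local alignment.

    Per class the hits are ranked by alignment score and the best-scoring
    hit is assigned only when its identity over the aligned columns is
    strictly above ``min_identity``; otherwise the class is unassigned.
    Up to ``top_k`` candidates are retained for reporting.
    """
    cfg = cfg or AnnotationConfig()

    def pick(refs):
        hits = _align_hits(read.seq, refs, cfg)[:cfg.top_k]
        best = hits[0] if hits and hits[0].identity > cfg.min_identity \
            else None
        return best, tuple(hits)

    v_best, v_hits = pick(v_refs)
    j_best, j_hits = pick(j_refs)
    return Annotation(v=v_best, j=j_best,
                      v_candidates=v_hits, j_candidates=j_hits)


@dataclass(frozen=True)
class Cdr3Span:
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


LocateFailure = Literal["no_cys_motif", "no_j_boundary", "inverted"]


def locate_cdr3(
    read: SequenceRead,
    annotation: Optional[Annotation],
    anchor: Optional[int],
    cfg: Optional[AnnotationConfig] = None,
    mode: Literal["full", "umi"] = "full",
) -> Cdr3Span | str:
    """Locate the CDR3 nucleotide span on an oriented read.

    5' boundary: start of the *last* conserved-Cys motif occurrence
    (``TG[TC]`` followed by ``[GA][CG]``) upstream of the 3' boundary,
    searched within/near the aligned V span when available; the CDR3
    includes this Cys codon. 3' boundary: in ``full`` mode the read
    position of the J reference origin (the conserved-Gly codon, since
    discovered J alleles are trimmed at the CDR3 border); in ``umi`` mode
    fixed ``constant_offset_nt`` upstream of the constant-region anchor.
    Returns a failure reason string when a boundary cannot be placed.
    """
    cfg = cfg or AnnotationConfig()
    if mode == "umi":
        if anchor is None:
            return "no_j_boundary"
        end = anchor - cfg.constant_offset_nt
    else:
        if annotation is None or annotation.j is None:
            return "no_j_boundary"
        end = annotation.j.ref_origin_on_read
    if end <= 0:
        return "inverted"
    search_start = 0
    if annotation is not None and annotation.v is not None:
        search_start = annotation.v.read_start
    region = read.seq[search_start:end + 2]  # +2: the [GA][CG] context may
    # extend past the boundary only via lookahead; motif start must fit
    starts = [
        search_start + m.start()
        for m in CYS_MOTIF.finditer(region)
        if search_start + m.start() + 3 <= end
        and not _spans_junction(read, search_start + m.start())
    ]
    if not starts:
        return "no_cys_motif"
    start = starts[-1]
    if start >= end:
        return "inverted"
    return Cdr3Span(start=start, end=end)


def _spans_junction(read: SequenceRead, motif_start: int) -> bool:
    # the 5-nt Cys context must not cross a concatenation junction
    if read.junction is None:
        return False
    return motif_start < read.junction < motif_start + 5


def filter_cdr3(cdr3_nt: str, cfg: Optional[AnnotationConfig] = None) -> Cdr3Filter:
    """Functional-CDR3 filter: length bounds, frame, premature stops.

    Pass iff 15 <= len <= 54 (inclusive), len is a codon multiple, and the
    translation contains no stop.
    """
    cfg = cfg or AnnotationConfig()
    n = len(cdr3_nt)
    if n < cfg.cdr3_min_nt:
        return "too_short"
    if n > cfg.cdr3_max_nt:
        return "too_long"
    if n % 3 != 0:
        return "frameshift"
    if "*" in translate(cdr3_nt):
        return "ptc"
    return "pass"


def extract_cdr3_records(
    reads: Iterable[tuple[SequenceRead, int]],
    v_refs: Sequence[tuple[str, str]],
    j_refs: Sequence[tuple[str, str]],
    cfg: Optional[AnnotationConfig] = None,
    umi_len: Optional[int] = None,
    mode: Literal["full", "umi"] = "full",
) -> tuple[list[Cdr3Record], Counter]:
    """Annotate → locate → filter for a stream of (oriented read, anchor).

    When ``umi_len`` is given the leading UMI is stripped from each read
    before annotation and carried on the record. Failures never raise; they
    are tallied per reason in the returned counter.
    """
    from tcrprof.umi import extract_umi  # local import: avoid cycle

    cfg = cfg or AnnotationConfig()
    records: list[Cdr3Record] = []
    rejections: Counter = Counter()
    for read, anchor in reads:
        umi = None
        if umi_len:
            pulled = extract_umi(read, umi_len)
            if pulled is None:
                rejections["umi_failed"] += 1
                continue
            umi, read = pulled
            anchor -= umi_len
        annotation = annotate_segments(read, v_refs, j_refs, cfg)
        span = locate_cdr3(read, annotation, anchor, cfg, mode=mode)
        if isinstance(span, str):
            rejections[span] += 1
            continue
        cdr3_nt = read.seq[span.start:span.end]
        verdict = filter_cdr3(cdr3_nt, cfg)
        if verdict != "pass":
            rejections[verdict] += 1
            continue
        records.append(
            Cdr3Record(
                cdr3_nt=cdr3_nt,
                cdr3_aa=translate(cdr3_nt),
                v_allele=annotation.v_allele,
                j_allele=annotation.j_allele,
                read_id=read.id,
                umi=umi,
            )
        )
    return records, rejections
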