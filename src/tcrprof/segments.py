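"""Reference-free discovery of V and J segment alleles from amplicon reads.

Full-variable-region reads that passed preprocessing are screened for the
conserved V and J residue patterns in a single stop-free reading frame;
reads with unspliced introns, frameshift indels or premature termination
codons fail this screen and are rejected with a typed reason. Extracted V
and J nucleotide segments (trimmed at the CDR3 border) are dereplicated,
frequency-filtered against sequencing/PCR artefacts, clustered greedily at
a class-specific identity threshold (CD-HIT style), and the major variant
of each cluster is called as a putative allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import edlib

from tcrprof.motif import ProteinPattern, find_pattern, translate
from tcrprof.preprocess import SequenceRead

RejectionReason = Literal[
    "no_v_pattern", "no_j_pattern", "frame_conflict", "ptc",
    "frameshift_or_intron",
]


@dataclass(frozen=True)
class VjExtraction:
    """V/J segments extracted from one read, trimmed at the CDR3 border.

    ``v_seq`` ends at the base before the conserved-Cys codon; ``j_seq``
    begins at the conserved-Gly codon and runs to the constant-region
    anchor. ``cdr3_span`` is the half-open nt span between them (the CDR3,
    Cys included).
    """

    v_seq: str
    j_seq: str
    cdr3_span: tuple[int, int]
    frame: int


@dataclass
class SegmentVariant:
    """A dereplicated V or J nucleotide variant with its sequencing depth."""

    seq: str
    depth: int
    frequency: float

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must be in (0, 1]")


@dataclass
class AlleleCluster:
    """A greedy identity cluster; the representative is the major variant."""

    representative: SegmentVariant
    members: list[SegmentVariant]
    seg_class: Literal["V", "J"] = "V"

    @property
    def total_depth(self) -> int:
        return sum(m.depth for m in self.members)


@dataclass
class DiscoveryConfig:
    """Frequency and identity thresholds of the allele-discovery stage.

    Defaults follow the minimum rare-allele frequencies and inter-locus
    similarity observed in human/mouse: V variants below 0.01% and J below
    0.1% are treated as artefacts; clustering identity is 95% for V and 85%
    for J; within-cluster members above 20% frequency are split off as
    probable true alleles.
    """

    v_min_freq: float = 0.0001
    j_min_freq: float = 0.001
    v_cluster_identity: float = 0.95
    j_cluster_identity: float = 0.85
    split_within_freq: float = 0.20

    def __post_init__(self) -> None:
        for name in (
            "v_min_freq", "j_min_freq", "v_cluster_identity",
            "j_cluster_identity", "split_within_freq",
        ):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1)")


def extract_vj(
    read: SequenceRead,
    v_pattern: ProteinPattern,
    j_pattern: ProteinPattern,
    anchor: Optional[int] = None,
) -> VjExtraction | str:
    """Extract V and J segments from an oriented full-variable-region read.

    Both patterns must occur in the same reading frame, J downstream of the
    conserved V cysteine, with no stop codon from the V-pattern start
    through the J-pattern end. On failure returns the rejection reason:
    ``no_v_pattern``, ``no_j_pattern``, ``ptc`` (in-frame stop between the
    patterns) or ``frameshift_or_intron`` (patterns found only in
    different frames — the common signature of indels and unspliced
    introns).
    """
    end = anchor if anchor is not None else len(read.seq)
    region = read.seq[:end]
    saw_v = False
    saw_ptc = False
    j_frames: set[int] = set()
    v_frames: set[int] = set()
    for frame in (0, 1, 2):
        aa = translate(region, frame)
        if find_pattern(aa, j_pattern, mode="first"):
            j_frames.add(frame)
        v_spans = find_pattern(aa, v_pattern, mode="first")
        if not v_spans:
            continue
        saw_v = True
        v_frames.add(frame)
        v_s, v_e = v_spans[0]
        cys_aa = v_e - 2  # pattern ends ...-C-x
        j_spans = find_pattern(aa, j_pattern, mode="first", start=cys_aa + 1)
        if not j_spans:
            continue
        j_s, j_e = j_spans[0]
        if "*" in aa[v_s:j_e]:
            saw_ptc = True
            continue
        cys_nt = frame + 3 * cys_aa
        gly_nt = frame + 3 * (j_s + 4)  # J pattern: x(4)-G-...
        return VjExtraction(
            v_seq=region[frame + 3 * v_s: cys_nt],
            j_seq=region[gly_nt:end],
            cdr3_span=(cys_nt, gly_nt),
            frame=frame,
        )
    if not saw_v:
        return "no_v_pattern"
    if saw_ptc:
        return "ptc"
    if j_frames - v_frames:
        return "frameshift_or_intron"
    return "no_j_pattern"


def dereplicate(segments: Iterable[str]) -> list[SegmentVariant]:
    """Group exact sequences into variants, ordered by depth descending.

    Depth ties are broken lexicographically by sequence for determinism.
    Frequencies are relative to the total input count.
    """
    counts = Counter(segments)
    total = sum(counts.values())
    variants = [
        SegmentVariant(seq=s, depth=d, frequency=d / total)
        for s, d in counts.items()
    ]
    variants.sort(key=lambda v: (-v.depth, v.seq))
    return variants


def frequency_filter(
    variants: Sequence[SegmentVariant], min_freq: float
) -> list[SegmentVariant]:
    """Keep variants with frequency >= min_freq (strictly-rarer removed)."""
    return [v for v in variants if v.frequency >= min_freq]


def identity(a: str, b: str, mode: Literal["global", "infix"] = "global") -> float:
    """Pairwise identity: matches / alignment columns of a global alignment.

    For equal-length sequences this reduces to 1 - Hamming/len. ``infix``
    aligns the shorter sequence end-gap-free within the longer (used for
    the short J segments).
    """
    if not a or not b:
        return 0.0
    if mode == "infix":
        query, target = (a, b) if len(a) <= len(b) else (b, a)
        res = edlib.align(query, target, mode="HW", task="path")
    else:
        res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    matches = columns - res["editDistance"]
    return matches / columns if columns else 0.0


def greedy_identity_cluster(
    variants: Sequence[SegmentVariant],
    min_identity: float,
    seg_class: Literal["V", "J"] = "V",
    alignment_mode: Literal["global", "infix"] = "global",
) -> list[AlleleCluster]:
    """CD-HIT-style greedy clustering of depth-sorted variants.

    Each variant (in depth order) joins the first existing cluster whose
    representative it matches at >= ``min_identity``; otherwise it founds a
    new cluster with itself as representative.
    """
    clusters: list[AlleleCluster] = []
    for var in variants:
        for cluster in clusters:
            if identity(var.seq, cluster.representative.seq,
                        mode=alignment_mode) >= min_identity:
                cluster.members.append(var)
                break
        else:
            clusters.append(
                AlleleCluster(representative=var, members=[var],
                              seg_class=seg_class)
            )
    return clusters


def split_high_frequency_members(
    clusters: Sequence[AlleleCluster], split_within_freq: float = 0.20
) -> list[AlleleCluster]:
    """Split off members with within-cluster frequency above the threshold.

    True but similar alleles co-clustered with a dominant variant carry a
    disproportionate share of their cluster's depth; every non-representative
    member whose depth exceeds ``split_within_freq`` of its cluster total is
    moved out to found its own cluster. The highest-frequency offender moves
    first and the rule is re-applied until a fixed point.
    """
    result = [
        AlleleCluster(representative=c.representative, members=list(c.members),
                      seg_class=c.seg_class)
        for c in clusters
    ]
    changed = True
    while changed:
        changed = False
        for cluster in result:
            if len(cluster.members) < 2:
                continue
            total = cluster.total_depth
            offenders = [
                m for m in cluster.members
                if m is not cluster.representative
                and m.depth / total > split_within_freq
            ]
            if not offenders:
                continue
            mover = max(offenders, key=lambda m: (m.depth, m.seq))
            cluster.members.remove(mover)
            result.append(
                AlleleCluster(representative=mover, members=[mover],
                              seg_class=cluster.seg_class)
            )
            changed = True
            break
    return result


def call_alleles(clusters: Sequence[AlleleCluster]) -> list[tuple[str, str]]:
    """One allele per cluster: the representative, deterministically named.

    Names are ``{class}{rank:03d}`` with rank by representative depth
    (ties lexicographic by sequence).
    """
    ordered = sorted(
        clusters,
        key=lambda c: (-c.representative.depth, c.representative.seq),
    )
    return [
        (f"{c.seg_class}{i + 1:03d}", c.representative.seq)
        for i, c in enumerate(ordered)
    ]


def nearest_reference(
    allele: str, refs: Sequence[tuple[str, str]]
) -> tuple[str, float]:
    """Best global-alignment identity against a set of named references.

    Ties are broken by lexicographic reference name. Raises on empty refs.
    """
    if not refs:
        raise ValueError("reference set is empty")
    best_name, best_id = None, -1.0
    for name, seq in sorted(refs):
        ident = identity(allele, seq, mode="global")
        if ident > best_id:
            best_name, best_id = name, ident
    return best_name, best_id


def discover_segments(
    extractions: Iterable[VjExtraction],
    cfg: Optional[DiscoveryConfig] = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]],
           list[AlleleCluster], list[AlleleCluster]]:
    """Run the full dereplicate→filter→cluster→split→call chain.

    Returns (v_alleles, j_alleles, v_clusters, j_clusters).
    """
    cfg = cfg or DiscoveryConfig()
    extractions = list(extractions)
    v_variants = frequency_filter(
        dereplicate(e.v_seq for e in extractions if e.v_seq), cfg.v_min_freq
    )
    j_variants = frequency_filter(
        dereplicate(e.j_seq for e in extractions if e.j_seq), cfg.j_min_freq
    )
    v_clusters = split_high_frequency_members(
        greedy_identity_cluster(v_variants, cfg.v_cluster_identity, "V"),
        cfg.split_within_freq,
    )
    j_clusters = split_high_frequency_members(
        greedy_identity_cluster(j_variants, cfg.j_cluster_identity, "J",
                                alignment_mode="infix"),
        cfg.split_within_freq,
    )
    return (call_alleles(v_clusters), call_alleles(j_clusters),
            v_clusters, j_clusters)
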