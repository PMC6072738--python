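"""Read-level preprocessing of 5'RACE TCRβ amplicon libraries.

Covers the four read-level contracts of the workflow: overlap merging of
paired MiSeq reads (FLASH-like), head-to-tail concatenation of
non-overlapping HiSeq pairs, mean-Phred quality filtering, and
orientation-normalising constant-region primer anchoring — plus seeded
reservoir subsampling so that amplicons of different depth are comparable.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Last 12 nt of the constant-region nested primer (MyglTCRb_3,
#: GGACTCACCTTGCTCAGATCCT); marks the 5' end of the constant TCRβ region.
DEFAULT_PRIMER_SUFFIX = "TGCTCAGATCCT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRead:
    """One read (or merged/concatenated amplicon) with per-base quality.

    ``junction`` marks the R1/R2 boundary of a concatenated pair so that
    downstream motif searches never span the artificial joint.
    """

    id: str
    seq: str
    qual: tuple[int, ...]
    junction: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return sum(self.qual) / len(self.qual)

    def reverse_complement(self) -> "SequenceRead":
        return replace(
            self, seq=revcomp(self.seq), qual=self.qual[::-1], junction=None
        )


@dataclass
class PreprocessConfig:
    """Thresholds for merging, quality and primer-anchor filtering.

    min_mean_phred:
        reads with mean Phred strictly below this are discarded (default 30).
    primer_suffix:
        exact anchor searched on both strands; a read is kept only if the
        constant-region primer suffix occurs, and is re-oriented so the
        anchor lies on the coding strand.
    min_overlap / max_overlap_mismatch_rate:
        FLASH-like overlap-merge acceptance bounds.
    """

    min_mean_phred: float = 30.0
    primer_suffix: str = DEFAULT_PRIMER_SUFFIX
    min_overlap: int = 10
    max_overlap_mismatch_rate: float = 0.25
    subsample_n: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_overlap_mismatch_rate < 1):
            raise ValueError("max_overlap_mismatch_rate must be in (0,1)")
        if self.subsample_n <= 0:
            raise ValueError("subsample_n must be positive")


def _base_match(a: str, b: str) -> bool:
    # N never matches anything, including another N
    return a == b and a != "N"


def merge_read_pair(
    r1: SequenceRead, r2: SequenceRead, cfg: PreprocessConfig
) -> Optional[SequenceRead]:
    """Overlap-merge a read pair; ``None`` on merge failure.

    r2 is reverse-complemented, then the longest suffix(r1)/prefix(r2')
    overlap with mismatch rate <= ``cfg.max_overlap_mismatch_rate`` and
    length >= ``cfg.min_overlap`` is taken; at each overlap mismatch the
    base with the higher Phred score wins (ties favour r1).
    """
    r2f = r2.reverse_complement()
    best: Optional[int] = None
    best_mm = 0
    max_ov = min(len(r1), len(r2f))
    for ov in range(max_ov, cfg.min_overlap - 1, -1):
        tail = r1.seq[len(r1) - ov:]
        head = r2f.seq[:ov]
        mm = sum(1 for a, b in zip(tail, head) if not _base_match(a, b))
        if mm / ov <= cfg.max_overlap_mismatch_rate:
            best, best_mm = ov, mm
            break  # scanning longest-first: first acceptable is maximal
    if best is None:
        return None
    ov = best
    left = len(r1) - ov
    seq = list(r1.seq[:left])
    qual = list(r1.qual[:left])
    for i in range(ov):
        a, qa = r1.seq[left + i], r1.qual[left + i]
        b, qb = r2f.seq[i], r2f.qual[i]
        if _base_match(a, b):
            seq.append(a)
            qual.append(max(qa, qb))
        elif qb > qa:
            seq.append(b)
            qual.append(qb)
        else:
            seq.append(a)
            qual.append(qa)
    seq.extend(r2f.seq[ov:])
    qual.extend(r2f.qual[ov:])
    return SequenceRead(
        id=r1.id, seq="".join(seq), qual=tuple(qual)
    )


def concatenate_read_pair(r1: SequenceRead, r2: Optional[SequenceRead]) -> SequenceRead:
    """Concatenate r1 with the reverse complement of r2 (non-overlapping pairs).

    The junction index is recorded so motif searches never span it.
    """
    if r2 is None:
        return r1
    r2f = r2.reverse_complement()
    return SequenceRead(
        id=r1.id,
        seq=r1.seq + r2f.seq,
        qual=r1.qual + r2f.qual,
        junction=len(r1),
    )


def quality_filter(read: SequenceRead, cfg: PreprocessConfig) -> bool:
    """Keep iff the mean Phred score is not strictly below the threshold."""
    return read.mean_quality >= cfg.min_mean_phred


def primer_anchor_filter(
    read: SequenceRead, cfg: PreprocessConfig
) -> Optional[tuple[SequenceRead, int]]:
    """Locate the constant-region primer suffix; orientation-normalise.

    Searches the read and its reverse complement for an exact occurrence of
    ``cfg.primer_suffix``. On success returns the read oriented so the
    anchor lies on the coding strand, together with the 0-based anchor
    start. With multiple occurrences the one closest to the 3' end (where
    the constant region is expected) is used. Returns ``None`` when neither
    strand matches.
    """
    if len(cfg.primer_suffix) < 8:
        raise ValueError("primer_suffix must be at least 8 nt")
    pos = read.seq.rfind(cfg.primer_suffix)
    if pos >= 0:
        return read, pos
    flipped = read.reverse_complement()
    pos = flipped.seq.rfind(cfg.primer_suffix)
    if pos >= 0:
        return flipped, pos
    return None


def subsample_reads(
    reads: Iterable[SequenceRead], n: int, seed: int
) -> list[SequenceRead]:
    """Uniform sample without replacement of min(n, total) reads.

    Single-pass reservoir sampling (Algorithm R); deterministic for a given
    seed. Output preserves reservoir order, not input order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = random.Random(seed)
    reservoir: list[SequenceRead] = []
    for i, read in enumerate(reads):
        if i < n:
            reservoir.append(read)
        else:
            j = rng.randrange(i + 1)
            if j < n:
                reservoir[j] = read
    return reservoir


# ---------------------------------------------------------------------------
# FASTQ I/O (plain or gzip)

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream a FASTQ file (optionally gzipped) as SequenceRead objects."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SequenceRead(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads to FASTQ (gzipped if the path ends in .gz); returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qual)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n
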