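"""MIG-based error correction of CDR3 reads via unique molecular identifiers.

Every cDNA molecule carries a random 12-nt UMI attached during synthesis,
so all reads sharing a UMI (a molecular identifier group, MIG) descend
from one template: any disagreement within a MIG is an artefact. The rules
are deliberately stringent, trading yield for precision:

* singleton MIGs are discarded outright;
* a two-read MIG survives only if both reads are identical;
* in larger MIGs a read *fails* if it differs from the most abundant
  sequence by more than 2 substitutions or by any length difference; the
  MIG is discarded as mosaic when at least half its reads fail, otherwise
  the consensus is the per-position majority over passing reads.

Surviving consensuses are collapsed to unique clonotypes with read and MIG
counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from tcrprof.cdr3 import Cdr3Record
from tcrprof.motif import translate
from tcrprof.preprocess import SequenceRead


@dataclass
class UmiConfig:
    """MIG consensus rules: similarity threshold and failure quorum."""

    umi_len: int = 12
    max_subs_to_top: int = 2
    fail_fraction: float = 0.5
    min_mig_size: int = 2

    def __post_init__(self) -> None:
        if self.max_subs_to_top < 0:
            raise ValueError("max_subs_to_top must be >= 0")
        if not (0 < self.fail_fraction <= 1):
            raise ValueError("fail_fraction must be in (0,1]")


@dataclass
class MIG:
    """All CDR3 reads sharing one UMI."""

    umi: str
    records: list[Cdr3Record]

    @property
    def size(self) -> int:
        return len(self.records)


@dataclass
class Clonotype:
    """A unique, error-corrected CDR3 variant with its support."""

    cdr3_nt: str
    cdr3_aa: str
    v_allele: str
    j_allele: str
    mig_count: int
    read_count: int


DiscardReason = Literal["singleton", "doubleton_mismatch", "mosaic"]


def extract_umi(
    read: SequenceRead, umi_len: int = 12, offset: int = 0
) -> Optional[tuple[str, SequenceRead]]:
    """Strip the UMI from the 5' end of an oriented read.

    Returns ``None`` (to be counted by the caller) when the read is too
    short or the UMI contains N.
    """
    if len(read.seq) < offset + umi_len + 1:
        return None
    umi = read.seq[offset:offset + umi_len]
    if any(base not in "ACGT" for base in umi):
        return None
    payload = SequenceRead(
        id=read.id,
        seq=read.seq[offset + umi_len:],
        qual=read.qual[offset + umi_len:],
        junction=(read.junction - offset - umi_len
                  if read.junction is not None else None),
    )
    return umi, payload


def group_migs(records: Iterable[Cdr3Record]) -> list[MIG]:
    """Group records by exact UMI; insertion order is preserved."""
    by_umi: dict[str, list[Cdr3Record]] = defaultdict(list)
    for rec in records:
        if rec.umi is None:
            raise ValueError(f"record {rec.read_id!r} has no UMI")
        by_umi[rec.umi].append(rec)
    return [MIG(umi=u, records=rs) for u, rs in sorted(by_umi.items())]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def consensus_mig(
    mig: MIG, cfg: Optional[UmiConfig] = None
) -> tuple[Optional[str], Optional[DiscardReason]]:
    """Infer the MIG consensus CDR3 or a typed discard.

    Returns ``(consensus_nt, None)`` on success or ``(None, reason)``.
    """
    cfg = cfg or UmiConfig()
    seqs = [r.cdr3_nt for r in mig.records]
    if len(seqs) == 1:
        return None, "singleton"
    if len(seqs) == 2:
        if seqs[0] == seqs[1]:
            return seqs[0], None
        return None, "doubleton_mismatch"
    counts = Counter(seqs)
    # most abundant sequence; ties broken lexicographically
    top = min(counts, key=lambda s: (-counts[s], s))
    passing = [
        s for s in seqs
        if len(s) == len(top) and _hamming(s, top) <= cfg.max_subs_to_top
    ]
    failing = len(seqs) - len(passing)
    if failing >= cfg.fail_fraction * len(seqs):
        return None, "mosaic"
    consensus = []
    for i in range(len(top)):
        column = Counter(s[i] for s in passing)
        best = max(column.values())
        winners = {b for b, c in column.items() if c == best}
        consensus.append(top[i] if top[i] in winners else
                         min(winners, key=lambda b: (-column[b], b)))
    return "".join(consensus), None


def _majority_label(labels: Sequence[str]) -> str:
    counts = Counter(labels)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unassigned"
    return ranked[0][0]


def collapse_to_clonotypes(
    consensuses: Iterable[tuple[str, str, str, int]],
) -> list[Clonotype]:
    """Collapse surviving MIG consensuses into unique clonotypes.

    Input items are ``(consensus_cdr3_nt, v_allele, j_allele, mig_reads)``.
    V/J annotation is decided by majority vote across MIGs (ties →
    unassigned). Output is sorted by MIG count descending, then sequence.
    """
    groups: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    for cdr3_nt, v, j, reads in consensuses:
        groups[cdr3_nt].append((v, j, reads))
    out = []
    for cdr3_nt, items in groups.items():
        out.append(
            Clonotype(
                cdr3_nt=cdr3_nt,
                cdr3_aa=translate(cdr3_nt),
                v_allele=_majority_label([v for v, _, _ in items]),
                j_allele=_majority_label([j for _, j, _ in items]),
                mig_count=len(items),
                read_count=sum(r for _, _, r in items),
            )
        )
    out.sort(key=lambda c: (-c.mig_count, c.cdr3_nt))
    return out


def correct_repertoire(
    records: Iterable[Cdr3Record], cfg: Optional[UmiConfig] = None
) -> tuple[list[Clonotype], Counter]:
    """Full UMI pipeline: group → consensus → collapse.

    Returns the clonotype list and a counter of discards (by reason, in
    units of MIGs, plus ``reads_discarded``).
    """
    cfg = cfg or UmiConfig()
    migs = group_migs(records)
    survivors: list[tuple[str, str, str, int]] = []
    discards: Counter = Counter()
    for mig in migs:
        consensus, reason = consensus_mig(mig, cfg)
        if consensus is None:
            discards[reason] += 1
            discards["reads_discarded"] += mig.size
            continue
        survivors.append(
            (
                consensus,
                _majority_label([r.v_allele for r in mig.records]),
                _majority_label([r.j_allele for r in mig.records]),
                mig.size,
            )
        )
    return collapse_to_clonotypes(survivors), discards
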