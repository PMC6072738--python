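"""Composed workflows and tabular I/O glue used by the CLI and scripts."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from tcrprof.cdr3 import (
    AnnotationConfig,
    Cdr3Record,
    extract_cdr3_records,
)
from tcrprof.motif import TRBJ_PATTERN, TRBV_PATTERN, compile_pattern
from tcrprof.preprocess import (
    PreprocessConfig,
    SequenceRead,
    primer_anchor_filter,
    quality_filter,
    subsample_reads,
)
from tcrprof.segments import DiscoveryConfig, discover_segments, extract_vj
from tcrprof.umi import Clonotype, UmiConfig, correct_repertoire


def clean_reads(
    reads: Iterable[SequenceRead], cfg: Optional[PreprocessConfig] = None
) -> tuple[list[tuple[SequenceRead, int]], Counter]:
    """Quality- and primer-anchor-filter a read stream.

    Returns oriented (read, anchor) pairs plus a tally of reads in /
    quality-failed / primer-failed / passed.
    """
    cfg = cfg or PreprocessConfig()
    out: list[tuple[SequenceRead, int]] = []
    tally: Counter = Counter()
    for read in reads:
        tally["reads_in"] += 1
        if not quality_filter(read, cfg):
            tally["quality_failed"] += 1
            continue
        anchored = primer_anchor_filter(read, cfg)
        if anchored is None:
            tally["primer_failed"] += 1
            continue
        out.append(anchored)
        tally["passed"] += 1
    return out, tally


def discover_from_reads(
    reads: Iterable[SequenceRead],
    pre_cfg: Optional[PreprocessConfig] = None,
    disc_cfg: Optional[DiscoveryConfig] = None,
    v_pattern: str = TRBV_PATTERN,
    j_pattern: str = TRBJ_PATTERN,
):
    """Full discovery: clean → pattern-extract → dereplicate/cluster/call.

    Returns (v_alleles, j_alleles, v_clusters, j_clusters, rejections).
    """
    vp = compile_pattern(v_pattern)
    jp = compile_pattern(j_pattern)
    anchored, tally = clean_reads(reads, pre_cfg)
    extractions = []
    rejections: Counter = Counter(tally)
    for read, anchor in anchored:
        res = extract_vj(read, vp, jp, anchor=anchor)
        if isinstance(res, str):
            rejections[res] += 1
        else:
            extractions.append(res)
    rejections["patterns_found"] = len(extractions)
    va, ja, vc, jc = discover_segments(extractions, disc_cfg)
    return va, ja, vc, jc, rejections


def quantitative_replicate(
    reads: Iterable[SequenceRead],
    v_refs: Sequence[tuple[str, str]],
    j_refs: Sequence[tuple[str, str]],
    pre_cfg: Optional[PreprocessConfig] = None,
    ann_cfg: Optional[AnnotationConfig] = None,
    umi_cfg: Optional[UmiConfig] = None,
    subsample_n: Optional[int] = None,
    seed: int = 0,
) -> tuple[list[Clonotype], Counter]:
    """One replicate of the UMI workflow: clean → extract CDR3 → correct.

    Returns the error-corrected unique clonotypes and the combined
    rejection/discard tally.
    """
    umi_cfg = umi_cfg or UmiConfig()
    if subsample_n is not None:
        reads = subsample_reads(reads, subsample_n, seed)
    anchored, tally = clean_reads(reads, pre_cfg)
    records, rejections = extract_cdr3_records(
        anchored, v_refs, j_refs, ann_cfg,
        umi_len=umi_cfg.umi_len, mode="umi",
    )
    clonotypes, discards = correct_repertoire(records, umi_cfg)
    return clonotypes, Counter(tally) + rejections + discards


# ---------------------------------------------------------------------------
# tabular I/O

def clonotypes_to_frame(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cdr3_nt": c.cdr3_nt, "cdr3_aa": c.cdr3_aa,
                "v_allele": c.v_allele, "j_allele": c.j_allele,
                "mig_count": c.mig_count, "read_count": c.read_count,
            }
            for c in clonotypes
        ]
    )


def frame_to_clonotypes(df: pd.DataFrame) -> list[Clonotype]:
    return [
        Clonotype(
            cdr3_nt=row.cdr3_nt, cdr3_aa=row.cdr3_aa,
            v_allele=row.v_allele, j_allele=row.j_allele,
            mig_count=int(row.mig_count), read_count=int(row.read_count),
        )
        for row in df.itertuples()
    ]


def write_clonotypes(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    clonotypes_to_frame(clonotypes).to_csv(path, sep="\t", index=False)


def read_clonotypes(path: str | Path) -> list[Clonotype]:
    return frame_to_clonotypes(pd.read_csv(path, sep="\t"))


def records_to_frame(records: Sequence[Cdr3Record]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id, "umi": r.umi or "",
                "v_allele": r.v_allele, "j_allele": r.j_allele,
                "cdr3_nt": r.cdr3_nt, "cdr3_aa": r.cdr3_aa,
            }
            for r in records
        ]
    )


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
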