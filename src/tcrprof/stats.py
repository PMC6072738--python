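"""Qualitative repertoire descriptors.

V-J usage and length distributions are measured over unique nucleotide
CDR3 variants (not transcript abundance) to avoid expression-level bias;
read-weighted means are reported separately where abundance is the point.
Records with an unassigned V or J are excluded from usage and spectratypes
but kept in the global length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from tcrprof.umi import Clonotype


@dataclass
class UsageMatrix:
    counts: pd.DataFrame  # V labels x J labels, unique-variant counts
    unassigned: int

    @property
    def frequencies(self) -> pd.DataFrame:
        total = self.counts.values.sum()
        return self.counts / total if total else self.counts.astype(float)

    def top_pairs(self, quantile: float = 0.99) -> list[tuple[str, str]]:
        """V-J pairs whose frequency exceeds the given cell quantile."""
        freq = self.frequencies
        cut = np.quantile(freq.values.ravel(), quantile)
        pairs = [
            (v, j)
            for v in freq.index
            for j in freq.columns
            if freq.loc[v, j] > cut
        ]
        return sorted(pairs, key=lambda p: -freq.loc[p[0], p[1]])


@dataclass
class LengthDistribution:
    unit: Literal["aa", "nt"]
    histogram: pd.Series          # length -> unique-variant count
    weighted_histogram: pd.Series  # length -> read-weighted count

    @property
    def median(self) -> Optional[float]:
        if self.histogram.empty:
            return None
        lengths = np.repeat(self.histogram.index.values,
                            self.histogram.values)
        return float(np.median(lengths))

    def share(self, lo: int, hi: int) -> float:
        """Fraction of unique variants with length in [lo, hi]."""
        total = self.histogram.sum()
        if total == 0:
            return float("nan")
        mask = (self.histogram.index >= lo) & (self.histogram.index <= hi)
        return float(self.histogram[mask].sum() / total)


def _assigned(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    return [c for c in clonotypes
            if c.v_allele != "unassigned" and c.j_allele != "unassigned"]


def vj_usage(clonotypes: Sequence[Clonotype]) -> UsageMatrix:
    """Unique-variant counts per V-J combination.

    Unassigned records are excluded from the matrix and counted
    separately, so that matrix total + unassigned = number of clonotypes.
    """
    assigned = _assigned(clonotypes)
    if not assigned:
        return UsageMatrix(counts=pd.DataFrame(),
                           unassigned=len(list(clonotypes)))
    df = pd.DataFrame(
        {"v": [c.v_allele for c in assigned],
         "j": [c.j_allele for c in assigned]}
    )
    counts = df.groupby(["v", "j"]).size().unstack(fill_value=0)
    counts = counts.sort_index().sort_index(axis=1)
    return UsageMatrix(counts=counts,
                       unassigned=len(clonotypes) - len(assigned))


def cdr3_length_distribution(
    clonotypes: Sequence[Clonotype], unit: Literal["aa", "nt"] = "aa"
) -> LengthDistribution:
    """Histogram of CDR3 lengths over unique variants (+ read-weighted)."""
    lengths = [
        len(c.cdr3_aa) if unit == "aa" else len(c.cdr3_nt)
        for c in clonotypes
    ]
    weights = [c.read_count for c in clonotypes]
    if not lengths:
        empty = pd.Series(dtype=int)
        return LengthDistribution(unit=unit, histogram=empty,
                                  weighted_histogram=empty)
    hist = pd.Series(lengths).value_counts().sort_index()
    whist = (
        pd.DataFrame({"len": lengths, "w": weights})
        .groupby("len")["w"].sum().sort_index()
    )
    return LengthDistribution(unit=unit, histogram=hist,
                              weighted_histogram=whist)


def weighted_mean_length(
    clonotypes: Sequence[Clonotype],
    by_segment: Literal["V", "J", "none"] = "none",
    unit: Literal["aa", "nt"] = "aa",
) -> float | pd.Series:
    """Read-weighted mean CDR3 length, overall or per V/J segment.

    mean = sum(length * reads) / sum(reads).
    """
    def length(c: Clonotype) -> int:
        return len(c.cdr3_aa) if unit == "aa" else len(c.cdr3_nt)

    if by_segment == "none":
        total = sum(c.read_count for c in clonotypes)
        if total == 0:
            raise ValueError("zero total read count")
        return sum(length(c) * c.read_count for c in clonotypes) / total
    key = (lambda c: c.v_allele) if by_segment == "V" else (
        lambda c: c.j_allele)
    assigned = _assigned(clonotypes)
    df = pd.DataFrame(
        {"seg": [key(c) for c in assigned],
         "len": [length(c) for c in assigned],
         "reads": [c.read_count for c in assigned]}
    )
    if df.empty:
        raise ValueError("no assigned clonotypes")
    grouped = df.groupby("seg").apply(
        lambda g: (g["len"] * g["reads"]).sum() / g["reads"].sum(),
        include_groups=False,
    )
    return grouped.sort_index()


def spectratype(
    clonotypes: Sequence[Clonotype],
    segment: Literal["V", "J"] = "V",
    unit: Literal["aa", "nt"] = "aa",
) -> dict[str, LengthDistribution]:
    """One CDR3 length distribution per V (or J) segment label."""
    key = (lambda c: c.v_allele) if segment == "V" else (
        lambda c: c.j_allele)
    by_seg: dict[str, list[Clonotype]] = {}
    for c in _assigned(clonotypes):
        by_seg.setdefault(key(c), []).append(c)
    return {
        label: cdr3_length_distribution(group, unit=unit)
        for label, group in sorted(by_seg.items())
    }
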