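"""Quantitative repertoire analysis: incidence, Chao2, rarefaction, sharing.

Repertoire size is estimated with the non-parametric, incidence-based
Chao2 lower bound. With m replicate samples per individual, S_obs observed
unique clonotypes, q1 clonotypes seen in exactly one replicate and q2 in
exactly two,

    S_chao2 = S_obs + ((m - 1) / m) * q1**2 / (2 * q2)        (q2 > 0)

falling back to the standard bias-corrected form
S_obs + ((m-1)/m) * q1*(q1-1)/2 when q2 = 0. The estimate is a lower
bound on true richness; abundance-based estimators are deliberately not
offered because transcript counts do not identify T-cell counts.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np


@dataclass
class IncidenceSummary:
    """Incidence-class counts across replicates.

    s_obs: unique clonotypes over all replicates; q1/q2: present in
    exactly one/two replicates; m: number of replicates;
    incidence_freq[k] = number present in exactly k replicates.
    """

    s_obs: int
    q1: int
    q2: int
    m: int
    incidence_freq: dict[int, int]

    @property
    def s_chao2(self) -> float:
        return chao2(self)

    @property
    def fraction_observed(self) -> float:
        """S_obs / S_chao2 — the share of the estimate directly observed."""
        est = self.s_chao2
        return self.s_obs / est if est else float("nan")


def incidence_counts(
    replicates: Sequence[Iterable[Hashable]],
) -> IncidenceSummary:
    """Tally presence/absence of clonotype keys across replicate samples."""
    sets = [set(r) for r in replicates]
    presence: Counter = Counter()
    for s in sets:
        presence.update(s)
    freq: Counter = Counter(presence.values())
    return IncidenceSummary(
        s_obs=len(presence),
        q1=freq.get(1, 0),
        q2=freq.get(2, 0),
        m=len(sets),
        incidence_freq={k: freq.get(k, 0) for k in range(1, len(sets) + 1)},
    )


def chao2(summary: IncidenceSummary) -> float:
    """Chao2 lower-bound richness estimate (bias-corrected when q2 = 0)."""
    if summary.m < 2:
        raise ValueError("Chao2 requires at least 2 replicates")
    factor = (summary.m - 1) / summary.m
    if summary.q2 > 0:
        return summary.s_obs + factor * summary.q1 ** 2 / (2 * summary.q2)
    return summary.s_obs + factor * summary.q1 * (summary.q1 - 1) / 2


def rarefaction(
    records: Sequence[Hashable],
    grid: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """Mean (+- SD) unique clonotypes at each subsampling depth.

    ``records`` is the read-level stream of clonotype keys. Depths above
    the population size are truncated. Returns (depth, mean, sd) triples.
    """
    if list(grid) != sorted(grid):
        raise ValueError("depth grid must be sorted ascending")
    rng = random.Random(seed)
    n = len(records)
    out = []
    for depth in grid:
        d = min(depth, n)
        uniques = []
        for _ in range(reps):
            sample = rng.sample(records, d)
            uniques.append(len(set(sample)))
        out.append((d, float(np.mean(uniques)), float(np.std(uniques))))
    return out


@dataclass
class SharingReport:
    pairwise: dict[tuple[str, str], dict[str, float]]
    public: set
    private: dict[str, set]
    public_fraction: float = float("nan")

    @property
    def mean_pairwise_share(self) -> float:
        """Mean over pairs of the per-individual-mean overlap share."""
        vals = [d["share_individual_mean"] for d in self.pairwise.values()]
        return float(np.mean(vals)) if vals else float("nan")


def sharing(
    repertoires: Mapping[str, Iterable[Hashable]],
) -> SharingReport:
    """Pairwise overlap, public and private clonotypes across individuals.

    For each pair (A, B) reports |A∩B| with two normalisations: share of
    the union and the mean of the per-individual shares |A∩B|/|A| and
    |A∩B|/|B| (the headline figure). Clonotypes in every individual form
    the public set; clonotypes in exactly one are private.
    """
    sets = {k: set(v) for k, v in repertoires.items()}
    if len(sets) < 2:
        raise ValueError("sharing requires at least 2 individuals")
    names = sorted(sets)
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sets[a] & sets[b]
            union = sets[a] | sets[b]
            pairwise[(a, b)] = {
                "intersection": float(len(inter)),
                "share_union": len(inter) / len(union) if union else 0.0,
                "share_individual_mean": (
                    (len(inter) / len(sets[a]) + len(inter) / len(sets[b])) / 2
                    if sets[a] and sets[b] else 0.0
                ),
                "size_a": float(len(sets[a])),
                "size_b": float(len(sets[b])),
            }
    public = set.intersection(*sets.values())
    membership: Counter = Counter()
    for s in sets.values():
        membership.update(s)
    private = {
        name: {c for c in sets[name] if membership[c] == 1}
        for name in names
    }
    mean_size = float(np.mean([len(s) for s in sets.values()]))
    return SharingReport(
        pairwise=pairwise,
        public=public,
        private=private,
        public_fraction=len(public) / mean_size if mean_size else float("nan"),
    )
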