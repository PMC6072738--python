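"""Synthetic 5'RACE TCRβ amplicon data with planted truth.

Generates germline V and J alleles that conform to the conserved-residue
patterns used for discovery, recombines them into functional CDR3
clonotypes (exonucleolytic trimming, untemplated N additions, a short D
segment), and emulates the library: molecules drawn from a skewed
clone-size distribution, optional 12-nt UMIs, a configurable number of
reads per molecule, i.i.d. substitution errors, and a constant-region
head carrying the primer anchor. Truth tables make every pipeline stage
verifiable: recovered clonotypes and alleles can be compared exactly to
what was planted.

What this emulates and what it does not: substitution errors (PCR +
sequencing) at a uniform per-base rate, amplification as identical reads
per molecule, and replicate sampling of molecules; it does not model
PCR chimeras, sequence-dependent error profiles, indel errors (unless
configured) or thymic selection.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from tcrprof.cdr3 import CYS_MOTIF, filter_cdr3
from tcrprof.motif import (
    TRBJ_PATTERN,
    TRBV_PATTERN,
    compile_pattern,
    find_pattern,
    translate,
)
from tcrprof.preprocess import (
    DEFAULT_PRIMER_SUFFIX,
    SequenceRead,
    revcomp,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

# codons per residue, standard code (no stops)
_CODONS: dict[str, list[str]] = defaultdict(list)
from Bio.Data.CodonTable import standard_dna_table as _tbl

for _codon, _aa in _tbl.forward_table.items():
    _CODONS[_aa].append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


@dataclass
class GermlineSpec:
    """Planted germline segments.

    V alleles end with the conserved Cys codon context (``TG[TC][GA][CG]``)
    plus a short germline CDR3 stub; J alleles consist of a germline CDR3
    part followed by a post-CDR3 tail of ``j_tail_len`` nt beginning at the
    conserved Gly codon. ``v_cys_offset[i]`` is the nt position of the
    conserved Cys in V allele i; ``j_gly_offset[i]`` that of the Gly in J
    allele i.
    """

    v_alleles: list[str]
    j_alleles: list[str]
    d_segments: list[str]
    constant_head: str
    v_cys_offset: list[int]
    j_gly_offset: list[int]
    j_tail_len: int = 31

    def v_segment(self, i: int) -> str:
        """The V segment as discovery reports it (trimmed before Cys)."""
        return self.v_alleles[i][: self.v_cys_offset[i]]

    def j_segment(self, i: int) -> str:
        """The J segment as discovery reports it (from the Gly codon)."""
        return self.j_alleles[i][self.j_gly_offset[i]:]


@dataclass
class SimulationConfig:
    """Study conditions for the simulated repertoire.

    Defaults: 500 functional clonotypes with lognormal(σ=1) clone sizes
    (skewed enough that replicate samples miss clones, the regime Chao2 is
    built for), trimming up to 3 nt per joint, geometric N-addition
    lengths, 12-nt UMIs, 6 reads per molecule and a 0.3% per-base
    substitution error rate, in 4 replicate samples. Six reads per
    molecule keeps MIGs above ~5 usable reads even after anchor-loss
    dropout, the regime where majority consensus outvotes coincident
    errors.
    """

    n_clonotypes: int = 500
    clone_size_distribution: Literal["uniform", "lognormal", "power"] = "lognormal"
    lognormal_sigma: float = 1.0
    power_alpha: float = 1.5
    trim_max: int = 3
    n_insert_geometric_p: float = 0.35
    reads_per_molecule: int = 6
    umi: bool = True
    umi_len: int = 12
    per_base_error: float = 0.003
    #: off by default: the consensus rules are substitution-based; turn on
    #: to exercise frameshift rejection downstream
    per_base_indel_rate: float = 0.0
    n_replicates: int = 4
    molecules_per_replicate: int = 2000
    #: when set, every clonotype contributes at least one molecule per
    #: replicate (pipeline-fidelity tests); leave off for diversity
    #: estimation, which needs the unseen-species regime
    guarantee_coverage: bool = False
    #: mean per-base Phred of emitted reads. Base qualities model
    #: sequencer confidence only; ``per_base_error`` is the combined
    #: PCR + sequencing substitution rate, most of which (PCR) is
    #: invisible to quality scores — hence the two are deliberately
    #: independent.
    quality_mean: float = 37.0
    quality_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if not (0 <= self.per_base_error <= 1):
            raise ValueError("per_base_error must be in [0,1]")
        if not (0 < self.n_insert_geometric_p <= 1):
            raise ValueError("n_insert_geometric_p must be in (0,1]")


@dataclass
class TrueClonotype:
    id: int
    v_index: int
    j_index: int
    seq: str          # recombined variable region (V..J tail), no constant
    cdr3_nt: str
    frequency: float

    @property
    def cdr3_aa(self) -> str:
        return translate(self.cdr3_nt)


@dataclass
class ReadTruth:
    read_id: str
    clonotype_id: int
    umi: Optional[str]
    n_errors: int
    replicate: int


@dataclass
class TruthTable:
    clonotypes: list[TrueClonotype]
    reads: list[ReadTruth] = field(default_factory=list)

    @property
    def cdr3_set(self) -> set[str]:
        return {c.cdr3_nt for c in self.clonotypes}


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _aa_to_nt(rng: np.random.Generator, aa: str) -> str:
    return "".join(
        _CODONS[res][rng.integers(len(_CODONS[res]))] for res in aa
    )


_V_PAT = compile_pattern(TRBV_PATTERN)
_J_PAT = compile_pattern(TRBJ_PATTERN)

#: identity ceiling enforced between planted alleles of a class, margin
#: below the clustering thresholds so discovery can separate them
_V_MAX_IDENT = 0.90
_J_MAX_IDENT = 0.75


def _make_v_allele(rng: np.random.Generator) -> tuple[str, int]:
    """One V allele nt and its conserved-Cys offset.

    Amino acid layout mirrors the V pattern and ends C-A plus a CASS-like
    germline CDR3 stub of two residues.
    """
    aa = (
        _random_aa(rng, 5) + "Q" + _random_aa(rng, 1) + "P"
        + _random_aa(rng, 14) + "C"
        + _random_aa(rng, int(rng.integers(10, 12))) + "WY"
        + _random_aa(rng, int(rng.integers(39, 43)))
        + ("L" if rng.random() < 0.5 else "M")
        + _random_aa(rng, 14)
    )
    cys_offset = 3 * len(aa)
    nt = _aa_to_nt(rng, aa)
    # conserved Cys + Ala gives the TG[TC]GC motif context; stub S-S
    cys_codon = "TGT" if rng.random() < 0.5 else "TGC"
    nt += cys_codon + "GCC" + _aa_to_nt(rng, "SS")
    assert find_pattern(translate(nt), _V_PAT, mode="first"), "pattern lost"
    return nt, cys_offset


def _make_j_allele(
    rng: np.random.Generator, tail_len: int = 31
) -> tuple[str, int]:
    """One J allele nt and its conserved-Gly offset.

    Germline CDR3 part of 5 residues ending in F, then the FG-x-G tail:
    G-x-G-x(2)-L-x-[VI]-x is 9 residues (27 nt); extra random nt pad the
    post-CDR3 tail to ``tail_len``.
    """
    cdr3_part = _random_aa(rng, 4) + "F"
    gly_offset = 3 * len(cdr3_part)
    tail_aa = (
        "G" + _random_aa(rng, 1) + "G" + _random_aa(rng, 2) + "L"
        + _random_aa(rng, 1) + ("V" if rng.random() < 0.5 else "I")
        + _random_aa(rng, 1)
    )
    tail_nt = _aa_to_nt(rng, tail_aa)
    pad = tail_len - len(tail_nt)
    if pad < 0:
        raise ValueError("j tail length must be >= 27 nt")
    tail_nt += "".join(rng.choice(list(_NT), size=pad))
    nt = _aa_to_nt(rng, cdr3_part) + tail_nt
    assert find_pattern(translate(nt), _J_PAT, mode="first"), "pattern lost"
    return nt, gly_offset


def simulate_germline(
    n_v: int = 5,
    n_j: int = 3,
    seed: int = 0,
    n_d: int = 2,
    j_tail_len: int = 31,
) -> GermlineSpec:
    """Generate pattern-conformant, mutually divergent germline segments.

    V alleles are kept below 90% and J below 75% pairwise identity (margin
    under the 95%/85% clustering thresholds) so discovery can separate
    them; D segments are 12-14 nt.
    """
    from tcrprof.segments import identity

    rng = np.random.default_rng(seed)
    v_alleles: list[str] = []
    v_cys: list[int] = []
    while len(v_alleles) < n_v:
        nt, cys = _make_v_allele(rng)
        # the leftmost pattern match must pin the intended conserved Cys,
        # or discovery would trim this allele at a spurious motif
        spans = find_pattern(translate(nt), _V_PAT, mode="first")
        if not spans or 3 * (spans[0][1] - 2) != cys or spans[0][0] != 0:
            continue
        if all(identity(nt[:cys], prev[:pc]) < _V_MAX_IDENT
               for prev, pc in zip(v_alleles, v_cys)):
            v_alleles.append(nt)
            v_cys.append(cys)
    j_alleles: list[str] = []
    j_gly: list[int] = []
    while len(j_alleles) < n_j:
        nt, gly = _make_j_allele(rng, j_tail_len)
        spans = find_pattern(translate(nt), _J_PAT, mode="first")
        if not spans or 3 * (spans[0][0] + 4) != gly:
            continue
        if all(identity(nt[gly:], prev[pg:]) < _J_MAX_IDENT
               for prev, pg in zip(j_alleles, j_gly)):
            j_alleles.append(nt)
            j_gly.append(gly)
    d_segments = [
        "".join(rng.choice(list(_NT), size=int(rng.integers(12, 15))))
        for _ in range(n_d)
    ]
    constant_head = DEFAULT_PRIMER_SUFFIX + "CACCGAGGTCTGGG"
    return GermlineSpec(
        v_alleles=v_alleles,
        j_alleles=j_alleles,
        d_segments=d_segments,
        constant_head=constant_head,
        v_cys_offset=v_cys,
        j_gly_offset=j_gly,
        j_tail_len=j_tail_len,
    )


def _truth_cdr3(seq: str, j_tail_len: int) -> Optional[str]:
    """CDR3 by the extraction boundary rules on a recombined sequence."""
    end = len(seq) - j_tail_len
    starts = [m.start() for m in CYS_MOTIF.finditer(seq[:end + 2])
              if m.start() + 3 <= end]
    if not starts:
        return None
    return seq[starts[-1]:end]


def recombine(
    germline: GermlineSpec,
    cfg: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> TruthTable:
    """V(D)J-recombine germline segments into functional clonotypes.

    Each clonotype is trimmed-V + N1 + trimmed-D + N2 + trimmed-J;
    candidates are resampled until ``n_clonotypes`` distinct CDR3s pass the
    functionality filter *and* the planted V/J segments are recoverable by
    the same boundary rules the pipeline uses. Clone frequencies are drawn
    from the configured clone-size distribution.
    """
    from tcrprof.segments import extract_vj

    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    clonotypes: list[TrueClonotype] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * cfg.n_clonotypes + 1000
    while len(clonotypes) < cfg.n_clonotypes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "recombination failed to produce enough functional "
                "clonotypes; loosen trims or check germline config"
            )
        vi = int(rng.integers(len(germline.v_alleles)))
        ji = int(rng.integers(len(germline.j_alleles)))
        di = int(rng.integers(len(germline.d_segments)))
        v = germline.v_alleles[vi]
        j = germline.j_alleles[ji]
        d = germline.d_segments[di]
        tv = int(rng.integers(cfg.trim_max + 1))
        tj = int(rng.integers(cfg.trim_max + 1))
        td5 = int(rng.integers(cfg.trim_max + 1))
        td3 = int(rng.integers(cfg.trim_max + 1))
        n1 = int(rng.geometric(cfg.n_insert_geometric_p)) - 1
        n2 = int(rng.geometric(cfg.n_insert_geometric_p)) - 1
        d_mid = d[td5: len(d) - td3] if td5 + td3 < len(d) else ""
        seq = (
            v[: len(v) - tv]
            + "".join(rng.choice(list(_NT), size=n1))
            + d_mid
            + "".join(rng.choice(list(_NT), size=n2))
            + j[tj:]
        )
        cdr3 = _truth_cdr3(seq, germline.j_tail_len)
        if cdr3 is None or cdr3 in seen:
            continue
        if filter_cdr3(cdr3) != "pass":
            continue
        # the planted segments must be exactly recoverable by discovery
        read = SequenceRead(id="probe", seq=seq + germline.constant_head,
                            qual=(40,) * (len(seq) + len(germline.constant_head)))
        res = extract_vj(read, _V_PAT, _J_PAT, anchor=len(seq))
        if isinstance(res, str):
            continue
        if (res.v_seq != germline.v_segment(vi)
                or res.j_seq != germline.j_segment(ji)):
            continue
        seen.add(cdr3)
        clonotypes.append(
            TrueClonotype(id=len(clonotypes), v_index=vi, j_index=ji,
                          seq=seq, cdr3_nt=cdr3, frequency=0.0)
        )
    freqs = _clone_frequencies(rng, cfg)
    for c, f in zip(clonotypes, freqs):
        c.frequency = float(f)
    return TruthTable(clonotypes=clonotypes)


def _clone_frequencies(
    rng: np.random.Generator, cfg: SimulationConfig
) -> np.ndarray:
    n = cfg.n_clonotypes
    if cfg.clone_size_distribution == "uniform":
        w = np.ones(n)
    elif cfg.clone_size_distribution == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n)
    else:
        w = np.arange(1, n + 1, dtype=float) ** (-cfg.power_alpha)
        rng.shuffle(w)
    return w / w.sum()


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, indel_rate: float = 0.0
) -> tuple[str, int]:
    n_total = 0
    if rate > 0:
        n_err = rng.binomial(len(seq), rate)
        if n_err:
            pos = rng.choice(len(seq), size=n_err, replace=False)
            out = list(seq)
            for p in pos:
                choices = [b for b in _NT if b != out[p]]
                out[p] = choices[int(rng.integers(3))]
            seq = "".join(out)
            n_total += int(n_err)
    if indel_rate > 0:
        n_ind = rng.binomial(len(seq), indel_rate)
        for _ in range(n_ind):
            p = int(rng.integers(len(seq)))
            if rng.random() < 0.5:
                seq = seq[:p] + seq[p + 1:]
            else:
                seq = seq[:p] + str(rng.choice(list(_NT))) + seq[p:]
        n_total += int(n_ind)
    return seq, n_total


def simulate_library(
    truth: TruthTable,
    germline: GermlineSpec,
    cfg: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> tuple[list[list[SequenceRead]], TruthTable]:
    """Emit pre-oriented reads with a constant tail, per replicate.

    Per replicate, ``molecules_per_replicate`` cDNA molecules are drawn
    from the clone frequencies; each gets a random UMI (when configured)
    and ``reads_per_molecule`` reads with i.i.d. substitution errors.
    Qualities are uniform at the Phred equivalent of the error rate.
    Returns one read list per replicate plus the truth table updated with
    per-read provenance.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(
        (cfg.seed if seed is None else seed) + 7_919)
    probs = np.array([c.frequency for c in truth.clonotypes])
    probs = probs / probs.sum()

    def _quals(n: int) -> tuple[int, ...]:
        q = rng.normal(cfg.quality_mean, cfg.quality_sd, size=n)
        return tuple(int(x) for x in np.clip(np.round(q), 2, 41))
    replicates: list[list[SequenceRead]] = []
    for rep in range(cfg.n_replicates):
        reads: list[SequenceRead] = []
        n_mol = cfg.molecules_per_replicate
        if cfg.guarantee_coverage:
            base = np.arange(len(truth.clonotypes))
            extra = rng.choice(
                len(truth.clonotypes),
                size=max(0, n_mol - len(base)), p=probs,
            )
            mol_clono = np.concatenate([base, extra])
        else:
            mol_clono = rng.choice(len(truth.clonotypes), size=n_mol, p=probs)
        for mol_i, ci in enumerate(mol_clono):
            clono = truth.clonotypes[int(ci)]
            umi = (
                "".join(rng.choice(list(_NT), size=cfg.umi_len))
                if cfg.umi else None
            )
            template = (umi or "") + clono.seq + germline.constant_head
            for k in range(cfg.reads_per_molecule):
                seq, n_err = _mutate(rng, template, cfg.per_base_error,
                                     cfg.per_base_indel_rate)
                rid = f"rep{rep}_mol{mol_i}_read{k}"
                reads.append(
                    SequenceRead(id=rid, seq=seq, qual=_quals(len(seq)))
                )
                truth.reads.append(
                    ReadTruth(read_id=rid, clonotype_id=clono.id, umi=umi,
                              n_errors=n_err, replicate=rep)
                )
        replicates.append(reads)
    return replicates, truth


def as_read_pairs(
    reads: Sequence[SequenceRead], read_len: int
) -> list[tuple[SequenceRead, SequenceRead]]:
    """Split full amplicons into R1/R2 pairs of the given read length.

    R1 is the first ``read_len`` nt; R2 the reverse complement of the last
    ``read_len`` nt — overlapping pairs when 2*read_len exceeds the
    amplicon (MiSeq merge mode), non-overlapping otherwise (HiSeq
    concatenate mode).
    """
    pairs = []
    for read in reads:
        n = len(read.seq)
        l = min(read_len, n)
        r1 = SequenceRead(id=read.id, seq=read.seq[:l], qual=read.qual[:l])
        r2 = SequenceRead(
            id=read.id,
            seq=revcomp(read.seq[n - l:]),
            qual=read.qual[n - l:][::-1],
        )
        pairs.append((r1, r2))
    return pairs


@dataclass
class TruthComparison:
    recall: float
    precision: float
    exact: bool
    n_truth: int
    n_output: int


def truth_compare(
    output_cdr3: set[str] | Sequence[str],
    truth: TruthTable,
) -> TruthComparison:
    """Set-level recall/precision of recovered CDR3 nt sequences."""
    out = set(output_cdr3)
    true = truth.cdr3_set
    tp = len(out & true)
    recall = tp / len(true) if true else float("nan")
    precision = tp / len(out) if out else float("nan")
    return TruthComparison(
        recall=recall,
        precision=precision,
        exact=(out == true),
        n_truth=len(true),
        n_output=len(out),
    )
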