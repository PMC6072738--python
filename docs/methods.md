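# Methods

This note documents the models, rules and numerical choices behind
`tcrprof`, in the order data flows through the package.

## Read preprocessing

Two read geometries are supported. Long overlapping pairs (MiSeq-style,
2×300 bp over a ~600 bp amplicon) are overlap-merged: among candidate
suffix/prefix overlaps of length ≥ `min_overlap` (default 10) whose
mismatch rate is ≤ `max_overlap_mismatch_rate` (default 0.25), the
longest is taken, and each overlap mismatch is resolved toward the base
with the higher Phred score (ties to read 1). `N` bases never match
anything, including another `N`. Short non-overlapping pairs
(HiSeq-style, 2×150 bp) are concatenated as R1 + revcomp(R2); the
junction index is carried on the read so that no downstream motif match
may span the artificial joint.

Reads are kept when their mean Phred is ≥ 30 (a read averaging exactly
30 is kept) and when the 12-nt constant-region primer suffix
(`TGCTCAGATCCT`, the tail of the nested constant primer) occurs exactly
on either strand; matching reads are re-oriented so the anchor lies on
the coding strand. With multiple anchor occurrences the 3′-most is used,
since the constant region is the 3′ terminus of the amplicon. Exact
matching is the strictest reading of the filter and is configurable.

**Anchor coordinate convention.** The fixed CDR3 boundary used in
short-read mode is defined as `constant_offset_nt` (default 31)
upstream of the *suffix-match start*. Where exactly the constant region
begins relative to the primer suffix is a protocol detail that varies
with primer design; the offset is therefore a single configurable
number, and the simulator builds its constant head to start with the
suffix so the geometry is self-consistent. When applying the package to
real data with a different primer, set `constant_offset_nt` to the
distance between your suffix match and the CDR3 3′ border.

Subsampling (to equalise sequencing depth across amplicons) is
single-pass reservoir sampling with an explicit seed; the same seed
always yields the same subset.

## Conserved-residue pattern engine

V and J segments are found without references via patterns of conserved
residues in a PROSITE subset — literals, residue sets `[VI]`, and
wildcards `x`, `x(n)`, `x(n,m)`:

* V: `x(5)-Q-x-P-x(14)-C-x(10,11)-W-Y-x(39,42)-[LM]-x(14)-C-x`
  (91–95 residues; the penultimate `C` is the CDR3-opening cysteine)
* J: `x(4)-G-x-G-x(2)-L-x-[VI]-x`
  (13 residues; the first `G` literal is the CDR3-closing glycine)

Patterns compile to regular expressions over the translated read.
Variable-length wildcards match non-greedily (shortest span at each
start), keeping the conserved anchors as close as the pattern allows.
Stop codons translate to `*` and match no token, so ORF-disrupted
transcripts fail pattern search naturally; codons containing `N`
translate to `X`, which matches wildcards but not literals or sets.
Coordinates obey `nt_start = frame + 3·aa_start` for every match.

## Segment discovery

A read yields a V/J extraction only when both patterns occur in the same
reading frame, J downstream of the conserved V cysteine, with no stop
codon from the V-pattern start through the J-pattern end. Failures are
typed: `no_v_pattern`, `no_j_pattern`, `ptc` (in-frame stop between the
patterns) and `frameshift_or_intron` (patterns found only in different
frames — the shared signature of indels and unspliced introns, which are
not separable without a reference). The V segment is trimmed at the base
before the Cys codon; the J segment starts at the Gly codon — both ends
of the CDR3 thus belong to the CDR3, not to the segments.

Extracted segments are dereplicated exactly (depth order, ties
lexicographic). Variants below a frequency floor — 0.01 % for V, 0.1 %
for J, the minimum rare-allele frequencies observed in well-studied
repertoires — are removed as PCR/sequencing artefacts. Survivors are
clustered greedily in depth order (CD-HIT style): a variant joins the
first cluster whose representative it matches at ≥ 95 % (V) or ≥ 85 %
(J) identity, else founds a new cluster. Identity is matches divided by
alignment columns of a global alignment (edit-distance alignment via
edlib; for equal lengths this is 1 − Hamming/len); the short J segments
use an end-gap-free (infix) variant. Because a true second allele can be
absorbed by a dominant near-identical one, any non-representative member
holding more than 20 % of its cluster's depth is split into its own
cluster; the highest-depth offender moves first and the rule is applied
to a fixed point, which terminates because each move strictly shrinks a
cluster. The representative (major variant) of each final cluster is
called as a putative allele, named by class and depth rank.

`nearest_reference` reports the closest named reference by global
identity (ties to the lexicographically first name) as a helper toward
orthology-based naming, which itself is out of scope.

## CDR3 extraction

Reads are annotated against the discovered (or supplied) V/J allele
FASTAs. Hits are ranked by alignment score, *never* by identity alone —
a local alignment of the wrong reference can reach 100 % identity over a
trivially short stretch — and the best-scoring hit is assigned only if
its identity over the aligned columns exceeds 90 %. The default aligner
is an edlib infix alignment (unit costs); an affine local aligner
(+2/−3, gap −5/−2, Smith–Waterman via Biopython) is available through
`AnnotationConfig(aligner_backend="local")`. Only the >90 % identity
contract is normative; both backends honour it.

The CDR3 5′ boundary is the start of the last occurrence of the
conserved-Cys context `TG[TC]` immediately followed by `[GA][CG]`
upstream of the 3′ boundary (searched from the aligned V start when
available); the CDR3 includes this Cys codon. The 3′ boundary is either
the read position of the J reference origin (full-length mode — J
alleles are trimmed at the CDR3 border, so their origin *is* the Gly
codon) or the fixed constant-anchor offset (short-read/UMI mode). When a
J tail is exactly 31 nt the two rules coincide, which the test suite
checks on simulated reads.

A CDR3 passes the functionality filter iff its length is 15–54 nt
inclusive (5–18 residues), a multiple of 3, and its translation is
stop-free; violations are counted as `too_short`, `too_long`,
`frameshift` and `ptc` respectively. Records whose V (or J) cannot be
annotated are kept with `unassigned` labels: repertoire-size estimation
needs every CDR3, while usage statistics skip unassigned records.

## UMI error correction

Reads sharing one of the 12-nt UMIs form a MIG. The consensus rules
trade yield for precision: singleton MIGs are discarded (one read is no
evidence); a doubleton survives only if both reads are identical; in
MIGs of three or more, the most abundant sequence is the provisional
*top* (count ties lexicographic), a read *fails* if it differs from top
by more than 2 substitutions or any length difference, the MIG is
discarded as mosaic when failing reads are ≥ half ("half fails" is read
as ≥, the stricter option, and is configurable), and otherwise the
consensus is the per-position majority over passing reads with ties
resolved toward top. Length differences always fail because the
similarity threshold is substitution-only. UMI collisions produce mosaic
MIGs and are discarded, not rescued; no fuzzy UMI merging is attempted.
Consensuses collapse to unique clonotypes keyed by CDR3 nucleotide
sequence, with MIG and read counts aggregated and V/J labels decided by
majority across MIGs (ties → unassigned). Every input read is accounted
for exactly once across clonotype read counts and discard counters, and
the output is invariant to input order.

## Diversity and sharing

Chao2 estimates the lower bound of repertoire size from presence/absence
across m replicates: `S_obs + ((m−1)/m)·q1²/(2·q2)` for q2 > 0, and the
standard bias-corrected `S_obs + ((m−1)/m)·q1(q1−1)/2` when q2 = 0 (the
raw formula is undefined there; the fallback never divides by zero and
reduces to S_obs when q1 ≤ 1). Incidence is keyed on `cdr3_nt` alone by
default. Abundance-based estimators are deliberately not provided:
identical CDR3s from one expanded clone and from convergent
recombination cannot be distinguished in mRNA counts.

Rarefaction subsamples the read-level clonotype stream without
replacement on a depth grid (seeded; mean ± SD over repetitions).
Pairwise sharing is reported with two normalisations — share of the
union, and the mean of |A∩B|/|A| and |A∩B|/|B| (the headline, since the
published percentages do not pin the denominator); the intersection over
all individuals is the public repertoire, clonotypes in exactly one are
private.

## Simulator

`simulate_germline` builds V and J alleles whose translations conform to
the patterns above, with the conserved Cys/Gly at validated positions
(candidates where the leftmost pattern match would pin a spurious
Cys/Gly are rejected), pairwise identity capped at 90 % (V) / 75 % (J)
so clustering can separate them, D segments of 12–14 nt, and a constant
head beginning with the primer suffix. V alleles are 270–300 nt; J
alleles carry a 31-nt post-CDR3 tail by default so that both 3′-boundary
rules agree.

`recombine` draws V, D, J uniformly, trims up to `trim_max` (default 3)
nt per joint, inserts geometric-length N regions (default p = 0.35), and
accepts a candidate only if its CDR3 — computed by the *same* boundary
rules the pipeline uses — passes the functionality filter and the
planted segments are exactly recoverable; this rejection sampling is
what guarantees truth tables agree with a correct pipeline. Clone
frequencies default to lognormal(σ = 1), skewed enough that replicate
samples miss rare clones — the unseen-species regime Chao2 addresses.

`simulate_library` draws `molecules_per_replicate` (default 2000) cDNA
molecules per replicate from the clone frequencies, tags each with a
random 12-nt UMI, and emits `reads_per_molecule` (default 6) reads with
i.i.d. substitution errors at `per_base_error` (default 0.003). Six
reads per molecule keeps a MIG at ≥ 5 usable reads after anchor-loss
dropout, the regime where majority consensus reliably outvotes
coincident errors; at 3 reads per molecule, chance pairs of identical
substitutions (≈100 such pairs per 48k-read run at 0.3 %) can tie the
vote. Base qualities are drawn from N(37, 2), modelling sequencer
confidence only — the substitution rate models combined PCR +
sequencing error, most of which is invisible to quality strings, so the
two are deliberately independent (tying Q to a 0.3 % combined rate
would flunk every read on the mean-Q30 filter, a combination real data
does not show). `guarantee_coverage` deals every clonotype at least one
molecule per replicate; it is used by pipeline-fidelity tests (which ask
whether the pipeline loses or invents clonotypes, not whether sampling
found them) and must stay off for diversity-estimation experiments.

What the simulator does not model: PCR chimeras, indel sequencing
errors (available as an option, off by default — the consensus rules are
substitution-based), sequence-dependent error profiles, amplification
bias within a MIG, or thymic selection of the repertoire. Passing tests
therefore demonstrate correctness of the algorithms under an idealised
error model, not performance on real libraries.

## Problem sizes and determinism

End-to-end checks run at 500 clonotypes × 4 replicates (2000 molecules
per replicate), the scale at which all workflow effects — frequency
filtering, clustering, UMI dropout classes — are exercised while a full
run stays around half a minute; the Chao2 bracketing property uses 100
seeded incidence draws at 500 true clonotypes and 700 molecules per
replicate, which reproduces the ≈86 %-observed regime reported for real
repertoires. All randomness flows from explicit seeds (Python `random`
or numpy `default_rng`); reruns with the same seed are bit-identical.

## Known limitations

* Segment discovery needs reads covering the whole variable region; the
  short-read arm assumes discovery (or external references) has already
  produced allele FASTAs.
* The PROSITE subset omits anchors (`<`, `>`) and exclusion sets
  (`{..}`), which the two TCR patterns do not use.
* D segments are extracted only implicitly (inside the CDR3) and never
  called as alleles: N-additions make their germline borders
  unidentifiable from transcripts.
* Identity definitions (global, end-gap-free for J) approximate, not
  replicate, CD-HIT-EST's internal definition; thresholds are exposed so
  users can compensate.
* Chao2 is a lower bound; with near-exhaustive sampling its estimate can
  slightly exceed the true richness, which is why the bracketing
  property is stated for the undersampled regime.
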