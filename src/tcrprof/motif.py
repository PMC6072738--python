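"""PROSITE-subset protein-pattern engine for conserved V/J residue search.

The V and J gene segments of rearranged TCRβ transcripts are located
reference-free, through short patterns of conserved residues written in a
subset of the PROSITE syntax: literal residues, residue sets ``[VI]``, and
fixed or variable-length wildcards ``x``, ``x(n)``, ``x(n,m)``. Patterns
are compiled to regular expressions over the translated read; variable
wildcards match non-greedily so conserved anchors stay as close together
as the pattern allows.

Matching conventions:

* stop codons translate to ``*`` and never match any token, so ORF
  disruptions fail pattern search naturally;
* codons containing ``N`` translate to ``X``, which matches wildcards but
  not literals or sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

from Bio.Data.CodonTable import standard_dna_table

#: Conserved-residue pattern of the TCRβ V segment: frames the FR1-FR3
#: scaffold (invariant Gln/Pro, the two Cys of the Ig fold, Trp-Tyr) and
#: ends at the conserved CDR3 cysteine (the penultimate ``C`` token).
TRBV_PATTERN = "x(5)-Q-x-P-x(14)-C-x(10,11)-W-Y-x(39,42)-[LM]-x(14)-C-x"

#: Conserved-residue pattern of the TCRβ J segment: the FGxG motif context;
#: the first ``G`` literal is the conserved CDR3-closing glycine.
TRBJ_PATTERN = "x(4)-G-x-G-x(2)-L-x-[VI]-x"

#: Residues a wildcard may match: the 20 standard amino acids plus X
#: (ambiguous codon); never '*'.
_WILDCARD_CLASS = "[ACDEFGHIKLMNPQRSTVWYX]"

_AA3 = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)

_TOKEN_RE = re.compile(
    r"^(?:(?P<lit>[ACDEFGHIKLMNPQRSTVWY])"
    r"|\[(?P<set>[ACDEFGHIKLMNPQRSTVWY]+)\]"
    r"|x(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?)$"
)


@dataclass(frozen=True)
class PatternToken:
    kind: Literal["literal", "set", "wildcard"]
    residues: Optional[str]  # literal residue or set members; None for wildcards
    min_n: int
    max_n: int

    @property
    def source(self) -> str:
        if self.kind == "literal":
            return self.residues  # type: ignore[return-value]
        if self.kind == "set":
            return f"[{self.residues}]"
        if self.min_n == self.max_n:
            return "x" if self.min_n == 1 else f"x({self.min_n})"
        return f"x({self.min_n},{self.max_n})"


@dataclass(frozen=True)
class ProteinPattern:
    source: str
    tokens: tuple[PatternToken, ...]
    min_len: int
    max_len: int

    @property
    def regex(self) -> re.Pattern:
        return re.compile(_tokens_to_regex(self.tokens))


@dataclass(frozen=True)
class PatternMatch:
    """A pattern hit with paired residue and nucleotide coordinates.

    Coordinates are 0-based half-open; ``nt_start = frame + 3*aa_start``.
    """

    frame: int
    aa_start: int
    aa_end: int

    @property
    def nt_start(self) -> int:
        return self.frame + 3 * self.aa_start

    @property
    def nt_end(self) -> int:
        return self.frame + 3 * self.aa_end

    @property
    def aa_len(self) -> int:
        return self.aa_end - self.aa_start


class PatternSyntaxError(ValueError):
    pass


def _tokens_to_regex(tokens: tuple[PatternToken, ...]) -> str:
    parts = []
    for tok in tokens:
        if tok.kind == "literal":
            parts.append(tok.residues)
        elif tok.kind == "set":
            parts.append(f"[{tok.residues}]")
        else:
            if tok.min_n == tok.max_n == 1:
                parts.append(_WILDCARD_CLASS)
            elif tok.min_n == tok.max_n:
                parts.append(f"{_WILDCARD_CLASS}{{{tok.min_n}}}")
            else:
                # non-greedy: shortest span starting at a given residue
                parts.append(f"{_WILDCARD_CLASS}{{{tok.min_n},{tok.max_n}}}?")
    return "".join(parts)


def compile_pattern(source: str) -> ProteinPattern:
    """Compile PROSITE-subset text into a :class:`ProteinPattern`.

    Supported tokens: literal residues, ``[..]`` residue sets, ``x``,
    ``x(n)``, ``x(n,m)``, separated by ``-``. Raises
    :class:`PatternSyntaxError` naming the offending token otherwise.
    """
    tokens: list[PatternToken] = []
    for raw in source.strip().split("-"):
        raw = raw.strip()
        m = _TOKEN_RE.match(raw)
        if not m:
            raise PatternSyntaxError(f"malformed PROSITE token: {raw!r}")
        if m.group("lit"):
            tokens.append(PatternToken("literal", m.group("lit"), 1, 1))
        elif m.group("set"):
            tokens.append(PatternToken("set", m.group("set"), 1, 1))
        else:
            n = int(m.group("n")) if m.group("n") else 1
            mx = int(m.group("m")) if m.group("m") else n
            if mx < n:
                raise PatternSyntaxError(f"malformed PROSITE token: {raw!r}")
            tokens.append(PatternToken("wildcard", None, n, mx))
    if not tokens:
        raise PatternSyntaxError("empty pattern")
    return ProteinPattern(
        source="-".join(t.source for t in tokens),
        tokens=tuple(tokens),
        min_len=sum(t.min_n for t in tokens),
        max_len=sum(t.max_n for t in tokens),
    )


def translate(nt: str, frame: int = 0) -> str:
    """Translate a nucleotide string in the given frame.

    Stops become ``*``; codons containing N (or any non-ACGT base) become
    ``X``; trailing 1-2 nt are ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    nt = nt.upper()
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i:i + 3]
        if codon in _AA3:
            out.append(_AA3[codon])
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def find_pattern(
    aa: str,
    pattern: ProteinPattern,
    mode: Literal["first", "last", "all"] = "all",
    start: int = 0,
    end: Optional[int] = None,
) -> list[tuple[int, int]]:
    """Non-overlapping, left-to-right pattern matches as residue spans.

    Variable-length wildcards match the shortest span starting at each
    position. ``mode`` selects the first span, the last, or all of them.
    """
    region = aa[:end] if end is not None else aa
    spans = [m.span() for m in pattern.regex.finditer(region, start)]
    if not spans:
        return []
    if mode == "first":
        return [spans[0]]
    if mode == "last":
        return [spans[-1]]
    return spans


def scan_frames(
    nt: str,
    pattern: ProteinPattern,
    anchor_frame: Optional[int] = None,
    mode: Literal["first", "last"] = "first",
) -> Optional[PatternMatch]:
    """Search all three frames of an oriented read for the pattern.

    If several frames match, the frame consistent with the constant-region
    anchor is preferred when given; otherwise the longest match wins (ties
    to the lower frame).
    """
    hits: list[PatternMatch] = []
    for frame in (0, 1, 2):
        aa = translate(nt, frame)
        spans = find_pattern(aa, pattern, mode=mode)
        if spans:
            s, e = spans[0]
            hits.append(PatternMatch(frame=frame, aa_start=s, aa_end=e))
    if not hits:
        return None
    if anchor_frame is not None:
        for hit in hits:
            if hit.frame == anchor_frame:
                return hit
    return max(hits, key=lambda h: (h.aa_len, -h.frame))
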