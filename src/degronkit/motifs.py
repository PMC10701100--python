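"""Consensus degron motif grammar, compiler, and proteome scanner.

Degron motifs are short linear motifs written in a deliberately small,
auditable ELM-like grammar rather than full regular expressions:

* an uppercase letter is an exact residue (``R``);
* ``x`` or ``.`` matches any residue, including the unknown residue ``X``;
* ``[...]`` is an allowed residue class, ``[^...]`` an excluded class —
  the unknown residue ``X`` never satisfies either, because a class is a
  claim about identity and an unknown residue makes no such claim;
* ``{m,n}`` bounds repetition of the preceding token (m <= n <= 10).

The classic APC/C D-box, for example, is written ``RxxLxx[LIVM]``.

Scanning reports every placement: overlapping matches are kept, with exactly
one (greedy-longest) match per (motif, start offset). With ``internal_only``
set, matches touching the first or last residue of the protein are discarded,
restricting the scan to internal degrons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA20
from .io import LoadError, ProteinRecord

MAX_REPEAT = 10


class MotifParseError(ValueError):
    """Malformed consensus pattern; carries the offending offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Token:
    """One grammar token: an allowed-residue set plus a repetition bound."""

    allowed: frozenset[str]  # residues satisfying this position
    wildcard: bool  # True for 'x'/'.'; only wildcards accept 'X'
    min_repeat: int = 1
    max_repeat: int = 1

    def accepts(self, residue: str) -> bool:
        if residue == "X":
            return self.wildcard
        return residue in self.allowed


def _parse_class(pattern: str, i: int) -> tuple[Token, int]:
    j = pattern.find("]", i)
    if j == -1:
        raise MotifParseError("unbalanced '['", i)
    body = pattern[i + 1 : j]
    negated = body.startswith("^")
    if negated:
        body = body[1:]
    if not body:
        raise MotifParseError("empty residue class", i)
    bad = [c for c in body if c not in AA20]
    if bad:
        raise MotifParseError(f"non-residue characters {bad} in class", i)
    members = frozenset(body)
    allowed = frozenset(AA20) - members if negated else members
    if not allowed:
        raise MotifParseError("class excludes every residue", i)
    return Token(allowed=allowed, wildcard=False), j + 1


_REPEAT = re.compile(r"\{(\d+),(\d+)\}")


def parse_pattern(pattern: str) -> list[Token]:
    """Parse a consensus pattern into tokens; errors carry the offset."""
    if not pattern:
        raise MotifParseError("empty pattern", 0)
    tokens: list[Token] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            token, i = _parse_class(pattern, i)
        elif c == "]":
            raise MotifParseError("unbalanced ']'", i)
        elif c in ("x", "."):
            token = Token(allowed=frozenset(AA20), wildcard=True)
            i += 1
        elif c == "{":
            m = _REPEAT.match(pattern, i)
            if m is None:
                raise MotifParseError("malformed repetition", i)
            lo, hi = int(m.group(1)), int(m.group(2))
            if not tokens:
                raise MotifParseError("repetition with no preceding token", i)
            if lo > hi:
                raise MotifParseError(f"repetition bounds reversed ({lo} > {hi})", i)
            if hi > MAX_REPEAT:
                raise MotifParseError(f"repetition bound exceeds {MAX_REPEAT}", i)
            prev = tokens[-1]
            if (prev.min_repeat, prev.max_repeat) != (1, 1):
                raise MotifParseError("double repetition", i)
            tokens[-1] = Token(prev.allowed, prev.wildcard, lo, hi)
            i = m.end()
            continue
        elif c.isupper() and c in AA20:
            token = Token(allowed=frozenset(c), wildcard=False)
            i += 1
        else:
            raise MotifParseError(f"unexpected character {c!r}", i)
        tokens.append(token)
    return tokens


def _token_regex(token: Token) -> str:
    if token.wildcard:
        body = f"[{AA20}X]"
    else:
        body = f"[{''.join(sorted(token.allowed))}]"
    if (token.min_repeat, token.max_repeat) == (1, 1):
        return body
    return f"{body}{{{token.min_repeat},{token.max_repeat}}}"


def compile_pattern(pattern: str) -> re.Pattern[str]:
    """Compile a consensus pattern to a regex that enumerates every start
    offset (overlaps included) via a capturing lookahead."""
    tokens = parse_pattern(pattern)
    body = "".join(_token_regex(t) for t in tokens)
    return re.compile(f"(?=({body}))")


def min_match_length(tokens: Sequence[Token]) -> int:
    return sum(t.min_repeat for t in tokens)


def max_match_length(tokens: Sequence[Token]) -> int:
    return sum(t.max_repeat for t in tokens)


@dataclass(frozen=True)
class DegronMotif:
    """A named consensus pattern bound to the E3 ligase that reads it."""

    motif_name: str
    e3_ligase: str
    pattern: str
    tokens: tuple[Token, ...] = field(repr=False, default=())
    compiled: re.Pattern[str] = field(repr=False, default=None, compare=False)  # type: ignore[assignment]

    @classmethod
    def from_pattern(cls, motif_name: str, e3_ligase: str, pattern: str) -> "DegronMotif":
        tokens = tuple(parse_pattern(pattern))
        if min_match_length(tokens) < 3:
            raise MotifParseError(
                f"motif {motif_name!r} can match fewer than 3 residues", 0
            )
        return cls(motif_name, e3_ligase, pattern, tokens, compile_pattern(pattern))


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    motif_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_seq):
            raise ValueError("span length disagrees with matched sequence")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_protein(
    protein: ProteinRecord,
    motifs: Iterable[DegronMotif],
    internal_only: bool = False,
) -> list[MotifMatch]:
    """All motif placements on one protein, sorted by (start, motif_name).

    One greedy-longest match per (motif, start); identical (motif, start, end)
    duplicates are impossible by construction. Internal-only scanning drops
    matches touching residue 1 or the final residue.
    """
    seq = protein.sequence
    out: list[MotifMatch] = []
    for motif in motifs:
        for m in motif.compiled.finditer(seq):
            frag = m.group(1)
            start = m.start() + 1
            end = start + len(frag) - 1
            if internal_only and (start <= 1 or end >= len(seq)):
                continue
            out.append(MotifMatch(protein.protein_id, motif.motif_name, start, end, frag))
    out.sort(key=lambda x: (x.protein_id, x.start, x.motif_name))
    return out


def scan_proteome(
    proteome: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    motifs: Iterable[DegronMotif],
    internal_only: bool = False,
) -> list[MotifMatch]:
    """Scan every protein; output sorted by (protein_id, start, motif_name)
    and independent of the input ordering of proteins or motifs."""
    if isinstance(proteome, Mapping):
        proteins = list(proteome.values())
    else:
        proteins = list(proteome)
    motifs = sorted(motifs, key=lambda m: m.motif_name)
    out: list[MotifMatch] = []
    for protein in sorted(proteins, key=lambda p: p.protein_id):
        out.extend(scan_protein(protein, motifs, internal_only=internal_only))
    return out


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined when either vector has zero variance."""


def match_count_length_correlation(
    matches: Iterable[MotifMatch],
    proteome: Mapping[str, ProteinRecord],
) -> float:
    """Pearson correlation between per-protein match count and protein length.

    Proteins with no matches contribute a count of zero; dropping them would
    bias the diagnostic, whose whole point is that chance matches accumulate
    with length. Used before/after classifier filtering as a false-positive
    indicator.
    """
    if len(proteome) < 3:
        raise ValueError("correlation diagnostic needs at least 3 proteins")
    counts = {pid: 0 for pid in proteome}
    for m in matches:
        if m.protein_id in counts:
            counts[m.protein_id] += 1
    pids = sorted(proteome)
    x = np.array([counts[p] for p in pids], dtype=float)
    y = np.array([len(proteome[p]) for p in pids], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "zero variance in match counts or protein lengths"
        )
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Motif tables on disk
# ---------------------------------------------------------------------------

def read_motifs(path) -> list[DegronMotif]:
    """Motif definition TSV: motif_name, e3_ligase, pattern."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("motif_name", "e3_ligase", "pattern"):
        if col not in df.columns:
            raise LoadError(f"motif table missing column {col!r}")
    motifs = [
        DegronMotif.from_pattern(r.motif_name, r.e3_ligase, r.pattern)
        for r in df.itertuples(index=False)
    ]
    names = [m.motif_name for m in motifs]
    if len(set(names)) != len(names):
        raise LoadError("duplicate motif names in motif table")
    return motifs


def write_matches(matches: Iterable[MotifMatch], path) -> None:
    df = pd.DataFrame(
        [(m.protein_id, m.motif_name, m.start, m.end, m.matched_seq) for m in matches],
        columns=["protein_id", "motif_name", "start", "end", "matched_seq"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_matches(path) -> list[MotifMatch]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        MotifMatch(r.protein_id, r.motif_name, int(r.start), int(r.end), r.matched_seq)
        for r in df.itertuples(index=False)
    ]
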