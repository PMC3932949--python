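"""Dot-bracket secondary-structure parsing and topology decomposition.

A hairpin candidate is a sequence plus a nested dot-bracket structure and a
minimum free energy (MFE).  Every structure feature downstream consumes the
pairing table and its decomposition into stems, hairpin loops and bulges, so
those primitives live here.  Pseudoknots are rejected: only '(', ')' and '.'
are accepted and brackets must nest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

RNA_ALPHABET = frozenset("ACGU")
_VIENNA_STRUCT_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


class StructureParseError(ValueError):
    """Raised for malformed dot-bracket input; carries the 1-based position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class HairpinRecord:
    """One candidate precursor: sequence, structure and folding energy.

    Positions are 1-based throughout the structure layer; exported genomic
    intervals are 0-based half-open (BED convention).
    """

    id: str
    sequence: str
    structure: str
    mfe: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")
        parse_dot_bracket(self.structure)  # validates balance/nesting

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_multi_stem(self) -> bool:
        return decompose(parse_dot_bracket(self.structure)).n_hairpin_loops > 1


@dataclass(frozen=True)
class PairTable:
    """Base-pairing map of one structure, 1-based, involutive and nested."""

    length: int
    pairs: dict[int, int]

    @property
    def n_paired(self) -> int:
        return len(self.pairs)

    @property
    def n_unpaired(self) -> int:
        return self.length - len(self.pairs)

    @property
    def n_basepairs(self) -> int:
        return len(self.pairs) // 2

    def basepairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, ascending in i."""
        return sorted((i, j) for i, j in self.pairs.items() if i < j)

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.basepairs():
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class StructureElements:
    """Counts of stems, hairpin loops and bulges of one structure.

    A bulge is any maximal internal unpaired region between helices; the two
    strands of an interior loop (and all unpaired stretches of a multiloop)
    count as one bulge whose size is their total nucleotide count.  Exterior
    (dangling) unpaired ends are neither bulges nor loops.
    """

    n_stems: int
    n_hairpin_loops: int
    n_bulges: int
    bulge_sizes: tuple[int, ...] = field(default=())
    hairpin_loop_sizes: tuple[int, ...] = field(default=())
    n_exterior_unpaired: int = 0
    mcpn: int = 0

    @property
    def largest_bulge(self) -> int:
        return max(self.bulge_sizes, default=0)


def parse_dot_bracket(structure: str) -> PairTable:
    """Parse a nested dot-bracket string into a :class:`PairTable`.

    Pairing is stack-based (innermost-first); unbalanced brackets raise
    :class:`StructureParseError` naming the offending 1-based position.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for pos, char in enumerate(structure, start=1):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise StructureParseError(
                    f"unmatched ')' at position {pos}", position=pos
                )
            opener = stack.pop()
            pairs[opener] = pos
            pairs[pos] = opener
        elif char != ".":
            raise StructureParseError(
                f"invalid character {char!r} at position {pos}", position=pos
            )
    if stack:
        raise StructureParseError(
            f"unmatched '(' at position {stack[0]}", position=stack[0]
        )
    return PairTable(length=len(structure), pairs=pairs)


def max_consecutive_paired(structure: str) -> int:
    """Length of the longest run of paired positions ('(' or ')')."""
    best = run = 0
    for char in structure:
        if char in "()":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _enclosing_pair(pt: PairTable, pos: int) -> tuple[int, int] | None:
    """Innermost pair (i, j) with i < pos < j, or None (exterior)."""
    best = None
    for i, j in pt.basepairs():
        if i < pos < j and (best is None or j - i < best[1] - best[0]):
            best = (i, j)
    return best


def decompose(pt: PairTable) -> StructureElements:
    """Decompose a pairing table into stems, hairpin loops and bulges.

    Stems are maximal runs of stacked pairs (i,j), (i+1,j-1), ...  A hairpin
    loop is an unpaired region closed directly by a single pair.  Remaining
    internal unpaired runs are grouped by their innermost enclosing pair:
    each group is one bulge (so an interior loop's two strands merge).
    """
    bps = pt.basepairs()
    pair_set = set(bps)

    n_stems = sum(1 for i, j in bps if (i - 1, j + 1) not in pair_set)

    # maximal unpaired runs as (start, end) inclusive, 1-based
    runs: list[tuple[int, int]] = []
    pos = 1
    while pos <= pt.length:
        if pos not in pt.pairs:
            start = pos
            while pos <= pt.length and pos not in pt.pairs:
                pos += 1
            runs.append((start, pos - 1))
        else:
            pos += 1

    # hairpin loops: innermost pairs; a zero-size loop (adjacent pair) counts,
    # keeping n_stems >= n_hairpin_loops on degenerate structures
    hairpin_sizes = [
        j - i - 1
        for i, j in bps
        if all(p not in pt.pairs for p in range(i + 1, j))
    ]
    n_exterior = 0
    bulge_groups: dict[tuple[int, int], int] = {}
    for start, end in runs:
        size = end - start + 1
        enclosing = _enclosing_pair(pt, start)
        if enclosing is None:
            n_exterior += size
        elif enclosing == (start - 1, end + 1):
            pass  # this run is a hairpin loop, counted above
        else:
            bulge_groups[enclosing] = bulge_groups.get(enclosing, 0) + size

    return StructureElements(
        n_stems=n_stems,
        n_hairpin_loops=len(hairpin_sizes),
        n_bulges=len(bulge_groups),
        bulge_sizes=tuple(sorted(bulge_groups.values(), reverse=True)),
        hairpin_loop_sizes=tuple(sorted(hairpin_sizes, reverse=True)),
        n_exterior_unpaired=n_exterior,
        mcpn=max_consecutive_paired(pt.to_dot_bracket()),
    )


# ---------------------------------------------------------------------------
# Vienna-dialect I/O: FASTA header, sequence line, structure line " (MFE)"
# ---------------------------------------------------------------------------

def read_vienna(path) -> list[HairpinRecord]:
    """Read records in the Vienna convention: ``>id`` / sequence /
    ``structure (-12.30)``.  Multi-line sequences are not part of the dialect.
    """
    records: list[HairpinRecord] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureParseError(f"expected FASTA header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise StructureParseError(f"truncated record at {lines[i]!r}")
        rec_id = lines[i][1:].split()[0]
        sequence = lines[i + 1].upper().replace("T", "U")
        match = _VIENNA_STRUCT_RE.match(lines[i + 2])
        if not match:
            raise StructureParseError(
                f"{rec_id}: malformed structure line {lines[i + 2]!r}"
            )
        records.append(
            HairpinRecord(
                id=rec_id,
                sequence=sequence,
                structure=match.group(1),
                mfe=float(match.group(2)),
            )
        )
        i += 3
    return records


def write_vienna(records: Iterable[HairpinRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n{rec.structure} ({rec.mfe:.2f})\n")


def iter_valid_dot_brackets(length: int) -> Iterator[str]:
    """Enumerate every valid dot-bracket string of exactly `length` characters.

    Used by exhaustive-oracle tests; grows as the Motzkin numbers so keep
    length small (<= ~14).
    """
    def rec(prefix: list[str], depth: int, remaining: int) -> Iterator[str]:
        if remaining == 0:
            if depth == 0:
                yield "".join(prefix)
            return
        prefix.append(".")
        yield from rec(prefix, depth, remaining - 1)
        prefix.pop()
        if remaining > depth:  # room to close what we open
            prefix.append("(")
            yield from rec(prefix, depth + 1, remaining - 1)
            prefix.pop()
        if depth > 0:
            prefix.append(")")
            yield from rec(prefix, depth - 1, remaining - 1)
            prefix.pop()

    yield from rec([], 0, length)
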