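"""Hierarchical small-RNAome annotation of collapsed sequencing tags.

Collapsed reads (unique tag sequences with per-library counts) are filtered
to 18-35 nt and a minimum observation count of 3, then assigned to RNA
categories by successive matching against reference sets in a fixed
priority order:

    miRNA -> ncRNA (rRNA / tRNA / snRNA/snoRNA) -> repeat -> mRNA -> piRNA

A tag claimed at one level never reaches later levels.  Two refinements act
at the repeat level: hits on repeats whose class annotation names an ncRNA
type are *recalled* to that ncRNA category, and the remaining repeat hits
are re-matched against the piRNA reference so that repeat-associated piRNAs
are not lost inside the repeat bin.  Multi-mapped tags contribute
fractionally (raw count / number of mapping positions per position).
Matching allows at most one nucleotide substitution on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_TAG_LEN = 18
MAX_TAG_LEN = 35
MIN_TAG_COUNT = 3
DEFAULT_MAX_MISMATCH = 1

#: category priority; earlier wins
CATEGORY_ORDER = ("miRNA", "ncRNA", "repeat", "mRNA", "piRNA")
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA/snoRNA")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadTag:
    """A collapsed unique read with its per-library observation counts."""

    id: str
    sequence: str
    counts: dict[str, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def max_count(self) -> int:
        return max(self.counts.values(), default=0)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class TagHit:
    """One mapping position of a tag, 0-based half-open, forward-strand coords."""

    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int


class SequenceIndex:
    """Exact + 1-substitution matcher over a small set of reference sequences.

    Uses a split-half pigeonhole search: any occurrence with at most one
    substitution contains one exact half, found with ``str.find``.  Both
    strands are searched; hits are reported in forward-strand coordinates
    of the reference.  Suitable for desk-scale references; genome-scale
    alignment is imported from SAM/BED instead.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {
            name: seq.upper().replace("T", "U") for name, seq in sequences.items()
        }

    def _find_in(self, ref: str, query: str, max_mismatch: int) -> list[tuple[int, int]]:
        qlen = len(query)
        if qlen == 0 or qlen > len(ref):
            return []
        half = qlen // 2
        candidates: set[int] = set()
        for part, delta in ((query[:half], 0), (query[half:], half)):
            pos = ref.find(part)
            while pos != -1:
                start = pos - delta
                if 0 <= start <= len(ref) - qlen:
                    candidates.add(start)
                pos = ref.find(part, pos + 1)
        hits = []
        for start in sorted(candidates):
            window = ref[start : start + qlen]
            mm = sum(1 for a, b in zip(window, query) if a != b)
            if mm <= max_mismatch:
                hits.append((start, mm))
        return hits

    def find(self, query: str, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[TagHit]:
        query = query.upper().replace("T", "U")
        rc = reverse_complement(query)
        out: list[TagHit] = []
        for name, ref in self.sequences.items():
            for start, mm in self._find_in(ref, query, max_mismatch):
                out.append(TagHit(name, start, start + len(query), "+", mm))
            if rc != query:
                for start, mm in self._find_in(ref, rc, max_mismatch):
                    out.append(TagHit(name, start, start + len(query), "-", mm))
        return out


@dataclass(frozen=True)
class AnnotationAssignment:
    """Final category call of one tag with its mapping positions."""

    tag_id: str
    category: str  # one of miRNA/rRNA/tRNA/"snRNA/snoRNA"/repeat/mRNA/piRNA/unclassified
    hits: tuple[TagHit, ...] = ()
    recalled_ncRNA: bool = False
    repeat_associated_piRNA: bool = False

    @property
    def n_positions(self) -> int:
        return len(self.hits)

    def fractional_counts(self, counts: dict[str, int]) -> dict[str, float]:
        """Per-library count attributed to each single mapping position."""
        n = max(self.n_positions, 1)
        return {lib: c / n for lib, c in counts.items()}


@dataclass
class QCReport:
    n_input: int = 0
    n_length_filtered: int = 0
    n_abundance_filtered: int = 0
    n_retained: int = 0
    retained_counts: dict[str, int] = field(default_factory=dict)


def preprocess(tags: list[ReadTag]) -> tuple[list[ReadTag], QCReport]:
    """Retain tags of 18-35 nt observed at least 3 times in some library."""
    report = QCReport(n_input=len(tags))
    retained: list[ReadTag] = []
    for tag in tags:
        if not MIN_TAG_LEN <= tag.length <= MAX_TAG_LEN:
            report.n_length_filtered += 1
        elif tag.max_count < MIN_TAG_COUNT:
            report.n_abundance_filtered += 1
        else:
            retained.append(tag)
    report.n_retained = len(retained)
    totals: dict[str, int] = {}
    for tag in retained:
        for lib, c in tag.counts.items():
            totals[lib] = totals.get(lib, 0) + c
    report.retained_counts = totals
    return retained, report


@dataclass
class ReferenceSet:
    """One annotation level: named sequences, optionally class-annotated.

    ``classes`` maps a sequence id to its class string; at the repeat level
    a class naming an ncRNA type triggers the recall rule.
    """

    category: str
    sequences: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    def index(self) -> SequenceIndex:
        return SequenceIndex(self.sequences)


def _match_ncrna_class(label: str | None) -> str | None:
    if label is None:
        return None
    norm = label.strip().lower().replace("_", "/")
    for cls in NCRNA_CLASSES:
        if norm == cls.lower() or norm in cls.lower().split("/"):
            return cls
    if norm in ("snrna", "snorna", "snrna/snorna"):
        return "snRNA/snoRNA"
    return None


def hierarchical_annotate(
    tags: list[ReadTag],
    references: dict[str, ReferenceSet],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[AnnotationAssignment]:
    """Assign every tag to exactly one category by the fixed priority order.

    ``references`` keys are a subset of :data:`CATEGORY_ORDER`; missing
    levels are skipped.  The ncRNA level reports the class of the best hit
    (fewest mismatches).  Repeat-level refinements: ncRNA recall and
    repeat-associated piRNA rescue.
    """
    indexes = {
        level: references[level].index() for level in CATEGORY_ORDER if level in references
    }
    pirna_index = indexes.get("piRNA")

    assignments: list[AnnotationAssignment] = []
    for tag in tags:
        assignment = None
        for level in CATEGORY_ORDER:
            if level not in indexes:
                continue
            hits = indexes[level].find(tag.sequence, max_mismatch)
            if not hits:
                continue
            if level == "miRNA":
                assignment = AnnotationAssignment(tag.id, "miRNA", tuple(hits))
            elif level == "ncRNA":
                best = min(hits, key=lambda h: h.mismatches)
                cls = _match_ncrna_class(
                    references["ncRNA"].classes.get(best.ref_id)
                ) or "snRNA/snoRNA"
                class_hits = tuple(
                    h
                    for h in hits
                    if (_match_ncrna_class(references["ncRNA"].classes.get(h.ref_id))
                        or "snRNA/snoRNA") == cls
                )
                assignment = AnnotationAssignment(tag.id, cls, class_hits)
            elif level == "repeat":
                repeat_classes = references["repeat"].classes
                recall_class = None
                for h in sorted(hits, key=lambda h: h.mismatches):
                    recall_class = _match_ncrna_class(repeat_classes.get(h.ref_id))
                    if recall_class:
                        break
                if recall_class:
                    class_hits = tuple(
                        h
                        for h in hits
                        if _match_ncrna_class(repeat_classes.get(h.ref_id)) == recall_class
                    )
                    assignment = AnnotationAssignment(
                        tag.id, recall_class, class_hits, recalled_ncRNA=True
                    )
                else:
                    pirna_hits = (
                        pirna_index.find(tag.sequence, max_mismatch) if pirna_index else []
                    )
                    if pirna_hits:
                        assignment = AnnotationAssignment(
                            tag.id,
                            "piRNA",
                            tuple(pirna_hits),
                            repeat_associated_piRNA=True,
                        )
                    else:
                        assignment = AnnotationAssignment(tag.id, "repeat", tuple(hits))
            else:  # mRNA, piRNA
                assignment = AnnotationAssignment(tag.id, level, tuple(hits))
            break
        if assignment is None:
            assignment = AnnotationAssignment(tag.id, "unclassified", ())
        assignments.append(assignment)
    return assignments


def assignment_table(
    tags: list[ReadTag], assignments: list[AnnotationAssignment]
) -> pd.DataFrame:
    """Long-form table: one row per tag with category, flags and raw counts."""
    by_id = {t.id: t for t in tags}
    rows = []
    for a in assignments:
        tag = by_id[a.tag_id]
        row = {
            "tag_id": a.tag_id,
            "sequence": tag.sequence,
            "length": tag.length,
            "category": a.category,
            "n_positions": a.n_positions,
            "recalled_ncRNA": a.recalled_ncRNA,
            "repeat_associated_piRNA": a.repeat_associated_piRNA,
        }
        row.update(tag.counts)
        rows.append(row)
    return pd.DataFrame(rows)


def category_totals(
    tags: list[ReadTag], assignments: list[AnnotationAssignment]
) -> pd.DataFrame:
    """Raw read counts per category x library (unclassified included)."""
    table = assignment_table(tags, assignments)
    libs = [c for c in table.columns if c not in (
        "tag_id", "sequence", "length", "category", "n_positions",
        "recalled_ncRNA", "repeat_associated_piRNA")]
    return table.groupby("category")[libs].sum()


@dataclass(frozen=True)
class PrecursorLocus:
    """An annotated pre-miRNA interval, BED-style 0-based half-open."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class IsomiRGroup:
    """All tags mapping within one precursor's tolerance window.

    The window extends the precursor 2 nt upstream and 5 nt downstream
    (strand-aware); the expression value of the miRNA is the count of its
    most abundant isomiR, per library.
    """

    precursor_id: str
    member_tag_ids: list[str]
    expression: dict[str, float]
    representative: str | None = None


def quantify_mirnas(
    tags: list[ReadTag],
    genome_hits: dict[str, list[TagHit]],
    precursors: list[PrecursorLocus],
    upstream: int = 2,
    downstream: int = 5,
) -> list[IsomiRGroup]:
    """Group miRNA-tag genome hits per precursor window and quantify.

    A tag belongs to a precursor when one of its genomic hits lies entirely
    inside [start - upstream, end + downstream) on the '+' strand (mirrored
    on '-').  Tags inside several (overlapping) precursor windows count for
    each.  Expression per library = the maximum member-tag count.
    """
    by_id = {t.id: t for t in tags}
    groups: list[IsomiRGroup] = []
    for pre in precursors:
        if pre.strand == "+":
            win_start, win_end = pre.start - upstream, pre.end + downstream
        else:
            win_start, win_end = pre.start - downstream, pre.end + upstream
        members: list[str] = []
        for tag_id, hits in genome_hits.items():
            for h in hits:
                if h.ref_id == pre.chrom and h.start >= win_start and h.end <= win_end:
                    members.append(tag_id)
                    break
        libs: set[str] = set()
        for tid in members:
            libs.update(by_id[tid].counts)
        expression = {
            lib: float(max((by_id[tid].counts.get(lib, 0) for tid in members), default=0))
            for lib in sorted(libs)
        }
        rep = None
        if members:
            rep = max(members, key=lambda tid: by_id[tid].total_count)
        groups.append(IsomiRGroup(pre.id, members, expression, representative=rep))
    return groups


def rpm_normalize(
    counts: pd.DataFrame, library_totals: dict[str, float] | pd.Series
) -> pd.DataFrame:
    """Reads-per-million scaling: count / library total * 1e6."""
    totals = pd.Series(library_totals)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive library totals: {bad}")
    return counts.div(totals[counts.columns], axis=1) * 1e6


def length_category_summary(
    tags: list[ReadTag], assignments: list[AnnotationAssignment]
) -> pd.DataFrame:
    """Per-library read and unique-tag counts by (length, category).

    The backbone of bimodal-length-distribution and class-transition plots:
    total counts show abundance, unique counts show diversity.
    """
    by_id = {t.id: t for t in tags}
    rows = []
    for a in assignments:
        tag = by_id[a.tag_id]
        for lib, count in tag.counts.items():
            if count > 0:
                rows.append(
                    {
                        "library": lib,
                        "length": tag.length,
                        "category": a.category,
                        "reads": count,
                        "unique_tags": 1,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return (
        table.groupby(["library", "length", "category"], as_index=False)[
            ["reads", "unique_tags"]
        ].sum()
    )
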