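"""piRNA cluster calling and sequence summaries.

A piRNA cluster is a genomic run of at least 10 unique piRNA loci in which
every adjacent locus pair is separated by strictly less than 1 kb (gap
measured end-to-start).  Clusters are built across both strands of a
chromosome by default, with per-strand locus counts recorded; a per-strand
mode restricts runs to one strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_LOCI = 10
DEFAULT_MAX_GAP = 1000


@dataclass(frozen=True)
class PiRNALocus:
    """One piRNA-producing genomic interval (BED-style, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    sequence: str = ""
    source: str = "non_repeat_associated"  # or "repeat_associated"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty locus {self.chrom}:{self.start}-{self.end}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class PiRNACluster:
    chrom: str
    start: int
    end: int
    loci: tuple[PiRNALocus, ...]

    @property
    def n_unique_loci(self) -> int:
        return len({l.key for l in self.loci})

    @property
    def strand_counts(self) -> dict[str, int]:
        return dict(Counter(l.strand for l in self.loci))

    @property
    def source_counts(self) -> dict[str, int]:
        return dict(Counter(l.source for l in self.loci))


def cluster_loci(
    loci: list[PiRNALocus],
    min_loci: int = DEFAULT_MIN_LOCI,
    max_gap: int = DEFAULT_MAX_GAP,
    per_strand: bool = False,
) -> list[PiRNACluster]:
    """Call clusters as maximal runs of nearby unique loci.

    Duplicate loci (same chrom/start/end/strand) are collapsed first.  Within
    a chromosome (or chromosome+strand when ``per_strand``), loci sorted by
    start form a run while ``next.start - prev.end < max_gap`` (strict); runs
    with at least ``min_loci`` unique loci are emitted.  Input order never
    matters.
    """
    unique = {l.key: l for l in loci}
    groups: dict[tuple, list[PiRNALocus]] = {}
    for locus in unique.values():
        key = (locus.chrom, locus.strand) if per_strand else (locus.chrom,)
        groups.setdefault(key, []).append(locus)

    clusters: list[PiRNACluster] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda l: (l.start, l.end, l.strand))
        run: list[PiRNALocus] = []
        prev_end = None
        for locus in members + [None]:
            if locus is not None and (prev_end is None or locus.start - prev_end < max_gap):
                run.append(locus)
                prev_end = locus.end
            else:
                if len(run) >= min_loci:
                    clusters.append(
                        PiRNACluster(
                            chrom=run[0].chrom,
                            start=min(l.start for l in run),
                            end=max(l.end for l in run),
                            loci=tuple(run),
                        )
                    )
                if locus is not None:
                    run = [locus]
                    prev_end = locus.end
    return clusters


def length_histogram(
    sequences: list[str], proportions: bool = False
) -> pd.Series:
    """Length distribution of piRNA sequences (counts or proportions)."""
    lengths = pd.Series([len(s) for s in sequences], dtype=int)
    hist = lengths.value_counts().sort_index()
    if proportions and len(lengths):
        hist = hist / hist.sum()
    return hist


def five_prime_logo_matrix(sequences: list[str], k: int = 15) -> pd.DataFrame:
    """Positionwise nucleotide frequencies of the 5'-terminal k nt.

    Sequences shorter than k are dropped (their number is reported via the
    attrs of the result).  Rows are positions 1..k, columns A/C/G/U; every
    row sums to 1.
    """
    kept = [s.upper().replace("T", "U")[:k] for s in sequences if len(s) >= k]
    if not kept:
        raise ValueError(f"no sequences of length >= {k}")
    counts = np.zeros((k, 4))
    lookup = {nt: i for i, nt in enumerate("ACGU")}
    for seq in kept:
        for pos, nt in enumerate(seq):
            if nt in lookup:
                counts[pos, lookup[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    table = pd.DataFrame(freqs, index=range(1, k + 1), columns=list("ACGU"))
    table.attrs["n_used"] = len(kept)
    table.attrs["n_dropped"] = len(sequences) - len(kept)
    return table


def clusters_to_bed(clusters: list[PiRNACluster]) -> pd.DataFrame:
    """BED-style cluster table with locus-count and strand-composition columns."""
    rows = []
    for i, c in enumerate(clusters):
        strands = c.strand_counts
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "name": f"pi_cluster_{i:03d}",
                "n_unique_loci": c.n_unique_loci,
                "strand_plus": strands.get("+", 0),
                "strand_minus": strands.get("-", 0),
                "repeat_associated": c.source_counts.get("repeat_associated", 0),
            }
        )
    return pd.DataFrame(rows)
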