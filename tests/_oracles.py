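"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by a different route than the package
(union-find stem grouping, per-position enclosing-pair scans, all-window run
checks) so agreement is evidence, not tautology.
"""

from __future__ import annotations


def decompose_oracle(structure: str) -> tuple[int, int, int, int]:
    """(n_stems, n_hairpin_loops, n_bulges, largest_bulge) by region labelling."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure, 1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[j], pairs[i] = i, j
    bps = sorted((i, j) for i, j in pairs.items() if i < j)
    bpset = set(bps)

    # stems via union-find over stacked neighbours
    parent = {bp: bp for bp in bps}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in bps:
        if (i + 1, j - 1) in bpset:
            parent[find((i + 1, j - 1))] = find((i, j))
    n_stems = len({find(bp) for bp in bps})

    # hairpin loops: pairs with a fully unpaired interior (size may be 0)
    hairpin_positions: set[int] = set()
    n_hairpin = 0
    for i, j in bps:
        interior = list(range(i + 1, j))
        if all(p not in pairs for p in interior):
            n_hairpin += 1
            hairpin_positions.update(interior)

    # bulges: remaining internal unpaired positions grouped by the innermost
    # enclosing pair
    groups: dict[tuple[int, int], int] = {}
    for p in range(1, len(structure) + 1):
        if p in pairs or p in hairpin_positions:
            continue
        enclosing = [(i, j) for i, j in bps if i < p < j]
        if not enclosing:
            continue  # exterior
        inner = min(enclosing, key=lambda ij: ij[1] - ij[0])
        groups[inner] = groups.get(inner, 0) + 1
    sizes = list(groups.values())
    return n_stems, n_hairpin, len(groups), max(sizes, default=0)


def cluster_oracle(loci, min_loci: int, max_gap: int) -> set[tuple]:
    """Maximal valid runs by checking every contiguous window of sorted loci.

    Returns a set of (chrom, start, end, n_loci) tuples for comparison.
    """
    out = set()
    by_chrom: dict[str, list] = {}
    for locus in {l.key: l for l in loci}.values():
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom, members in by_chrom.items():
        members.sort(key=lambda l: (l.start, l.end, l.strand))
        n = len(members)
        bad = [0]  # prefix count of adjacent gaps >= max_gap
        for k in range(n - 1):
            bad.append(bad[-1] + (members[k + 1].start - members[k].end >= max_gap))

        def run_valid(a, b):  # inclusive indices: no over-limit gap inside
            return bad[b] - bad[a] == 0

        for a in range(n):
            for b in range(a, n):
                if not run_valid(a, b):
                    continue
                # maximal: cannot extend either way
                if a > 0 and run_valid(a - 1, b):
                    continue
                if b < n - 1 and run_valid(a, b + 1):
                    continue
                if b - a + 1 >= min_loci:
                    out.add(
                        (
                            chrom,
                            min(l.start for l in members[a : b + 1]),
                            max(l.end for l in members[a : b + 1]),
                            b - a + 1,
                        )
                    )
    return out


def fscore_oracle(pos: list[float], neg: list[float]) -> float:
    """Direct transcription of the F-score definition, scalar arithmetic only."""
    n_p, n_n = len(pos), len(neg)
    mean_all = sum(pos + neg) / (n_p + n_n)
    mean_p = sum(pos) / n_p
    mean_n = sum(neg) / n_n
    num = (mean_p - mean_all) ** 2 + (mean_n - mean_all) ** 2
    den = sum((x - mean_p) ** 2 for x in pos) / (n_p - 1) + sum(
        (x - mean_n) ** 2 for x in neg
    ) / (n_n - 1)
    if den == 0:
        return float("inf") if mean_p != mean_n else 0.0
    return num / den
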