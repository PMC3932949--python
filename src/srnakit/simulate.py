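"""Seeded synthetic-data generation with known ground truth.

Everything the toolkit consumes can be generated here at desk scale: a toy
genome with planted pre-miRNA hairpins, piRNA clusters (some inside
repeats), class-annotated repeats, mRNAs and ncRNAs; stage-wise collapsed
read libraries with a programmable piRNA-to-miRNA abundance shift and the
bimodal 22 nt / 28 nt length profile characteristic of embryonic small-RNA
libraries; and labelled real-vs-pseudo hairpin training sets.

Folding is never invoked: hairpin structures are emitted directly by
construction and free energies are drawn from a pairing-dependent linear
model with noise, so the suite runs deterministically with no external
tools.  An adapter can substitute real folded structures where needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ReadTag, ReferenceSet
from .features import feature_matrix
from .pirna import PiRNALocus
from .annotate import PrecursorLocus
from .structures import HairpinRecord

NUCLEOTIDES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

STAGE_NAMES = tuple(f"stage{i}" for i in range(1, 9))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(NUCLEOTIDES), size=length, p=p))


def _synthetic_mfe(rng: np.random.Generator, structure: str, sequence: str) -> float:
    """Pairing-dependent linear energy model with Gaussian noise.

    Roughly -1 kcal/mol per base pair with a GC bonus, mimicking the rank
    ordering (not the values) of a thermodynamic folder: heavily paired
    hairpins land near -30 kcal/mol, sparse folds near -5.
    """
    n_bp = structure.count("(")
    gc = sum(1 for c in sequence if c in "GC") / max(len(sequence), 1)
    mfe = -(0.85 * n_bp + 8.0 * gc) + rng.normal(0.0, 1.2)
    return round(min(mfe, -0.1), 2)


# ---------------------------------------------------------------------------
# Hairpin training sets
# ---------------------------------------------------------------------------

def make_stemloop(
    rng: np.random.Generator,
    arm: int | None = None,
    loop: int | None = None,
    with_bulge: bool | None = None,
    gc: float = 0.55,
) -> tuple[str, str]:
    """One single-stem hairpin (sequence, structure) built inside-out."""
    arm = arm if arm is not None else int(rng.integers(25, 36))
    loop = loop if loop is not None else int(rng.integers(4, 9))
    with_bulge = bool(rng.random() < 0.6) if with_bulge is None else with_bulge

    seq = _random_seq(rng, loop, gc=0.4)
    struct = "." * loop
    inner = int(rng.integers(8, arm - 4)) if with_bulge else arm
    stem1 = _random_seq(rng, inner, gc=gc)
    seq = stem1 + seq + _revcomp(stem1)
    struct = "(" * inner + struct + ")" * inner
    if with_bulge:
        bulge = int(rng.integers(1, 5))
        seq = _random_seq(rng, bulge, gc=0.4) + seq
        struct = "." * bulge + struct
        outer = arm - inner
        stem2 = _random_seq(rng, outer, gc=gc)
        seq = stem2 + seq + _revcomp(stem2)
        struct = "(" * outer + struct + ")" * outer
    # dangling ends, as folders leave on real precursors
    lead, tail = int(rng.integers(0, 4)), int(rng.integers(0, 4))
    seq = _random_seq(rng, lead, gc=0.4) + seq + _random_seq(rng, tail, gc=0.4)
    struct = "." * lead + struct + "." * tail
    return seq, struct


def make_sparse_fold(rng: np.random.Generator, length: int) -> tuple[str, str]:
    """A shuffled-composition decoy with one short helix and long loops."""
    seq = _random_seq(rng, length, gc=0.45)
    helix = int(rng.integers(4, 9))
    loop = int(rng.integers(10, 20))
    span = 2 * helix + loop
    lead = int(rng.integers(0, max(length - span, 1)))
    struct = (
        "." * lead
        + "(" * helix
        + "." * loop
        + ")" * helix
        + "." * (length - lead - span)
    )
    return seq, struct[:length]


def generate_hairpin_sets(
    n_pos: int = 200, n_neg: int = 200, seed: int = 0
) -> tuple[list[HairpinRecord], list[HairpinRecord]]:
    """Labelled training data: real-hairpin-like positives, decoy negatives.

    Positives are long stacked stem-loops with strongly negative synthetic
    energies; negatives share the composition range but fold sparsely with
    weak energies.  Class separation of at least 2 pooled SD on at least 5
    catalog features is verified at generation time.
    """
    rng = np.random.default_rng(seed)
    positives, negatives = [], []
    for i in range(n_pos):
        seq, struct = make_stemloop(rng)
        positives.append(
            HairpinRecord(f"pos_{i:04d}", seq, struct, _synthetic_mfe(rng, struct, seq))
        )
    for i in range(n_neg):
        length = int(rng.integers(60, 90))
        seq, struct = make_sparse_fold(rng, length)
        negatives.append(
            HairpinRecord(f"neg_{i:04d}", seq, struct, _synthetic_mfe(rng, struct, seq))
        )
    _check_separation(positives, negatives)
    return positives, negatives


def _check_separation(
    positives: list[HairpinRecord], negatives: list[HairpinRecord], min_features: int = 5
) -> None:
    pos = feature_matrix(positives)
    neg = feature_matrix(negatives)
    separated = 0
    for name in pos.columns:
        pooled_sd = np.sqrt((pos[name].var() + neg[name].var()) / 2)
        if pooled_sd > 0 and abs(pos[name].mean() - neg[name].mean()) >= 2 * pooled_sd:
            separated += 1
    if separated < min_features:
        raise RuntimeError(
            f"hairpin sets separate on only {separated} features (< {min_features})"
        )


def random_structures(n: int = 1000, seed: int = 0) -> list[HairpinRecord]:
    """A mixed bag of valid structures for property tests: stem-loops,
    sparse folds, and a few fully unpaired degenerates."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        kind = rng.random()
        if kind < 0.45:
            seq, struct = make_stemloop(rng)
        elif kind < 0.9:
            seq, struct = make_sparse_fold(rng, int(rng.integers(40, 90)))
        else:
            length = int(rng.integers(20, 60))
            seq, struct = _random_seq(rng, length), "." * length
        mfe = _synthetic_mfe(rng, struct, seq) if "(" in struct else 0.0
        records.append(HairpinRecord(f"rand_{i:05d}", seq, struct, mfe))
    return records


# ---------------------------------------------------------------------------
# Toy genome + stage-wise libraries
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Study conditions for the toy small-RNAome.

    Defaults emulate an eight-stage embryonic time course: 50,000 reads per
    stage, piRNA abundance falling from 80% to 10% while miRNA rises from
    5% to 60%, miRNA read lengths near 22 nt and piRNA lengths near 28 nt.
    """

    seed: int = 0
    genome_length: int = 120_000
    n_premirnas: int = 20
    n_pirna_clusters: int = 4
    loci_per_cluster: int = 12
    cluster_spacing: int = 500
    repeat_assoc_cluster_fraction: float = 0.5
    n_repeats: int = 6
    n_ncrna_labelled_repeats: int = 2
    n_ncrnas_per_class: int = 3
    n_mrnas: int = 6
    stages: tuple[str, ...] = STAGE_NAMES
    reads_per_stage: int = 50_000
    pirna_start: float = 0.8
    pirna_end: float = 0.1
    mirna_start: float = 0.05
    mirna_end: float = 0.6
    other_proportions: dict = field(
        default_factory=lambda: {
            "rRNA": 0.04,
            "tRNA": 0.03,
            "snRNA/snoRNA": 0.02,
            "repeat": 0.03,
            "mRNA": 0.02,
        }
    )
    mismatch_rate: float = 0.0

    def stage_proportions(self) -> pd.DataFrame:
        n = len(self.stages)
        pirna = np.linspace(self.pirna_start, self.pirna_end, n)
        mirna = np.linspace(self.mirna_start, self.mirna_end, n)
        rows = {}
        for i, stage in enumerate(self.stages):
            props = dict(self.other_proportions)
            props["piRNA"] = pirna[i]
            props["miRNA"] = mirna[i]
            rest = 1.0 - sum(props.values())
            if rest < 0:
                raise ValueError(f"proportions exceed 1 at {stage}")
            props["unclassified"] = rest
            rows[stage] = props
        return pd.DataFrame(rows)


@dataclass
class Fixture:
    """Generated toy data plus its truth tables."""

    spec: FixtureSpec
    genome: dict[str, str]
    precursors: list[PrecursorLocus]
    mature_sequences: dict[str, str]
    pirna_loci: list[PiRNALocus]
    references: dict[str, ReferenceSet]
    tags: list[ReadTag]
    truth: dict[str, str]  # tag id -> planted category
    planted_totals: pd.DataFrame  # category x stage read counts

    def write(self, outdir) -> None:
        """Emit the fixture as plain-text files plus a JSON truth manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        for category, ref in self.references.items():
            fname = category.replace("/", "_") + ".fa"
            with open(out / fname, "w") as fh:
                for name, seq in ref.sequences.items():
                    cls = ref.classes.get(name)
                    header = f">{name}" + (f" class={cls}" if cls else "")
                    fh.write(f"{header}\n{seq}\n")
        pd.DataFrame(
            [
                {"chrom": p.chrom, "start": p.start, "end": p.end,
                 "name": p.id, "score": 0, "strand": p.strand}
                for p in self.precursors
            ]
        ).to_csv(out / "premirnas.bed", sep="\t", header=False, index=False)
        pd.DataFrame(
            [
                {"chrom": l.chrom, "start": l.start, "end": l.end,
                 "name": f"pi_{i:04d}", "score": 0, "strand": l.strand}
                for i, l in enumerate(self.pirna_loci)
            ]
        ).to_csv(out / "pirna_loci.bed", sep="\t", header=False, index=False)
        rows = []
        for tag in self.tags:
            row = {"tag_id": tag.id, "sequence": tag.sequence}
            row.update(tag.counts)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "tags.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.spec.seed,
            "stages": list(self.spec.stages),
            "truth": self.truth,
            "planted_totals": {
                s: self.planted_totals[s].to_dict() for s in self.planted_totals.columns
            },
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def generate(spec: FixtureSpec | None = None) -> Fixture:
    """Build the toy genome, references and stage libraries for a spec."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"

    genome = list(_random_seq(rng, spec.genome_length))
    cursor = 500

    def plant(seq: str, gap_after: int) -> int:
        nonlocal cursor
        start = cursor
        end = start + len(seq)
        if end > spec.genome_length:
            raise ValueError(
                f"infeasible spec: features need {end} nt, genome has {spec.genome_length}"
            )
        genome[start:end] = list(seq)
        cursor = end + gap_after
        return start

    # --- pre-miRNAs: single stem-loops; mature = the 5' arm's first 22 nt ---
    precursors: list[PrecursorLocus] = []
    mature_sequences: dict[str, str] = {}
    mirna_windows: dict[str, tuple[int, int]] = {}
    for i in range(spec.n_premirnas):
        seq, struct = make_stemloop(rng, with_bulge=False)
        start = plant(seq, gap_after=int(rng.integers(300, 600)))
        pre_id = f"pre_mir_{i:03d}"
        precursors.append(PrecursorLocus(pre_id, chrom, start, start + len(seq), "+"))
        lead = len(struct) - len(struct.lstrip("."))
        mature_sequences[f"mir_{i:03d}"] = seq[lead : lead + 22]
        mirna_windows[pre_id] = (start - 2, start + len(seq) + 5)

    # --- piRNA clusters, some embedded in repeats ---
    pirna_loci: list[PiRNALocus] = []
    repeat_seqs: dict[str, str] = {}
    repeat_classes: dict[str, str] = {}
    n_assoc = int(round(spec.n_pirna_clusters * spec.repeat_assoc_cluster_fraction))
    for c in range(spec.n_pirna_clusters):
        repeat_assoc = c < n_assoc
        cluster_start = cursor
        for j in range(spec.loci_per_cluster):
            length = int(
                rng.choice([26, 27, 28, 29, 30], p=[0.08, 0.22, 0.40, 0.22, 0.08])
            )
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _random_seq(rng, length)
            if rng.random() < 0.8:  # 5'-U bias on the piRNA's own 5' end
                seq = "U" + seq[1:]
            start = plant(
                seq if strand == "+" else _revcomp(seq),
                gap_after=spec.cluster_spacing - length,
            )
            pirna_loci.append(
                PiRNALocus(
                    chrom, start, start + length, strand,
                    sequence=seq,
                    source="repeat_associated" if repeat_assoc else "non_repeat_associated",
                )
            )
        cluster_end = cursor
        cursor += 3000  # > max_gap, so clusters never merge
        if repeat_assoc:
            rep_id = f"repeat_pi_{c:02d}"
            repeat_seqs[rep_id] = "".join(genome[cluster_start:cluster_end])

    # --- plain repeats, ncRNA-labelled repeats, ncRNAs, mRNAs ---
    for i in range(spec.n_repeats):
        seq = _random_seq(rng, int(rng.integers(200, 400)))
        plant(seq, gap_after=int(rng.integers(200, 400)))
        repeat_seqs[f"repeat_{i:02d}"] = seq
    labelled_classes = ["tRNA", "rRNA", "snRNA/snoRNA"]
    for i in range(spec.n_ncrna_labelled_repeats):
        cls = labelled_classes[i % len(labelled_classes)]
        seq = _random_seq(rng, int(rng.integers(150, 250)))
        plant(seq, gap_after=int(rng.integers(200, 400)))
        rep_id = f"repeat_nc_{i:02d}"
        repeat_seqs[rep_id] = seq
        repeat_classes[rep_id] = cls

    ncrna_seqs: dict[str, str] = {}
    ncrna_classes: dict[str, str] = {}
    for cls, prefix in (("rRNA", "rrna"), ("tRNA", "trna"), ("snRNA/snoRNA", "snrna")):
        for i in range(spec.n_ncrnas_per_class):
            seq = _random_seq(rng, int(rng.integers(100, 200)))
            plant(seq, gap_after=int(rng.integers(150, 300)))
            ncrna_seqs[f"{prefix}_{i:02d}"] = seq
            ncrna_classes[f"{prefix}_{i:02d}"] = cls

    mrna_seqs: dict[str, str] = {}
    for i in range(spec.n_mrnas):
        seq = _random_seq(rng, int(rng.integers(400, 700)))
        plant(seq, gap_after=int(rng.integers(200, 400)))
        mrna_seqs[f"mrna_{i:02d}"] = seq

    intergenic_start = cursor + 500
    if intergenic_start + 5000 > spec.genome_length:
        raise ValueError("infeasible spec: no intergenic room left for decoy reads")
    genome_str = "".join(genome)

    references = {
        "miRNA": ReferenceSet(
            "miRNA",
            {
                p.id: genome_str[mirna_windows[p.id][0] : mirna_windows[p.id][1]]
                for p in precursors
            },
        ),
        "ncRNA": ReferenceSet("ncRNA", ncrna_seqs, classes=ncrna_classes),
        "repeat": ReferenceSet("repeat", repeat_seqs, classes=repeat_classes),
        "mRNA": ReferenceSet("mRNA", mrna_seqs),
        "piRNA": ReferenceSet(
            "piRNA", {f"pi_{i:04d}": l.sequence for i, l in enumerate(pirna_loci)}
        ),
    }

    # --- read pools per category: small pools keep every tag above the
    # count-3 floor at 50k reads per stage ---
    pools: dict[str, list[str]] = {"miRNA": [], "piRNA": []}
    for i, p in enumerate(precursors):
        mature = mature_sequences[f"mir_{i:03d}"]
        mature_start = p.start + genome_str[p.start : p.end].find(mature)
        for offset in (-2, -1, 0, 1, 2):  # stays inside the -2/+5 window
            for length in (21, 22, 22, 22, 23):  # canonical 22-mer dominates
                s = mature_start + offset
                pools["miRNA"].append(genome_str[s : s + length])
    pools["piRNA"] = [l.sequence for l in pirna_loci]

    def substr_pool(seqs: dict[str, str], n: int, lo=18, hi=35) -> list[str]:
        names = sorted(seqs)
        out = []
        for _ in range(n):
            name = names[int(rng.integers(len(names)))]
            seq = seqs[name]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(len(seq) - length, 1)))
            out.append(seq[start : start + length])
        return out

    # ncRNA pools mix direct Rfam-style hits with reads from class-labelled
    # repeats, so the recall path carries real traffic in the pipeline
    for cls in ("rRNA", "tRNA", "snRNA/snoRNA"):
        pool = substr_pool(
            {k: v for k, v in ncrna_seqs.items() if ncrna_classes[k] == cls}, 25
        )
        labelled = {
            k: repeat_seqs[k] for k in repeat_classes if repeat_classes[k] == cls
        }
        if labelled:
            pool += substr_pool(labelled, 8)
        pools[cls] = pool
    plain_repeats = {
        k: v
        for k, v in repeat_seqs.items()
        if k not in repeat_classes and not k.startswith("repeat_pi_")
    }
    pools["repeat"] = substr_pool(plain_repeats, 30)
    pools["mRNA"] = substr_pool(mrna_seqs, 30)
    pools["unclassified"] = substr_pool(
        {"intergenic": genome_str[intergenic_start : intergenic_start + 5000]}, 30
    )

    # de-duplicate pools (a repeated draw would double-count a tag); weight
    # miRNA pool entries toward the canonical 22-mer
    pools = {cat: sorted(set(p)) for cat, p in pools.items()}
    pool_weights: dict[str, np.ndarray] = {}
    for cat, pool in pools.items():
        if cat == "miRNA":
            w = np.array([3.0 if len(s) == 22 else 1.0 for s in pool])
        else:
            w = np.ones(len(pool))
        pool_weights[cat] = w / w.sum()

    proportions = spec.stage_proportions()
    categories = list(proportions.index)
    tag_counts: dict[str, dict[str, int]] = {}
    tag_truth: dict[str, str] = {}
    seq_to_id: dict[str, str] = {}
    planted = pd.DataFrame(0, index=categories, columns=list(spec.stages))

    for stage in spec.stages:
        n_per_cat = rng.multinomial(
            spec.reads_per_stage, proportions[stage].to_numpy()
        )
        for cat, n_reads in zip(categories, n_per_cat):
            pool = pools[cat]
            draws = rng.multinomial(n_reads, pool_weights[cat])
            planted.loc[cat, stage] += int(n_reads)
            for seq, count in zip(pool, draws):
                if count == 0:
                    continue
                if spec.mismatch_rate > 0 and rng.random() < spec.mismatch_rate:
                    pos = int(rng.integers(len(seq)))
                    alt = rng.choice([c for c in NUCLEOTIDES if c != seq[pos]])
                    seq = seq[:pos] + alt + seq[pos + 1 :]
                tag_id = seq_to_id.get(seq)
                if tag_id is None:
                    tag_id = f"tag_{len(seq_to_id):05d}"
                    seq_to_id[seq] = tag_id
                    tag_truth[tag_id] = cat
                tag_counts.setdefault(tag_id, {})[stage] = (
                    tag_counts.get(tag_id, {}).get(stage, 0) + int(count)
                )

    tags = [
        ReadTag(tag_id, seq, {s: tag_counts[tag_id].get(s, 0) for s in spec.stages})
        for seq, tag_id in sorted(seq_to_id.items(), key=lambda kv: kv[1])
    ]

    return Fixture(
        spec=spec,
        genome={chrom: genome_str},
        precursors=precursors,
        mature_sequences=mature_sequences,
        pirna_loci=pirna_loci,
        references=references,
        tags=tags,
        truth=tag_truth,
        planted_totals=planted,
    )
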