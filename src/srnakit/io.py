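"""Shared plain-text readers and writers (FASTA, tag TSV, BED6, matrices).

Every writer stamps a ``# srnakit-format: <name>/1`` comment header on TSV
outputs; readers tolerate and strip such comments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotate import ReadTag
from .pirna import PiRNALocus

FORMAT_TAG = "# srnakit-format: {}/1\n"


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered id -> RNA-uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tag_table(path) -> list[ReadTag]:
    """Collapsed tag TSV: tag_id, sequence, then one count column per library."""
    table = pd.read_csv(path, sep="\t", comment="#")
    libs = [c for c in table.columns if c not in ("tag_id", "sequence")]
    return [
        ReadTag(
            str(row["tag_id"]),
            str(row["sequence"]).upper().replace("T", "U"),
            {lib: int(row[lib]) for lib in libs},
        )
        for _, row in table.iterrows()
    ]


def write_tsv(table: pd.DataFrame, path, fmt: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_TAG.format(fmt))
        table.to_csv(fh, sep="\t", index=index)


def read_bed_loci(path) -> list[PiRNALocus]:
    """BED6 -> piRNA loci (name/score columns optional)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    table = pd.read_csv(path, sep="\t", comment="#", header=None)
    table.columns = names[: table.shape[1]]
    if "strand" not in table.columns:
        table["strand"] = "+"
    return [
        PiRNALocus(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"]))
        for _, r in table.iterrows()
    ]


def write_bed_loci(loci: list[PiRNALocus], path) -> None:
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\tlocus_{i:04d}\t0\t{l.strand}\n")


def ensure_dir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
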