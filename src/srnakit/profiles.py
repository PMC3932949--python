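"""miRNA-centric summaries and novel-candidate triage.

Mature miRNAs are grouped into families by the seed (positions 2-8,
1-based), positionwise nucleotide preferences are tabulated over
5'-anchored alignments, per-stage top-k families are ranked from RPM
expression, and candidate novel precursors are scored with the trained
hairpin classifier and kept at a probability cutoff (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import HairpinClassifier
from .features import feature_matrix
from .structures import HairpinRecord

SEED_START = 2  # 1-based, inclusive
SEED_END = 8
DEFAULT_CUTOFF = 0.8


def seed_of(mature: str) -> str:
    """The 7-nt seed: mature positions 2-8, 1-based inclusive."""
    if len(mature) < SEED_END:
        raise ValueError(f"mature sequence shorter than {SEED_END} nt: {mature!r}")
    return mature.upper().replace("T", "U")[SEED_START - 1 : SEED_END]


def seed_family(matures: dict[str, str]) -> tuple[dict[str, list[str]], list[str]]:
    """Group mature miRNAs by identical seed.

    Returns (families keyed by seed -> member ids, skipped ids shorter than
    8 nt).
    """
    families: dict[str, list[str]] = {}
    skipped: list[str] = []
    for name, seq in matures.items():
        if len(seq) < SEED_END:
            skipped.append(name)
            continue
        families.setdefault(seed_of(seq), []).append(name)
    return {k: sorted(v) for k, v in sorted(families.items())}, skipped


def family_expression(
    families: dict[str, list[str]], expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-family expression = sum of member expression, per library."""
    rows = {}
    for seed, members in families.items():
        present = [m for m in members if m in expression.index]
        rows[seed] = expression.loc[present].sum() if present else pd.Series(
            0.0, index=expression.columns
        )
    return pd.DataFrame(rows).T


def position_preferences(sequences: list[str]) -> pd.DataFrame:
    """Nucleotide frequency per 5'-anchored position.

    Ragged 3' ends are handled with per-position denominators (only
    sequences long enough to reach a position contribute there).  Rows sum
    to 1 wherever at least one sequence contributes.
    """
    seqs = [s.upper().replace("T", "U") for s in sequences]
    max_len = max((len(s) for s in seqs), default=0)
    counts = np.zeros((max_len, 4))
    lookup = {nt: i for i, nt in enumerate("ACGU")}
    for seq in seqs:
        for pos, nt in enumerate(seq):
            if nt in lookup:
                counts[pos, lookup[nt]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(freqs, index=range(1, max_len + 1), columns=list("ACGU"))


def top_families(expression: pd.DataFrame, k: int = 5) -> dict[str, list[str]]:
    """Per stage (column), the k most expressed families, ties by family id."""
    ranked = {}
    for stage in expression.columns:
        order = expression[stage].sort_values(ascending=False, kind="mergesort")
        ranked[stage] = list(order.index[: max(k, 0)])
    return ranked


@dataclass
class NovelCandidate:
    """A candidate novel miRNA: precursor hairpin, mature arm, stage counts."""

    id: str
    precursor: HairpinRecord
    mature_start: int  # 0-based on the precursor
    mature_len: int
    counts: dict[str, float] = field(default_factory=dict)
    score: float | None = None

    @property
    def mature_sequence(self) -> str:
        return self.precursor.sequence[self.mature_start : self.mature_start + self.mature_len]


def read_candidate_table(path) -> list[NovelCandidate]:
    """Load candidates from the interchange TSV.

    Required columns: id, precursor_seq, structure, mfe, mature_start,
    mature_len; every remaining column is treated as a per-stage count.
    Rows whose structure fails to parse are skipped with a reason recorded
    in the returned objects' companion list (see :func:`filter_novel`).
    """
    table = pd.read_csv(path, sep="\t")
    required = {"id", "precursor_seq", "structure", "mfe", "mature_start", "mature_len"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    stage_cols = [c for c in table.columns if c not in required]
    candidates = []
    for _, row in table.iterrows():
        rec = HairpinRecord(
            id=str(row["id"]),
            sequence=str(row["precursor_seq"]).upper().replace("T", "U"),
            structure=str(row["structure"]),
            mfe=float(row["mfe"]),
        )
        candidates.append(
            NovelCandidate(
                id=str(row["id"]),
                precursor=rec,
                mature_start=int(row["mature_start"]),
                mature_len=int(row["mature_len"]),
                counts={c: float(row[c]) for c in stage_cols},
            )
        )
    return candidates


def filter_novel(
    candidates: list[NovelCandidate],
    model: HairpinClassifier,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[NovelCandidate], pd.DataFrame]:
    """Score candidates with the hairpin classifier; keep score >= cutoff.

    Returns (accepted candidates, audit table of every candidate with its
    score and fate, descending by score).  Invalid rows (unparseable
    structure) are skipped with reason "invalid".
    """
    valid: list[NovelCandidate] = []
    audit_rows = []
    for cand in candidates:
        try:
            cand.precursor  # construction already validated; keep hook for lazy inputs
            valid.append(cand)
        except Exception as exc:  # pragma: no cover - defensive
            audit_rows.append({"id": cand.id, "score": np.nan, "accepted": False,
                               "reason": f"invalid: {exc}"})
    if valid:
        matrix = feature_matrix([c.precursor for c in valid])
        scores = model.predict_score(matrix)
        for cand, score in zip(valid, scores):
            cand.score = float(score)
            audit_rows.append(
                {
                    "id": cand.id,
                    "score": float(score),
                    "accepted": bool(score >= cutoff),
                    "reason": "ok" if score >= cutoff else "below_cutoff",
                }
            )
    audit = pd.DataFrame(audit_rows).sort_values(
        "score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    accepted = [c for c in valid if c.score is not None and c.score >= cutoff]
    accepted.sort(key=lambda c: (-c.score, c.id))
    return accepted, audit


def novel_report(accepted: list[NovelCandidate]) -> pd.DataFrame:
    """Result table: name, per-stage counts, classifier score (descending)."""
    rows = []
    for cand in accepted:
        row = {"name": cand.id}
        row.update(cand.counts)
        row["score"] = cand.score
        rows.append(row)
    return pd.DataFrame(rows)
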