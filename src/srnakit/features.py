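"""The 65-feature hairpin catalog and F-score feature-set selection.

Features, in export order:

====== ==========================================================
No.    Feature
====== ==========================================================
1      %(|G|+|C|) — GC content in percent
2–17   %XY — overlapping dinucleotide frequencies in percent
18     MCPN — maximum consecutive paired nucleotides
19–26  pairing-topology scalars (r_p_n, r_unp_n, r_p_unp,
       avg_bp_stem, dP, n_bulge, r_unp_bulge, r_bulge_l)
27–58  32 triplet structure-sequence elements (frequencies)
59–65  MFE and MFE-derived ratios (dG, MFE1–MFE5)
====== ==========================================================

A triplet element is the paired/unpaired pattern of three consecutive
positions combined with the middle nucleotide ('(' and ')' collapse to one
"paired" state), giving 8 x 4 = 32 categories; frequencies are normalized by
the number of interior windows (L - 2).

Ratios with a vanishing denominator (no unpaired nt, zero stems/loops/
bulges/pairs) are defined as 0 so that degenerate structures still yield a
finite vector; such inputs are rejected upstream by the >=19-bp filter in
any case.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import (
    HairpinRecord,
    PairTable,
    StructureElements,
    decompose,
    max_consecutive_paired,
    parse_dot_bracket,
)

NUCLEOTIDES = "ACGU"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]
TRIPLET_PATTERNS = ["".join(p) for p in itertools.product("(.", repeat=3)]
TRIPLET_ELEMENTS = [f"{nt}{pat}" for nt in NUCLEOTIDES for pat in TRIPLET_PATTERNS]

COMPOSITION_NAMES = ["%(|G|+|C|)"] + [f"%{xy}" for xy in DINUCLEOTIDES]
PAIRING_NAMES = [
    "MCPN",
    "r_p_n",
    "r_unp_n",
    "r_p_unp",
    "avg_bp_stem",
    "dP",
    "n_bulge",
    "r_unp_bulge",
    "r_bulge_l",
]
ENERGY_NAMES = ["MFE", "dG", "MFE1", "MFE2", "MFE3", "MFE4", "MFE5"]

#: the 65 feature names in canonical export order
FEATURE_NAMES: tuple[str, ...] = tuple(
    COMPOSITION_NAMES + PAIRING_NAMES + TRIPLET_ELEMENTS + ENERGY_NAMES
)
assert len(FEATURE_NAMES) == 65


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def composition_features(sequence: str) -> dict[str, float]:
    """GC content plus the 16 overlapping dinucleotide frequencies (percent).

    The dinucleotide frequencies are counts over the L-1 overlapping windows,
    scaled by 100, so they sum to 100 for any sequence of length >= 2.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError(f"sequence too short for composition features: L={L}")
    gc = sum(1 for c in sequence if c in "GC")
    values = {"%(|G|+|C|)": gc / L * 100.0}
    counts = {xy: 0 for xy in DINUCLEOTIDES}
    for i in range(L - 1):
        counts[sequence[i : i + 2]] += 1
    for xy in DINUCLEOTIDES:
        values[f"%{xy}"] = counts[xy] / (L - 1) * 100.0
    return values


def pairing_features(pt: PairTable, elems: StructureElements) -> dict[str, float]:
    """The nine pairing-topology scalars (features 18-26)."""
    L = pt.length
    return {
        "MCPN": float(elems.mcpn),
        "r_p_n": _safe_div(pt.n_paired, L),
        "r_unp_n": _safe_div(pt.n_unpaired, L),
        "r_p_unp": _safe_div(pt.n_paired, pt.n_unpaired),
        "avg_bp_stem": _safe_div(pt.n_basepairs, elems.n_stems),
        "dP": _safe_div(pt.n_basepairs, L),
        "n_bulge": float(elems.n_bulges),
        "r_unp_bulge": _safe_div(pt.n_unpaired, elems.n_bulges),
        "r_bulge_l": _safe_div(elems.n_bulges, L),
    }


def triplet_features(sequence: str, structure: str) -> dict[str, float]:
    """Frequencies of the 32 triplet structure-sequence elements.

    Each interior position i (2..L-1, 1-based) contributes one window: the
    paired/unpaired states of (i-1, i, i+1) plus the nucleotide at i.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError(f"sequence too short for triplet features: L={L}")
    if len(structure) != L:
        raise ValueError("sequence/structure length mismatch")
    states = "".join("(" if c in "()" else "." for c in structure)
    counts = dict.fromkeys(TRIPLET_ELEMENTS, 0)
    for i in range(1, L - 1):
        key = f"{sequence[i]}{states[i - 1 : i + 2]}"
        counts[key] += 1
    n_windows = L - 2
    return {k: v / n_windows for k, v in counts.items()}


def energy_features(
    mfe: float,
    length: int,
    pct_gc: float,
    pt: PairTable,
    elems: StructureElements,
) -> dict[str, float]:
    """MFE and its six normalized variants (features 59-65).

    dG = MFE/L; MFE1 = dG / %(G+C); MFE2 = dG / n_stems; MFE3 = dG /
    n_hairpin_loops; MFE4 = MFE / n_basepairs; MFE5 = dG / n_bulges.
    """
    dG = _safe_div(mfe, length)
    return {
        "MFE": mfe,
        "dG": dG,
        "MFE1": _safe_div(dG, pct_gc),
        "MFE2": _safe_div(dG, elems.n_stems),
        "MFE3": _safe_div(dG, elems.n_hairpin_loops),
        "MFE4": _safe_div(mfe, pt.n_basepairs),
        "MFE5": _safe_div(dG, elems.n_bulges),
    }


def extract_all(record: HairpinRecord) -> dict[str, float]:
    """Compute the full 65-feature vector of one hairpin, in catalog order."""
    pt = parse_dot_bracket(record.structure)
    elems = decompose(pt)
    values: dict[str, float] = {}
    values.update(composition_features(record.sequence))
    values.update(pairing_features(pt, elems))
    values.update(triplet_features(record.sequence, record.structure))
    values.update(
        energy_features(record.mfe, record.length, values["%(|G|+|C|)"], pt, elems)
    )
    return {name: values[name] for name in FEATURE_NAMES}


def feature_matrix(records: list[HairpinRecord]) -> pd.DataFrame:
    """Feature table with one row per record, columns in catalog order."""
    rows = [extract_all(r) for r in records]
    return pd.DataFrame(rows, index=[r.id for r in records], columns=list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# F-score feature selection
# ---------------------------------------------------------------------------

def fscore(positive: np.ndarray, negative: np.ndarray) -> float:
    """Fisher-style discrimination score of one feature.

    F = [(mean+ - mean)^2 + (mean- - mean)^2] /
        [var+(unbiased sum) + var-(unbiased sum)]

    where the denominator terms are 1/(n-1) * sum of squared deviations per
    class.  When both within-class variances vanish the score is +inf if the
    class means differ and 0 otherwise.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >=2 samples per class for an F-score")
    mean_all = np.concatenate([pos, neg]).mean()
    mean_pos, mean_neg = pos.mean(), neg.mean()
    numerator = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    denominator = ((pos - mean_pos) ** 2).sum() / (pos.size - 1) + (
        (neg - mean_neg) ** 2
    ).sum() / (neg.size - 1)
    if denominator == 0:
        return float("inf") if mean_pos != mean_neg else 0.0
    return float(numerator / denominator)


@dataclass(frozen=True)
class FeatureSetCatalog:
    """Grouping of features into sets for set-level F-score ranking.

    The shipped default groups the 16 dinucleotides as one set and the 32
    triplet elements as another; every remaining feature is its own
    singleton set.
    """

    sets: dict[str, tuple[str, ...]]

    def __post_init__(self):
        seen: set[str] = set()
        for set_id, members in self.sets.items():
            if not members:
                raise ValueError(f"feature set {set_id!r} is empty")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"features in more than one set: {sorted(overlap)}")
            seen.update(members)

    @classmethod
    def default(cls) -> "FeatureSetCatalog":
        sets: dict[str, tuple[str, ...]] = {
            "dinucleotides": tuple(f"%{xy}" for xy in DINUCLEOTIDES),
            "triplet_elements": tuple(TRIPLET_ELEMENTS),
        }
        grouped = set(sets["dinucleotides"]) | set(sets["triplet_elements"])
        for name in FEATURE_NAMES:
            if name not in grouped:
                sets[name] = (name,)
        return cls(sets=sets)


def rank_feature_sets(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    catalog: FeatureSetCatalog | None = None,
    k: int = 19,
) -> pd.DataFrame:
    """Rank feature sets by mean member F-score, descending; return the top k.

    Singleton sets are scored by their feature's F-score directly;
    multi-feature sets by the mean of member scores.  Labels are +1/-1.
    """
    catalog = catalog or FeatureSetCatalog.default()
    labels = np.asarray(labels)
    pos_mask = labels == 1
    neg_mask = labels == -1
    per_feature = {
        name: fscore(matrix.loc[pos_mask, name].values, matrix.loc[neg_mask, name].values)
        for members in catalog.sets.values()
        for name in members
        if name in matrix.columns
    }
    rows = []
    for set_id, members in catalog.sets.items():
        scores = [per_feature[m] for m in members if m in per_feature]
        if not scores:
            continue
        rows.append(
            {
                "set_id": set_id,
                "mean_fscore": float(np.mean(scores)),
                "n_features": len(scores),
                "members": ",".join(m for m in members if m in per_feature),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["mean_fscore", "set_id"], ascending=[False, True], kind="mergesort"
    )
    return table.head(k).reset_index(drop=True)
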