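"""Pseudo-hairpin negative-set construction from protein-coding sequence.

Coding sequences are randomly concatenated and cut into non-overlapping
segments whose length multiset matches the positive (real precursor) set.
Segments are folded externally (structures supplied alongside), then kept
only if the hairpin has at least 19 base pairings (G:U wobbles included via
the supplied structure) and a free energy of at most -15.79 kcal/mol.  The
final negative set is drawn to a fixed single-/multi-stem composition
(325 + 19 in the reference training set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import HairpinRecord, decompose, parse_dot_bracket

DEFAULT_MIN_BASEPAIRS = 19
DEFAULT_MAX_MFE = -15.79
DEFAULT_N_SINGLE = 325
DEFAULT_N_MULTI = 19


@dataclass(frozen=True)
class PseudoHairpinConfig:
    min_basepairs: int = DEFAULT_MIN_BASEPAIRS
    max_mfe: float = DEFAULT_MAX_MFE
    n_single: int = DEFAULT_N_SINGLE
    n_multi: int = DEFAULT_N_MULTI
    seed: int = 0

    def __post_init__(self):
        if self.min_basepairs < 1:
            raise ValueError("min_basepairs must be >= 1")
        if self.max_mfe >= 0:
            raise ValueError("max_mfe must be negative")


@dataclass(frozen=True)
class Segment:
    """A CDS fragment with its origin on the concatenated sequence."""

    id: str
    sequence: str
    offset: int  # 0-based start on the concatenation

    @property
    def length(self) -> int:
        return len(self.sequence)


def concat_and_fragment(
    cds_sequences: dict[str, str],
    length_distribution: list[int],
    seed: int = 0,
) -> list[Segment]:
    """Join CDS records in seeded random order and cut consecutive segments.

    One segment is produced per requested length (with multiplicity), in a
    seeded shuffle of the requested lengths, so the emitted length multiset
    equals the positive set's exactly.  Segments never overlap: each starts
    where the previous one ended.
    """
    rng = np.random.default_rng(seed)
    order = list(cds_sequences)
    rng.shuffle(order)
    concatenation = "".join(cds_sequences[name].upper().replace("T", "U") for name in order)

    lengths = list(length_distribution)
    rng.shuffle(lengths)
    needed = sum(lengths)
    if needed > len(concatenation):
        raise ValueError(
            f"insufficient CDS: need {needed} nt, have {len(concatenation)} "
            f"(short by {needed - len(concatenation)})"
        )
    segments = []
    offset = 0
    for idx, length in enumerate(lengths):
        segments.append(
            Segment(
                id=f"pseudo_{idx:04d}",
                sequence=concatenation[offset : offset + length],
                offset=offset,
            )
        )
        offset += length
    return segments


def filter_pseudo(
    record: HairpinRecord, cfg: PseudoHairpinConfig | None = None
) -> tuple[bool, str]:
    """Accept a folded segment iff bp count and MFE pass both thresholds.

    Returns (accepted, reason); reason is "ok", "basepairs" or "mfe" (the
    base-pair check is reported first when both fail).
    """
    cfg = cfg or PseudoHairpinConfig()
    pt = parse_dot_bracket(record.structure)
    if pt.n_basepairs < cfg.min_basepairs:
        return False, "basepairs"
    if record.mfe > cfg.max_mfe:
        return False, "mfe"
    return True, "ok"


def sample_negatives(
    accepted: list[HairpinRecord], cfg: PseudoHairpinConfig | None = None
) -> list[HairpinRecord]:
    """Draw the configured single-/multi-stem mix without replacement."""
    cfg = cfg or PseudoHairpinConfig()
    rng = np.random.default_rng(cfg.seed)
    single = [r for r in accepted if decompose(parse_dot_bracket(r.structure)).n_hairpin_loops == 1]
    multi = [r for r in accepted if decompose(parse_dot_bracket(r.structure)).n_hairpin_loops > 1]
    if len(single) < cfg.n_single or len(multi) < cfg.n_multi:
        raise ValueError(
            f"insufficient pool: need {cfg.n_single} single / {cfg.n_multi} multi, "
            f"have {len(single)} / {len(multi)}"
        )
    chosen = [single[i] for i in rng.choice(len(single), cfg.n_single, replace=False)]
    chosen += [multi[i] for i in rng.choice(len(multi), cfg.n_multi, replace=False)]
    return chosen


def build_negative_set(
    cds_sequences: dict[str, str],
    positive_lengths: list[int],
    fold,
    cfg: PseudoHairpinConfig | None = None,
) -> tuple[list[HairpinRecord], list[dict]]:
    """Full pipeline: fragment, fold (via callback), filter, report.

    ``fold(id, sequence) -> (structure, mfe)`` supplies secondary structures;
    the audit list records every segment with its fate.  Sampling to the
    final composition is left to :func:`sample_negatives` so callers can
    inspect the accepted pool first.
    """
    cfg = cfg or PseudoHairpinConfig()
    segments = concat_and_fragment(cds_sequences, positive_lengths, seed=cfg.seed)
    accepted: list[HairpinRecord] = []
    audit: list[dict] = []
    for seg in segments:
        structure, mfe = fold(seg.id, seg.sequence)
        rec = HairpinRecord(id=seg.id, sequence=seg.sequence, structure=structure, mfe=mfe)
        ok, reason = filter_pseudo(rec, cfg)
        pt = parse_dot_bracket(structure)
        audit.append(
            {
                "id": seg.id,
                "offset": seg.offset,
                "length": seg.length,
                "n_basepairs": pt.n_basepairs,
                "mfe": mfe,
                "multi_stem": decompose(pt).n_hairpin_loops > 1,
                "accepted": ok,
                "reason": reason,
            }
        )
        if ok:
            accepted.append(rec)
    return accepted, audit
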