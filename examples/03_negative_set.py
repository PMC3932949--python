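"""Build a pseudo-hairpin negative set from coding sequence.

Concatenates CDS records in seeded random order, cuts segments whose length
multiset matches a positive set, folds them (stub folder here; swap in any
structure provider), and filters at >= 19 base pairs and <= -15.79 kcal/mol.
"""

import numpy as np

from srnakit import (
    PseudoHairpinConfig,
    build_negative_set,
    generate_hairpin_sets,
    sample_negatives,
)

rng = np.random.default_rng(0)
cds = {
    f"cds_{i}": "".join(rng.choice(list("ACGU"), p=[0.24, 0.28, 0.28, 0.20], size=900))
    for i in range(40)
}
positives, _ = generate_hairpin_sets(n_pos=150, n_neg=10, seed=0)
positive_lengths = [r.length for r in positives]


def stub_fold(seg_id, sequence):
    """Stand-in folder: depth keyed to the segment ordinal (use RNAfold etc.
    for real sequence data)."""
    ordinal = int(seg_id.split("_")[1])
    n_bp = min(15 + ordinal % 12, (len(sequence) - 6) // 2)
    structure = "(" * n_bp + "." * (len(sequence) - 2 * n_bp) + ")" * n_bp
    return structure, -12.0 - (ordinal % 15)


cfg = PseudoHairpinConfig(seed=0)
accepted, audit = build_negative_set(cds, positive_lengths, stub_fold, cfg)
rejected = [row for row in audit if not row["accepted"]]
print(f"{len(audit)} segments cut; {len(accepted)} pass the filters, "
      f"{len(rejected)} rejected")
reasons = {}
for row in rejected:
    reasons[row["reason"]] = reasons.get(row["reason"], 0) + 1
print("rejection reasons:", reasons)

small = PseudoHairpinConfig(n_single=50, n_multi=0, seed=0)
chosen = sample_negatives(accepted, small)
print(f"sampled {len(chosen)} single-stem pseudo hairpins; "
      "lengths mirror the positive set so the classifier cannot cheat on length.")
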