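"""Extract the 65-feature vector of a single pre-miRNA-like hairpin.

Builds one stem-loop record (sequence, dot-bracket structure, MFE), runs the
feature extractor, and prints a few representative features from each block.
"""

from srnakit import HairpinRecord, extract_all

record = HairpinRecord(
    id="example_hairpin",
    sequence="GGCUGGUUGAAGGGAACCAAUUCAGUUCCCUUCAACCAGCC",
    structure="(" * 18 + "." * 5 + ")" * 18,
    mfe=-28.4,
)

vector = extract_all(record)
print(f"hairpin {record.id}: {record.length} nt, MFE {record.mfe} kcal/mol")
for name in ("%(|G|+|C|)", "%GG", "MCPN", "r_p_n", "dP", "n_bulge", "dG", "MFE4"):
    print(f"  {name:>12s} = {vector[name]:.4f}")

# The composition block (%XY) sums to 100, the 32 triplet frequencies to 1:
from srnakit.features import DINUCLEOTIDES, TRIPLET_ELEMENTS  # noqa: E402

print("  sum %XY      =", round(sum(vector[f"%{xy}"] for xy in DINUCLEOTIDES), 6))
print("  sum triplets =", round(sum(vector[t] for t in TRIPLET_ELEMENTS), 6))
print("Paired-nucleotide ratios and energy densities like these separate real "
      "precursor hairpins from background folds.")
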