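# Methods

## Secondary-structure model

Structures are nested dot-bracket strings; pseudoknots are rejected at
parse time. Positions are 1-based internally; every exported genomic
interval is 0-based half-open (BED convention). Decomposition follows the
standard loop picture with two conventions chosen for a single-scalar bulge
count:

- a **stem** is a maximal run of stacked pairs (i,j), (i+1,j−1), …;
- a **hairpin loop** is the region closed by an innermost pair. A pair with
  zero unpaired interior still counts as a (size-0) loop, which keeps
  `n_stems ≥ n_hairpin_loops` on degenerate strings;
- a **bulge** is the set of unpaired nucleotides inside one non-hairpin
  loop, grouped by the innermost enclosing pair: the two strands of an
  interior loop — and all unpaired stretches of a multiloop — merge into
  one bulge whose size is their total nucleotide count;
- exterior (dangling) unpaired ends are neither loops nor bulges, so a
  linear molecule has zero bulges.

A structure with more than one hairpin loop is flagged multi-stem; single-
and multi-stem precursors run through the same code path.

## Feature catalog and selection

The 65 features (composition, pairing topology, 32 triplet elements, energy
densities) are listed in the package docstrings; export order is fixed so
model files are reproducible. Numerical conventions:

- **zero denominators** (no unpaired nt for `r_p_unp`; zero stems, loops,
  bulges or pairs for `avg_bp_stem`, `r_unp_bulge`, `MFE2/3/4/5`) yield 0.
  This keeps vectors finite on degenerate folds, which the ≥ 19-bp training
  filter excludes from real training sets anyway;
- **triplet windows** span the whole sequence (no loop exclusion), treat
  '(' and ')' as one paired state, and are normalized by the window count
  `L − 2` rather than by `L`;
- `n_loops` in `MFE3` means hairpin (terminal) loops — the only loop count
  that is unambiguous for hairpin classification.

F-scores use the unbiased per-class sums of squared deviations. When both
within-class variances vanish the score is +∞ for differing means and 0
otherwise (the feature is either perfectly or not at all discriminative).
Set-level ranking averages member F-scores; the shipped catalog groups the
16 dinucleotides and the 32 triplet elements as two blocks and leaves every
other feature a singleton, since no finer grouping is canonical. A separate
multi-stem-specific feature block is deliberately not implemented: with
multi-stem precursors a ~5% minority, discriminating them with dedicated
features adds nothing the mixed training set does not already carry.

## Classifier

scikit-learn's `SVC` (the libsvm binding) with an RBF kernel, `C = 8.0` and
`γ = 0.03125` — values found by grid search in the original zebrafish
setting and kept as defaults; a helper can re-search them. Features are
rescaled to [−1, 1] by training-set min/max (svm-scale semantics: constant
columns map to 0, unseen values extrapolate without clipping). The scaler
is fitted inside each CV training fold only, so no information leaks into
held-out folds. Probability calibration is libsvm's built-in Platt sigmoid
fit, seeded for determinism; the calibrated score supports the 0.8
novel-candidate cutoff (inclusive). Cross-validation uses seeded stratified
folds; `folds = n` and leave-one-out are the same computation. Confusion
metrics follow the standard definitions; an MCC with a zero denominator is
reported as 0.

## Negative-set construction

Coding sequences are concatenated in a seeded random order and cut into
consecutive, non-overlapping segments; one segment is produced per positive
precursor length (with multiplicity), so the emitted length multiset equals
the positive set's exactly — the strongest reading of length matching, and
the one that prevents the classifier from using length as a shortcut.
Folding is delegated to a caller-supplied structure provider (pre-folded
files, or an adapter to an external folder such as RNAfold). Segments pass
iff they carry ≥ 19 base pairs in the supplied structure (G:U wobbles are
whatever the folder paired) and MFE ≤ −15.79 kcal/mol; the final draw takes
a configured single-/multi-stem mix (default 325 + 19) without replacement
and errors with pool counts when the accepted pool cannot supply it.

## Annotation pipeline

Tag QC keeps 18–35 nt tags observed ≥ 3 times in at least one library
(boundaries inclusive). Matching uses an exact-plus-one-substitution
split-half matcher over both strands, applied uniformly to every reference
level; it is intended for desk-scale references, with SAM/BED import as the
path for genome-scale alignments. The priority order is fixed; a tag
claimed at one level never reaches later levels, so category totals plus
unclassified reconstruct the retained total exactly. At the repeat level,
class annotations naming rRNA/tRNA/snRNA/snoRNA recall the tag to that
ncRNA category, and remaining repeat hits are re-matched against the piRNA
reference (repeat-associated piRNAs). Multi-mapped tags contribute
`count / n_positions` per position. The isomiR window extends each
precursor 2 nt upstream and 5 nt downstream along its strand; a miRNA's
expression is its most abundant isoform's count per library. RPM uses the
per-library mapped-read total as denominator, making categories comparable
across libraries with different mapping rates.

piRNA clusters: unique loci (distinct chrom/start/end/strand), sorted per
chromosome; runs extend while `next.start − prev.end < 1000` (strict) and
emit at ≥ 10 unique loci. Clusters span both strands by default with
per-strand counts recorded; a per-strand mode is available because the
strand assignment of a mixed cluster is not canonical.

## Synthetic data

The generator emulates an eight-stage embryonic time course at 50,000 reads
per stage: piRNA abundance falls linearly 80% → 10% while miRNA rises
5% → 60%, with fixed small fractions for rRNA/tRNA/snRNA–snoRNA, repeats
and mRNA and the remainder intergenic ("unclassified"). miRNA reads are
isomiR variants (offsets −2…+2, lengths 21–23 weighted toward the canonical
22-mer) of planted single-stem precursors; piRNA reads come from planted
clusters (12 loci, 500 bp start spacing; half the clusters sit inside
repeats to exercise the rescue path) with lengths drawn from a discrete law
peaked at 28 nt and an 80% 5′-U bias on the piRNA's own 5′ end. Reads are
drawn multinomially from small per-category pools so every tag clears the
3-read floor at the default depth.

Free energies are assigned by a pairing-dependent linear model with
Gaussian noise (≈ −0.85 kcal/mol per pair plus a GC term), not by
thermodynamic folding: the suite needs the rank structure of MFE, not its
physical value, and this keeps the toolkit deterministic with no external
tools. Consequently passing tests demonstrate the correctness of the
feature, classification and annotation machinery on separable, clean data —
they do not certify real-data accuracy, where folding energies, sequencing
error, adaptor artefacts and reference incompleteness all intrude. Training
sets are verified at generation to separate by ≥ 2 pooled SD on ≥ 5
features, which is what makes the ceiling-level CV expectation meaningful.
The generator plants no 1-mismatch collisions between categories; with the
toy genome's random sequence the chance of an accidental ≤ 1-mismatch
cross-category match at 18–35 nt is negligible, and truth-agreement checks
would surface one.

## Problem sizes and determinism

Default test and acceptance sizes: 200 + 200 training hairpins, 1,000
random structures for feature invariants, exhaustive structure enumeration
to length 12 (≈ 27k strings), eight 50,000-read libraries, 100 random locus
sets (n ≤ 200) against the brute-force cluster oracle, 20 label-permutation
CV repeats. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns with the same seed are byte-identical,
including written fixture files.

## Known limitations

- No thermodynamic folding, pseudoknot handling or ping-pong (10-nt 5′
  overlap) analysis; candidate excision from unclassified reads is left to
  external tools whose output the candidate TSV consumes.
- The internal matcher is quadratic-ish at genome scale; use aligner output
  for real genomes.
- Published-benchmark reconstruction recovers accuracy and MCC from printed
  Sn/Sp pairs at known class sizes; it cannot recover per-sample decisions,
  and the real-data training experiment requires the user to supply the
  miRBase precursor set and CDS sequences.
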