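# Methods

## Problem and model

A synonymous single-nucleotide variant (sSNV) changes a codon without
changing the encoded amino acid. Pathogenic sSNVs act mostly through
splicing disruption, loss of conserved sequence, or codon-optimality
shifts. `synpred` casts their detection as binary classification: each
variant is represented by a fixed-length feature vector and scored by a
random forest whose output is the fraction of trees voting "deleterious".

The forest is defined by contract — bagged randomized trees with `mtry`
candidate features per split — and implemented with scikit-learn's
`RandomForestClassifier`, seeded for exact reproducibility. Defaults are
`ntree = 500`, `mtry = 3`, decision threshold 0.5.

## Coordinates and variant projection

Internally all intervals are 0-based half-open; VCF/GTF boundaries are
converted once at parse time (BED is already half-open), and user-facing
variant positions stay 1-based to match VCF. Each variant is projected
onto one **canonical transcript** — the transcript with the longest CDS
containing the position, ties broken by lexicographically smallest
transcript id — and its ref/alt codons are reported on the coding strand
(reverse-complemented for minus-strand genes). Only the standard genetic
code is supported; a stop-to-stop exchange counts as synonymous.
Transcripts whose CDS length is not divisible by 3 are skipped with a
warning. Multiallelic VCF rows are decomposed and only SNVs retained.

## Feature conventions

Several features come from tool chains whose exact formulas are not
published; the conventions adopted here are deliberate and documented:

- **dsp** — minimum distance in nucleotides from the variant to a splice
  site of its exon, with the boundary base itself counting as 0.
  Transcript-terminal exon edges carry no splice site and are excluded
  whenever an internal boundary exists; single-exon transcripts yield a
  missing value (zero after imputation).
- **mde** = dsp / (exon_len / 2); **dve** = (0-based offset from the
  exon's 5′ end in transcript orientation) / (exon_len − 1), 0 for
  length-1 exons.
- **mes** — log-odds PWM scoring, not a true maximum-entropy model: both
  donor and acceptor matrices (default widths 9 and 23) slide over every
  coding-strand window that covers the variant, introns included, and the
  maximum column-sum score is returned. Matrices are user-supplied; the
  bundled donor/acceptor matrices are synthetic consensus-derived
  log-odds tables.
- **ese_dens** — (# hexamer hits among the exon's length-6 windows) /
  (len − 5); exons shorter than 6 nt score 0.
- **sr_lost / sr_gained** — motif hits counted in an 11-nt window centred
  on the variant (truncated at exon boundaries, so every hexamer
  overlapping the variant is covered), differenced between ref and alt.
- **te** — natural log of the tRNA-adaptation (tAI) weight of the **alt**
  codon. Weights follow the standard recipe: W(codon) = Σ over decoding
  anticodons of (1 − s_class)·copies, with Watson–Crick plus wobble
  pairing classes (defaults s = 0, 0.41, 0.28, 0.9999, 0.68 for WC, G:U,
  I:C, I:A, U:G), normalised by max W; codons with no decoder receive the
  geometric mean of the nonzero weights. Because the source description
  is ambiguous between the alt-codon weight and a variant-induced change,
  `te_delta` (= ln w(alt) − ln w(ref)) is available as an optional column.
- **RSCU** — count / mean count of the synonymous family; single-codon
  families are 1.0 and all-zero families 0.0, so family sums equal family
  size whenever the family is observed.
- **Ingested tracks** — conservation and splicing-z scores arrive as TSV
  extracts keyed by position or (position, ref, alt); keys are matched
  exactly as published, without strand normalisation. Each BED file
  becomes one boolean feature named after the file.

## Matrix construction

Missing values (absent score keys, undefined geometry) are tracked in a
mask, set to **zero on the raw scale**, and only then z-scored — this
impute-then-normalise order is part of the method. Normalisation uses the
sample (n−1) standard deviation; constant columns map to zero.
Parameters are fitted on training rows only and frozen for held-out data;
inside cross-validation they are re-fitted on every training fold, so no
test information leaks into the criterion.

## Selection, tuning, evaluation

The model-selection criterion is the AUC of **pooled out-of-fold scores**
from stratified, seeded k-fold CV (k = 10 by default). Grid search
evaluates every point of ntree ∈ {50..1000 step 50} × mtry ∈ {1..10}
(200 configurations); ties prefer smaller ntree, then smaller mtry, and
points with mtry exceeding the feature count are skipped with a warning.

Sequential backward selection evaluates the criterion with each single
feature removed and accepts the best removal while the criterion does not
decrease (`strict=True` demands strict improvement); ties drop the
lexicographically smallest name. Grid search is run once on the full
feature set and the configuration held fixed during selection.

Evaluation reports confusion counts, recall, precision, AUC and the
weighted F-measure with β equal to the rounded majority/minority ratio
(e.g. 5178/153 → 34); β = 1 on balanced data. Balanced-subset evaluation
draws |positives| negatives without replacement, independently per run
(5 runs by default), and reports mean ± sample SD; the sampled indices are
returned so competing methods can be scored on identical subsets, which is
what the paired two-tailed t-test assumes (identical vectors give p = 1 by
convention). Published recall/precision/F triples are reproduced to three
decimals by the F formula for every self-consistent row; four printed
rows (two in the balanced-subset table, two in the leave-one-out table)
differ from their own recall/precision by one unit in the third decimal
and are treated as source rounding artefacts, not asserted.

## Synthetic benchmark

The generator emulates the *shape* of the real study — a balanced
600-variant training set over multi-exon genes — not its biology. One
contig per gene (30 genes, 4 exons of 60–120 nt, canonical GT/AG intron
edges, half on the minus strand), with the CDS spanning the exons and free
of stop codons. All emitted variants are synonymous by construction.

Class signal is injected at the feature level:

- deleterious variants are placed near splice sites (exponential distance,
  mean 5 nt) and preferentially in ESE-dense exons; benign are uniform;
- deleterious variants take the lowest-tAI synonymous codon (probability
  0.85), benign the highest;
- simulated conservation and splicing-z tracks are unit-variance normals
  shifted by +1.5 / −1.5 for the deleterious class; the TFBS track covers
  deleterious variants with probability 0.55 vs 0.15;
- a tenth score column, `noise`, has zero shift for both classes — a
  known-uninformative control for selection tests;
- 10% of score keys are omitted to exercise zero-imputation.

`EffectSizes.null()` zeroes every channel, giving chance-level AUC.

Because signal is injected directly into features, passing tests show that
the pipeline recovers planted signal and ranks a pure-noise column last —
they say nothing about how discriminative these features are on real
genomes, where effects are correlated, weaker, and annotation-dependent.
Other unmodelled aspects: mutation-rate heterogeneity, linkage between
variants, realistic splice-site strength distributions, and RNA secondary
structure (folding-energy features enter only as precomputed columns).

## Problem sizes and numerical choices

Tests and examples run the full 600 × 10 benchmark for cross-validation
and backward selection (forest sizes 100–500), and a reduced 60-variant
subset with 2-fold CV for the exhaustive 200-point grid; these sizes are
the package's chosen desk-scale defaults and are trivially increased via
`SimConfig`. AUC uses rank-based (Mann–Whitney) counting with ties
credited 0.5 and is cross-checked against brute-force pair enumeration.
Degenerate inputs fail loudly: single-class labels, classes smaller than
k, empty variant lists, all-zero tRNA tables and malformed files raise
errors rather than guess.

## Known limitations

- The headline cross-validation/independent-test AUCs of the original
  study depend on real genome annotation, conservation tracks and
  splicing-prediction scores, and are out of reach of a self-contained
  synthetic benchmark; this package reproduces the method and its
  evaluation arithmetic, not those dataset-bound numbers.
- PWM splice scoring approximates maximum-entropy models; scores are
  comparable within a matrix, not across published MaxEnt scales.
- One canonical transcript per variant; no per-transcript feature
  aggregation.
- No probability calibration; the 0.5 threshold is a convention.
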