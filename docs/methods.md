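# Methods

## Sequence model and ORF definition

Input transcripts are DNA strings over {A, C, G, T, N}; lowercase is
uppercased and U is transliterated to T on ingest so RNA FASTA works
unchanged. An open reading frame is an ATG followed by in-frame codons
up to and including the **first** in-frame stop codon (TAA/TAG/TGA),
scanned in the three forward frames only — no reverse strand, no
alternative starts (GTG/TTG), no codon-table variants. Two
interpretation choices were genuinely open and are fixed as follows:

- the stop codon counts toward the ORF length (minimum ORF = 6 nt), so
  the region used for k-mer counting contains the stop triplet, whose
  strong enrichment is part of the coding signal;
- ORFs that run off the 3′ end without a stop are not ORFs: pairing
  starts with stops keeps the length *l* well defined.

Codons containing N are neither start nor stop. Internally coordinates
are 0-based half-open; reports are 1-based inclusive (BED6 output
stays 0-based half-open by format definition). When several ORFs tie
in length, ties break by ascending start, then ascending frame — an
arbitrary but frozen rule that makes the "longest ORF" deterministic.

## Feature vector

1,366 features: longest-ORF length (nt), ORF coverage (fraction of the
transcript), then all k-mer frequencies for k = 1..5 in a frozen order
(k ascending, lexicographic within k over A < C < G < T), counted with
overlapping windows inside the longest ORF and normalized by
l − k + 1. k is capped at 5 because k = 6 quadruples the feature count
(4,096) without separating the classes better; the k = 6 mode is not
implemented, only the combinatorial count is exposed. Windows
containing N are skipped in the numerator while the denominator stays
l − k + 1, keeping the formula literal; consequently k-blocks sum to
exactly 1 only on N-free regions (asserted at 1e-9). A transcript with
no ORF at all falls back to whole-sequence counting with
orf_length = 0 and coverage = 0, so prediction is total rather than
partial. A `region="full"` mode counts on the whole transcript, which
makes the UTR-dilution effect demonstrable on synthetic data. No k-mer
group weighting is applied.

Class contrasts use log2(mean frequency in lncRNAs / mean frequency in
coding); pairs with a zero mean are reported as NaN, never ±inf.

## Classifier

RBF-kernel SVM (scikit-learn SVC) on features min-max scaled to [0, 1]
with parameters fitted on training rows only; features constant in
training map to 0. Defaults: cost C = 1 and kernel width
gamma = 1/1366 (one over the feature count) — explicit package choices,
since nothing pins them from first principles. An optional grid search
(C ∈ 2^−3..2^7, gamma ∈ 2^−9..2^1, selected by 5-fold CV accuracy on
the training data) can replace them; the values used are always stored
in the model metadata. lncRNA is the positive class and the decision
threshold is fixed at score 0 — deliberately no user-tunable cutoff.
No class weighting by default (training sets are balanced by design);
`class_weight="balanced"` enables inverse-frequency weights. Training
is seeded and the seed stored; SVC's solver is deterministic given the
data, so retraining reproduces predictions exactly (label-flip
symmetry holds to solver tolerance, ~1e-3 in decision score).

Models persist as a single versioned joblib archive carrying the SVM,
the scaling parameters, the feature-schema version and metadata.
Loading verifies the archive format and schema version and fails
loudly on mismatch or truncation — never a silent misprediction.

## Evaluation

Confusion-matrix metrics (lncRNA positive): sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy, precision TP/(TP+FP), F-measure
(harmonic mean of sensitivity and precision), MCC, and Cohen's Kappa
(Pr(a) − Pr(e))/(1 − Pr(e)) with Pr(e) the marginal chance agreement.
Undefined denominators yield NaN, excluded from averages with a
warning — never substituted by 0.

Cross-validation is stratified with a seeded shuffle; transcripts with
identical base strings are forced into the same fold (grouped
splitting) so no duplicate spans a train/test boundary. Scaling and
the SVM are refitted per fold on the training folds only. Both
aggregation modes are provided — fold-averaged metrics (the default
headline) and pooled out-of-fold metrics — because either reading of
"average of the test-set results" is defensible. ROC/AUC comes from a
threshold sweep over pooled out-of-fold decision scores
(trapezoidal AUC; equals the tie-aware rank statistic).

SVM-RFE: the RBF model has no per-feature weights, so ranking uses the
canonical linear-kernel surrogate — iteratively drop the fraction
`step` of surviving features with the smallest squared weights
(at least one per round); ties break in ascending schema order; a
feature's importance is its squared weight at elimination; rank 1 is
the last survivor.

## Synthetic study set

The generator emulates the structural contrast the classifier
exploits, not the composition statistics of any real annotation
database. Defaults (chosen once):

| parameter | default | meaning |
|---|---|---|
| n_per_class | 400 | transcripts per class |
| seed | 42 | master seed; per-class child streams |
| min/max_codons | 80 / 300 | internal codons of the planted coding ORF |
| utr5/utr3_range | 20–150 / 50–300 nt | UTR lengths, noncoding composition |
| coding_base_weights | A/C/G/T = .18/.32/.32/.18 | GC-rich codon bias (product measure over the 61 sense codons) |
| noncoding_base_weights | .32/.18/.18/.32 | AT-rich lncRNA-like bias |
| noncoding_length_range | 300–1500 nt | all transcripts > 200 nt |
| max_orf_codons | 30 | noncoding longest-ORF cap (≤ 96 nt) |

Noncoding transcripts are rejection-sampled against the ORF cap rather
than having stops edited in, keeping the composition model clean; a
bounded retry budget turns impossible caps into an explicit error. A
null control draws both classes from the noncoding model with
different child seeds.

What passing tests show — and do not show: the planted classes are
strongly separated in both ORF structure and composition, so perfect
cross-validated recovery demonstrates the pipeline's correctness
(features computed as defined, no leakage, calibrated chance level on
the null control), not the accuracy achievable on real annotations,
where class overlap, isoform redundancy, sequencing noise and
unbalanced class sizes all matter. The generator has no splice
structure, no length/GC confounding between classes, and UTRs share
the noncoding composition exactly.

## Numerical and design notes

- Feature extraction is pure and deterministic; feature tables,
  simulated FASTA and prediction TSVs are byte-identical across runs
  given the same inputs and seeds (TSV floats use 6 significant
  digits).
- When classes differ **only** in ORF structure (identical base
  composition), the two informative dimensions are diluted among 1,364
  near-noise dimensions: at the fixed default kernel width the ranking
  stays near-perfect (AUC ≈ 1) but the 0-threshold is miscalibrated
  (accuracy ~0.7–0.85). The grid search recovers ≥ 0.95 accuracy; this
  is the intended use of the optional search and the reason it exists.
- Problem sizes in the test suite and acceptance script (≤ 400 per
  class, 10 folds) are the package's default study conditions; the
  full pipeline on them runs in seconds.
- The whole-sequence comparison mode operates on the transcript, not
  the gene; gene-level sequence is out of scope.
- No pre-trained species models ship with the package (they would
  require external annotation downloads); users train on their own
  FASTA via `lncsieve train` or `CodingPotentialSVM.from_fasta`.

## Known limitations

- Forward-strand only; transcripts in unknown orientation must be
  reverse-complemented upstream.
- The fallback for ORF-less transcripts mixes whole-sequence k-mers
  with orf_length = 0; such vectors live in a slightly different
  feature regime than ORF-bearing ones.
- No probability calibration is provided; the decision score is a
  signed margin, comparable only within one model.
- SVM-RFE on the full 1,366-feature set is O(rounds × SVM fits) and is
  intended for moderate sample sizes.
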