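# Methods

## Problem and model

The package classifies mammalian proteins as secreted (SP) or non-secreted
from primary sequence. The model is a binary RBF-SVM over a fixed
60-dimensional encoding; no alignment, homology search or structural
information is used. The underlying assumptions are that (i) secreted
proteins differ systematically in residue composition, (ii) short conserved
sequence patterns (leucine-rich, glycine/cysteine-rich motifs) are
differentially prevalent between the classes, and (iii) bulk
physicochemical character (hydrophobicity, polarity, surface area, …)
shifts with secretion. Each assumption maps to one feature block (AAC,
MTF, PCP).

## Data handling

FASTA input is uppercased; the 20 standard residues plus the ambiguity
codes X, B, Z, U, O, J are accepted. Ambiguity codes are second-class
everywhere: they are excluded from composition denominators and property
profiles and can match neither a motif literal nor the `-` wildcard (the
wildcard means "any of the 20 standard residues"). Records with other
characters are rejected individually, never fatally.

Redundancy reduction implements the "cluster at 30% identity, keep the
longest member" policy with a greedy surrogate instead of an external
aligner: estimated identity between two sequences is the fraction of the
shorter sequence's distinct 3-mers shared with the longer one; records are
visited longest-first and each joins the first cluster whose representative
it matches at ≥ 30%, else founds one. Because founders are visited
longest-first they are automatically their cluster's longest member. The
surrogate over-estimates identity for repetitive sequences and is not a
BLAST replacement; it reproduces the policy, not the tool.

The train/test split takes ⌊4/5 · numP⌋ positives (flooring is what the
published dataset tables imply) plus an equal number of uniformly drawn
negatives for training; all remaining proteins of both classes form the
test set. Negatives are not length- or species-matched — the source
protocol does not say they were, so the simplest defensible choice is
uniform sampling.

## Motif mining

Candidates are every pattern with 3–5 literal residues, at most one
internal wildcard and total length ≤ 6 that is instantiated by a window of
a positive sequence — the smallest shape space containing every motif the
method is expected to find, and never a free 20^k enumeration. A support
filter (default: present in ≥ 5% of positives) prunes the candidate set.
Presence is per protein (at least one match anywhere), so counting via
per-sequence window sets is exact for this pattern class.

Scoring: IG(M) = log₂N − [p·log₂(pN) + (1−p)·log₂((1−p)N)] with
0·log 0 = 0, which reduces to the binary entropy of the containment
fraction p; RDI(M) = IG_P/I_P(S) − IG_N/I_N(S). Logs are base 2 (IG in
bits); RDI is base-invariant because each term is normalised by its set
entropy. Singleton class sets are rejected (zero entropy makes the ratio
undefined) rather than silently scored 0. Ties in RDI are broken by higher
positive count, then lexicographic pattern — feature columns must be
reproducible run to run.

### Mining leakage and nested evaluation

Choosing the top-20 motifs by RDI is model fitting: the patterns are chosen
from thousands of candidates to maximise apparent class contrast. If
mining sees data that later serves as held-out folds, cross-validation is
optimistically biased — on completely signal-free data the naive protocol
reaches ≈ 0.77 accuracy where chance is 0.5. The package therefore
provides `nested_cross_validate`, which re-mines motifs inside every fold
on the training part only; on signal-free data it sits at ≈ 0.5 as it
should. The plain workflow (mine once on the training split, then
cross-validate on it) is retained because it is the conventional protocol
in this literature, but its CV numbers should be read as in-sample for the
motif-selection step; honest generalisation claims should come from the
nested procedure or the independent test set.

## Encoding

* AAC: frequencies over standard residues, then the record-level min–max
  map ((x − min)/(max − min) − ½)·2. A constant vector maps to all zeros
  (the continuous limit of the centring).
* MTF: +1/−1 presence flags for the mined motif list, in mining order.
* PCP: the 10×L profile (index-table column per residue); the feature
  vector is the 10 per-property means concatenated with the 10 population
  standard deviations, then the same record-level min–max map. Twenty
  values from ten properties is a deliberate choice: the mean alone
  discards all within-sequence variability, and the sd is the cheapest
  second moment; `pcp_mode="mean_only"` gives the 10-mean variant and
  `pcp_scaling="dataset"` switches to per-feature dataset-level scaling
  for users who want cross-record comparability of the PCP block.
* The shipped index table (`data/pcp_index.csv`, sha256-pinned) compiles
  literature values for the ten named properties; each property stays on
  its native scale since the normalisation removes scale anyway. Tests
  validate encoders against the shipped table, not against any particular
  published value.

## Feature selection

The ranking criterion is the linear-kernel Fisher–Markov form
score_k = (1/n)Σ_c n_c(μ_ck − μ_k)² − γ·(1/n)Σ_i x_ik² — between-class
variance of the feature minus γ times its second moment. γ defaults to 0,
reducing to pure between-class separation, which is adequate because all
60 features live on comparable [−1, 1] scales; γ is exposed for users who
want the sparsity-pressure behaviour. Ties keep original column order.

Incremental feature selection evaluates ranking prefixes of sizes 5, 10,
…, 60 (step 5; every interesting optimum in this problem family falls on a
multiple of 5). Each prefix is scored by pooled 5-fold CV MCC with one
fixed, seeded fold assignment per run so that subset comparisons are
paired; the optimum maximises MCC with ties broken by higher AUC, then by
parsimony. The selected subset is always a prefix, never a re-ordering.

## Training and evaluation

Grid search is exhaustive over C ∈ 2^−5…2^15, γ ∈ 2^−15…2^3 in powers of 4
(the LIBSVM-conventional ranges), selecting on inner stratified 5-fold
accuracy. Inside iterated searches (IFS, repeated-seed studies) a coarse
3×3 grid (C ∈ {0.5, 8, 128}, γ ∈ {2^−7, 2^−3, 2}) is used and, within one
IFS run, hyperparameters are searched once on the full feature set and
held fixed across prefix sizes — re-searching per size multiplies cost
~40-fold for no measurable benefit at these sample sizes. The final model
is always re-searched on the selected subset with the full grid and refit
on all training data.

Probabilities come from sigmoid (Platt) calibration fitted on
cross-validated decision values, with the final SVC refit on all data
(`ensemble=False`); the hard-label threshold is 0.5. Pooled evaluation
combines all held-out fold predictions into a single confusion matrix and
a single ROC; MCC with any zero marginal is defined as 0 (standard
convention). Folds are stratified — plain random division can produce
single-class folds on small species sets. AUC is trapezoidal over the
threshold-swept ROC, equal to the tie-aware pairwise probability.
Probability deciles are half-open [lo, hi) with the last bin closed at
100%, percentages rounded to two decimals.

The species comparison is paired: per species one stratified fold
assignment is fixed; the species model trains on the species' remaining
folds and the universal model on everything outside the held-out fold, and
both predict exactly the same proteins. Both schemes mine their motifs on
their own full data, so the mining-leakage caveat above applies equally to
both arms and cancels in the contrast.

## Synthetic data

The generator draws residues i.i.d. from a class-specific composition
(positives get per-residue log2 fold-changes applied and renormalised),
lengths uniform over a range, and plants motifs by overwriting residues at
a uniform position in a Bernoulli-selected subset of each class
(overwriting keeps length and near-keeps composition, so the motif and
composition signals stay orthogonal). It emulates exactly the three
signal channels the encoder measures and nothing else: no signal peptides,
no disorder, no phylogenetic correlation between sequences, no realistic
length distribution. Passing tests therefore demonstrate computational
correctness and signal recovery, not performance on real secretomes.

Benchmark fixtures (all deterministic given one seed): `separable`
(150/class, strong composition shift + three planted motifs),
`null` (150/class, no signal), `motif-only` (200/class, one motif at
0.60 vs 0.05 prevalence), `composition-only`, and
`two-species-divergent` (120/class/species, opposite leucine shifts and
swapped motif roles, so a pooled model must compromise). The null fixture
is mined at support 0.02 rather than 0.05 because uniform background
sequences rarely repeat any 3-mer in 5% of proteins — at 0.05 the
candidate set under the null is empty and the mining stage would go
unexercised.

## Problem sizes and numerical choices

Evaluation studies use 150–200 sequences per class, lengths 60–160 —
large enough that binomial noise on motif prevalences is small relative to
the planted gaps, small enough to keep full runs in seconds to minutes.
Seed-averaged claims use 10–20 seeds. Other conventions: 0·log 0 = 0;
min–max of a constant vector is 0; IG clamped at 0 against −0.0; all
randomness flows from explicit integer seeds (Python `random` for
splitting, numpy `default_rng` for generation, `random_state` for
scikit-learn); model bundles are checksummed and reload bit-identically.

## Limitations

* The identity surrogate is not BLAST; clusters can differ from an
  alignment-based tool's, especially for multidomain or repetitive proteins.
* The candidate motif space (≤ 6 long, ≤ 1 wildcard) cannot represent
  longer or multi-gap patterns.
* Index-table values are a literature compilation, not a canonical set;
  models trained with a different table are not comparable.
* Published benchmark performance on real UniProt-derived corpora is out
  of reach without those corpora; nothing here claims to reproduce it.
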