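# Methods

## The model

`traitpred` treats microbial trait prediction as a bank of independent
binary classification problems, one per functional class. The feature
vector of a genome is its KO copy-number profile: for each KEGG ortholog
(K#####), the number of genes annotated with it. The label of a genome
for class *F* is 1 iff any taxid on the genome's lineage (its own taxid
or an ancestor) is a matched member taxon of the corresponding
taxon→function database group — i.e. database membership propagates
*downward only*: an ancestor's function is inherited by all descendants,
never the reverse.

The core assumption is that trait-bearing genomes share gene content
that a discriminative model can find, even when the trait is not
representable as a complete KEGG module. The one-vs-rest framing means a
genome may be positive for any number of classes, and each classifier
sees a heavily imbalanced problem — hence Matthews correlation
coefficient (MCC) as the selection and success metric throughout. MCC is
the Pearson correlation of the binary truth/prediction vectors; our
implementation defines it as 0 when any factor of the denominator is 0,
and the equivalence with the Pearson form is enforced by test to 1e−12.

## Training protocol (per class)

1. Stratified 80/20 train/test split (positive proportion preserved to
   within one genome; deterministic per seed). Classes with fewer than
   2 positives or 2 negatives are unstratifiable and skipped; classes
   with fewer than 3 positive genomes are excluded upstream.
2. Features are z-scored with a scaler fit on the *training* split only.
   Constant columns scale to 0. Each class keeps its own scaler even
   though the feature space is shared.
3. For each candidate algorithm — logistic regression (LR), support
   vector machine (SVM), random forest (RF) — hyperparameters are tuned
   by nested stratified 3-fold cross-validation: the inner loop grid
   search picks the combination with the highest inner mean MCC (ties →
   grid order); the outer loop refits it and scores it on the held-out
   fold. The final combination is the outer winner with the highest
   outer MCC (ties → higher inner mean, then grid order).
4. Each algorithm's finalist is refit on the full training split and
   scored by MCC on the 20% test split; the argmax becomes the class's
   bundle. Exact ties are broken by the fixed preference
   LR > SVM > RF > NN, chosen because linear coefficients are directly
   interpretable for gene-importance extraction.

Default grids (all config-overridable): LR C ∈ {0.01, 0.1, 1, 10, 100} ×
penalty {l1, l2} (liblinear); RF trees ∈ {100, 300, 500} × max-features
{sqrt, log2}; SVM kernel {linear, rbf} × C {0.1, 1, 10}. A neural
network (one ReLU dense layer with tuned units ∈ {64, 256, 1024} →
dropout ∈ {0.1, 0.3, 0.5} → sigmoid; binary cross-entropy, ≤50 epochs
with early stopping, tuning repeated 5 times with the best repeat kept)
is available as an optional keras-backed extra; requesting it without
the backend raises an explicit error. NN model selection uses only the
training split; the test split is reserved for final scoring.

## Prediction and evaluation

Query genomes are ingested from eggNOG-mapper annotation tables (each
K-number listed for a gene adds one copy; `-` rows contribute nothing)
and aligned to the registry's feature order: missing KOs are zero-filled
and novel KOs dropped with a logged count. Probabilistic models decide
at probability ≥ 0.5; margin models at their native threshold.

When truth labels are available, per-class confusion counts and MCC are
reported. For classes with zero truth positives MCC is uninformative; it
is reported as NaN by default with a strict-compatibility flag to emit 0
instead. Superclass scores pool member-class confusion counts and
compute one MCC on the pooled table; seven superclass names (carbon,
nitrogen, sulfur, arsenic and metal metabolisms, parasites or symbionts,
phototrophy) are declared as the default vocabulary and unmapped
functions stay ungrouped.

## Gene importance

LR keeps nonzero coefficients; RF keeps positive impurity importances;
a linear-kernel SVM keeps its primal coefficients. An rbf-kernel SVM has
no primal coefficients, so a linear-kernel SVM with the same C is
retrained on the same training split solely for importance; an NN bundle
falls back to the class's second-best classical algorithm, likewise
retrained. `source_algorithm` always records the surrogate so users know
when importance does not come from the predicting model. Zero scores are
filtered. Lists longer than 1,000 rows (configurable) are truncated to
the top and bottom 10% by signed score; the extreme scores always
survive truncation.

A consequence worth knowing: when an l1-regularized LR wins, redundant
informative KOs receive *exact-zero* coefficients and drop out of the
table entirely. The retained KOs are a minimal sufficient subset, not
the full causal set. On the planted fixture this is visible directly —
an l1 winner reports ~12 of 20 planted KOs, all of them genuine, with no
background KO outranking any planted one.

## Fragmentation simulation

Simulated fragmented genomes emulate MAG incompleteness by length
accounting: removal lengths are drawn from Normal(mean 5,000 bp, sd
1,500 bp) truncated to the remaining excess, a contig is chosen with
probability proportional to its current length, a uniform start is
drawn, and the interval is excised (0-based, half-open), splitting the
contig. Removal stops once the retained length falls to
target × reference_size × (1 + tolerance), tolerance 0.01. Completeness
is measured against a supplied species reference size (defaulting to the
genome's own length), so it is purely length-based and blind to gene
content — matching how MAG completeness is usually reported. The normal
parameters are package defaults recorded in the output manifest; no
published values exist for them. Retained + removed lengths equal the
original exactly, and every output contig is an exact substring of its
parent at the coordinates recorded in its header.

## Refinement

Refining class *F* with user-curated genomes: previous positives of *F*
become negatives; user genomes already present in the base are removed
and re-enter only as positives of *F* (so no genome is simultaneously a
positive and a negative example); holdout ids are dropped from every
row; novel KOs from the new genomes are appended as new feature columns.
New genomes default to label 0 for every other class — a deliberate
conservative choice, logged so users can supply overrides — and the
refined class trains along the standard protocol.

## The synthetic study conditions

The planted-signal fixture is the package's standard benchmark: 200
genomes × 500 KOs, 5 disjoint classes of 30 positive genomes each, 20
informative KOs per class. Informative KO counts are Poisson(5) in
positives and Poisson(0.1) in negatives; 400 background KOs are
Poisson(0.5) everywhere; each count cell is perturbed with probability
0.05 (resampled from Poisson(1)). Poisson counts match the non-negative
integer semantics of copy numbers; 30 positives per class is a typical
mid-size functional class. The generators are pure functions of their
parameters and seed and return their own ground truth.

What the fixture does *not* emulate: phylogenetic correlation among
genomes (real positives are often clades, so real train/test splits are
less independent than ours), KO co-occurrence structure, annotation
error beyond i.i.d. count noise, and contamination. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
a planted signal — not field performance on real MAGs, which in the
motivating application degrades noticeably between 70% and 50%
completeness.

The robustness experiment links fragmentation to classification through
sequence: every fixture genome is materialized as a synthetic contig
carrying one 300 bp interval per KO gene copy (200 bp spacers), the
contig is fragmented at each completeness level, and a gene copy counts
after fragmentation only if its interval survives intact. Mean MCC over
the five classes is then compared across levels; at the defaults the
profile is flat from 100% to 90%, nearly flat at 70%, and collapses at
50%.

## Numerical and design choices

- All randomness flows from explicit integer seeds; per-genome
  fragmentation seeds are derived as sha256(master:genome:level) mod
  2³¹, so per-genome outputs are independent of dict iteration order.
- Row/column orders are deterministic (lexicographic) wherever a matrix
  is assembled from sets.
- Taxon name matching resolves ambiguous names (one name, several
  taxids) to *unmatched* rather than guessing; the cascade order
  (case-fold → synonyms → bracket-stripped) is fixed and auditable.
- Multi-KO genes count once per listed KO, not fractionally.
- The quality filter keeps the boundary values (completeness exactly 90,
  contamination exactly 5).
- The per-species cap samples drafts uniformly without replacement with
  a seed derived from (seed, species taxid), after keeping all complete
  assemblies.
- Registry artifacts are joblib files plus a JSON manifest carrying a
  format version, the dataset hash and the training seed; loading
  refuses version mismatches and corrupted artifacts outright.

## Scale of the shipped experiments

The test suite and the acceptance script run the full protocol at the
fixture scale above (≈90 s of training for the 5-class registry on one
CPU); the desk-scale numbers they print are properties of these
synthetic study conditions. Training on a real database-derived corpus
(tens of thousands of genomes × >11,000 KOs) uses the same code paths
unchanged via the CLI.

## Known limitations

- The NN backend is optional and untested in environments without
  keras; its tuning protocol (repeat-and-keep-best) is simple by design.
- Importance for sparse l1 winners under-reports redundant causal
  features (see above); treat importance tables as sufficient marker
  sets, not exhaustive gene inventories.
- Name matching does not attempt fuzzy edit-distance repairs of typos;
  genuinely misspelled database entries stay unmatched and are left to
  a user-supplied override table.
- Fragmentation does not simulate sequencing error, chimerism or
  contamination — only length-based incompleteness.
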