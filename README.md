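# traitpred

Predict microbial phenotypic traits — methanogenesis, fermentation,
nitrification, host association, and other metabolic or ecological
functions — directly from a genome's KEGG-ortholog (KO) gene content.

Genome-centric metagenomics produces metagenome-assembled genomes (MAGs)
and single-amplified genomes far faster than they can be characterized
experimentally. Literature-curated taxon→function databases (FAPROTAX-style
flat files) link *taxa* to functions, but most MAGs are not in any such
database. `traitpred` bridges the gap: it uses the taxon→function database
to label reference genomes, learns one binary classifier per functional
class from their KO copy-number profiles, and then predicts the traits of
new — possibly incomplete — genomes from nothing but their eggNOG-mapper
annotations.

## What it does

1. **Database parsing** (`traitpred.faprotax`) — parses the hierarchical
   flat-file dialect (asterisk-delimited taxon paths; `add_group` /
   `subtract_group` / `intersect_group` set operations), resolves the
   directive graph and emits a binary taxon×function membership matrix.
2. **Taxonomy mapping** (`traitpred.taxonomy`) — loads NCBI-style
   `names.dmp`/`nodes.dmp`/`merged.dmp` dumps, matches database taxon
   names to taxids (perfect match, then a case-fold → synonym →
   punctuation-stripped cascade), expands descendant subtrees, applies a
   per-species genome cap (default 30, complete assemblies first) and the
   quality filter (completeness ≥ 90%, contamination ≤ 5%).
3. **Dataset assembly** (`traitpred.dataset`) — ingests eggNOG-mapper
   annotation tables into KO copy-number vectors, builds the genome×KO
   feature matrix and the genome×function label matrix by downward
   lineage propagation, and drops classes with fewer than 3 positives.
4. **Learning** (`traitpred.learn`) — per class: stratified 80/20 split,
   z-scoring fit on the training split, nested stratified 3-fold
   cross-validated grid search for logistic regression, SVM and random
   forest (a single-hidden-layer neural network is an optional extra),
   and selection of the algorithm with the best held-out **Matthews
   correlation coefficient (MCC)**:

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   MCC is used throughout because the classes are heavily imbalanced.
5. **Application** (`traitpred.apply`) — aligns query KO vectors to the
   training feature space, emits binary calls per genome, evaluates
   against known labels, pools classes into functional superclasses, and
   extracts per-class KO importance (LR/linear-SVM coefficients, RF
   impurity importances; surrogate models for rbf-SVM and NN bundles).
6. **Fragmentation simulation** (`traitpred.fragsim`) — produces
   simulated fragmented genomes (SFGs) at target completeness levels by
   excising normally-distributed segments, to probe classifier robustness
   to MAG incompleteness.
7. **Refinement** (`traitpred.refine`) — replaces or creates a functional
   class from user-curated genomes with conflict-removal semantics (no
   genome is ever both a positive and a negative of the class).
8. **Synthetic fixtures** (`traitpred.synth`) — seeded generators for
   every input format with known ground truth, so the whole pipeline is
   testable offline.

The ML core is scikit-learn-estimator shaped: `FunctionClassifier` is a
standard classifier (`fit`/`predict`/`get_params`) that runs the whole
per-class protocol, and `train_registry` builds one fitted bundle per
class.

## Worked example

```python
from traitpred import synth, learn, apply

# a planted-signal benchmark: 200 genomes x 500 KOs, 5 trait classes,
# 20 informative KOs per class (expected copy number 5 in positives),
# 5% count noise
truth = synth.make_default_truth(seed=1)
annotations, labels, dataset = synth.synth_dataset(truth)

registry = learn.train_registry(dataset, learn.TrainConfig(seed=1))
print(registry.test_mccs())
```

```
class_0    1.0
class_1    1.0
class_2    1.0
class_3    1.0
class_4    1.0
```

Every class is recovered with held-out MCC 1.0: the planted KO signal is
strong and the tuned models find it. Robustness to incompleteness,
measured by fragmenting the same genomes and re-counting surviving
genes:

```python
profile = synth.fragmentation_robustness_profile(dataset, registry, seed=1)
print(profile)
```

```
       mean_mcc  n_genomes
level
1.0    1.000000        200
0.9    1.000000        200
0.7    0.960000        200
0.5    0.442000        200
```

Performance is unchanged at 90% completeness, nearly unchanged at 70%,
and degrades sharply at 50% — the classifiers tolerate moderate MAG
incompleteness but not severe truncation.

The same workflow is available from the shell:

```bash
traitpred fixtures --seed 1 --out fx/
traitpred train --dataset fx/dataset --seed 1 --out registry/
traitpred predict --registry registry/ --annotations fx/annotations \
    --out calls.tsv --truth fx/labels.tsv
traitpred fragment --fasta genomes/ --levels 0.9,0.7,0.5 --seed 1 --out sfg/
```

## Documentation

The model, its assumptions, parameter defaults, and known limitations
are described in [docs/methods.md](docs/methods.md).
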