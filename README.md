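# mirfuse

Ensemble classification of pre-miRNA hairpins, and mining of candidate
pre-miRNAs from metagenomic contigs, by neural-network decision fusion.

## The problem

MicroRNA precursors (pre-miRNAs) are ~60–70 nt RNAs that fold into a
characteristic stem-loop (hairpin). Many machine-learning predictors tell
genuine precursors apart from *pseudo hairpins* — genomic segments that fold
hairpin-like but are not miRNA precursors — but they differ in features,
learning algorithms and training corpora, and none dominates. `mirfuse`
implements a committee approach for people who want to scan assembled
(meta)genomic sequence for hairpin candidates: four feature-based base
classifiers each vote, and a small neural network fuses their votes into a
single decision.

## The model

**Base committee.** Four surrogate classifiers, in fixed order:

| role               | algorithm      | features                                   |
|--------------------|----------------|--------------------------------------------|
| `triplet_svm_like` | RBF-SVM        | 32-dim triplet structure–sequence vector   |
| `mipred_like`      | random forest  | triplet vector + MFE + Monte-Carlo P-value |
| `virgo_like`       | RBF-SVM        | 512-dim sequence–structure vector          |
| `eumir_like`       | RBF-SVM        | 512-dim vector, different training corpus  |

The triplet features tally, for every window of 3 adjacent nucleotides, the
paired/unpaired pattern (`')'` normalized to `'('`, 8 patterns) × the middle
nucleotide (4 letters) over the L−2 windows of the hairpin, normalized to sum
to 1. The 512-dim features cross the trinucleotide (64) with the 3-bit
bound/unbound state of its positions (8), labelled e.g. `AUG001`. The
P-value is the fraction of dinucleotide-shuffled copies of the sequence
(Altschul–Erickson Euler-path shuffling) whose MFE is strictly lower than the
original's.

**Decision fusion.** The four hard decisions d ∈ {−1,+1}⁴ feed a 4-3-1
network with logistic hidden units and a linear output (19 parameters):

    score(d) = b_out + Σ_k w_out,k · σ(b_k + Σ_i w_ki d_i)

Training is extreme-learning-machine style: hidden weights are drawn
uniform(−1,1) and the output layer is solved in closed form by the
pseudo-inverse (least squares against ±1 teaching targets); the best of
several random restarts — minimum sum of squared errors — is kept. A frozen,
published parameter set ships with the package (`mirfuse.table2_network()`).

**Evaluation.** Accuracy, sensitivity, specificity, precision, F-measure and
NPV as percentages; ROC by Fawcett's threshold linear scan (ties grouped);
AUC with DeLong placement-value standard errors and normal 95% CIs.

**Mining.** Contigs are cut into 70-nt windows shifted by 1 nt, transcribed,
folded (built-in Nussinov-style base-pair maximizer by default, ViennaRNA's
`RNAfold` optionally), featurized, voted on and fused; positive windows are
reported and can be merged into candidate regions.

## Worked example

```python
import numpy as np
import mirfuse as mf

# 1. fold a candidate hairpin
seq = mf.RnaSequence("cand", "GGCUGGGUUCGGCAGAGAUGGCGCAACCCGAGCCAUCUCUGUCGGACCCGGCC")
result = mf.fold(seq)
print(result.structure.symbols)
print(f"surrogate MFE: {result.mfe} kcal/mol")

# 2. train the ensemble on a synthetic corpus, evaluate on held-out data
train = mf.gen_dataset(n_pos=150, n_neg=150, rng=1, n_shuffles=25)
test = mf.gen_dataset(n_pos=100, n_neg=100, rng=2, n_shuffles=25)
models = mf.train_committee(
    {s: train.labeled(s) for s in ("triplet32", "hybrid34", "seqstruct512")},
    seed=1,
)

from mirfuse.base_committee import committee_decision_matrix
from mirfuse.feature_extraction import build_feature_bundle
rng = np.random.default_rng(3)
dm = lambda ds: committee_decision_matrix(
    [build_feature_bundle(mf.fold(s), 25, rng) for s in ds.sequences], models
)
net, record = mf.train_elm(dm(train).astype(float), train.labels.astype(float),
                           restarts=50, rng=4)
print(f"fusion SSE: {record.selected_sse:.3f} over {record.n_restarts} restarts")

scores = mf.forward_batch(net, dm(test).astype(float))
pred = np.where(scores >= 0, 1, -1)
print(mf.metrics(mf.confusion(test.labels, pred)).rounded())
curve = mf.roc_linear_scan(scores, test.labels)
print(f"AUC {curve.auc:.3f} +/- {curve.se:.3f} "
      f"(95% CI {curve.ci95[0]:.3f}-{curve.ci95[1]:.3f})")
```

prints

```
(((((((((((((((((((((.(...)))(...))))))))))))))))))))
surrogate MFE: -23.0 kcal/mol
fusion SSE: 4.468 over 50 restarts
{'accuracy': 97.0, 'sensitivity': 98.0, 'specificity': 96.0, 'precision': 96.1, 'f_measure': 97.0, 'npv': 98.0}
AUC 0.979 +/- 0.012 (95% CI 0.956-1.000)
```

The fold pairs 21 of the designed sequence's stem positions (each pair
contributes −1 kcal/mol under the built-in scoring); the fused ensemble
classifies 97% of 200 held-out synthetic hairpins/pseudo-hairpins correctly,
with an AUC of 0.979 ± 0.012.

The same stages are scriptable from the shell:

```bash
mirfuse simulate --kind contigs --n-contigs 20 --contig-length 500 \
    --n-planted 3 --seed 3 --out-dir sim/
mirfuse train-base --n-pos 150 --n-neg 150 --n-shuffles 25 --seed 1 \
    --out-dir models/
mirfuse mine sim/contigs.fasta --models-dir models/ --n-shuffles 15 \
    --seed 4 --out-prefix run
```

`mirfuse mine` writes `run.candidates.tsv` (one row per classified window:
coordinates, the four base decisions, fusion score, label),
`run.summary.json` (per-stage counts) and `run.positives.fasta`.

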