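# triadsig

Sequence-only prediction of protein–protein interactions (PPIs) under
realistic class imbalance. `triadsig` is for computational biologists who
want to (a) encode protein primary sequences into composition-corrected
*triad significance* features, (b) train an efficient density-based
classifier on interacting vs. non-interacting protein pairs, and (c)
evaluate predictors honestly on datasets whose positive-to-negative ratio
ranges from 1:1 to 1:15 — because in a real interactome non-interacting
pairs outnumber interacting ones by orders of magnitude.

## Method

**Features.** The 20 amino acids are reduced to 7 physicochemical groups
(1 = {A,G,V}, 2 = {I,L,F,P}, 3 = {Y,M,T,S}, 4 = {H,N,Q,W}, 5 = {R,K},
6 = {D,E}, 7 = {C}). Every window of three consecutive residues is a
*conjoint triad*, one of 7³ = 343 types, counted along the grouped
sequence into an occurrence vector **O**. Raw triad counts track the
background residue composition, so each count o_i is replaced by its
permutation significance

&nbsp;&nbsp;&nbsp;&nbsp;s_i = Pr(X_i < o_i),

where X_i is the count of triad i in a composition-preserving random
shuffle of the sequence (estimated over n = 10,000 shuffles; one minus
the permutation p-value). A protein pair is the 686-dimensional
concatenation of its two significance vectors, in lexicographic protein
order so the encoding is symmetric.

**Classifier.** A relaxed variable kernel density estimator (RVKDE) is
fitted per class: each training sample s_i gets a Gaussian bandwidth
σ_i = β·(V_m(R(s_i))/ks)^(1/m) from the radius R(s_i) of its ks-nearest-
neighbour ball (V_m the m-ball volume, computed in log-space). A query
**v** is scored by the log-ratio of class likelihoods
L_j(**v**) = |S_j|^α · f̂_j(**v**), where f̂_j sums only the kt nearest
kernels. Hyperparameters (α, β, ks, kt) are selected by grid search
maximising the F-measure of a stratified 5-fold cross-validation;
training is O(n log n), which is what makes the highly unbalanced
datasets tractable.

**Evaluation.** Precision, sensitivity, specificity, accuracy and
F-measure = 2TP/(2TP+FP+FN); trivial baselines (fair coin, always-
negative, always-positive) expose why accuracy is misleading on
imbalanced data — an all-negative predictor already scores
r/(r+1) accuracy on a 1:r dataset (93.8% at 1:15).

A synthetic module generates desk-scale proteomes and interaction
networks with plantable triad-level signal, so the whole pipeline runs
and is tested without any external database.

## Worked example

```python
from triadsig import SyntheticConfig, run_benchmark

result = run_benchmark(SyntheticConfig(seed=0), repetitions=5, seed=0)
for r, block in result.summary["ratios"].items():
    print(f"1:{r:>2}  F = {block['formatted']['f_measure']} %  "
          f"(all-negative accuracy {block['opportunistic_neg_accuracy_pct']}%)")
```

prints (300 proteins, 400 interactions, fully motif-determined wiring):

```
1: 1  F = 80.4 ± 1.3 %  (all-negative accuracy 50.0%)
1: 3  F = 62.7 ± 1.7 %  (all-negative accuracy 75.0%)
1: 7  F = 42.1 ± 1.5 %  (all-negative accuracy 87.5%)
1:15  F = 28.5 ± 6.3 %  (all-negative accuracy 93.75%)
```

The learned F-measure (mean ± sd over 5 repetitions) degrades as the
negative class grows — the problem genuinely gets harder — while the
trivial all-negative baseline's *accuracy* climbs towards 100%, which is
exactly why F-measure is the headline metric here.

The same pipeline is available from the shell:

```bash
triadsig simulate --n-proteins 300 --n-interactions 400 --seed 0 --out sim/
triadsig build-data --interactions sim/interactions.tsv --fasta sim/proteome.fasta \
    --ratios 1,3,7,15 --train-pos 300 --test-pos 100 --reps 5 --seed 0 --out data/
triadsig encode --fasta sim/proteome.fasta --n-perm 10000 --seed 0 --out features.tsv
triadsig benchmark --seed 0 --out results/
```

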