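# Methods

## Triad significance encoding

A protein sequence over the 20 standard residues is mapped position-wise
onto 7 physicochemical groups; any other character (U, B, Z, X, …) is
rejected, with an option at dataset load to drop the offending sequence
instead. Conjoint triads — overlapping windows of three consecutive
groups — are counted into a 343-dimensional occurrence vector **O**; a
sequence of length L contributes exactly max(0, L − 2) window counts.

The significance vector **S** replaces each count o_i with
s_i = Pr(X_i < o_i), the probability that a *composition-preserving*
uniform shuffle of the sequence contains strictly fewer occurrences of
triad i. The inequality is strict: ties count against significance, and
any triad with o_i = 0 has s_i = 0 exactly. s_i equals one minus the
permutation p-value of the observed count and is invariant to the
background residue composition, which is the point of the encoding:
a triad of abundant groups is only significant if it occurs more often
than its composition alone predicts.

Estimation is Monte-Carlo with n = 10,000 shuffles by default (keeping
the relative error of each s_i around the percent level); n is
configurable and the test profile uses 1,000. Two implementation choices
matter for reproducibility:

- The null shuffles permute a *canonical* arrangement of the sequence's
  group composition, not the observed order. A uniform shuffle of any
  fixed arrangement is uniform over arrangements, so this is
  distributionally identical — and it makes the null depend only on the
  composition, allowing null count matrices to be cached and shared by
  proteins with identical composition.
- The RNG substream for each protein is derived deterministically from
  (seed, composition), so results never depend on encoding order.

Pair features concatenate the two per-protein vectors in lexicographic
order of protein identifier (686 dimensions; without the 7-group
reduction it would be 2·20³ = 16,000). PPI pairs are unordered, and the
canonical order makes the encoding symmetric without duplicating
training instances.

The classical conjoint-triad *frequency* encoding is provided as a
comparison feature set, normalised as o_i/(L − 2); its original
normalisation is not recoverable from the sources available here, so the
plain relative frequency is used and stated.

## RVKDE classifier

Given training samples {s_1 … s_n} in R^m, each sample receives a
Gaussian bandwidth from the radius R(s_i) of the ball containing its ks
nearest *other* samples (Euclidean, exact neighbour search):

    sigma_i = beta * ( V_m(R(s_i)) / ks )^(1/m),
    V_m(R) = pi^(m/2) R^m / Gamma(m/2 + 1).

This is beta times the radius-equivalent per-neighbour volume of the
ks-NN ball. **This closed form is a reconstruction**: it is built from
the estimator's documented ingredients (R(s_i), ks, the Gamma function)
but the exact published expression was not available; beta absorbs any
constant discrepancy and is tuned by cross-validation anyway. All volume
terms are evaluated in log-space because at m = 686 the raw m-ball
volume under- or overflows. Duplicate training points give R = 0 and are
floored at 1e-8 times the mean positive bandwidth to avoid singular
kernels.

The density at a query v averages the per-sample kernels; only the kt
nearest training samples of v contribute (the remaining terms are
bounded by the kt-th and negligible in practice), while the normalising
1/n keeps the truncated estimate a lower bound of the full one, so the
truncation error shrinks monotonically as kt grows. kt = n recovers the
exact estimator; tests verify the equality against a naive double-loop
implementation and that the untruncated density integrates to 1 in one
and two dimensions.

Classification builds one estimator per class and predicts by the sign
of

    score(v) = alpha*log|S_pos| + log f_pos(v)
             - alpha*log|S_neg| - log f_neg(v),

with ties (score 0) resolved to the negative, majority class. The
exponent alpha on the class prior is a deviation hook: alpha = 1 is
plain prior weighting, alpha < 1 tempers the imbalance penalty; its
exact role in the original estimator could not be recovered, so it is
exposed as an ordinary hyperparameter. Whether the prior uses |S_j| or
|S_j|/N changes only an additive constant shared by both classes, never
the decision. Everything is computed in log-space; queries whose kernels
underflow in both classes score 0 (predicted negative) and emit a
warning.

Hyperparameters (alpha, beta, ks, kt) are selected by grid search
maximising mean F-measure of a stratified 5-fold cross-validation,
seeded and deterministic, with exact ties broken by grid order. The
default grid is alpha ∈ {0.5, 1}, beta ∈ {0.25, 0.5, 1, 2},
ks ∈ {1, 3, 7}, kt ∈ {20, 50, 100} — centred, after pilot
cross-validation on balanced synthetic data, on the small-bandwidth
regime that the narrow per-sample kernels of high-dimensional
significance vectors favour.

## Dataset construction

Positives come from curated interaction records filtered to: exactly two
participants (complex records with more are removed, since pairwise
physical contact is ambiguous there), in-vivo detections only (in-vitro
interactions risk laboratory artifacts), and sequences free of
non-standard residues. Pairs are canonical unordered tuples; self-pairs
are legal.

Negatives are sampled uniformly, without replacement, from the
complement of the *entire* known-interaction set (including in-vitro and
complex-derived pairs) over the positive-set proteins: n proteins with m
exclusions give n(n+1)/2 − m candidates — the formula counts self-pairs,
and self-pair negatives are included by default (a flag excludes
homotypic pairs). Sampling enumerates the complement explicitly when the
pair space is below 10⁶ and otherwise uses rejection sampling against a
used-pair registry, so the 20-million-pair spaces of real interactomes
never materialise.

A ratio sweep reuses one random positive train/test split per repetition
across all ratios and draws r negatives per positive for each set.
Negative sets are pairwise disjoint *within a repetition* (across ratios
and train/test); repetitions re-sample independently. Strict global
disjointness across repetitions is available behind a flag but is
arithmetically infeasible at desk scale (5 repetitions of the default
sweep need 52,000 disjoint negatives from a 44,750-pair space), so
per-repetition scope is the default.

## Synthetic data generator

The generator emulates a curated interactome's statistical shape at desk
scale. Defaults: 300 proteins, lengths uniform in 50–300, 400
interactions, group frequencies at the groups' natural abundances
(22.0 / 24.2 / 17.3 / 11.4 / 11.4 / 12.2 / 1.4 percent), signal strength
θ = 1, 16 motif triads (drawn deterministically from the seed), motif
planting up to 30% of residues, pair-compatibility sharpness γ = 6.

Sequences draw their residue composition i.i.d. from the group profile.
Learnable signal is planted at the *arrangement* level, which is exactly
— and only — what the significance encoding can see: each protein has a
latent stickiness u ~ Uniform(0,1), and a composition-preserving
rearrangement assembles motif-triad occurrences in proportion to u.
Because planting never changes composition, empirical group frequencies
converge to the profile regardless of θ. The network then wires
round(θ·n_interactions) edges by weight (u_a·u_b)^γ — with u re-derived
from the sequences as the rank percentile of a motif-enrichment z-score
(observed minus composition-expected motif counts over their standard
deviation) — and the remaining edges uniformly. θ = 0 is a pure-noise
network; θ = 1 fully motif-determined. Edge-level mixing (rather than
mixing inside the weights) keeps intermediate θ informative: at θ = 0.5
half of the positives carry signal.

What the generator does **not** model: homology and domain structure,
realistic degree distributions, false negatives in the gold standard,
cellular localisation. Passing tests therefore demonstrate that the
pipeline recovers triad-level signal under imbalance — not performance
on real interactomes, where the dominant difficulties are gold-standard
incompleteness and negative-set construction.

## Benchmark protocol and problem sizes

The benchmark encodes all proteins once (1,000 permutations in the test
profile), builds the ratio sweep {1, 3, 7, 15} with a 300/100 positive
split over 5 repetitions, selects hyperparameters by grid search on the
most balanced ratio's training set of the first repetition, reuses them
across all ratios and repetitions (one selection, as the sweep compares
datasets, not tunings), and reports per-ratio mean ± sample standard
deviation in percent, one decimal. These sizes keep a full sweep under a
minute on one CPU while leaving the qualitative imbalance trend
(F-measure falling from ~80% at 1:1 to ~29% at 1:15, all-negative
accuracy rising to 93.8%) well clear of its noise band. Manifests omit
wall-clock timestamps by default so identical inputs and seeds give
byte-identical artifacts.

## Numerical and degenerate-input conventions

- Metrics with zero denominators are NaN (explicit undefined marker),
  except F-measure, which is 0 whenever 2TP+FP+FN > 0; mean ± sd
  aggregates use the sample standard deviation (ddof = 1) — the choice
  of sd over standard error is stated in the output labels.
- Precision–sensitivity curves sweep unique scores descending with ties
  grouped at one threshold and no interpolation; the final point always
  has sensitivity 1.
- Monte-Carlo significance of short sequences is validated against exact
  enumeration of all distinct permutations; with ~10⁴ coordinate
  comparisons a strict everywhere-within-3-SE assertion fails by chance,
  so the oracle test allows 1% of coordinates outside 3 SE and none
  outside 6 SE, and requires exact agreement where the enumerated
  probability is 0 or 1.
- All randomness flows from one seed through SHA-256-derived substreams
  (< 2³¹), so no stage's results depend on the order other stages run.

## Known limitations

- The bandwidth formula and the role of alpha are reconstructions (see
  above); results are internally consistent but the constant factors may
  differ from the original estimator's.
- Exact k-NN search is O(n²) per query batch at worst; no approximate
  or GPU backends are provided.
- The comparison frequency encoding's original normalisation is
  uncertain; relative frequency is used.
- Negative sampling assumes missing interactions are true negatives; on
  real data the measured F-measure is therefore pessimistic, and no
  correction for gold-standard incompleteness is attempted beyond the
  analytic ceiling reported by the acceptance script.
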