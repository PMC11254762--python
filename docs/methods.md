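# Methods

## Overview

`neurosem` analyses word-aligned single-unit activity recorded (or
simulated) while a listener hears naturalistic sentences. The pipeline has
five analytic layers — semantic-domain discovery, response alignment,
per-neuron selectivity, population decoding, and the neuronal–semantic
space — plus a synthetic generator that serves as the package's test bed.
Every stochastic step derives its stream from a single integer seed through
a CRC-based splitting scheme (`neurosem._rng`), so identical configurations
reproduce byte-identical results.

## Semantic domains from embeddings

Words are unit-norm vectors (d = 300 by default) compared by cosine
distance. Domain discovery is spherical k-means: k-means++ seeding under
cosine distance, Lloyd iteration with centroids renormalised to the sphere,
empty clusters re-seeded from the point farthest from its centroid, and the
best of 4 restarts kept by the summed cosine objective (single restarts of
Lloyd on well-separated clusters converge to merged/split local optima often
enough to disturb model selection). The domain count is chosen by repeating
the clustering at each k ∈ [5, 20] with pseudorandom seeding and averaging
the mean silhouette under cosine distance across repeats (default 100
repeats; recovery tests use 5–10 because only the argmax over k is
asserted). Ties go to the smaller k (parsimony). A `weak_separation` flag
fires when the best mean silhouette is below 0.25; isotropic clouds at
moderate dimension reach ≈ 0.2 under cosine distance, so values below the
floor indicate no usable cluster structure.

Quality metrics: purity counts the best-matched overlap between a re-derived
and a reference partition, (1/n) Σᵢ maxⱼ |ωᵢ ∩ cⱼ|; d′ contrasts within- vs
between-domain cosine distances, (μ_between − μ_within)/√((σ²_w + σ²_b)/2),
positive when domains are tight. The sign convention (positive = separable)
is the package's choice.

High-frequency function words are removed before clustering via an injected
word → frequency-score mapping with a configurable threshold and comparison
direction; the package does not assume any particular frequency scale.

## The synthetic world

The generator emulates one recording session at the scale of the
intraoperative data it stands in for:

| parameter | default | rationale |
|---|---|---|
| domains × words | 9 × 51 (= 459 words) | session-scale vocabulary |
| sentences | 131 × 8 words (1,048 tokens) | session-scale token count |
| word spacing | 341 ± 5 ms (truncated Gaussian) | measured inter-onset interval |
| units | 133, 15% selective | session-scale population |
| baseline rate | 2 Hz | low prefrontal rates; keeps rank-sum cross-domain bias small |
| tuning gain | 2.3 Hz | measured SI ≈ 0.3 (see below) |
| word-list attenuation γ | 0.5 | reproduces the ≈ 0.3 → ≈ 0.18 SI drop |
| analysis window | 100–500 ms after onset | evoked-response lag |
| homophone pairs | 12 cross-domain, ≥ 8 occurrences each | power for the pair contrast |
| story vocabulary | 70 words, 28 shared | transfer test with novel words |

Centroids are exactly orthonormal (QR of a Gaussian matrix); word vectors
are normalize(centroid + ε/concentration) with standard-normal ε and
concentration 25, giving within-domain cosines ≈ 0.8 and a planted structure
the silhouette criterion recovers from geometry alone.

Spikes are Poisson counts per word window placed uniformly in the window
(only windowed rates are analysed; no between-window process is simulated).
At 341-ms spacing, the 400-ms window overlaps each neighbour by 59 ms, so a
word's measured rate is contaminated by ≈ 0.1475 of each neighbour's rate.
The defaults account for this: with baseline b and gain g, the measured SI of
a planted unit is ≈ g / (2.59·b + 1.066·g); b = 2, g = 2.3 gives ≈ 0.3, and
γ = 0.5 gives ≈ 0.18 in word lists. The rates were fixed from this
closed-form calculation, not adjusted afterwards.

Generator modes: `geometry_mode` scales each unit's gain by the positive
cosine between the word vector and the unit's preferred-domain centroid
(continuous tuning; enables recovery of embedding geometry from rates);
`phonetic_mode` is a negative control in which units respond to a random set
of phonetic ids rather than meaning, which reverses the homophone contrast;
`surprisal_sensitivity` β scales the gain by (1−β) + β·predictability for a
planted context effect. Homophone mates share a `phonetic_id` but belong to
different domains; both they and a matched set of same-domain control words
are re-inserted into sentences until they occur ≥ 8 times, because at the
natural ≈ 2.3 occurrences per word the |Δ rate| noise floor (≈ 1.7 Hz)
swamps a 2.3-Hz tuning signal — the stand-in for homophones recurring
naturally across a much longer recording.

What the generator does *not* emulate: real embedding anisotropy and
polysemy, sentence syntax (tokens are sampled, not composed), graded or
mixed selectivity beyond the planted binary/geometry modes, non-Poisson
spiking statistics, and recording artefacts. A green recovery test
establishes that the statistics detect the planted effect at session scale,
not that real cortex behaves this way.

## Selectivity

Per unit and domain: two-sided Wilcoxon rank-sum of in-domain vs
out-of-domain rates, BH step-up across the k domains per unit; a unit is
selective iff any adjusted p < α (0.05). The preferred domain is the
significant domain with the smallest adjusted p, ties broken by larger
|FR_domain − FR_other| then lower index. SI = |FR_domain − FR_other| /
(FR_domain + FR_other) on raw (not z-scored) rates; 0/0 propagates as NaN
and is excluded from group means. Bootstrap robustness re-estimates SI on
100 random 60% *sentence* subsamples (splits are sentence-level everywhere,
so words from one sentence never straddle a split). The FDR validation
measures the false-discovery proportion per unit-level BH family, averaged
over units and seeds — the quantity the BH procedure as applied actually
controls.

One caveat documented rather than hidden: because each domain is tested
against *all* other words, a strongly tuned unit's preferred-domain events
sit in the "other" sample of every non-preferred test, deflecting those
tests away from the null. At default gain this makes secondary-domain
detections in the bootstrap (≈ 10–20% of iterations) a property of the
one-vs-rest construction, not an error of the implementation; recordings
with weaker effects show correspondingly smaller cross-domain rates.

## Decoding

Features are the selected units' rates per word event; labels the domain of
the word. Each iteration: draw 60% of sentences, standardise features on the
training split only, fit one-vs-rest SVC (linear kernel, C = 1, balanced
class weights; one-vs-one available behind a flag), and score class-balanced
accuracy (mean per-domain recall) on held-out words, making chance exactly
1/k. Permutation nulls shuffle labels over events before splitting and rerun
the identical pipeline once per permutation; the empirical p is the fraction
of null accuracies ≥ the observed mean, floored at 1/n_perm (a +1-smoothed
variant is available). Cross-material transfer fits on all sentence events
and evaluates on story events with their own label-shuffled null. The
improvement surface re-clusters the vocabulary at each d ∈ [2, 20], draws
unit subsets of each size n, and reports
100·(PA_actual − PA_shuffle)/PA_actual.

## Context dependence

*Word lists*: SI per condition on the units selected from the sentence
condition, compared by paired signed-rank; a companion rank-sum on overall
mean rates should be null since only tuning gain, not baseline, is
attenuated. *Homophones*: per unit, mean |Δ rate| over cross-domain
homophone pairs vs same-domain control pairs matched in count and token
frequency (frequency matching equalises the sampling-noise floor of the two
pair sets; without it the contrast is dominated by occurrence counts).
Pooled permutation test (10,000 shuffles, two-sided) plus a one-tailed
paired t; units with no response or beyond 2.5 × IQR are excluded; several
sessions can be pooled, as the analysis is underpowered on a single
session's ≈ 20 selective units. *Surprisal*: −ln P from any model exposing
`cond_prob(word, prefix)`; the default is an absolute-discounting backoff
bigram fit on the session's own sentences (conditional distributions sum to
1 over the vocabulary). Decoding accuracy is aggregated per event across
iterations and compared between bottom and top surprisal deciles by
rank-sum (deciles widen to quintiles below 10 words per bin). *Dropout*: any
analysis expressed as a callable over sessions is rerun leaving each session
out; flips of its significance decision are flagged and a one-way ANOVA
across dropout value distributions checks homogeneity.

## Neuronal–semantic space

For each unit, the mean z-scored rate per word F_{i,w} is regressed on the
word's embedding vector by ridge (normal equations, λ = 10⁻⁴). The stacked
θ (units × dim) is PCA-reduced along the neuronal dimension (5 PCs),
preserving embedding dimensionality so words project into the space.
Correlations: (i) pairwise cosine distances of projections vs embeddings
over all unordered pairs, permutation p by shuffling word identity;
(ii) |Δ population rate| vs embedding cosine distance, percentile-binned
(100 bins), one-sided permutation p; (iii) |Δ population rate| vs
single-linkage cophenetic distances of the embedding space, with optional
per-session correlations using finer bins and 2.5 × IQR outlier exclusion.
Words are sorted lexicographically before linkage so zero-distance ties
break deterministically. Dendrograms export to Newick with merge-height
increments as branch lengths. The pair-distance and hierarchy correlations
are computed on the selective subpopulation, where the semantic geometry is
carried; population averages over all units dilute them.

## Numerical conventions

Windows are half-open [onset+lag, onset+end) in seconds, preventing double
counting. Rates are spikes/s; z-scoring is per unit across events with
constant units mapped to 0. Empirical p-values are never reported below
1/n_perm. Percentile binning merges duplicate quantile edges. Ridge uses
`solve` on (VᵀV + λI), well-posed for λ > 0. BH adjustment comes from
statsmodels, SVCs and silhouette/PCA from scikit-learn, rank-based tests
from scipy; all are cross-checked against brute-force oracles in the test
suite.

## Known limitations

- The pipeline operates per-session; multi-participant aggregation is
  concatenation (decoding) or pooling of per-unit measurements (homophones).
- The bigram language model is a stand-in: real surprisal estimates need a
  stronger model behind the same interface.
- The improvement surface is O(|d_range| × |n_range| × iterations) SVC fits
  and is the one analysis that does not run at full scale in the tests.
- Acceptance-style recovery tests are run at reduced repeat/permutation
  counts; the asserted quantities (argmax k, detection rates, directions of
  effects) are insensitive to this scaling, but exact p-values are not.
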