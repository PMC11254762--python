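# neurosem

Single-neuron semantic-encoding analysis: from word-embedding domain
discovery to neuronal selectivity, population decoding, context-dependence
tests, and the neuronal–semantic space — with a synthetic generator of
semantically tuned spiking populations so the entire pipeline runs and is
testable without any recordings.

## The problem

During natural speech, single neurons in human association cortex respond
selectively to *what words mean*: a cell may fire more for food words than
for anything else, shift its tuning when sentence context is removed, and
treat homophones ("sun" vs "son") by their meaning rather than their sound.
Analysing such recordings requires a chain of steps — grouping a vocabulary
into semantic domains from word embeddings, aligning spikes to word onsets,
testing each unit's domain tuning, decoding domains from population
activity, and relating population geometry to embedding geometry. `neurosem`
implements that chain as a reusable, seeded, fully tested library.

## Core quantities

- **Semantic domains** — spherical k-means (cosine distance, k-means++
  seeding, best-of-restarts Lloyd) over unit-norm word vectors; the domain
  count is chosen by a repeated mean-silhouette criterion over k ∈ [5, 20].
  Cluster quality: purity(Ω, ℂ) = (1/n) Σᵢ maxⱼ |ωᵢ ∩ cⱼ| and a d′
  contrast of within- vs between-domain cosine distances.
- **Selectivity** — per unit and domain, a two-sided rank-sum test of
  in-domain vs out-of-domain firing rates in a 400-ms window lagged 100 ms
  after word onset, BH-FDR-adjusted across the k domains; tuning magnitude
  is the selectivity index
  **SI = |FR_domain − FR_other| / (FR_domain + FR_other)** ∈ [0, 1].
- **Decoding** — one-vs-rest linear SVCs (min ½wᵀw + C Σζᵢ, C = 1, balanced
  class weights) on 60/40 sentence-level splits; class-balanced accuracy so
  chance = 1/k; empirical p from label-shuffled permutation nulls.
- **Context** — sentence vs word-list SI (Wilcoxon signed-rank), a pooled
  10,000-shuffle permutation test on homophone vs same-domain pair response
  differences, and decoding conditioned on surprisal
  s(wᵢ) = −ln P(wᵢ | w₁…wᵢ₋₁) from a pluggable language model (backoff
  bigram by default).
- **Neuronal–semantic space** — per-unit ridge regression F_{i,w} = v_w θᵢ + εᵢ
  (λ = 10⁻⁴, normal equations), PCA of the stacked θ along the neuronal
  dimension, word projections on the components, and correlations of
  |Δ rate| with embedding and single-linkage cophenetic distances.

## Worked example

```sh
python examples/02_selectivity.py
```

```
22/133 units selective (17%); 20/20 planted units recovered
mean SI of selective units: 0.29 (0 = untuned, 1 = responds to a single domain only)
unit 1: SI 0.35, bootstrap mean over 60% sentence subsamples 0.35 (stability check)
meaning specificity (keeping only centroid-nearest words per domain):
  top 100% of words -> mean SI 0.29
  top 75% of words -> mean SI 0.29
  top 50% of words -> mean SI 0.30
  top 25% of words -> mean SI 0.31
70/133 units distinguish words from nonwords (Welch t-test)
```

A default synthetic session has 133 units (20 planted as selective), 131
eight-word sentences over 459 unique words in 9 domains, plus word-list,
nonword, homophone, and story controls. All planted selective units are
recovered at 5% FDR; their SI sits near the planted 0.3; restricting domains
to their most central words sharpens tuning; and roughly half the
population (the planted fraction) separates words from nonwords.
`examples/03_decoding.py` continues the session: ~31% balanced decoding
accuracy against an 11% shuffled-label chance level, and transfer to a
story containing words never used for training. `examples/04_context.py`
shows the SI dropping 0.29 → 0.16 when sentences are scrambled into word
lists (matched overall rates), and better decoding for predictable words.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the full pipeline on a freshly generated default-scale session —
domain discovery (silhouette + spherical k-means), alignment, selectivity,
decoding with a 100-permutation null, the context battery, and the
semantic-space analyses — writes the target JSON to `--out`, and leaves the
complete stage report in `pipeline_report.json` next to it. Everything is
deterministic in `--seed`.

See `docs/methods.md` for the model, parameter choices, and limitations.
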