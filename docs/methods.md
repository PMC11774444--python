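# Methods

## The model

The package studies where a linear encoding model of word-level brain
responses breaks down. A session consists of `n_words` word events in
presentation order, grouped into contiguous sentences. Each word `w` has an
embedding `L[w]` (one row of an `n_words × embed_dim` matrix, one matrix
per candidate layer) and a response `M[w]`, a `n_channels × n_timebins`
grid of sensor amplitudes time-locked to word onset. The epoch is 0–500 ms
in non-overlapping 25 ms bins (20 bins) by default; both are configurable,
and the default epoch bounds are a convention — the responses are
synthetic, so only the bin count matters.

The encoding model is ridge regression per timebin with all channels as
joint targets:

    M̂[:, :, t] = L Ŵ_t + b̂_t ,   Ŵ_t = argmin ‖M_t − L W − b‖² + λ‖W‖²

with the bias unpenalized (centering convention: predictors and targets
are centered with training-fold means only, so no test statistics leak
into the fit). Cross-validation is 10-fold and *contiguous* — test folds
are blocks of consecutive words — because stimulus-locked responses are
temporally autocorrelated and shuffled folds would leak context between
train and test. λ is chosen per fold and per timebin by nested contiguous
5-fold cross-validation on the training block, maximizing the mean inner
held-out Pearson correlation across channels; ties break to the smallest
λ, and a per-channel λ option exists behind a config switch
(`encoding.per_channel_lambda`). Held-out predictions from all folds are
concatenated back into word order, and model quality is summarized as the
Pearson correlation across words per (channel, timebin) cell. When several
embedding layers are supplied, the layer with the highest mean correlation
over all cells is selected (ties to the lowest index).

## Divergence statistic and contrast corpora

Cells whose held-out correlation is significantly positive form the gate
set S: one-sided test of r > 0 via the exact transform
t = r·√(n−2)/√(1−r²) against Student's t with n−2 degrees of freedom, at a
raw (uncorrected) threshold p < 0.001. The per-word divergence statistic
is the mean squared prediction error over S,

    MSE_w = 1/|S| · Σ_{i∈S} (M̂_wi − M_wi)² .

S pools the full (channel, timebin) grid by default; a channel-only
variant (keep a channel at every bin if it is significant in any bin) is
available as `divergence.pool = "channels"`, and the variant used is
recorded in the output metadata. Sentences are scored by the unweighted
mean of their words' MSE_w (a length-bias diagnostic — the correlation of
sentence score with sentence length — is computed alongside), ranked
descending, and the top/bottom 100 become the contrast corpora D0
(least-predicted) and D1 (best-predicted). With fewer than 200 sentences
the corpus size shrinks symmetrically so the two stay disjoint.

## Hypothesis discovery

A proposer generates candidate natural-language differences between D0 and
D1; a verifier judges each hypothesis per sentence. Validity is the
held-out difference of verified fractions (D0 minus D1), which is
antisymmetric under corpus swap and lives in [−1, 1]. Proposal and
verification repeat over 3 cross-validation folds: in each fold the
verifier scores the held-out split while the proposer sees a sample (25
sentences per corpus by default) of the rest. Hypotheses are deduplicated
by exact text; final validity is the mean over the folds where a
hypothesis was evaluated. Significance comes from permuting corpus labels
over the pooled held-out sentences with the add-one estimator
p = (1 + #{permuted ≥ observed}) / (n_perm + 1).

The shipped backends are deterministic token-statistics mocks: the
proposer emits "contain the word '<t>'" for the tokens with the largest
document-frequency difference between corpora, and the verifier is a
membership test. The backend interface (two methods, `propose` and
`verify`) mirrors what an LLM-backed proposer/verifier pair would
implement, so remote backends plug in without touching the loop. A
null-model verifier (seeded cryptographic-hash coin flips) supports
calibration checks; a linear checksum is deliberately avoided there
because its GF(2) structure correlates verdicts across hypotheses and
visibly distorts the p-value distribution.

Because the verdicts are binary, the permutation distribution of validity
is a (conditionally) hypergeometric lattice; with small held-out sets its
atoms make the add-one p conservative. Calibration checks therefore use
corpora of ~200 sentences per side, where the atoms are small and the
p-values are uniform to KS < 0.1 over 200 replicates.

## Model comparison

Multiple-choice scoring treats an N-option item as N language-modeling
tasks: each option is appended to the context, and the scorer's logits for
the realized option tokens (each read from the prediction made after all
preceding tokens) are summed into one score per option. Training minimizes
the cross-entropy of the score vector against the correct option. The raw
summed-logit reading is the default; summed log-softmax probabilities (the
normalized likelihood reading) are available for evaluation via
`use_log_softmax`, and the choice is recorded in the run manifest.

The toy scorer realizing this contract is a two-parameter-family model
over the synthetic vocabulary: `logit[t, v] = bias[v] + c · freq(v in
tokens[:t])`, a unigram bias plus a copy term using the relative frequency
of `v` among preceding tokens. The frequency (not raw count) keeps the
feature bounded in [0, 1] and the convex training objective well
conditioned on long streams. Gradients are analytic; training is
full-batch gradient descent. The copy statistic is exactly what solves the
planted multiple-choice rule, so the scorer reaches ≥ 95% held-out
accuracy in ~30 epochs, while its simplicity keeps training in
milliseconds.

Comparing a base against a "fine-tuned" encoding uses three statistics:

* **Per-cell permutation test.** Δr = r(M, M̂_ft) − r(M, M̂_base) per
  (channel, timebin) cell; the null permutes the word order of the
  measured responses, applying the same permutation to both correlations
  per draw so shared word-level structure cancels. 10,000 permutations,
  two-sided add-one p, cells labeled better/worse at p < 0.05 by the sign
  of Δr. No multiple-comparison correction is applied by default (the
  labels report a raw empirical threshold); `bh_fdr` can be applied to the
  returned p-grid when desired.
* **Category improvement.** Per timebin, the improvement
  ΔMSE_w = MSE_base,w − MSE_ft,w (positive = fine-tuned better) computed
  over the significant channels of that bin, compared between in-category
  and out-of-category words with a two-sample Student t-test, then
  Benjamini–Hochberg across timebins at level 0.05 (via statsmodels, with
  a brute-force step-up oracle in the tests).
* **Language-modeling control.** Contiguous 3-fold cross-validation on the
  stimulus token stream; per fold each scorer is trained with the
  next-token objective and evaluated by mean held-out cross-entropy. Close
  average losses indicate the comparison is not confounded by a plain
  language-modeling gap.

## Synthetic data: what it emulates, what it does not

The generator plants every structure the pipeline is supposed to find, so
each stage has a ground-truth target:

* **Forward model.** `M[w] = L[w]·W + b + ε`, ε i.i.d. Gaussian with
  `noise_sd = 1`. W, b are drawn once per seed; W is scaled by
  1/√embed_dim so signal variance is O(1) against unit noise.
* **Context-dependent embeddings.** Row `w` mixes the word's token vector
  with a geometrically decaying sum (weight 0.5, decay 0.8) over the
  preceding 19 tokens — a linear stand-in for contextual hidden states:
  repeated tokens get context-dependent rows, and a word's row depends
  only on its token window, never on future words.
* **Layer stack.** Three candidate layers; the middle one generates the
  responses, the others are noise-degraded mixtures (weight 0.5^|j−j*|),
  giving layer selection a correct answer.
* **Planted category.** 30% of sentences are planted: they contain a
  marker keyword and their words receive a residual `r[w] =
  (effect/√2)·(a_w1·u_1 + a_w2·u_2)` — a fixed rank-2 spatial pattern
  (rows scaled to unit mean square) times word-specific Gaussian
  amplitudes, independent of the embeddings. Mean residual power on
  planted words is `planted_effect²` per cell (so effect 5 against unit
  noise gives second moments ≈ 26 vs ≈ 1). The default effect is 3·noise_sd,
  the level at which divergence recovery is expected to
  be near-ceiling. Appending the amplitudes to the embeddings makes the
  residual linearly predictable — that augmented representation plays the
  "fine-tuned model" in the comparison stage.
* **Multiple-choice task.** The correct option's tokens are drawn from the
  item's context; distractor tokens come from the disjoint half of the
  vocabulary. Correctness is decidable from token statistics alone, and
  constant guessing sits at 1/N.
* **Repetitions.** Responses can be generated for several repetitions that
  share the signal and redraw only the noise; averaging them scales noise
  variance by 1/n, emulating averaging a story's repeated recordings.

All randomness flows from one seed through named per-stream generators
(tokens, sentence structure, token vectors, weights, noise, planted
residual, multiple-choice, categories, layers), so identical
configurations are bit-identical and enlarging one stream does not perturb
another.

What the generator does *not* emulate — hence what passing tests do not
show about real recordings: sensor geometry and spatially correlated
noise, temporally autocorrelated noise within and across words (noise here
is i.i.d.; the contiguous folds guard against leakage that real data
would exhibit, but the synthetic null cannot produce it), 1/f spectra and
artifacts, real lexical statistics (the vocabulary is 200 integer tokens),
and any nonlinearity in the embedding-to-response map. Recovery results
on this data certify the machinery — algebra, gating, ranking, permutation
and FDR logic — not the empirical claims one could make from real MEG.

## Study conditions and problem sizes

The shipped analysis (and `scripts/acceptance.py`) runs at 2000 words over
400 sentences, 20 channels × 10 bins, 16-dimensional embeddings, three
layers, λ grid {0.01, 0.1, 1, 10, 100, 1000}, with the procedural
constants above (10 outer folds, p = 0.001 gate, top-100 corpora, 3
discovery folds, 999 discovery permutations, 10,000 channel-test
permutations, FDR at 0.05). These sizes give stable statistics — held-out
r ≈ 0.54 at unit noise, gate near-saturated, D0 enrichment at ceiling —
while a full run completes in under a minute on one core. Statistical
property checks in the test suite use smaller grids chosen per check, with
corpus sizes for p-value calibration as noted above.

## Numerical choices and degenerate inputs

* Ridge is solved through the SVD of the centered design; the λ grid is
  evaluated from a single decomposition per fold. With λ = 0 a
  rank-deficient design raises by default (`allow_singular` switches to
  the pseudo-inverse solution).
* Pearson correlation of a zero-variance column is undefined and returned
  as NaN; NaNs are excluded from averages, never counted as significant,
  and propagate to per-bin MSE as "bin undefined" (excluded from t-tests).
* Ties break deterministically everywhere: smallest λ, lowest layer index,
  lower sentence id in rankings, ascending p then lexicographic text in
  hypothesis ranking.
* Permutation p-values always use the add-one estimator, so they are
  never exactly zero.
* Empty significant sets, empty corpora, empty held-out splits, categories
  with fewer than two words in or out, and shape mismatches raise
  immediately with named errors rather than producing silent NaNs.
* HDF5 outputs are written with `track_times=False`; together with the
  seeded generators this makes whole pipeline runs byte-identical, which
  the manifest verifies by content hash (timings are kept in a separate
  log outside the reproducibility contract).

## Known limitations

* The proposer/verifier backends shipped are token-statistics mocks; the
  validity and p-value definitions are this package's documented choices
  for an interface whose original backends are generative models.
* The permutation unit for the channel test is the word; block
  permutations preserving temporal autocorrelation are not implemented
  (the synthetic noise is i.i.d., so they would be indistinguishable
  here).
* The toy scorer's two-parameter family cannot represent order-sensitive
  sequence structure; it exercises the scoring/training contracts, not
  language modeling.
* Per-channel λ selection and the channel-pooling gate variant are
  provided but not exercised by the default analysis.
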