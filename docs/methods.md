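# Methods

## The analysis in one paragraph

Brain activity recorded during naturalistic listening is modelled voxel by
voxel as a linear response to stimulus-derived features. Restricting the
feature stream — keeping only content words (semantic view), or replacing
every token by its (POS, Morph, NCN) triplet (syntactic view) — restricts
what information the downstream embeddings *can* carry, so differences
between encoding models trained on the restricted views localise semantic
and syntactic sensitivity in the brain. Context-bounded embeddings extend
the logic to temporal integration: a model allowed at most *k* past tokens
can only explain voxels whose integration window fits inside *k*.

## Feature restriction

* Content words are the open classes {NOUN, PROPN, VERB, ADJ, ADV, NUM,
  INTJ}; everything else (closed classes, punctuation) is filtered from the
  semantic stream. The split is configurable.
* NCN (number of closing nodes) counts every constituency-tree node —
  preterminals and root included — whose span ends at the token;
  equivalently the run of closing brackets after the leaf. Summed over a
  sentence it equals the tree's node count, which is the invariant the
  tests check against an independent bracket-counting oracle.
* Morphological bundles are canonicalised to a sorted `Feat=Val|…` string
  (`_` when empty) so triplet identities are stable across sources.

## Embeddings

The lexical trainer minimises the weighted least-squares objective on log
co-occurrence counts, J = Σ f(X_ij)(w_i·w̃_j + b_i + b̃_j − log X_ij)², with
f(x) = min((x/x_max)^α, 1), α = 0.75, x_max = 100 by default, full-batch
AdaGrad (lr 0.05), per-symbol vector = w + w̃. Co-occurrence uses a
symmetric window (default choices in the pipeline: window 15,
inverse-distance weighting). Reported loss is J divided by the number of
nonzero pairs. The monotone per-epoch loss decrease asserted in the tests
is a property of full-batch AdaGrad at the default step on the tested
problems, not a theorem; a hostile learning rate can break it (and a
non-finite loss raises a divergence error suggesting a smaller step).

Contextual embeddings go through a provider contract: anything causal that
maps a symbol sequence to one vector per position qualifies (a transformer
layer, for instance). Two extraction protocols are implemented exactly as
an encoding study would drive such a model over a long stimulus:

* **sliding window**: window of N tokens, stride 1, read the next-to-last
  position; the first N−2 tokens use the longest available prefix window
  and the final token is read from the last position of the final window
  (the edges are our choice; nothing downstream is sensitive to it);
* **fixed context**: sequences of k+5 tokens — the current token plus up to
  k+4 predecessors — reading only the current token's vector, so position
  t is provably blind to anything more than k+4 tokens back (tested by
  perturbation).

The bundled `ToyContextualProvider` is a desk-scale causal embedder: a
decaying weighted mean of per-symbol base vectors. Its decay may be
per-dimension, giving channels with different integration timescales the
way a trained contextual model mixes fast lexical and slow discourse
information. This matters for the context-window analyses: with a single
timescale, lengthening the extraction window *changes* every regressor
(oversmoothing), whereas real long-context models nest shorter windows.
With multiple channels, a 45-token extraction reproduces the 15-token
model's slow channel almost exactly (weight mass beyond 19 tokens at decay
0.88 is 9%), which is what makes the ctx45-vs-ctx15 contrast a true
plateau test.

## Encoding model

* Events are placed at **word offsets**; amplitudes are embedding values
  (z-scored per run before fitting).
* HRF: canonical SPM double-gamma — gamma densities with shape 6 and 16
  (dispersion 1), undershoot ratio 1/6, 32 s duration — peak-normalised,
  oversampled 16× per TR (TR = 2 s). Convolution runs on the oversampled
  grid; regressors are read out at scan times.
* Baseline (confound) model: HRF-convolved acoustic RMS (10 ms sampling),
  word-rate impulses at offsets, and a mean-centred natural-log unigram
  frequency modulator. Frequencies come from the training stream itself.
* BOLD preprocessing: per-voxel linear detrend, then z-scoring; constant
  voxels are flagged and zeroed.
* Ridge with nested leave-one-run-out CV: the outer loop holds out one run;
  the inner loop leaves out each training run in turn and scores a
  10-point log-spaced alpha grid (1e−3…1e5); alpha is selected **per
  voxel** (argmax of mean inner correlation; ties resolve to the smaller
  alpha), the model is refit on all training runs and scored on the
  held-out run; R is the mean per-fold Pearson correlation. The solver is
  an SVD path, verified in the tests against the closed-form penalised
  normal equations and scikit-learn's Ridge to 1e−8.
* ΔR is the per-voxel increase in cross-validated R when a feature space's
  columns are appended to the baseline in a single fit (column
  concatenation, not residualisation). Unique contribution =
  R(concat) − R(single); synergy = R(integral) − R(concat); context
  contrast = R(larger k) − R(smaller k).

## Group statistics

Subject maps are smoothed with an isotropic Gaussian (FWHM 6 mm, σ =
FWHM/2.355) on the voxel lattice, with kernel renormalisation inside the
voxel mask (as with a brain mask) so constants are preserved and nothing
bleeds in from outside the mask. A one-sided one-sample *t*-test against
zero (z from the normal quantile of 1−p; zero-variance voxels resolved by
the sign of the mean) feeds Benjamini–Hochberg FDR at q = 0.005; z_FDR is
the smallest z among rejected voxels. Peak regions are the top
ceil(0.10·n) voxels, ties broken by voxel id. The specificity index
x = log₁₀(ΔR_sem/ΔR_syn) is defined only where both increases are
positive; other voxels are masked invalid rather than erroring, since a
log-ratio of non-positive sensitivities has no interpretation.

## Decoding probes

A multinomial logistic classifier (L2, C = 1, ≤1000 iterations) predicts a
per-token label from its embedding under run-wise CV (one fold per run); a
per-fold majority-class dummy estimates chance. Eligibility masks
(all-tokens vs content-only) compose idempotently and are recorded in the
task metadata, because chance level depends on the eligible set.

## Synthetic cohort

The generator is the study-conditions definition, not a convenience:

* **Stimulus**: a template grammar (transitive, adjectival, prepositional
  and adverbial clause patterns over ~130 content forms) emits annotated
  tokens, well-formed constituency trees and jittered word timings (word
  duration 0.2–0.4 s, gaps 0.1–0.3 s); the template mixture is solved so
  the expected content-word fraction hits the configured target (0.5).
  Nine runs of ≥300 tokens per subject, 20 subjects, TR 2 s by default.
* **Factors**: semantic vectors per content word (d = 8), syntactic
  vectors per triplet (d = 8), drawn independently. Because a word fixes
  its (POS, Morph) signature, raw per-word vectors would correlate with
  the syntactic space; semantic vectors are therefore centred within
  signature groups, making the spaces orthogonal in expectation (empirical
  first canonical correlation ≈ 0.14 at default sizes; the effective
  sample for such checks is the vocabulary, not the token count).
* **Voxels**: a 10×10 lattice × 9 layers at 4 mm, with layers 3–4 absent
  from the mask: planted classes fill layers 0–2 (300 voxels), null voxels
  layers 5–8 (400). The two-layer gap plays the role of an anatomical
  boundary: 6 mm smoothing on a 4 mm grid moves ~7–18% of a plateau into
  face/edge neighbours, so without the gap the null compartment would
  inherit signal from geometry alone and any false-positive count would
  measure smoothing bleed instead of statistical calibration.
* **Classes**: semantic and syntactic blocks (40 each) sit in the left
  hemisphere (x < 0), disjoint — the segregated construction; a mixed
  block (40) and interaction voxels (110) sit on the right — the
  overlapping construction. Context-5/15 blocks (35 each) are on the left.
  Mixed voxels carry *both* components at dedicated-voxel strength (each
  scaled to the configured SNR), so they dominate both the semantic and
  syntactic right-hemisphere maps and the top-decile peak sets largely
  coincide there by pigeonhole. Interaction voxels are driven by
  elementwise products of semantic and syntactic factors — representable
  by the integral space (which appends four product dimensions) but not by
  any concatenation of the linear spaces. Context-k voxels are driven by
  geometrically decaying averages (hard window k) of per-symbol base
  vectors on the provider channel with the matching timescale (decay 0.55
  for k = 5, 0.88 for k = 15).
* **Noise**: AR(1) with coefficient 0.3, unit marginal variance; per-voxel
  SNR (signal variance / noise variance) 1.0 by default; subjects share
  class structure and base weights, with Gaussian weight jitter (sd 0.2)
  and independent noise. Every stream of randomness descends from one seed
  (bit-reproducible).

## What the generator does and does not emulate

It reproduces the statistical skeleton of a naturalistic listening study —
run structure, word-rate timing, HRF dynamics, autocorrelated noise,
between-subject variability, and planted effects of known class — so that
recovery, calibration and contrast tests have exact ground truth. It does
not emulate linguistic realism (template grammar, uniform vocabularies),
scanner artefacts, motion or physiological noise beyond AR(1), spatial
correlation of the noise, or anatomical variability. Passing tests
demonstrate that the pipeline recovers what it is supposed to recover under
its own model assumptions; they say nothing about tagger/parser quality or
about any particular neural language model's representations.

## Problem sizes and defaults

The standard cohort used by the recovery tests is 20 subjects × 9 runs ×
~300 tokens (≈81 scans per run) × 700 voxels with embedding dimensions 8–20
— sizes at which the full eight-model analysis completes in a few minutes
on one core while leaving every statistical mechanism (nested CV, FDR,
smoothing) fully exercised. The embedding dimensionality of full-scale
studies (d = 768) and larger cohorts are plain configuration changes; the
extraction defaults honour the full-scale protocol (N = 512 sliding
window; k ∈ {5, 15, 45} fixed-context bounds).

## Known limitations

* The toy provider is linear; synergy of *contextual* integral features is
  exercised only through the product dimensions of the lexical integral
  space.
* Per-voxel alpha selection (rather than one alpha per subject) is a
  choice; with very few runs the inner CV estimate of alpha is noisy, and
  the boundary-alpha warning fires when >90% of selections sit at a grid
  endpoint.
* The specificity index is undefined where either ΔR ≤ 0; group maps
  should be read jointly with the FDR masks.
* Real annotated corpora are consumed as given (CoNLL-U + trees + timings);
  the package neither tags nor parses.
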