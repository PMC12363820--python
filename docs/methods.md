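# Methods

## The model

`qaenc` implements question-answering (QA) encoding models: a way to turn
qualitative theories of language selectivity into quantitative, per-target
predictive models of brain responses to narrative speech.

A theory ("some areas respond to language about locations") is recast as a
yes/no question about a piece of text ("Does the input mention a specific
location?").  Given a bank of Q such questions and a word-timed transcript,
an annotator answers every question for the window of text ending at every
word — by default the 10 most recent words.  The result is a binary
windows × questions matrix: an interpretable text embedding in which column
q is theory q's presence over time.

For fMRI, these word-rate columns are low-pass resampled to the scan grid
(Lanczos kernel, cutoff at the output Nyquist frequency), FIR-delayed
copies are appended to absorb the hemodynamic lag, and a ridge regression
is fit per voxel:

    y_v(t) = Σ_{q,d} β_{q,d,v} · x_q(t − d) + ε_v(t)

with the regularization strength chosen per voxel by cross-validation.
Models are evaluated by the Pearson correlation between predicted and
observed held-out responses.  Because each feature is one theory, the
fitted weight β for question q in voxel v is directly readable: a
*selectivity map* of where that theory explains responses.

## Annotators

The annotator contract is a deterministic callable
`(window text, question text) → {0, 1}` with a stable identifier.  Two are
bundled:

- `KeywordAnnotator` — answers from a per-question keyword lexicon.  Fully
  offline and exact on the synthetic corpora; it is the reference
  implementation for tests.
- `CallableAnnotator` — the seam for LLM-backed annotation.  The prompt
  template demands a strict "Yes"/"No"; anything else is an error after
  retries, never silently coerced, so the binary invariant is enforced
  rather than assumed.

Answers are memoized in an append-only cache keyed by a hash of
(annotator id, question text, window text), making annotation idempotent
and resumable.  Several annotators can be combined by majority vote; an
exact tie votes 1 (the answer is present), a fixed and testable rule.
`annotator_faithfulness` scores any annotator against gold labels per
question.

## Cross-validation and standardization

Narrative fMRI responses are strongly autocorrelated, so rows are never
shuffled: the time axis is cut into contiguous chunks (default 20 samples)
and whole chunks are dealt to folds (default 5).  The per-target alpha
maximizes the mean held-out correlation across folds; weights are then
refit on all training rows at that alpha.  The default alpha grid is
log-spaced 10⁰…10⁴ (10 points), the usual encoding-model range.

Design and response columns are z-scored inside the fit using training
statistics only — never at feature-construction time — so no test
statistics leak into the model.  Degenerate correlations (constant
prediction or observation) are reported as a sentinel 0 with a validity
flag, keeping map arithmetic total while marking the invalid targets.

The ridge path is computed by a thin SVD shared across the alpha grid,
which makes the per-target alpha search cheap; it agrees with the
closed-form solution (X'X + αI)⁻¹X'y to machine precision (tested to
1e−8).

## Feature timing defaults

- TR 2 s; FIR delays [1, 2, 3, 4] TRs, spanning the hemodynamic peak at
  2–8 s.  The canonical double-gamma response (peak 5 s, undershoot 15 s at
  1/6 amplitude) places ~96% of its energy in that span at TR 2; the
  residual tail bounds noise-free prediction near r ≈ 0.98 rather than 1,
  which the recovery tests account for.
- Lanczos resampling uses a = 3 lobes.  Kernel weights are normalized to
  sum to 1 per output sample, so constant columns stay constant and a word
  exactly on the grid passes through unchanged.

## Stability selection

To compress a large bank to a compact subset, an L1-regularized regression
of each target on the design is fit on B chunk-respecting subsamples
(complementary contiguous-chunk halves, frac = 0.5, B = 100 by default)
across a relative penalty grid (fractions 0.05…1 of each fit's own
λ_max).  A question's delayed copies count as a single selection unit.
Frequency(q) is the best over-λ fraction of subsamples in which q is
active; per-target frequencies are pooled by their mean over a
user-specified target subset (default: all targets).

Two numerical choices matter:

- A per-fit sparsity cap (`max_active`, default max(target_k, ⌈Q/4⌉)):
  penalties whose fit activates more groups than the cap do not count.
  Without it the smallest penalties select everything and noise columns
  saturate at frequency 1.
- Ties at the target_k boundary break by frequency, then mean |weight|,
  then qid order — a total order, so results are reproducible bit-for-bit
  under a fixed seed.

A caveat documented by the null tests: with a fixed noise-only response, a
regressor that is correlated with that noise by chance is selected
consistently across subsamples, so single-run maximum null frequencies are
occasionally high.  The controlled quantity is the aggregate null level
(mean frequency ≈ 0.2 under the default cap), which is what the suite
asserts.

## Map evaluation

- Masking: `top_fraction_mask` keeps the ⌈fraction·V⌉ best-predicted
  targets (ties to the lower index).
- Reference-map comparison: Pearson correlation across masked targets,
  one value per question.
- Permutation test on the mean correlation: the *reference* map is
  permuted across targets per question (preserving the weight maps'
  spatial statistics), with the add-one rule
  p = (1 + #{null ≥ observed})/(1 + n_perm).  Calibration is verified:
  under a true null the p-values are uniform.
- Multiple testing: Benjamini–Hochberg step-up, inclusive at the
  boundary; verified against a brute-force evaluation of the definition
  and against statsmodels.
- Inter-subject consistency: leave-one-subject-out through a shared
  template space.  Alignment operators (matrices or callables) are
  consumed as inputs — the package never performs registration; identity
  operators serve for synthetic data.  With maps = shared signal + unit
  noise, the expected consistency is 1/√((1+1)(1+1/2)) = 1/√3, which the
  suite checks.
- Condition averages: responses to probe segments tagged to one question
  are averaged after a +2-sample shift (≈4 s at TR 2) for the hemodynamic
  lag; the contrast against the grand mean is compared to the question's
  weight map.  Weight maps are compared raw (not z-scored); a flag on the
  maps records the choice.

## ECoG branch

QA features are built at three contextual timescales — the single word,
1.5 s and 3 s of context — giving 3Q columns (105 for a 35-question bank),
optionally concatenated with spectral columns consumed as input.  One
cross-validated ridge model is fit per lag on word-aligned high-gamma
values (lag grid −2000…+2000 ms in 100 ms steps by default; negative lags
probe prediction before word onset).  High-gamma extraction is upstream
preprocessing and is consumed as input.

Downstream: electrodes are kept when their *minimum* score across compared
models clears a threshold; per-electrode question weights (timescale-
averaged, z-scored per electrode) are Ward-clustered; fMRI vertex maps are
carried to electrode positions by an inverse-distance-weighted average of
the 10 nearest template vertices (a convex combination; a coincident
vertex wins exactly); and per-question fMRI↔ECoG correlations over the
best-predicted electrode fraction are tested by permuting the electrode
assignment of the interpolated values (permutation p on the mean, plus a
paired t-test of observed vs permutation-averaged correlations).

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the pipeline is supposed to recover:

- Themed transcripts: each word slot is a question-specific keyword with
  the per-word probability that yields a requested per-window positive
  rate (default 0.1 per question at 10-gram windows, word rate 2.5 words/s
  — dense enough to identify 35 features, sparse enough that the
  per-slot plant probabilities stay well below 1).  Gold annotations
  follow from the planted word identities, and the keyword annotator
  reproduces them exactly because lexicons are disjoint from filler
  vocabulary.
- Ground truth: a global active question set (default 8 of 35), each of V
  targets loading on a random subset of it with magnitudes bounded away
  from zero.
- fMRI-like responses: downsampled annotations × planted weights,
  convolved with the canonical HRF, plus stationary AR(1) noise
  (coefficient 0.3, a realistic autocorrelation that keeps chunked-CV
  tests meaningful) scaled per target to a requested SNR
  (var(signal)/var(noise)).
- ECoG-like responses: linear signal at exactly one planted lag, matched-
  variance noise elsewhere, with per-electrode SNR optionally graded.

Passing recovery tests on this data shows the pipeline is correct and
well-calibrated under its own assumptions: linear mixing, known HRF shape,
stationary Gaussian AR(1) noise, exact binary annotations.  It does not
show robustness to real-data phenomena — annotator error, vascular and
motion artifacts, non-stationarity, correlated question semantics, or
electrode-contact variability.

## Problem sizes used by the batteries

Chosen once as desk-scale defaults: stability-selection recovery uses a
35-question bank, T = 1000 scans, V = 200 targets with frequencies pooled
over a seed-chosen subset of 25 targets, B = 50 subsamples, SNR 1, 10
seeds.  Attenuation uses T = 2500 scans (500 held out), 10 targets, 20
seeds — enough data that estimation error is small against the √(SNR/(1+SNR))
ceiling being measured.  Calibration uses 200 replicates of 199
permutations; lag/cluster recovery use 900-word corpora, 5 lags, and up to
40 electrodes.

## Known limitations

- The bundled QA-35 bank is a labelled synthetic reconstruction; the
  method is bank-agnostic and real studies should supply their own.
- Stability selection cost grows as B × targets × λ-grid lasso paths;
  pooling over a target subset is the intended use at desk scale.
- `relative_improvement` is a ratio of mean correlations and requires a
  positive baseline mean; restrict to well-predicted targets first.
- The TextGrid reader covers standard long/short interval tiers only.
- Lagged models refit the full ridge path per lag; very fine lag grids are
  linear in cost.
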