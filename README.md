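# qaenc — question-answering encoding models for language neuroscience

`qaenc` turns qualitative theories of language selectivity into
quantitative encoding models of brain responses to narrative speech.  Each
theory is phrased as a yes/no question ("Does the input mention a specific
location?"); an annotator answers every question about the window of text
ending at every word, producing a binary, fully interpretable text
embedding.  Regularized linear models then predict each voxel's (fMRI) or
electrode's (ECoG) response from these features:

    y_v(t) = Σ_{q,d} β_{q,d,v} · x_q(t − d) + ε_v(t)

where `x_q` is question q's answer timecourse resampled to the scan grid
and `d` ranges over FIR delays absorbing the hemodynamic lag.  Because
each feature is a theory, the fitted weight β read per voxel is a
*selectivity map* of where that theory explains responses.  The package is
aimed at researchers fitting voxelwise/electrode-wise encoding models to
naturalistic language data who want models they can read, not only score.

What's inside:

- **corpus / questions** — word-timed transcripts (TSV or TextGrid),
  question banks (JSON/CSV) with stable ordering, answer-correlation
  matrices.  A packaged 35-question compact bank is included (a synthetic
  reconstruction spanning the usual high-level categories).
- **annotation** — n-gram and time-context windowing, a pluggable
  deterministic annotator contract with persistent caching, a bundled
  offline keyword annotator, an LLM adapter seam, ensembling by majority
  vote, and faithfulness scoring against gold labels.
- **features** — Lanczos downsampling of word-rate annotations to the TR
  grid and FIR delay stacking.
- **encoding** — `RidgeEncodingModel(Y, X).fit() → RidgeEncodingResults`:
  per-target ridge with contiguous-chunk CV for the alpha choice,
  held-out Pearson scoring, and `summary()`.
- **stability selection** — compact question subsets by resampled lasso
  with question-level grouping of FIR columns.
- **map evaluation** — best-predicted masking, reference-map correlation,
  permutation tests, Benjamini–Hochberg FDR, leave-one-subject-out
  consistency through user-supplied alignment operators, and
  condition-average comparison for probe stimuli.
- **ecog** — three-timescale QA features (+ spectral), per-lag encoding
  models around word onset, minimum-performance electrode selection, Ward
  clustering of weight profiles, and fMRI↔ECoG map agreement via
  nearest-vertex interpolation.
- **synthetic** — seeded generators for themed corpora, planted sparse
  weights, HRF-convolved AR(1) fMRI responses, and lagged ECoG responses,
  so the whole pipeline runs offline.

See `docs/methods.md` for the model details, defaults and their
rationale.

## Worked example

Generate a synthetic story whose words trigger known questions, simulate
BOLD responses from planted sparse weights at SNR 1, and fit the encoding
model:

```python
import numpy as np
from qaenc import (load_qa35, make_windows, annotate, lanczos_downsample,
                   add_fir_delays, RidgeEncodingModel, FeatureMatrix)
from qaenc.synthetic import (generate_synthetic_corpus, make_ground_truth,
                             simulate_bold_responses)

bank = load_qa35()
corpus = generate_synthetic_corpus(bank, n_words=5000, seed=0)
gt = make_ground_truth(bank, n_targets=50, n_active_questions=8, seed=0)
Y = simulate_bold_responses(gt, corpus.gold, tr=2.0, n_tr=1000, seed=0, snr=1.0)

windows = make_windows(corpus.transcript, mode="ngram", n=10)
A = annotate(windows, bank, corpus.annotator)
X = add_fir_delays(lanczos_downsample(A, tr=2.0, n_tr=1000), [1, 2, 3, 4])

train, test = slice(0, 800), slice(800, 1000)
Xtr = FeatureMatrix(X.values[train], X.labels, X.tr)
Xte = FeatureMatrix(X.values[test], X.labels, X.tr)
results = RidgeEncodingModel(Y[train], Xtr).fit(seed=0)
print(results.summary())
scores = results.score(Xte, Y[test])
print(f"\nmean held-out r: {scores.r.mean():.3f}")
print("planted questions:", sorted(gt.active_qids))
```

Output:

```
Ridge encoding model results
================================
targets:            50
design columns:     140
mean CV r:          0.6257
median CV r:        0.6269
alpha range chosen: [167, 1.29e+03]
top questions by mean |weight| across targets:
  q09      0.0566
  q01      0.0565
  q03      0.0521
  q16      0.0480
  q24      0.0478

mean held-out r: 0.640
planted questions: ['q01', 'q02', 'q03', 'q09', 'q10', 'q16', 'q19', 'q24']
```

The mean held-out correlation of 0.640 sits a little below the
√(SNR/(1+SNR)) = 0.707 noise ceiling for SNR 1, as expected from finite
training data and the FIR approximation to the hemodynamic response — and
the questions with the largest average weights are planted ones, which is
exactly the interpretability the model is built for.  Stability selection
(`qaenc.stability.stability_select`) recovers the full planted set at
`target_k=8`.

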