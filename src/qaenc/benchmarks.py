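"""Self-contained recovery and calibration batteries.

Each function generates its own synthetic data with planted structure, runs
the corresponding piece of the pipeline from scratch, and returns the
measured quantity.  They serve as end-to-end sanity checks of the package:
structural feature counts, oracle agreement of the ridge path, recovery of
planted sparse supports, noise-ceiling attenuation of prediction
correlations, statistical calibration of the permutation/FDR machinery, lag
recovery, cross-modality self-agreement and planted-cluster recovery.

Problem sizes are fixed desk-scale defaults (documented in the methods
note); every function is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from .corpus import load_qa35
from .ecog import (LaggedEncodingModel, build_multiscale_features,
                   cluster_electrode_weights, crossmodal_correlation_test,
                   interpolate_fmri_to_electrodes)
from .encoding import RidgeEncodingModel
from .features import FeatureMatrix, add_fir_delays, lanczos_downsample
from .maps import (bh_fdr, make_map_permutation_null,
                   observed_map_correlations, permutation_pvalue_mean)
from .stability import stability_select
from .synthetic import (generate_synthetic_corpus, generate_template_geometry,
                        make_electrode_profiles, make_ground_truth,
                        simulate_bold_responses, simulate_ecog_responses)

__all__ = [
    "multiscale_qa_column_count",
    "ridge_oracle_max_rel_error",
    "stability_recovery_battery",
    "encoding_recovery_battery",
    "permutation_calibration_ks",
    "bh_fdr_brute_force_agreement",
    "lag_recovery",
    "crossmodal_self_agreement",
    "cluster_recovery_ari",
]


def multiscale_qa_column_count(seed: int = 0, n_words: int = 300) -> int:
    """QA columns produced by the three-timescale ECoG feature builder for
    the packaged 35-question bank (expected: 105)."""
    bank = load_qa35()
    corpus = generate_synthetic_corpus(bank, n_words=n_words, seed=seed)
    feat = build_multiscale_features(corpus.transcript, bank, corpus.annotator)
    return len(feat.qa_columns)


def ridge_oracle_max_rel_error(n_instances: int = 20, seed: int = 0) -> float:
    """Worst relative error of fitted ridge weights against the closed-form
    solution (X'X + aI)^-1 X'y across random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        T = int(rng.integers(25, 51))
        F = int(rng.integers(3, 11))
        X = rng.standard_normal((T, F))
        Y = rng.standard_normal((T, 3))
        res = RidgeEncodingModel(Y, X, alphas=[0.1, 1.0, 10.0],
                                 chunk_len=5).fit()
        xm, xs = X.mean(0), X.std(0)
        ym, ys = Y.mean(0), Y.std(0)
        Xz, Yz = (X - xm) / xs, (Y - ym) / ys
        for v in range(Y.shape[1]):
            a = res.alpha_per_target[v]
            w = np.linalg.solve(Xz.T @ Xz + a * np.eye(F), Xz.T @ Yz[:, v])
            rel = np.abs(res.weights[:, v] - w).max() / max(np.abs(w).max(),
                                                            1e-300)
            worst = max(worst, float(rel))
    return worst


def _bold_design(seed: int, n_words: int, n_tr: int, n_targets: int,
                 snr: float, tr: float = 2.0):
    bank = load_qa35()
    corpus = generate_synthetic_corpus(bank, n_words=n_words, seed=seed)
    gt = make_ground_truth(bank, n_targets=n_targets, seed=seed)
    Y = simulate_bold_responses(gt, corpus.gold, tr=tr, n_tr=n_tr, seed=seed,
                                snr=snr)
    X = add_fir_delays(lanczos_downsample(corpus.gold, tr, n_tr))
    return gt, X, Y


def stability_recovery_battery(n_seeds: int = 10, B: int = 50,
                               snr: float = 1.0, n_targets: int = 200,
                               n_tr: int = 1000, pool_targets: int = 25,
                               seed: int = 0) -> float:
    """Mean fraction of planted active questions recovered by stability
    selection at target_k = planted support size, across seeds.

    Selection frequencies are pooled over a seed-chosen subset of targets.
    """
    recoveries = []
    for s in range(n_seeds):
        run_seed = (seed * 1009 + s) % (2**31)
        gt, X, Y = _bold_design(run_seed, n_words=5 * n_tr, n_tr=n_tr,
                                n_targets=n_targets, snr=snr)
        rng = np.random.default_rng(run_seed + 1)
        targets = rng.choice(Y.shape[1], size=min(pool_targets, Y.shape[1]),
                             replace=False)
        k = len(gt.active_qids)
        sel = stability_select(X, Y, B=B, target_k=k, seed=run_seed,
                               targets=targets)
        rec = len(set(sel.selected_qids) & set(gt.active_qids)) / k
        recoveries.append(rec)
    return float(np.mean(recoveries))


def encoding_recovery_battery(n_seeds: int = 20, snr: float = 1.0,
                              n_tr: int = 2500, n_targets: int = 10,
                              test_tr: int = 500, seed: int = 0) -> dict:
    """Noise-ceiling behaviour of the full fMRI pipeline.

    Returns the minimum per-target held-out correlation of one noise-free
    run (expected near 1) and the mean held-out correlation across seeds at
    the requested SNR (expected near sqrt(snr/(1+snr)) for additive noise).
    """
    def run(run_seed: int, run_snr: float) -> np.ndarray:
        _, X, Y = _bold_design(run_seed, n_words=5 * n_tr, n_tr=n_tr,
                               n_targets=n_targets, snr=run_snr)
        T = X.shape[0]
        cut = T - test_tr
        Xtr = FeatureMatrix(X.values[:cut], X.labels, X.tr)
        Xte = FeatureMatrix(X.values[cut:], X.labels, X.tr)
        res = RidgeEncodingModel(Y[:cut], Xtr).fit(0)
        return res.score(Xte, Y[cut:]).r

    zero_noise_r = run((seed * 7919 + 104729) % (2**31), np.inf)
    means = [run((seed * 7919 + s) % (2**31), snr).mean()
             for s in range(n_seeds)]
    return {
        "zero_noise_min_r": float(zero_noise_r.min()),
        "mean_r": float(np.mean(means)),
        "expected_attenuation": float(np.sqrt(snr / (1.0 + snr))),
    }


def permutation_calibration_ks(n_replicates: int = 200, n_perm: int = 199,
                               n_questions: int = 8, n_targets: int = 150,
                               seed: int = 0) -> float:
    """KS-test p-value for uniformity of permutation p-values under a true
    null (weight and reference maps independent)."""
    rng = np.random.default_rng(seed)
    ps = []
    for rep in range(n_replicates):
        W = rng.standard_normal((n_questions, n_targets))
        R = rng.standard_normal((n_questions, n_targets))
        obs = observed_map_correlations(W, R)
        ps.append(permutation_pvalue_mean(
            obs, make_map_permutation_null(W, R), n_perm=n_perm,
            seed=(seed * 31 + rep) % (2**31)))
    return float(kstest(ps, "uniform").pvalue)


def bh_fdr_brute_force_agreement(n_vectors: int = 1000, q: float = 0.05,
                                 seed: int = 0) -> float:
    """Fraction of random p-vectors on which the FDR routine matches a
    literal evaluation of the step-up definition (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 40)))
        m = len(p)
        order = np.argsort(p, kind="stable")
        k = 0
        for i in range(1, m + 1):
            if p[order[i - 1]] <= i * q / m:
                k = i
        brute = np.sort(order[:k])
        agree += int(np.array_equal(bh_fdr(p, q), brute))
    return agree / n_vectors


def _ecog_setup(seed: int, n_words: int = 900, E: int = 12,
                n_profiles: int = 2, snr: float = 3.0,
                lags=tuple(range(-400, 401, 200)), planted_lag: int = 200):
    bank = load_qa35()
    corpus = generate_synthetic_corpus(bank, n_words=n_words, seed=seed,
                                       window_positive_rate=0.15)
    feat = build_multiscale_features(corpus.transcript, bank, corpus.annotator)
    Q = len(bank)
    Wq, groups = make_electrode_profiles(E, n_profiles, Q, seed=seed)
    W = np.zeros((feat.shape[1], E))
    for ts in range(3):
        W[ts * Q:(ts + 1) * Q, :] = Wq / 3.0
    resp = simulate_ecog_responses(W, feat, list(lags), planted_lag, snr=snr,
                                   seed=seed + 1)
    return feat, resp, list(lags), groups


def lag_recovery(seed: int = 0, planted_lag: int = 200) -> dict:
    """Fit per-lag models to responses whose signal lives at one lag and
    report the lag at which the score profile peaks."""
    feat, resp, lags, _ = _ecog_setup(seed, planted_lag=planted_lag)
    res = LaggedEncodingModel(resp, feat, lags).fit(seed=0)
    return {"planted_lag_ms": planted_lag, "recovered_lag_ms": res.best_lag()}


def crossmodal_self_agreement(seed: int = 0, n_vertices: int = 300,
                              n_electrodes: int = 40, n_questions: int = 8,
                              n_perm: int = 499) -> dict:
    """Self-agreement control: with ECoG weights set equal to the
    interpolated fMRI weights, every per-question correlation must be 1 and
    the permutation test must return its floor p."""
    rng = np.random.default_rng(seed)
    vc, ec = generate_template_geometry(n_vertices, n_electrodes, seed=seed)
    fmri = rng.standard_normal((n_questions, n_vertices))
    interp = np.stack([
        interpolate_fmri_to_electrodes(fmri[q], vc, ec, 10)
        for q in range(n_questions)
    ])
    scores = rng.uniform(0.1, 0.9, n_electrodes)
    res = crossmodal_correlation_test(fmri, vc, interp, ec, scores,
                                      fraction=1.0, n_perm=n_perm, seed=seed)
    return {
        "min_r": float(res.r.min()),
        "p": res.p_permutation,
        "floor_p": 1.0 / (1 + n_perm),
    }


def cluster_recovery_ari(seed: int = 0, k: int = 5, n_electrodes: int = 40,
                         ) -> float:
    """Adjusted Rand index of Ward clustering against planted electrode
    profile groups, after a full lagged-model fit (expected: 1.0)."""
    feat, resp, lags, groups = _ecog_setup(seed, E=n_electrodes,
                                           n_profiles=k, snr=6.0)
    res = LaggedEncodingModel(resp, feat, lags).fit(seed=0)
    qw, _ = res.question_weights_at(res.best_lag())
    labels = cluster_electrode_weights(qw, k)
    return float(adjusted_rand_score(groups, labels))
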