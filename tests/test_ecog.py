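import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from qaenc.annotate import make_windows, annotate
from qaenc.ecog import (LaggedEncodingModel, build_multiscale_features,
                        cluster_electrode_weights, crossmodal_correlation_test,
                        interpolate_fmri_to_electrodes,
                        select_electrodes_min_performance,
                        validate_electrode_table)
from qaenc.encoding import ScoreVector
from qaenc.synthetic import (generate_synthetic_corpus,
                             generate_template_geometry,
                             make_electrode_profiles, simulate_ecog_responses)

LAGS = list(range(-400, 401, 200))


@pytest.fixture(scope="module")
def ecog_setup(qa35):
    corpus = generate_synthetic_corpus(qa35, n_words=900, seed=2,
                                       window_positive_rate=0.15)
    feat = build_multiscale_features(corpus.transcript, qa35, corpus.annotator)
    return corpus, feat


class TestMultiscaleFeatures:
    def test_qa_block_is_three_per_question(self, ecog_setup, qa35):
        _, feat = ecog_setup
        assert len(feat.qa_columns) == 3 * len(qa35) == 105

    @pytest.mark.parametrize("q", [1, 4])
    def test_small_bank_column_count(self, q, small_bank, small_corpus):
        from qaenc.corpus import QuestionBank

        bank = QuestionBank(small_bank.questions[:q])
        feat = build_multiscale_features(small_corpus.transcript, bank,
                                         small_corpus.annotator)
        assert feat.shape[1] == 3 * q

    def test_word_level_equals_unigram_annotation(self, ecog_setup, qa35):
        corpus, feat = ecog_setup
        A1 = annotate(make_windows(corpus.transcript, "ngram", n=1), qa35,
                      corpus.annotator)
        word_cols = [j for j, lab in enumerate(feat.labels) if lab[1] == "word"]
        assert np.array_equal(feat.values[:, word_cols], A1.values)

    def test_spectral_block_appended_unchanged(self, ecog_setup, qa35, rng):
        corpus, _ = ecog_setup
        S = rng.standard_normal((len(corpus.transcript), 5))
        feat = build_multiscale_features(corpus.transcript, qa35,
                                         corpus.annotator, spectral=S)
        assert feat.shape[1] == 105 + 5
        assert np.allclose(feat.values[:, -5:], S)

    def test_mismatched_spectral_rows_rejected(self, ecog_setup, qa35, rng):
        corpus, _ = ecog_setup
        with pytest.raises(ValueError, match="rows"):
            build_multiscale_features(corpus.transcript, qa35,
                                      corpus.annotator,
                                      spectral=rng.standard_normal((3, 2)))


def _planted_lag_fit(feat, qa_q, seed=4, snr=3.0, E=10, lags=LAGS,
                     planted_lag=200):
    Wq, groups = make_electrode_profiles(E, 2, qa_q, seed=seed)
    W = np.zeros((feat.shape[1], E))
    for ts in range(3):
        W[ts * qa_q : (ts + 1) * qa_q, :] = Wq / 3.0
    resp = simulate_ecog_responses(W, feat, lags, planted_lag, snr=snr,
                                   seed=seed)
    res = LaggedEncodingModel(resp, feat, lags).fit(seed=0)
    return res, groups


class TestLaggedModels:
    def test_score_peaks_at_planted_lag(self, ecog_setup):
        _, feat = ecog_setup
        res, _ = _planted_lag_fit(feat, 35)
        assert res.best_lag() == 200
        li = res.lags.index(200)
        others = np.delete(res.scores.mean(axis=1), li)
        assert res.scores[li].mean() > others.max() + 0.2

    def test_pure_noise_flat_near_zero(self, ecog_setup, rng):
        _, feat = ecog_setup
        resp = rng.standard_normal((feat.shape[0], len(LAGS), 6))
        res = LaggedEncodingModel(resp, feat, LAGS).fit(seed=0)
        assert np.abs(res.scores.mean(axis=1)).max() < 0.12

    def test_affine_response_rescaling_invariance(self, ecog_setup):
        _, feat = ecog_setup
        Wq, _ = make_electrode_profiles(5, 2, 35, seed=9)
        W = np.zeros((feat.shape[1], 5))
        W[:35] = Wq
        resp = simulate_ecog_responses(W, feat, LAGS, 0, snr=2.0, seed=9)
        scale = np.array([0.5, 2.0, 10.0, 1.0, 3.0])
        shifted = resp * scale[None, None, :] + 7.0
        r1 = LaggedEncodingModel(resp, feat, LAGS).fit(0).scores
        r2 = LaggedEncodingModel(shifted, feat, LAGS).fit(0).scores
        assert np.allclose(r1, r2, atol=1e-10)

    def test_lag_grid_must_match_response(self, ecog_setup, rng):
        _, feat = ecog_setup
        resp = rng.standard_normal((feat.shape[0], 3, 4))
        with pytest.raises(ValueError, match="lags"):
            LaggedEncodingModel(resp, feat, LAGS)


class TestElectrodeSelection:
    def test_minimum_across_models_rule(self):
        scores = {
            "qa": np.array([0.3, 0.1, 0.25]),
            "spectral": np.array([0.2, 0.4, 0.25]),
            "llm": np.array([0.25, 0.3, 0.15]),
        }
        assert select_electrodes_min_performance(scores, 0.2).tolist() == [0]
        assert select_electrodes_min_performance(scores, -1.0).tolist() == [0, 1, 2]

    def test_table_rows_returned(self):
        table = pd.DataFrame({
            "electrode_id": ["e1", "e2"], "subject_id": ["s", "s"],
            "x": [0.0, 1.0], "y": [0.0, 1.0], "z": [0.0, 1.0],
        })
        scores = {"m": ScoreVector(np.array([0.5, 0.1]), n_test=10)}
        kept = select_electrodes_min_performance(scores, 0.3, table=table)
        assert kept["electrode_id"].tolist() == ["e1"]

    def test_misaligned_scores_rejected(self):
        with pytest.raises(ValueError, match="different"):
            select_electrodes_min_performance(
                {"a": np.ones(3), "b": np.ones(4)}, 0.1)

    def test_duplicate_electrode_ids_rejected(self):
        table = pd.DataFrame({
            "electrode_id": ["e1", "e1"], "subject_id": ["s", "s"],
            "x": [0.0, 1.0], "y": [0.0, 1.0], "z": [0.0, 1.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            validate_electrode_table(table)


class TestClustering:
    @pytest.mark.parametrize("k", [2, 5])
    def test_planted_profiles_recovered(self, k, rng):
        W, groups = make_electrode_profiles(40, k, 20, within_noise=0.05,
                                            seed=k)
        labels = cluster_electrode_weights(W.T, k)
        assert adjusted_rand_score(groups, labels) == 1.0

    def test_identical_vectors_deterministic(self):
        W = np.ones((6, 8))
        a = cluster_electrode_weights(W, 2)
        b = cluster_electrode_weights(W, 2)
        assert np.array_equal(a, b)
        assert set(a) <= {0, 1}

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError, match="clusters"):
            cluster_electrode_weights(rng.standard_normal((3, 4)), 5)

    def test_end_to_end_cluster_recovery_through_fit(self, ecog_setup):
        _, feat = ecog_setup
        res, groups = _planted_lag_fit(feat, 35, seed=11, snr=5.0, E=14)
        qw, _ = res.question_weights_at(res.best_lag())
        labels = cluster_electrode_weights(qw, 2)
        assert adjusted_rand_score(groups, labels) == 1.0


class TestInterpolation:
    def test_coincident_electrode_takes_vertex_value(self):
        vc = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0]], float)
        v = np.array([5.0, 7.0, 9.0])
        out = interpolate_fmri_to_electrodes(v, vc, np.array([[2.0, 0, 0]]), 2)
        assert out[0] == pytest.approx(7.0)

    def test_equidistant_pair_averages(self):
        vc = np.array([[0, 0, 0], [2, 0, 0]], float)
        out = interpolate_fmri_to_electrodes(np.array([0.0, 1.0]), vc,
                                             np.array([[1.0, 0, 0]]), 2)
        assert out[0] == pytest.approx(0.5)

    def test_constant_map_stays_constant(self, rng):
        vc, ec = generate_template_geometry(50, 8, seed=1)
        out = interpolate_fmri_to_electrodes(np.full(50, 3.3), vc, ec, 10)
        assert np.allclose(out, 3.3)

    def test_convex_combination_bounds(self, rng):
        vc, ec = generate_template_geometry(60, 15, seed=2)
        v = rng.standard_normal(60)
        out = interpolate_fmri_to_electrodes(v, vc, ec, 10)
        assert out.min() >= v.min() - 1e-12 and out.max() <= v.max() + 1e-12

    def test_fewer_vertices_than_neighbors_warns(self, rng):
        vc, ec = generate_template_geometry(4, 2, seed=3)
        with pytest.warns(UserWarning, match="vertices"):
            interpolate_fmri_to_electrodes(rng.standard_normal(4), vc, ec, 10)


class TestCrossModal:
    def _setup(self, rng, Q=8, Vv=300, E=40):
        vc, ec = generate_template_geometry(Vv, E, seed=6)
        fmri = rng.standard_normal((Q, Vv))
        interp = np.stack([
            interpolate_fmri_to_electrodes(fmri[q], vc, ec, 10)
            for q in range(Q)
        ])
        return vc, ec, fmri, interp

    def test_self_agreement_unit_r_and_floor_p(self, rng):
        vc, ec, fmri, interp = self._setup(rng)
        scores = rng.uniform(0.1, 0.9, 40)
        res = crossmodal_correlation_test(fmri, vc, interp, ec, scores,
                                          fraction=1.0, n_perm=499, seed=0)
        assert np.allclose(res.r, 1.0)
        assert res.p_permutation == pytest.approx(1 / 500)

    def test_independent_maps_non_significant(self, rng):
        vc, ec, fmri, _ = self._setup(rng)
        ecog = rng.standard_normal((8, 40))
        res = crossmodal_correlation_test(fmri, vc, ecog, ec,
                                          rng.uniform(0, 1, 40),
                                          fraction=1.0, n_perm=300, seed=1)
        assert abs(res.r.mean()) < 0.2
        assert res.p_permutation > 0.05

    def test_agreement_improves_with_best_electrode_fraction(self, rng):
        # electrode noise graded by prediction score: restricting to the
        # best-predicted fraction must raise the mean correlation
        vc, ec, fmri, interp = self._setup(rng, Q=10, E=60)
        noise_sd = np.linspace(0.2, 3.0, 60)
        scores = 1.0 / (1.0 + noise_sd)  # best electrodes = least noise
        ecog = interp + noise_sd[None, :] * rng.standard_normal((10, 60))
        r_full = crossmodal_correlation_test(fmri, vc, ecog, ec, scores,
                                             fraction=1.0, n_perm=199,
                                             seed=2).r.mean()
        r_best = crossmodal_correlation_test(fmri, vc, ecog, ec, scores,
                                             fraction=0.25, n_perm=199,
                                             seed=2).r.mean()
        assert r_best > r_full

    def test_too_few_electrodes_after_mask_rejected(self, rng):
        vc, ec, fmri, interp = self._setup(rng, E=4)
        with pytest.raises(ValueError, match="3"):
            crossmodal_correlation_test(fmri, vc, interp[:, :4], ec,
                                        np.ones(4), fraction=0.25)
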