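import numpy as np
import pytest

from qaenc.encoding import ScoreVector
from qaenc.maps import (bh_fdr, condition_average_response,
                        intersubject_consistency, make_map_permutation_null,
                        map_correlation, observed_map_correlations,
                        permutation_pvalue_mean, top_fraction_mask)


class TestTopFractionMask:
    def test_fraction_counts(self, rng):
        s = rng.standard_normal(100)
        assert len(top_fraction_mask(s, 0.1)) == 10
        assert len(top_fraction_mask(s, 1.0)) == 100

    def test_tie_straddling_cutoff_prefers_lower_index(self):
        s = np.array([0.5, 0.9, 0.5, 0.5])
        mask = top_fraction_mask(s, 0.5)  # k=2: the 0.9 plus first 0.5
        assert mask.tolist() == [0, 1]

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_mask(np.ones(5), 0.0)


class TestMapCorrelation:
    def test_self_correlation_and_linear_map(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert map_correlation(a, a) == pytest.approx(1.0)
        assert map_correlation(a, 2 * a) == pytest.approx(1.0)

    def test_shuffled_null_mean_near_zero(self, rng):
        a = rng.standard_normal(1000)
        rs = [map_correlation(a, rng.permutation(a)) for _ in range(50)]
        assert abs(np.mean(rs)) < 0.02

    def test_full_mask_equals_no_mask(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert map_correlation(a, b, np.arange(50)) == pytest.approx(
            map_correlation(a, b))

    def test_constant_masked_vector_sentinel(self):
        with pytest.warns(UserWarning, match="constant"):
            assert map_correlation(np.ones(5), np.arange(5.0)) == 0.0

    def test_short_mask_rejected(self):
        with pytest.raises(ValueError, match="3"):
            map_correlation(np.ones(2), np.ones(2))


class TestPermutationPvalue:
    def test_observed_above_all_nulls_hits_floor(self, rng):
        obs = np.full(5, 0.9)
        p = permutation_pvalue_mean(obs, lambda r: r.normal(0, 0.01, 5),
                                    n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_observed_below_all_nulls_is_one(self, rng):
        obs = np.full(5, -0.9)
        p = permutation_pvalue_mean(obs, lambda r: r.normal(0, 0.01, 5),
                                    n_perm=200, seed=0)
        assert p == 1.0

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue_mean(np.array([]), lambda r: r.normal(size=3))

    def test_permutes_reference_not_weights(self, rng):
        W = rng.standard_normal((3, 40))
        R = rng.standard_normal((3, 40))
        draw = make_map_permutation_null(W, R)
        Wc = W.copy()
        draw(np.random.default_rng(0))
        assert np.array_equal(W, Wc)  # weight maps untouched


class TestBhFdr:
    def test_step_up_hand_case(self):
        rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert rej.tolist() == [0, 1, 2]

    def test_all_ones_rejects_none(self):
        assert bh_fdr(np.ones(6), 0.05).size == 0

    def test_boundary_is_inclusive(self):
        assert bh_fdr(np.array([0.05]), 0.05).tolist() == [0]

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]), 0.05)

    def test_matches_brute_force_step_up_oracle(self, rng):
        def brute(p, q):
            m = len(p)
            order = np.argsort(p, kind="stable")
            k = 0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i * q / m:
                    k = i
            return np.sort(order[:k])

        for _ in range(300):
            p = rng.random(int(rng.integers(1, 30)))
            assert np.array_equal(bh_fdr(p, 0.05), brute(p, 0.05))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(20)
            mine = np.zeros(20, bool)
            mine[bh_fdr(p, 0.1)] = True
            ref = multipletests(p, 0.1, method="fdr_bh")[0]
            assert np.array_equal(mine, ref)


class TestIntersubjectConsistency:
    def test_identical_maps_give_unit_correlation(self, rng):
        m = {f"q{i}": rng.standard_normal(80) for i in range(3)}
        df = intersubject_consistency({"s1": m, "s2": m, "s3": m})
        assert np.allclose(df["r"], 1.0)
        assert len(df) == 9

    def test_independent_maps_near_zero(self, rng):
        subs = {s: {"q": rng.standard_normal(2000)} for s in "abc"}
        df = intersubject_consistency(subs)
        assert abs(df["r"].mean()) < 0.1

    def test_shared_signal_attenuation_closed_form(self, rng):
        # maps = shared + unit noise (SNR 1); averaging two others halves
        # their noise: r = 1/sqrt((1+1)(1+1/2)) = 1/sqrt(3)
        V = 4000
        shared = rng.standard_normal(V)
        subs = {s: {"q": shared + rng.standard_normal(V)} for s in "abc"}
        df = intersubject_consistency(subs)
        assert df["r"].mean() == pytest.approx(1 / np.sqrt(3), abs=0.04)

    def test_alignment_operators_applied(self, rng):
        # flip operator: consistency through the template still works when
        # both directions are supplied
        flip = np.eye(30)[::-1]
        base = rng.standard_normal(30)
        maps = {"s1": {"q": base}, "s2": {"q": base[::-1]}, "s3": {"q": base[::-1]}}
        df = intersubject_consistency(
            maps,
            to_template={"s2": flip, "s3": flip},
            from_template={},
        )
        r_s1 = df.loc[df.subject == "s1", "r"].iloc[0]
        assert r_s1 == pytest.approx(1.0)

    def test_missing_qid_skipped_with_warning(self, rng):
        maps = {"s1": {"q1": rng.standard_normal(10), "q2": rng.standard_normal(10)},
                "s2": {"q1": rng.standard_normal(10)}}
        with pytest.warns(UserWarning, match="q2"):
            df = intersubject_consistency(maps)
        # q2 has no partner subject, so it is dropped from the output
        assert set(df.qid) == {"q1"}

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            intersubject_consistency({"s1": {}})


class TestConditionAverages:
    def test_constant_response_passthrough(self):
        Y = np.full((20, 3), 2.5)
        out = condition_average_response(Y, [("q1", 2, 6), ("q2", 8, 12)])
        assert all(np.allclose(c.mean_response, 2.5) for c in out)

    def test_hand_mean_without_lag(self):
        Y = np.arange(12.0).reshape(6, 2)
        out = condition_average_response(Y, [("q", 2, 4)], offset=0)
        assert np.allclose(out[0].mean_response, Y[2:4].mean(axis=0))

    def test_hemodynamic_offset_shifts_rows(self):
        Y = np.zeros((10, 1))
        Y[5:7] = 1.0  # response lags the stimulus by 2 samples
        out = condition_average_response(Y, [("q", 3, 5)], offset=2)
        assert out[0].mean_response[0] == pytest.approx(1.0)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            condition_average_response(np.zeros((5, 1)), [("q", 3, 3)])

    def test_planted_contrast_recovers_weights(self, rng):
        # each question's segments add +1 to its planted voxels (with the
        # +2-sample lag); the condition contrast should match the planted map
        T, V, Q = 120, 40, 4
        planted = (rng.random((Q, V)) < 0.25).astype(float)
        Y = 0.3 * rng.standard_normal((T, V))
        segments = []
        for q in range(Q):
            for s in range(3):
                start = q * 30 + s * 10
                segments.append((f"q{q}", start, start + 6))
                Y[start + 2 : start + 8] += planted[q]
        out = condition_average_response(Y, segments, offset=2)
        for q, cond in enumerate(sorted(out, key=lambda c: c.qid)):
            grand = Y.mean(axis=0)
            r = np.corrcoef(cond.mean_response - grand, planted[q])[0, 1]
            assert r > 0.9

    def test_masking_to_predictive_targets_raises_agreement(self, rng):
        # targets split into signal-carrying and noise-only; restricting the
        # map comparison to the best-predicted targets must improve the mean
        # condition-average correlation, mirroring masked-map evaluation
        T, V, Q = 160, 60, 3
        planted = np.zeros((Q, V))
        planted[:, :30] = rng.uniform(0.5, 1.5, (Q, 30)) * \
            (rng.random((Q, 30)) < 0.5)
        Y = 1.0 * rng.standard_normal((T, V))
        segments = []
        for q in range(Q):
            for s in range(4):
                start = q * 50 + s * 12
                segments.append((f"q{q}", start, start + 8))
                Y[start + 2 : start + 10, :] += planted[q]
        score = ScoreVector(np.r_[np.full(30, 0.8) + 0.01 * rng.random(30),
                                  0.01 * rng.random(30)], n_test=T)
        mask = top_fraction_mask(score, 0.5)
        conds = {c.qid: c.mean_response - Y.mean(axis=0)
                 for c in condition_average_response(Y, segments, offset=2)}
        W = np.stack([planted[q] for q in range(Q)])
        R = np.stack([conds[f"q{q}"] for q in range(Q)])
        masked = observed_map_correlations(W, R, mask).mean()
        unmasked = observed_map_correlations(W, R).mean()
        assert masked > unmasked
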