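"""Unit and property tests for the per-gene scores and the fudge factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from halfsam import (LabeledExpressionMatrix, estimate_fudge_factor,
                     fudge_factor_for, half_sam_scores, half_t_scores,
                     sam_scores, student_t_scores, summarize_groups)
from halfsam.data import InvalidDesignError


def summarize(values, labels):
    return summarize_groups(LabeledExpressionMatrix(values=values, labels=labels))


class TestGroupSummary:
    def test_constant_gene(self):
        s = summarize([[5.0] * 6], [1, 1, 1, 0, 0, 0])
        assert s.mean1[0] == 5 and s.mean0[0] == 5
        assert s.sd1[0] == s.sd0[0] == s.sp[0] == 0

    def test_hand_example(self, hand_matrix):
        s = summarize_groups(hand_matrix)
        assert s.mean1[0] == pytest.approx(3.0)
        assert s.mean0[0] == pytest.approx(1.0)
        expected_sd = np.sqrt(4.0 / 3.0)
        for val in (s.sd1[0], s.sd0[0], s.sp[0]):
            assert val == pytest.approx(expected_sd, abs=1e-14)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidDesignError):
            LabeledExpressionMatrix(values=[[1.0, 2.0, 3.0]], labels=[1, 0, 0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(hnp.arrays(float, (7, 9),
                      elements=st.floats(-1e4, 1e4, allow_nan=False)))
    def test_pooled_sd_reconstruction_identity(self, values):
        s = summarize(values, [1, 1, 1, 1, 0, 0, 0, 0, 0])
        lhs = s.sp**2 * (s.n1 + s.n0 - 2)
        rhs = (s.n1 - 1) * s.sd1**2 + (s.n0 - 1) * s.sd0**2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-8)


class TestScores:
    def test_student_t_hand_example(self, hand_matrix):
        sv = student_t_scores(summarize_groups(hand_matrix))
        assert sv.scores[0] == pytest.approx(np.sqrt(6.0))
        assert sv.df == 6

    def test_half_t_hand_example(self, hand_matrix):
        sv = half_t_scores(summarize_groups(hand_matrix))
        assert sv.scores[0] == pytest.approx(np.sqrt(6.0))
        assert sv.df == 3

    def test_sam_hand_example_with_unit_fudge(self, hand_matrix):
        s = summarize_groups(hand_matrix)
        expected = 2.0 / (np.sqrt(2.0 / 3.0) + 1.0)
        assert sam_scores(s, 1.0).scores[0] == pytest.approx(expected)
        assert half_sam_scores(s, 1.0).scores[0] == pytest.approx(expected)

    def test_equal_means_give_zero_scores(self):
        s = summarize([[1.0, 3.0, 1.0, 3.0, 2.0, 0.0, 2.0, 4.0]],
                      [1, 1, 1, 1, 0, 0, 0, 0])
        assert student_t_scores(s).scores[0] == 0
        assert half_t_scores(s).scores[0] == 0
        assert sam_scores(s, 2.0).scores[0] == 0
        assert half_sam_scores(s, 2.0).scores[0] == 0

    def test_zero_denominator_flagged_not_raised(self):
        s = summarize([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]], [1, 1, 1, 0, 0, 0])
        for sv in (student_t_scores(s), half_t_scores(s),
                   sam_scores(s, 0.0), half_sam_scores(s, 0.0)):
            assert sv.undefined[0]
            assert np.isnan(sv.scores[0])

    def test_zero_fudge_reduces_to_t_statistics(self, random_matrix):
        s = summarize_groups(random_matrix)
        np.testing.assert_array_equal(sam_scores(s, 0.0).scores,
                                      student_t_scores(s).scores)
        np.testing.assert_array_equal(half_sam_scores(s, 0.0).scores,
                                      half_t_scores(s).scores)

    def test_homogeneous_sds_collapse_half_variants(self):
        # mirrored case/control values force s1 == s0 exactly
        rng = np.random.default_rng(3)
        ctrl = rng.normal(0, 1, (30, 4))
        case = ctrl + rng.normal(0, 1, (30, 1))  # same spread, shifted mean
        s = summarize(np.hstack([case, ctrl]), [1] * 4 + [0] * 4)
        np.testing.assert_allclose(s.sd1, s.sd0, rtol=1e-12)
        np.testing.assert_allclose(half_t_scores(s).scores,
                                   student_t_scores(s).scores, rtol=1e-12)
        np.testing.assert_allclose(half_sam_scores(s, 0.7).scores,
                                   sam_scores(s, 0.7).scores, rtol=1e-12)

    def test_student_t_matches_scipy_on_random_genes(self):
        rng = np.random.default_rng(11)
        values = rng.normal(10.0, 3.0, (100, 13))
        labels = np.array([1] * 6 + [0] * 7)
        sv = student_t_scores(summarize(values, labels))
        ref = sps.ttest_ind(values[:, labels == 1], values[:, labels == 0],
                            axis=1, equal_var=True).statistic
        np.testing.assert_allclose(sv.scores, ref, rtol=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("method", ["sam", "half_sam"])
    def test_scale_equivariance_with_reestimated_c0(self, random_matrix, method):
        from halfsam import sam_scores as ss, half_sam_scores as hss

        score_fn = ss if method == "sam" else hss
        k = 3.7
        scaled = LabeledExpressionMatrix(values=random_matrix.values * k,
                                         gene_ids=random_matrix.gene_ids,
                                         labels=random_matrix.labels)
        s1 = summarize_groups(random_matrix)
        s2 = summarize_groups(scaled)
        f1 = fudge_factor_for(s1, method)
        f2 = fudge_factor_for(s2, method)
        assert f2.percentile == f1.percentile
        assert f2.c0 == pytest.approx(k * f1.c0, rel=1e-12)
        np.testing.assert_allclose(score_fn(s2, f2).scores,
                                   score_fn(s1, f1).scores, atol=1e-10)

    def test_location_invariance_all_four(self, random_matrix):
        shifted = LabeledExpressionMatrix(values=random_matrix.values + 123.0,
                                          gene_ids=random_matrix.gene_ids,
                                          labels=random_matrix.labels)
        a, b = summarize_groups(random_matrix), summarize_groups(shifted)
        for fn in (student_t_scores, half_t_scores):
            np.testing.assert_allclose(fn(b).scores, fn(a).scores, atol=1e-9)
        for fn in (sam_scores, half_sam_scores):
            np.testing.assert_allclose(fn(b, 0.5).scores, fn(a, 0.5).scores,
                                       atol=1e-9)


class TestFudgeFactor:
    def test_degenerate_identical_scatters_tie_break_low(self):
        rng = np.random.default_rng(0)
        f = estimate_fudge_factor(rng.normal(size=50), np.full(50, 2.0))
        assert f.percentile == 0.0
        assert f.c0 == pytest.approx(2.0)
        assert np.allclose(f.cv_profile, f.cv_profile[0])

    def test_matches_brute_force_grid_oracle(self):
        rng = np.random.default_rng(5)
        scatters = np.exp(rng.normal(0.0, 1.0, 500))
        numerators = rng.normal(0.0, 1.0, 500) * (scatters + 0.5)

        # independent plain-loop evaluation of the criterion over the grid
        def oracle():
            grid = list(range(0, 101, 5))
            order = sorted(range(500), key=lambda i: (scatters[i], i))
            wins = [order[i * 5:(i + 1) * 5] for i in range(100)]
            best_p, best_cv = None, None
            for p in grid:
                cand = np.percentile(scatters, p)
                mads = []
                for w in wins:
                    d = [numerators[i] / (scatters[i] + cand) for i in w]
                    med = sorted(d)[len(d) // 2] if len(d) % 2 else \
                        0.5 * (sorted(d)[len(d) // 2 - 1] + sorted(d)[len(d) // 2])
                    dev = sorted(abs(x - med) for x in d)
                    mads.append(dev[len(dev) // 2] if len(dev) % 2 else
                                0.5 * (dev[len(dev) // 2 - 1] + dev[len(dev) // 2]))
                mean = sum(mads) / len(mads)
                cv = (sum((x - mean) ** 2 for x in mads) /
                      (len(mads) - 1)) ** 0.5 / mean
                if best_cv is None or cv < best_cv:
                    best_cv, best_p = cv, p
            return best_p

        f = estimate_fudge_factor(numerators, scatters)
        assert f.percentile == oracle()

    def test_c0_is_a_scatter_percentile_and_nonnegative(self):
        rng = np.random.default_rng(9)
        scatters = rng.gamma(2.0, 1.0, 200)
        f = estimate_fudge_factor(rng.normal(size=200), scatters)
        assert f.c0 >= 0
        assert any(np.isclose(f.c0, np.percentile(scatters, p))
                   for p in range(0, 101, 5))

    def test_all_zero_scatters_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_fudge_factor(np.ones(30), np.zeros(30))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="20"):
            estimate_fudge_factor(np.ones(10), np.ones(10))
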