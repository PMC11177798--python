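"""Fixed-effect pooling, Cochran's Q and the I2 point estimate."""

import math
import random

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from sctbias.meta import (
    DegenerateStudyError,
    FixedEffectMeta,
    StudyEffect,
    i_squared,
    mean_difference,
    pool_fixed,
    round_half_away,
)
from sctbias.trial_data import ArmSummary


def oracle_pool(mds, variances):
    """Independent direct-summation implementation of fixed-effect pooling.

    Written with plain Python loops and the textbook formulas only; kept free
    of any code from the package under test.
    """
    weights = [1.0 / v for v in variances]
    total = sum(weights)
    pooled = sum(w * m for w, m in zip(weights, mds)) / total
    q = sum(w * (m - pooled) ** 2 for w, m in zip(weights, mds))
    df = len(mds) - 1
    i2 = 0.0 if q <= df else 100.0 * (q - df) / q
    return pooled, math.sqrt(1.0 / total), q, i2


class TestMeanDifference:
    def test_cohort_arms_hand_arithmetic(self):
        test = ArmSummary("test", 64.22, 12.00, 31)
        control = ArmSummary("control", 50.73, 14.00, 30)
        effect = mean_difference(test, control)
        assert effect.md == pytest.approx(13.49)
        assert effect.variance == pytest.approx(144.0 / 31 + 196.0 / 30)  # ~11.178

    def test_identical_arms_give_zero_md(self):
        arm = ArmSummary("x", 81.30, 4.80, 41)
        assert mean_difference(arm, arm).md == 0.0

    def test_zero_variance_pair_is_degenerate(self):
        a = ArmSummary("a", 5.0, 0.0, 5)
        b = ArmSummary("b", 6.0, 0.0, 5)
        with pytest.raises(DegenerateStudyError):
            mean_difference(a, b)


class TestISquared:
    def test_matches_published_cohort_value_after_rounding(self):
        assert round_half_away(i_squared(6.895, 2)) == 71

    @pytest.mark.parametrize("q, df", [(2.0, 2), (0.004, 2), (0.0, 1)])
    def test_truncates_to_zero_when_q_at_most_df(self, q, df):
        assert i_squared(q, df) == 0.0

    @given(q=st.floats(0, 1e6), df=st.integers(1, 50))
    def test_always_in_unit_interval(self, q, df):
        assert 0.0 <= i_squared(q, df) < 100.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            i_squared(-0.1, 2)
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestPoolFixed:
    def test_two_identical_studies_have_no_heterogeneity(self):
        res = pool_fixed([StudyEffect("a", 1.3, 2.0), StudyEffect("b", 1.3, 2.0)])
        assert res.q == pytest.approx(0.0)
        assert res.i_squared == 0.0

    def test_three_unit_variance_studies(self):
        # mds {0,1,2}, all variance 1: pooled 1, Q = 2 = df, so I2 truncates
        res = pool_fixed([StudyEffect(s, m, 1.0) for s, m in zip("abc", [0.0, 1.0, 2.0])])
        assert res.pooled_md == pytest.approx(1.0)
        assert res.q == pytest.approx(2.0)
        assert res.df == 2
        assert res.i_squared == 0.0

    def test_cohort_three_study_pool(self, reference_trials, reference_scts):
        trial = reference_trials["REF17"]
        (a1, b1), (a2, b2) = reference_scts["REF17"]
        res = pool_fixed(
            [
                mean_difference(a1, b1, "SCT 1"),
                mean_difference(a2, b2, "SCT 2"),
                mean_difference(trial.test_arm, trial.control_arm, "REF17"),
            ]
        )
        assert res.i_squared_rounded == 71

    def test_pooled_md_within_study_range_and_weight_identity(self):
        effects = [StudyEffect(str(i), m, v) for i, (m, v) in enumerate([(0.5, 1.0), (2.0, 0.3), (-1.0, 2.5)])]
        res = pool_fixed(effects)
        assert min(e.md for e in effects) <= res.pooled_md <= max(e.md for e in effects)
        assert res.weights.sum() == pytest.approx(1.0 / res.pooled_se**2)

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([StudyEffect("a", 1.0, 1.0)])

    def test_summary_mentions_heterogeneity(self):
        res = pool_fixed([StudyEffect("a", 0.0, 1.0), StudyEffect("b", 3.0, 1.0)])
        text = res.summary()
        assert "Q =" in text and "I2" in text and "pooled" in text


@st.composite
def effect_lists(draw, max_k=6):
    k = draw(st.integers(2, max_k))
    mds = draw(st.lists(st.floats(-50, 50), min_size=k, max_size=k))
    variances = draw(st.lists(st.floats(0.01, 100), min_size=k, max_size=k))
    return [StudyEffect(str(i), m, v) for i, (m, v) in enumerate(zip(mds, variances))]


class TestPoolingProperties:
    @given(effects=effect_lists())
    def test_oracle_equivalence(self, effects):
        res = pool_fixed(effects)
        pooled, se, q, i2 = oracle_pool([e.md for e in effects], [e.variance for e in effects])
        assert res.pooled_md == pytest.approx(pooled, rel=1e-10, abs=1e-10)
        assert res.pooled_se == pytest.approx(se, rel=1e-10)
        assert res.q == pytest.approx(q, rel=1e-10, abs=1e-10)
        assert res.i_squared == pytest.approx(i2, rel=1e-10, abs=1e-10)

    @given(effects=effect_lists(), seed=st.integers(0, 10**6))
    def test_permutation_invariance(self, effects, seed):
        shuffled = effects[:]
        random.Random(seed).shuffle(shuffled)
        a, b = pool_fixed(effects), pool_fixed(shuffled)
        assert a.pooled_md == pytest.approx(b.pooled_md, rel=1e-12, abs=1e-12)
        assert a.q == pytest.approx(b.q, rel=1e-9, abs=1e-9)
        assert a.i_squared == pytest.approx(b.i_squared, rel=1e-9, abs=1e-9)

    @given(effects=effect_lists())
    def test_sign_invariance(self, effects):
        negated = [StudyEffect(e.study_id, -e.md, e.variance) for e in effects]
        a, b = pool_fixed(effects), pool_fixed(negated)
        assert b.pooled_md == pytest.approx(-a.pooled_md, rel=1e-12, abs=1e-12)
        assert b.q == pytest.approx(a.q, rel=1e-9, abs=1e-9)
        assert b.i_squared == pytest.approx(a.i_squared, rel=1e-9, abs=1e-9)

    @given(effects=effect_lists(), scale=st.floats(0.01, 100))
    def test_scale_equivariance(self, effects, scale):
        # scaling all means and sds by c scales md by c and variance by c^2
        scaled = [StudyEffect(e.study_id, scale * e.md, scale**2 * e.variance) for e in effects]
        a, b = pool_fixed(effects), pool_fixed(scaled)
        assert b.pooled_md == pytest.approx(scale * a.pooled_md, rel=1e-9, abs=1e-9)
        assert b.i_squared == pytest.approx(a.i_squared, rel=1e-6, abs=1e-6)


class TestNullCalibration:
    def test_q_is_chi_square_under_homogeneity(self):
        """Q over homogeneous normal effects follows chi-square with k-1 df."""
        rng = np.random.default_rng(20240515)
        k, n_rep = 5, 10_000
        variances = np.array([0.5, 1.0, 2.0, 4.0, 0.8])
        mds = rng.normal(0.0, np.sqrt(variances), size=(n_rep, k))
        q_values = np.array(
            [
                pool_fixed([StudyEffect(str(i), m, v) for i, (m, v) in enumerate(zip(row, variances))]).q
                for row in mds
            ]
        )
        stat, _ = scipy.stats.kstest(q_values, scipy.stats.chi2(k - 1).cdf)
        assert stat < 0.025  # coarse Monte-Carlo tolerance at 10^4 replicates
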