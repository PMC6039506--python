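"""Two competing targets: joint law, moments, correlation, noise effects."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sequest.distributions import DiscreteDistribution, JointDistribution, total_variation
from sequest.extrinsic_noise import ExtrinsicNoiseSpec
from sequest.oracles import steady_state_joint, two_target_network
from sequest.single_target import SequestrationParams, steady_state_distribution
from sequest.two_target import (
    TwoTargetParams,
    correlation_maximum_locus,
    correlation_sweep,
    feasible_region,
    joint_distribution,
    mixed_joint,
    moments,
    pearson,
)


class TestFeasibleRegion:
    def test_plentiful_sequestrant(self):
        r = feasible_region(TwoTargetParams(20, 20, 60, 1.0, 1.0))
        assert r["S"] == (20, 60)
        assert r["T1"] == (0, 20) and r["T2"] == (0, 20)

    def test_scarce_sequestrant_forces_free_targets(self):
        r = feasible_region(TwoTargetParams(100, 20, 60, 1.0, 1.0))
        assert r["T1"] == (40, 100)

    def test_empty_species_is_pinned(self):
        r = feasible_region(TwoTargetParams(0, 5, 10, 1.0, 1.0))
        assert r["T1"] == (0, 0)


class TestJointDistribution:
    def test_reduces_to_single_target_when_other_is_absent(self):
        joint = joint_distribution(TwoTargetParams(6, 0, 4, 0.7, 1.0))
        single = steady_state_distribution(SequestrationParams(6, 4, 0.7))
        assert total_variation(joint.marginal(0), single) < 1e-13

    def test_relabeling_symmetry_transposes_the_table(self):
        p = TwoTargetParams(5, 3, 4, 0.3, 2.0)
        a = joint_distribution(p)
        b = joint_distribution(p.swapped())
        np.testing.assert_allclose(a.table, b.table.T, atol=1e-15)

    def test_matches_enumerated_generator_null_space(self):
        p = TwoTargetParams(3, 2, 3, 1.0, 2.0)
        exact = joint_distribution(p)
        oracle = steady_state_joint(
            two_target_network(3, 2, 3, 1.0, 2.0), ("T1", "T2")
        )
        assert total_variation(exact, oracle) < 1e-10

    @given(
        t1=st.integers(0, 9),
        t2=st.integers(0, 9),
        s=st.integers(0, 12),
        k1=st.floats(0.1, 5.0),
        k2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_detailed_balance_on_every_feasible_edge(self, t1, t2, s, k1, k2):
        """Zero flux across both binding reactions, edge by edge."""
        params = TwoTargetParams(t1, t2, s, k1, k2)
        joint = joint_distribution(params)
        p = joint.table
        assert abs(p.sum() - 1.0) <= 1e-12
        i = np.arange(t1 + 1)[:, None]
        j = np.arange(t2 + 1)[None, :]
        s_free = s - (t1 - i) - (t2 - j)
        # binding of target 1: (T1, T2) -> (T1-1, T2)
        lhs = p[1:, :] * i[1:, :] * np.clip(s_free[1:, :], 0, None)
        rhs = k1 * (t1 - i[1:, :] + 1) * p[:-1, :]
        ok = np.maximum(lhs, rhs) > 0
        assert np.all(np.abs(lhs - rhs)[ok] / np.maximum(lhs, rhs)[ok] <= 1e-10)
        # binding of target 2
        lhs = p[:, 1:] * j[:, 1:] * np.clip(s_free[:, 1:], 0, None)
        rhs = k2 * (t2 - j[:, 1:] + 1) * p[:, :-1]
        ok = np.maximum(lhs, rhs) > 0
        assert np.all(np.abs(lhs - rhs)[ok] / np.maximum(lhs, rhs)[ok] <= 1e-10)

    def test_nonpositive_affinity_rejected(self):
        with pytest.raises(ValueError):
            TwoTargetParams(3, 3, 3, 0.0, 1.0)


class TestMomentsAndPearson:
    def test_point_mass_has_zero_spread(self):
        joint = JointDistribution((4, 2), np.array([[1.0]]))
        m = moments(joint)
        assert m.variance == (0.0, 0.0) and m.covariance == 0.0
        assert math.isnan(pearson(joint))

    def test_product_joint_has_zero_covariance(self, rng):
        p1 = rng.dirichlet(np.ones(5))
        p2 = rng.dirichlet(np.ones(4))
        joint = JointDistribution((0, 0), np.outer(p1, p2))
        assert abs(moments(joint).covariance) < 1e-14

    def test_diagonal_and_antidiagonal_saturate_pearson(self):
        diag = JointDistribution((0, 0), np.array([[0.5, 0.0], [0.0, 0.5]]))
        anti = JointDistribution((0, 0), np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert pearson(diag) == pytest.approx(1.0)
        assert pearson(anti) == pytest.approx(-1.0)

    def test_mean_threshold_sits_at_equimolarity(self):
        """<T_1>(T_1T) turns over near T_1T* = S_T - T_2T = 40."""
        tts = np.arange(30, 52)
        means = [
            moments(joint_distribution(TwoTargetParams(int(t), 20, 60, 0.1, 0.1))).mean[0]
            for t in tts
        ]
        curvature = np.diff(means, n=2)
        assert abs(tts[1 + int(np.argmax(curvature))] - 40) <= 2

    def test_strong_affinity_saturation_approaches_minus_one(self):
        joint = joint_distribution(TwoTargetParams(100, 20, 60, 1e-6, 1e-6))
        assert pearson(joint) < -0.999


class TestIntrinsicCorrelationShape:
    def test_competition_never_correlates_positively(self):
        for t1 in (5, 20, 40, 60, 80, 100):
            for k in (0.1, 1.0):
                rho = pearson(joint_distribution(TwoTargetParams(t1, 20, 60, k, k)))
                assert rho <= 1e-9

    def test_flat_then_dropping_profile(self):
        sweep = correlation_sweep(
            range(5, 101, 5), t2_t=20, s_t=60, k1_d=0.1, k2_d=0.1
        )
        rho = sweep["rho"].to_numpy()
        assert rho[0] > -0.05  # far below threshold: uncorrelated
        assert np.all(np.diff(rho) <= 1e-9)  # monotone decrease
        assert rho[-1] < -0.9


class TestExtrinsicNoise:
    def test_point_noise_recovers_pure_joint(self):
        params = TwoTargetParams(30, 20, 60, 0.1, 0.1)
        mixed = mixed_joint(params, ExtrinsicNoiseSpec.point(60))
        assert total_variation(mixed, joint_distribution(params)) < 1e-13

    def test_mixture_linearity_for_two_point_noises(self):
        params = TwoTargetParams(12, 8, 15, 0.3, 1.0)
        noise = DiscreteDistribution(10, np.array([0.3] + [0.0] * 9 + [0.7]))
        mixed = mixed_joint(params, noise)
        a = joint_distribution(TwoTargetParams(12, 8, 10, 0.3, 1.0))
        b = joint_distribution(TwoTargetParams(12, 8, 20, 0.3, 1.0))
        manual = 0.3 * a.table + 0.7 * b.table
        np.testing.assert_allclose(mixed.table, manual, atol=1e-14)

    def test_strong_noise_turns_correlation_positive(self):
        strong = correlation_sweep(
            range(20, 70, 10), t2_t=20, s_t=60, k1_d=0.1, k2_d=0.1, sigma=12
        )["rho"].to_numpy()
        weak = correlation_sweep(
            range(20, 70, 10), t2_t=20, s_t=60, k1_d=0.1, k2_d=0.1, sigma=2
        )["rho"].to_numpy()
        assert strong.max() > 0
        assert np.all(weak < strong)


class TestCorrelationMaximumLocus:
    def test_unequal_affinities_shift_the_global_peak(self):
        """Lowering K_1^d below K_2^d moves the correlation peak toward more
        of target 1 and less of target 2."""
        t2ts = [10, 18, 26, 34, 42]
        t1ts = range(2, 81, 2)
        equal = correlation_maximum_locus(
            t2ts, t1ts, st_mean=60, sigma=4, k1_d=0.1, k2_d=0.1
        )
        unequal = correlation_maximum_locus(
            t2ts, t1ts, st_mean=60, sigma=4, k1_d=0.1, k2_d=1.0
        )
        peak_eq = equal.loc[equal["rho_max"].idxmax()]
        peak_un = unequal.loc[unequal["rho_max"].idxmax()]
        assert peak_un["t2_t"] < peak_eq["t2_t"]
        assert peak_un["t1t_star"] > peak_eq["t1t_star"]

    def test_empty_search_range_rejected(self):
        with pytest.raises(ValueError):
            correlation_maximum_locus([10], [], st_mean=60, sigma=4, k1_d=0.1, k2_d=0.1)
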