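"""Noise laws, total-probability mixtures, mode counting, bimodality scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sequest.distributions import DiscreteDistribution
from sequest.extrinsic_noise import (
    ExtrinsicNoiseSpec,
    bimodality_scan,
    count_modes,
    discretise_noise,
    mix_over_sequestrant,
)
from sequest.single_target import SequestrationParams, steady_state_distribution


def conditional(t_t, k_d):
    return lambda s: steady_state_distribution(SequestrationParams(t_t, s, k_d))


class TestDiscretiseNoise:
    def test_degenerate_gaussian_is_point_mass(self):
        d = discretise_noise(ExtrinsicNoiseSpec.gaussian(30, 0.0))
        assert d.offset == 30 and d.probs.tolist() == [1.0]

    def test_uniform_weights(self):
        d = discretise_noise(ExtrinsicNoiseSpec.uniform(0, 3))
        np.testing.assert_allclose(d.probs, [0.25] * 4)

    def test_gaussian_weights_follow_the_kernel(self):
        d = discretise_noise(ExtrinsicNoiseSpec.gaussian(30, 8.0))
        s = d.support
        kernel = np.exp(-((s - 30.0) ** 2) / (2 * 64.0))
        np.testing.assert_allclose(d.probs, kernel / kernel.sum(), rtol=1e-12)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mean,sigma", [(30, 8), (50, 10), (12, 4)])
    def test_truncation_barely_moves_the_mean(self, mean, sigma):
        d = discretise_noise(ExtrinsicNoiseSpec.gaussian(mean, sigma))
        assert abs(d.mean() - mean) <= 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="gaussian", mean=30.0, sigma=-1.0),
            dict(family="uniform", lo=5, hi=2),
            dict(family="gaussian", mean=-3.0, sigma=1.0),
            dict(family="nope"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExtrinsicNoiseSpec(**kwargs)


class TestMixOverSequestrant:
    def test_point_noise_recovers_the_conditional(self):
        noise = discretise_noise(ExtrinsicNoiseSpec.point(30))
        mixed = mix_over_sequestrant(conditional(40, 0.1), noise)
        pure = conditional(40, 0.1)(30)
        assert mixed.offset == pure.offset
        np.testing.assert_allclose(mixed.probs, pure.probs, atol=1e-14)

    def test_two_component_noise_averages_the_conditionals(self):
        noise = DiscreteDistribution(20, np.array([0.5] + [0.0] * 19 + [0.5]))
        mixed = mix_over_sequestrant(conditional(25, 0.5), noise)
        a = conditional(25, 0.5)(20)
        b = conditional(25, 0.5)(40)
        for t in range(0, 26):
            assert mixed.prob(t) == pytest.approx(
                0.5 * a.prob(t) + 0.5 * b.prob(t), abs=1e-14
            )

    def test_law_of_total_expectation(self):
        noise = discretise_noise(ExtrinsicNoiseSpec.gaussian(30, 8))
        mixed = mix_over_sequestrant(conditional(40, 0.1), noise)
        expected = sum(
            w * conditional(40, 0.1)(int(s)).mean()
            for s, w in zip(noise.support, noise.probs)
        )
        assert mixed.mean() == pytest.approx(expected, abs=1e-10)
        assert mixed.probs.sum() == pytest.approx(1.0, abs=1e-10)

    @given(w=st.floats(0.05, 0.95), sa=st.integers(10, 30), sb=st.integers(31, 60))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mixture_is_linear_in_the_noise_weights(self, w, sa, sb):
        probs = np.zeros(sb - sa + 1)
        probs[0], probs[-1] = w, 1 - w
        noise = DiscreteDistribution(sa, probs)
        mixed = mix_over_sequestrant(conditional(35, 0.2), noise)
        a = conditional(35, 0.2)(sa)
        b = conditional(35, 0.2)(sb)
        manual = w * np.array([a.prob(t) for t in range(36)]) + (1 - w) * np.array(
            [b.prob(t) for t in range(36)]
        )
        np.testing.assert_allclose([mixed.prob(t) for t in range(36)], manual, atol=1e-13)

    def test_solver_failure_reports_offending_total(self):
        def bad(s):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="S_T=30"):
            mix_over_sequestrant(bad, DiscreteDistribution.point(30))


class TestCountModes:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ([0.4, 0.3, 0.2, 0.1], 1),  # boundary maximum
            ([0.1, 0.4, 0.1, 0.3, 0.1], 2),  # two interior peaks
            ([0.1, 0.3, 0.3, 0.2, 0.1], 1),  # plateau counts once
            ([0.5, 0.5], 1),  # global plateau
            ([0.1, 0.2, 0.3, 0.4], 1),  # increasing, right-edge maximum
        ],
    )
    def test_known_shapes(self, vector, expected):
        dist = DiscreteDistribution(0, np.array(vector) / np.sum(vector))
        assert count_modes(dist) == expected

    @pytest.mark.parametrize("k_d", [0.1, 1.0, 5.0])
    @pytest.mark.parametrize("t_t", [10, 30, 40])
    def test_pure_intrinsic_laws_are_unimodal(self, k_d, t_t):
        d = steady_state_distribution(SequestrationParams(t_t, 30, k_d))
        assert count_modes(d) == 1


class TestThresholdSmoothing:
    def test_noise_smooths_the_mean_profile(self):
        """The threshold of <T> vs T_T flattens as the noise level grows."""
        tts = np.arange(20, 46)
        steepness = []
        for sigma in (0.0, 5.0, 8.0, 13.0):
            noise = discretise_noise(
                ExtrinsicNoiseSpec.gaussian(30, sigma)
                if sigma
                else ExtrinsicNoiseSpec.point(30)
            )
            means = [
                mix_over_sequestrant(conditional(int(t), 0.1), noise).mean() for t in tts
            ]
            steepness.append(np.max(np.diff(means)))
        assert all(a > b for a, b in zip(steepness, steepness[1:]))


class TestUniformNoise:
    @pytest.mark.parametrize("t_t", [35, 40, 45])
    @pytest.mark.parametrize("lo,hi", [(20, 40), (25, 55), (10, 50)])
    def test_flat_noise_never_builds_an_unrepressed_peak(self, t_t, lo, hi):
        """A uniform sequestrant law spanning the threshold piles mass into
        the repressed peak but produces no competing high-count mode."""
        noise = discretise_noise(ExtrinsicNoiseSpec.uniform(lo, hi))
        mixed = mix_over_sequestrant(conditional(t_t, 0.1), noise)
        assert count_modes(mixed) == 1


class TestBimodalityScan:
    def test_small_scan_flags_the_known_bimodal_node(self):
        scan = bimodality_scan(
            conditional_solver, range(38, 43), 30.0, sigma_values=[0.0, 8.0]
        )
        assert scan.mode_counts[:, 0].max() == 1  # no noise, no bimodality
        assert scan.is_bimodal(40, 8.0)
        assert scan.bimodal_area() >= 1
        assert all(
            (t, s) in {(int(a), float(b)) for a in scan.tt_values for b in scan.sigma_values}
            for t, s in scan.boundary
        )

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            bimodality_scan(conditional_solver, [], 30.0, sigma_values=[0.0])


def conditional_solver(t_t, s_t):
    return steady_state_distribution(SequestrationParams(t_t, s_t, 0.1))
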