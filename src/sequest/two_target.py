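"""Exact joint steady state of two targets competing for one sequestrant.

Targets ``T_1`` and ``T_2`` bind reversibly to a shared sequestrant ``S``
with dissociation constants ``K_1^d`` and ``K_2^d``; all three totals are
conserved.  Detailed balance again holds and the stationary joint law is

    P(T_1, T_2) ∝ (K_1^d)^{T_1} (K_2^d)^{T_2} C(T_1T, T_1) C(T_2T, T_2)
                  / [S_T + T_1 + T_2 − (T_1T + T_2T)]!

over the feasible region where the free-sequestrant count is nonnegative —
the grand-canonical form of an ideal particle mixture.  Competition for the
common pool correlates the two free counts negatively; extrinsic noise on
``S_T`` pushes both targets the same way and can flip the Pearson
coefficient positive near the titration threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .distributions import DiscreteDistribution, JointDistribution
from .extrinsic_noise import (
    ExtrinsicNoiseSpec,
    discretise_noise,
    mix_joint_over_sequestrant,
)

__all__ = [
    "TwoTargetParams",
    "Moments",
    "feasible_region",
    "joint_distribution",
    "moments",
    "pearson",
    "mixed_joint",
    "correlation_sweep",
    "correlation_maximum_locus",
]


@dataclass(frozen=True)
class TwoTargetParams:
    """Totals and affinities of the two-target competition network."""

    t1_t: int
    t2_t: int
    s_t: int
    k1_d: float
    k2_d: float

    def __post_init__(self) -> None:
        if min(self.t1_t, self.t2_t, self.s_t) < 0:
            raise ValueError("total copy numbers must be nonnegative")
        if not (self.k1_d > 0 and self.k2_d > 0):
            raise ValueError("dissociation constants must be positive")

    def swapped(self) -> "TwoTargetParams":
        return TwoTargetParams(self.t2_t, self.t1_t, self.s_t, self.k2_d, self.k1_d)


def feasible_region(params: TwoTargetParams) -> dict[str, tuple[int, int]]:
    """Per-species (min, max) bounds implied by the conservation laws.

    A state ``(T_1, T_2)`` is feasible iff ``0 ≤ T_i ≤ T_iT`` and the free
    sequestrant ``S_T − (T_1T − T_1) − (T_2T − T_2)`` is nonnegative.
    """
    return {
        "T1": (max(0, params.t1_t - params.s_t), params.t1_t),
        "T2": (max(0, params.t2_t - params.s_t), params.t2_t),
        "S": (max(0, params.s_t - params.t1_t - params.t2_t), params.s_t),
    }


def joint_distribution(params: TwoTargetParams) -> JointDistribution:
    """Exact stationary joint law of the free counts ``(T_1, T_2)``.

    Materialized densely over ``[0, T_1T] × [0, T_2T]`` with exact zeros
    outside the feasible region; weights assembled in log space.
    """
    t1 = np.arange(params.t1_t + 1)
    t2 = np.arange(params.t2_t + 1)
    s_free = (
        params.s_t
        - (params.t1_t - t1)[:, None]
        - (params.t2_t - t2)[None, :]
    )
    feasible = s_free >= 0
    log_w = np.full(feasible.shape, -np.inf)
    lb1 = (
        t1 * math.log(params.k1_d)
        + gammaln(params.t1_t + 1)
        - gammaln(t1 + 1)
        - gammaln(params.t1_t - t1 + 1)
    )
    lb2 = (
        t2 * math.log(params.k2_d)
        + gammaln(params.t2_t + 1)
        - gammaln(t2 + 1)
        - gammaln(params.t2_t - t2 + 1)
    )
    log_w[feasible] = (lb1[:, None] + lb2[None, :] - gammaln(s_free + 1.0))[feasible]
    table = np.exp(log_w - logsumexp(log_w))
    return JointDistribution((0, 0), table / table.sum())


@dataclass(frozen=True)
class Moments:
    mean: tuple[float, float]
    variance: tuple[float, float]
    covariance: float


def moments(joint: JointDistribution) -> Moments:
    """Means, variances and covariance of a two-axis joint table."""
    if joint.ndim != 2:
        raise ValueError("moments are defined for two-axis joints")
    x = joint.axis_support(0)[:, None].astype(float)
    y = joint.axis_support(1)[None, :].astype(float)
    p = joint.table
    m1 = float((x * p).sum())
    m2 = float((y * p).sum())
    v1 = float(((x - m1) ** 2 * p).sum())
    v2 = float(((y - m2) ** 2 * p).sum())
    cov = float(((x - m1) * (y - m2) * p).sum())
    return Moments((m1, m2), (max(v1, 0.0), max(v2, 0.0)), cov)


def pearson(joint: JointDistribution) -> float:
    """Pearson coefficient ``cov/(σ_1 σ_2)`` of a two-axis joint.

    Returns ``nan`` when a marginal is degenerate (zero variance), where
    the coefficient is undefined.
    """
    m = moments(joint)
    v1, v2 = m.variance
    if v1 <= 0.0 or v2 <= 0.0:
        return float("nan")
    return m.covariance / math.sqrt(v1 * v2)


def _as_noise_distribution(
    noise: ExtrinsicNoiseSpec | DiscreteDistribution,
) -> DiscreteDistribution:
    if isinstance(noise, ExtrinsicNoiseSpec):
        return discretise_noise(noise)
    return noise


def mixed_joint(
    params: TwoTargetParams,
    noise: ExtrinsicNoiseSpec | DiscreteDistribution,
) -> JointDistribution:
    """Joint law under extrinsic noise on the total sequestrant."""
    noise_dist = _as_noise_distribution(noise)

    def solve(s_t: int) -> JointDistribution:
        return joint_distribution(
            TwoTargetParams(params.t1_t, params.t2_t, s_t, params.k1_d, params.k2_d)
        )

    return mix_joint_over_sequestrant(solve, noise_dist)


def correlation_sweep(
    t1t_values,
    *,
    t2_t: int,
    s_t: float,
    k1_d: float,
    k2_d: float,
    sigma: float = 0.0,
) -> pd.DataFrame:
    """Pearson coefficient along a sweep of the total of target 1.

    ``sigma = 0`` gives the pure-intrinsic case; otherwise ``s_t`` is the
    mean of the Gaussian extrinsic noise.
    """
    noise = discretise_noise(
        ExtrinsicNoiseSpec.gaussian(s_t, sigma) if sigma > 0 else ExtrinsicNoiseSpec.point(s_t)
    )
    rows = []
    for t1_t in t1t_values:
        params = TwoTargetParams(int(t1_t), t2_t, int(round(s_t)), k1_d, k2_d)
        joint = mixed_joint(params, noise) if noise.probs.size > 1 else joint_distribution(
            TwoTargetParams(int(t1_t), t2_t, int(noise.offset), k1_d, k2_d)
        )
        rows.append({"t1_t": int(t1_t), "sigma": float(sigma), "rho": pearson(joint)})
    return pd.DataFrame(rows)


def correlation_maximum_locus(
    t2t_values,
    t1t_values,
    *,
    st_mean: float,
    sigma: float,
    k1_d: float,
    k2_d: float,
) -> pd.DataFrame:
    """Location and value of the correlation maximum for each ``T_2T``.

    For every ``T_2T`` the mixed-joint Pearson coefficient is maximized
    over integer ``T_1T``; ties break toward the smaller ``T_1T`` so locus
    tables are reproducible.
    """
    noise = discretise_noise(ExtrinsicNoiseSpec.gaussian(st_mean, sigma))
    t1t_values = np.asarray(list(t1t_values), dtype=int)
    if t1t_values.size == 0:
        raise ValueError("empty T_1T search range")
    rows = []
    for t2_t in t2t_values:
        rhos = np.array(
            [
                pearson(
                    mixed_joint(
                        TwoTargetParams(int(t1), int(t2_t), int(round(st_mean)), k1_d, k2_d),
                        noise,
                    )
                )
                for t1 in t1t_values
            ]
        )
        best = int(np.nanargmax(rhos))  # first index on ties -> smaller T_1T
        rows.append(
            {
                "t2_t": int(t2_t),
                "t1t_star": int(t1t_values[best]),
                "rho_max": float(rhos[best]),
            }
        )
    return pd.DataFrame(rows)
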