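"""Competitive enzyme inhibition under quasi-equilibrium.

A free enzyme ``T_F`` either binds an inhibitor ``S`` into the inactive
complex ``C`` (dissociation constant ``K_d = k_-/k_+``) or binds substrate
(held at fixed concentration ``c_s``) to become the active form ``T_A``
with composite activation ratio ``a = c_s·k_f/k_r``.  In the
quasi-equilibrium limit — product formation much slower than binding and
activation — the remaining reversible network satisfies detailed balance
and the stationary joint law of ``(T_A, C)`` has the product form

    P(T_A, C) ∝ a^{T_A} (1/K_d)^{C}
                · T_T! / [(T_T − T_A − C)! T_A! C!] · 1/(S_T − C)!

on ``{T_A ≥ 0, C ≥ 0, T_A + C ≤ T_T, C ≤ S_T}``.  The form is re-derived
here from the edge-wise detailed-balance ratios, which every constructed
table asserts; the enumerated master-equation oracle provides the
independent cross-check in the tests.  The two-enzyme variant shares the
inhibitor pool and adds per-enzyme activation, giving a four-axis product
form whose ``(T_1A, T_2A)`` projection carries the correlations of the
active enzymes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .distributions import DiscreteDistribution, JointDistribution
from .extrinsic_noise import (
    BimodalityScanResult,
    ExtrinsicNoiseSpec,
    _region_boundary,
    count_modes,
    discretise_noise,
    mix_discrete,
    mix_joint_over_sequestrant,
)

__all__ = [
    "InhibitionParams",
    "TwoEnzymeParams",
    "inhibition_joint",
    "detailed_balance_residual",
    "inhibition_marginals",
    "inhibition_bimodality_scans",
    "two_enzyme_joint",
    "active_pair_joint",
    "two_enzyme_correlation_sweep",
]

_DB_TOL = 1e-8


@dataclass(frozen=True)
class InhibitionParams:
    """One enzyme species, one inhibitor.

    ``a = c_s·k_f/k_r`` is the only activation quantity entering the
    steady state; raw rates are optional and used by the stochastic
    simulator alone.
    """

    t_t: int
    s_t: int
    k_d: float
    a: float
    k_plus: float | None = None
    k_minus: float | None = None
    k_f: float | None = None
    k_r: float | None = None
    c_s: float | None = None

    def __post_init__(self) -> None:
        if self.t_t < 0 or self.s_t < 0:
            raise ValueError("total copy numbers must be nonnegative")
        if not (self.k_d > 0 and self.a > 0):
            raise ValueError("k_d and the activation ratio a must be positive")
        if self.k_plus is not None and self.k_minus is not None:
            if abs(self.k_d - self.k_minus / self.k_plus) > 1e-12 * self.k_d:
                raise ValueError("k_d must equal k_minus / k_plus")
        if self.k_f is not None and self.k_r is not None and self.c_s is not None:
            if abs(self.a - self.c_s * self.k_f / self.k_r) > 1e-12 * self.a:
                raise ValueError("a must equal c_s * k_f / k_r")


@dataclass(frozen=True)
class TwoEnzymeParams:
    """Two enzyme species inhibited by a shared pool of ``S_T`` inhibitors."""

    t1_t: int
    k1_d: float
    a1: float
    t2_t: int
    k2_d: float
    a2: float
    s_t: int

    def __post_init__(self) -> None:
        if min(self.t1_t, self.t2_t, self.s_t) < 0:
            raise ValueError("total copy numbers must be nonnegative")
        if not (self.k1_d > 0 and self.k2_d > 0 and self.a1 > 0 and self.a2 > 0):
            raise ValueError("dissociation constants and activation ratios must be positive")

    def swapped(self) -> "TwoEnzymeParams":
        return TwoEnzymeParams(
            self.t2_t, self.k2_d, self.a2, self.t1_t, self.k1_d, self.a1, self.s_t
        )

    def enzyme(self, i: int) -> InhibitionParams:
        if i == 1:
            return InhibitionParams(self.t1_t, self.s_t, self.k1_d, self.a1)
        return InhibitionParams(self.t2_t, self.s_t, self.k2_d, self.a2)


def _single_log_table(t_t: int, s_t: int, k_d: float, a: float) -> np.ndarray:
    """Log weights over (T_A, C); -inf outside the feasible wedge."""
    ta = np.arange(t_t + 1)[:, None]
    c = np.arange(min(t_t, s_t) + 1)[None, :]
    feasible = ta + c <= t_t
    log_w = np.where(
        feasible,
        ta * math.log(a)
        - c * math.log(k_d)
        + gammaln(t_t + 1)
        - gammaln(np.where(feasible, t_t - ta - c, 0) + 1.0)
        - gammaln(ta + 1.0)
        - gammaln(c + 1.0)
        - gammaln(s_t - c + 1.0),
        -np.inf,
    )
    return log_w


def detailed_balance_residual(joint: JointDistribution, params: InhibitionParams) -> float:
    """Max relative detailed-balance residual over both reaction edges.

    Binding edge (T_A, C) → (T_A, C+1):  P(T_A,C+1) = P(T_A,C)·(1/K_d)·
    T_F·(S_T−C)/(C+1);  activation edge (T_A, C) → (T_A+1, C):
    P(T_A+1,C) = P(T_A,C)·a·T_F/(T_A+1), with T_F = T_T − T_A − C.
    """
    p = joint.table
    t_t, s_t = params.t_t, params.s_t
    ta = joint.axis_support(0)[:, None].astype(float)
    c = joint.axis_support(1)[None, :].astype(float)
    t_f = t_t - ta - c

    worst = 0.0
    # binding edges
    if p.shape[1] > 1:
        lhs = p[:, 1:]
        ratio = (1.0 / params.k_d) * t_f[:, :-1] * (s_t - c[:, :-1]) / (c[:, :-1] + 1.0)
        rhs = p[:, :-1] * ratio
        scale = np.maximum(np.abs(lhs), np.abs(rhs))
        mask = scale > 0
        if mask.any():
            worst = max(worst, float(np.max(np.abs(lhs - rhs)[mask] / scale[mask])))
    # activation edges
    if p.shape[0] > 1:
        lhs = p[1:, :]
        ratio = params.a * t_f[:-1, :] / (ta[:-1, :] + 1.0)
        rhs = p[:-1, :] * ratio
        scale = np.maximum(np.abs(lhs), np.abs(rhs))
        mask = scale > 0
        if mask.any():
            worst = max(worst, float(np.max(np.abs(lhs - rhs)[mask] / scale[mask])))
    return worst


def inhibition_joint(params: InhibitionParams) -> JointDistribution:
    """Quasi-equilibrium stationary joint of (active enzyme, complex).

    The product form is asserted against edge-wise detailed balance at
    construction; a violation raises rather than returning a bad table.
    """
    log_w = _single_log_table(params.t_t, params.s_t, params.k_d, params.a)
    table = np.exp(log_w - logsumexp(log_w))
    joint = JointDistribution((0, 0), table / table.sum())
    residual = detailed_balance_residual(joint, params)
    if residual > _DB_TOL:
        raise AssertionError(
            f"detailed-balance residual {residual:.3e} exceeds {_DB_TOL}"
        )
    return joint


def inhibition_marginals(
    params: InhibitionParams,
    noise: ExtrinsicNoiseSpec | DiscreteDistribution | None = None,
) -> tuple[DiscreteDistribution, DiscreteDistribution]:
    """Marginals of the (mixed) joint: active enzyme ``T_A`` and complex ``C``."""
    if noise is None:
        joint = inhibition_joint(params)
        return joint.marginal(0), joint.marginal(1)
    noise_dist = discretise_noise(noise) if isinstance(noise, ExtrinsicNoiseSpec) else noise
    comps_ta, comps_c, weights = [], [], []
    for s, w in zip(noise_dist.support, noise_dist.probs):
        if w == 0.0:
            continue
        joint = inhibition_joint(
            InhibitionParams(params.t_t, int(s), params.k_d, params.a)
        )
        comps_ta.append(joint.marginal(0))
        comps_c.append(joint.marginal(1))
        weights.append(w)
    w = np.asarray(weights) / np.sum(weights)
    return mix_discrete(comps_ta, w), mix_discrete(comps_c, w)


def inhibition_bimodality_scans(
    tt_values,
    st_mean: float,
    k_d: float,
    a: float,
    sigma_values=None,
    *,
    sigma_max: float = 13.0,
    dsigma: float = 0.25,
    rel_tol: float = 1e-12,
) -> tuple[BimodalityScanResult, BimodalityScanResult]:
    """Mode-count scans of the ``T_A`` and ``C`` marginals on a (T_T, σ) grid.

    Both marginals come from the same conditional joints, computed once per
    ``(T_T, S_T)`` pair and reused across every noise level.
    """
    tt_values = np.asarray(list(tt_values), dtype=int)
    if sigma_values is None:
        sigma_values = np.arange(0.0, sigma_max + dsigma / 2, dsigma)
    sigma_values = np.asarray(list(sigma_values), dtype=float)
    if tt_values.size == 0 or sigma_values.size == 0:
        raise ValueError("empty scan ranges")

    noises = [
        discretise_noise(ExtrinsicNoiseSpec.gaussian(st_mean, s)) for s in sigma_values
    ]
    s_needed = sorted({int(s) for nz in noises for s in nz.support})

    counts_ta = np.zeros((tt_values.size, sigma_values.size), dtype=int)
    counts_c = np.zeros_like(counts_ta)
    for i, tt in enumerate(tt_values):
        marg = {}
        for s in s_needed:
            joint = inhibition_joint(InhibitionParams(int(tt), s, k_d, a))
            marg[s] = (joint.marginal(0), joint.marginal(1))
        for j, noise in enumerate(noises):
            w = noise.probs
            comps_ta = [marg[int(s)][0] for s in noise.support]
            comps_c = [marg[int(s)][1] for s in noise.support]
            counts_ta[i, j] = count_modes(mix_discrete(comps_ta, w), rel_tol=rel_tol)
            counts_c[i, j] = count_modes(mix_discrete(comps_c, w), rel_tol=rel_tol)

    scans = []
    for counts in (counts_ta, counts_c):
        boundary = _region_boundary(tt_values, sigma_values, counts)
        scans.append(
            BimodalityScanResult(tt_values, sigma_values, counts, boundary, float(st_mean))
        )
    return scans[0], scans[1]


def two_enzyme_joint(
    params: TwoEnzymeParams, *, max_states: int = 50_000_000
) -> JointDistribution:
    """Four-axis stationary law over ``(T_1A, C_1, T_2A, C_2)``.

    Product-form weights with the shared-inhibitor factor
    ``1/(S_T − C_1 − C_2)!``; detailed balance is asserted on all four
    reaction edge families.  The dense table is guarded by ``max_states``.
    """
    t1_t, t2_t, s_t = params.t1_t, params.t2_t, params.s_t
    d1a, d1c = t1_t + 1, min(t1_t, s_t) + 1
    d2a, d2c = t2_t + 1, min(t2_t, s_t) + 1
    n_cells = d1a * d1c * d2a * d2c
    if n_cells > max_states:
        raise ValueError(
            f"two-enzyme table would hold {n_cells} cells, above the "
            f"max_states guard of {max_states}; reduce the copy numbers "
            "or raise the guard"
        )
    t1a = np.arange(d1a).reshape(-1, 1, 1, 1)
    c1 = np.arange(d1c).reshape(1, -1, 1, 1)
    t2a = np.arange(d2a).reshape(1, 1, -1, 1)
    c2 = np.arange(d2c).reshape(1, 1, 1, -1)
    feasible = (t1a + c1 <= t1_t) & (t2a + c2 <= t2_t) & (c1 + c2 <= s_t)
    log_w = np.where(
        feasible,
        t1a * math.log(params.a1)
        + t2a * math.log(params.a2)
        - c1 * math.log(params.k1_d)
        - c2 * math.log(params.k2_d)
        + gammaln(t1_t + 1)
        - gammaln(np.where(t1a + c1 <= t1_t, t1_t - t1a - c1, 0) + 1.0)
        - gammaln(t1a + 1.0)
        - gammaln(c1 + 1.0)
        + gammaln(t2_t + 1)
        - gammaln(np.where(t2a + c2 <= t2_t, t2_t - t2a - c2, 0) + 1.0)
        - gammaln(t2a + 1.0)
        - gammaln(c2 + 1.0)
        - gammaln(np.where(c1 + c2 <= s_t, s_t - c1 - c2, 0) + 1.0),
        -np.inf,
    )
    table = np.exp(log_w - logsumexp(log_w))
    joint = JointDistribution((0, 0, 0, 0), table / table.sum())
    _assert_two_enzyme_detailed_balance(joint, params)
    return joint


def _assert_two_enzyme_detailed_balance(
    joint: JointDistribution, params: TwoEnzymeParams
) -> None:
    p = joint.table
    t1_t, t2_t, s_t = params.t1_t, params.t2_t, params.s_t
    t1a = np.arange(p.shape[0]).reshape(-1, 1, 1, 1).astype(float)
    c1 = np.arange(p.shape[1]).reshape(1, -1, 1, 1).astype(float)
    t2a = np.arange(p.shape[2]).reshape(1, 1, -1, 1).astype(float)
    c2 = np.arange(p.shape[3]).reshape(1, 1, 1, -1).astype(float)
    t1f = t1_t - t1a - c1
    t2f = t2_t - t2a - c2
    s_free = s_t - c1 - c2

    def check(lhs: np.ndarray, rhs: np.ndarray) -> None:
        scale = np.maximum(np.abs(lhs), np.abs(rhs))
        mask = scale > 0
        if mask.any():
            worst = float(np.max(np.abs(lhs - rhs)[mask] / scale[mask]))
            if worst > _DB_TOL:
                raise AssertionError(
                    f"two-enzyme detailed-balance residual {worst:.3e}"
                )

    # activation of enzyme 1: (t1a, .) -> (t1a+1, .)
    check(p[1:], p[:-1] * params.a1 * t1f[:-1] / (t1a[:-1] + 1.0))
    # binding of enzyme 1: (c1) -> (c1+1)
    check(
        p[:, 1:],
        p[:, :-1] * (1.0 / params.k1_d) * t1f[:, :-1] * s_free[:, :-1] / (c1[:, :-1] + 1.0),
    )
    # activation of enzyme 2
    check(p[:, :, 1:], p[:, :, :-1] * params.a2 * t2f[:, :, :-1] / (t2a[:, :, :-1] + 1.0))
    # binding of enzyme 2
    check(
        p[:, :, :, 1:],
        p[:, :, :, :-1]
        * (1.0 / params.k2_d)
        * t2f[:, :, :, :-1]
        * s_free[:, :, :, :-1]
        / (c2[:, :, :, :-1] + 1.0),
    )


def active_pair_joint(
    params: TwoEnzymeParams,
    noise: ExtrinsicNoiseSpec | DiscreteDistribution | None = None,
    *,
    max_states: int = 50_000_000,
) -> JointDistribution:
    """Joint law of the two active-enzyme counts ``(T_1A, T_2A)``.

    With ``noise`` given, the projection is mixed over the inhibitor total.
    """
    if noise is None:
        return two_enzyme_joint(params, max_states=max_states).project((0, 2))
    noise_dist = discretise_noise(noise) if isinstance(noise, ExtrinsicNoiseSpec) else noise

    def solve(s_t: int) -> JointDistribution:
        p = TwoEnzymeParams(
            params.t1_t, params.k1_d, params.a1, params.t2_t, params.k2_d, params.a2, s_t
        )
        return two_enzyme_joint(p, max_states=max_states).project((0, 2))

    return mix_joint_over_sequestrant(solve, noise_dist)


def two_enzyme_correlation_sweep(
    t1t_values,
    sigma_values,
    *,
    t2_t: int,
    st_mean: float,
    k1_d: float,
    k2_d: float,
    a1: float,
    a2: float,
) -> pd.DataFrame:
    """Pearson coefficient of the active enzymes over a (T_1T, σ) grid."""
    from .two_target import pearson

    rows = []
    for sigma in sigma_values:
        noise = (
            ExtrinsicNoiseSpec.gaussian(st_mean, float(sigma))
            if sigma > 0
            else ExtrinsicNoiseSpec.point(st_mean)
        )
        for t1_t in t1t_values:
            params = TwoEnzymeParams(
                int(t1_t), k1_d, a1, int(t2_t), k2_d, a2, int(round(st_mean))
            )
            joint = active_pair_joint(params, noise)
            rows.append(
                {"t1_t": int(t1_t), "sigma": float(sigma), "rho": pearson(joint)}
            )
    return pd.DataFrame(rows)
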