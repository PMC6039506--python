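"""Exact steady state of the minimal sequestration network.

One target species ``T`` binds reversibly to one sequestrant ``S``,

    T + S  <-> complex        (binding k_+, unbinding k_-)

with both total copy numbers conserved (``T_T = T + complex``,
``S_T = S + complex``).  The free-target count is then the single stochastic
degree of freedom.  Because the network is reversible and one-dimensional,
detailed balance holds and the stationary law of the chemical master
equation is available in closed form,

    P(T) ∝ (K^d)^T · C(T_T, T) / [S_T − (T_T − T)]!

on the support ``T ∈ [max(0, T_T − S_T), T_T]``, where ``K^d = k_-/k_+`` is
the dissociation constant in molecule-number units.  All combinatorics are
evaluated through log-gamma and normalized by log-sum-exp, so copy numbers
of order 10^4 remain finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .distributions import DiscreteDistribution

__all__ = [
    "SequestrationParams",
    "support_range",
    "deterministic_free_target",
    "steady_state_distribution",
    "analytic_mean",
    "log_gain",
]


@dataclass(frozen=True)
class SequestrationParams:
    """Totals and affinity of one target/sequestrant pair.

    Parameters
    ----------
    t_t, s_t : int
        Total (free + bound) copy numbers of target and sequestrant.
    k_d : float
        Dissociation constant ``k_- / k_+`` in molecule-number units.
        Small ``k_d`` means strong binding and a sharp titration threshold.
    k_plus, k_minus : float, optional
        Individual rates, only needed by the stochastic simulator; the
        steady state depends on them through ``k_d`` alone.
    """

    t_t: int
    s_t: int
    k_d: float
    k_plus: float | None = None
    k_minus: float | None = None

    def __post_init__(self) -> None:
        if self.t_t < 0 or self.s_t < 0:
            raise ValueError("total copy numbers must be nonnegative")
        if not (self.k_d > 0):
            raise ValueError("dissociation constant must be positive")
        if (self.k_plus is None) != (self.k_minus is None):
            raise ValueError("k_plus and k_minus must be given together")
        if self.k_plus is not None:
            if self.k_plus <= 0 or self.k_minus <= 0:
                raise ValueError("rates must be positive")
            if abs(self.k_d - self.k_minus / self.k_plus) > 1e-12 * self.k_d:
                raise ValueError("k_d must equal k_minus / k_plus")


def support_range(params: SequestrationParams) -> tuple[int, int]:
    """Smallest and largest possible free-target counts.

    When the sequestrant outnumbers the target every target molecule can be
    bound (``T_min = 0``); otherwise ``T_T − S_T`` targets are always free.
    """
    return max(0, params.t_t - params.s_t), params.t_t


def deterministic_free_target(params: SequestrationParams) -> float:
    """Mass-action (rate-equation) steady state for the free-target count.

    Root of the quadratic fixed-point equation,
    ``2T = T_T − S_T − K^d + sqrt((T_T − S_T − K^d)² + 4·K^d·T_T)``,
    evaluated in the cancellation-free branch.
    """
    t_t, s_t, k = float(params.t_t), float(params.s_t), params.k_d
    b = t_t - s_t - k
    disc = math.sqrt(b * b + 4.0 * k * t_t)
    if b >= 0:
        return 0.5 * (b + disc)
    if disc == b:  # t_t == 0
        return 0.0
    return 2.0 * k * t_t / (disc - b)


def _log_weights(params: SequestrationParams) -> tuple[int, np.ndarray]:
    t_min, t_max = support_range(params)
    t = np.arange(t_min, t_max + 1)
    log_w = (
        t * math.log(params.k_d)
        + gammaln(params.t_t + 1)
        - gammaln(t + 1)
        - gammaln(params.t_t - t + 1)
        - gammaln(params.s_t - params.t_t + t + 1)
    )
    return t_min, log_w


def steady_state_distribution(params: SequestrationParams) -> DiscreteDistribution:
    """Exact stationary law of the free-target copy number.

    Degenerate pools (``T_T = 0`` or ``S_T = 0``) return the forced point
    mass rather than erroring; they are legitimate boundary models.
    """
    t_min, log_w = _log_weights(params)
    return DiscreteDistribution.from_log_weights(t_min, log_w)


def _log_1f1_terminating(n: int, b: float, k: float) -> float:
    """log of ₁F₁(−n, b; −k) for integer n ≥ 0, b > 0, k > 0.

    The series terminates after n+1 terms and, at a negative argument,
    every term  (n)_k↓ · k^j / ((b)_j · j!)  is positive, so the sum is
    evaluated in log space with no cancellation.
    """
    if n == 0:
        return 0.0
    j = np.arange(n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(n - j + 1)
        + j * math.log(k)
        - (gammaln(b + j) - gammaln(b))
        - gammaln(j + 1)
    )
    return float(logsumexp(log_terms))


def analytic_mean(params: SequestrationParams) -> float:
    """Mean free-target count via terminating confluent-hypergeometric sums.

    Two branches, for the repressed-capable (``T_T ≤ S_T``) and always-free
    (``T_T > S_T``) regimes; each is a ratio of ₁F₁ values with
    negative-integer first argument, i.e. finite polynomials in ``K^d``.
    """
    t_t, s_t, k = params.t_t, params.s_t, params.k_d
    if t_t == 0:
        return 0.0
    if s_t == 0:
        return float(t_t)
    if t_t <= s_t:
        b_den = s_t - t_t + 1
        log_mean = (
            math.log(k)
            + math.log(t_t)
            - math.log(b_den)
            + _log_1f1_terminating(t_t - 1, b_den + 1, k)
            - _log_1f1_terminating(t_t, b_den, k)
        )
        return math.exp(log_mean)
    d = t_t - s_t
    log_ratio = _log_1f1_terminating(s_t, float(d), k) - _log_1f1_terminating(
        s_t, float(d + 1), k
    )
    return d * math.exp(log_ratio)


def log_gain(
    tt_values: np.ndarray, s_t: int, k_d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Logarithmic gain d ln⟨T⟩ / d ln T_T along a sweep of the total target.

    The maximum of this gain over the sweep is the effective Hill
    coefficient of the titration response; values above 1 near the
    equimolar point signal ultrasensitivity.

    Returns
    -------
    (tt_values, gain) arrays of equal length.
    """
    tt = np.asarray(tt_values, dtype=int)
    if np.any(tt <= 0):
        raise ValueError("total target counts must be positive for log gain")
    means = np.array(
        [analytic_mean(SequestrationParams(int(t), s_t, k_d)) for t in tt]
    )
    gain = np.gradient(np.log(means), np.log(tt.astype(float)))
    return tt, gain
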