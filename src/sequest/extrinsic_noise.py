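"""Static extrinsic noise on the sequestrant pool and its consequences.

Cell-to-cell variability of the total sequestrant ``S_T`` is modeled as a
static mixture: each realization draws ``S_T`` from a discretised law
(truncated-renormalized Gaussian, uniform, or a point mass) and the
observed target distribution is the superposition of the conditional
stationary laws weighted by that noise law (law of total probability),

    P(T) = Σ_{S_T} P(T | S_T) · P(S_T).

Near the titration threshold this mixture can become bimodal even though
every conditional law is unimodal: realizations with ``S_T > T_T`` pile up
in a repressed peak near zero while realizations with ``S_T < T_T``
contribute a broad unrepressed peak.  This module provides the noise laws,
the mixer, a strict-local-maximum mode counter, and the grid scan that maps
out the bimodal region in the ``(T_T, σ)`` plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .distributions import DiscreteDistribution, JointDistribution, mix_discrete, mix_joint

__all__ = [
    "ExtrinsicNoiseSpec",
    "discretise_noise",
    "mix_over_sequestrant",
    "mix_joint_over_sequestrant",
    "count_modes",
    "BimodalityScanResult",
    "bimodality_scan",
]

# per-point weights below this fraction of the peak are dropped from the
# discretised Gaussian; bounds the infinite total-probability sum with an
# error far below any test tolerance
_WEIGHT_CUTOFF = 1e-16


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """A noise law for the total sequestrant copy number.

    ``family`` is one of ``"gaussian"`` (mean/sigma, truncated to s ≥ 0 and
    renormalized), ``"uniform"`` (equal weights on integers in [lo, hi]) or
    ``"point"`` (no extrinsic noise; unit mass at round(mean)).
    """

    family: str
    mean: float | None = None
    sigma: float | None = None
    lo: int | None = None
    hi: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform", "point"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family in ("gaussian", "point"):
            if self.mean is None or self.mean < 0:
                raise ValueError("mean must be a nonnegative real")
        if self.family == "gaussian":
            if self.sigma is None or self.sigma < 0:
                raise ValueError("sigma must be a nonnegative real")
        if self.family == "uniform":
            if self.lo is None or self.hi is None or not (0 <= self.lo <= self.hi):
                raise ValueError("uniform noise requires 0 <= lo <= hi")

    @classmethod
    def gaussian(cls, mean: float, sigma: float) -> "ExtrinsicNoiseSpec":
        return cls("gaussian", mean=mean, sigma=sigma)

    @classmethod
    def uniform(cls, lo: int, hi: int) -> "ExtrinsicNoiseSpec":
        return cls("uniform", lo=lo, hi=hi)

    @classmethod
    def point(cls, mean: float) -> "ExtrinsicNoiseSpec":
        return cls("point", mean=mean)


def discretise_noise(spec: ExtrinsicNoiseSpec) -> DiscreteDistribution:
    """Discretise a noise law onto the nonnegative integers."""
    if spec.family == "uniform":
        n = spec.hi - spec.lo + 1
        return DiscreteDistribution(spec.lo, np.full(n, 1.0 / n))
    if spec.family == "point" or spec.sigma == 0:
        return DiscreteDistribution.point(round(spec.mean))
    s_hi = math.ceil(spec.mean + 10.0 * spec.sigma)
    s = np.arange(0, s_hi + 1)
    log_w = -((s - spec.mean) ** 2) / (2.0 * spec.sigma**2)
    w = np.exp(log_w - log_w.max())
    keep = np.nonzero(w >= _WEIGHT_CUTOFF)[0]
    if keep.size == 0:
        raise ValueError("discretised noise law has empty support")
    lo, hi = keep[0], keep[-1]
    w = w[lo : hi + 1]
    return DiscreteDistribution(int(s[lo]), w / w.sum())


def mix_over_sequestrant(
    solve: Callable[[int], DiscreteDistribution],
    noise: DiscreteDistribution,
) -> DiscreteDistribution:
    """Superpose conditional laws ``P(·|S_T)`` under a noise law on ``S_T``."""
    comps, weights = [], []
    for s, w in zip(noise.support, noise.probs):
        if w == 0.0:
            continue
        try:
            comps.append(solve(int(s)))
        except Exception as exc:
            raise RuntimeError(f"conditional solver failed at S_T={int(s)}") from exc
        weights.append(w)
    return mix_discrete(comps, np.asarray(weights) / np.sum(weights))


def mix_joint_over_sequestrant(
    solve: Callable[[int], JointDistribution],
    noise: DiscreteDistribution,
) -> JointDistribution:
    """Same superposition for joint tables (any number of axes)."""
    comps, weights = [], []
    for s, w in zip(noise.support, noise.probs):
        if w == 0.0:
            continue
        try:
            comps.append(solve(int(s)))
        except Exception as exc:
            raise RuntimeError(f"conditional solver failed at S_T={int(s)}") from exc
        weights.append(w)
    return mix_joint(comps, np.asarray(weights) / np.sum(weights))


def count_modes(dist: DiscreteDistribution, rel_tol: float = 1e-12) -> int:
    """Number of strict local maxima of a discrete probability vector.

    Values outside the support count as zero, so a boundary maximum is a
    mode.  A flat plateau (consecutive values equal within ``rel_tol``)
    flanked by strictly smaller neighbours counts once.  No prominence
    threshold is applied; ``rel_tol`` only guards against floating-point
    ties.
    """
    v = np.concatenate(([0.0], dist.probs, [0.0]))

    def gt(a: float, b: float) -> bool:
        return a > b * (1.0 + rel_tol)

    n = v.size
    modes = 0
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n - 1 and not gt(v[j + 1], v[i]) and not gt(v[i], v[j + 1]):
            j += 1
        if gt(v[i], v[i - 1]) and gt(v[j], v[j + 1]):
            modes += 1
        i = j + 1
    return modes


@dataclass(frozen=True)
class BimodalityScanResult:
    """Mode counts on a ``(T_T, σ)`` grid and the bimodal-region boundary."""

    tt_values: np.ndarray
    sigma_values: np.ndarray
    mode_counts: np.ndarray  # shape (len(tt_values), len(sigma_values))
    boundary: tuple[tuple[int, float], ...]
    st_mean: float

    def bimodal_area(self) -> int:
        """Number of grid nodes with exactly two modes."""
        return int(np.sum(self.mode_counts == 2))

    def is_bimodal(self, t_t: int, sigma: float) -> bool:
        i = int(np.nonzero(self.tt_values == t_t)[0][0])
        j = int(np.argmin(np.abs(self.sigma_values - sigma)))
        return bool(self.mode_counts[i, j] == 2)


def _region_boundary(
    tt_values: np.ndarray, sigma_values: np.ndarray, counts: np.ndarray
) -> tuple[tuple[int, float], ...]:
    inside = counts == 2
    boundary = []
    ni, nj = counts.shape
    for i in range(ni):
        for j in range(nj):
            if not inside[i, j]:
                continue
            edge = i in (0, ni - 1) or j in (0, nj - 1)
            if not edge:
                edge = not (
                    inside[i - 1, j]
                    and inside[i + 1, j]
                    and inside[i, j - 1]
                    and inside[i, j + 1]
                )
            if edge:
                boundary.append((int(tt_values[i]), float(sigma_values[j])))
    return tuple(boundary)


def bimodality_scan(
    solve_conditional: Callable[[int, int], DiscreteDistribution],
    tt_values: Sequence[int],
    st_mean: float,
    sigma_values: Sequence[float] | None = None,
    *,
    sigma_max: float = 13.0,
    dsigma: float = 0.25,
    rel_tol: float = 1e-12,
) -> BimodalityScanResult:
    """Count modes of the Gaussian-noise mixture on a ``(T_T, σ)`` grid.

    Parameters
    ----------
    solve_conditional : callable ``(t_t, s_t) -> DiscreteDistribution``
        Conditional stationary law of the observable of interest for a
        fixed total sequestrant.
    tt_values : sequence of int
        Grid along the total target, default step 1.
    st_mean : float
        Mean of the Gaussian noise on ``S_T``.
    sigma_values : sequence of float, optional
        Noise-level grid; default ``0, dsigma, …, sigma_max``.

    The conditional laws are computed once per ``(T_T, S_T)`` pair and
    reused across every noise level.
    """
    tt_values = np.asarray(list(tt_values), dtype=int)
    if sigma_values is None:
        sigma_values = np.arange(0.0, sigma_max + dsigma / 2, dsigma)
    sigma_values = np.asarray(list(sigma_values), dtype=float)
    if tt_values.size == 0 or sigma_values.size == 0:
        raise ValueError("empty scan ranges")

    noises = [discretise_noise(ExtrinsicNoiseSpec.gaussian(st_mean, s)) for s in sigma_values]
    s_needed = sorted({int(s) for nz in noises for s in nz.support})

    counts = np.zeros((tt_values.size, sigma_values.size), dtype=int)
    for i, tt in enumerate(tt_values):
        cond = {s: solve_conditional(int(tt), s) for s in s_needed}
        for j, noise in enumerate(noises):
            mixed = mix_over_sequestrant(lambda s: cond[s], noise)
            counts[i, j] = count_modes(mixed, rel_tol=rel_tol)

    boundary = _region_boundary(tt_values, sigma_values, counts)
    return BimodalityScanResult(tt_values, sigma_values, counts, boundary, float(st_mean))
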