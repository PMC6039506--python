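"""Discrete probability containers shared by every solver in the package.

Two containers cover everything the sequestration models produce:

* :class:`DiscreteDistribution` — a probability vector over consecutive
  integers (e.g. the free-target copy number ``T``).
* :class:`JointDistribution` — a dense probability table over a rectangular
  integer grid of one or more axes (e.g. ``(T_1, T_2)`` or the four-axis
  ``(T_1A, C_1, T_2A, C_2)`` table of the two-enzyme model).  Infeasible
  states carry exact zeros.

Both are normalized at construction; builders work in log space and only
exponentiate after a max shift, so the containers never see overflowed
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DiscreteDistribution",
    "JointDistribution",
    "mix_discrete",
    "mix_joint",
    "total_variation",
]

_SUM_TOL = 1e-8


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probabilities over consecutive integers starting at ``offset``."""

    offset: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a nonempty 1-D vector")
        if np.any(probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if not np.isfinite(total) or abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "offset", int(self.offset))
        object.__setattr__(self, "probs", probs)

    @classmethod
    def point(cls, value: int) -> "DiscreteDistribution":
        return cls(int(value), np.array([1.0]))

    @classmethod
    def from_log_weights(cls, offset: int, log_w: np.ndarray) -> "DiscreteDistribution":
        log_w = np.asarray(log_w, dtype=float)
        p = np.exp(log_w - logsumexp(log_w))
        return cls(offset, p / p.sum())

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + self.probs.size)

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def variance(self) -> float:
        m = self.mean()
        return float(((self.support - m) ** 2) @ self.probs)

    def prob(self, value: int) -> float:
        i = int(value) - self.offset
        if 0 <= i < self.probs.size:
            return float(self.probs[i])
        return 0.0


@dataclass(frozen=True)
class JointDistribution:
    """Dense probability table over a rectangular integer grid.

    ``offsets[k]`` is the integer value of index 0 along axis ``k``; entries
    outside the feasible region of the underlying model are exactly zero.
    """

    offsets: tuple[int, ...]
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        offsets = tuple(int(o) for o in self.offsets)
        if table.ndim != len(offsets):
            raise ValueError("one offset per table axis is required")
        if np.any(table < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        table = np.clip(table, 0.0, None)
        total = table.sum()
        if not np.isfinite(total) or abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "table", table)

    @property
    def ndim(self) -> int:
        return self.table.ndim

    def axis_support(self, axis: int) -> np.ndarray:
        return np.arange(self.offsets[axis], self.offsets[axis] + self.table.shape[axis])

    def marginal(self, axis: int) -> DiscreteDistribution:
        other = tuple(a for a in range(self.ndim) if a != axis)
        p = self.table.sum(axis=other)
        return DiscreteDistribution(self.offsets[axis], p / p.sum())

    def project(self, axes: Sequence[int]) -> "JointDistribution":
        axes = tuple(axes)
        drop = tuple(a for a in range(self.ndim) if a not in axes)
        # summing preserves the relative order of kept axes; reorder to `axes`
        kept_order = tuple(sorted(axes))
        perm = tuple(kept_order.index(a) for a in axes)
        q = self.table.sum(axis=drop).transpose(perm)
        return JointDistribution(tuple(self.offsets[a] for a in axes), q / q.sum())

    def mean(self, axis: int) -> float:
        return float(self.axis_support(axis) @ self.marginal(axis).probs)


def _mix_aligned(
    offsets: list[tuple[int, ...]],
    tables: list[np.ndarray],
    weights: np.ndarray,
) -> tuple[tuple[int, ...], np.ndarray]:
    ndim = tables[0].ndim
    lo = tuple(min(o[a] for o in offsets) for a in range(ndim))
    hi = tuple(
        max(o[a] + t.shape[a] for o, t in zip(offsets, tables)) for a in range(ndim)
    )
    out = np.zeros(tuple(h - l for l, h in zip(lo, hi)))
    for o, t, w in zip(offsets, tables, weights):
        if w == 0.0:
            continue
        sl = tuple(slice(o[a] - lo[a], o[a] - lo[a] + t.shape[a]) for a in range(ndim))
        out[sl] += w * t
    return lo, out


def mix_discrete(
    components: Sequence[DiscreteDistribution], weights: Sequence[float]
) -> DiscreteDistribution:
    """Convex combination of distributions, supports aligned on the integers."""
    w = np.asarray(weights, dtype=float)
    if len(components) != w.size or w.size == 0:
        raise ValueError("need one weight per component")
    if np.any(w < 0) or abs(w.sum() - 1.0) > _SUM_TOL:
        raise ValueError("weights must be a probability vector")
    lo, out = _mix_aligned(
        [(c.offset,) for c in components], [c.probs for c in components], w
    )
    return DiscreteDistribution(lo[0], out / out.sum())


def mix_joint(
    components: Sequence[JointDistribution], weights: Sequence[float]
) -> JointDistribution:
    """Convex combination of joint tables, axes aligned on the integer grid."""
    w = np.asarray(weights, dtype=float)
    if len(components) != w.size or w.size == 0:
        raise ValueError("need one weight per component")
    if np.any(w < 0) or abs(w.sum() - 1.0) > _SUM_TOL:
        raise ValueError("weights must be a probability vector")
    lo, out = _mix_aligned(
        [c.offsets for c in components], [c.table for c in components], w
    )
    return JointDistribution(lo, out / out.sum())


def total_variation(
    a: DiscreteDistribution | JointDistribution,
    b: DiscreteDistribution | JointDistribution,
) -> float:
    """Total-variation distance ``½·Σ|p−q|`` between two aligned laws."""
    if isinstance(a, DiscreteDistribution):
        offs_a, tab_a = (a.offset,), a.probs
    else:
        offs_a, tab_a = a.offsets, a.table
    if isinstance(b, DiscreteDistribution):
        offs_b, tab_b = (b.offset,), b.probs
    else:
        offs_b, tab_b = b.offsets, b.table
    if len(offs_a) != len(offs_b):
        raise ValueError("distributions have different dimensionality")
    _, diff = _mix_aligned([offs_a, offs_b], [tab_a, -tab_b], np.array([1.0, 1.0]))
    return 0.5 * float(np.abs(diff).sum())
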