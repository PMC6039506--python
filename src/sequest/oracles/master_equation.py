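"""Exhaustive master-equation steady states by generator null-space solve.

For networks whose conservation laws bound the reachable state space, the
full generator can be enumerated and the stationary distribution obtained
as the (unique, for these irreducible reversible networks) normalized null
vector of its transpose.  This is the package's independent ground truth:
it knows nothing about the closed-form solutions it validates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..distributions import DiscreteDistribution, JointDistribution
from .networks import ReactionNetwork

__all__ = [
    "enumerate_states",
    "me_steady_state",
    "steady_state_marginal",
    "steady_state_joint",
]


def enumerate_states(
    network: ReactionNetwork, *, max_states: int = 2_000_000
) -> np.ndarray:
    """All nonnegative integer states satisfying every conservation law.

    Deterministic lexicographic order over the species tuple.
    """
    idx = {s: i for i, s in enumerate(network.species)}
    n_sp = len(network.species)
    laws = []
    for coeffs, total in network.conservation_laws:
        vec = np.zeros(n_sp, dtype=np.int64)
        for s, c in coeffs:
            vec[idx[s]] = c
        laws.append((vec, int(total)))

    states: list[tuple[int, ...]] = []
    x = np.zeros(n_sp, dtype=np.int64)

    def bound(i: int, remaining: list[int]) -> int:
        b = None
        for (vec, _), rem in zip(laws, remaining):
            if vec[i] > 0:
                cap = rem // vec[i]
                b = cap if b is None else min(b, cap)
        # species not covered by any law would be unbounded; the four model
        # networks cover every species
        if b is None:
            raise ValueError(f"species {network.species[i]} is not bounded by any law")
        return b

    def rec(i: int, remaining: list[int]) -> None:
        if i == n_sp:
            if all(r == 0 for r in remaining):
                if len(states) >= max_states:
                    raise ValueError(f"state count exceeds guard of {max_states}")
                states.append(tuple(int(v) for v in x))
            return
        for v in range(bound(i, remaining) + 1):
            x[i] = v
            rec(i + 1, [r - law[0][i] * v for law, r in zip(laws, remaining)])
        x[i] = 0

    rec(0, [total for _, total in laws])
    return np.array(states, dtype=np.int64)


def _propensities(network: ReactionNetwork, states: np.ndarray) -> np.ndarray:
    """Mass-action propensity of every reaction at every state."""
    reactants = network.reactant_matrix()
    rates = network.rates()
    n, n_rxn = states.shape[0], rates.size
    a = np.tile(rates, (n, 1))
    for j in range(n_rxn):
        for i in range(states.shape[1]):
            for m in range(reactants[j, i]):
                a[:, j] *= states[:, i] - m
    return np.clip(a, 0.0, None)


def me_steady_state(
    network: ReactionNetwork, *, max_states: int = 2_000_000
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary distribution over the enumerated state space.

    Returns ``(states, probs)`` with states in lexicographic order.  The
    linear system ``Qᵀ p = 0`` with the normalization row appended is
    solved sparsely; a residual above tolerance raises.
    """
    states = enumerate_states(network, max_states=max_states)
    n = states.shape[0]
    if n == 1:
        return states, np.array([1.0])
    index = {tuple(s): i for i, s in enumerate(states)}
    change = network.change_matrix()
    a = _propensities(network, states)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for j in range(change.shape[0]):
        nz = np.nonzero(a[:, j] > 0)[0]
        for i in nz:
            target = tuple(states[i] + change[j])
            k = index[target]  # conservation + positive propensity => feasible
            rows.append(k)
            cols.append(i)
            vals.append(a[i, j])
            diag[i] -= a[i, j]
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    qt = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    sys = qt.tolil()
    sys[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    p = spla.spsolve(sys.tocsc(), b)

    residual = float(np.max(np.abs(qt @ p)))
    scale = float(np.max(np.abs(a))) if a.size else 1.0
    if not np.isfinite(p).all() or residual > 1e-9 * max(scale, 1.0):
        raise RuntimeError(
            f"null-space solve failed (residual {residual:.3e}); the "
            "generator may be singular beyond tolerance"
        )
    if np.min(p) < -1e-12:
        raise RuntimeError("stationary solution has significantly negative entries")
    p = np.clip(p, 0.0, None)
    return states, p / p.sum()


def _dense_box(
    states: np.ndarray, probs: np.ndarray, axes: tuple[int, ...]
) -> tuple[tuple[int, ...], np.ndarray]:
    sub = states[:, list(axes)]
    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    table = np.zeros(tuple(hi - lo + 1))
    np.add.at(table, tuple((sub - lo).T), probs)
    return tuple(int(v) for v in lo), table


def steady_state_marginal(network: ReactionNetwork, species: str) -> DiscreteDistribution:
    """Stationary marginal law of one species."""
    states, probs = me_steady_state(network)
    axis = network.species.index(species)
    lo, table = _dense_box(states, probs, (axis,))
    return DiscreteDistribution(lo[0], table / table.sum())


def steady_state_joint(
    network: ReactionNetwork, species: tuple[str, ...]
) -> JointDistribution:
    """Stationary joint law of a tuple of species (dense bounding box)."""
    states, probs = me_steady_state(network)
    axes = tuple(network.species.index(s) for s in species)
    lo, table = _dense_box(states, probs, axes)
    return JointDistribution(lo, table / table.sum())
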