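"""Gillespie direct-method sampler for the sequestration networks.

Stochastic realizations of the same mass-action dynamics the analytic
modules solve, used as a statistical cross-check.  Time units are set by
the unbinding rate (the builders default to ``k_- = 1``), with defaults of
50 time units of burn-in and one sample every 5 units; relaxation of these
small reversible networks is fast on that scale and the stationarity test
guards the choice.  The inner loop is jit-compiled when numba is
available and runs as plain Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..distributions import DiscreteDistribution, JointDistribution
from .networks import ReactionNetwork

__all__ = ["SSAConfig", "gillespie_sample", "empirical_joint", "empirical_marginal"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class SSAConfig:
    """Sampling plan for one simulation; the seed is mandatory."""

    seed: int
    n_samples: int
    burn_in_time: float = 50.0
    sample_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.burn_in_time < 0:
            raise ValueError("burn_in_time must be nonnegative")


@njit(cache=False)
def _direct_method(reactants, change, rates, x0, burn_in, n_samples, interval, seed):
    np.random.seed(seed)
    n_sp = x0.shape[0]
    n_rxn = rates.shape[0]
    x = x0.copy()
    out = np.empty((n_samples, n_sp), dtype=np.int64)
    a = np.empty(n_rxn)
    t = 0.0
    next_sample = burn_in
    k = 0
    while k < n_samples:
        a0 = 0.0
        for j in range(n_rxn):
            aj = rates[j]
            for i in range(n_sp):
                for m in range(reactants[j, i]):
                    aj *= x[i] - m
            if aj < 0.0:
                aj = 0.0
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            # absorbing state: the chain stays here forever
            while k < n_samples:
                for i in range(n_sp):
                    out[k, i] = x[i]
                k += 1
            break
        tau = -np.log(np.random.random()) / a0
        while t + tau >= next_sample and k < n_samples:
            for i in range(n_sp):
                out[k, i] = x[i]
            k += 1
            next_sample += interval
        t += tau
        u = np.random.random() * a0
        acc = 0.0
        for j in range(n_rxn):
            acc += a[j]
            if u <= acc:
                for i in range(n_sp):
                    x[i] += change[j, i]
                break
    return out


def gillespie_sample(network: ReactionNetwork, config: SSAConfig) -> np.ndarray:
    """Sampled state counts, one row per sample, columns in species order.

    Samples are taken every ``sample_interval`` after ``burn_in_time``;
    integer arithmetic keeps the conservation laws exact at every sample.
    """
    out = _direct_method(
        network.reactant_matrix(),
        network.change_matrix(),
        network.rates(),
        np.array(network.initial_state, dtype=np.int64),
        float(config.burn_in_time),
        int(config.n_samples),
        float(config.sample_interval),
        int(config.seed),
    )
    return out


def empirical_marginal(
    samples: np.ndarray, network: ReactionNetwork, species: str
) -> DiscreteDistribution:
    """Empirical law of one species from SSA samples."""
    col = samples[:, network.species.index(species)]
    lo, hi = int(col.min()), int(col.max())
    counts = np.bincount(col - lo, minlength=hi - lo + 1).astype(float)
    return DiscreteDistribution(lo, counts / counts.sum())


def empirical_joint(
    samples: np.ndarray, network: ReactionNetwork, species: tuple[str, ...]
) -> JointDistribution:
    """Empirical joint law of a species tuple from SSA samples."""
    cols = samples[:, [network.species.index(s) for s in species]]
    lo = cols.min(axis=0)
    hi = cols.max(axis=0)
    table = np.zeros(tuple(hi - lo + 1))
    np.add.at(table, tuple((cols - lo).T), 1.0)
    return JointDistribution(tuple(int(v) for v in lo), table / table.sum())
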