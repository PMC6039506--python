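"""Mass-action reaction networks for the sequestration models.

A :class:`ReactionNetwork` carries species names, per-reaction reactant and
product stoichiometries with mass-action rate constants, the conservation
laws with their totals, and a feasible initial state.  Builders are
provided for the four networks the package solves analytically, so the
enumerated master-equation solver and the Gillespie simulator can act as
independent ground truth for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "single_target_network",
    "two_target_network",
    "inhibition_network",
    "two_enzyme_network",
]


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float

    @classmethod
    def make(
        cls, reactants: Mapping[str, int], products: Mapping[str, int], rate: float
    ) -> "Reaction":
        if rate < 0:
            raise ValueError("rate constants must be nonnegative")
        return cls(tuple(sorted(reactants.items())), tuple(sorted(products.items())), rate)


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    conservation_laws: tuple[tuple[tuple[tuple[str, int], ...], int], ...]
    initial_state: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.species)}
        if len(idx) != len(self.species):
            raise ValueError("duplicate species names")
        change = self.change_matrix()
        for coeffs, total in self.conservation_laws:
            vec = np.zeros(len(self.species))
            for s, c in coeffs:
                vec[idx[s]] = c
            if np.any(change @ vec != 0):
                raise ValueError(f"conservation law {dict(coeffs)} is not invariant")
            if int(vec @ np.array(self.initial_state)) != total:
                raise ValueError("initial state violates a conservation law")
        if len(self.initial_state) != len(self.species) or min(self.initial_state) < 0:
            raise ValueError("initial state must be a nonnegative count per species")

    def _matrix(self, which: str) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        m = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for s, c in getattr(rxn, which):
                m[j, idx[s]] += c
        return m

    def reactant_matrix(self) -> np.ndarray:
        return self._matrix("reactants")

    def change_matrix(self) -> np.ndarray:
        return self._matrix("products") - self._matrix("reactants")

    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.reactions])


def single_target_network(
    t_t: int, s_t: int, k_d: float, k_minus: float = 1.0
) -> ReactionNetwork:
    """T + S <-> complex; totals of target and sequestrant conserved."""
    k_plus = k_minus / k_d
    return ReactionNetwork(
        species=("T", "S", "C"),
        reactions=(
            Reaction.make({"T": 1, "S": 1}, {"C": 1}, k_plus),
            Reaction.make({"C": 1}, {"T": 1, "S": 1}, k_minus),
        ),
        conservation_laws=(
            ((("C", 1), ("T", 1)), t_t),
            ((("C", 1), ("S", 1)), s_t),
        ),
        initial_state=(t_t, s_t, 0),
    )


def two_target_network(
    t1_t: int,
    t2_t: int,
    s_t: int,
    k1_d: float,
    k2_d: float,
    k1_minus: float = 1.0,
    k2_minus: float = 1.0,
) -> ReactionNetwork:
    """Two targets competing for one sequestrant pool."""
    return ReactionNetwork(
        species=("T1", "T2", "S", "C1", "C2"),
        reactions=(
            Reaction.make({"T1": 1, "S": 1}, {"C1": 1}, k1_minus / k1_d),
            Reaction.make({"C1": 1}, {"T1": 1, "S": 1}, k1_minus),
            Reaction.make({"T2": 1, "S": 1}, {"C2": 1}, k2_minus / k2_d),
            Reaction.make({"C2": 1}, {"T2": 1, "S": 1}, k2_minus),
        ),
        conservation_laws=(
            ((("C1", 1), ("T1", 1)), t1_t),
            ((("C2", 1), ("T2", 1)), t2_t),
            ((("C1", 1), ("C2", 1), ("S", 1)), s_t),
        ),
        initial_state=(t1_t, t2_t, s_t, 0, 0),
    )


def inhibition_network(
    t_t: int,
    s_t: int,
    k_d: float,
    a: float,
    k_minus: float = 1.0,
    k_r: float = 1.0,
    k_cat: float = 0.0,
) -> ReactionNetwork:
    """Enzyme/inhibitor network; ``k_cat > 0`` adds slow product formation.

    Product formation ``T_A -> T_F (+ product)`` has the same state change
    as deactivation, so the quasi-equilibrium solver applies when
    ``k_cat = 0`` and the simulator covers the general case.
    """
    reactions = [
        Reaction.make({"TF": 1, "S": 1}, {"C": 1}, k_minus / k_d),
        Reaction.make({"C": 1}, {"TF": 1, "S": 1}, k_minus),
        Reaction.make({"TF": 1}, {"TA": 1}, a * k_r),  # substrate binding, c_s·k_f
        Reaction.make({"TA": 1}, {"TF": 1}, k_r),
    ]
    if k_cat > 0:
        reactions.append(Reaction.make({"TA": 1}, {"TF": 1}, k_cat))
    return ReactionNetwork(
        species=("TF", "TA", "S", "C"),
        reactions=tuple(reactions),
        conservation_laws=(
            ((("C", 1), ("TA", 1), ("TF", 1)), t_t),
            ((("C", 1), ("S", 1)), s_t),
        ),
        initial_state=(t_t, 0, s_t, 0),
    )


def two_enzyme_network(
    t1_t: int,
    t2_t: int,
    s_t: int,
    k1_d: float,
    k2_d: float,
    a1: float,
    a2: float,
    k_minus: float = 1.0,
    k_r: float = 1.0,
) -> ReactionNetwork:
    """Two enzyme species sharing one inhibitor pool (quasi-equilibrium)."""
    return ReactionNetwork(
        species=("T1F", "T1A", "C1", "T2F", "T2A", "C2", "S"),
        reactions=(
            Reaction.make({"T1F": 1, "S": 1}, {"C1": 1}, k_minus / k1_d),
            Reaction.make({"C1": 1}, {"T1F": 1, "S": 1}, k_minus),
            Reaction.make({"T1F": 1}, {"T1A": 1}, a1 * k_r),
            Reaction.make({"T1A": 1}, {"T1F": 1}, k_r),
            Reaction.make({"T2F": 1, "S": 1}, {"C2": 1}, k_minus / k2_d),
            Reaction.make({"C2": 1}, {"T2F": 1, "S": 1}, k_minus),
            Reaction.make({"T2F": 1}, {"T2A": 1}, a2 * k_r),
            Reaction.make({"T2A": 1}, {"T2F": 1}, k_r),
        ),
        conservation_laws=(
            ((("C1", 1), ("T1A", 1), ("T1F", 1)), t1_t),
            ((("C2", 1), ("T2A", 1), ("T2F", 1)), t2_t),
            ((("C1", 1), ("C2", 1), ("S", 1)), s_t),
        ),
        initial_state=(t1_t, 0, 0, t2_t, 0, 0, s_t),
    )
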