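"""Mutual information between competing targets.

With the exact joint law in hand, the dependence between the two free
counts can be quantified beyond the Pearson coefficient by

    I(T_1; T_2) = Σ P(T_1,T_2) log₂ [ P(T_1,T_2) / (P(T_1) P(T_2)) ],

in bits by default (a nats switch exists).  The Gaussian-equivalent
transform −½·log₂(1 − ρ²) gives the mutual information two jointly
Gaussian variables with the same correlation would carry, a useful
linear-dependence baseline: the discrete sequestration joints typically
carry more information than that baseline, except deep past saturation
where the joint is strongly non-Gaussian.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .distributions import JointDistribution
from .two_target import TwoTargetParams, joint_distribution, mixed_joint, pearson
from .extrinsic_noise import ExtrinsicNoiseSpec, discretise_noise

__all__ = ["mutual_information", "gaussian_equivalent_mi", "information_sweep"]

_LOG2 = math.log(2.0)


def mutual_information(joint: JointDistribution, *, units: str = "bits") -> float:
    """Mutual information of a two-axis joint; zero cells contribute zero."""
    if joint.ndim != 2:
        raise ValueError("mutual information is defined for two-axis joints")
    if units not in ("bits", "nats"):
        raise ValueError("units must be 'bits' or 'nats'")
    p = joint.table
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    outer = p1[:, None] * p2[None, :]
    mask = p > 0.0
    i_nats = float(np.sum(p[mask] * (np.log(p[mask]) - np.log(outer[mask]))))
    i_nats = max(i_nats, 0.0)  # clip the 1e-16-scale rounding residue
    return i_nats / _LOG2 if units == "bits" else i_nats


def gaussian_equivalent_mi(rho: float, *, units: str = "bits") -> float:
    """−½·log₂(1−ρ²): the MI of a bivariate Gaussian with correlation ρ.

    Returns ``inf`` for |ρ| ≥ 1 (perfect linear dependence) and ``nan``
    for an undefined ρ.
    """
    if units not in ("bits", "nats"):
        raise ValueError("units must be 'bits' or 'nats'")
    if math.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return float("inf")
    i_nats = -0.5 * math.log1p(-rho * rho)
    return i_nats / _LOG2 if units == "bits" else i_nats


def information_sweep(
    t1t_values,
    *,
    t2_t: int,
    s_t: float,
    k1_d: float,
    k2_d: float,
    sigma: float = 0.0,
) -> pd.DataFrame:
    """Pearson, MI and Gaussian-equivalent MI along a ``T_1T`` sweep."""
    if sigma > 0:
        noise = discretise_noise(ExtrinsicNoiseSpec.gaussian(s_t, sigma))
    else:
        noise = None
    rows = []
    for t1_t in t1t_values:
        params = TwoTargetParams(int(t1_t), t2_t, int(round(s_t)), k1_d, k2_d)
        joint = mixed_joint(params, noise) if noise is not None else joint_distribution(params)
        rho = pearson(joint)
        rows.append(
            {
                "t1_t": int(t1_t),
                "sigma": float(sigma),
                "rho": rho,
                "mi_bits": mutual_information(joint),
                "gauss_mi_bits": gaussian_equivalent_mi(rho),
            }
        )
    return pd.DataFrame(rows)
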