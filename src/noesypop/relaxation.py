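"""Dipolar cross-relaxation and full relaxation-matrix NOESY simulation.

The homonuclear dipolar cross-relaxation rate between two protons a distance
r apart, for isotropic tumbling with correlation time tau_c at Larmor
frequency w0, is the Solomon rate

    sigma = K * r^-6 * tau_c * [ 6/(1 + 4 w0^2 tau_c^2) - 1 ],
    K = (1/10) * (mu0 / 4 pi)^2 * hbar^2 * gamma^4,

so sigma ~ r^-6 with a sign change at w0 tau_c = sqrt(5)/2 (positive-NOE
regime for fast tumbling, negative for slow).  For a molecule exchanging
between conformers faster than relaxation, the observed rate is the
population-weighted mean over conformers, sigma_exp = sum_i sigma_i x_i.

NOESY build-ups are simulated by evolving the full relaxation matrix:
cross-peak and diagonal-peak intensity blocks are M(tau_m) = exp(-R tau_m)
with off-diagonals -sigma_ij and diagonals the like-spin auto-relaxation
rho_i (plus an optional external leakage rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .errors import DomainError, LookupLabelError

__all__ = [
    "SpectrometerContext",
    "EnsembleRates",
    "SpinSystem",
    "cross_relaxation_rate",
    "auto_relaxation_rate",
    "ensemble_rate",
    "build_relaxation_matrix",
    "evolve_magnetization",
]

HBAR = 1.054571817e-34  # J s
MU0 = 4.0e-7 * math.pi  # T m / A
GAMMA_1H = 2.6752218744e8  # rad / s / T
ANGSTROM = 1.0e-10  # m


@dataclass(frozen=True)
class SpectrometerContext:
    """Field and motion parameters entering the dipolar rates.

    ``larmor_frequency`` is the 1H Larmor frequency in rad/s (default the
    500.17 MHz field used for the bicalutamide measurements); ``tau_c`` the
    rotational correlation time in seconds.
    """

    tau_c: float
    larmor_frequency: float = 2.0 * math.pi * 500.17e6
    hbar: float = HBAR
    mu0: float = MU0
    gamma: float = GAMMA_1H

    def __post_init__(self):
        for name in ("tau_c", "larmor_frequency", "hbar", "mu0", "gamma"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def dipolar_constant(self) -> float:
        """K = (1/10)(mu0/4pi)^2 hbar^2 gamma^4, in m^6 s^-2."""
        return 0.1 * (self.mu0 / (4.0 * math.pi)) ** 2 * self.hbar ** 2 * self.gamma ** 4


def cross_relaxation_rate(r_angstrom: float, ctx: SpectrometerContext) -> float:
    """Solomon cross-relaxation rate sigma (s^-1) for a proton pair at r Å.

    Signed: positive in the extreme-narrowing regime (w0 tau_c < sqrt(5)/2),
    negative for slow tumbling, zero exactly at the crossover.
    """
    if r_angstrom <= 0:
        raise DomainError("distance must be positive")
    x2 = (ctx.larmor_frequency * ctx.tau_c) ** 2
    j_part = 6.0 / (1.0 + 4.0 * x2) - 1.0
    r6 = (r_angstrom * ANGSTROM) ** 6
    return ctx.dipolar_constant / r6 * ctx.tau_c * j_part


def auto_relaxation_rate(r_angstrom: float, ctx: SpectrometerContext) -> float:
    """Like-spin auto-relaxation contribution rho (s^-1) of one partner at r Å.

    rho = K r^-6 tau_c [1 + 3/(1 + w0^2 tau_c^2) + 6/(1 + 4 w0^2 tau_c^2)];
    the diagonal of the relaxation matrix sums this over all partners.
    """
    if r_angstrom <= 0:
        raise DomainError("distance must be positive")
    x2 = (ctx.larmor_frequency * ctx.tau_c) ** 2
    j_part = 1.0 + 3.0 / (1.0 + x2) + 6.0 / (1.0 + 4.0 * x2)
    r6 = (r_angstrom * ANGSTROM) ** 6
    return ctx.dipolar_constant / r6 * ctx.tau_c * j_part


@dataclass(frozen=True)
class EnsembleRates:
    """Per-conformer rates sigma_i with populations x_i (sum to 1)."""

    rates: tuple[float, ...]
    populations: tuple[float, ...]

    def __post_init__(self):
        s = np.asarray(self.rates, dtype=float)
        x = np.asarray(self.populations, dtype=float)
        if s.shape != x.shape or s.size == 0:
            raise DomainError("rates and populations must align and be nonempty")
        if np.any(x < 0):
            raise DomainError("populations must be nonnegative")
        if abs(x.sum() - 1.0) > 1e-9:
            raise DomainError(f"populations sum to {x.sum():.12f}, expected 1")
        object.__setattr__(self, "rates", tuple(float(v) for v in s))
        object.__setattr__(self, "populations", tuple(float(v) for v in x))


def ensemble_rate(rates: EnsembleRates) -> float:
    """Population-weighted mean cross-relaxation rate, sum_i sigma_i x_i."""
    return float(np.dot(rates.rates, rates.populations))


@dataclass
class SpinSystem:
    """Proton groups with pairwise effective distances, ready for evolution.

    ``distances`` maps frozenset({label_a, label_b}) -> Å.  ``multiplicities``
    optionally gives the number of equivalent protons behind each label; the
    inter-group transfer rate from i to j is then scaled by n_j (the group
    treated as n equivalent spins), switchable off by leaving all at 1.
    ``leakage`` is an external relaxation rate (s^-1) added to every diagonal.
    """

    labels: tuple[str, ...]
    distances: Mapping[frozenset, float]
    context: SpectrometerContext
    multiplicities: Mapping[str, int] = field(default_factory=dict)
    leakage: float = 0.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.leakage < 0:
            raise DomainError("leakage rate must be nonnegative")
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1 :]:
                key = frozenset((a, b))
                if key not in self.distances:
                    raise LookupLabelError(f"missing distance for pair {a}-{b}")
                if self.distances[key] <= 0:
                    raise DomainError(f"nonpositive distance for pair {a}-{b}")

    def distance(self, a: str, b: str) -> float:
        return self.distances[frozenset((a, b))]

    def multiplicity(self, label: str) -> int:
        return int(self.multiplicities.get(label, 1))


def build_relaxation_matrix(system: SpinSystem) -> np.ndarray:
    """Assemble the symmetric relaxation-rate matrix R (s^-1).

    R[i, j] = -sigma_ij (i != j); R[i, i] = sum_j rho_ij * n_j + leakage.
    With nonnegative leakage the matrix is diagonally dominant, since the
    auto term exceeds |sigma| distance-for-distance.
    """
    n = len(system.labels)
    r_mat = np.zeros((n, n))
    for i, a in enumerate(system.labels):
        for j, b in enumerate(system.labels):
            if i == j:
                continue
            d = system.distance(a, b)
            mult = system.multiplicity(b)
            r_mat[i, j] = -cross_relaxation_rate(d, system.context) * mult
            r_mat[i, i] += auto_relaxation_rate(d, system.context) * mult
        r_mat[i, i] += system.leakage
    return r_mat


def evolve_magnetization(
    matrix: np.ndarray, mixing_times: Sequence[float]
) -> np.ndarray:
    """Intensity blocks M(tau_m) = exp(-R tau_m), shape (n_times, n, n).

    Unit magnetization starts on each source spin; element [t, i, j] is the
    cross-peak amplitude j -> i at mixing time t (diagonal elements are the
    diagonal-peak amplitudes).  Symmetric matrices are evolved by
    eigendecomposition for determinism.
    """
    r_mat = np.asarray(matrix, dtype=float)
    if r_mat.ndim != 2 or r_mat.shape[0] != r_mat.shape[1]:
        raise DomainError("relaxation matrix must be square")
    times = np.asarray(list(mixing_times), dtype=float)
    if np.any(times < 0):
        raise DomainError("mixing times must be nonnegative")
    if np.allclose(r_mat, r_mat.T, atol=1e-12):
        vals, vecs = scipy.linalg.eigh(r_mat)
        out = np.einsum(
            "ik,tk,jk->tij", vecs, np.exp(-np.outer(times, vals)), vecs
        )
    else:  # general fall-back
        out = np.array([scipy.linalg.expm(-r_mat * t) for t in times])
    return out
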