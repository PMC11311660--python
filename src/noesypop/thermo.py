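"""Boltzmann conformer weighting and Gibbs solvation energies.

Given per-conformer free energies (gas-phase or continuum-solvent-corrected,
in kJ/mol), the thermal population of conformer i is proportional to
exp(-dG_i / RT).  Energies are re-referenced to the column minimum before
exponentiation, which changes nothing physically (weights are invariant to a
uniform shift) but keeps the arithmetic well-conditioned.

The Gibbs solvation energy of a conformer is simply the difference between
its total energy in the continuum solvent and in the gas phase (negative =
the solvent stabilizes it).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "GAS_CONSTANT_KJ",
    "HARTREE_KJ",
    "EnergyTable",
    "BoltzmannWeights",
    "gibbs_solvation",
    "boltzmann_weights",
    "hartree_to_kj_per_mol",
    "read_energy_table",
]

GAS_CONSTANT_KJ = 8.31446e-3  # kJ / mol / K
HARTREE_KJ = 2625.4996  # kJ/mol per hartree


@dataclass
class EnergyTable:
    """Per-conformer energy columns (kJ/mol) at a working temperature (K)."""

    energies: pd.DataFrame
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")
        if self.energies.shape[1] < 1:
            raise DomainError("energy table needs at least one energy column")


@dataclass(frozen=True)
class BoltzmannWeights:
    """exp(-dG/RT) factors and their normalized weights, per conformer."""

    conformer_ids: tuple[str, ...]
    factors: tuple[float, ...]
    weights: tuple[float, ...]
    column: str
    temperature: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.conformer_ids), name="weight")


def gibbs_solvation(e_solvent: float, e_gas: float) -> float:
    """dG_solv = E(solvent) - E(gas), kJ/mol; negative means stabilizing."""
    if not (np.isfinite(e_solvent) and np.isfinite(e_gas)):
        raise DomainError("energies must be finite")
    return float(e_solvent - e_gas)


def boltzmann_weights(
    table: EnergyTable, column: str, temperature: float | None = None
) -> BoltzmannWeights:
    """Normalized Boltzmann weights from one energy column.

    Raises with the offending conformer list if the column has gaps.
    """
    if column not in table.energies.columns:
        raise DomainError(
            f"no energy column {column!r}; have {list(table.energies.columns)}"
        )
    temp = table.temperature if temperature is None else float(temperature)
    if temp <= 0:
        raise DomainError("temperature must be positive")
    col = table.energies[column]
    missing = col[col.isna()].index.tolist()
    if missing:
        raise DomainError(f"missing {column!r} energies for conformers {missing}")
    d_g = col.to_numpy(float)
    factors = np.exp(-(d_g - d_g.min()) / (GAS_CONSTANT_KJ * temp))
    weights = factors / factors.sum()
    return BoltzmannWeights(
        conformer_ids=tuple(str(i) for i in col.index),
        factors=tuple(float(f) for f in factors),
        weights=tuple(float(w) for w in weights),
        column=column,
        temperature=temp,
    )


def hartree_to_kj_per_mol(e_hartree: float) -> float:
    """Explicit unit converter; energy tables themselves are kJ/mol only."""
    return float(e_hartree) * HARTREE_KJ


def read_energy_table(source, temperature: float = 298.15, sep: str = ",") -> EnergyTable:
    """Read a delimited energy table: conformer id column + named energy
    columns in kJ/mol."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, comment="#")
    df = df.set_index(df.columns[0])
    return EnergyTable(energies=df, temperature=temperature)
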