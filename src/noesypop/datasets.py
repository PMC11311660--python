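"""Packaged bicalutamide fixtures: distance tables, energies, measured rates.

These small delimited-text tables carry the published quantities the
population analysis consumes — model-averaged distances for the ten computed
conformers and the seven deposited solid-state/bioactive structures, the
gas-phase relative conformer energies, and the PANIC/IRA cross-relaxation
rates in CDCl3 and DMSO-d6 — so the headline analyses run with no downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .distances import GroupAverages, group_effective_distance, read_distance_table
from .thermo import EnergyTable, read_energy_table

__all__ = [
    "REFERENCE_PAIR_CDCL3",
    "REFERENCE_PAIR_DMSO",
    "MARKER_PAIR",
    "QC_OPEN",
    "QC_CLOSED",
    "SOLID_OPEN",
    "SOLID_CLOSED",
    "load_qc_distances",
    "load_solid_state_distances",
    "load_conformer_energies",
    "load_rates",
    "group_averages",
]

#: Conformation-independent reference pairs (per solvent) and the
#: conformation-determining marker pair.
REFERENCE_PAIR_CDCL3 = "H12a-H12b"
REFERENCE_PAIR_DMSO = "H15/17-H14/18"
MARKER_PAIR = "H12b-H14/18"

#: Open/closed families of the computed conformers (fluorine-distance rule).
QC_OPEN = ("BCL-3", "BCL-4", "BCL-5", "BCL-8", "BCL-9", "BCL-10")
QC_CLOSED = ("BCL-1", "BCL-2", "BCL-6", "BCL-7")

#: Open/closed families of the deposited structures (marker-distance rule,
#: 3.85 Å threshold).
SOLID_OPEN = ("JAYCES01", "FAHFIG", "KIHZIL", "JAYCES")
SOLID_CLOSED = ("JAYCES02", "KIHZOR", "1Z95")


def _read_csv(name: str) -> str:
    return resources.files("noesypop.data").joinpath(name).read_text()


def load_qc_distances() -> pd.DataFrame:
    """Distance table for the ten computed conformers (Å)."""
    return read_distance_table(_read_csv("qc_conformer_distances.csv"))


def load_solid_state_distances() -> pd.DataFrame:
    """Distance table for the seven deposited structures (Å)."""
    return read_distance_table(_read_csv("solid_state_distances.csv"))


def load_conformer_energies(temperature: float = 298.15) -> EnergyTable:
    """Gas-phase relative conformer energies (kJ/mol)."""
    return read_energy_table(_read_csv("conformer_energies.csv"), temperature)


def load_rates() -> pd.DataFrame:
    """Measured cross-relaxation rates (s^-1), indexed by (solvent, role)."""
    import io

    df = pd.read_csv(io.StringIO(_read_csv("cross_relaxation_rates.csv")), comment="#")
    return df.set_index(["solvent", "role"])


def group_averages(
    table: pd.DataFrame,
    marker_pair: str,
    open_ids,
    closed_ids,
    reference_pairs=(),
) -> GroupAverages:
    """r^-6 group averages of the marker column over the open/closed families,
    plus r^-6 averages of any reference columns over all rows."""
    refs = {
        pair: group_effective_distance(table[pair].to_numpy())
        for pair in reference_pairs
    }
    return GroupAverages(
        r_open=group_effective_distance(table.loc[list(open_ids), marker_pair]),
        r_close=group_effective_distance(table.loc[list(closed_ids), marker_pair]),
        reference_averages=refs,
    )
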