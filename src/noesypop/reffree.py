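"""Reference-free NOE screen: rank conformers by how well their predicted
distances explain the measured cross-relaxation rates.

For each candidate conformer, the measured rates sigma_exp are regressed on
the conformer's model-averaged distances through the one-parameter power law
sigma = A * r^-6 (linear in A, closed form).  The coefficient of
determination R^2 about the mean rate scores the conformer; data that the
inverse-sixth-power model cannot explain can score negative.  The screen is
a qualitative filter — for flexible molecules with many interconverting
conformers it typically cannot single out one structure, which is what
motivates the quantitative population analysis in
:mod:`noesypop.populations`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import DomainError, FitDegenerateError

__all__ = [
    "RateDistancePairing",
    "ConformerFit",
    "fit_inverse_sixth",
    "rank_conformers",
    "fit_report",
]


@dataclass(frozen=True)
class RateDistancePairing:
    """Matched (pair_id, r_calc, sigma_exp) points for one conformer."""

    conformer_id: str
    pair_ids: tuple[str, ...]
    r_calc: tuple[float, ...]
    sigma_exp: tuple[float, ...]

    def __post_init__(self):
        r = np.asarray(self.r_calc, float)
        s = np.asarray(self.sigma_exp, float)
        if not (len(self.pair_ids) == r.size == s.size):
            raise DomainError("pair ids, distances and rates must align")
        if r.size < 3:
            raise DomainError("need at least 3 points for a meaningful fit")
        if np.any(r <= 0):
            raise DomainError("distances must be positive")


@dataclass(frozen=True)
class ConformerFit:
    """Amplitude A (s^-1 Å^6 units) and R^2 of the sigma = A r^-6 fit."""

    conformer_id: str
    amplitude: float
    r_squared: float
    exponent: float = 6.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise DomainError("fit amplitude must be positive")


def fit_inverse_sixth(
    pairing: RateDistancePairing, free_exponent: bool = False
) -> ConformerFit:
    """Least-squares A minimizing sum (sigma_k - A r_k^-6)^2.

    Closed form A = sum(sigma r^-6) / sum(r^-12); R^2 = 1 - SS_res/SS_tot
    about the mean sigma, negative when the model fits worse than that mean.
    With ``free_exponent=True`` the exponent is also fitted (exploratory
    variant, not the default screen).
    """
    r = np.asarray(pairing.r_calc, float)
    s = np.asarray(pairing.sigma_exp, float)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    if np.ptp(s) == 0.0 and np.ptp(r) == 0.0:
        raise FitDegenerateError(
            f"{pairing.conformer_id}: all points identical; fit carries no information"
        )
    if free_exponent:
        a0 = float(np.sum(s * r ** -6.0) / np.sum(r ** -12.0))
        (amp, expo), _ = scipy.optimize.curve_fit(
            lambda rr, a, n: a * rr ** -n, r, s, p0=[max(a0, 1e-12), 6.0], maxfev=10000
        )
        pred = amp * r ** -expo
    else:
        amp = float(np.sum(s * r ** -6.0) / np.sum(r ** -12.0))
        expo = 6.0
        pred = amp * r ** -6.0
    if amp <= 0:
        raise FitDegenerateError(
            f"{pairing.conformer_id}: nonpositive amplitude (rates anticorrelate "
            "with r^-6); inverse-sixth-power model inapplicable"
        )
    ss_res = float(np.sum((s - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return ConformerFit(pairing.conformer_id, float(amp), float(r2), float(expo))


def rank_conformers(fits: Sequence[ConformerFit]) -> list[ConformerFit]:
    """Descending by R^2; ties broken by conformer id for a stable order."""
    if not fits:
        raise DomainError("no fits to rank")
    return sorted(fits, key=lambda f: (-f.r_squared, f.conformer_id))


def fit_report(fits: Sequence[ConformerFit]) -> pd.DataFrame:
    """Per-conformer R^2 report (ranked), ready for delimited-text output."""
    ranked = rank_conformers(fits)
    return pd.DataFrame(
        {
            "conformer": [f.conformer_id for f in ranked],
            "r_squared": [f.r_squared for f in ranked],
            "amplitude": [f.amplitude for f in ranked],
            "exponent": [f.exponent for f in ranked],
        }
    )
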