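"""ISPA experimental distances and two-state conformer-population inversion.

The isolated spin-pair approximation (ISPA) turns a measured rate ratio into
a distance: with a reference pair whose separation r0 is conformation-
independent and known from computed structures,

    r_exp = r0 * (sigma_0 / sigma_exp)^(1/6).

If the molecule exchanges rapidly between an "open" and a "closed" conformer
family with effective marker distances r_open and r_close, the observed
r_exp is the population-weighted r^-6 mixture, which inverts to

    P_open = r_open^6 (r_close^6 - r_exp^6) / (r_exp^6 (r_close^6 - r_open^6)).

r_exp outside [min(r_open, r_close), max(...)] makes the inversion
infeasible (P outside [0, 1]); that outcome is reported as a status, not an
exception, because it is itself a finding — it says the candidate structure
set cannot explain the measurement (as happens for bicalutamide in DMSO
against the crystallographic ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distances import GroupAverages
from .errors import DomainError, UncertaintyUndefinedError

__all__ = [
    "IspaInput",
    "ExperimentalDistance",
    "TwoStateResult",
    "ispa_distance",
    "two_state_populations",
    "population_uncertainty",
    "analytic_uncertainty",
    "forward_check",
]


@dataclass(frozen=True)
class IspaInput:
    """Reference distance r0 (Å) and the two measured rates with errors."""

    r0: float
    sigma0: float
    sigma_exp: float
    sigma0_err: float = 0.0
    sigma_exp_err: float = 0.0

    def __post_init__(self):
        if min(self.r0, self.sigma0, self.sigma_exp) <= 0:
            raise DomainError("r0 and both rates must be positive")
        if min(self.sigma0_err, self.sigma_exp_err) < 0:
            raise DomainError("rate uncertainties must be nonnegative")


@dataclass(frozen=True)
class ExperimentalDistance:
    """Conformation-determining distance from ISPA, with propagated error."""

    r_exp: float
    stderr: float = 0.0

    def __post_init__(self):
        if self.r_exp <= 0:
            raise DomainError("experimental distance must be positive")
        if self.stderr < 0:
            raise DomainError("stderr must be nonnegative")


@dataclass(frozen=True)
class TwoStateResult:
    """Open/closed fractions with feasibility status and input echo.

    When infeasible, ``p_open``/``p_close`` carry the raw out-of-range
    values for diagnostics; they still sum to 1 algebraically.
    """

    p_open: float
    p_close: float
    feasible: bool
    stderr_open: float | None = None
    r_exp: float | None = None
    r_open: float | None = None
    r_close: float | None = None


def ispa_distance(inp: IspaInput) -> ExperimentalDistance:
    """r_exp = r0 (sigma0/sigma_exp)^(1/6) with first-order error.

    The relative rate errors enter damped by the 1/6 power:
    stderr = (r_exp/6) * sqrt((d sigma0/sigma0)^2 + (d sigma_exp/sigma_exp)^2).
    """
    r_exp = inp.r0 * (inp.sigma0 / inp.sigma_exp) ** (1.0 / 6.0)
    rel = np.hypot(inp.sigma0_err / inp.sigma0, inp.sigma_exp_err / inp.sigma_exp)
    return ExperimentalDistance(r_exp=float(r_exp), stderr=float(r_exp / 6.0 * rel))


def two_state_populations(
    r_exp: ExperimentalDistance | float, groups: GroupAverages
) -> TwoStateResult:
    """Invert the two-state r^-6 mixture for the open fraction.

    Feasible iff the implied P_open lies in [0, 1] (equivalently r_exp lies
    between the two group averages); otherwise the result is flagged and the
    raw value retained.
    """
    r = r_exp.r_exp if isinstance(r_exp, ExperimentalDistance) else float(r_exp)
    if r <= 0:
        raise DomainError("experimental distance must be positive")
    ro6, rc6, re6 = groups.r_open ** 6, groups.r_close ** 6, r ** 6
    p_open = ro6 * (rc6 - re6) / (re6 * (rc6 - ro6))
    feasible = -1e-12 <= p_open <= 1.0 + 1e-12
    p_open_clipped = float(np.clip(p_open, 0.0, 1.0)) if feasible else float(p_open)
    return TwoStateResult(
        p_open=p_open_clipped,
        p_close=1.0 - p_open_clipped,
        feasible=feasible,
        r_exp=r,
        r_open=groups.r_open,
        r_close=groups.r_close,
    )


def forward_check(p_open: float, groups: GroupAverages) -> float:
    """Forward two-state mixture: r_exp from a given open fraction.

    r_exp^-6 = P_open r_open^-6 + (1 - P_open) r_close^-6 — the algebraic
    inverse of :func:`two_state_populations` on the feasible interval.
    """
    if not (0.0 <= p_open <= 1.0):
        raise DomainError("p_open must lie in [0, 1]")
    inv6 = p_open * groups.r_open ** -6.0 + (1.0 - p_open) * groups.r_close ** -6.0
    return float(inv6 ** (-1.0 / 6.0))


def population_uncertainty(
    inp: IspaInput,
    groups: GroupAverages,
    n_draws: int = 100_000,
    seed: int = 0,
    group_errs: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, int]:
    """Monte-Carlo standard deviation of P_open under the rate uncertainties.

    Rates (and optionally the group averages, via ``group_errs``) are drawn
    from independent normals truncated to positive values; infeasible draws
    are counted and excluded from the spread.  Returns (stderr_open,
    n_infeasible).  All-infeasible raises
    :class:`~noesypop.errors.UncertaintyUndefinedError`.
    """
    if n_draws < 1000:
        raise DomainError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)

    def trunc_normal(mean, sd, size):
        if sd == 0:
            return np.full(size, mean)
        x = rng.normal(mean, sd, size)
        while np.any(x <= 0):  # resample the nonphysical tail
            bad = x <= 0
            x[bad] = rng.normal(mean, sd, bad.sum())
        return x

    s0 = trunc_normal(inp.sigma0, inp.sigma0_err, n_draws)
    se = trunc_normal(inp.sigma_exp, inp.sigma_exp_err, n_draws)
    ro = trunc_normal(groups.r_open, group_errs[0], n_draws)
    rc = trunc_normal(groups.r_close, group_errs[1], n_draws)
    re = inp.r0 * (s0 / se) ** (1.0 / 6.0)
    p = ro ** 6 * (rc ** 6 - re ** 6) / (re ** 6 * (rc ** 6 - ro ** 6))
    ok = (p >= 0.0) & (p <= 1.0)
    n_bad = int((~ok).sum())
    if not ok.any():
        raise UncertaintyUndefinedError("every Monte-Carlo draw was infeasible")
    return float(np.std(p[ok])), n_bad


def analytic_uncertainty(inp: IspaInput, groups: GroupAverages) -> float:
    """First-order (delta-method) stderr of P_open, for comparison with the
    Monte-Carlo spread: |dP/dr_exp| evaluated at r_exp times its stderr."""
    dist = ispa_distance(inp)
    ro6, rc6 = groups.r_open ** 6, groups.r_close ** 6
    re = dist.r_exp
    # d/dr [ ro6 (rc6 - r^6) / (r^6 (rc6 - ro6)) ] = -6 ro6 rc6 / (r^7 (rc6 - ro6))
    dp_dr = -6.0 * ro6 * rc6 / (re ** 7 * (rc6 - ro6))
    return float(abs(dp_dr) * dist.stderr)
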