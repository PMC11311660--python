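"""NOESY peak tables, PANIC normalization, and initial-rate fitting.

A peak table holds, for every proton-group pair and mixing time, the
cross-peak intensity and the two diagonal-peak intensities.  PANIC (Peak
Amplitude Normalization for Improved Cross-relaxation) divides the cross
peak by the diagonal intensity, cancelling external relaxation losses and
linearizing the build-up; within the initial-rate approximation (IRA) the
normalized amplitude grows as a(tau_m) ~ sigma * tau_m, so the
cross-relaxation rate is the origin-constrained slope over the linear part
of the curve.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, InsufficientDataError

__all__ = [
    "PeakTable",
    "BuildupSeries",
    "RateEstimate",
    "PANIC_MODES",
    "read_peak_table",
    "write_peak_table",
    "panic_normalize",
    "ira_fit_rate",
    "apply_qc_exclusions",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pair_id", "tau_m_s", "cross", "diag_a", "diag_b")
PANIC_MODES = ("panic_geometric", "panic_single_a", "panic_single_b")

#: Default linearity window: points with normalized amplitude above this are
#: outside the initial-rate regime and are dropped from the fit.
IRA_WINDOW = 0.1


@dataclass
class PeakTable:
    """Long-format NOESY intensities with acquisition metadata.

    ``data`` columns: pair_id, tau_m_s, cross, diag_a, diag_b (+ optional
    ``excluded`` / ``qc_reason`` added by QC).  ``metadata`` carries the
    solvent tag, field frequency, and any unknown columns from the source.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"peak table missing mandatory columns {missing}")
        if (self.data["tau_m_s"] < 0).any():
            raise DomainError("negative mixing time in peak table")
        numeric = self.data[["tau_m_s", "cross", "diag_a", "diag_b"]].to_numpy(float)
        if not np.all(np.isfinite(numeric)):
            raise DomainError("non-finite intensity or mixing time in peak table")

    @property
    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["pair_id"]))


@dataclass
class BuildupSeries:
    """Normalized build-up a(tau_m) for one pair, sorted by mixing time."""

    pair_id: str
    tau: np.ndarray
    amplitude: np.ndarray
    normalization: str = "panic_geometric"
    qc_flags: set = field(default_factory=set)

    def __post_init__(self):
        order = np.argsort(self.tau)
        self.tau = np.asarray(self.tau, dtype=float)[order]
        self.amplitude = np.asarray(self.amplitude, dtype=float)[order]
        if not np.all(np.isfinite(self.amplitude)):
            raise DomainError(f"{self.pair_id}: non-finite normalized amplitude")


@dataclass(frozen=True)
class RateEstimate:
    """Fitted |sigma| with its ordinary-least-squares standard error.

    The magnitude is reported (build-up amplitudes are phased positive in
    practice); the sign convention of the underlying Solomon rate lives in
    :mod:`noesypop.relaxation`.
    """

    pair_id: str
    sigma: float
    stderr: float
    n_points: int
    qc_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.stderr < 0 or not np.isfinite(self.sigma):
            raise DomainError("invalid rate estimate")


def read_peak_table(source, sep: str = ",") -> PeakTable:
    """Read a delimited peak table with a header naming the five mandatory
    columns; unknown columns are preserved in metadata."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"peak table missing mandatory columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    meta = {}
    for c in extra:
        vals = df[c].unique()
        meta[c] = vals[0] if len(vals) == 1 else list(vals)
    return PeakTable(data=df[list(REQUIRED_COLUMNS)].copy(), metadata=meta)


def write_peak_table(table: PeakTable, path=None, sep: str = ",") -> str:
    df = table.data.copy()
    for key, val in table.metadata.items():
        if np.isscalar(val) and key not in df.columns:
            df[key] = val
    text = df.to_csv(path, sep=sep, index=False)
    return text if path is None else ""


def panic_normalize(table: PeakTable, mode: str = "panic_geometric") -> list[BuildupSeries]:
    """Normalize cross peaks by diagonal intensity, one series per pair.

    Default mode divides by the geometric mean of the two diagonals (the
    symmetric choice, halving single-diagonal distortion); the alternatives
    divide by one named diagonal.  Points with a nonpositive divisor are
    excluded per-point with a ``zero_diagonal`` flag rather than failing the
    whole series.  Pairs marked excluded by QC are skipped.
    """
    if mode not in PANIC_MODES:
        raise ConfigError(f"unknown PANIC mode {mode!r}; choose from {PANIC_MODES}")
    out: list[BuildupSeries] = []
    df = table.data
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    for pair_id, grp in df.groupby("pair_id", sort=False):
        if mode == "panic_geometric":
            divisor = np.sqrt(grp["diag_a"].to_numpy() * grp["diag_b"].to_numpy())
        elif mode == "panic_single_a":
            divisor = grp["diag_a"].to_numpy(float)
        else:
            divisor = grp["diag_b"].to_numpy(float)
        good = np.isfinite(divisor) & (divisor > 0)
        flags = set()
        if not good.all():
            flags.add("zero_diagonal")
            log.warning("%s: %d point(s) dropped (zero diagonal)", pair_id, (~good).sum())
        out.append(
            BuildupSeries(
                pair_id=pair_id,
                tau=grp["tau_m_s"].to_numpy(float)[good],
                amplitude=grp["cross"].to_numpy(float)[good] / divisor[good],
                normalization=mode,
                qc_flags=flags,
            )
        )
    return out


def ira_fit_rate(series: BuildupSeries, window: float = IRA_WINDOW) -> RateEstimate:
    """Initial-rate fit: origin-constrained slope of a(tau) over the window.

    Points with |a| <= window (and tau > 0) are kept; the slope of the
    no-intercept least-squares line is the rate, reported as a magnitude,
    with the OLS standard error.  Fewer than two usable points raises
    :class:`InsufficientDataError` carrying the series' QC flags.
    """
    if "excluded" in series.qc_flags or "t1_noise" in series.qc_flags:
        raise InsufficientDataError(
            f"{series.pair_id}: series flagged {sorted(series.qc_flags)}",
            frozenset(series.qc_flags),
        )
    keep = (np.abs(series.amplitude) <= window) & (series.tau > 0)
    tau, amp = series.tau[keep], series.amplitude[keep]
    if tau.size < 2:
        raise InsufficientDataError(
            f"{series.pair_id}: {tau.size} point(s) inside window {window}",
            frozenset(series.qc_flags | {"insufficient_points"}),
        )
    stt = float(np.dot(tau, tau))
    slope = float(np.dot(tau, amp)) / stt
    resid = amp - slope * tau
    dof = tau.size - 1
    stderr = float(np.sqrt(np.dot(resid, resid) / dof / stt)) if dof > 0 else 0.0
    return RateEstimate(
        pair_id=series.pair_id,
        sigma=abs(slope),
        stderr=stderr,
        n_points=int(tau.size),
        qc_flags=frozenset(series.qc_flags),
    )


def apply_qc_exclusions(
    table: PeakTable, rules: Mapping[str, str] | Iterable[tuple[str, str]]
) -> PeakTable:
    """Flag pairs named by QC rules (pair_id -> reason) as excluded.

    Flagged pairs stay in the table for provenance but are skipped by
    :func:`panic_normalize`; each exclusion is logged.  A rule naming an
    unknown pair is a configuration error.
    """
    rules = dict(rules)
    known = set(table.pair_ids)
    unknown = set(rules) - known
    if unknown:
        raise ConfigError(f"QC rules reference unknown pair(s): {sorted(unknown)}")
    df = table.data.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
        df["qc_reason"] = ""
    for pair_id, reason in rules.items():
        mask = df["pair_id"] == pair_id
        df.loc[mask, "excluded"] = True
        df.loc[mask, "qc_reason"] = reason
        log.info("excluding %s: %s", pair_id, reason)
    if rules and df["excluded"].all():
        log.warning("QC rules excluded every pair; no build-ups remain")
    return PeakTable(data=df, metadata=dict(table.metadata))
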