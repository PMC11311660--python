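"""Conformer geometries, proton groups, and geometric descriptors.

Coordinates are Cartesian and in angstrom throughout; no unit auto-detection.
Structures arrive as XYZ files (optionally carrying a 5th label column, so the
chemical atom numbering used in NMR assignment — H12a, H14/18 members, ... —
can travel with the coordinates) or as minimal PDB ATOM/HETATM records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, LookupLabelError, ParseError

__all__ = [
    "AtomRecord",
    "ConformerGeometry",
    "ProtonGroup",
    "HBondGeometry",
    "REGIMES",
    "parse_xyz",
    "write_xyz",
    "parse_pdb",
    "atom_distance",
    "dihedral_angle",
    "hbond_geometry",
]

#: Internal-motion regimes and the rotational-correlation-time bands they
#: denote: slow (>100 ps, aromatic CH), medium (50-100 ps, CH2), fast
#: (<50 ps, CH3).  The regime selects the distance-averaging model.
REGIMES = ("slow", "medium", "fast")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: a unique label, an element symbol, and a position in Å."""

    label: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ParseError(f"atom {self.label!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.label:
            raise ParseError("atom label must be nonempty")


@dataclass
class ConformerGeometry:
    """Labeled Cartesian atoms of one conformer, with an optional energy.

    Parameters
    ----------
    conformer_id
        Identifier such as ``"BCL-1"`` or a CSD refcode like ``"JAYCES01"``.
    atoms
        Ordered atom records; labels must be unique within the conformer.
    relative_energy
        Relative conformer energy in kJ/mol, if known.
    """

    conformer_id: str
    atoms: list[AtomRecord]
    relative_energy: float | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self._index = {}
        for i, atom in enumerate(self.atoms):
            if atom.label in self._index:
                raise ParseError(
                    f"{self.conformer_id}: duplicate atom label {atom.label!r}"
                )
            self._index[atom.label] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def position(self, label: str) -> np.ndarray:
        try:
            return self.atoms[self._index[label]].position
        except KeyError:
            raise LookupLabelError(
                f"{self.conformer_id}: no atom labeled {label!r}"
            ) from None

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([a.position for a in self.atoms])


@dataclass(frozen=True)
class ProtonGroup:
    """A set of magnetically equivalent protons.

    ``n`` is the number of equivalent protons (the n_I / n_S entering the
    distance-averaging denominators) and ``regime`` the internal-motion class
    that selects the averaging model.
    """

    group_id: str
    member_labels: tuple[str, ...]
    regime: str = "slow"

    def __post_init__(self):
        if len(self.member_labels) < 1:
            raise ParseError(f"group {self.group_id!r}: needs at least one member")
        if self.regime not in REGIMES:
            raise ParseError(
                f"group {self.group_id!r}: regime {self.regime!r} not in {REGIMES}"
            )
        object.__setattr__(self, "member_labels", tuple(self.member_labels))

    @property
    def n(self) -> int:
        return len(self.member_labels)


@dataclass(frozen=True)
class HBondGeometry:
    """Hydrogen-bond geometry X-H...Y: heavy-heavy and H...acceptor distances
    plus the angle at the hydrogen, as tabulated for conformer H-bond surveys."""

    donor_heavy: str
    hydrogen: str
    acceptor: str
    r_xy: float
    r_hy: float
    angle_xhy: float

    def __post_init__(self):
        if not (0.0 < self.r_hy < self.r_xy):
            raise DegenerateGeometryError(
                f"H-bond {self.donor_heavy}-{self.hydrogen}...{self.acceptor}: "
                f"require 0 < r_hy ({self.r_hy:.3f}) < r_xy ({self.r_xy:.3f})"
            )
        if not (0.0 <= self.angle_xhy <= 180.0):
            raise DegenerateGeometryError("angle must lie in [0, 180] degrees")


# ---------------------------------------------------------------------------
# file formats


def parse_xyz(text: str, conformer_id: str = "conformer") -> ConformerGeometry:
    """Parse a standard XYZ block into a :class:`ConformerGeometry`.

    Layout: atom-count line, comment line, then ``element x y z [label]``
    rows.  XYZ has no canonical label column; when a 5th column is present it
    is taken as the atom label, otherwise labels are synthesized as
    element + 1-based ordinal (H1, H2, ..., per element).
    """
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < count:
        raise ParseError(
            f"atom count {count} declared but only {len(body)} coordinate rows found"
        )
    atoms: list[AtomRecord] = []
    counters: dict[str, int] = {}
    for i, line in enumerate(body[:count], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {i}: expected 'element x y z [label]', got {line!r}")
        element = parts[0]
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"line {i}: non-numeric coordinate in {line!r}") from None
        if len(parts) >= 5:
            label = parts[4]
        else:
            counters[element] = counters.get(element, 0) + 1
            label = f"{element}{counters[element]}"
        atoms.append(AtomRecord(label=label, element=element, position=np.array(xyz)))
    return ConformerGeometry(conformer_id=conformer_id, atoms=atoms)


def write_xyz(geom: ConformerGeometry, with_labels: bool = True) -> str:
    """Serialize to XYZ; labels go in the optional 5th column."""
    out = [str(len(geom)), geom.conformer_id]
    for a in geom.atoms:
        row = f"{a.element} {a.position[0]:.6f} {a.position[1]:.6f} {a.position[2]:.6f}"
        if with_labels:
            row += f" {a.label}"
        out.append(row)
    return "\n".join(out) + "\n"


def parse_pdb(text: str, conformer_id: str = "conformer") -> ConformerGeometry:
    """Minimal PDB reader: ATOM/HETATM records only; first altLoc wins.

    Atom names become labels (stripped of whitespace); occupancy, insertion
    codes and everything else are ignored.  Crystal structures should
    normally be converted to XYZ upstream; this reader covers quick checks.
    """
    atoms: list[AtomRecord] = []
    seen: set[str] = set()
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        if name in seen and altloc:  # keep the first alternate location
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError:
            raise ParseError(f"line {i}: non-numeric coordinate field") from None
        element = line[76:78].strip() or name[:1]
        seen.add(name)
        atoms.append(AtomRecord(label=name, element=element, position=np.array(xyz)))
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    return ConformerGeometry(conformer_id=conformer_id, atoms=atoms)


# ---------------------------------------------------------------------------
# descriptors


def atom_distance(geom: ConformerGeometry, a: str, b: str) -> float:
    """Euclidean distance in Å between atoms ``a`` and ``b``."""
    return float(np.linalg.norm(geom.position(a) - geom.position(b)))


def dihedral_angle(geom: ConformerGeometry, a: str, b: str, c: str, d: str) -> float:
    """Signed IUPAC torsion angle a-b-c-d about the b-c bond, in (-180, 180].

    The cis (eclipsed) arrangement is 0 deg and trans is 180 deg; the sign
    follows the right-hand rule looking from b to c.  This is the convention
    for torsions like tau1(C10-C12-S-C13) distinguishing folded/unfolded
    conformers.
    """
    if len({a, b, c, d}) != 4:
        raise DegenerateGeometryError("dihedral needs four distinct atoms")
    p = [geom.position(x) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    if np.linalg.norm(b2) < 1e-12:
        raise DegenerateGeometryError("central atoms coincide; torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear atoms; torsion plane undefined")
    b2u = b2 / np.linalg.norm(b2)
    angle = math.degrees(
        math.atan2(float(np.dot(np.cross(n1, n2), b2u)), float(np.dot(n1, n2)))
    )
    if angle <= -180.0:
        angle += 360.0
    return angle


def hbond_geometry(
    geom: ConformerGeometry, x: str, h: str, y: str
) -> HBondGeometry:
    """Hydrogen-bond descriptor for donor X, hydrogen H, acceptor Y.

    Returns R(X...Y), R(H...Y) and the X-H...Y angle measured at H between
    the H->X and H->Y directions (180 deg = linear bond).
    """
    px, ph, py = geom.position(x), geom.position(h), geom.position(y)
    v_hx, v_hy = px - ph, py - ph
    n_hx, n_hy = np.linalg.norm(v_hx), np.linalg.norm(v_hy)
    if n_hx < 1e-10 or n_hy < 1e-10:
        raise DegenerateGeometryError("hydrogen coincides with donor or acceptor")
    cosang = float(np.clip(np.dot(v_hx, v_hy) / (n_hx * n_hy), -1.0, 1.0))
    return HBondGeometry(
        donor_heavy=x,
        hydrogen=h,
        acceptor=y,
        r_xy=float(np.linalg.norm(px - py)),
        r_hy=float(n_hy),
        angle_xhy=math.degrees(math.acos(cosang)),
    )
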