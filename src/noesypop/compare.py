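"""Optimal rigid superposition and RMSD matrices for conformer comparison.

RMSD after least-squares superposition, RMSD = sqrt(sum_i d_i^2 / N), is the
workhorse similarity measure between conformers of the same molecule and
between computed conformers and crystal/bioactive structures.  The rotation
is the Kabsch solution (via scipy's align_vectors), constrained to proper
rotations: enantiomers are *not* superposed onto each other, a deliberate
caveat for racemic compounds.

Hydrogens are excluded from the default atom map — crystallographic H
positions are usually riding-model artifacts — but an all-atom map is a
keyword away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import MappingError, UnderdeterminedError
from .geometry import ConformerGeometry

__all__ = ["Superposition", "superpose", "pairwise_rmsd_matrix", "write_rmsd_matrix"]


@dataclass(frozen=True)
class Superposition:
    """Proper rotation + translation taking mov onto ref, and the RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        if self.rmsd < 0:
            raise MappingError("rmsd cannot be negative")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise MappingError("rotation must be proper (determinant +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _mapped_coords(
    ref: ConformerGeometry,
    mov: ConformerGeometry,
    atom_map: Sequence[tuple[str, str]] | None,
    heavy_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if atom_map is None:
        by_label = {a.label: a for a in mov.atoms}
        atom_map = [(a.label, a.label) for a in ref.atoms if a.label in by_label]
    pairs = []
    for ref_label, mov_label in atom_map:
        a = ref.atoms[ref._index[ref_label]] if ref_label in ref._index else None
        b = mov.atoms[mov._index[mov_label]] if mov_label in mov._index else None
        if a is None or b is None:
            raise MappingError(f"atom map entry ({ref_label}, {mov_label}) not found")
        if a.element != b.element:
            raise MappingError(
                f"element mismatch in map: {ref_label} ({a.element}) vs "
                f"{mov_label} ({b.element})"
            )
        if heavy_only and a.element.upper() == "H":
            continue
        pairs.append((a.position, b.position))
    if len(pairs) < 3:
        raise UnderdeterminedError(f"only {len(pairs)} mapped atoms; need >= 3")
    p = np.array([x for x, _ in pairs])
    q = np.array([y for _, y in pairs])
    for coords in (p, q):
        if np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-8) < 2:
            raise UnderdeterminedError(
                "mapped atoms are collinear; rotation undetermined"
            )
    return p, q


def superpose(
    ref: ConformerGeometry,
    mov: ConformerGeometry,
    atom_map: Sequence[tuple[str, str]] | None = None,
    heavy_only: bool = True,
) -> Superposition:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    ``atom_map`` pairs (ref_label, mov_label); by default atoms are matched
    by identical labels.  Elements must agree pair-for-pair (structures of
    identical chemical composition).
    """
    p, q = _mapped_coords(ref, mov, atom_map, heavy_only)
    p_c, q_c = p.mean(axis=0), q.mean(axis=0)
    rot, _ = Rotation.align_vectors(p - p_c, q - q_c)
    r_mat = rot.as_matrix()
    # recompute the residual explicitly: scipy's rssd loses precision near 0
    diff = (p - p_c) - (q - q_c) @ r_mat.T
    rmsd = float(np.sqrt((diff ** 2).sum() / len(p)))
    return Superposition(
        rotation=r_mat, translation=p_c - r_mat @ q_c, rmsd=max(rmsd, 0.0)
    )


def pairwise_rmsd_matrix(
    ensemble: Sequence[ConformerGeometry],
    atom_map: Sequence[tuple[str, str]] | None = None,
    heavy_only: bool = True,
) -> pd.DataFrame:
    """Symmetric all-against-all RMSD matrix (Å), zero diagonal.

    A failing pair (unmappable atoms, degenerate geometry) yields NaN in
    both mirror cells rather than aborting the whole matrix.
    """
    ids = [g.conformer_id for g in ensemble]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = superpose(
                    ensemble[i], ensemble[j], atom_map, heavy_only=heavy_only
                ).rmsd
            except (MappingError, UnderdeterminedError):
                val = np.nan
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_rmsd_matrix(matrix: pd.DataFrame, path=None, sep: str = ",") -> str:
    text = matrix.round(3).to_csv(path, sep=sep)
    return text if path is None else ""
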