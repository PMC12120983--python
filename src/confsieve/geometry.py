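"""Rigid-body superposition, RMSD and chirality consistency.

All structure-based filtering in this package rests on three primitives:

* Kabsch least-squares superposition restricted to *proper* rotations
  (determinant +1), so that mirror images are never superposed onto each
  other and chirality information cannot leak into RMSD values;
* heavy-atom RMSD of every conformer to the ensemble reference (the
  lowest low-level-energy conformer), the geometric feature used by the
  pruning and clustering strategies;
* a determinant-sign test for inverted tetrahedral centers, used to drop
  conformers whose handedness changed during the low-level search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .ensemble_io import Conformer, ConformerEnsemble

__all__ = [
    "Superposition",
    "ChiralityReport",
    "kabsch_rmsd",
    "heavy_atom_mask",
    "rmsd_to_reference",
    "pairwise_heavy_rmsd",
    "detect_chirality_flips",
    "remove_flipped",
    "PLANARITY_TOL",
]

#: |det| (A^3) below which a 4-coordinate center counts as planar and its
#: handedness sign is considered noise.
PLANARITY_TOL = 1e-3


@dataclass(frozen=True)
class Superposition:
    """Optimal proper-rotation alignment of one structure onto another.

    ``rotation`` and ``translation`` map the *test* coordinates onto the
    reference frame: ``aligned = test @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    rank_deficient: bool = False

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ChiralityReport:
    """Result of comparing tetrahedral-center handedness between two conformers."""

    centers: tuple[int, ...]
    flipped: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.flipped <= set(self.centers):
            raise ValueError("flipped centers must be a subset of tested centers")

    @property
    def any_flipped(self) -> bool:
        return bool(self.flipped)


def _as_coords(x: np.ndarray) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an N x 3 coordinate array, got shape {a.shape}")
    return a


def kabsch_rmsd(
    ref_coords: np.ndarray,
    test_coords: np.ndarray,
    mask: Sequence[int] | np.ndarray | None = None,
) -> Superposition:
    """Least-squares RMSD over proper rotations + translations (Kabsch).

    Parameters
    ----------
    ref_coords, test_coords
        N x 3 Cartesian coordinates in angstrom, identical atom order.
    mask
        Atom subset (integer indices or boolean mask) over which the
        superposition is computed. ``None`` uses all atoms.

    The rotation is constrained to determinant +1: a reflected copy of a
    chiral structure keeps a non-zero RMSD. Fewer than 3 masked atoms give
    a well-defined but rank-deficient fit, flagged on the result.
    """
    ref = _as_coords(ref_coords)
    test = _as_coords(test_coords)
    if ref.shape != test.shape:
        raise ValueError("coordinate arrays must have identical shapes")
    if mask is None:
        idx = np.arange(ref.shape[0])
    else:
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)
    if idx.size == 0:
        raise ValueError("atom mask must select at least one atom")

    p = test[idx]
    q = ref[idx]
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc

    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = qc - pc @ rot.T

    diff = p0 @ rot.T - q0
    rmsd = float(np.sqrt((diff**2).sum() / idx.size))
    rank = np.linalg.matrix_rank(np.vstack([p0, q0]), tol=1e-10)
    return Superposition(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        rank_deficient=bool(idx.size < 3 or rank < 2),
    )


def heavy_atom_mask(elements: Sequence[str]) -> np.ndarray:
    """Boolean mask of non-hydrogen atoms (metal included)."""
    return np.array([e.strip().capitalize() != "H" for e in elements], dtype=bool)


def rmsd_to_reference(ensemble: "ConformerEnsemble") -> np.ndarray:
    """Heavy-atom Kabsch RMSD of each conformer to the ensemble reference.

    The reference is the lowest low-level-energy conformer; its own entry
    is exactly 0. Raises on an all-hydrogen structure.
    """
    if len(ensemble.conformers) == 0:
        raise ValueError("ensemble is empty")
    mask = heavy_atom_mask(ensemble.conformers[0].elements)
    if not mask.any():
        raise ValueError("no heavy atoms: RMSD over heavy atoms is undefined")
    ref = ensemble.conformers[ensemble.reference_index].coords
    out = np.empty(len(ensemble.conformers))
    for i, conf in enumerate(ensemble.conformers):
        if i == ensemble.reference_index:
            out[i] = 0.0
        else:
            out[i] = kabsch_rmsd(ref, conf.coords, mask).rmsd
    return out


def pairwise_heavy_rmsd(ensemble: "ConformerEnsemble") -> np.ndarray:
    """Symmetric matrix of heavy-atom Kabsch RMSDs between all conformers."""
    n = len(ensemble.conformers)
    mask = heavy_atom_mask(ensemble.conformers[0].elements)
    if not mask.any():
        raise ValueError("no heavy atoms: RMSD over heavy atoms is undefined")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_rmsd(
                ensemble.conformers[i].coords, ensemble.conformers[j].coords, mask
            ).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def _center_determinants(
    coords: np.ndarray, connectivity: np.ndarray
) -> dict[int, float]:
    """Signed volume at every exactly-4-coordinate atom.

    The handedness of a center is the sign of det[v1 v2 v3] where v1..v3
    are the edge vectors to its first three neighbours in index order; a
    fixed neighbour convention makes signs comparable between conformers
    that share atom order and connectivity.
    """
    adj = np.asarray(connectivity, dtype=bool)
    out: dict[int, float] = {}
    for a in range(adj.shape[0]):
        nbrs = np.flatnonzero(adj[a])
        if nbrs.size != 4:
            continue
        v = coords[nbrs[:3]] - coords[a]
        out[a] = float(np.linalg.det(v))
    return out


def detect_chirality_flips(
    reference: "Conformer", test: "Conformer", connectivity: np.ndarray
) -> ChiralityReport:
    """Flag 4-coordinate centers whose handedness differs from the reference.

    A center is flipped when the determinant signs differ *and* both
    magnitudes exceed :data:`PLANARITY_TOL` (near-planar centers carry no
    reliable handedness).
    """
    det_ref = _center_determinants(np.asarray(reference.coords, float), connectivity)
    det_test = _center_determinants(np.asarray(test.coords, float), connectivity)
    centers = tuple(sorted(det_ref))
    flipped = frozenset(
        a
        for a in centers
        if abs(det_ref[a]) > PLANARITY_TOL
        and abs(det_test[a]) > PLANARITY_TOL
        and np.sign(det_ref[a]) != np.sign(det_test[a])
    )
    return ChiralityReport(centers=centers, flipped=flipped)


def remove_flipped(
    ensemble: "ConformerEnsemble", reference: "Conformer | None" = None
) -> "ConformerEnsemble":
    """Drop conformers whose handedness changed relative to the input structure.

    ``reference`` defaults to the ensemble's own reference conformer. The
    returned ensemble keeps the surviving conformers' identity indices and
    recomputes relative energies, the reference index and RMSD-to-reference.
    """
    from .ensemble_io import ConformerEnsemble

    if reference is None:
        reference = ensemble.conformers[ensemble.reference_index]
    keep = [
        c
        for c in ensemble.conformers
        if not detect_chirality_flips(reference, c, ensemble.connectivity).any_flipped
    ]
    if not keep:
        raise ValueError("chirality filtering removed every conformer")
    return ConformerEnsemble.from_conformers(
        keep, connectivity=ensemble.connectivity, metal_index=ensemble.metal_index
    )
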