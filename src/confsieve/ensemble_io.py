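"""Reading and writing the file formats the workflow touches.

* multi-structure XYZ in the CREST ``crest_conformers.xyz`` dialect
  (atom-count line, comment line whose first float token is the energy,
  atom lines), one frame per conformer;
* MDL Molfile V2000 for the explicit connectivity matrix of the complex
  (bond orders are discarded, only adjacency is kept);
* a distilled delimited table of high-level (DFT) outcomes per conformer;
* machine-readable selection results (JSON) that round-trip exactly.

Internally every energy is kJ/mol and every coordinate angstrom. XYZ
comment-line energies default to Hartree (the CREST convention) and are
converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry

__all__ = [
    "HARTREE_TO_KJMOL",
    "KCAL_TO_KJMOL",
    "Conformer",
    "ConformerEnsemble",
    "DftRecord",
    "EnsembleFormatError",
    "read_multi_xyz",
    "write_multi_xyz",
    "read_molfile_connectivity",
    "write_molfile",
    "read_dft_table",
    "write_dft_table",
]

#: CODATA conversion, 1 Hartree in kJ/mol.
HARTREE_TO_KJMOL = 2625.4996394799
#: Thermochemical calorie: 1 kcal/mol in kJ/mol.
KCAL_TO_KJMOL = 4.184

_UNIT_FACTORS = {
    "hartree": HARTREE_TO_KJMOL,
    "kj/mol": 1.0,
    "kjmol": 1.0,
    "kcal/mol": KCAL_TO_KJMOL,
}

# Periodic table symbols, for input validation only.
_ELEMENTS = set(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe
    Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg
    Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu""".split()
)


class EnsembleFormatError(ValueError):
    """Malformed input file (inconsistent frames, bad counts line, ...)."""


def _unit_factor(unit: str) -> float:
    key = unit.strip().lower()
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unknown energy unit {unit!r}; use one of {sorted(_UNIT_FACTORS)}")
    return _UNIT_FACTORS[key]


@dataclass(frozen=True)
class Conformer:
    """One geometry of the complex with its low-level energy.

    ``index`` is the conformer's identity within its ensemble and is
    preserved across filtering steps. ``energy_low`` is kJ/mol.
    """

    index: int
    elements: tuple[str, ...]
    coords: np.ndarray
    energy_low: float
    energy_is_relative: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("element count does not match coordinate rows")
        bad = [e for e in self.elements if e.capitalize() not in _ELEMENTS]
        if bad:
            raise ValueError(f"unknown element symbols: {sorted(set(bad))}")
        if not np.isfinite(coords).all() or not math.isfinite(self.energy_low):
            raise ValueError("coordinates and energy must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class ConformerEnsemble:
    """Ordered conformers sharing one atom ordering and connectivity.

    ``reference_index`` is the position of the lowest low-level-energy
    conformer; ``rel_energy`` (kJ/mol) and ``rmsd_ref`` (angstrom, heavy
    atoms) are stored per conformer, positionally aligned with
    ``conformers``.
    """

    conformers: tuple[Conformer, ...]
    connectivity: np.ndarray | None
    metal_index: int
    reference_index: int
    rel_energy: np.ndarray
    rmsd_ref: np.ndarray

    @classmethod
    def from_conformers(
        cls,
        conformers: Sequence[Conformer],
        connectivity: np.ndarray | None = None,
        metal_index: int = 0,
    ) -> "ConformerEnsemble":
        confs = tuple(conformers)
        if not confs:
            raise ValueError("ensemble must contain at least one conformer")
        n = confs[0].n_atoms
        elems = confs[0].elements
        for c in confs:
            if c.n_atoms != n or c.elements != elems:
                raise EnsembleFormatError(
                    "all conformers must share atom count and element order"
                )
        if connectivity is not None:
            adj = np.asarray(connectivity, dtype=bool)
            if adj.shape != (n, n):
                raise ValueError("connectivity shape does not match atom count")
            if not np.array_equal(adj, adj.T) or adj.diagonal().any():
                raise ValueError("connectivity must be symmetric with zero diagonal")
            connectivity = adj
        if not 0 <= metal_index < n:
            raise ValueError("metal_index out of range")
        energies = np.array([c.energy_low for c in confs])
        ref = int(np.argmin(energies))
        obj = cls(
            conformers=confs,
            connectivity=connectivity,
            metal_index=metal_index,
            reference_index=ref,
            rel_energy=energies - energies[ref],
            rmsd_ref=np.zeros(len(confs)),
        )
        object.__setattr__(obj, "rmsd_ref", geometry.rmsd_to_reference(obj))
        return obj

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def indices(self) -> tuple[int, ...]:
        """Identity indices of the conformers, in storage order."""
        return tuple(c.index for c in self.conformers)

    def position_of(self, index: int) -> int:
        """Storage position of the conformer with identity ``index``."""
        try:
            return self.indices.index(index)
        except ValueError:
            raise KeyError(f"no conformer with index {index}") from None


@dataclass(frozen=True)
class DftRecord:
    """High-level (DFT) outcome for one conformer.

    ``energy_high`` (kJ/mol) is present iff the optimization converged to
    a true minimum; conformers that kept imaginary frequencies are marked
    non-converged and excluded from the evaluation universe upstream.
    """

    conformer_index: int
    converged: bool
    energy_high: float | None = None
    gibbs: float | None = None
    n_imaginary: int = 0

    def __post_init__(self) -> None:
        if self.converged != (self.energy_high is not None):
            raise ValueError("energy_high must be present iff converged")
        if self.n_imaginary < 0:
            raise ValueError("n_imaginary must be >= 0")


# ---------------------------------------------------------------------------
# multi-structure XYZ (CREST dialect)
# ---------------------------------------------------------------------------


def _first_float(text: str) -> float | None:
    for tok in text.split():
        try:
            return float(tok)
        except ValueError:
            continue
    return None


def read_multi_xyz(
    path: str | Path,
    energy_unit: str = "hartree",
    connectivity: np.ndarray | None = None,
    metal_index: int = 0,
) -> ConformerEnsemble:
    """Read a CREST-style multi-structure XYZ file into an ensemble.

    Each frame is ``natoms`` line, comment line (first parseable float =
    energy, interpreted per ``energy_unit``, default Hartree), then one
    ``element x y z`` line per atom. Every frame must repeat the same atom
    count and element order.
    """
    factor = _unit_factor(energy_unit)
    lines = Path(path).read_text().splitlines()
    conformers: list[Conformer] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise EnsembleFormatError(
                f"frame {frame}: expected an atom-count line, got {lines[pos]!r}"
            ) from None
        if pos + 2 + natoms > len(lines):
            raise EnsembleFormatError(f"frame {frame}: truncated file")
        energy = _first_float(lines[pos + 1])
        if energy is None:
            raise EnsembleFormatError(
                f"frame {frame}: no parseable energy in comment line {lines[pos + 1]!r}"
            )
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            parts = lines[pos + 2 + a].split()
            if len(parts) < 4:
                raise EnsembleFormatError(f"frame {frame}: malformed atom line {a}")
            elements.append(parts[0])
            coords[a] = [float(x) for x in parts[1:4]]
        conformers.append(
            Conformer(
                index=frame,
                elements=tuple(elements),
                coords=coords,
                energy_low=energy * factor,
            )
        )
        pos += 2 + natoms
        frame += 1
    if not conformers:
        raise EnsembleFormatError("no XYZ frames found")
    return ConformerEnsemble.from_conformers(
        conformers, connectivity=connectivity, metal_index=metal_index
    )


def write_multi_xyz(
    ensemble: ConformerEnsemble, path: str | Path, energy_unit: str = "kj/mol"
) -> None:
    """Write an ensemble as CREST-dialect multi-XYZ (energy in comment line)."""
    factor = _unit_factor(energy_unit)
    out: list[str] = []
    for c in ensemble.conformers:
        out.append(str(c.n_atoms))
        out.append(f"{c.energy_low / factor:.10f}")
        for el, (x, y, z) in zip(c.elements, c.coords):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# MDL Molfile V2000 connectivity
# ---------------------------------------------------------------------------


def read_molfile_connectivity(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Extract the adjacency matrix (and element order) from a V2000 Molfile.

    Bond orders are discarded: only presence matters. The element order is
    returned so callers can cross-check it against the XYZ atom order.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise EnsembleFormatError("Molfile too short for a V2000 header")
    counts = lines[3]
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError:
        raise EnsembleFormatError(f"malformed counts line: {counts!r}") from None
    if natoms <= 0:
        raise EnsembleFormatError("Molfile declares no atoms")
    atom_lines = lines[4 : 4 + natoms]
    bond_lines = lines[4 + natoms : 4 + natoms + nbonds]
    if len(atom_lines) < natoms or len(bond_lines) < nbonds:
        raise EnsembleFormatError("Molfile truncated relative to counts line")
    elements = []
    for ln in atom_lines:
        sym = ln[31:34].strip() if len(ln) >= 34 else ln.split()[3]
        elements.append(sym)
    adj = np.zeros((natoms, natoms), dtype=bool)
    for ln in bond_lines:
        try:
            a = int(ln[0:3])
            b = int(ln[3:6])
        except ValueError:
            raise EnsembleFormatError(f"malformed bond line: {ln!r}") from None
        if not (1 <= a <= natoms and 1 <= b <= natoms) or a == b:
            raise EnsembleFormatError(f"bond references out-of-range atom: {ln!r}")
        adj[a - 1, b - 1] = adj[b - 1, a - 1] = True
    return adj, tuple(elements)


def write_molfile(
    elements: Sequence[str],
    coords: np.ndarray,
    connectivity: np.ndarray,
    path: str | Path,
    title: str = "confsieve",
) -> None:
    """Write a minimal V2000 Molfile (all bonds order 1)."""
    coords = np.asarray(coords, dtype=float)
    adj = np.asarray(connectivity, dtype=bool)
    n = len(elements)
    bonds = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    lines = [title, "  confsieve", ""]
    lines.append(f"{n:3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, (x, y, z) in zip(elements, coords):
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i, j in bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}  1  0  0  0  0")
    lines.append("M  END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DFT outcome table
# ---------------------------------------------------------------------------


def read_dft_table(path: str | Path, energy_unit: str = "kj/mol") -> list[DftRecord]:
    """Read the distilled per-conformer DFT outcome table (CSV).

    Required columns: ``conformer_index``, ``converged``, ``energy_high``;
    optional: ``gibbs``, ``n_imaginary``. Energies are converted to kJ/mol
    per ``energy_unit``.
    """
    factor = _unit_factor(energy_unit)
    df = pd.read_csv(path)
    required = {"conformer_index", "converged", "energy_high"}
    missing = required - set(df.columns)
    if missing:
        raise EnsembleFormatError(f"DFT table missing columns: {sorted(missing)}")
    if df["conformer_index"].duplicated().any():
        dupes = df.loc[df["conformer_index"].duplicated(), "conformer_index"].tolist()
        raise EnsembleFormatError(f"duplicate conformer_index values: {dupes}")
    records: list[DftRecord] = []
    for _, row in df.iterrows():
        converged = bool(row["converged"])
        e = row["energy_high"]
        if converged and pd.isna(e):
            raise EnsembleFormatError(
                f"converged conformer {row['conformer_index']} lacks energy_high"
            )
        g = row.get("gibbs")
        records.append(
            DftRecord(
                conformer_index=int(row["conformer_index"]),
                converged=converged,
                energy_high=float(e) * factor if converged else None,
                gibbs=float(g) * factor if g is not None and not pd.isna(g) else None,
                n_imaginary=int(row["n_imaginary"]) if "n_imaginary" in df.columns else 0,
            )
        )
    return records


def write_dft_table(records: Iterable[DftRecord], path: str | Path) -> None:
    """Write DFT records as CSV (kJ/mol), readable by :func:`read_dft_table`."""
    rows = [
        {
            "conformer_index": r.conformer_index,
            "converged": r.converged,
            "energy_high": r.energy_high,
            "gibbs": r.gibbs,
            "n_imaginary": r.n_imaginary,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
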