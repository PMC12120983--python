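"""Basin-structured synthetic conformer ensembles with known ground truth.

Real low-level (CREST/xTB-style) ensembles of transition-metal complexes
show a characteristic structure: many low-level conformers collapse onto
a handful of high-level (DFT) minima, and the low-level energy ranking is
poorly correlated with the high-level one. The generator emulates exactly
that:

* a rigid random scaffold (metal + two phosphorus donors + bridged carbon
  backbone + a trans-coordinated moiety) fixes elements, atom order and
  connectivity;
* each *basin* is a displaced copy of the scaffold, kept at least
  ``between_rmsd_min`` heavy-atom RMSD from every other basin template;
* conformers are jittered copies of their basin template, rescaled so the
  realized heavy-atom RMSD to the template matches ``within_rmsd``;
* DFT energies are per-basin values (gaps >= ``basin_energy_min_gap``)
  plus <= 1 kJ/mol intra-basin noise, so chemical-accuracy grouping
  recovers the basins exactly;
* xTB energies add a per-basin bias (sd ``xtb_bias_sd``) that decorrelates
  the low-level ranking from the high-level one, plus small per-conformer
  noise;
* optionally a fraction of conformers is inverted through the metal to
  exercise chirality filtering.

Everything is reproducible from the seed, and the full ground truth
(basin membership, mirrored conformers, templates) is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import geometry
from .descriptors import BONDI_RADII, ligand_atom_subset
from .ensemble_io import (
    Conformer,
    ConformerEnsemble,
    DftRecord,
    read_dft_table,
    read_molfile_connectivity,
    read_multi_xyz,
    write_dft_table,
    write_molfile,
    write_multi_xyz,
)
from .evaluation import MinimumAssignment, read_truth_table, write_truth_table

__all__ = ["BasinSpec", "SyntheticEnsemble", "generate_ensemble", "write_fixture",
           "read_fixture", "generate_benchmark"]


@dataclass(frozen=True)
class BasinSpec:
    """Study conditions for one synthetic ensemble.

    Defaults reflect the structure of the precatalyst dataset the workflow
    targets: a few well-separated DFT basins (>= 6 kJ/mol apart, >= 1.0
    angstrom between-basin RMSD), tight basins (0.15 angstrom within-basin
    RMSD), and a basin-level xTB bias (sd 10 kJ/mol) large enough to
    decorrelate low-level from high-level energy ranking.
    """

    n_basins: int = 3
    conformers_per_basin: tuple[int, int] = (4, 12)
    dft_energy_spread: float = 10.0
    basin_energy_min_gap: float = 6.0
    within_rmsd: float = 0.15
    between_rmsd_min: float = 1.0
    xtb_bias_sd: float = 10.0
    xtb_noise_sd: float = 0.5
    n_atoms: int = 24
    fraction_h: float = 0.3
    mirror_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_basins < 1:
            raise ValueError("n_basins must be >= 1")
        if not 0 < self.within_rmsd < self.between_rmsd_min:
            raise ValueError("need between_rmsd_min > within_rmsd > 0")
        if min(self.xtb_bias_sd, self.xtb_noise_sd, self.dft_energy_spread) < 0:
            raise ValueError("spreads and noise levels must be non-negative")
        lo, hi = self.conformers_per_basin
        if not 1 <= lo <= hi:
            raise ValueError("conformers_per_basin must be a valid range")
        if not 0.0 <= self.mirror_fraction < 1.0:
            raise ValueError("mirror_fraction must be in [0, 1)")
        if self.n_atoms < 10:
            raise ValueError("scaffold needs at least 10 atoms")


@dataclass(frozen=True)
class SyntheticEnsemble:
    """A generated ensemble with its complete ground truth."""

    ensemble: ConformerEnsemble
    records: tuple[DftRecord, ...]
    truth: MinimumAssignment
    basin_of: dict[int, int]
    mirrored: frozenset[int]
    donors: tuple[int, int]
    templates: tuple[np.ndarray, ...]
    spec: BasinSpec


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _build_scaffold(
    spec: BasinSpec, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray, tuple[int, int]]:
    """Random rigid complex: Rh at origin, P donors, backbone, trans moiety.

    Returns (elements, coords, adjacency, donor indices). Atom 0 is the
    metal, bonded to both donors and to a two-carbon trans moiety, so the
    metal is always a testable 4-coordinate chirality center; the donors
    are bridged through a carbon backbone so the bidentate ligand is one
    connected component once the metal is removed.
    """
    n = spec.n_atoms
    n_h = int(round(spec.fraction_h * n))
    elements = ["Rh", "P", "P", "C", "C", "C", "C"]
    coords = [
        np.zeros(3),
        2.3 * _unit(np.array([1.0, 0.05, -0.05])),
        2.3 * _unit(np.array([0.05, 1.0, 0.05])),
        2.1 * _unit(np.array([-1.0, -0.9, -0.5])),   # trans moiety
        2.1 * _unit(np.array([-0.9, -1.0, 0.6])),
        None,  # backbone C bonded to P1
        None,  # backbone C bonded to P2
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (3, 4), (1, 5), (2, 6), (5, 6)]
    coords[5] = coords[1] + 1.85 * _unit(np.array([0.6, 0.9, 0.4]))
    coords[6] = coords[2] + 1.85 * _unit(np.array([0.9, 0.6, -0.4]))

    def too_close(p: np.ndarray, limit: float, element: str = "C") -> bool:
        # keep every atom outside the metal's vdW exclusion zone so tangent
        # cones (arcsin(r/d)) stay defined for all conformers of the ensemble
        if np.linalg.norm(p) < BONDI_RADII[element] + 0.6:
            return True
        return any(np.linalg.norm(p - q) < limit for q in coords if q is not None)

    n_heavy_extra = max(0, n - n_h - len(elements))
    degree = {i: 0 for i in range(len(elements))}
    for a, b in bonds:
        degree[a] += 1
        degree[b] += 1
    # extra carbons grow chain-biased trees off the ligand / moiety heavy
    # atoms; chain extension keeps subtrees deep enough that torsional
    # displacement can move the whole complex by > 1 angstrom RMSD
    last_added: int | None = None
    for _ in range(n_heavy_extra):
        for _attempt in range(200):
            if (
                last_added is not None
                and degree[last_added] < 4
                and rng.random() < 0.7
            ):
                parent = last_added
            else:
                parents = [
                    i for i, e in enumerate(elements) if e != "Rh" and e != "H"
                    and degree[i] < 4
                ]
                parent = int(rng.choice(parents))
            p = coords[parent] + 1.52 * _unit(rng.normal(size=3))
            if not too_close(p, 1.1):
                break
        else:
            raise RuntimeError("scaffold construction failed: no room for atom")
        idx = len(elements)
        elements.append("C")
        coords.append(p)
        bonds.append((parent, idx))
        degree[parent] += 1
        degree[idx] = 1
        last_added = idx
    # hydrogens cap under-coordinated carbons
    for _ in range(n - len(elements)):
        for _attempt in range(200):
            parents = [
                i for i, e in enumerate(elements) if e == "C" and degree[i] < 4
            ]
            if not parents:
                parents = [
                    i for i, e in enumerate(elements) if e == "P" and degree[i] < 4
                ]
            parent = int(rng.choice(parents))
            p = coords[parent] + 1.09 * _unit(rng.normal(size=3))
            if not too_close(p, 0.75, "H"):
                break
        else:
            raise RuntimeError("scaffold construction failed: no room for H")
        idx = len(elements)
        elements.append("H")
        coords.append(p)
        bonds.append((parent, idx))
        degree[parent] += 1
        degree[idx] = 1

    adj = np.zeros((len(elements), len(elements)), dtype=bool)
    for a, b in bonds:
        adj[a, b] = adj[b, a] = True
    return elements, np.array(coords), adj, (1, 2)


def _bridge_subtrees(adj: np.ndarray, metal_index: int) -> list[tuple[int, int, np.ndarray]]:
    """Rotatable bonds: bridges (a, b) whose removal leaves a component
    containing ``b`` but neither ``a`` nor the metal; returns that component.
    """
    n = adj.shape[0]
    out = []
    for a in range(n):
        for b in range(a + 1, n):
            if not adj[a, b]:
                continue
            for tail, head in ((a, b), (b, a)):
                # BFS from head with the tail-head bond removed
                seen = np.zeros(n, dtype=bool)
                seen[head] = True
                stack = [head]
                while stack:
                    cur = stack.pop()
                    for nxt in np.flatnonzero(adj[cur]):
                        if (cur, nxt) in ((tail, head), (head, tail)):
                            continue
                        if not seen[nxt]:
                            seen[nxt] = True
                            stack.append(int(nxt))
                if not seen[tail] and not seen[metal_index] and 2 <= seen.sum() <= n - 3:
                    out.append((tail, head, np.flatnonzero(seen)))
    return out


def _torsion_displace(
    coords: np.ndarray,
    subtrees: list[tuple[int, int, np.ndarray]],
    target: float,
    rng: np.random.Generator,
    heavy: np.ndarray,
    ligand: np.ndarray | None = None,
    max_moves: int = 25,
) -> np.ndarray | None:
    """Displace by random internal moves until the heavy-atom Kabsch RMSD to
    the start reaches ``target``; None if the moves cannot reach it.

    Two move types, both bond-length preserving: torsions (subtree rotation
    about a bridge bond) and, when ``ligand`` atom indices are given, rigid
    twists of the whole ligand about a random axis through the metal
    (atom 0) emulating a ligand rearrangement relative to the trans moiety.
    """
    from scipy.spatial.transform import Rotation

    out = coords.copy()
    for _ in range(max_moves):
        if geometry.kabsch_rmsd(coords, out, heavy).rmsd >= target:
            return out
        if ligand is not None and (not subtrees or rng.random() < 0.35):
            axis = _unit(rng.normal(size=3))
            angle = rng.uniform(0.35, 1.0) * (1 if rng.random() < 0.5 else -1)
            rot = Rotation.from_rotvec(axis * angle)
            out[ligand] = rot.apply(out[ligand] - out[0]) + out[0]
            continue
        a, b, comp = subtrees[int(rng.integers(len(subtrees)))]
        axis = out[b] - out[a]
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            continue
        angle = rng.uniform(0.5 * np.pi, np.pi) * (1 if rng.random() < 0.5 else -1)
        rot = Rotation.from_rotvec(axis / nrm * angle)
        moving = comp[comp != b]
        out[moving] = rot.apply(out[moving] - out[b]) + out[b]
    if geometry.kabsch_rmsd(coords, out, heavy).rmsd >= target:
        return out
    return None


def _jitter_to_rmsd(
    base: np.ndarray,
    target: float,
    rng: np.random.Generator,
    heavy: np.ndarray,
    rel_tol: float = 0.02,
) -> np.ndarray:
    """Displaced copy of ``base`` whose heavy-atom Kabsch RMSD to it matches
    ``target`` within ``rel_tol`` (rescaling the displacement iteratively)."""
    d = rng.normal(size=base.shape)
    d *= target / max(np.sqrt((d[heavy] ** 2).sum() / heavy.sum()), 1e-12)
    for _ in range(50):
        test = base + d
        r = geometry.kabsch_rmsd(base, test, heavy).rmsd
        if abs(r - target) <= rel_tol * target:
            return test
        d *= target / max(r, 1e-12)
    raise RuntimeError("jitter rescaling did not converge")


def _basin_energies(spec: BasinSpec, rng: np.random.Generator) -> np.ndarray:
    """Basin DFT energies: consecutive gaps of at least the minimum gap."""
    if spec.n_basins == 1:
        return np.zeros(1)
    extra_total = max(spec.dft_energy_spread - spec.basin_energy_min_gap, 0.0)
    gaps = spec.basin_energy_min_gap + rng.uniform(
        0, extra_total / (spec.n_basins - 1), size=spec.n_basins - 1
    )
    return np.concatenate([[0.0], np.cumsum(gaps)])


def _basin_biases(
    spec: BasinSpec, rng: np.random.Generator, dft: np.ndarray
) -> np.ndarray:
    """Per-basin xTB offsets, redrawn until basin mean xTB energies stay
    >= 6 kJ/mol apart (basins remain resolvable in the energy-RMSD plane
    while the ranking is still decorrelated)."""
    if spec.xtb_bias_sd == 0 or spec.n_basins == 1:
        return np.zeros(spec.n_basins)
    for _ in range(1000):
        bias = rng.normal(0.0, spec.xtb_bias_sd, size=spec.n_basins)
        means = dft + bias
        diffs = np.abs(means[:, None] - means[None, :])[
            np.triu_indices(spec.n_basins, 1)
        ]
        if diffs.min() >= 6.0:
            return bias
    raise RuntimeError("could not draw separable basin xTB offsets")


def generate_ensemble(spec: BasinSpec) -> SyntheticEnsemble:
    """Generate one basin-structured ensemble with full ground truth.

    Conformers are ordered by ascending xTB energy (as a CREST output
    would be) and indexed 0..N-1 in that order.
    """
    rng = np.random.default_rng(spec.seed)
    elements, scaffold, adj, donors = _build_scaffold(spec, rng)
    heavy = geometry.heavy_atom_mask(elements)

    _scaffold_ref = Conformer(0, tuple(elements), scaffold, 0.0)
    _min_clear = np.array(
        [0.0] + [BONDI_RADII[e] + 0.3 for e in elements[1:]]
    )

    def rejected(coords: np.ndarray) -> bool:
        """Reject geometries with flipped chirality or atoms pushed inside
        the metal's vdW exclusion zone (cone angle would be undefined)."""
        d = np.linalg.norm(coords - coords[0], axis=1)
        if (d[1:] < _min_clear[1:]).any():
            return True
        test = Conformer(0, tuple(elements), coords, 0.0)
        return geometry.detect_chirality_flips(_scaffold_ref, test, adj).any_flipped

    # basin templates: torsionally displaced scaffolds (random subtree
    # rotations about bridge bonds), mutually >= between_rmsd_min apart
    subtrees = _bridge_subtrees(adj, metal_index=0)
    ligand = np.array(ligand_atom_subset(adj, 0, donors))
    templates: list[np.ndarray] = [scaffold]
    for _ in range(spec.n_basins - 1):
        for _attempt in range(300):
            target = spec.between_rmsd_min * rng.uniform(1.15, 1.9)
            cand = _torsion_displace(scaffold, subtrees, target, rng, heavy, ligand)
            if cand is None:
                continue
            ok = all(
                geometry.kabsch_rmsd(t, cand, heavy).rmsd >= spec.between_rmsd_min
                for t in templates
            ) and not rejected(cand)
            if ok:
                templates.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place basin templates under the RMSD constraints"
            )

    dft_basin = _basin_energies(spec, rng)
    bias = _basin_biases(spec, rng, dft_basin)

    lo, hi = spec.conformers_per_basin
    geoms: list[np.ndarray] = []
    basin_seq: list[int] = []
    e_dft: list[float] = []
    e_xtb: list[float] = []
    for b, tpl in enumerate(templates):
        n_b = int(rng.integers(lo, hi + 1))
        for _ in range(n_b):
            for _attempt in range(100):
                cand = _jitter_to_rmsd(tpl, spec.within_rmsd, rng, heavy)
                if not rejected(cand):
                    break
            else:
                raise RuntimeError("conformer jitter kept flipping chirality")
            geoms.append(cand)
            basin_seq.append(b)
            dft = float(dft_basin[b] + rng.uniform(0.0, 1.0))
            noise = float(
                np.clip(
                    rng.normal(0.0, spec.xtb_noise_sd) if spec.xtb_noise_sd else 0.0,
                    -2 * spec.xtb_noise_sd,
                    2 * spec.xtb_noise_sd,
                )
            )
            e_dft.append(dft)
            e_xtb.append(dft + float(bias[b]) + noise)

    total = len(geoms)
    n_mirror = int(round(spec.mirror_fraction * total))
    mirror_pos = set(
        rng.choice(total, size=n_mirror, replace=False).tolist()
    ) if n_mirror else set()
    for p in mirror_pos:
        geoms[p] = -geoms[p]  # inversion through the metal (at the origin)

    # CREST-like output order: ascending xTB energy
    order = sorted(range(total), key=lambda p: (e_xtb[p], p))
    conformers = [
        Conformer(
            index=i,
            elements=tuple(elements),
            coords=geoms[p],
            energy_low=e_xtb[p],
        )
        for i, p in enumerate(order)
    ]
    ensemble = ConformerEnsemble.from_conformers(
        conformers, connectivity=adj, metal_index=0
    )

    basin_of = {i: basin_seq[p] for i, p in enumerate(order)}
    mirrored = frozenset(i for i, p in enumerate(order) if p in mirror_pos)
    records = tuple(
        DftRecord(conformer_index=i, converged=True, energy_high=e_dft[p])
        for i, p in enumerate(order)
    )
    # truth labels: basins relabeled by ascending basin DFT energy
    basin_rank = {b: r for r, b in enumerate(np.argsort(dft_basin).tolist())}
    truth = MinimumAssignment(
        labels={i: basin_rank[basin_of[i]] for i in basin_of},
        minima={
            basin_rank[b]: float(dft_basin[b]) for b in range(spec.n_basins)
        },
    )
    return SyntheticEnsemble(
        ensemble=ensemble,
        records=records,
        truth=truth,
        basin_of=basin_of,
        mirrored=mirrored,
        donors=donors,
        templates=tuple(templates),
        spec=spec,
    )


def write_fixture(synth: SyntheticEnsemble, directory: str | Path) -> dict[str, Path]:
    """Write a generated ensemble as the on-disk fixture the readers consume.

    Files: ``conformers.xyz`` (CREST dialect, energies kJ/mol),
    ``complex.mol`` (V2000 connectivity), ``dft.csv``, ``truth.csv`` and a
    ``manifest.json`` recording units, metal index and donors.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "xyz": directory / "conformers.xyz",
        "mol": directory / "complex.mol",
        "dft": directory / "dft.csv",
        "truth": directory / "truth.csv",
        "manifest": directory / "manifest.json",
    }
    write_multi_xyz(synth.ensemble, paths["xyz"], energy_unit="kj/mol")
    ref = synth.ensemble.conformers[synth.ensemble.reference_index]
    write_molfile(ref.elements, ref.coords, synth.ensemble.connectivity, paths["mol"])
    write_dft_table(synth.records, paths["dft"])
    write_truth_table(synth.truth, paths["truth"])
    manifest = {
        "energy_unit": "kj/mol",
        "metal_index": synth.ensemble.metal_index,
        "donors": list(synth.donors),
        "mirrored": sorted(synth.mirrored),
        "seed": synth.spec.seed,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return paths


def read_fixture(
    directory: str | Path,
) -> tuple[ConformerEnsemble, list[DftRecord], MinimumAssignment, dict]:
    """Load a fixture directory back through the package's own readers."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    adj, _ = read_molfile_connectivity(directory / "complex.mol")
    ensemble = read_multi_xyz(
        directory / "conformers.xyz",
        energy_unit=manifest["energy_unit"],
        connectivity=adj,
        metal_index=manifest["metal_index"],
    )
    records = read_dft_table(directory / "dft.csv")
    truth = read_truth_table(directory / "truth.csv")
    return ensemble, records, truth, manifest


def generate_benchmark(
    n_ensembles: int = 24,
    seed: int = 0,
    base_spec: BasinSpec | None = None,
) -> list[SyntheticEnsemble]:
    """A seeded suite of ensembles with varying basin counts and sizes.

    Basin counts cycle over 1..4 (so single-minimum and multi-minimum
    ensembles are both represented) and every ensemble derives its own
    child seed from ``seed``.
    """
    base = base_spec or BasinSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_ensembles)
    out = []
    for k in range(n_ensembles):
        spec = BasinSpec(
            n_basins=1 + k % 4,
            conformers_per_basin=base.conformers_per_basin,
            dft_energy_spread=base.dft_energy_spread * (1 + k % 4) / 2,
            basin_energy_min_gap=base.basin_energy_min_gap,
            within_rmsd=base.within_rmsd,
            between_rmsd_min=base.between_rmsd_min,
            xtb_bias_sd=base.xtb_bias_sd,
            xtb_noise_sd=base.xtb_noise_sd,
            n_atoms=base.n_atoms,
            fraction_h=base.fraction_h,
            mirror_fraction=base.mirror_fraction,
            seed=int(child_seeds[k] % (2**31)),
        )
        out.append(generate_ensemble(spec))
    return out
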