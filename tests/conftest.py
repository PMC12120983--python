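from __future__ import annotations

import numpy as np
import pytest

from confsieve import BasinSpec, Conformer, ConformerEnsemble, generate_ensemble


def make_conformer(coords, elements=None, index=0, energy=0.0) -> Conformer:
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = ("C",) * len(coords)
    return Conformer(
        index=index, elements=tuple(elements), coords=coords, energy_low=energy
    )


def make_ensemble(coord_list, elements=None, energies=None, connectivity=None,
                  metal_index=0) -> ConformerEnsemble:
    energies = energies if energies is not None else [float(i) for i in range(len(coord_list))]
    confs = [
        make_conformer(c, elements, index=i, energy=e)
        for i, (c, e) in enumerate(zip(coord_list, energies))
    ]
    return ConformerEnsemble.from_conformers(
        confs, connectivity=connectivity, metal_index=metal_index
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def synthetic_default():
    """One mid-sized basin-structured ensemble reused across test modules."""
    return generate_ensemble(BasinSpec(seed=11))


@pytest.fixture(scope="session")
def tetrahedral():
    """A methane-like 4-coordinate center: C at origin, 4 H at tetrahedron
    vertices, plus connectivity."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    )
    adj = np.zeros((5, 5), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return coords, ("C", "H", "H", "H", "H"), adj
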