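"""File-format round trips and format-error handling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confsieve import (
    HARTREE_TO_KJMOL,
    EnsembleFormatError,
    SelectionResult,
    read_dft_table,
    read_molfile_connectivity,
    read_multi_xyz,
    read_selection,
    write_dft_table,
    write_molfile,
    write_multi_xyz,
    write_selection,
)
from confsieve.ensemble_io import DftRecord


def write_xyz(path, frames, comments=None):
    """frames: list of (elements, coords); comments default to energies."""
    lines = []
    for k, (elements, coords) in enumerate(frames):
        lines.append(str(len(elements)))
        lines.append(comments[k] if comments else f"-{10 - k / 10.0}")
        for el, (x, y, z) in zip(elements, coords):
            lines.append(f"{el} {x} {y} {z}")
    path.write_text("\n".join(lines) + "\n")


FRAME = (("C", "O", "H"), [(0.0, 0, 0), (1.2, 0, 0), (-0.5, 0.9, 0)])


class TestMultiXyz:
    def test_relative_energies_from_comment_line(self, tmp_path):
        p = tmp_path / "e.xyz"
        write_xyz(p, [FRAME, FRAME], comments=["-10.0", "-9.9"])
        ens = read_multi_xyz(p, energy_unit="kj/mol")
        assert np.allclose(ens.rel_energy, [0.0, 0.1])
        assert ens.reference_index == 0

    def test_single_frame(self, tmp_path):
        p = tmp_path / "one.xyz"
        write_xyz(p, [FRAME], comments=["-3.5 some label"])
        ens = read_multi_xyz(p, energy_unit="kj/mol")
        assert len(ens) == 1
        assert ens.rel_energy.tolist() == [0.0]
        assert ens.rmsd_ref.tolist() == [0.0]

    def test_hartree_conversion_is_default(self, tmp_path):
        p = tmp_path / "h.xyz"
        write_xyz(p, [FRAME, FRAME], comments=["-1.0", "-0.999"])
        ens = read_multi_xyz(p)
        assert ens.rel_energy[1] == pytest.approx(0.001 * HARTREE_TO_KJMOL)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        two_atom = (("C", "O"), [(0, 0, 0), (1.2, 0, 0)])
        write_xyz(p, [FRAME, two_atom], comments=["-1.0", "-2.0"])
        with pytest.raises(EnsembleFormatError, match="share atom count"):
            read_multi_xyz(p, energy_unit="kj/mol")

    def test_unparseable_energy_names_frame(self, tmp_path):
        p = tmp_path / "noe.xyz"
        write_xyz(p, [FRAME, FRAME], comments=["-1.0", "no numbers here"])
        with pytest.raises(EnsembleFormatError, match="frame 1"):
            read_multi_xyz(p, energy_unit="kj/mol")

    def test_frame_count_and_line_consumption(self, tmp_path, synthetic_default):
        ens = synthetic_default.ensemble
        p = tmp_path / "round.xyz"
        write_multi_xyz(ens, p, energy_unit="kj/mol")
        text = p.read_text().rstrip("\n").splitlines()
        n_headers = sum(1 for ln in text if ln.strip() == str(ens.conformers[0].n_atoms))
        assert n_headers == len(ens)
        assert len(text) == len(ens) * (ens.conformers[0].n_atoms + 2)

    def test_write_read_round_trip(self, tmp_path, synthetic_default):
        ens = synthetic_default.ensemble
        p = tmp_path / "round.xyz"
        write_multi_xyz(ens, p, energy_unit="kj/mol")
        back = read_multi_xyz(p, energy_unit="kj/mol")
        assert len(back) == len(ens)
        assert np.allclose(back.rel_energy, ens.rel_energy, atol=1e-8)
        for a, b in zip(back.conformers, ens.conformers):
            assert a.elements == b.elements
            assert np.allclose(a.coords, b.coords, atol=1e-9)


MOLFILE_WATER = """water
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.9572    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2400    0.9266    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
M  END
"""


class TestMolfile:
    def test_three_atom_two_bond_adjacency(self, tmp_path):
        p = tmp_path / "w.mol"
        p.write_text(MOLFILE_WATER)
        adj, elements = read_molfile_connectivity(p)
        assert adj.sum() == 4  # two bonds, symmetric
        assert elements == ("O", "H", "H")
        assert adj[0].sum() == 2 and adj[1].sum() == 1 and adj[2].sum() == 1
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_zero_bond_molfile(self, tmp_path):
        p = tmp_path / "atoms.mol"
        write_molfile(("C", "C"), np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                      np.zeros((2, 2), dtype=bool), p)
        adj, elements = read_molfile_connectivity(p)
        assert not adj.any()
        assert elements == ("C", "C")

    def test_malformed_counts_line(self, tmp_path):
        p = tmp_path / "bad.mol"
        p.write_text("t\n\n\nxxx\n")
        with pytest.raises(EnsembleFormatError, match="counts"):
            read_molfile_connectivity(p)

    def test_out_of_range_bond(self, tmp_path):
        p = tmp_path / "oob.mol"
        p.write_text(MOLFILE_WATER.replace("  1  3  1", "  1  9  1"))
        with pytest.raises(EnsembleFormatError, match="out-of-range"):
            read_molfile_connectivity(p)

    def test_round_trip_matches_rdkit(self, tmp_path, synthetic_default):
        rdkit_chem = pytest.importorskip("rdkit.Chem")
        ens = synthetic_default.ensemble
        ref = ens.conformers[0]
        p = tmp_path / "complex.mol"
        write_molfile(ref.elements, ref.coords, ens.connectivity, p)
        adj, elements = read_molfile_connectivity(p)
        assert np.array_equal(adj, ens.connectivity)
        mol = rdkit_chem.MolFromMolFile(str(p), sanitize=False, removeHs=False)
        rd_adj = rdkit_chem.GetAdjacencyMatrix(mol).astype(bool)
        assert np.array_equal(adj, rd_adj)
        assert tuple(a.GetSymbol() for a in mol.GetAtoms()) == elements


class TestDftTable:
    def test_three_converged_rows(self, tmp_path):
        p = tmp_path / "dft.csv"
        p.write_text(
            "conformer_index,converged,energy_high,n_imaginary\n"
            "0,True,0.0,0\n1,True,3.2,0\n2,True,9.9,0\n"
        )
        records = read_dft_table(p)
        assert len(records) == 3
        assert records[1].energy_high == pytest.approx(3.2)

    def test_non_converged_row_without_energy(self, tmp_path):
        p = tmp_path / "dft.csv"
        p.write_text(
            "conformer_index,converged,energy_high\n0,True,0.0\n1,False,\n"
        )
        records = read_dft_table(p)
        assert records[1].converged is False
        assert records[1].energy_high is None

    def test_duplicate_index_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("conformer_index,converged,energy_high\n0,True,0.0\n0,True,1.0\n")
        with pytest.raises(EnsembleFormatError, match="duplicate"):
            read_dft_table(p)

    def test_converged_without_energy_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("conformer_index,converged,energy_high\n0,True,\n")
        with pytest.raises(EnsembleFormatError, match="lacks energy"):
            read_dft_table(p)

    def test_write_read_round_trip(self, tmp_path):
        records = [
            DftRecord(0, True, 0.0, gibbs=1.5),
            DftRecord(3, False, None, n_imaginary=2),
        ]
        p = tmp_path / "dft.csv"
        write_dft_table(records, p)
        back = read_dft_table(p)
        assert back == records


class TestSelectionRoundTrip:
    def test_dbscan_selection_round_trip(self, tmp_path):
        sel = SelectionResult(
            method="dbscan",
            parameters={"epsilon": 0.19, "min_samples": 2},
            selected=frozenset({0, 2}),
            eliminated=frozenset({1, 3}),
            cluster_labels={0: 0, 1: 0, 2: -1, 3: 0},
        )
        p = tmp_path / "sel.json"
        write_selection(sel, p)
        assert read_selection(p) == sel

    def test_empty_selection_is_valid(self, tmp_path):
        sel = SelectionResult("energy", {"energy_threshold": 1.0},
                              frozenset(), frozenset({0, 1}))
        p = tmp_path / "empty.json"
        write_selection(sel, p)
        back = read_selection(p)
        assert back.selected == frozenset()
        assert back.eliminated == {0, 1}

    def test_reserialization_is_byte_identical(self, tmp_path):
        sel = SelectionResult("rmsd", {"rmsd_threshold": 0.35},
                              frozenset({5, 1}), frozenset({2}))
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_selection(sel, p1)
        write_selection(read_selection(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        universe=st.sets(st.integers(0, 200), min_size=1, max_size=30),
        pick=st.data(),
    )
    def test_round_trip_arbitrary_selections(self, tmp_path_factory, universe, pick):
        selected = {
            i for i in universe if pick.draw(st.booleans(), label=f"keep{i}")
        }
        sel = SelectionResult(
            method="energy",
            parameters={"energy_threshold": 12.55},
            selected=frozenset(selected),
            eliminated=frozenset(universe - selected),
        )
        p = tmp_path_factory.mktemp("sel") / "sel.json"
        write_selection(sel, p)
        assert read_selection(p) == sel
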