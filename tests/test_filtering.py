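"""Selection strategies: pruning, extremes, PCA, DBSCAN."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from confsieve import (
    ClusterConfig,
    DescriptorRow,
    PruningConfig,
    dbscan_select,
    pca_project,
    prune_combined,
    prune_energy,
    prune_rmsd,
    select_extremes,
)
from conftest import make_ensemble


def ensemble_with_energies(rel, rng=None, spread=5.0):
    """Ensemble whose conformers are far apart geometrically (no RMSD dups)."""
    rng = rng or np.random.default_rng(0)
    coords = [rng.normal(scale=spread, size=(4, 3)) for _ in rel]
    return make_ensemble(coords, energies=list(rel))


def feature_stub(rel_energy, rmsd_ref):
    """Minimal ensemble stand-in for the feature-space clustering step."""
    rel = np.asarray(rel_energy, float)
    rmsd = np.asarray(rmsd_ref, float)
    confs = [SimpleNamespace(index=i) for i in range(len(rel))]
    return SimpleNamespace(
        rel_energy=rel,
        rmsd_ref=rmsd,
        conformers=confs,
        indices=tuple(range(len(rel))),
    )


class TestPruneEnergy:
    def test_threshold_rule(self):
        ens = ensemble_with_energies([0.0, 5.0, 13.0])
        sel = prune_energy(ens)
        assert sel.selected == {0, 1}
        assert sel.eliminated == {2}

    def test_all_zero_selected(self):
        ens = ensemble_with_energies([0.0, 0.0, 0.0])
        assert prune_energy(ens).selected == {0, 1, 2}

    def test_boundary_value_kept(self):
        ens = ensemble_with_energies([0.0, 12.55])
        assert prune_energy(ens).selected == {0, 1}

    def test_monotone_in_threshold(self):
        ens = ensemble_with_energies([0.0, 3.0, 8.0, 14.0, 22.0])
        prev: set[int] = set()
        for thr in (1.0, 5.0, 10.0, 20.0, 30.0):
            cur = prune_energy(ens, PruningConfig(energy_threshold=thr)).selected
            assert prev <= cur
            prev = cur


class TestPruneRmsd:
    def test_duplicate_of_reference_removed(self, rng):
        a = rng.normal(size=(4, 3))
        ens = make_ensemble([a, a.copy()], energies=[0.0, 1.0])
        sel = prune_rmsd(ens)
        assert sel.selected == {0}

    def test_distinct_geometries_kept(self, rng):
        a = rng.normal(size=(4, 3))
        b = a + rng.normal(scale=2.0, size=(4, 3))
        ens = make_ensemble([a, b], energies=[0.0, 1.0])
        assert prune_rmsd(ens).selected == {0, 1}

    def test_three_tight_families_give_three(self, rng):
        # three geometric families: tiny within-family jitter, large shifts
        base = rng.normal(scale=2.0, size=(5, 3))
        deformed = base.copy()
        deformed[0] += [4.0, 0, 0]  # internal deformation, survives alignment
        fams = [base, deformed, base * [1, -1, 1]]  # mirror: proper rotations only
        coords, energies = [], []
        e = 0.0
        for fam in fams:
            for _ in range(3):
                coords.append(fam + rng.normal(scale=0.01, size=fam.shape))
                energies.append(e)
                e += 1.0
        ens = make_ensemble(coords, energies=energies)
        sel = prune_rmsd(ens)
        assert len(sel.selected) == 3

    def test_lowest_energy_always_kept(self, rng):
        ens = ensemble_with_energies([4.0, 0.0, 9.0], rng)
        assert 1 in prune_rmsd(ens).selected
        assert 1 in prune_energy(ens).selected
        assert 1 in prune_combined(ens).selected

    def test_monotone_in_threshold(self, rng):
        coords = [rng.normal(scale=1.0, size=(5, 3)) for _ in range(8)]
        ens = make_ensemble(coords)
        prev = None
        for thr in (0.1, 0.5, 1.5, 4.0):
            cur = prune_rmsd(ens, PruningConfig(rmsd_threshold=thr)).selected
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestPruneCombined:
    def test_nothing_removed_when_thresholds_loose(self, rng):
        ens = ensemble_with_energies([0.0, 1.0, 2.0], rng)
        sel = prune_combined(ens, PruningConfig(energy_threshold=100.0,
                                                rmsd_threshold=0.01))
        assert sel.selected == {0, 1, 2}

    def test_geometrically_unique_but_high_energy_eliminated(self, rng):
        ens = ensemble_with_energies([0.0, 50.0], rng)
        sel = prune_combined(ens)
        assert sel.selected == {0}
        assert sel.eliminated == {1}

    def test_never_larger_than_either_rule(self, synthetic_default):
        ens = synthetic_default.ensemble
        combined = prune_combined(ens).selected
        energy = prune_energy(ens).selected
        rmsd = prune_rmsd(ens).selected
        assert len(combined) <= min(len(energy), len(rmsd))
        assert combined <= energy

    def test_partition_invariant(self, synthetic_default):
        ens = synthetic_default.ensemble
        for sel in (prune_energy(ens), prune_rmsd(ens), prune_combined(ens),
                    dbscan_select(ens)):
            assert sel.selected | sel.eliminated == set(ens.indices)
            assert not sel.selected & sel.eliminated


def row(i, vbur, cone):
    return DescriptorRow(
        conformer_index=i, buried_volume_pct=vbur, cone_angle=cone,
        bite_angle=90.0, donor_distances=(2.3, 2.3), rmsd_ref=0.0, rel_energy=0.0,
    )


class TestSelectExtremes:
    def test_single_candidate(self):
        rows = [row(0, 30.0, 120.0), row(1, 40.0, 150.0)]
        sel = select_extremes(rows, [1])
        assert sel.selected == {1}
        assert sel.eliminated == {0}

    def test_argmin_argmax_union(self):
        rows = [row(0, 10, 90), row(1, 20, 80), row(2, 30, 100)]
        sel = select_extremes(rows)
        assert sel.selected == {0, 1, 2}

    def test_tie_broken_to_lower_index(self):
        rows = [row(0, 10, 90), row(1, 30, 90), row(2, 30, 90)]
        sel = select_extremes(rows)
        # max Vbur tied between 1 and 2 -> 1; cone extremes tied -> 0
        assert sel.selected == {0, 1}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_extremes([row(0, 10, 90)], [])


class TestPcaProject:
    def test_perfectly_correlated_features_rank_one(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        _, explained, _ = pca_project(x)
        assert explained[0] == pytest.approx(1.0, abs=1e-10)
        assert explained[1] == pytest.approx(0.0, abs=1e-10)

    def test_isotropic_square_splits_evenly(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        _, explained, _ = pca_project(x)
        assert explained[0] == pytest.approx(0.5, abs=1e-10)
        assert explained[1] == pytest.approx(0.5, abs=1e-10)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        x = rng.normal(size=(10, 5))
        scores, explained, dropped = pca_project(x)
        assert dropped == []
        z = (x - x.mean(0)) / x.std(0)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = z @ vt[:2].T
        for k in range(2):
            direct = np.allclose(scores[:, k], oracle[:, k], atol=1e-8)
            flipped = np.allclose(scores[:, k], -oracle[:, k], atol=1e-8)
            assert direct or flipped
        assert np.allclose(explained[:2], (s**2)[:2] / (s**2).sum(), atol=1e-10)

    def test_sign_convention_largest_loading_positive(self, rng):
        x = rng.normal(size=(20, 4))
        scores1, _, _ = pca_project(x)
        scores2, _, _ = pca_project(-x)  # flipped data cannot flip convention twice
        assert np.allclose(np.abs(scores1), np.abs(scores2), atol=1e-8)

    def test_constant_feature_dropped(self):
        x = np.column_stack([np.arange(4.0), np.ones(4), np.arange(4.0) ** 2])
        _, _, dropped = pca_project(x, ["a", "const", "b"])
        assert dropped == ["const"]

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="non-constant"):
            pca_project(np.ones((5, 3)))


class TestDbscanSelect:
    def test_epsilon_to_zero_selects_everything(self):
        ens = feature_stub([0, 3, 9, 14], [0, 0.2, 1.1, 2.0])
        sel = dbscan_select(ens, ClusterConfig(epsilon=1e-9))
        assert sel.selected == {0, 1, 2, 3}
        assert set(sel.cluster_labels.values()) == {-1}

    def test_epsilon_above_diameter_gives_one(self):
        ens = feature_stub([0, 3, 9, 14], [0, 0.2, 1.1, 2.0])
        sel = dbscan_select(ens, ClusterConfig(epsilon=100.0))
        assert sel.selected == {0}
        assert set(sel.cluster_labels.values()) == {0}

    def test_two_groups_and_noise_point(self):
        # standardized plane: two tight pairs + one isolated point
        rel = [0.0, 0.1, 10.0, 10.1, 10.2, 0.05, 20.0]
        rmsd = [0.0, 0.01, 1.0, 1.01, 1.02, 0.005, 3.0]
        ens = feature_stub(rel, rmsd)
        sel = dbscan_select(ens, ClusterConfig(epsilon=0.2))
        labels = sel.cluster_labels
        assert labels[6] == -1
        clusters = {lab for lab in labels.values() if lab >= 0}
        assert len(clusters) == 2
        # representatives: lowest rel-energy member of each cluster + noise
        assert sel.selected == {0, 2, 6}

    def test_single_conformer_is_noise_and_selected(self):
        ens = feature_stub([0.0], [0.0])
        sel = dbscan_select(ens)
        assert sel.selected == {0}
        assert sel.cluster_labels == {0: -1}

    def test_every_cluster_has_min_samples_members(self, synthetic_default):
        sel = dbscan_select(synthetic_default.ensemble, ClusterConfig(epsilon=0.15))
        labels = list(sel.cluster_labels.values())
        for lab in set(labels):
            if lab >= 0:
                assert labels.count(lab) >= 2

    def test_cluster_count_non_increasing_in_epsilon(self):
        rng = np.random.default_rng(8)
        rel = np.concatenate([rng.normal(0, 0.5, 10), rng.normal(20, 0.5, 10)])
        rmsd = np.concatenate([rng.normal(0.2, 0.02, 10), rng.normal(1.5, 0.02, 10)])
        ens = feature_stub(rel, rmsd)
        counts = []
        for eps in (0.2, 0.5, 1.0, 2.0, 5.0):
            sel = dbscan_select(ens, ClusterConfig(epsilon=eps))
            counts.append(len({v for v in sel.cluster_labels.values() if v >= 0}))
        assert counts == sorted(counts, reverse=True)
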