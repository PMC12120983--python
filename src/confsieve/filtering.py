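"""Conformer selection strategies over a low-level ensemble.

Four families of strategies are provided, all producing a
:class:`SelectionResult` that partitions the ensemble into *selected*
(kept for high-level refinement) and *eliminated* conformers:

* **energy pruning** — drop conformers whose relative low-level energy
  exceeds a threshold (default 12.55 kJ/mol = 3.0 kcal/mol);
* **RMSD pruning** — greedy geometric deduplication in ascending energy
  order: a conformer survives only if its heavy-atom RMSD to every
  already-kept conformer exceeds a threshold (default 0.35 angstrom);
* **extreme-descriptor selection** — keep the conformers with minimal and
  maximal percent buried volume and cone angle (at most four);
* **DBSCAN clustering** on standardized (relative energy, RMSD-to-
  reference) features: one representative (lowest energy) per cluster is
  kept, and every noise point is retained so that unusual conformers are
  never silently dropped.

A 2-component PCA of descriptor tables is included for exploratory
chemical-space projection; no selection strategy is built on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from . import geometry

if TYPE_CHECKING:  # pragma: no cover
    from .descriptors import DescriptorRow
    from .ensemble_io import ConformerEnsemble

__all__ = [
    "PruningConfig",
    "ClusterConfig",
    "SelectionResult",
    "prune_energy",
    "prune_rmsd",
    "prune_combined",
    "select_extremes",
    "pca_project",
    "dbscan_select",
    "write_selection",
    "read_selection",
]


@dataclass(frozen=True)
class PruningConfig:
    """Thresholds of the energy / RMSD pruning rules.

    Defaults are the study conditions: 12.55 kJ/mol (3.0 kcal/mol) and
    0.35 angstrom. Comparisons are boundary-inclusive (values equal to the
    threshold are kept by energy pruning; an RMSD exactly at the threshold
    counts as a duplicate).
    """

    energy_threshold: float = 12.55
    rmsd_threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.energy_threshold <= 0 or self.rmsd_threshold <= 0:
            raise ValueError("pruning thresholds must be positive")


@dataclass(frozen=True)
class ClusterConfig:
    """DBSCAN parameters on the standardized (rel. energy, RMSD) plane."""

    epsilon: float = 0.19
    min_samples: int = 2
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection strategy.

    ``selected`` and ``eliminated`` are disjoint sets of conformer
    identity indices whose union is the full universe the strategy saw.
    ``cluster_labels`` (index -> label, -1 = noise) is populated by the
    clustering strategy only.
    """

    method: str
    parameters: Mapping[str, object]
    selected: frozenset[int]
    eliminated: frozenset[int]
    cluster_labels: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if self.selected & self.eliminated:
            raise ValueError("selected and eliminated must be disjoint")
        object.__setattr__(self, "selected", frozenset(self.selected))
        object.__setattr__(self, "eliminated", frozenset(self.eliminated))
        object.__setattr__(self, "parameters", dict(self.parameters))
        if self.cluster_labels is not None:
            object.__setattr__(self, "cluster_labels", dict(self.cluster_labels))

    @property
    def universe(self) -> frozenset[int]:
        return self.selected | self.eliminated


def prune_energy(
    ensemble: "ConformerEnsemble", config: PruningConfig | None = None
) -> SelectionResult:
    """Keep conformers with relative low-level energy <= the threshold."""
    config = config or PruningConfig()
    keep = {
        c.index
        for c, e in zip(ensemble.conformers, ensemble.rel_energy)
        if e <= config.energy_threshold
    }
    return SelectionResult(
        method="energy",
        parameters={"energy_threshold": config.energy_threshold},
        selected=frozenset(keep),
        eliminated=frozenset(set(ensemble.indices) - keep),
    )


def _greedy_rmsd_keep(
    ensemble: "ConformerEnsemble", positions: Sequence[int], threshold: float
) -> set[int]:
    """Greedy geometric deduplication over the given storage positions.

    Positions are visited in ascending (rel_energy, index) order; a
    conformer is kept iff its heavy-atom Kabsch RMSD to every kept
    conformer exceeds ``threshold``. The lowest-energy conformer is always
    kept.
    """
    mask = geometry.heavy_atom_mask(ensemble.conformers[0].elements)
    order = sorted(
        positions, key=lambda p: (ensemble.rel_energy[p], ensemble.conformers[p].index)
    )
    kept: list[int] = []
    for p in order:
        dup = False
        for q in kept:
            r = geometry.kabsch_rmsd(
                ensemble.conformers[q].coords, ensemble.conformers[p].coords, mask
            ).rmsd
            if r <= threshold:
                dup = True
                break
        if not dup:
            kept.append(p)
    return {ensemble.conformers[p].index for p in kept}


def prune_rmsd(
    ensemble: "ConformerEnsemble", config: PruningConfig | None = None
) -> SelectionResult:
    """Greedy RMSD deduplication in ascending energy order (geometry pruning)."""
    config = config or PruningConfig()
    keep = _greedy_rmsd_keep(ensemble, range(len(ensemble)), config.rmsd_threshold)
    return SelectionResult(
        method="rmsd",
        parameters={"rmsd_threshold": config.rmsd_threshold},
        selected=frozenset(keep),
        eliminated=frozenset(set(ensemble.indices) - keep),
    )


def prune_combined(
    ensemble: "ConformerEnsemble", config: PruningConfig | None = None
) -> SelectionResult:
    """Energy pruning first, then RMSD deduplication among the survivors."""
    config = config or PruningConfig()
    by_energy = prune_energy(ensemble, config).selected
    survivors = [
        p for p, c in enumerate(ensemble.conformers) if c.index in by_energy
    ]
    keep = _greedy_rmsd_keep(ensemble, survivors, config.rmsd_threshold)
    return SelectionResult(
        method="combined",
        parameters={
            "energy_threshold": config.energy_threshold,
            "rmsd_threshold": config.rmsd_threshold,
        },
        selected=frozenset(keep),
        eliminated=frozenset(set(ensemble.indices) - keep),
    )


def select_extremes(
    rows: Sequence["DescriptorRow"], candidate_set: Sequence[int] | None = None
) -> SelectionResult:
    """Keep conformers with extreme buried volume and cone angle.

    Selects the argmin and argmax of both descriptors over the candidate
    set (at most four conformers, fewer when extremes coincide); ties are
    broken toward the lowest conformer index. The result's universe is all
    conformers covered by ``rows``: candidates that are not extreme and
    non-candidates are eliminated.
    """
    universe = {r.conformer_index for r in rows}
    if candidate_set is None:
        candidates = universe
    else:
        candidates = set(int(i) for i in candidate_set)
        if not candidates <= universe:
            raise ValueError("candidate_set contains conformers without rows")
    if not candidates:
        raise ValueError("candidate set is empty")
    cand_rows = sorted(
        (r for r in rows if r.conformer_index in candidates),
        key=lambda r: r.conformer_index,
    )
    keep: set[int] = set()
    for key in ("buried_volume_pct", "cone_angle"):
        keep.add(min(cand_rows, key=lambda r: (getattr(r, key), r.conformer_index)).conformer_index)
        keep.add(max(cand_rows, key=lambda r: (getattr(r, key), -r.conformer_index)).conformer_index)
    return SelectionResult(
        method="extremes",
        parameters={"descriptors": ["buried_volume_pct", "cone_angle"]},
        selected=frozenset(keep),
        eliminated=frozenset(universe - keep),
    )


def pca_project(
    matrix: np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardize features and project onto the first two principal axes.

    Each feature is scaled to zero mean and unit (population) standard
    deviation; constant features are dropped and reported. Components come
    from the eigendecomposition of the correlation matrix, with the sign
    convention that each component's largest-magnitude loading is
    positive.

    Returns ``(scores, explained_fractions, dropped_features)`` where
    ``scores`` is n x 2 and ``explained_fractions`` are the variance
    fractions of the two components.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 observations")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(x.shape[1])
    ]
    std = x.std(axis=0)
    keep = std > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    if keep.sum() < 2:
        raise ValueError("PCA needs at least 2 non-constant features")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / std[keep]
    corr = z.T @ z / z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order[:2]]
    for k in range(2):
        j = int(np.argmax(np.abs(comps[:, k])))
        if comps[j, k] < 0:
            comps[:, k] = -comps[:, k]
    scores = z @ comps
    explained = evals[:2] / evals.sum() if evals.sum() > 0 else np.zeros(2)
    return scores, explained, dropped


def dbscan_select(
    ensemble: "ConformerEnsemble", config: ClusterConfig | None = None
) -> SelectionResult:
    """DBSCAN on (relative energy, RMSD-to-reference); keep one conformer per
    cluster plus all noise points.

    Features are standardized per ensemble to zero mean and unit
    population variance (a zero-variance feature becomes all zeros), then
    clustered with Euclidean DBSCAN (boundary-inclusive neighbourhoods).
    Each cluster contributes its lowest-relative-energy member (ties to
    the lowest index); noise points (label -1) are always retained.
    """
    config = config or ClusterConfig()
    feats = np.column_stack([ensemble.rel_energy, ensemble.rmsd_ref]).astype(float)
    if config.standardize:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd_safe = np.where(sd > 1e-12, sd, 1.0)
        feats = np.where(sd > 1e-12, (feats - mu) / sd_safe, 0.0)
    labels = DBSCAN(eps=config.epsilon, min_samples=config.min_samples).fit_predict(
        feats
    )
    keep: set[int] = set()
    for lab in set(labels.tolist()):
        members = np.flatnonzero(labels == lab)
        if lab == -1:
            keep.update(ensemble.conformers[p].index for p in members)
        else:
            best = min(
                members,
                key=lambda p: (ensemble.rel_energy[p], ensemble.conformers[p].index),
            )
            keep.add(ensemble.conformers[best].index)
    label_map = {
        ensemble.conformers[p].index: int(lab) for p, lab in enumerate(labels)
    }
    return SelectionResult(
        method="dbscan",
        parameters={
            "epsilon": config.epsilon,
            "min_samples": config.min_samples,
            "standardize": config.standardize,
        },
        selected=frozenset(keep),
        eliminated=frozenset(set(ensemble.indices) - keep),
        cluster_labels=label_map,
    )


# ---------------------------------------------------------------------------
# selection serialization (deterministic, round-tripping JSON)
# ---------------------------------------------------------------------------


def write_selection(result: SelectionResult, path: str | Path) -> None:
    """Write a selection as sorted, machine-readable JSON.

    Re-serializing a file read back produces byte-identical output.
    """
    payload: dict[str, object] = {
        "method": result.method,
        "parameters": {k: result.parameters[k] for k in sorted(result.parameters)},
        "selected": sorted(result.selected),
        "eliminated": sorted(result.eliminated),
    }
    if result.cluster_labels is not None:
        payload["cluster_labels"] = {
            str(k): result.cluster_labels[k] for k in sorted(result.cluster_labels)
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_selection(path: str | Path) -> SelectionResult:
    """Read a selection written by :func:`write_selection`."""
    data = json.loads(Path(path).read_text())
    labels = data.get("cluster_labels")
    return SelectionResult(
        method=data["method"],
        parameters=data["parameters"],
        selected=frozenset(int(i) for i in data["selected"]),
        eliminated=frozenset(int(i) for i in data["eliminated"]),
        cluster_labels=(
            {int(k): int(v) for k, v in labels.items()} if labels is not None else None
        ),
    )
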