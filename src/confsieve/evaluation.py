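"""Scoring predicted conformer subsets against a DFT ground truth.

The ground truth is built from converged high-level (DFT) energies:
conformers within a chemical-accuracy window (default 5 kJ/mol) of a
group's lowest member are considered the same DFT minimum. A predicted
subset is then scored with a confusion matrix defined per minimum:

* exactly one conformer per minimum is *significant* (needed to cover the
  DFT ensemble); all others are *redundant*;
* a covered minimum contributes one true positive (attributed to its
  lowest-energy selected member), its other selected members are false
  positives, and its eliminated members true negatives;
* a missed minimum contributes one false negative and its remaining
  members are true negatives.

Hence TP + FN = number of minima, TP + FP = size of the selection, and
TN + FP = number of redundant conformers. A good selection maximizes TN
(redundancy removed) while keeping FN at zero (no minimum overlooked).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import (
    ClusterConfig,
    PruningConfig,
    SelectionResult,
    dbscan_select,
    prune_combined,
    prune_energy,
    prune_rmsd,
)

if TYPE_CHECKING:  # pragma: no cover
    from .ensemble_io import ConformerEnsemble, DftRecord

__all__ = [
    "MinimumAssignment",
    "ConfusionCounts",
    "SweepPoint",
    "group_dft_minima",
    "read_truth_table",
    "write_truth_table",
    "restrict_to_labeled",
    "confusion",
    "epsilon_sweep",
    "method_report",
    "MethodReport",
]

#: Chemical-accuracy window for grouping DFT energies, kJ/mol.
CHEMICAL_ACCURACY_KJMOL = 5.0


@dataclass(frozen=True)
class MinimumAssignment:
    """Mapping of every evaluable conformer to its DFT-minimum label.

    Labels are contiguous integers from 0, ordered by ascending minimum
    energy; ``minima`` maps each label to the lowest high-level energy
    (kJ/mol) of its group.
    """

    labels: Mapping[int, int]
    minima: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "minima", dict(self.minima))
        expect = list(range(len(self.minima)))
        if sorted(self.minima) != expect:
            raise ValueError("minimum labels must be contiguous from 0")
        energies = [self.minima[k] for k in expect]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise ValueError("labels must be ordered by ascending minimum energy")
        if not set(self.labels.values()) <= set(expect):
            raise ValueError("conformer labels must reference existing minima")

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    @property
    def n_conformers(self) -> int:
        return len(self.labels)

    def members(self, label: int) -> set[int]:
        return {i for i, lab in self.labels.items() if lab == label}


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts for one (selection, truth) pair."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_minima: int
    n_conformers: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn != self.n_minima:
            raise ValueError("TP + FN must equal the number of minima")
        if self.tp + self.fp + self.tn + self.fn != self.n_conformers:
            raise ValueError("counts must sum to the number of conformers")

    @property
    def n_redundant(self) -> int:
        """Conformers not needed to cover the DFT ensemble."""
        return self.n_conformers - self.n_minima

    @property
    def redundant_removed_pct(self) -> float:
        """TN as a percentage of the redundant total (the paper-style %)."""
        return 100.0 * self.tn / self.n_redundant if self.n_redundant else 0.0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
            n_minima=self.n_minima + other.n_minima,
            n_conformers=self.n_conformers + other.n_conformers,
        )


@dataclass(frozen=True)
class SweepPoint:
    """Aggregated confusion counts at one DBSCAN epsilon."""

    epsilon: float
    tn: int
    fn: int
    tp: int
    fp: int
    per_ensemble: tuple[ConfusionCounts, ...]


def group_dft_minima(
    records: Iterable["DftRecord"],
    window: float = CHEMICAL_ACCURACY_KJMOL,
    use_gibbs: bool = False,
) -> MinimumAssignment:
    """Group converged DFT outcomes into minima by anchored energy windows.

    Records are sorted by ascending energy; a record joins the current
    group iff it lies within ``window`` kJ/mol of the group's anchor (its
    lowest member), otherwise it starts a new group. Labels follow energy
    order. Non-converged records are ignored; ``use_gibbs`` ranks by Gibbs
    energy instead of the electronic energy.
    """
    conv = [r for r in records if r.converged]
    if not conv:
        raise ValueError("no converged DFT records to group")

    def energy(r: "DftRecord") -> float:
        if use_gibbs:
            if r.gibbs is None:
                raise ValueError(
                    f"conformer {r.conformer_index} lacks a Gibbs energy"
                )
            return r.gibbs
        return float(r.energy_high)  # type: ignore[arg-type]

    conv.sort(key=lambda r: (energy(r), r.conformer_index))
    labels: dict[int, int] = {}
    minima: dict[int, float] = {}
    anchor = None
    lab = -1
    for r in conv:
        e = energy(r)
        if anchor is None or e - anchor > window:
            lab += 1
            anchor = e
            minima[lab] = e
        labels[r.conformer_index] = lab
    return MinimumAssignment(labels=labels, minima=minima)


def read_truth_table(path: str | Path) -> MinimumAssignment:
    """Read an explicit (conformer_index, minimum_label[, minimum_energy]) CSV.

    The override channel for manually curated ground truths. Without an
    energy column, labels keep their stated order with placeholder
    energies.
    """
    df = pd.read_csv(path)
    labels = {
        int(r["conformer_index"]): int(r["minimum_label"]) for _, r in df.iterrows()
    }
    if "minimum_energy" in df.columns:
        minima = {
            int(lab): float(df.loc[df["minimum_label"] == lab, "minimum_energy"].min())
            for lab in sorted(set(labels.values()))
        }
    else:
        minima = {lab: float(lab) for lab in sorted(set(labels.values()))}
    return MinimumAssignment(labels=labels, minima=minima)


def write_truth_table(truth: MinimumAssignment, path: str | Path) -> None:
    rows = [
        {
            "conformer_index": i,
            "minimum_label": lab,
            "minimum_energy": truth.minima[lab],
        }
        for i, lab in sorted(truth.labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def restrict_to_labeled(
    selection: SelectionResult, truth: MinimumAssignment
) -> SelectionResult:
    """Drop conformers without a DFT label from a selection's universe.

    Mirrors the exclusion of non-converged / imaginary-frequency conformers
    from the evaluation universe before scoring.
    """
    labeled = set(truth.labels)
    return SelectionResult(
        method=selection.method,
        parameters=selection.parameters,
        selected=frozenset(selection.selected & labeled),
        eliminated=frozenset(selection.eliminated & labeled),
        cluster_labels=selection.cluster_labels,
    )


def confusion(selection: SelectionResult, truth: MinimumAssignment) -> ConfusionCounts:
    """Score a selection against the DFT-minimum assignment.

    Every conformer in the selection's universe must carry a label
    (restrict with :func:`restrict_to_labeled` first if needed).
    """
    unlabeled = selection.universe - set(truth.labels)
    if unlabeled:
        raise ValueError(f"conformers without a DFT label: {sorted(unlabeled)}")
    tp = fp = tn = fn = 0
    for lab in truth.minima:
        members = truth.members(lab) & selection.universe
        if not members:
            continue  # minimum entirely outside the evaluation universe
        sel = members & selection.selected
        if sel:
            tp += 1
            fp += len(sel) - 1
            tn += len(members) - len(sel)
        else:
            fn += 1
            tn += len(members) - 1
    n_conf = len(selection.universe)
    return ConfusionCounts(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_minima=tp + fn,
        n_conformers=n_conf,
    )


def epsilon_sweep(
    ensembles: Sequence[tuple["ConformerEnsemble", MinimumAssignment]],
    grid: Sequence[float],
    config: ClusterConfig | None = None,
) -> list[SweepPoint]:
    """Aggregated confusion counts of the DBSCAN strategy over an epsilon grid."""
    if len(grid) == 0:
        raise ValueError("epsilon grid is empty")
    base = config or ClusterConfig()
    points: list[SweepPoint] = []
    for eps in grid:
        cfg = ClusterConfig(
            epsilon=float(eps),
            min_samples=base.min_samples,
            standardize=base.standardize,
        )
        per: list[ConfusionCounts] = []
        for ens, truth in ensembles:
            sel = restrict_to_labeled(dbscan_select(ens, cfg), truth)
            per.append(confusion(sel, truth))
        points.append(
            SweepPoint(
                epsilon=float(eps),
                tn=sum(c.tn for c in per),
                fn=sum(c.fn for c in per),
                tp=sum(c.tp for c in per),
                fp=sum(c.fp for c in per),
                per_ensemble=tuple(per),
            )
        )
    return points


def sweep_to_frame(points: Sequence[SweepPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epsilon": [p.epsilon for p in points],
            "tn": [p.tn for p in points],
            "fn": [p.fn for p in points],
            "tp": [p.tp for p in points],
            "fp": [p.fp for p in points],
        }
    )


@dataclass(frozen=True)
class MethodReport:
    """Per-method aggregated confusion counts plus the missed-minimum listing."""

    aggregated: Mapping[str, ConfusionCounts]
    missed: tuple[tuple[str, str, int, int], ...]
    """(method, ensemble id, minimum label, energy rank) for each FN."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, c in self.aggregated.items():
            rows.append(
                {
                    "method": method,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "n_minima": c.n_minima,
                    "n_conformers": c.n_conformers,
                    "redundant_removed_pct": c.redundant_removed_pct,
                }
            )
        return pd.DataFrame(rows)


def method_report(
    ensembles: Sequence[tuple["ConformerEnsemble", MinimumAssignment]],
    pruning: PruningConfig | None = None,
    cluster: ClusterConfig | None = None,
    names: Sequence[str] | None = None,
) -> MethodReport:
    """Compare the pruning strategies (and DBSCAN) across ensembles.

    For every strategy, aggregates the confusion counts over all ensembles
    and lists each minimum missed (its ensemble, label and energy rank —
    rank 0 being the global DFT minimum of that ensemble).
    """
    pruning = pruning or PruningConfig()
    cluster = cluster or ClusterConfig()
    if names is None:
        names = [f"E{i}" for i in range(len(ensembles))]
    strategies = {
        "rmsd": lambda e: prune_rmsd(e, pruning),
        "energy": lambda e: prune_energy(e, pruning),
        "combined": lambda e: prune_combined(e, pruning),
        "dbscan": lambda e: dbscan_select(e, cluster),
    }
    aggregated: dict[str, ConfusionCounts] = {}
    missed: list[tuple[str, str, int, int]] = []
    for method, run in strategies.items():
        total: ConfusionCounts | None = None
        for name, (ens, truth) in zip(names, ensembles):
            sel = restrict_to_labeled(run(ens), truth)
            c = confusion(sel, truth)
            total = c if total is None else total + c
            if c.fn:
                for lab in truth.minima:
                    if not truth.members(lab) & sel.universe & sel.selected:
                        # label order == energy rank by construction
                        missed.append((method, name, lab, lab))
        assert total is not None
        aggregated[method] = total
    return MethodReport(aggregated=aggregated, missed=tuple(missed))
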