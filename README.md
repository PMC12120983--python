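# confsieve

Automated conformer selection for transition-metal complexes: map a cheap,
over-complete low-level conformer ensemble (CREST/GFN2-xTB style) onto the
small set of minima that survive DFT refinement — without running the DFT.

## The problem

High-throughput screening of homogeneous catalysts (e.g. Rh–bisphosphine
hydrogenation precatalysts) needs conformer-aware molecular representations.
Low-level ensemble generators are cheap but overestimate flexibility: dozens
of low-level conformers typically collapse onto one or two DFT minima, and
the low-level energy ranking correlates poorly with the DFT ranking. Refining
every conformer at the DFT level wastes most of the compute; picking only
low-energy conformers risks missing true DFT minima. `confsieve` implements
and evaluates the filtering strategies for this selection step:

1. **energy pruning** — drop conformers with relative low-level energy
   ΔE > 12.55 kJ/mol (3.0 kcal/mol);
2. **RMSD pruning** — greedy geometric deduplication: visiting conformers in
   ascending energy, keep one only if its heavy-atom Kabsch RMSD to every
   kept conformer exceeds 0.35 Å;
3. **descriptor extremes** — keep the conformers with minimal/maximal percent
   buried volume (%V<sub>bur</sub>, 4 Å sphere at the metal) and exact ligand
   cone angle, optionally after pruning;
4. **DBSCAN clustering** on standardized (ΔE, RMSD) features with
   `min_samples = 2`: keep the lowest-energy member of each cluster plus every
   noise point, tunable through the neighbourhood radius ε.

Any predicted subset is scored against a DFT ground truth in which converged
DFT energies within a 5 kJ/mol chemical-accuracy window count as one minimum.
The confusion matrix is defined per minimum: a covered minimum contributes one
true positive (its other selected members are false positives, its eliminated
members true negatives); a missed minimum is a false negative. So
TP + FN = #minima, TP + FP = |selection|, and TN counts the redundant
conformers correctly eliminated — the quantity a good filter maximizes while
holding FN at zero.

Because real CREST + DFT data is bulky, the package ships a synthetic
generator that emulates the essential structure — many conformers per basin,
well-separated basins, decorrelated low-level energies — with exact ground
truth, so the whole pipeline is testable end to end.

## Worked example

```bash
confsieve simulate --out demo/fx --seed 7 --n-basins 3
confsieve cluster demo/fx --epsilon 0.19 --out demo/sel.json
confsieve evaluate demo/fx --selection demo/sel.json --out demo/confusion.csv
confsieve pipeline demo/fx --out demo/report.csv
```

which logs

```
INFO confsieve: wrote 30 conformers in 3 basins to demo/fx
INFO confsieve: DBSCAN eps=0.190: 3 clusters, kept 4 / 30
INFO confsieve: TP 3  FP 1  TN 26  FN 0 (3 minima, 30 conformers)
INFO confsieve: rmsd     TN   27  FN  0  (removed 100% of redundant)
INFO confsieve: energy   TN   11  FN  1  (removed 41% of redundant)
INFO confsieve: combined TN   27  FN  1  (removed 100% of redundant)
INFO confsieve: dbscan   TN   26  FN  0  (removed 96% of redundant)
INFO confsieve: missed minimum: method=energy ensemble=fx label=2 energy_rank=2
```

Reading: the simulated ensemble has 30 conformers in 3 DFT basins (so 27 are
redundant). DBSCAN at ε = 0.19 keeps 4 conformers covering all 3 minima
(TP 3, FN 0) with one redundant pick (FP 1), eliminating 26 of 27 redundant
conformers. Energy pruning keeps far more conformers yet still misses the
highest-energy DFT minimum (`energy_rank=2`) — the low-level energies are
decorrelated from the DFT ones, which is exactly why energy-only filtering is
unreliable. RMSD pruning removes all 27 redundant conformers and misses
nothing.

The library mirrors the CLI one-to-one:

```python
from confsieve import (BasinSpec, ClusterConfig, generate_ensemble,
                       group_dft_minima, dbscan_select, restrict_to_labeled,
                       confusion)

synth = generate_ensemble(BasinSpec(n_basins=3, seed=7))
truth = group_dft_minima(list(synth.records))          # 5 kJ/mol grouping
sel = dbscan_select(synth.ensemble, ClusterConfig(epsilon=0.19))
print(confusion(restrict_to_labeled(sel, truth), truth))
# ConfusionCounts(tp=3, fp=1, tn=26, fn=0, n_minima=3, n_conformers=30)
```

Real data enters through the same readers the fixtures use: CREST-dialect
multi-structure XYZ (energy in the comment line, Hartree by default), an MDL
V2000 Molfile for connectivity, and a CSV of per-conformer DFT outcomes
(`conformer_index, converged, energy_high[, gibbs, n_imaginary]`).

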