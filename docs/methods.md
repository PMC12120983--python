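# Methods

This note documents the models, conventions and numerical choices behind
`confsieve`, and what the synthetic benchmark does and does not demonstrate.

## Geometry

**Superposition and RMSD.** All RMSDs are least-squares Kabsch
superpositions over *proper* rotations (SVD with a determinant correction;
reflections excluded). Excluding reflections is deliberate: a mirror image
keeps a non-zero RMSD, so chirality information cannot leak into
geometry-based filtering. "Heavy atoms" means every element except hydrogen,
including the metal. Atom order is assumed identical across conformers (the
ensemble generators this package consumes guarantee it); no graph matching or
symmetry-corrected reordering is attempted, because silent reordering would
change results invisibly. Fewer than three (or collinear) masked atoms give a
well-defined but rank-deficient fit, flagged on the result.

**Chirality consistency.** A testable center is any atom with exactly four
bonded neighbours. Its handedness is the sign of det[v1 v2 v3] over the edge
vectors to its first three neighbours in index order — a fixed convention
that is comparable between conformers sharing atom order and connectivity,
which is all the preprocessing step needs (full CIP ranking is out of scope).
A center is flipped only when the signs differ *and* both determinant
magnitudes exceed 1e-3 Å³; near-planar centers carry no reliable handedness
and are never flagged. Conformers with any flipped center are removed before
filtering, and ensemble bookkeeping (reference conformer, relative energies,
RMSD-to-reference) is recomputed.

## Steric descriptors

**Percent buried volume.** Deterministic uniform cubic-grid integration
(default spacing 0.10 Å) of the sphere of radius 4.0 Å centered on the metal:
a grid point is buried if it lies inside any subset atom's scaled van der
Waals sphere. Defaults follow the conventions of the standard buried-volume
tooling: Bondi radii × 1.17, hydrogens excluded, the metal itself excluded
from occupancy. Halving the grid spacing moves values by < 0.3 percentage
points on the test fixtures; rigid rotations of the complex move them by
< 0.2 points (grid anisotropy). A Monte-Carlo integrator exists in the test
suite purely as an independent oracle — the grid is the implementation
because it is deterministic.

**Exact cone angle.** Each ligand atom contributes a tangent cone with
half-angle β = arcsin(r/d) about the metal→atom axis (r = unscaled Bondi
radius, Tolman-style convention; d = distance to the metal, which must exceed
r). The reported angle is the full aperture of the minimal cone containing
every atom cone. The minimal cone is pinned by one, two or three atom cones;
all three candidate families are enumerated: single cones, pair candidates on
the geodesic between two axes (half-aperture (γ + βi + βj)/2), and triple
candidates found by solving n·mk = cos(α − βk) as a linear system in the axis
n and root-finding |n(α)|² = 1 (bracket scan over 256 apertures, Brent
refinement to 1e-10). Feasibility testing uses a 1e-7 rad slack because
arccos is ill-conditioned near ±1. The smallest feasible candidate is
returned; equal-aperture ties break by lexicographic axis order for
determinism. Triples are skipped only when provably unable to beat the
current best (their max β already exceeds it).

**Descriptor atom subset.** By default the connected component(s) containing
the donor atoms after deleting the metal from the connectivity graph — the
bidentate ligand without the trans-coordinated moiety. A whole-complex subset
can be passed explicitly; the convention is configurable because published
usage is ambiguous about whether trans ligands count.

## Selection strategies

* **Energy pruning**: keep ΔE ≤ 12.55 kJ/mol (3.0 kcal/mol). Boundary
  values are kept (≤, not <) for determinism.
* **RMSD pruning**: greedy pairwise deduplication in ascending-energy order
  (threshold 0.35 Å), not merely comparison against the single lowest-energy
  conformer: comparing only against the reference would keep near-duplicates
  of non-reference conformers. The lowest-energy conformer is always kept.
* **Combined**: energy pruning first, then RMSD deduplication among the
  survivors. The order matters for which near-duplicates survive and is a
  package choice; the configuration object keeps both thresholds explicit.
* **Extreme descriptors**: argmin/argmax of %Vbur and cone angle over a
  candidate pool (at most four conformers; ties to the lowest index).
* **DBSCAN** on (ΔE, RMSD-to-reference): features are standardized per
  ensemble to zero mean and unit population variance (a zero-variance feature
  becomes identically zero — raw kJ/mol and Å are incommensurable, and ε
  values near 0.1–0.3 are only meaningful on standardized features).
  Euclidean neighbourhoods are boundary-inclusive; `min_samples = 2`. Each
  cluster is represented by its lowest-energy member (the natural candidate
  for refinement); noise points are always retained so that geometric
  outliers — precisely the conformers most likely to be distinct minima —
  are never silently dropped.
* **PCA** of the descriptor table (standard scaling, eigendecomposition of
  the correlation matrix, first two components, largest-magnitude loading
  forced positive) is provided for exploratory projection only; no selection
  strategy is built on it, since descriptor-space proximity does not track
  DFT energy grouping.

## Ground truth and scoring

Converged DFT records are sorted by energy and grouped by **anchored**
5 kJ/mol windows: a record joins the current group iff it lies within the
window of the group's *lowest* member, else it starts a new group. Anchoring
(rather than transitive chaining) is used because chaining can merge
arbitrarily distant energies through stepping stones; the window and the
choice of electronic vs Gibbs energy are configurable. Non-converged or
imaginary-frequency conformers are excluded from the evaluation universe
before scoring. A manually curated truth table can be supplied as a CSV
override.

Within a covered minimum the true positive is attributed to the lowest-energy
selected member; this split between TP and FP never affects TN or FN, which
are the assessment parameters that matter (TN = redundancy removed,
FN = minima lost).

## Synthetic benchmark

The generator emulates the structure of real low-level ensembles of
Rh–bisphosphine complexes:

* a rigid scaffold with the metal at the origin, two P donors (bite angle
  ≈ 90°, Rh–P 2.3 Å), a two-carbon trans moiety, a carbon backbone bridging
  the donors, chain-biased random carbon substituents and capping hydrogens
  (24 atoms, 30 % H by default). The metal is always a testable 4-coordinate
  chirality center.
* **basins** are torsionally displaced scaffold copies: random subtree
  rotations about bridge bonds plus rigid ligand twists about axes through
  the metal, accepted when mutually ≥ 1.0 Å heavy-atom RMSD apart
  (`between_rmsd_min`), chirality-consistent, and outside the metal's vdW
  exclusion zone.
* **conformers** add isotropic Gaussian jitter rescaled iteratively until the
  realized RMSD-to-template matches `within_rmsd` (0.15 Å default) within
  2 %; rescaling avoids deriving the Kabsch shrinkage analytically.
* **DFT energies**: consecutive basin anchors ≥ 6 kJ/mol apart
  (`basin_energy_min_gap`), plus ≤ 1 kJ/mol uniform intra-basin noise — so
  5 kJ/mol anchored grouping recovers exactly the generated basins.
* **xTB energies**: DFT energy + a per-basin bias ~ N(0, 10 kJ/mol) +
  per-conformer noise ~ N(0, 0.5) truncated at 2σ. Basin offsets are redrawn
  until all basin mean xTB energies stay ≥ 6 kJ/mol apart: basins remain
  resolvable in the standardized (ΔE, RMSD) plane — matching the empirical
  situation where a zero-false-negative ε range exists — while the bias
  still scrambles the low-level ranking (at bias twice the DFT spread the
  mean basin-level Spearman correlation is ≈ 0.34; at bias equal to the
  spread the pinned ≥ 6 kJ/mol gaps retain ≈ 0.65).
* an optional `mirror_fraction` of conformers is inverted through the metal
  to exercise the chirality filter; fixtures are written in kJ/mol (a
  Hartree-mode path exists to test unit conversion); everything is
  reproducible from the seed, and conformers are emitted in ascending xTB
  energy order as a real ensemble file would be.

The default benchmark is 24 ensembles with basin counts cycling 1–4 and
4–12 conformers per basin (≈ 470 conformers, ≈ 60 minima) — sized so the
full pipeline, the ε sweep and the descriptor route run in minutes on one
core while still averaging ~20 conformers and ~2.5 minima per ensemble.

**What passing means.** The generator produces *clean* basins: well
separated in RMSD, gap-bounded in DFT energy, with isotropic intra-basin
noise. Success on it shows the machinery is correct (grouping recovers the
construction, DBSCAN finds an FN = 0 regime eliminating > 90 % of redundancy,
energy pruning misses minima once the ranking is decorrelated while RMSD
pruning does not). It does not show that any particular ε transfers to real
chemistry, where basins overlap in the (ΔE, RMSD) plane, RMSD-to-reference
can alias distinct basins at equal distance, and the ground truth itself
required manual curation. On real data ε must be re-tuned per structural
family, and the zero-FN window can be empty.

## Other numerical choices

* Energies are kJ/mol internally (1 Eh = 2625.4996394799 kJ/mol;
  1 kcal = 4.184 kJ); coordinates are Å.
* XYZ comment-line energies default to Hartree; the first parseable float
  token is used, so trailing labels are tolerated.
* Selection files are sorted JSON: re-serialization of a read file is
  byte-identical.
* All tie-breaks (pruning order, cluster representatives, extreme
  descriptors) resolve toward the lowest conformer index.

## Known limitations

* No symmetry-corrected RMSD: topologically equivalent atom permutations
  count as geometric difference.
* The chirality test covers only 4-coordinate centers with the index-order
  determinant convention; exotic coordination geometries may need a custom
  criterion.
* The cone angle is undefined when the metal sits inside a ligand atom's
  vdW sphere (an error is raised rather than a value extrapolated).
* Gaussian/xTB log parsing is out of scope; DFT outcomes enter as a
  distilled CSV.
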