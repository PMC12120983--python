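"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the implementation
it validates: quaternion eigendecomposition vs SVD Kabsch, Monte-Carlo vs
grid integration, direction grid search vs geometric candidate
enumeration, sequential textbook DBSCAN vs scikit-learn, and a literal
per-conformer reading of the confusion-matrix definitions vs the grouped
formula.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def quaternion_rmsd(ref: np.ndarray, test: np.ndarray, mask=None) -> float:
    """Horn's closed-form minimum RMSD via the 4x4 key-matrix eigenproblem."""
    ref = np.asarray(ref, float)
    test = np.asarray(test, float)
    if mask is not None:
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ref, test = ref[idx], test[idx]
    n = ref.shape[0]
    p = test - test.mean(axis=0)
    q = ref - ref.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    gp = (p**2).sum()
    gq = (q**2).sum()
    return math.sqrt(max(0.0, (gp + gq - 2.0 * lam)) / n)


def mc_buried_volume(
    centers: np.ndarray,
    radii: np.ndarray,
    sphere_radius: float,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo %Vbur: uniform samples in the metal sphere (at origin)."""
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_samples, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    r = sphere_radius * np.cbrt(rng.uniform(size=n_samples))
    pts = d * r[:, None]
    buried = np.zeros(n_samples, dtype=bool)
    for c, rad in zip(np.asarray(centers, float), np.asarray(radii, float)):
        buried |= ((pts - c) ** 2).sum(axis=1) <= rad * rad
    return 100.0 * buried.mean()


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi * i), rho * np.sin(phi * i), z])


def gridsearch_cone_angle(
    vectors: np.ndarray, radii: np.ndarray, n_dirs: int = 100_000
) -> float:
    """Minimal enclosing cone aperture (degrees) by direction grid search.

    Scans a Fibonacci sphere of candidate axes minimizing
    max_i(angle(axis, m_i) + beta_i), then refines the best axis locally
    (Nelder-Mead on the tangent plane).
    """
    v = np.asarray(vectors, float)
    d = np.linalg.norm(v, axis=1)
    m = v / d[:, None]
    beta = np.arcsin(np.asarray(radii, float) / d)
    dirs = _fibonacci_sphere(n_dirs)
    f = np.arccos(np.clip(dirs @ m.T, -1, 1)) + beta
    worst = f.max(axis=1)
    best = dirs[int(np.argmin(worst))]
    # local refinement around the best axis: parametrize by tangent offsets
    t1 = np.cross(best, [1.0, 0.0, 0.0])
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(best, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(best, t1)

    def objective(ab):
        axis = best + ab[0] * t1 + ab[1] * t2
        axis /= np.linalg.norm(axis)
        return float(np.max(np.arccos(np.clip(m @ axis, -1, 1)) + beta))

    res = minimize(
        objective, [0.0, 0.0], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return math.degrees(2.0 * res.fun)


def textbook_dbscan(x: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Sequential DBSCAN exactly as in the original region-query/expansion
    formulation: boundary-inclusive neighbourhoods that count the point
    itself; cluster ids in order of discovery; -1 for noise."""
    x = np.asarray(x, float)
    n = len(x)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if len(neighbors[i]) < min_samples:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbors[i])
        k = 0
        while k < len(queue):
            j = queue[k]
            k += 1
            if labels[j] == -1:
                labels[j] = cluster  # border point claimed by this cluster
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if len(neighbors[j]) >= min_samples:
                queue.extend(neighbors[j])
    return labels


def bruteforce_confusion(
    labels: dict[int, int],
    energies: dict[int, float],
    selected: set[int],
) -> tuple[int, int, int, int]:
    """Literal per-conformer application of the confusion definitions.

    For every conformer, asks "is its DFT minimum represented by other
    conformers in the predicted subset?"; within a minimum the single
    necessary ('significant') conformer is its lowest-energy selected
    member if covered, else its lowest-energy member overall.
    Returns (tp, fp, tn, fn).
    """
    tp = fp = tn = fn = 0
    for i, lab in labels.items():
        group = [j for j, l in labels.items() if l == lab]
        sel_group = [j for j in group if j in selected]
        if sel_group:
            significant = min(sel_group, key=lambda j: (energies[j], j))
        else:
            significant = min(group, key=lambda j: (energies[j], j))
        if i in selected:
            if i == significant:
                tp += 1  # needed: its minimum is not covered by anyone else
            else:
                fp += 1  # redundant: minimum already represented
        else:
            if i == significant:
                fn += 1  # necessary conformer wrongly eliminated
            else:
                tn += 1  # redundant conformer correctly eliminated
    return tp, fp, tn, fn
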