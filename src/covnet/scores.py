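"""Network integrity scores, Dice matching, t-maps, goodness-of-fit selection.

*Integrity* of a structural covariance network for one subject is the OLS
coefficient of that network's component map when the subject's voxel map is
spatially regressed on **all** component maps jointly (plus an intercept) —
a high coefficient means the subject expresses the network's covariance
pattern strongly, a low one means the network is disrupted in that subject.

*Goodness of fit* (GOF) of a statistic map to a binary network template is
the mean of the map inside the template minus its mean outside; the
functional component with the highest GOF is selected as the functional
counterpart of a structural network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "integrity_scores",
    "integrity_table",
    "dice",
    "match_component_sets",
    "one_sample_tmap",
    "gof",
    "select_best_functional",
]


def integrity_scores(subject_matrix: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Per-subject network integrity via joint spatial regression.

    Regresses each subject's voxel vector on all k component maps plus an
    intercept (one multiple regression per subject); returns the
    subjects × k beta matrix.  Including all maps jointly decorrelates
    overlapping networks.  Raises on rank-deficient maps, listing the
    collinear components.
    """
    X = np.asarray(subject_matrix, dtype=float)
    M = np.asarray(maps, dtype=float)
    k, V = M.shape
    if X.shape[1] != V:
        raise ValueError("subject matrix and maps disagree on voxel count")
    D = np.column_stack([np.ones(V), M.T])
    rank = np.linalg.matrix_rank(D)
    if rank < k + 1:
        # identify offending components by leave-one-in correlation
        corr = np.corrcoef(M)
        np.fill_diagonal(corr, 0.0)
        bad = sorted(set(map(int, np.argwhere(np.abs(corr) > 0.999).ravel())))
        raise ValueError(f"component maps are rank deficient (collinear: {bad})")
    betas = np.linalg.lstsq(D, X.T, rcond=None)[0][1:]
    return betas.T


def integrity_table(subject_matrix, maps, meta: pd.DataFrame | None = None,
                    names: list[str] | None = None) -> pd.DataFrame:
    """Integrity scores as a tidy table with optional subject metadata."""
    betas = integrity_scores(subject_matrix, maps)
    k = betas.shape[1]
    names = names or [f"IC{j + 1}" for j in range(k)]
    df = pd.DataFrame(betas, columns=names)
    if meta is not None:
        df = pd.concat([meta.reset_index(drop=True), df], axis=1)
    return df


def dice(binA: np.ndarray, binB: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A| + |B|) of two binary masks.

    Returns 0.0 when both masks are empty (documented convention).
    """
    A = np.asarray(binA).astype(bool)
    B = np.asarray(binB).astype(bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((A & B).sum()) / denom


def match_component_sets(mapsA: np.ndarray, mapsB: np.ndarray,
                         z_threshold: float = 3.0) -> list[tuple[int, int, float]]:
    """Greedy pairing of two component sets by Dice of their z > t masks.

    Computes Dice between every pair of supra-threshold masks, then
    repeatedly pairs the best remaining (A, B) couple until one set is
    exhausted.  Returns ``[(iA, iB, dice), ...]`` sorted by descending Dice.
    """
    A = np.asarray(mapsA) > z_threshold
    B = np.asarray(mapsB) > z_threshold
    ka, kb = A.shape[0], B.shape[0]
    D = np.array([[dice(A[i], B[j]) for j in range(kb)] for i in range(ka)])
    pairs = []
    used_a, used_b = set(), set()
    for _ in range(min(ka, kb)):
        best, bi, bj = -1.0, -1, -1
        for i in range(ka):
            if i in used_a:
                continue
            for j in range(kb):
                if j in used_b:
                    continue
                if D[i, j] > best:
                    best, bi, bj = D[i, j], i, j
        pairs.append((bi, bj, float(best)))
        used_a.add(bi)
        used_b.add(bj)
    return pairs


def one_sample_tmap(subject_maps: np.ndarray):
    """Voxel-wise one-sample t-map, ``t = mean / (SD/√n)``.

    Zero-variance voxels get t = 0; the count of such voxels is returned
    alongside the map as ``(tmap, n_zero_variance)``.
    """
    X = np.asarray(subject_maps, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("one-sample t-map needs at least 3 subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros_like(mean)
    t[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(n))
    return t, int(zero.sum())


def gof(score_map: np.ndarray, template: np.ndarray) -> float:
    """Goodness of fit: mean score inside the template − mean outside."""
    m = np.asarray(score_map, dtype=float).ravel()
    t = np.asarray(template).astype(bool).ravel()
    if m.shape != t.shape:
        raise ValueError("score map and template shapes differ")
    n_in = int(t.sum())
    if n_in == 0 or n_in == t.size:
        raise ValueError("template must have both inside and outside voxels")
    return float(m[t].mean() - m[~t].mean())


def select_best_functional(maps: np.ndarray, labels, template: np.ndarray,
                           subject_maps: np.ndarray):
    """Pick the functional component best matching a structural template.

    ``subject_maps`` has shape (subjects, k, V) — per-subject component maps
    from dual regression.  Every subject gets one GOF score per signal
    component; the selected component maximizes the mean GOF across
    subjects (ties broken toward the lower component index).  Returns
    ``(selected_index, gof_table)`` where the table has one row per subject
    and one column per component (artifact components hold NaN).
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    n_sub, k, V = subject_maps.shape
    signal = [i for i, lab in enumerate(labels) if lab == "signal"]
    if not signal:
        raise ValueError("no signal components to select from")
    table = np.full((n_sub, k), np.nan)
    for j in signal:
        for s in range(n_sub):
            table[s, j] = gof(subject_maps[s, j], template)
    mean_gof = np.full(k, -np.inf)
    mean_gof[signal] = table[:, signal].mean(axis=0)
    selected = int(np.argmax(mean_gof))  # argmax takes the first (lowest) index on ties
    cols = [f"IC{j + 1}" for j in range(k)]
    return selected, pd.DataFrame(table, columns=cols)
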