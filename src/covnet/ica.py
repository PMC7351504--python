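"""Spatial group ICA: PCA whitening, Infomax, dual regression, thresholding.

The structural decomposition treats the subjects × voxels matrix of
morphometric maps as a linear mixture of spatial sources ("structural
covariance networks"): PCA reduces the subject dimension to the model order,
Infomax ICA unmixes the whitened data into maximally independent spatial
maps, and a stability wrapper (see :mod:`covnet.icasso`) repeats the
stochastic ICA step and keeps cluster centrotypes.  The functional
decomposition follows the standard two-stage group ICA recipe: per-subject
temporal PCA, temporal concatenation, group PCA, then the same spatial ICA.

Component maps are z-scored over the analysis mask, thresholded at z > 3 for
binary masks, and labelled *artifact* when most supra-threshold voxels fall
outside the brain mask — emulating how analysts discard non-brain components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "WhitenedData",
    "ComponentSet",
    "pca_reduce",
    "infomax_ica",
    "decompose_structural",
    "decompose_functional",
    "dual_regression",
    "threshold_map",
    "flag_artifact_components",
]


@dataclass
class WhitenedData:
    """PCA-reduced, whitened data ready for ICA.

    ``reduced`` (k × m) has uncorrelated unit-variance rows; ``dewhitening``
    (n_obs × k) maps component space back to the observation dimension so
    that ``dewhitening @ reduced ≈`` the centred input.
    """

    reduced: np.ndarray
    dewhitening: np.ndarray
    explained_variance: np.ndarray
    mean: np.ndarray  # per-feature mean removed before reduction

    @property
    def k(self) -> int:
        return self.reduced.shape[0]


@dataclass
class ComponentSet:
    """ICA component maps plus per-subject (or per-time) loadings."""

    maps: np.ndarray  # k × V, z-scored over the analysis mask
    loadings: np.ndarray  # subjects (or time) × k
    mask: np.ndarray  # analysis mask (grid-shaped bool)
    labels: list = field(default_factory=list)  # per-component signal/artifact
    iq: np.ndarray | None = None  # ICASSO stability per component
    converged: bool = True

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def signal_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab == "signal"],
                        dtype=int)


def pca_reduce(X: np.ndarray, k: int, center: str = "both") -> WhitenedData:
    """Whiten an observations × features matrix to its top-k subspace.

    Features (columns) are the samples the spatial sources are estimated
    over; observations (rows) are reduced from n to k.  Row i of ``reduced``
    is the i-th whitened principal coordinate, scaled to unit variance over
    the m feature-samples; ``dewhitening @ reduced`` reconstructs the
    centred data with error equal to the discarded eigenvalue mass.

    ``center`` controls internal centering: ``"both"`` (default) removes the
    mean feature map across observations — the common-anatomy removal used
    for group decompositions — and then each observation's own mean so the
    whitened rows are exactly zero-mean; ``"rows"`` removes only
    per-observation means (appropriate when observations are few mixture
    channels rather than a cohort).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(X.shape)={min(n, m)}")
    if center not in ("both", "rows"):
        raise ValueError("center must be 'both' or 'rows'")
    mean = X.mean(axis=0) if center == "both" else np.zeros(m)
    Xc = X - mean
    # remove per-observation means so whitened rows are exactly zero-mean
    Xc = Xc - Xc.mean(axis=1, keepdims=True)
    # eigendecomposition of the small n×n Gram matrix
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if evals[k - 1] <= max(n, m) * np.finfo(float).eps * evals[0]:
        raise ValueError(f"k={k} exceeds numerical rank of X")
    sv = np.sqrt(evals[:k])  # singular values of Xc
    U = evecs[:, :k]
    # whitened rows: sqrt(m) * V^T rows (unit variance over m samples)
    reduced = (U / sv).T @ Xc * np.sqrt(m)
    dewhitening = U * sv / np.sqrt(m)
    total = evals.sum()
    ev = evals[:k] / total if total > 0 else np.zeros(k)
    return WhitenedData(reduced=reduced, dewhitening=dewhitening,
                        explained_variance=ev, mean=mean)


def infomax_ica(
    Xw: WhitenedData | np.ndarray,
    seed: int = 0,
    max_steps: int = 512,
    tol: float = 1e-6,
    lrate: float | None = None,
    block: int | None = None,
):
    """Infomax ICA by stochastic natural-gradient ascent.

    Iterates ``W ← W + η (I + (1 − 2y) uᵀ / L) W`` over randomized data
    blocks, with ``u = W x_block`` and ``y = logistic(u)`` — the classic
    natural-gradient Infomax update with a logistic (super-Gaussian-seeking)
    nonlinearity.  The learning rate anneals by ×0.9 whenever the update
    direction turns by more than 60°, and the whole pass restarts from a
    fresh random matrix at a lower rate if the weights blow up.

    Returns ``(W, S, converged)``: the unmixing matrix, unit-variance source
    estimates ``S = W @ X``, and a convergence flag (False when ``max_steps``
    passes completed without convergence).  The stopping rule is the
    conventional one for this algorithm family: a pass's summed squared
    weight change ``sum(ΔW²)`` dropping below ``tol``.  Deterministic for a
    fixed seed.
    """
    from scipy.special import expit

    X = Xw.reduced if isinstance(Xw, WhitenedData) else np.asarray(Xw, dtype=float)
    k, m = X.shape
    rng = np.random.default_rng(seed)
    if lrate is None:
        lrate = 0.015 / np.log(k) if k > 1 else 0.01
    if block is None:
        block = max(8, int(np.sqrt(m / 3.0)))
    W = _random_orthonormal(k, rng)
    I = np.eye(k)
    eta = float(lrate)
    prev_dW = None
    converged = False
    max_weight = 1e8

    for step in range(max_steps):
        Xp = X[:, rng.permutation(m)]
        W_old = W.copy()
        blew_up = False
        for start in range(0, m - block + 1, block):
            xb = Xp[:, start:start + block]
            u = W @ xb
            y = expit(u)
            W = W + eta * (I + (1.0 - 2.0 * y) @ u.T / xb.shape[1]) @ W
            if not np.isfinite(W).all() or np.abs(W).max() > max_weight:
                blew_up = True
                break
        if blew_up:
            # restart from a fresh point with a gentler rate
            eta *= 0.5
            W = _random_orthonormal(k, rng)
            prev_dW = None
            continue
        dW = W - W_old
        if prev_dW is not None:
            denom = np.linalg.norm(dW) * np.linalg.norm(prev_dW)
            if denom > 0:
                cos_angle = float((dW * prev_dW).sum() / denom)
                if cos_angle < 0.5:  # direction turned by > 60 degrees
                    eta *= 0.9
        prev_dW = dW
        if float((dW**2).sum()) < tol:
            converged = True
            break

    S = W @ X
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = S / sd
    return W, S, converged


def _random_orthonormal(k: int, rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def fix_sign_and_order(maps: np.ndarray, loadings: np.ndarray | None = None):
    """Resolve ICA indeterminacies: positive map skewness, variance order.

    Each map's sign is flipped so its skewness is positive (spatial sources
    of interest are sparse positive blobs); components are ordered by the
    variance they explain in the data (norm of the mixing column times the
    source variance; with unit-variance sources, the loading column norm).
    """
    maps = maps.copy()
    signs = np.sign(_sstats.skew(maps, axis=1))
    signs[signs == 0] = 1.0
    maps *= signs[:, None]
    if loadings is not None:
        loadings = loadings * signs[None, :]
        order = np.argsort(-np.linalg.norm(loadings, axis=0))
    else:
        order = np.arange(maps.shape[0])
    maps = maps[order]
    if loadings is not None:
        loadings = loadings[:, order]
    return maps, loadings


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """z-score each component map over its voxels (mean 0, SD 1)."""
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (maps - mu) / sd


def threshold_map(zmap: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """Binary mask of voxels with z strictly greater than the threshold."""
    return np.asarray(zmap) > z_threshold


def flag_artifact_components(
    maps: np.ndarray,
    analysis_mask: np.ndarray,
    brain_mask: np.ndarray,
    z_threshold: float = 3.0,
) -> list[str]:
    """Label components signal/artifact by where their active voxels sit.

    A component is an *artifact* when more than half of its supra-threshold
    (z > z_threshold) voxels fall outside the brain mask, or when it has no
    supra-threshold voxels at all (a degenerate, unlocalized component).
    ``maps`` are k × V over the analysis-mask voxels; both masks are
    grid-shaped booleans with the brain mask contained in the analysis mask.
    """
    analysis_mask = np.asarray(analysis_mask).astype(bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    in_brain = brain_mask.ravel()[analysis_mask.ravel()]
    labels = []
    for zmap in maps:
        active = threshold_map(zmap, z_threshold)
        n_active = int(active.sum())
        if n_active == 0:
            labels.append("artifact")
            continue
        frac_outside = float((~in_brain[active]).sum() / n_active)
        labels.append("artifact" if frac_outside > 0.5 else "signal")
    return labels


def _loadings_by_regression(X: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Per-subject OLS of each row of X on all maps + intercept (betas only)."""
    k, V = maps.shape
    D = np.column_stack([np.ones(V), maps.T])  # V × (k+1)
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    return coef[1:].T  # subjects × k


def decompose_structural(
    stack: np.ndarray,
    cfg,
    analysis_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> tuple["ComponentSet", "object"]:
    """Group spatial ICA of a subjects × voxels (or subjects × grid) stack.

    PCA reduces the subject dimension to ``cfg.n_components``, ICASSO
    (``cfg.n_icasso_runs`` Infomax runs from random starts) yields stable
    centrotype maps, maps are z-scored, and per-subject loadings are
    re-estimated by spatially regressing each subject's map on all component
    maps jointly — the same operation that defines the network integrity
    score downstream, so there is a single code path for it.

    Returns ``(ComponentSet, IcassoResult)``.
    """
    from .icasso import run_icasso  # deferred to avoid an import cycle
    from .scores import integrity_scores

    stack = np.asarray(stack)
    if stack.ndim > 2:
        grid = stack.shape[1:]
        if analysis_mask is None:
            analysis_mask = np.ones(grid, dtype=bool)
        X = stack.reshape(stack.shape[0], -1)[:, analysis_mask.ravel()]
    else:
        X = stack
        if analysis_mask is None:
            raise ValueError("analysis_mask required for pre-flattened input")
    k = cfg.n_components
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} subjects, got {X.shape[0]}")

    Xw = pca_reduce(X, k)
    result = run_icasso(Xw, k=k, n_runs=cfg.n_icasso_runs, seed=cfg.seed)
    maps = result.centrotypes  # k × V
    maps, _ = fix_sign_and_order(maps, None)
    # order by explained variance: project data onto maps, rank by beta norm
    betas = _loadings_by_regression(X, zscore_maps(maps))
    order = np.argsort(-np.linalg.norm(betas, axis=0))
    maps = zscore_maps(maps[order])
    iq_sorted = result.iq_per_centrotype()[order] if result.iq is not None else None

    loadings = integrity_scores(X, maps)
    labels = (
        flag_artifact_components(maps, analysis_mask, brain_mask, cfg.z_threshold)
        if brain_mask is not None
        else ["signal"] * k
    )
    cs = ComponentSet(
        maps=maps, loadings=loadings, mask=analysis_mask, labels=labels,
        iq=iq_sorted, converged=all(result.converged),
    )
    return cs, result


def decompose_functional(
    series_list,
    cfg,
    analysis_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    subject_pca_factor: float = 1.5,
) -> tuple["ComponentSet", "object"]:
    """Two-stage group spatial ICA of per-subject (time × voxels) series.

    Each subject's series is PCA-reduced in time to ``1.5 · k`` whitened
    rows; the reduced rows are concatenated across subjects; a group PCA to
    ``k`` then feeds the same ICASSO-stabilized Infomax used structurally.
    Group maps are z-scored; loadings are the group-level mixing rows
    (concatenated reduced-time coordinates); per-subject time courses come
    from :func:`dual_regression`.
    """
    from .icasso import run_icasso

    k = cfg.n_components
    reduced_rows = []
    V = None
    for series in series_list:
        series = np.asarray(series)
        if series.ndim > 2:
            grid = series.shape[1:]
            if analysis_mask is None:
                analysis_mask = np.ones(grid, dtype=bool)
            X = series.reshape(series.shape[0], -1)[:, analysis_mask.ravel()]
        else:
            X = series
        if V is None:
            V = X.shape[1]
        elif X.shape[1] != V:
            raise ValueError("inconsistent voxel counts across subjects")
        n_keep = min(int(np.ceil(subject_pca_factor * k)), X.shape[0])
        Xw = pca_reduce(X, n_keep)
        reduced_rows.append(Xw.reduced)
    concat = np.vstack(reduced_rows)
    Xw_group = pca_reduce(concat, k)
    result = run_icasso(Xw_group, k=k, n_runs=cfg.n_icasso_runs, seed=cfg.seed)
    maps, _ = fix_sign_and_order(result.centrotypes, None)
    betas = _loadings_by_regression(concat, zscore_maps(maps))
    order = np.argsort(-np.linalg.norm(betas, axis=0))
    maps = zscore_maps(maps[order])
    iq_sorted = result.iq_per_centrotype()[order] if result.iq is not None else None
    loadings = betas[:, order]
    labels = (
        flag_artifact_components(maps, analysis_mask, brain_mask, cfg.z_threshold)
        if brain_mask is not None
        else ["signal"] * k
    )
    cs = ComponentSet(
        maps=maps, loadings=loadings, mask=analysis_mask, labels=labels,
        iq=iq_sorted, converged=all(result.converged),
    )
    return cs, result


def dual_regression(subject_series: np.ndarray, group_maps: np.ndarray):
    """Subject-specific time courses and maps from group component maps.

    Stage 1 regresses every volume (time point) on the group maps plus an
    intercept, giving time × k time courses; stage 2 regresses every voxel's
    time series on those time courses plus an intercept, giving k × V
    subject maps.  A constant offset added to the series is absorbed by the
    intercepts and leaves both outputs unchanged.
    """
    Y = np.asarray(subject_series, dtype=float)  # T × V
    G = np.asarray(group_maps, dtype=float)  # k × V
    k, V = G.shape
    if Y.shape[1] != V:
        raise ValueError("series and group maps disagree on voxel count")
    if np.linalg.matrix_rank(G) < k:
        raise ValueError("group maps are rank deficient")
    # normal equations (maps are z-scored and full rank, so well conditioned)
    D1 = np.column_stack([np.ones(V), G.T])  # V × (k+1)
    tcs = np.linalg.solve(D1.T @ D1, D1.T @ Y.T)[1:].T  # T × k
    D2 = np.column_stack([np.ones(Y.shape[0]), tcs])  # T × (k+1)
    subject_maps = np.linalg.solve(D2.T @ D2, D2.T @ Y)[1:]  # k × V
    return tcs, subject_maps
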