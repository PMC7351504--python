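"""Synthetic spatial sources ("phantom networks") on a small 3D grid.

The phantom stands in for the large-scale brain networks a morphometric ICA
would recover: each source is a sum of 3D Gaussian blobs on a desk-scale grid
(default 32×40×32 voxels at 3 mm isotropic) with an ellipsoidal brain mask.
Sources carry a role label: anterior cingulate, posterior cingulate,
frontoparietal, generic "other", or an artifact source whose energy lies
outside the brain mask (emulating the non-brain components that group ICA of
real data produces and that analysts discard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SourceAtlas", "make_phantom_sources", "DEFAULT_ROLES"]

#: Default role assignment for k_true = 6, mirroring the networks the
#: analysis cares about plus background and artifact sources.
DEFAULT_ROLES = (
    "anterior_cingulate",
    "posterior_cingulate",
    "frontoparietal",
    "other",
    "other",
    "artifact",
)


@dataclass
class SourceAtlas:
    """Planted spatial sources plus the grid geometry they live on.

    ``sources`` has shape (k_true, *grid_shape); every source is scaled to
    unit RMS amplitude over the grid so that a noise SD of ~0.5 is a
    meaningful fraction of the signal.  Non-artifact sources keep >=95% of
    their energy inside ``brain_mask``; artifact sources keep >=80% outside.
    """

    grid_shape: tuple[int, int, int]
    voxel_mm: float
    brain_mask: np.ndarray
    sources: np.ndarray
    roles: tuple[str, ...]
    seed: int | None = None
    blob_centers: list = field(default_factory=list, repr=False)

    @property
    def k_true(self) -> int:
        return self.sources.shape[0]

    def role_index(self, role: str) -> int:
        """Index of the first source carrying ``role``."""
        return self.roles.index(role)

    def flat_sources(self) -> np.ndarray:
        """Sources as a (k_true, n_voxels) matrix (C-order linearization)."""
        return self.sources.reshape(self.k_true, -1)

    def energy_fraction_inside(self, j: int) -> float:
        """Fraction of source j's squared amplitude inside the brain mask."""
        s2 = self.sources[j] ** 2
        return float(s2[self.brain_mask].sum() / s2.sum())


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid filling ~80% of each grid dimension."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    semi = [0.40 * n for n in grid_shape]
    return (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0


def _gaussian_blob(grid_shape, center, sigma_vox) -> np.ndarray:
    axes = [np.arange(n) for n in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma_vox**2))


def _candidate_centers(mask: np.ndarray, rng, inside: bool, margin: float):
    """Draw a voxel coordinate inside (or outside) the mask region."""
    region = mask if inside else ~mask
    idx = np.argwhere(region)
    # keep blobs away from the box edge so their energy stays on-grid
    shape = np.array(mask.shape)
    keep = np.all((idx >= margin) & (idx <= shape - 1 - margin), axis=1)
    idx = idx[keep]
    if idx.size == 0:
        raise ValueError("grid too small to place sources with the required margin")
    return idx[rng.integers(idx.shape[0])]


def make_phantom_sources(
    grid_shape: tuple[int, int, int] = (32, 40, 32),
    k_true: int = 6,
    seed: int = 0,
    *,
    voxel_mm: float = 3.0,
    roles: tuple[str, ...] | None = None,
    blobs_per_source: int = 2,
    sigma_vox: float | None = None,
    max_pairwise_r: float = 0.2,
    max_tries: int = 200,
) -> SourceAtlas:
    """Build a seeded atlas of k_true spatial sources on a 3D grid.

    Sources are sums of ``blobs_per_source`` Gaussian blobs.  Blob centers
    are drawn at random (inside the brain mask for non-artifact roles,
    outside it for the artifact role) and redrawn until every pair of
    sources has absolute spatial correlation below ``max_pairwise_r``.

    Deterministic for a fixed seed.  Raises a sizing error when the grid is
    too small to place sufficiently non-overlapping blobs.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 16 for n in grid_shape):
        raise ValueError("each grid dimension must be >= 16")
    if sigma_vox is None:
        # scale blob width with the grid so small test grids stay placeable
        sigma_vox = min(grid_shape) / 13.0
    if k_true < 4:
        raise ValueError("k_true must be >= 4")
    if roles is None:
        roles = DEFAULT_ROLES if k_true == 6 else tuple(
            list(DEFAULT_ROLES[:3]) + ["other"] * (k_true - 4) + ["artifact"]
        )
    if len(roles) != k_true:
        raise ValueError("roles length must equal k_true")

    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(grid_shape)
    n_vox = int(np.prod(grid_shape))
    margin = 2.0 * sigma_vox

    sources: list[np.ndarray] = []
    centers: list[list[np.ndarray]] = []
    for j, role in enumerate(roles):
        inside = role != "artifact"
        for attempt in range(max_tries):
            cs = [
                _candidate_centers(mask, rng, inside, margin)
                for _ in range(blobs_per_source)
            ]
            vol = np.zeros(grid_shape)
            for c in cs:
                vol += _gaussian_blob(grid_shape, c, sigma_vox)
            # unit RMS over the grid
            vol /= np.sqrt((vol**2).mean())
            flat = vol.ravel()
            ok = all(
                abs(np.corrcoef(flat, s.ravel())[0, 1]) < max_pairwise_r
                for s in sources
            )
            # enforce the energy-location invariant for this role
            inside_frac = float((vol[mask] ** 2).sum() / (vol**2).sum())
            ok = ok and (inside_frac >= 0.95 if inside else inside_frac <= 0.2)
            if ok:
                sources.append(vol)
                centers.append(cs)
                break
        else:
            raise ValueError(
                f"could not place source {j} ({role}) with pairwise |r| < "
                f"{max_pairwise_r} in {max_tries} tries; grid too small?"
            )

    return SourceAtlas(
        grid_shape=grid_shape,
        voxel_mm=float(voxel_mm),
        brain_mask=mask,
        sources=np.stack(sources),
        roles=tuple(roles),
        seed=seed,
        blob_centers=centers,
    )
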