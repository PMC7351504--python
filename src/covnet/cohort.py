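"""Synthetic cohorts: structural maps, BOLD-like series, clinical tables.

The generator plants the statistical structure the downstream analysis is
designed to detect:

* **Structural cohort** — each subject's deformation-style map is a linear
  mixture of the atlas sources plus voxelwise Gaussian noise.  The loadings
  of the anterior- and posterior-cingulate sources are drawn with a
  group-specific correlation (strong in healthy controls, weak in patients),
  so "structural covariance disruption" is a planted, recoverable effect.
* **Functional cohort** — each subject's 4D series is sources × band-limited
  time courses plus noise, with a planted anterior–posterior time-course
  correlation per (group, visit).  The first volumes carry an additive
  transient so the drop-initial-volumes step has something to remove.
* **Clinical table** — Gaussian draws around published-style group summaries
  (age, sex, education, disease duration, UPDRS, H-Y, PDQ-39, MMSE).

All draws go through one seeded :class:`numpy.random.Generator` per call, so
every output is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import SourceAtlas

__all__ = [
    "GroundTruth",
    "simulate_structural_cohort",
    "simulate_functional_cohort",
    "simulate_clinical_table",
    "DEFAULT_RHO_STRUCT",
    "DEFAULT_RHO_FUNC",
    "CLINICAL_SPEC_PD",
    "CLINICAL_SPEC_HC",
    "CLINICAL_SPEC_PD_SUBGROUP",
    "CLINICAL_SPEC_PD_FOLLOWUP",
]

#: Planted structural loading correlations (anterior vs posterior cingulate).
DEFAULT_RHO_STRUCT = {"HC": 0.6, "PD": 0.1}

#: Planted functional time-course correlations per (group, visit).
DEFAULT_RHO_FUNC = {
    ("HC", "baseline"): 0.25,
    ("PD", "baseline"): 0.55,
    ("PD", "followup"): 0.25,
}


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort, kept for recovery tests."""

    loadings: np.ndarray  # subjects × k_true mixing matrix A
    rho_struct_hc: float | None = None
    rho_struct_pd: float | None = None
    rho_func: dict | None = None
    noise_sigma: float = 0.0
    seed: int | None = None
    groups: np.ndarray | None = None  # per-subject group label
    timecourses: np.ndarray | None = None  # subjects × k_true × T (functional)

    def to_dict(self) -> dict:
        """JSON-serializable summary (loadings/timecourses omitted)."""
        return {
            "rho_struct_hc": self.rho_struct_hc,
            "rho_struct_pd": self.rho_struct_pd,
            "rho_func": {f"{g}:{v}": r for (g, v), r in (self.rho_func or {}).items()},
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "n_subjects": int(self.loadings.shape[0]),
            "k_true": int(self.loadings.shape[1]),
        }


def _correlated_pair(n: int, rho: float, rng) -> np.ndarray:
    """n draws of a standard-normal pair with correlation rho (Cholesky)."""
    z = rng.standard_normal((n, 2))
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    return z @ L.T


def simulate_structural_cohort(
    atlas: SourceAtlas,
    n_pd: int = 100,
    n_hc: int = 70,
    rho_hc: float = DEFAULT_RHO_STRUCT["HC"],
    rho_pd: float = DEFAULT_RHO_STRUCT["PD"],
    noise_sigma: float = 0.5,
    seed: int = 0,
    cingulate_shift_pd: float = -0.6,
):
    """Simulate per-subject structural maps with planted loading covariance.

    Returns ``(stack, truth)`` where ``stack`` has shape
    (n_pd + n_hc, \\*grid) — PD subjects first, then HC — and ``truth`` holds
    the planted mixing matrix and correlations.

    Each subject map is ``sum_j A[s, j] * source_j + noise_sigma * eps``.
    The anterior/posterior loading columns are drawn with correlation
    ``rho_pd`` in the PD rows and ``rho_hc`` in the HC rows; all other
    columns are i.i.d. standard normal.  ``cingulate_shift_pd`` (in SD
    units) is added to the PD anterior/posterior loading means, planting the
    mean network-integrity deficit the group comparison is meant to detect
    (default −0.6, a moderate effect a 100-vs-70 comparison detects
    reliably); it leaves all correlations untouched.
    """
    for name, rho in (("rho_hc", rho_hc), ("rho_pd", rho_pd)):
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"{name} must lie in [0, 1), got {rho}")
    if n_pd < 10 or n_hc < 10:
        raise ValueError("need at least 10 subjects per group")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    rng = np.random.default_rng(seed)
    k = atlas.k_true
    n = n_pd + n_hc
    ia = atlas.role_index("anterior_cingulate")
    ip = atlas.role_index("posterior_cingulate")

    A = rng.standard_normal((n, k))
    A[:n_pd, [ia, ip]] = _correlated_pair(n_pd, rho_pd, rng) + cingulate_shift_pd
    A[n_pd:, [ia, ip]] = _correlated_pair(n_hc, rho_hc, rng)

    flat = atlas.flat_sources()
    stack = (A @ flat).reshape(n, *atlas.grid_shape)
    if noise_sigma > 0:
        stack = stack + noise_sigma * rng.standard_normal(stack.shape)

    groups = np.array(["PD"] * n_pd + ["HC"] * n_hc)
    truth = GroundTruth(
        loadings=A,
        rho_struct_hc=rho_hc,
        rho_struct_pd=rho_pd,
        noise_sigma=noise_sigma,
        seed=seed,
        groups=groups,
    )
    return stack, truth


def _band_limited_tc(n_vols: int, tr_s: float, n_series: int, rng,
                     f_hi: float = 0.1) -> np.ndarray:
    """Gaussian time courses with power restricted to [0, f_hi] Hz.

    Built in the frequency domain: complex Gaussian coefficients up to
    ``f_hi``, zero above, inverse rFFT, then unit-variance scaling.  The
    dominant power thus sits inside the analysis band.
    """
    freqs = np.fft.rfftfreq(n_vols, d=tr_s)
    keep = (freqs > 0) & (freqs <= f_hi)
    coef = np.zeros((n_series, freqs.size), dtype=complex)
    coef[:, keep] = rng.standard_normal((n_series, keep.sum())) + 1j * rng.standard_normal(
        (n_series, keep.sum())
    )
    tc = np.fft.irfft(coef, n=n_vols, axis=1)
    tc /= tc.std(axis=1, keepdims=True)
    return tc


def simulate_functional_subject(
    atlas: SourceAtlas,
    rho: float,
    n_volumes: int = 230,
    tr_s: float = 2.0,
    noise_sigma: float = 1.0,
    transient_amp: float = 5.0,
    n_drop_affected: int = 10,
    seed: int = 0,
    dtype=np.float32,
):
    """Simulate one subject's BOLD-like series.

    Returns ``(series, tc)``: the (n_volumes, \\*grid) series and the planted
    (k_true, n_volumes) component time courses.  Each source receives a
    band-limited (≲0.1 Hz) unit-variance Gaussian time course; the
    anterior/posterior pair carries correlation ``rho``; the volume at time t
    is ``sum_j tc[j, t] * source_j + noise`` plus a decaying start-of-scan
    transient on the first ``n_drop_affected`` volumes (a T1-saturation
    stand-in that the initial-volume removal step must discard).
    """
    if n_volumes < 60:
        raise ValueError("n_volumes must be >= 60 to resolve the 0.013 Hz band")
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    k = atlas.k_true
    ia = atlas.role_index("anterior_cingulate")
    ip = atlas.role_index("posterior_cingulate")
    flat = atlas.flat_sources().astype(dtype)

    tc = _band_limited_tc(n_volumes, tr_s, k, rng)
    a, b = tc[ia], tc[ip]
    b_orth = b - (a @ b) / (a @ a) * a
    b_orth /= b_orth.std()
    tc[ip] = rho * a + np.sqrt(1.0 - rho**2) * b_orth

    vols = tc.T.astype(dtype) @ flat  # (T, V)
    if noise_sigma > 0:
        vols += noise_sigma * rng.standard_normal(vols.shape).astype(dtype)
    transient = transient_amp * np.exp(-np.arange(n_volumes) / (n_drop_affected / 3.0))
    transient[n_drop_affected:] = 0.0
    vols += transient[:, None].astype(dtype)
    return vols.reshape(n_volumes, *atlas.grid_shape), tc


def simulate_functional_cohort(
    atlas: SourceAtlas,
    n_subjects: int = 50,
    n_volumes: int = 230,
    tr_s: float = 2.0,
    rho_func: float | np.ndarray = 0.55,
    noise_sigma: float = 1.0,
    transient_amp: float = 5.0,
    n_drop_affected: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    dtype=np.float32,
):
    """Simulate a stack of BOLD-like 4D series driven by the atlas sources.

    Returns ``(series, truth)``; ``series`` has shape
    (n_subjects, n_volumes, \\*grid) and ``truth.timecourses`` the planted
    per-subject component time courses.  ``rho_func`` is the planted
    anterior–posterior time-course correlation, a scalar or a per-subject
    array (use the latter to encode group/visit differences).

    Memory scales as n_subjects × n_volumes × grid; for large cohorts
    generate subjects one at a time with :func:`simulate_functional_subject`
    and per-subject child seeds (the pipeline does exactly that).
    """
    rhos = np.broadcast_to(np.asarray(rho_func, dtype=float), (n_subjects,)).copy()
    if np.any(np.abs(rhos) >= 1.0):
        raise ValueError("|rho_func| must be < 1")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=n_subjects)

    series = np.empty((n_subjects, n_volumes, *atlas.grid_shape), dtype=dtype)
    tcs = np.empty((n_subjects, atlas.k_true, n_volumes))
    for s in range(n_subjects):
        series[s], tcs[s] = simulate_functional_subject(
            atlas, rhos[s], n_volumes, tr_s, noise_sigma,
            transient_amp, n_drop_affected, seed=int(child_seeds[s]), dtype=dtype,
        )
    truth = GroundTruth(
        loadings=tcs.std(axis=2),
        rho_func={"planted": rhos},
        noise_sigma=noise_sigma,
        seed=seed,
        groups=groups,
        timecourses=tcs,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

#: Published-style group summaries (mean, SD) used as simulation defaults.
CLINICAL_SPEC_PD = {
    "age": (59.77, 9.08), "education": (8.15, 4.45), "duration": (2.82, 1.74),
    "hy_stage": (1.85, 0.64), "updrs_i": (1.23, 1.45), "updrs_ii": (8.96, 5.21),
    "updrs_iii": (25.26, 22.27), "updrs_iv": (0.96, 4.97),
    "updrs_total": (36.05, 18.78), "pdq39": (24.18, 19.48), "mmse": (26.98, 3.42),
}
CLINICAL_SPEC_HC = {
    "age": (59.76, 7.63), "education": (9.09, 3.57), "mmse": (27.93, 2.14),
}
CLINICAL_SPEC_PD_SUBGROUP = {
    "age": (60.49, 8.19), "education": (8.69, 4.46), "duration": (3.06, 2.00),
    "hy_stage": (1.96, 0.49), "updrs_i": (1.10, 1.14), "updrs_ii": (8.18, 4.27),
    "updrs_iii": (22.27, 12.03), "updrs_iv": (0.67, 1.34),
    "updrs_total": (32.41, 16.03), "pdq39": (21.72, 17.57), "mmse": (27.75, 2.77),
}
CLINICAL_SPEC_PD_FOLLOWUP = {
    "age": (62.45, 8.11), "education": (8.69, 4.46), "duration": (5.02, 1.92),
    "hy_stage": (2.15, 0.52), "updrs_i": (1.63, 1.95), "updrs_ii": (7.78, 5.14),
    "updrs_iii": (18.49, 10.48), "updrs_iv": (1.16, 1.29),
    "updrs_total": (29.06, 14.89), "pdq39": (23.32, 20.68), "mmse": (27.45, 2.72),
}

#: Plausibility clips per variable (floor, ceiling).
_CLIPS = {
    "age": (18.0, 95.0), "education": (0.0, 25.0), "duration": (0.0, 30.0),
    "hy_stage": (0.0, 5.0), "updrs_i": (0.0, 16.0), "updrs_ii": (0.0, 52.0),
    "updrs_iii": (0.0, 108.0), "updrs_iv": (0.0, 23.0), "updrs_total": (0.0, 199.0),
    "pdq39": (0.0, 156.0), "mmse": (0.0, 30.0),
}


def simulate_clinical_table(spec: dict, seed: int = 0) -> pd.DataFrame:
    """Simulate a clinical/demographic table from per-group summaries.

    ``spec`` maps group name -> dict with keys ``n`` (count), ``visit``
    (optional, default "baseline"), ``male_frac`` (optional, default 0.5)
    and per-variable ``(mean, sd)`` pairs.  Values are Gaussian draws clipped
    to plausible ranges; group sizes are exact; an ``n`` of 0 yields no rows.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gname, gspec in spec.items():
        n = int(gspec.get("n", 0))
        visit = gspec.get("visit", "baseline")
        group = gspec.get("group", gname)
        male_frac = float(gspec.get("male_frac", 0.5))
        variables = {k: v for k, v in gspec.items()
                     if k not in ("n", "visit", "group", "male_frac")}
        for _, (mu, sd) in variables.items():
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        n_male = int(round(male_frac * n))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        for i in range(n):
            row = {
                "id": f"{group}{i:03d}",
                "group": group,
                "visit": visit,
                "sex": sexes[i],
            }
            for var, (mu, sd) in variables.items():
                val = rng.normal(mu, sd)
                lo, hi = _CLIPS.get(var, (-np.inf, np.inf))
                row[var] = float(np.clip(val, lo, hi))
            rows.append(row)
    cols = ["id", "group", "visit", "sex"]
    df = pd.DataFrame(rows, columns=cols + sorted({c for r in rows for c in r} - set(cols))
                      if rows else cols)
    return df
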