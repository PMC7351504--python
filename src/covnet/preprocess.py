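"""Spatial smoothing/masking of 3D maps and temporal conditioning of time courses.

Spatial maps are smoothed with an isotropic Gaussian kernel specified by its
full width at half maximum (FWHM), the conventional unit in morphometry and
fMRI pipelines.  Component time courses are conditioned the way resting-state
connectivity pipelines prepare them for correlation: linear detrend, robust
despike (Hampel winsorization at 3.5 scaled-MAD), and a zero-phase Butterworth
band-pass (default 0.013–0.24 Hz at TR = 2 s).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "fwhm_to_sigma",
    "smooth_map",
    "apply_mask",
    "unmask",
    "detrend_despike",
    "bandpass",
    "condition_timecourse",
    "drop_initial_volumes",
]

#: FWHM = sigma * sqrt(8 ln 2) for a Gaussian kernel.
_FWHM_FACTOR = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float) -> float:
    """Convert a FWHM in mm to a Gaussian sigma in voxel units."""
    return fwhm_mm / (voxel_mm * _FWHM_FACTOR)


def smooth_map(vol: np.ndarray, fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    """Smooth a 3D map with an isotropic Gaussian kernel.

    ``fwhm_mm = 0`` is the identity.  The volume boundary is zero-padded,
    so mass is conserved only for signal away from the edges.  Anisotropic
    voxel sizes are not supported: pass the scalar isotropic size.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("smooth_map expects a 3D volume")
    if np.ndim(voxel_mm) != 0:
        raise ValueError("anisotropic voxel sizes are unsupported; pass a scalar")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma = fwhm_to_sigma(fwhm_mm, float(voxel_mm))
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant", cval=0.0)


def apply_mask(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask voxels from a stack of volumes.

    ``stack`` may be a single 3D volume or an array of shape
    ``(n, *grid)``.  Columns follow C-order (row-major) linearization of the
    in-mask voxels, i.e. ``np.flatnonzero(mask.ravel())`` order, which is the
    fixed convention used throughout the package.
    """
    mask = np.asarray(mask).astype(bool)
    stack = np.asarray(stack)
    single = stack.ndim == mask.ndim
    if single:
        stack = stack[None]
    if stack.shape[1:] != mask.shape:
        raise ValueError(f"stack grid {stack.shape[1:]} != mask grid {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    out = stack.reshape(stack.shape[0], -1)[:, mask.ravel()]
    return out[0] if single else out


def unmask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`apply_mask`; out-of-mask voxels are filled with 0."""
    mask = np.asarray(mask).astype(bool)
    data = np.asarray(data, dtype=float)
    single = data.ndim == 1
    data2 = np.atleast_2d(data)
    n_in = int(mask.sum())
    if data2.shape[1] != n_in:
        raise ValueError(f"expected {n_in} in-mask values, got {data2.shape[1]}")
    out = np.zeros((data2.shape[0], mask.size), dtype=float)
    out[:, mask.ravel()] = data2
    out = out.reshape((data2.shape[0], *mask.shape))
    return out[0] if single else out


def detrend_despike(tc: np.ndarray) -> np.ndarray:
    """Remove a linear trend, then winsorize outliers (Hampel rule).

    After least-squares removal of intercept + linear trend, samples beyond
    ``median ± 3.5 · 1.4826 · MAD`` are clipped to that bound.  A constant
    input returns the zero vector.  The output is re-centred to mean 0.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1:
        raise ValueError("detrend_despike expects a 1D time course")
    if tc.size < 20:
        raise ValueError("time course too short (< 20 samples)")
    detr = signal.detrend(tc, type="linear")
    med = np.median(detr)
    mad = np.median(np.abs(detr - med))
    if mad == 0.0:
        # Degenerate spread (e.g. constant input): nothing to winsorize.
        return detr - detr.mean()
    bound = 3.5 * 1.4826 * mad
    clipped = np.clip(detr, med - bound, med + bound)
    return clipped - clipped.mean()


def bandpass(tc: np.ndarray, band_hz: tuple[float, float], tr_s: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a time course.

    A 5th-order Butterworth filter is applied forward and backward
    (``filtfilt``), which doubles the effective order and cancels phase
    distortion.  The band must sit strictly inside (0, Nyquist).
    """
    tc = np.asarray(tc, dtype=float)
    low, high = band_hz
    nyq = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"band upper edge {high} Hz >= Nyquist frequency {nyq} Hz at TR={tr_s}s"
        )
    sos = signal.butter(5, [low, high], btype="bandpass", fs=1.0 / tr_s, output="sos")
    return signal.sosfiltfilt(sos, tc)


def condition_timecourse(
    tc: np.ndarray, band_hz: tuple[float, float], tr_s: float
) -> np.ndarray:
    """Full conditioning pipeline: detrend → despike → band-pass."""
    return bandpass(detrend_despike(tc), band_hz, tr_s)


def drop_initial_volumes(series: np.ndarray, n_drop: int) -> np.ndarray:
    """Discard the first ``n_drop`` time points of a (time × …) series."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= series.shape[0]:
        raise ValueError("cannot drop all volumes")
    return series[n_drop:]
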