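"""Functional network connectivity between two selected components.

FNC is the Pearson correlation between the conditioned (detrended, despiked,
band-passed) time courses of two components; each subject-visit contributes
exactly one value.  Group statistics downstream operate on the Fisher
z-transform ``atanh(r)`` for variance stabilization, but the raw correlation
is kept since it is the quantity usually plotted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocess import condition_timecourse

__all__ = ["fnc_value", "fnc_table"]


def fnc_value(tcA: np.ndarray, tcB: np.ndarray, cfg) -> float:
    """Conditioned-time-course Pearson correlation between two components.

    Both inputs are conditioned with the pipeline settings (linear detrend,
    Hampel despike, ``cfg.band_hz`` band-pass at ``cfg.tr_s``).  Returns NaN
    (an undefined-value flag, not an exception) if either course has zero
    variance after conditioning.
    """
    tcA = np.asarray(tcA, dtype=float)
    tcB = np.asarray(tcB, dtype=float)
    if tcA.shape != tcB.shape:
        raise ValueError("time courses must have equal length")
    if tcA.size < 60:
        raise ValueError("time courses too short (< 60 samples) for the band")
    a = condition_timecourse(tcA, cfg.band_hz, cfg.tr_s)
    b = condition_timecourse(tcB, cfg.band_hz, cfg.tr_s)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fnc_table(timecourse_pairs, meta: pd.DataFrame, cfg) -> pd.DataFrame:
    """One FNC value per subject-visit.

    ``timecourse_pairs`` is an iterable of ``(tcA, tcB)`` per subject-visit
    (or None for a missing visit, which is excluded with a warning);
    ``meta`` supplies matching rows with at least subject/group/visit
    columns.  Returns a tidy table with columns of ``meta`` plus ``r`` and
    ``fisher_z``.
    """
    rows = []
    pairs = list(timecourse_pairs)
    if len(pairs) != len(meta):
        raise ValueError("metadata rows must match the number of series")
    for i, pair in enumerate(pairs):
        if pair is None:
            warnings.warn(f"missing series for row {i}; excluded")
            continue
        r = fnc_value(pair[0], pair[1], cfg)
        row = dict(meta.iloc[i])
        row["r"] = r
        row["fisher_z"] = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))) \
            if np.isfinite(r) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
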