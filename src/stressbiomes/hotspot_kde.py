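"""Compact-support kernel density surfaces for polytolerance hotspots.

Polytolerant hexagon centers are turned into a continuous relative-density
surface with a triweight kernel of fixed radius (711,000 planar units by
default, ~10,000 km2).  The surface is normalized to a maximum of 1 so the
banded values read as relative probability of finding polytolerant
assemblages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_RADIUS = 711_000.0
DEFAULT_BANDS = ((0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0))


def triweight(u: np.ndarray) -> np.ndarray:
    """Triweight kernel (1 - u^2)^3 on |u| <= 1, zero outside.

    The (35/32) normalizing constant is omitted: the surface is rescaled
    to max 1 afterwards, so it cancels.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = np.abs(u) <= 1.0
    out[inside] = (1.0 - u[inside] ** 2) ** 3
    return out


def band_label(
    normalized: np.ndarray, bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Band a normalized density: half-open intervals, last band closed.

    Values below the first band's lower edge map to ``"none"``.
    """
    labels = np.full(np.shape(normalized), "none", dtype=object)
    for i, (lo, hi) in enumerate(bands):
        last = i == len(bands) - 1
        if last:
            mask = (normalized >= lo) & (normalized <= hi)
        else:
            mask = (normalized >= lo) & (normalized < hi)
        labels[mask] = f"{lo:g}-{hi:g}"
    return labels


def kde_hotspots(
    events: np.ndarray,
    eval_points: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Triweight KDE of event points, evaluated at ``eval_points``.

    ``density(x) = sum_e K(||x - e|| / radius)``; compact support makes the
    density exactly zero farther than ``radius`` from every event.  Returns
    a frame with raw density, max-normalized density, and band labels.  An
    empty event set yields an all-zero map with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    events = np.asarray(events, dtype=float).reshape(-1, 2)
    if len(events) == 0:
        warnings.warn("no events: hotspot map is identically zero", stacklevel=2)
        raw = np.zeros(len(eval_points))
    else:
        d = cdist(eval_points, events)
        raw = triweight(d / radius).sum(axis=1)
    peak = raw.max()
    normalized = raw / peak if peak > 0 else raw
    return pd.DataFrame(
        {
            "raw_density": raw,
            "normalized": normalized,
            "band": band_label(normalized, bands),
        }
    )
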