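"""Environmental and vegetation-class summaries of biomes and hotspots.

Each stress tolerance biome (STB) and polytolerance class is described by
(a) its cumulative area overlap with a categorical vegetation layer
(potential natural vegetation classes or any other per-hexagon class
column) and (b) the distribution of the retained component scores and
topographic variables inside it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def overlap_with_classes(
    region_labels: pd.Series, class_labels: pd.Series
) -> pd.DataFrame:
    """Percentage of each region's cells falling in each vegetation class.

    Labels must be aligned (same index / length).  With equal-area cells,
    the cell-count fraction equals the area fraction.  Regions with no
    cells are omitted with a warning.
    """
    if len(region_labels) != len(class_labels):
        raise ValueError("region and class labels are not aligned")
    df = pd.DataFrame({"region": region_labels.values, "cls": class_labels.values})
    rows = []
    for region, sub in df.groupby("region", observed=True, sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empty
            warnings.warn(f"region {region!r} has no cells; omitted", stacklevel=2)
            continue
        counts = sub["cls"].value_counts()
        for cls, n in counts.items():
            rows.append(
                {
                    "region": region,
                    "class": cls,
                    "n_cells": int(n),
                    "overlap_pct": 100.0 * n / len(sub),
                }
            )
    return pd.DataFrame(rows)


def summarize_strategy_space(
    region_labels: pd.Series, scores: pd.DataFrame
) -> pd.DataFrame:
    """Per-region mean, sd, and 5/95 percentiles of each score column.

    ``scores`` typically holds the retained rotated components plus
    elevation/TRI/TWI, row-aligned with ``region_labels``.
    """
    if len(region_labels) != len(scores):
        raise ValueError("labels and scores are not row-aligned")
    rows = []
    values = scores.reset_index(drop=True)
    regions = pd.Series(region_labels.values, name="region")
    for region, idx in regions.groupby(regions).groups.items():
        sub = values.loc[idx]
        for col in values.columns:
            v = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "region": region,
                    "variable": col,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "q05": float(np.percentile(v, 5)),
                    "q95": float(np.percentile(v, 95)),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)
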