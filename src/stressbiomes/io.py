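"""CSV/GeoJSON writers and hashing helpers for pipeline artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping

from stressbiomes.grid_aggregation import HexGrid


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify, sort_keys=True))
    return path


def _jsonify(o):
    try:
        import numpy as np

        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_grid_geojson(
    grid: HexGrid, path: str | Path, properties: pd.DataFrame | None = None
) -> Path:
    """Write hexagon polygons as a GeoJSON FeatureCollection.

    ``properties`` (keyed by hex_id) attaches per-cell attributes.
    """
    props_by_id = {}
    if properties is not None:
        props_by_id = properties.set_index("hex_id").to_dict(orient="index")
    features = []
    for i, hid in enumerate(grid.hex_ids):
        feat = {
            "type": "Feature",
            "geometry": mapping(grid.polygon(i)),
            "properties": {"hex_id": int(hid), **props_by_id.get(hid, {})},
        }
        features.append(feat)
    collection = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(collection, default=_jsonify))
    return path


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
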