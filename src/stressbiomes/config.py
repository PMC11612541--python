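"""Configuration objects for the synthetic world and the full pipeline.

The synthetic world emulates the statistical structure the downstream
analysis assumes: a triangular stress tolerance space (STS) whose first
axis is the drought <-> waterlogging/cold trade-off and whose second axis
is the shade tolerance spectrum; species pools for three woody plant
functional types (PFTs); trait values coupled to the STS axes; and a
hexagonal landscape whose environmental gradients drive where species
occur.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Plant functional types, in the order species pools are generated.
PFTS = ("deciduous_angiosperm", "evergreen_angiosperm", "evergreen_gymnosperm")

#: The six functional traits (units: m, mg mm-3, mg, mm2, mg g-1, mm2 mg-1).
TRAITS = ("PH", "SSD", "SM", "LA", "LN", "SLA")

#: Vertex strategy names, in canonical tie-break order.
STRATEGIES = ("drought", "shade", "waterlogging_cold")

#: All four planted strategy groups (three vertices + low-intermediate center).
GROUPS = STRATEGIES + ("low_intermediate",)

#: Default STS triangle: axis1 is the drought <-> waterlogging/cold trade-off,
#: axis2 the shade spectrum.
DEFAULT_TRIANGLE = {
    "drought": (1.0, -0.5),
    "shade": (0.0, 1.0),
    "waterlogging_cold": (-1.0, -0.5),
}

N_CLIMATE = 22
N_SOIL = 8

CLIMATE_VARS = tuple(f"clim_{i:02d}" for i in range(1, N_CLIMATE + 1))
SOIL_VARS = tuple(f"soil_{i}" for i in range(1, N_SOIL + 1))
TOPO_VARS = ("elevation", "tri", "twi")


def _default_n_species() -> dict[str, int]:
    # Pool sizes for the three PFTs in the Northern-Hemisphere tolerance
    # data set the generator emulates.
    return {
        "deciduous_angiosperm": 547,
        "evergreen_angiosperm": 134,
        "evergreen_gymnosperm": 106,
    }


def _default_trait_loadings() -> dict[str, tuple[float, float]]:
    """Loadings of each log-trait on (axis1, axis2).

    Positive axis1 (toward the drought vertex) raises stem density, seed
    mass, plant height and leaf area: a conservative, tall-statured
    syndrome.  Positive axis2 (toward the shade vertex) raises stature
    traits and lowers the acquisitive leaf-economics pair (SLA, LN).
    """
    return {
        "PH": (0.30, 0.40),
        "SSD": (0.50, 0.30),
        "SM": (0.50, 0.30),
        "LA": (0.30, 0.30),
        "LN": (0.20, -0.25),
        "SLA": (0.20, -0.25),
    }


def _default_trait_log_means() -> dict[str, float]:
    # Baseline natural-log trait values: roughly a 10 m tree with wood
    # density 0.6 mg mm-3, 10 mg seeds, 1000 mm2 leaves, 20 mg g-1 leaf N
    # and SLA 15 mm2 mg-1.
    return {"PH": 2.3, "SSD": -0.5, "SM": 2.3, "LA": 6.9, "LN": 3.0, "SLA": 2.7}


def _default_env_loadings() -> dict[str, tuple[float, ...]]:
    """Loadings of each environmental variable on the latent factors.

    Factor order: (g1, g2, c1, c2, s1).  g1 runs west-east and sorts the
    drought <-> waterlogging/cold axis; g2 runs south-north and sorts the
    shade spectrum.  c1/c2 are climate-only nuisance factors and s1 a
    soil-only one (spatially white), so each block retains more than one
    component without inflating cross-block correlations.  Climate
    variables load mostly on g2 (temperature/season length drives the
    shade spectrum), soil variables on g1 (fertility/pH drives the
    trade-off), mirroring the structure the analysis is meant to recover.
    Signs alternate so no bundle is a strict copy of another variable.
    """
    loadings: dict[str, tuple[float, ...]] = {}
    for i, name in enumerate(CLIMATE_VARS):
        sign = 1.0 if i % 2 == 0 else -1.0
        if i < 10:  # temperature/season-length bundle
            loadings[name] = (0.08 * sign, 0.9 * sign, 0.0, 0.0, 0.0)
        elif i < 16:  # precipitation-like bundle
            loadings[name] = (0.2 * sign, 0.4 * sign, 0.75 * sign, 0.0, 0.0)
        else:  # seasonality-like bundle
            loadings[name] = (0.0, 0.25 * sign, 0.0, 0.8 * sign, 0.0)
    for i, name in enumerate(SOIL_VARS):
        sign = 1.0 if i % 2 == 0 else -1.0
        if i < 5:  # fertility/pH bundle
            loadings[name] = (0.9 * sign, 0.08 * sign, 0.0, 0.0, 0.0)
        else:  # texture bundle
            loadings[name] = (0.15 * sign, 0.0, 0.0, 0.0, 0.85 * sign)
    loadings["elevation"] = (0.15, 0.1, 0.0, 0.0, 0.0)
    loadings["tri"] = (0.12, -0.05, 0.0, 0.0, 0.0)
    loadings["twi"] = (-0.1, 0.08, 0.0, 0.0, 0.0)
    return loadings


@dataclass
class WorldConfig:
    """Parameters of the synthetic world generator.

    Defaults are the study conditions the package is tested under: species
    pool sizes 547/134/106 for the three PFTs, 7500 km2 hexagons, and four
    planted strategy groups (three STS vertices plus a low-intermediate
    center) with equal mixture weights.
    """

    n_species: dict[str, int] = field(default_factory=_default_n_species)
    triangle: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRIANGLE)
    )
    group_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # sd of each planted Gaussian (STS units): at 0.10 the four groups are
    # well separated and recoverable; larger values (~0.2) spread mass along
    # the triangle edges, producing split-membership (polytolerant)
    # assemblages at the few-percent level
    group_dispersion: float = 0.10
    trait_loadings: dict[str, tuple[float, float]] = field(
        default_factory=_default_trait_loadings
    )
    trait_log_means: dict[str, float] = field(default_factory=_default_trait_log_means)
    trait_noise_sd: float = 0.25  # lognormal noise on traits (log scale)

    # Landscape
    extent: tuple[float, float, float, float] = (0.0, 0.0, 2.6e6, 2.8e6)  # m
    cell_area_km2: float = 7500.0
    gradient1_range: tuple[float, float] = (-1.3, 1.3)  # west -> east
    gradient2_range: tuple[float, float] = (-0.8, 1.3)  # south -> north
    env_loadings: dict[str, tuple[float, ...]] = field(
        default_factory=_default_env_loadings
    )
    env_noise_sd: float = 0.25  # per-variable Gaussian noise
    index_noise_sd: float = 0.05  # noise on the latent suitability index
    pnv_thresholds: tuple[float, float] = (-0.35, 0.45)  # on gradient 1
    pnv_classes: tuple[str, str, str] = ("wet_boreal", "temperate", "xeric")

    # Occurrences
    suitability_sd: float = 0.22  # Gaussian kernel width in STS units
    intensity_scale: float = 3.0  # expected count at perfect suitability
    max_rejection_tries: int = 10_000

    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_species.values()):
            raise ValueError("species counts must be non-negative")
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group mixture weights must sum to 1")
        if self.group_dispersion <= 0:
            raise ValueError("group dispersion must be > 0")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell area must be positive")
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must be a non-degenerate rectangle")

    def triangle_vertices(self) -> np.ndarray:
        """Vertices as a (3, 2) array in STRATEGIES order."""
        return np.array([self.triangle[s] for s in STRATEGIES], dtype=float)

    def group_centers(self) -> np.ndarray:
        """Centers of the four planted groups (3 vertices + triangle centroid)."""
        verts = self.triangle_vertices()
        return np.vstack([verts, verts.mean(axis=0)])


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (synthetic or real-data mode)."""

    mode: str = "synthetic"
    world: WorldConfig = field(default_factory=WorldConfig)
    # real-data mode inputs
    species_csv: str | None = None
    occurrences_csv: str | None = None
    landscape_csv: str | None = None

    min_species: int = 3

    # component retention / rotation
    paran_iter: int = 1000

    # random forests
    n_trees: int = 500
    min_node_size: int = 5
    n_perm: int = 500
    spatial_cv_folds: int = 5

    # fuzzy clustering
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    fuzziness: float = 2.0
    fs_alpha: float = 1.0
    n_rep: int = 99
    band: tuple[float, float] = (0.4, 0.6)

    # hotspot KDE
    kde_radius: float = 711_000.0
    kde_bands: tuple[tuple[float, float], ...] = (
        (0.2, 0.4),
        (0.4, 0.6),
        (0.6, 0.8),
        (0.8, 1.0),
    )

    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for name in ("species_csv", "occurrences_csv", "landscape_csv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"real mode requires existing {name}")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness m must be > 1")
        lo, hi = self.band
        if not (0 <= lo < hi <= 1):
            raise ValueError("polytolerance band must satisfy 0 <= lo < hi <= 1")
        if self.kde_radius <= 0:
            raise ValueError("KDE radius must be positive")
        if min(self.k_range) < 2:
            raise ValueError("K range must start at 2 or above")
        self.world.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        world_raw = raw.pop("world", {})
        world = WorldConfig(**_coerce(WorldConfig, world_raw))
        cfg = cls(world=world, **_coerce(cls, raw))
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _coerce(cls: type, raw: dict[str, Any]) -> dict[str, Any]:
    """Keep only known fields; turn lists back into tuples where needed."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "world":
            continue
        if key not in fields:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if isinstance(value, dict):
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
        out[key] = value
    return out
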