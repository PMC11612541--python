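"""Synthetic world generator.

Produces species pools, hexagonal landscapes and occurrence records with
the statistical structure the downstream analysis assumes, so that every
stage of the pipeline can be exercised without external data downloads:

* species tolerance coordinates drawn from four planted strategy groups
  (the three triangle vertices — drought, shade, waterlogging/cold — plus
  a low-intermediate center), confined to the triangular stress tolerance
  space by rejection sampling;
* traits coupled to the tolerance axes through a log-linear loading matrix
  with lognormal noise, so trait–axis correlations have configured signs;
* a landscape of equal-area hexagons carrying 22 climate variables,
  8 soil variables and topography, each loading on two latent spatial
  gradients plus Gaussian noise, and a categorical vegetation class
  obtained by thresholding the first gradient;
* occurrence counts that are Poisson with a Gaussian suitability kernel
  peaked where a cell's latent environment matches the species' tolerance
  optimum, which makes assemblages sort along the environmental gradients.

All three generators are deterministic functions of (config, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stressbiomes.config import (
    CLIMATE_VARS,
    GROUPS,
    PFTS,
    SOIL_VARS,
    TOPO_VARS,
    TRAITS,
    WorldConfig,
)
from stressbiomes.grid_aggregation import HexGrid, build_hex_grid

_SQRT3 = np.sqrt(3.0)


def _rng(config: WorldConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible substream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _points_in_triangle(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized point-in-triangle test via barycentric sign checks."""
    a, b, c = vertices
    def cross(o, d, p):
        return (d[0] - o[0]) * (p[:, 1] - o[1]) - (d[1] - o[1]) * (p[:, 0] - o[0])
    eps = 1e-12
    d1, d2, d3 = cross(a, b, points), cross(b, c, points), cross(c, a, points)
    has_neg = (d1 < -eps) | (d2 < -eps) | (d3 < -eps)
    has_pos = (d1 > eps) | (d2 > eps) | (d3 > eps)
    return ~(has_neg & has_pos)


def _sample_group_positions(
    rng: np.random.Generator,
    centers: np.ndarray,
    groups: np.ndarray,
    dispersion: float,
    vertices: np.ndarray,
    max_tries: int,
) -> np.ndarray:
    """Gaussian around each point's group center, rejected to the triangle."""
    n = len(groups)
    out = np.empty((n, 2))
    pending = np.arange(n)
    for _ in range(max_tries):
        cand = centers[groups[pending]] + rng.normal(0, dispersion, (len(pending), 2))
        ok = _points_in_triangle(cand, vertices)
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            return out
    raise RuntimeError(
        f"rejection sampling failed to place {len(pending)} points inside the "
        f"triangle after {max_tries} rounds"
    )


def generate_species_pool(config: WorldConfig) -> pd.DataFrame:
    """Generate the species table: PFT, planted group, STS axes, six traits.

    Tolerance coordinates come from the four-component planted mixture,
    clipped to the triangle by rejection; each trait is
    ``exp(log_mean + loading . axes + Normal(0, noise))`` so every trait
    value is strictly positive and log-trait/axis correlations carry the
    configured signs.
    """
    config.validate()
    rng = _rng(config, 1)
    vertices = config.triangle_vertices()
    group_centers = config.group_centers()

    rows = []
    for pft in PFTS:
        n = int(config.n_species.get(pft, 0))
        if n == 0:
            continue
        groups = rng.choice(len(GROUPS), size=n, p=np.asarray(config.group_weights))
        pos = _sample_group_positions(
            rng, group_centers, groups, config.group_dispersion, vertices,
            config.max_rejection_tries,
        )
        loadings = np.array([config.trait_loadings[t] for t in TRAITS])  # 6 x 2
        log_means = np.array([config.trait_log_means[t] for t in TRAITS])
        log_traits = (
            log_means[None, :]
            + pos @ loadings.T
            + rng.normal(0, config.trait_noise_sd, (n, len(TRAITS)))
        )
        prefix = "".join(w[0] for w in pft.split("_"))
        for i in range(n):
            rows.append(
                {
                    "species_id": f"{prefix}_{i:04d}",
                    "pft": pft,
                    "group": GROUPS[groups[i]],
                    "axis1": pos[i, 0],
                    "axis2": pos[i, 1],
                    **{t: float(np.exp(log_traits[i, j])) for j, t in enumerate(TRAITS)},
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species_id", "pft", "group", "axis1", "axis2", *TRAITS],
    )


def generate_hex_landscape(config: WorldConfig) -> tuple[HexGrid, pd.DataFrame]:
    """Generate the hexagon grid and its environmental table.

    Two latent gradients run linearly across the extent (gradient 1
    west-east, gradient 2 south-north).  Every environmental variable is
    ``loading . (g1, g2) + Normal(0, env_noise_sd)``; the vegetation class
    (``pnv_class``) thresholds gradient 1; ``true_group`` records which
    planted strategy group the cell's latent environment corresponds to
    (ground truth for recovery checks).
    """
    config.validate()
    rng = _rng(config, 2)
    grid = build_hex_grid(config.extent, config.cell_area_km2)
    x0, y0, x1, y1 = config.extent
    cx, cy = grid.centers[:, 0], grid.centers[:, 1]
    g1_lo, g1_hi = config.gradient1_range
    g2_lo, g2_hi = config.gradient2_range
    g1 = g1_lo + (cx - x0) / (x1 - x0) * (g1_hi - g1_lo)
    g2 = g2_lo + (cy - y0) / (y1 - y0) * (g2_hi - g2_lo)
    latent = np.column_stack([g1, g2])

    df = pd.DataFrame(
        {
            "hex_id": grid.hex_ids,
            "center_x": cx,
            "center_y": cy,
            "area_km2": grid.cell_area_km2,
            "env_index_1": g1 + rng.normal(0, config.index_noise_sd, len(grid)),
            "env_index_2": g2 + rng.normal(0, config.index_noise_sd, len(grid)),
        }
    )
    # latent factors: the two spatial gradients plus spatially white
    # block-specific nuisance factors (any loading entries beyond g1, g2)
    n_factors = max(len(w) for w in config.env_loadings.values())
    factors = np.column_stack(
        [g1, g2] + [rng.standard_normal(len(grid)) for _ in range(n_factors - 2)]
    )
    for name in (*CLIMATE_VARS, *SOIL_VARS, *TOPO_VARS):
        w = np.zeros(n_factors)
        w[: len(config.env_loadings[name])] = config.env_loadings[name]
        df[name] = factors @ w + rng.normal(0, config.env_noise_sd, len(grid))

    t_lo, t_hi = config.pnv_thresholds
    classes = np.where(
        g1 > t_hi, config.pnv_classes[2],
        np.where(g1 > t_lo, config.pnv_classes[1], config.pnv_classes[0]),
    )
    df["pnv_class"] = classes

    centers = config.group_centers()
    d = np.linalg.norm(latent[:, None, :] - centers[None, :, :], axis=2)
    df["true_group"] = np.asarray(GROUPS)[d.argmin(axis=1)]
    return grid, df


def _jitter_in_hexagon(
    rng: np.random.Generator, n: int, R: float
) -> np.ndarray:
    """Uniform offsets inside a flat-top hexagon of circumradius R."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = int((n - filled) * 1.4) + 8
        cand = np.column_stack(
            [rng.uniform(-R, R, m), rng.uniform(-_SQRT3 / 2 * R, _SQRT3 / 2 * R, m)]
        )
        ok = _SQRT3 * np.abs(cand[:, 0]) + np.abs(cand[:, 1]) <= _SQRT3 * R + 1e-12
        take = cand[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def generate_occurrences(
    species: pd.DataFrame, grid: HexGrid, landscape: pd.DataFrame, config: WorldConfig
) -> pd.DataFrame:
    """Sample occurrence points (species_id, x, y).

    Each species' count in each cell is Poisson with intensity
    ``intensity_scale * exp(-||env_index - optimum||^2 / (2 sd^2))`` where
    the species' optimum is its own STS coordinate pair (the latent
    gradients are expressed in STS units).  Points are jittered uniformly
    within their hexagon.
    """
    if len(species) == 0:
        raise ValueError("species pool is empty")
    if len(landscape) == 0:
        raise ValueError("landscape is empty")
    rng = _rng(config, 3)
    optima = species[["axis1", "axis2"]].to_numpy()
    env = landscape[["env_index_1", "env_index_2"]].to_numpy()
    d2 = ((optima[:, None, :] - env[None, :, :]) ** 2).sum(axis=2)
    lam = config.intensity_scale * np.exp(-d2 / (2.0 * config.suitability_sd**2))
    counts = rng.poisson(lam)  # (n_species, n_cells)

    sp_idx, cell_idx = np.nonzero(counts)
    reps = counts[sp_idx, cell_idx]
    sp_rows = np.repeat(sp_idx, reps)
    cell_rows = np.repeat(cell_idx, reps)
    jitter = _jitter_in_hexagon(rng, len(sp_rows), grid.circumradius)
    centers = landscape[["center_x", "center_y"]].to_numpy()[cell_rows]
    return pd.DataFrame(
        {
            "species_id": species["species_id"].to_numpy()[sp_rows],
            "x": centers[:, 0] + jitter[:, 0],
            "y": centers[:, 1] + jitter[:, 1],
        }
    )


def expected_intensity(
    species_row: pd.Series, landscape: pd.DataFrame, config: WorldConfig
) -> np.ndarray:
    """Per-cell expected occurrence count for one species (no sampling)."""
    env = landscape[["env_index_1", "env_index_2"]].to_numpy()
    opt = np.array([species_row["axis1"], species_row["axis2"]])
    d2 = ((env - opt) ** 2).sum(axis=1)
    return config.intensity_scale * np.exp(-d2 / (2.0 * config.suitability_sd**2))


def generate_world(
    config: WorldConfig,
) -> tuple[pd.DataFrame, HexGrid, pd.DataFrame, pd.DataFrame, dict]:
    """Compose the three generators.

    Returns (species, grid, landscape, occurrences, metadata); the
    metadata records the seed and headline sizes so a run can be replayed.
    """
    species = generate_species_pool(config)
    grid, landscape = generate_hex_landscape(config)
    occurrences = generate_occurrences(species, grid, landscape, config)
    meta = {
        "seed": config.seed,
        "n_species": len(species),
        "n_cells": len(grid),
        "n_occurrences": len(occurrences),
        "cell_area_km2": config.cell_area_km2,
    }
    return species, grid, landscape, occurrences, meta
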