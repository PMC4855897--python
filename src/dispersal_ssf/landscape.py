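"""Synthetic landscape generation: aligned covariate raster layers.

The generated stack emulates a Rocky-Mountain-foothills study area: a
smooth elevation field with a mountains-to-plains west-east gradient,
terrain ruggedness derived from it, percent canopy cover loosely tracking
mid elevations, a sparse road network rasterized to a distance surface,
and twelve monthly NDVI layers following a green-up curve that peaks in
mid-summer.  Terrain layers default to 30-m cells and NDVI to 250-m cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .covariates import terrain_ruggedness
from .raster import RasterGrid

__all__ = ["LandscapeStack", "generate_landscape", "seasonal_ndvi_scale"]

MIN_EXTENT_M = 120_000.0  # 100-km dispersals must fit with margin


@dataclass
class LandscapeStack:
    """Aligned raster covariate layers sharing one projected frame."""

    elevation: RasterGrid
    ruggedness: RasterGrid
    canopy: RasterGrid          # percent, [0, 100]
    dist_roads: RasterGrid      # metres, 0 on road cells
    ndvi_by_month: list[RasterGrid]  # 12 layers, values in [-1, 1]
    seed: int | None = None
    scaling_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Intersection of all layer extents: any in-extent point samples
        finitely on every layer."""
        grids = [self.elevation, self.ruggedness, self.canopy, self.dist_roads, *self.ndvi_by_month]
        return (
            max(g.extent[0] for g in grids),
            max(g.extent[1] for g in grids),
            min(g.extent[2] for g in grids),
            min(g.extent[3] for g in grids),
        )

    def __post_init__(self) -> None:
        if len(self.ndvi_by_month) != 12:
            raise ValueError("ndvi_by_month must hold 12 monthly layers")
        if not self.scaling_stats:
            self.scaling_stats = self._landscape_stats()

    def _landscape_stats(self) -> dict[str, tuple[float, float]]:
        """Landscape-wide mean/SD per covariate (July NDVI), the scale on
        which generator selection coefficients are expressed."""
        stats = {}
        for name, grid in [
            ("ruggedness", self.ruggedness),
            ("canopy", self.canopy),
            ("dist_roads", self.dist_roads),
            ("ndvi", self.ndvi_by_month[6]),
        ]:
            vals = grid.data
            stats[name] = (float(vals.mean()), float(vals.std()))
        return stats

    def sample_covariates(self, x, y, month: int) -> dict[str, np.ndarray]:
        return {
            "ruggedness": self.ruggedness.sample(x, y),
            "ndvi": self.ndvi_by_month[month - 1].sample(x, y),
            "dist_roads": self.dist_roads.sample(x, y),
            "canopy": self.canopy.sample(x, y),
        }

    def scaled_covariate_matrix(self, x, y, month: int) -> np.ndarray:
        """Design rows (rugg, rugg², ndvi, dist_roads, canopy, canopy²)
        z-scaled by landscape-wide statistics; quadratics are squares of
        the scaled linear terms (centred so betas stay interpretable)."""
        raw = self.sample_covariates(x, y, month)
        z = {}
        for name in ("ruggedness", "ndvi", "dist_roads", "canopy"):
            mu, sd = self.scaling_stats[name]
            z[name] = (raw[name] - mu) / sd
        return np.column_stack(
            [
                z["ruggedness"],
                z["ruggedness"] ** 2 - 1.0,
                z["ndvi"],
                z["dist_roads"],
                z["canopy"],
                z["canopy"] ** 2 - 1.0,
            ]
        )

    # ---- plain-text persistence -------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.elevation.write_ascii(directory / "elevation.asc")
        self.ruggedness.write_ascii(directory / "ruggedness.asc")
        self.canopy.write_ascii(directory / "canopy.asc")
        self.dist_roads.write_ascii(directory / "dist_roads.asc")
        for m, layer in enumerate(self.ndvi_by_month, start=1):
            layer.write_ascii(directory / f"ndvi_{m:02d}.asc")

    @classmethod
    def load(cls, directory: str | Path) -> "LandscapeStack":
        directory = Path(directory)
        return cls(
            elevation=RasterGrid.read_ascii(directory / "elevation.asc"),
            ruggedness=RasterGrid.read_ascii(directory / "ruggedness.asc"),
            canopy=RasterGrid.read_ascii(directory / "canopy.asc"),
            dist_roads=RasterGrid.read_ascii(directory / "dist_roads.asc"),
            ndvi_by_month=[
                RasterGrid.read_ascii(directory / f"ndvi_{m:02d}.asc") for m in range(1, 13)
            ],
        )


def seasonal_ndvi_scale(month: int) -> float:
    """Seasonal green-up multiplier, peaking in July (month 7)."""
    return 0.35 + 0.6 * float(np.exp(-((month - 7.0) ** 2) / (2 * 2.2**2)))


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    return (f - f.mean()) / f.std()


def _road_distance(rng, shape, cell, n_roads) -> np.ndarray:
    """Rasterize a sparse network of straightish roads; Euclidean distance."""
    road = np.zeros(shape, dtype=bool)
    nr, nc = shape
    for _ in range(n_roads):
        # road runs across the extent between two random boundary points
        if rng.random() < 0.5:
            p0 = np.array([0.0, rng.uniform(0, nc)])
            p1 = np.array([nr - 1.0, rng.uniform(0, nc)])
        else:
            p0 = np.array([rng.uniform(0, nr), 0.0])
            p1 = np.array([rng.uniform(0, nr), nc - 1.0])
        n_pts = int(np.hypot(*(p1 - p0)) * 2) + 2
        t = np.linspace(0, 1, n_pts)[:, None]
        wobble = 0.03 * nr * np.sin(t.ravel() * rng.uniform(2, 5) + rng.uniform(0, 6.28))
        pts = p0 + t * (p1 - p0)
        pts[:, 1] = pts[:, 1] + wobble
        ij = np.clip(np.round(pts).astype(int), [0, 0], [nr - 1, nc - 1])
        road[ij[:, 0], ij[:, 1]] = True
    return ndimage.distance_transform_edt(~road) * cell


def generate_landscape(
    extent: tuple[float, float] = (MIN_EXTENT_M, MIN_EXTENT_M),
    rng_seed: int = 0,
    *,
    terrain_cell: float = 30.0,
    ndvi_cell: float = 250.0,
    relief_m: float = 1200.0,
    n_roads: int = 14,
) -> LandscapeStack:
    """Generate a reproducible synthetic landscape stack.

    ``extent`` is (width, height) in metres and must be at least
    120 km x 120 km so that 100-km dispersal paths fit inside.
    """
    width, height = float(extent[0]), float(extent[1])
    if width < MIN_EXTENT_M or height < MIN_EXTENT_M:
        raise ValueError(
            f"extent {extent} too small: need at least {MIN_EXTENT_M:.0f} m per side "
            "so 100-km dispersal paths fit"
        )
    rng = np.random.default_rng(rng_seed)
    nr = int(np.ceil(height / terrain_cell))
    nc = int(np.ceil(width / terrain_cell))

    # mountains in the west grading to plains in the east
    gradient = np.linspace(1.0, 0.0, nc)[None, :] ** 1.5
    rough = _smooth_field(rng, (nr, nc), sigma_cells=max(2.0, 1500.0 / terrain_cell))
    broad = _smooth_field(rng, (nr, nc), sigma_cells=max(4.0, 8000.0 / terrain_cell))
    # cell-scale relief so ruggedness varies at the resolution animals
    # experience within single steps, as real terrain does
    fine = _smooth_field(rng, (nr, nc), sigma_cells=1.0)
    elevation = 900.0 + relief_m * (
        0.8 * gradient + 0.25 * broad + 0.25 * rough * gradient
    ) + 18.0 * fine * (0.4 + gradient)
    elev_grid = RasterGrid(elevation, 0.0, 0.0, terrain_cell)

    rugg_grid = RasterGrid(terrain_ruggedness(elevation), 0.0, 0.0, terrain_cell)

    canopy_field = _smooth_field(rng, (nr, nc), sigma_cells=max(3.0, 2500.0 / terrain_cell))
    canopy_stand = _smooth_field(rng, (nr, nc), sigma_cells=1.0)  # stand-scale patchiness
    canopy = np.clip(45 + 22 * canopy_field + 12 * canopy_stand + 15 * gradient, 0.0, 100.0)
    canopy_grid = RasterGrid(canopy, 0.0, 0.0, terrain_cell)

    dist_grid = RasterGrid(_road_distance(rng, (nr, nc), terrain_cell, n_roads), 0.0, 0.0, terrain_cell)

    nrn = int(np.ceil(height / ndvi_cell))
    ncn = int(np.ceil(width / ndvi_cell))
    # broad valley-scale greenness structure plus local patch structure
    ndvi_base = (
        0.55
        + 0.14 * _smooth_field(rng, (nrn, ncn), sigma_cells=max(3.0, 18_000.0 / ndvi_cell))
        + 0.14 * _smooth_field(rng, (nrn, ncn), sigma_cells=max(2.0, 3000.0 / ndvi_cell))
    )
    # vegetation patchiness: real satellite NDVI is heterogeneous from one
    # cell to the next, not a smooth field
    ndvi_patch = 0.08 * _smooth_field(rng, (nrn, ncn), sigma_cells=1.0)
    ndvi_layers = []
    for month in range(1, 13):
        noise = 0.015 * _smooth_field(rng, (nrn, ncn), sigma_cells=1.0)
        layer = np.clip((ndvi_base + ndvi_patch) * seasonal_ndvi_scale(month) + noise, -1.0, 1.0)
        ndvi_layers.append(RasterGrid(layer, 0.0, 0.0, ndvi_cell))

    return LandscapeStack(
        elevation=elev_grid,
        ruggedness=rugg_grid,
        canopy=canopy_grid,
        dist_roads=dist_grid,
        ndvi_by_month=ndvi_layers,
        seed=rng_seed,
    )
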