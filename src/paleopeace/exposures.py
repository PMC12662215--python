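"""Per-individual Monte-Carlo exposure sampling.

Attaches to every individual a set of draws of the climatic, oceanic and
demographic conditions they may have experienced, given their spatial
location and calendar-time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiocarbon import PopulationKDE

EARTH_RADIUS_KM = 6371.0088

TERRESTRIAL_VARIABLES = (
    "mean_temperature",
    "mean_precipitation",
    "sd_temperature",
    "sd_precipitation",
)

COAST_MAX_DISTANCE_KM = 15.0
COAST_MAX_ELEVATION_M = 500.0


class CoverageError(ValueError):
    """No grid cells / series values available for an individual."""


@dataclass(frozen=True)
class Individual:
    """One adult skeletal record."""

    id: str
    site_id: str
    lon: float
    lat: float
    elevation: float
    distance_to_coast: float
    window: tuple[float, float]  # (start, end) cal BP, start >= end
    trauma: int  # 1 = craniofacial trauma present
    complexity: int  # 0 nonstate / 1 state / 2 empire
    region: str  # coast | inland

    def __post_init__(self) -> None:
        start, end = self.window
        if start < end:
            raise ValueError(f"{self.id}: window start must be >= end (cal BP)")
        if self.trauma not in (0, 1):
            raise ValueError(f"{self.id}: trauma must be 0/1")
        if self.complexity not in (0, 1, 2):
            raise ValueError(f"{self.id}: complexity must be 0/1/2")


@dataclass
class ClimateGridSet:
    """Century-resolution rasters on a shared lon/lat grid.

    ``data`` maps variable name -> array of shape
    (n_centuries, n_lat, n_lon).
    """

    lons: np.ndarray
    lats: np.ndarray
    centuries: np.ndarray  # cal BP, ascending
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.centuries = np.asarray(self.centuries, dtype=float)
        shape = (self.centuries.size, self.lats.size, self.lons.size)
        for k, v in self.data.items():
            if v.shape != shape:
                raise ValueError(f"variable {k}: shape {v.shape} != {shape}")
        if self.centuries.size > 1:
            steps = np.diff(self.centuries)
            if not np.all(steps > 0) or not np.allclose(steps, steps[0]):
                raise ValueError("centuries must ascend with a uniform step")

    def century_index(self, century: float) -> int:
        i = int(np.argmin(np.abs(self.centuries - century)))
        if abs(self.centuries[i] - century) > 1e-6:
            raise KeyError(f"century {century} not on grid")
        return i

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (century, lat, lon, variable columns)."""
        cc, la, lo = np.meshgrid(self.centuries, self.lats, self.lons, indexing="ij")
        cols = {"century": cc.ravel(), "lat": la.ravel(), "lon": lo.ravel()}
        for k, v in self.data.items():
            cols[k] = v.ravel()
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClimateGridSet":
        lons = np.unique(df["lon"].to_numpy())
        lats = np.unique(df["lat"].to_numpy())
        cents = np.unique(df["century"].to_numpy())
        shape = (cents.size, lats.size, lons.size)
        variables = [c for c in df.columns if c not in ("century", "lat", "lon")]
        df = df.sort_values(["century", "lat", "lon"])
        if len(df) != int(np.prod(shape)):
            raise ValueError("climate table is not a full grid")
        data = {v: df[v].to_numpy().reshape(shape) for v in variables}
        return cls(lons, lats, cents, data)


@dataclass(frozen=True)
class SSTSeries:
    """Sea-surface temperature series at a fixed core location."""

    core_id: str
    lon: float
    lat: float
    centuries: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centuries, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError(f"{self.core_id}: centuries must ascend")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.core_id}: values must be finite")
        object.__setattr__(self, "centuries", c)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EventSeries:
    """Events-per-century series from a single core."""

    core_id: str
    centuries: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centuries, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError(f"{self.core_id}: centuries must ascend")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.core_id}: values must be finite")
        object.__setattr__(self, "centuries", c)
        object.__setattr__(self, "values", v)


@dataclass
class ExposureDraws:
    """Monte-Carlo predictor vectors for one individual.

    ``draws`` maps variable name -> array of length n_draws; ``sst`` is
    present only for coastal individuals. ``complexity`` is a fixed
    covariate repeated across draws when tabulated.
    """

    individual_id: str
    n_draws: int
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    complexity: int = 0

    def variable_names(self) -> list[str]:
        return list(self.draws)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in km (spherical approximation)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def classify_region(distance_to_coast: float, elevation: float) -> str:
    """Coast iff distance < 15 km AND elevation < 500 masl; else inland."""
    if distance_to_coast is None or elevation is None:
        raise ValueError("distance_to_coast and elevation are required")
    d = float(distance_to_coast)
    e = float(elevation)
    if not (np.isfinite(d) and np.isfinite(e)):
        raise ValueError("distance_to_coast and elevation must be finite")
    if d < 0 or e < 0:
        raise ValueError("distance_to_coast and elevation must be nonnegative")
    return "coast" if (d < COAST_MAX_DISTANCE_KM and e < COAST_MAX_ELEVATION_M) else "inland"


def buffer_mean(
    grid_set: ClimateGridSet,
    lon: float,
    lat: float,
    century: float,
    variable: str,
    radius_km: float = 20.0,
) -> float:
    """Mean of ``variable`` over cells whose centers lie within radius."""
    mask = _buffer_mask(grid_set, lon, lat, radius_km)
    ci = grid_set.century_index(century)
    vals = grid_set.data[variable][ci][mask]
    return float(vals.mean())


def _buffer_mask(grid_set: ClimateGridSet, lon: float, lat: float, radius_km: float) -> np.ndarray:
    lo, la = np.meshgrid(grid_set.lons, grid_set.lats)
    dist = great_circle_km(lon, lat, lo, la)
    mask = dist <= radius_km
    if not mask.any():
        raise CoverageError(
            f"no grid cells within {radius_km} km of ({lon:.3f}, {lat:.3f})"
        )
    return mask


def window_centuries(centuries: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Indices of century values falling inside [end, start] cal BP."""
    start, end = window
    return np.flatnonzero((centuries >= end) & (centuries <= start))


def draw_climate(
    individual: Individual,
    grid_set: ClimateGridSet,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    radius_km: float = 20.0,
) -> dict[str, np.ndarray]:
    """Sample terrestrial climate for an individual's window.

    Candidate values are 20-km buffer means per century inside the
    window; one century index is drawn per draw and all four variables
    taken from it jointly.
    """
    rng = np.random.default_rng() if rng is None else rng
    idx = window_centuries(grid_set.centuries, individual.window)
    if idx.size == 0:
        raise CoverageError(
            f"{individual.id}: window {individual.window} overlaps no grid century"
        )
    mask = _buffer_mask(grid_set, individual.lon, individual.lat, radius_km)
    candidates = {
        v: np.array([grid_set.data[v][i][mask].mean() for i in idx])
        for v in grid_set.data
    }
    pick = rng.integers(idx.size, size=n)
    return {v: c[pick] for v, c in candidates.items()}


def assign_sst_core(individual: Individual, cores: list[SSTSeries]) -> str:
    """Nearest core by great-circle distance; ties go to smallest core_id."""
    if individual.region != "coast":
        raise ValueError(f"{individual.id}: SST applies to coastal individuals only")
    if not cores:
        raise ValueError("no SST cores supplied")
    dists = np.array(
        [float(great_circle_km(individual.lon, individual.lat, c.lon, c.lat)) for c in cores]
    )
    # exact ties (to within rounding) resolve to the smallest core_id
    near = [c.core_id for c, d in zip(cores, dists) if d <= dists.min() + 1e-6]
    return min(near)


def draw_series(
    series: SSTSeries | EventSeries,
    window: tuple[float, float],
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform-with-replacement draws from series values inside the window."""
    rng = np.random.default_rng() if rng is None else rng
    idx = window_centuries(series.centuries, window)
    if idx.size == 0:
        raise CoverageError(f"{series.core_id}: window {window} overlaps no century")
    return series.values[idx][rng.integers(idx.size, size=n)]


def draw_population(
    individual: Individual,
    kdes: list[PopulationKDE],
    n: int = 1000,
    rng: np.random.Generator | None = None,
    density_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Per draw: pick a replicate and a year in the window, read its density.

    ``density_matrix`` (n_replicates, n_grid) can be precomputed once per
    region to avoid restacking replicate densities per individual.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not kdes:
        raise ValueError("no population KDE replicates supplied")
    grid = kdes[0].cal_bp
    idx = window_centuries(grid, individual.window)
    if idx.size == 0:
        raise CoverageError(
            f"{individual.id}: window {individual.window} outside KDE grid"
        )
    if density_matrix is None:
        density_matrix = np.stack([k.density for k in kdes])
    reps = rng.integers(len(kdes), size=n)
    years = idx[rng.integers(idx.size, size=n)]
    return density_matrix[reps, years]


def build_exposures(
    individuals: list[Individual],
    grid_set: ClimateGridSet,
    sst_cores: list[SSTSeries],
    enso: EventSeries,
    kdes_by_region: dict[str, list[PopulationKDE]],
    n_draws: int = 1000,
    radius_km: float = 20.0,
    rng: np.random.Generator | None = None,
) -> list[ExposureDraws]:
    """Full exposure sampling for a cohort.

    Climate, SST, ENSO and population draws are mutually independent
    across sources within a draw index; SST is attached only for coastal
    individuals.
    """
    rng = np.random.default_rng() if rng is None else rng
    density_matrices = {
        region: np.stack([k.density for k in ks])
        for region, ks in kdes_by_region.items()
    }
    out = []
    for ind in individuals:
        draws = draw_climate(ind, grid_set, n=n_draws, rng=rng, radius_km=radius_km)
        if ind.region == "coast":
            core_id = assign_sst_core(ind, sst_cores)
            core = next(c for c in sst_cores if c.core_id == core_id)
            draws["sst"] = draw_series(core, ind.window, n=n_draws, rng=rng)
        draws["enso_frequency"] = draw_series(enso, ind.window, n=n_draws, rng=rng)
        draws["population_density"] = draw_population(
            ind,
            kdes_by_region[ind.region],
            n=n_draws,
            rng=rng,
            density_matrix=density_matrices[ind.region],
        )
        out.append(ExposureDraws(ind.id, n_draws, draws, complexity=ind.complexity))
    return out


def exposures_to_frame(exposures: list[ExposureDraws]) -> pd.DataFrame:
    """Long-format table keyed (individual_id, draw_index)."""
    frames = []
    for e in exposures:
        df = pd.DataFrame(e.draws)
        df.insert(0, "draw_index", np.arange(e.n_draws))
        df.insert(0, "individual_id", e.individual_id)
        df["complexity"] = e.complexity
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def draw_means(exposures: list[ExposureDraws]) -> pd.DataFrame:
    """Per-individual means over draws (plus fixed complexity)."""
    rows = []
    for e in exposures:
        row = {"individual_id": e.individual_id}
        row.update({k: float(v.mean()) for k, v in e.draws.items()})
        row["complexity"] = e.complexity
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual_id")
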