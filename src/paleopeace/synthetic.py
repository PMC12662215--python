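"""Synthetic study world with recoverable ground truth.

Builds grids, ocean cores, radiocarbon dates and adult individuals
whose trauma outcomes follow a known logistic model on their true
exposures, so every downstream stage can be validated against the
generative parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exposures import (
    ClimateGridSet,
    EventSeries,
    Individual,
    SSTSeries,
    TERRESTRIAL_VARIABLES,
    classify_region,
)
from .radiocarbon import CalibrationCurve, RadiocarbonDate


class ConfigurationError(ValueError):
    """Invalid world configuration."""


@dataclass
class TraumaCoefficients:
    """Log-odds model for trauma on standardized true exposures.

    log-odds = intercept + sum(linear[v] * z_v)
             + population_quadratic * z_pop**2
             + interaction coefficient * z_a * z_b
    """

    intercept: float = -1.3
    linear: dict[str, float] = field(
        default_factory=lambda: {
            "mean_temperature": -0.4,
            "sd_temperature": 0.6,
            "population_density": -0.3,
        }
    )
    population_quadratic: float = 0.5
    interaction: tuple[str, str, float] | None = ("sd_temperature", "population_density", 0.3)


@dataclass
class GridExtent:
    lon_min: float = -77.0
    lon_max: float = -74.0
    lat_min: float = -16.0
    lat_max: float = -12.0
    cell_size: float = 0.05

    def validate(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ConfigurationError("grid extent must have positive span")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")


@dataclass
class WorldConfig:
    seed: int = 0
    n_sites: int = 30
    n_individuals: int = 600
    n_dates: int = 400
    time_span: tuple[float, float] = (10000.0, 200.0)  # (oldest, youngest) cal BP
    grid_extent: GridExtent = field(default_factory=GridExtent)
    century_step: float = 100.0
    trauma_coefficients: TraumaCoefficients = field(default_factory=TraumaCoefficients)
    coastal_fraction: float = 0.5
    sd_coupling: float = 0.9  # SD fields ~ coupling * mean + noise
    window_halfwidth: float = 150.0  # individual dating window half-width, years
    date_error_range: tuple[float, float] = (20.0, 80.0)
    large_error_fraction: float = 0.05  # dates given errors > 100 yr (filter fodder)

    def validate(self) -> None:
        oldest, youngest = self.time_span
        if not (oldest > youngest >= 0):
            raise ConfigurationError("time_span must satisfy oldest > youngest >= 0")
        if min(self.n_sites, self.n_individuals) <= 0 or self.n_dates < 0:
            raise ConfigurationError("counts must be positive")
        if not (0 <= self.coastal_fraction <= 1):
            raise ConfigurationError("coastal_fraction must be in [0, 1]")
        self.grid_extent.validate()


@dataclass
class Site:
    id: str
    lon: float
    lat: float
    elevation: float
    distance_to_coast: float
    region: str
    # occupation density: Gaussian mixture (weights, means, sds) over cal BP
    occupation: tuple[np.ndarray, np.ndarray, np.ndarray] = None


@dataclass
class SyntheticWorld:
    config: WorldConfig
    sites: list[Site]
    climate: ClimateGridSet
    sst_cores: list[SSTSeries]
    enso: EventSeries
    dates: list[RadiocarbonDate]
    individuals: list[Individual]
    true_exposures: pd.DataFrame  # indexed by individual id
    true_trauma_probability: np.ndarray
    date_true_years: dict[str, float] = field(default_factory=dict)

    def _region_density_raw(self, region: str, years: np.ndarray) -> np.ndarray:
        dens = np.zeros_like(years, dtype=float)
        for s in self.sites:
            if s.region != region:
                continue
            w, mu, sd = s.occupation
            for wi, mi, si in zip(w, mu, sd):
                dens += wi * np.exp(-0.5 * ((years - mi) / si) ** 2) / si
        return dens

    def region_density(self, region: str, years) -> np.ndarray | float:
        """True relative population density of a region, normalized to
        integrate to 1 over the configured time span (trapezoid)."""
        oldest, youngest = self.config.time_span
        ref = np.arange(youngest, oldest + 1.0, 10.0)
        area = np.trapezoid(self._region_density_raw(region, ref), ref)
        scalar = np.isscalar(years)
        vals = self._region_density_raw(region, np.atleast_1d(np.asarray(years, dtype=float)))
        if area > 0:
            vals = vals / area
        return float(vals[0]) if scalar else vals


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.8, sigma: float = 1.0) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0, sigma / np.sqrt(1 - phi**2))
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0, sigma)
    return x


def synthetic_curve(
    oldest: float = 12500.0, step: float = 5.0, slope: float = 0.95
) -> CalibrationCurve:
    """Strictly monotone wiggly calibration curve for fabrication tests."""
    cal = np.arange(0.0, oldest + step / 2, step)
    c14 = slope * cal + 150 * np.sin(cal / 800.0) + 40 * np.sin(cal / 180.0 + 1.0)
    sigma = 8.0 + cal / 1000.0
    return CalibrationCurve("synthetic", cal, c14, sigma)


def _centuries(config: WorldConfig) -> np.ndarray:
    oldest, youngest = config.time_span
    return np.arange(youngest, oldest + 0.5 * config.century_step, config.century_step)


def _make_climate(config: WorldConfig, rng: np.random.Generator) -> ClimateGridSet:
    ext = config.grid_extent
    lons = np.arange(ext.lon_min + ext.cell_size / 2, ext.lon_max, ext.cell_size)
    lats = np.arange(ext.lat_min + ext.cell_size / 2, ext.lat_max, ext.cell_size)
    cents = _centuries(config)
    nlon, nlat, nc = lons.size, lats.size, cents.size
    lo, la = np.meshgrid(lons, lats)
    # smooth spatial structure; AR(1) century anomalies shared spatially
    t_spatial = 22.0 - 1.2 * (la - la.mean()) - 0.6 * (lo - lo.mean())
    p_spatial = 600.0 + 120.0 * (lo - lo.mean()) + 40.0 * np.sin(2 * np.pi * (la - la.min()) / max(float(np.ptp(la)), 1e-9))
    t_anom = _ar1(rng, nc, phi=0.85, sigma=0.6)
    p_anom = _ar1(rng, nc, phi=0.85, sigma=35.0)
    mean_t = t_spatial[None] + t_anom[:, None, None]
    mean_p = np.clip(p_spatial[None] + p_anom[:, None, None], 1.0, None)
    c = config.sd_coupling
    noise_scale = np.sqrt(max(1 - c**2, 1e-6))
    sd_t = 0.15 * (c * mean_t + noise_scale * rng.normal(0, 1.5, size=mean_t.shape)) + 2.0
    sd_p = 0.25 * (c * mean_p + noise_scale * rng.normal(0, 60.0, size=mean_p.shape))
    # float32 keeps the grids cheap to generate and slice
    data = {
        "mean_temperature": mean_t.astype(np.float32),
        "mean_precipitation": mean_p.astype(np.float32),
        "sd_temperature": np.clip(sd_t, 0.05, None).astype(np.float32),
        "sd_precipitation": np.clip(sd_p, 0.05, None).astype(np.float32),
    }
    return ClimateGridSet(lons, lats, cents, data)


def _make_cores(config: WorldConfig, rng: np.random.Generator) -> tuple[list[SSTSeries], EventSeries]:
    ext = config.grid_extent
    cents = _centuries(config)
    core_lats = (-4.0, -11.0, -15.0, -17.0)
    cores = []
    for i, lat in enumerate(core_lats, start=1):
        sst = 20.0 - 0.15 * (lat + 11.0) + _ar1(rng, cents.size, phi=0.8, sigma=0.5)
        cores.append(SSTSeries(f"core_{i:02d}", ext.lon_min - 1.0, lat, cents, sst))
    # smooth century-scale event-rate series (counts jittered around an
    # AR(1) rate would destroy window-mean recoverability at this step)
    events = np.clip(8.0 + _ar1(rng, cents.size, phi=0.95, sigma=1.0), 0.0, None)
    enso = EventSeries("enso_core", cents, np.round(events, 2))
    return cores, enso


def _make_sites(config: WorldConfig, rng: np.random.Generator) -> list[Site]:
    ext = config.grid_extent
    oldest, youngest = config.time_span
    n_coast = int(round(config.coastal_fraction * config.n_sites))
    sites = []
    # keep sites off the extent margins so 20-km buffers have coverage
    lon_pad = 0.3 * (ext.lon_max - ext.lon_min)
    lat_pad = 0.05 * (ext.lat_max - ext.lat_min)
    for i in range(config.n_sites):
        coastal = i < n_coast
        lon = rng.uniform(ext.lon_min + lon_pad / 3, ext.lon_max - lon_pad)
        lat = rng.uniform(ext.lat_min + lat_pad, ext.lat_max - lat_pad)
        if coastal:
            dist = rng.uniform(0.0, 14.0)
            elev = rng.uniform(0.0, 450.0)
        else:
            dist = rng.uniform(20.0, 250.0)
            elev = rng.uniform(600.0, 4200.0)
        k = int(rng.integers(1, 4))
        mu = rng.uniform(youngest, oldest, size=k)
        sd = rng.uniform((oldest - youngest) / 30, (oldest - youngest) / 8, size=k)
        w = rng.dirichlet(np.ones(k))
        sites.append(
            Site(
                id=f"site_{i + 1:03d}",
                lon=float(lon),
                lat=float(lat),
                elevation=float(elev),
                distance_to_coast=float(dist),
                region=classify_region(dist, elev),
                occupation=(w, mu, sd),
            )
        )
    return sites


def _sample_occupation_year(
    site: Site, config: WorldConfig, rng: np.random.Generator
) -> float:
    oldest, youngest = config.time_span
    w, mu, sd = site.occupation
    for _ in range(1000):
        k = rng.choice(len(w), p=w)
        y = rng.normal(mu[k], sd[k])
        if youngest <= y <= oldest:
            return float(y)
    return float(rng.uniform(youngest, oldest))  # pragma: no cover - fallback


def generate_dates(
    sites: list[Site],
    config: WorldConfig,
    curve: CalibrationCurve,
    rng: np.random.Generator,
) -> tuple[list[RadiocarbonDate], dict[str, float]]:
    """Fabricate dates through the curve; true years returned for tests."""
    if config.n_dates == 0:
        return [], {}
    young, old = curve.span
    oldest, youngest = config.time_span
    if oldest > old or youngest < young:
        raise ConfigurationError(
            f"time_span {config.time_span} outside curve span {curve.span}"
        )
    weights = np.array([s.occupation[0].sum() for s in sites])
    weights = weights / weights.sum()
    alloc = rng.multinomial(config.n_dates, weights)
    dates, true_years = [], {}
    lo_err, hi_err = config.date_error_range
    n = 0
    for site, count in zip(sites, alloc):
        for _ in range(count):
            n += 1
            true_year = _sample_occupation_year(site, config, rng)
            mu, sg = curve.interpolate(np.array([true_year]))
            err = (
                rng.uniform(120.0, 300.0)
                if rng.random() < config.large_error_fraction
                else rng.uniform(lo_err, hi_err)
            )
            c14 = float(rng.normal(mu[0], np.sqrt(err**2 + sg[0] ** 2)))
            lab_id = f"lab_{n:05d}"
            dates.append(
                RadiocarbonDate(
                    lab_id=lab_id,
                    site_id=site.id,
                    c14_age=c14,
                    error=float(err),
                    material="terrestrial",
                    delta_r=0.0,
                    region=site.region,
                )
            )
            true_years[lab_id] = true_year
    return dates, true_years


def _true_exposures(
    individuals: list[Individual],
    true_years: np.ndarray,
    world_climate: ClimateGridSet,
    cores: list[SSTSeries],
    enso: EventSeries,
    sites: dict[str, Site],
    region_density,
) -> pd.DataFrame:
    from .exposures import _buffer_mask, assign_sst_core

    masks = {}
    rows = []
    pop_by_region = {
        r: region_density(r, true_years) for r in {i.region for i in individuals}
    }
    for k, (ind, ty) in enumerate(zip(individuals, true_years)):
        ci = int(np.argmin(np.abs(world_climate.centuries - ty)))
        if ind.site_id not in masks:
            masks[ind.site_id] = _buffer_mask(world_climate, ind.lon, ind.lat, 20.0)
        mask = masks[ind.site_id]
        row = {"individual_id": ind.id}
        for v in TERRESTRIAL_VARIABLES:
            row[v] = float(world_climate.data[v][ci][mask].mean())
        si = int(np.argmin(np.abs(enso.centuries - ty)))
        row["enso_frequency"] = float(enso.values[si])
        if ind.region == "coast":
            core_id = assign_sst_core(ind, cores)
            core = next(c for c in cores if c.core_id == core_id)
            row["sst"] = float(core.values[int(np.argmin(np.abs(core.centuries - ty)))])
        else:
            row["sst"] = np.nan
        row["population_density"] = float(pop_by_region[ind.region][k])
        row["complexity"] = ind.complexity
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual_id")


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    z = df.copy()
    for c in z.columns:
        col = z[c].astype(float)
        sd = col.std(ddof=0)
        z[c] = (col - col.mean()) / sd if sd > 0 else 0.0
    return z.fillna(0.0)


def trauma_log_odds(z: pd.DataFrame, coeffs: TraumaCoefficients) -> np.ndarray:
    """Generative log-odds of trauma given standardized exposures."""
    eta = np.full(len(z), coeffs.intercept, dtype=float)
    for v, b in coeffs.linear.items():
        if b != 0 and v in z.columns:
            eta += b * z[v].to_numpy()
    if coeffs.population_quadratic and "population_density" in z.columns:
        eta += coeffs.population_quadratic * z["population_density"].to_numpy() ** 2
    if coeffs.interaction is not None:
        a, b_, c = coeffs.interaction
        if c and a in z.columns and b_ in z.columns:
            eta += c * z[a].to_numpy() * z[b_].to_numpy()
    return eta


def generate_world(
    config: WorldConfig, curve: CalibrationCurve | None = None
) -> SyntheticWorld:
    """Build a fully populated world from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    curve = synthetic_curve(config.time_span[0] + 2000) if curve is None else curve

    climate = _make_climate(config, rng)
    cores, enso = _make_cores(config, rng)
    sites = _make_sites(config, rng)
    dates, date_true_years = generate_dates(sites, config, curve, rng)

    oldest, youngest = config.time_span
    site_by_id = {s.id: s for s in sites}
    weights = np.array([s.occupation[0].sum() for s in sites])
    alloc = rng.multinomial(config.n_individuals, weights / weights.sum())
    individuals, true_years = [], []
    n = 0
    for site, count in zip(sites, alloc):
        for _ in range(count):
            n += 1
            ty = _sample_occupation_year(site, config, rng)
            start = min(ty + config.window_halfwidth, oldest)
            end = max(ty - config.window_halfwidth, youngest)
            # socio-political complexity: later periods more complex
            age_frac = (ty - youngest) / (oldest - youngest)
            if age_frac < 0.15 and rng.random() < 0.6:
                complexity = 2
            elif age_frac < 0.5 and rng.random() < 0.5:
                complexity = 1
            else:
                complexity = 0
            individuals.append(
                Individual(
                    id=f"ind_{n:05d}",
                    site_id=site.id,
                    lon=site.lon,
                    lat=site.lat,
                    elevation=site.elevation,
                    distance_to_coast=site.distance_to_coast,
                    window=(float(start), float(end)),
                    trauma=0,  # assigned below
                    complexity=complexity,
                    region=site.region,
                )
            )
            true_years.append(ty)
    true_years = np.array(true_years)

    world = SyntheticWorld(
        config=config,
        sites=sites,
        climate=climate,
        sst_cores=cores,
        enso=enso,
        dates=dates,
        individuals=individuals,
        true_exposures=pd.DataFrame(),
        true_trauma_probability=np.empty(0),
        date_true_years=date_true_years,
    )
    exposures = _true_exposures(
        individuals, true_years, climate, cores, enso, site_by_id, world.region_density
    )
    z = _standardize(exposures)
    prob = _logistic(trauma_log_odds(z, config.trauma_coefficients))
    outcomes = rng.random(len(individuals)) < prob
    world.individuals = [
        Individual(
            id=i.id,
            site_id=i.site_id,
            lon=i.lon,
            lat=i.lat,
            elevation=i.elevation,
            distance_to_coast=i.distance_to_coast,
            window=i.window,
            trauma=int(t),
            complexity=i.complexity,
            region=i.region,
        )
        for i, t in zip(individuals, outcomes)
    ]
    exposures["true_year"] = true_years
    world.true_exposures = exposures
    world.true_trauma_probability = prob
    return world


# ---------------------------------------------------------------------------
# on-disk schemas (the same CSVs the pipeline reads)


def individuals_to_frame(individuals: list[Individual]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "site_id": [i.site_id for i in individuals],
            "lon": [i.lon for i in individuals],
            "lat": [i.lat for i in individuals],
            "elevation": [i.elevation for i in individuals],
            "distance_to_coast": [i.distance_to_coast for i in individuals],
            "window_start": [i.window[0] for i in individuals],
            "window_end": [i.window[1] for i in individuals],
            "trauma": [i.trauma for i in individuals],
            "complexity": [i.complexity for i in individuals],
            "region": [i.region for i in individuals],
        }
    )


def individuals_from_frame(df: pd.DataFrame) -> list[Individual]:
    return [
        Individual(
            id=str(r.id),
            site_id=str(r.site_id),
            lon=float(r.lon),
            lat=float(r.lat),
            elevation=float(r.elevation),
            distance_to_coast=float(r.distance_to_coast),
            window=(float(r.window_start), float(r.window_end)),
            trauma=int(r.trauma),
            complexity=int(r.complexity),
            region=str(r.region),
        )
        for r in df.itertuples()
    ]


def dates_to_frame(dates: list[RadiocarbonDate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lab_id": [d.lab_id for d in dates],
            "site_id": [d.site_id for d in dates],
            "c14_age": [d.c14_age for d in dates],
            "error": [d.error for d in dates],
            "material": [d.material for d in dates],
            "delta_r": [d.delta_r for d in dates],
            "region": [d.region for d in dates],
        }
    )


def dates_from_frame(df: pd.DataFrame) -> list[RadiocarbonDate]:
    return [
        RadiocarbonDate(
            lab_id=str(r.lab_id),
            site_id=str(r.site_id),
            c14_age=float(r.c14_age),
            error=float(r.error),
            material=str(r.material),
            delta_r=float(r.delta_r),
            region=str(r.region),
        )
        for r in df.itertuples()
    ]


def save_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write individuals/dates/cores/enso/climate CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out / "individuals.csv"
    individuals_to_frame(world.individuals).to_csv(p, index=False)
    paths["individuals"] = p
    p = out / "dates.csv"
    dates_to_frame(world.dates).to_csv(p, index=False)
    paths["dates"] = p
    for core in world.sst_cores:
        p = out / f"sst_{core.core_id}.csv"
        pd.DataFrame(
            {"century": core.centuries, "sst": core.values}
        ).to_csv(p, index=False)
        paths[f"sst_{core.core_id}"] = p
    p = out / "enso.csv"
    pd.DataFrame(
        {"century": world.enso.centuries, "events": world.enso.values}
    ).to_csv(p, index=False)
    paths["enso"] = p
    p = out / "climate.csv"
    world.climate.to_frame().to_csv(p, index=False)
    paths["climate"] = p
    cfg = asdict(world.config)
    cfg["trauma_coefficients"]["interaction"] = (
        list(cfg["trauma_coefficients"]["interaction"])
        if cfg["trauma_coefficients"]["interaction"]
        else None
    )
    manifest = {
        "config": cfg,
        "core_locations": {
            c.core_id: {"lon": c.lon, "lat": c.lat} for c in world.sst_cores
        },
        "n_individuals": len(world.individuals),
        "n_dates": len(world.dates),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=float))
    paths["manifest"] = p
    return paths
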