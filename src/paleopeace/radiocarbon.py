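"""Radiocarbon calibration and composite KDE population proxies.

Calibrates 14C determinations against tabulated curves, applies the
standard quality filters (error cutoff, same-site binning) and builds
bootstrap ensembles of kernel density population curves, optionally
corrected for taphonomic loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "CalibrationCurve",
    "RadiocarbonDate",
    "CalibratedDensity",
    "DateBin",
    "PopulationKDE",
    "TaphonomicParams",
    "read_curve",
    "load_reference_curve",
    "calibrate",
    "filter_dates",
    "bin_dates",
    "build_ckde",
    "taphonomic_correct",
]


class CurveParseError(ValueError):
    """Raised when a .14c file cannot be parsed."""


class CalibrationRangeError(ValueError):
    """Raised when a date falls outside the usable span of a curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Tabulated mapping from calendar years (cal BP) to 14C age.

    ``cal_bp`` must be strictly monotone (ascending or descending);
    ``c14_age`` and ``sigma`` are the curve value and 1-sigma error at
    each knot.
    """

    name: str
    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        cal_bp = np.asarray(self.cal_bp, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if not (cal_bp.shape == c14.shape == sig.shape) or cal_bp.ndim != 1:
            raise ValueError("curve arrays must be equal-length 1-D")
        if cal_bp.size < 2:
            raise ValueError("curve needs at least 2 knots")
        d = np.diff(cal_bp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("cal_bp grid must be strictly monotone")
        if np.any(sig < 0):
            raise ValueError("curve sigma must be nonnegative")
        object.__setattr__(self, "cal_bp", cal_bp)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "sigma", sig)

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) cal BP covered by the curve."""
        return float(self.cal_bp.min()), float(self.cal_bp.max())

    def interpolate(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (c14_age, sigma) onto ``grid``."""
        order = np.argsort(self.cal_bp)
        x = self.cal_bp[order]
        mu = np.interp(grid, x, self.c14_age[order])
        sg = np.interp(grid, x, self.sigma[order])
        return mu, sg


@dataclass(frozen=True)
class RadiocarbonDate:
    """One uncalibrated 14C determination."""

    lab_id: str
    site_id: str
    c14_age: float
    error: float
    material: str = "terrestrial"  # or "marine"
    delta_r: float = 0.0
    region: str = "inland"  # or "coast"

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ValueError(f"{self.lab_id}: error must be > 0")
        if not np.isfinite(self.delta_r):
            raise ValueError(f"{self.lab_id}: delta_r must be finite")
        if self.material not in ("terrestrial", "marine"):
            raise ValueError(f"{self.lab_id}: unknown material {self.material!r}")


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized posterior over calendar years for one date."""

    cal_bp: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0):
            raise ValueError("calibrated density must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("calibrated density must sum to 1")
        object.__setattr__(self, "cal_bp", np.asarray(self.cal_bp, dtype=float))
        object.__setattr__(self, "p", p)

    @property
    def mode(self) -> float:
        return float(self.cal_bp[int(np.argmax(self.p))])

    def hpd_interval(self, mass: float = 0.954) -> tuple[float, float]:
        """Smallest set of grid years holding ``mass`` probability; returns its span."""
        order = np.argsort(self.p)[::-1]
        csum = np.cumsum(self.p[order])
        k = int(np.searchsorted(csum, mass)) + 1
        years = self.cal_bp[order[:k]]
        return float(years.min()), float(years.max())

    def sample_year(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(self.cal_bp, size=size, p=self.p)


@dataclass
class DateBin:
    """Same-site cluster of dates treated as one sampling unit."""

    site_id: str
    lab_ids: list[str]
    densities: list[CalibratedDensity] = field(default_factory=list)


@dataclass
class PopulationKDE:
    """One bootstrap replicate of a regional relative-density curve."""

    replicate_id: int
    cal_bp: np.ndarray
    density: np.ndarray
    taphonomically_corrected: bool = False

    def value_at(self, year: float) -> float:
        """Density at the grid year nearest ``year``."""
        i = int(np.argmin(np.abs(self.cal_bp - year)))
        return float(self.density[i])


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Parse a calibration curve in the standard ``.14c`` layout.

    Comment lines start with '#'; data rows are comma- or
    whitespace-separated with CAL BP, 14C age and error in the first
    three columns (extra columns ignored).
    """
    cal_bp, c14, sigma = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 3:
                raise CurveParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                vals = [float(v) for v in parts[:3]]
            except ValueError as exc:
                raise CurveParseError(f"{path}: line {lineno}: non-numeric value") from exc
            cal_bp.append(vals[0])
            c14.append(vals[1])
            sigma.append(vals[2])
    if not cal_bp:
        raise CurveParseError(f"{path}: no data rows")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return CalibrationCurve(name, np.array(cal_bp), np.array(c14), np.array(sigma))


def load_reference_curve() -> CalibrationCurve:
    """Bundled Southern Hemisphere-style reference curve (0-12500 cal BP)."""
    from importlib.resources import files

    path = files("paleopeace.data").joinpath("refcurve_sh.14c")
    return read_curve(str(path), name="refcurve_sh")


def calibrate(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
) -> CalibratedDensity:
    """Calibrate one date against ``curve``.

    p(t) is proportional to the Normal density of the reservoir-corrected
    14C age at curve mean c14(t) with variance error^2 + sigma(t)^2,
    evaluated on a regular ``grid_step``-year grid spanning the curve and
    normalized to sum to 1.
    """
    age = date.c14_age - date.delta_r
    lo = float(curve.c14_age.min()) - 4 * (date.error + float(curve.sigma.max()))
    hi = float(curve.c14_age.max()) + 4 * (date.error + float(curve.sigma.max()))
    if not (lo <= age <= hi):
        raise CalibrationRangeError(
            f"{date.lab_id}: corrected age {age:.0f} outside curve {curve.name} range"
        )
    young, old = curve.span
    grid = np.arange(young, old + 0.5 * grid_step, grid_step)
    mu, sg = curve.interpolate(grid)
    var = date.error**2 + sg**2
    logp = -0.5 * (age - mu) ** 2 / var - 0.5 * np.log(var)
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise CalibrationRangeError(f"{date.lab_id}: degenerate calibrated density")
    return CalibratedDensity(grid, p / total)


def filter_dates(
    dates: list[RadiocarbonDate], max_error: float = 100.0
) -> tuple[list[RadiocarbonDate], int]:
    """Retain dates with error <= max_error; return (kept, n_dropped)."""
    kept = [d for d in dates if d.error <= max_error]
    return kept, len(dates) - len(kept)


def bin_dates(dates: list[RadiocarbonDate], cutoff: float = 200.0) -> list[DateBin]:
    """Cluster one site's dates with complete linkage on uncalibrated ages.

    The dendrogram is cut at ``cutoff`` years; ties in input order are
    broken by lab_id sort so the result is permutation-invariant.
    """
    if not dates:
        return []
    sites = {d.site_id for d in dates}
    if len(sites) != 1:
        raise ValueError(f"bin_dates expects a single site, got {sorted(sites)}")
    ordered = sorted(dates, key=lambda d: (d.c14_age, d.lab_id))
    if len(ordered) == 1:
        return [DateBin(ordered[0].site_id, [ordered[0].lab_id])]
    ages = np.array([[d.c14_age] for d in ordered], dtype=float)
    z = linkage(ages, method="complete", metric="euclidean")
    labels = fcluster(z, t=cutoff, criterion="distance")
    bins: dict[int, DateBin] = {}
    for lab, d in zip(labels, ordered):
        bins.setdefault(int(lab), DateBin(d.site_id, [])).lab_ids.append(d.lab_id)
    # order bins by their youngest member age for determinism
    out = sorted(bins.values(), key=lambda b: b.lab_ids[0])
    return out


def attach_densities(
    bins: list[DateBin],
    densities: dict[str, CalibratedDensity],
) -> list[DateBin]:
    """Attach per-lab-id calibrated densities to bins (missing ids error)."""
    out = []
    for b in bins:
        try:
            ds = [densities[lab] for lab in b.lab_ids]
        except KeyError as exc:
            raise KeyError(f"no calibrated density for lab_id {exc.args[0]}") from exc
        out.append(DateBin(b.site_id, list(b.lab_ids), ds))
    return out


def build_ckde(
    bins: list[DateBin],
    grid: np.ndarray,
    n_replicates: int = 1000,
    bandwidth: float = 50.0,
    rng: np.random.Generator | None = None,
) -> list[PopulationKDE]:
    """Composite KDE bootstrap: ``n_replicates`` kernel density curves.

    Each replicate samples one date per bin, one calendar year from that
    date's calibrated density, and fits a fixed-bandwidth Gaussian KDE on
    ``grid``, normalized to integrate to 1 (trapezoid rule).
    """
    if not bins:
        raise ValueError("build_ckde requires at least one bin")
    for b in bins:
        if not b.densities:
            raise ValueError(f"bin at site {b.site_id} has no calibrated densities")
    rng = np.random.default_rng() if rng is None else rng
    grid = np.asarray(grid, dtype=float)
    reps = []
    for r in range(1, n_replicates + 1):
        years = np.empty(len(bins))
        for i, b in enumerate(bins):
            j = int(rng.integers(len(b.densities)))
            years[i] = b.densities[j].sample_year(rng)
        dens = np.exp(-0.5 * ((grid[:, None] - years[None, :]) / bandwidth) ** 2).sum(axis=1)
        area = np.trapezoid(dens, grid)
        if area <= 0:
            dens = np.full_like(grid, 1.0)
            area = np.trapezoid(dens, grid)
        reps.append(PopulationKDE(r, grid, dens / area))
    return reps


@dataclass(frozen=True)
class TaphonomicParams:
    """Survival-curve parameters n(t) = a * (t + b) ** c."""

    a: float = 5.726442e6
    b: float = 2176.4
    c: float = -1.3925309


def taphonomic_correct(
    kde: PopulationKDE, params: TaphonomicParams = TaphonomicParams()
) -> PopulationKDE:
    """Divide a replicate by the survival curve and renormalize."""
    t = kde.cal_bp
    if np.any(t + params.b <= 0):
        raise ValueError("t + b must be positive over the whole grid")
    survival = params.a * (t + params.b) ** params.c
    dens = kde.density / survival
    area = np.trapezoid(dens, t)
    return replace(kde, density=dens / area, taphonomically_corrected=True)
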