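import numpy as np
import pytest

from paleopeace.radiocarbon import CalibrationCurve, load_reference_curve
from paleopeace.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def reference_curve() -> CalibrationCurve:
    return load_reference_curve()


@pytest.fixture(scope="session")
def flat_curve() -> CalibrationCurve:
    """c14_age(t) = 1000 for all t, zero curve error."""
    cal = np.arange(0.0, 2001.0, 1.0)
    return CalibrationCurve("flat", cal, np.full_like(cal, 1000.0), np.zeros_like(cal))


@pytest.fixture(scope="session")
def small_world():
    cfg = WorldConfig(seed=42, n_sites=14, n_individuals=250, n_dates=150)
    return generate_world(cfg)


def brute_force_calibration(age, error, curve, step=0.2):
    """Independent fine-grid numerical oracle for calibrate().

    Evaluates the unnormalized Normal density on a fine calendar grid by
    direct linear interpolation of the curve, then normalizes by the
    trapezoid integral. Returns (grid, pdf) where pdf integrates to 1.
    """
    young, old = curve.span
    grid = np.arange(young, old + step / 2, step)
    order = np.argsort(curve.cal_bp)
    mu = np.interp(grid, curve.cal_bp[order], curve.c14_age[order])
    sg = np.interp(grid, curve.cal_bp[order], curve.sigma[order])
    var = error**2 + sg**2
    dens = np.exp(-0.5 * (age - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def hpd_mass_pair(dens, grid, pdf, mass=0.954):
    """Masses of implementation vs oracle over the same cell-aligned interval.

    The oracle HPD endpoints are snapped to the implementation's grid-cell
    boundaries so the two masses integrate the same real interval and the
    comparison tests pdf agreement rather than binning artifacts.
    """
    o_lo, o_hi = oracle_hpd(grid, pdf, mass)
    lo = np.round(o_lo)
    hi = np.round(o_hi)
    impl = dens.p[(dens.cal_bp >= lo) & (dens.cal_bp <= hi)].sum()
    step = grid[1] - grid[0]
    sel = (grid >= lo - 0.5) & (grid <= hi + 0.5)
    oracle = pdf[sel].sum() * step
    return float(impl), float(oracle)


def oracle_hpd(grid, pdf, mass=0.954):
    """HPD set of a fine-grid pdf by greedy accumulation; returns span."""
    step = grid[1] - grid[0]
    order = np.argsort(pdf)[::-1]
    csum = np.cumsum(pdf[order] * step)
    k = int(np.searchsorted(csum, mass)) + 1
    years = grid[order[:k]]
    return float(years.min()), float(years.max())
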