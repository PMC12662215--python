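"""Aggregation of ensemble runs into summary surfaces.

Collapses the per-run metrics, importances and partial-dependence
curves of a regional ensemble into means with 2-SD bands and 95%
confidence intervals, probability-of-peaceful-interaction (PPI) ranges
and predictor correlation matrices, with plot-ready CSV/JSON writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import ModelRun

METRIC_NAMES = ("auc", "mse", "log_loss", "log_loss_probability")


@dataclass
class EnsembleSummary:
    region: str
    n_runs: int
    importance_mean: dict[str, float]
    importance_sd: dict[str, float]
    importance_ci: dict[str, tuple[float, float]]  # 95% CI of the mean
    importance_band: dict[str, tuple[float, float]]  # mean +/- 2 SD
    metric_mean: dict[str, float]
    metric_ci: dict[str, tuple[float, float]]
    pd_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # variable -> (grid, mean PPI)
    pd_surfaces: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    ppi_ranges: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation: pd.DataFrame | None = None


def _mean_sd_ci(values: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    m = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(values.size)
    return m, sd, (m - half, m + half)


def aggregate(runs: list[ModelRun]) -> EnsembleSummary:
    """Means, SDs and normal-approximation CIs across runs.

    PD curves are averaged pointwise; the runs must share grids (an
    aggregation error is raised otherwise).
    """
    if len(runs) < 2:
        raise ValueError("aggregate requires >= 2 runs")
    variables = list(runs[0].importance)
    for r in runs[1:]:
        if list(r.importance) != variables:
            raise ValueError("runs have inconsistent variable sets")

    imp_mean, imp_sd, imp_ci, imp_band = {}, {}, {}, {}
    for v in variables:
        vals = np.array([r.importance[v] for r in runs])
        m, sd, ci = _mean_sd_ci(vals)
        imp_mean[v], imp_sd[v], imp_ci[v] = m, sd, ci
        imp_band[v] = (m - 2 * sd, m + 2 * sd)

    met_mean, met_ci = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics[name] for r in runs if name in r.metrics])
        if vals.size:
            m, _, ci = _mean_sd_ci(vals)
            met_mean[name], met_ci[name] = m, ci

    pd_curves = {}
    for v in variables:
        grids = [r.pd_curves[v][0] for r in runs]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
                raise ValueError(f"inconsistent PD grids for variable {v!r}")
        mean_curve = np.mean([r.pd_curves[v][1] for r in runs], axis=0)
        pd_curves[v] = (grids[0], mean_curve)

    pd_surfaces = {}
    pairs = {p for r in runs for p in r.pd_surfaces}
    for pair in sorted(pairs):
        having = [r for r in runs if pair in r.pd_surfaces]
        ga, gb = having[0].pd_surfaces[pair][0], having[0].pd_surfaces[pair][1]
        surf = np.mean([r.pd_surfaces[pair][2] for r in having], axis=0)
        pd_surfaces[pair] = (ga, gb, surf)

    ranges = {v: ppi_range(curve) for v, curve in pd_curves.items()}
    return EnsembleSummary(
        region=runs[0].region,
        n_runs=len(runs),
        importance_mean=imp_mean,
        importance_sd=imp_sd,
        importance_ci=imp_ci,
        importance_band=imp_band,
        metric_mean=met_mean,
        metric_ci=met_ci,
        pd_curves=pd_curves,
        pd_surfaces=pd_surfaces,
        ppi_ranges=ranges,
    )


def ppi_range(mean_pd_curve: tuple[np.ndarray, np.ndarray]) -> dict[str, float]:
    """PPI at the predictor-grid extremes, plus curve min/max.

    ``low_end``/``high_end`` are the curve values at the lowest and
    highest grid points; ``curve_min``/``curve_max`` cover non-monotone
    curves whose extrema sit in the interior.
    """
    grid, curve = mean_pd_curve
    if len(curve) == 0:
        raise ValueError("empty PD curve")
    order = np.argsort(grid)
    curve = np.asarray(curve)[order]
    return {
        "low_end": float(curve[0]),
        "high_end": float(curve[-1]),
        "curve_min": float(curve.min()),
        "curve_max": float(curve.max()),
    }


def correlation_matrix(draw_means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-individual mean exposures.

    Constant columns get NaN rows/columns (flagged, not dropped); the
    diagonal is forced to 1 for non-constant columns.
    """
    if len(draw_means) < 3:
        raise ValueError("correlation matrix requires >= 3 individuals")
    corr = draw_means.corr(method="pearson")
    for c in draw_means.columns:
        if draw_means[c].nunique() <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    return corr


# ---------------------------------------------------------------------------
# writers


def summary_to_dict(s: EnsembleSummary) -> dict:
    return {
        "region": s.region,
        "n_runs": s.n_runs,
        "importance": {
            v: {
                "mean": s.importance_mean[v],
                "sd": s.importance_sd[v],
                "ci95": list(s.importance_ci[v]),
                "band_2sd": list(s.importance_band[v]),
            }
            for v in s.importance_mean
        },
        "metrics": {
            m: {"mean": s.metric_mean[m], "ci95": list(s.metric_ci[m])}
            for m in s.metric_mean
        },
        "ppi_ranges": s.ppi_ranges,
        "correlation": None
        if s.correlation is None
        else json.loads(s.correlation.to_json(orient="split")),
    }


def write_summary(s: EnsembleSummary, out_dir: str | Path) -> dict[str, Path]:
    """Write summary JSON plus plot-ready CSVs; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out / f"summary_{s.region}.json"
    p.write_text(json.dumps(summary_to_dict(s), indent=2, sort_keys=True))
    paths["summary"] = p

    imp = pd.DataFrame(
        {
            "variable": list(s.importance_mean),
            "mean": list(s.importance_mean.values()),
            "sd": list(s.importance_sd.values()),
            "ci_lo": [s.importance_ci[v][0] for v in s.importance_mean],
            "ci_hi": [s.importance_ci[v][1] for v in s.importance_mean],
            "band_lo": [s.importance_band[v][0] for v in s.importance_mean],
            "band_hi": [s.importance_band[v][1] for v in s.importance_mean],
        }
    )
    p = out / f"importance_{s.region}.csv"
    imp.to_csv(p, index=False)
    paths["importance"] = p

    rows = []
    for v, (grid, curve) in s.pd_curves.items():
        for g, c in zip(grid, curve):
            rows.append({"variable": v, "grid_value": g, "p_no_trauma": c})
    p = out / f"pd_curves_{s.region}.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths["pd_curves"] = p

    if s.pd_surfaces:
        rows = []
        for (va, vb), (ga, gb, surf) in s.pd_surfaces.items():
            for i, a in enumerate(ga):
                for j, b in enumerate(gb):
                    rows.append(
                        {
                            "variable_a": va,
                            "variable_b": vb,
                            "value_a": a,
                            "value_b": b,
                            "p_no_trauma": surf[i, j],
                        }
                    )
        p = out / f"pd_surfaces_{s.region}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["pd_surfaces"] = p

    ppi = pd.DataFrame(
        [{"variable": v, **vals} for v, vals in s.ppi_ranges.items()]
    )
    p = out / f"ppi_ranges_{s.region}.csv"
    ppi.to_csv(p, index=False)
    paths["ppi_ranges"] = p

    if s.correlation is not None:
        p = out / f"correlation_{s.region}.csv"
        s.correlation.to_csv(p)
        paths["correlation"] = p
    return paths
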