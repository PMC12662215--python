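"""Iterated probability-forest ensemble over Monte-Carlo exposure draws.

Each run takes one draw index per individual, caps per-site sample
sizes, splits with class stratification, fits a bagged probability
forest for P(no trauma), and records metrics, permutation importance
and partial dependence. A second fit on all rows supplies log-loss
accuracy measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

# Means are preferred over SDs when a correlated pair must be pruned.
DEFAULT_PREFERENCE = (
    "mean_temperature",
    "mean_precipitation",
    "sst",
    "enso_frequency",
    "population_density",
    "complexity",
    "sd_temperature",
    "sd_precipitation",
)

NON_PREDICTORS = ("individual_id", "site_id", "trauma", "draw_index", "region")


class StratificationError(ValueError):
    """Raised when a split cannot preserve both outcome classes."""


@dataclass
class ModelConfig:
    """Knobs for one regional ensemble."""

    n_models: int = 1000
    site_cap: int = 30
    test_fraction: float = 0.25
    n_trees: int = 500
    variables_per_split: int | None = None  # None -> floor(sqrt(p))
    min_node_size: int = 10
    collinearity_threshold: float = 0.7
    pd_grid_size: int = 25
    pd_surface_every: int = 10  # 2D PD only on every k-th run
    pd_surface_pairs: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.site_cap < 1:
            raise ValueError("site_cap must be >= 1")
        if not (0 < self.collinearity_threshold <= 1):
            raise ValueError("collinearity_threshold must be in (0, 1]")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass
class ModelRun:
    """Artifacts of a single draw-indexed model."""

    run_id: int
    region: str
    draw_index: int
    metrics: dict[str, float]
    importance: dict[str, float]
    pd_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    pd_surfaces: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def screen_collinearity(
    draw_table: pd.DataFrame,
    threshold: float = 0.7,
    preference_order: tuple[str, ...] = DEFAULT_PREFERENCE,
) -> tuple[list[str], pd.DataFrame]:
    """Prune pairwise-correlated predictors.

    Pearson correlations are computed on per-individual draw means; for
    each pair with |r| >= threshold the variable lower in
    ``preference_order`` is dropped. Returns (retained, correlation
    matrix) — the matrix covers all input variables for reporting.
    """
    variables = [c for c in draw_table.columns if c not in NON_PREDICTORS]
    if len(variables) < 2 or len(draw_table) < 3:
        raise ValueError("need >=2 variables and >=3 rows")
    for v in variables:
        if draw_table[v].nunique() <= 1:
            raise ValueError(f"variable {v!r} is constant; correlation undefined")
    corr = draw_table[variables].corr(method="pearson")

    def rank(v: str) -> int:
        try:
            return preference_order.index(v)
        except ValueError:
            return len(preference_order)

    dropped: set[str] = set()
    pairs = [
        (a, b)
        for i, a in enumerate(variables)
        for b in variables[i + 1 :]
        if abs(corr.loc[a, b]) >= threshold
    ]
    for a, b in sorted(pairs, key=lambda p: -abs(corr.loc[p[0], p[1]])):
        if a in dropped or b in dropped:
            continue
        dropped.add(b if rank(a) <= rank(b) else a)
    retained = [v for v in variables if v not in dropped]
    return retained, corr


def subsample_sites(
    rows: pd.DataFrame, cap: int = 30, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """At most ``cap`` rows per site, uniform without replacement; every site kept."""
    rng = np.random.default_rng() if rng is None else rng
    keep = []
    for _, grp in rows.groupby("site_id", sort=True):
        if len(grp) <= cap:
            keep.append(grp.index.to_numpy())
        else:
            keep.append(rng.choice(grp.index.to_numpy(), size=cap, replace=False))
    return rows.loc[np.concatenate(keep)].sort_index()


def stratified_split(
    rows: pd.DataFrame,
    test_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive split preserving the trauma/no-trauma ratio."""
    rng = np.random.default_rng() if rng is None else rng
    classes = rows["trauma"].unique()
    if len(classes) < 2:
        raise StratificationError("both trauma classes required for a stratified split")
    test_idx = []
    for _, grp in rows.groupby("trauma", sort=True):
        n_test = int(round(len(grp) * test_fraction))
        n_test = min(max(n_test, 0), len(grp))
        test_idx.append(rng.choice(grp.index.to_numpy(), size=n_test, replace=False))
    test_idx = np.concatenate(test_idx)
    mask = rows.index.isin(test_idx)
    return rows.loc[~mask], rows.loc[mask]


class ProbabilityForest:
    """Bagged decision-tree ensemble returning P(no trauma)."""

    def __init__(self, variables: list[str], config: ModelConfig, rng: np.random.Generator):
        self.variables = list(variables)
        mtry = config.variables_per_split
        if mtry is None:
            mtry = max(1, int(np.sqrt(len(self.variables))))
        self._rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=min(mtry, len(self.variables)),
            min_samples_leaf=config.min_node_size,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        self._no_trauma_col: int | None = None

    def fit(self, rows: pd.DataFrame) -> "ProbabilityForest":
        if len(rows) == 0:
            raise ValueError("empty training set")
        y = rows["trauma"].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self._rf.fit(rows[self.variables].to_numpy(), y)
        self._no_trauma_col = int(np.flatnonzero(self._rf.classes_ == 0)[0])
        return self

    def predict_p_no_trauma(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.variables].to_numpy()
        return self._rf.predict_proba(x)[:, self._no_trauma_col]


def fit_probability_forest(
    train_rows: pd.DataFrame,
    variables: list[str],
    config: ModelConfig,
    rng: np.random.Generator,
) -> ProbabilityForest:
    if not variables:
        raise ValueError("at least one retained variable required")
    return ProbabilityForest(variables, config, rng).fit(train_rows)


def evaluate(model: ProbabilityForest, test_rows: pd.DataFrame) -> dict[str, float]:
    """AUC / MSE / log-loss / log-loss-as-probability on held-out rows.

    All metrics score P(no trauma) against the no-trauma indicator; AUC
    raises on a one-class test set (other metrics still computed by the
    ensemble driver via the all-rows refit).
    """
    if len(test_rows) == 0:
        raise ValueError("empty test set")
    p_no = model.predict_p_no_trauma(test_rows)
    y_no = 1 - test_rows["trauma"].to_numpy()
    out = _probability_metrics(p_no, y_no)
    if len(np.unique(y_no)) < 2:
        raise StratificationError("AUC undefined on a one-class test set")
    out["auc"] = float(roc_auc_score(y_no, p_no))
    return out


def _probability_metrics(p_no: np.ndarray, y_no: np.ndarray) -> dict[str, float]:
    p = np.clip(p_no, 1e-15, 1 - 1e-15)
    ll = float(-np.mean(y_no * np.log(p) + (1 - y_no) * np.log(1 - p)))
    return {
        "mse": float(np.mean((p_no - y_no) ** 2)),
        "log_loss": ll,
        "log_loss_probability": float(np.exp(-ll)),
    }


def permutation_importance(
    model: ProbabilityForest,
    rows: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_permutations: int = 5,
) -> dict[str, float]:
    """Mean increase in squared error when one predictor is permuted."""
    rng = np.random.default_rng() if rng is None else rng
    x = rows[model.variables].to_numpy()
    y_no = 1 - rows["trauma"].to_numpy()
    n = len(x)
    base = float(np.mean((model.predict_p_no_trauma(x) - y_no) ** 2))
    out = {}
    for j, v in enumerate(model.variables):
        # one batched prediction over all permutations of column j
        stacked = np.tile(x, (n_permutations, 1))
        for k in range(n_permutations):
            stacked[k * n : (k + 1) * n, j] = rng.permutation(x[:, j])
        p = model.predict_p_no_trauma(stacked).reshape(n_permutations, n)
        errs = np.mean((p - y_no[None, :]) ** 2, axis=1)
        out[v] = float(np.mean(errs - base))
    return out


def pd_grid(values: np.ndarray, grid_size: int) -> np.ndarray:
    """Equally spaced grid between the 1st and 99th percentiles."""
    lo, hi = np.percentile(values, [1, 99])
    if hi <= lo:
        return np.full(1, lo)
    return np.linspace(lo, hi, grid_size)


def partial_dependence(
    model: ProbabilityForest,
    rows: pd.DataFrame,
    variables: list[str],
    grid_size: int = 25,
    grids: dict[str, np.ndarray] | None = None,
):
    """Mean P(no trauma) with one or two predictors forced across a grid.

    Returns (grid, curve) for one variable, or (grid_a, grid_b, surface)
    for a pair; surface[i, j] corresponds to (grid_a[i], grid_b[j]).
    Grids default to 1st-99th percentile linspaces of ``rows`` but can
    be supplied to keep an ensemble's runs on a common grid.
    """
    unknown = [v for v in variables if v not in model.variables]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    if len(variables) not in (1, 2):
        raise ValueError("partial dependence supports 1 or 2 variables")
    x = rows[model.variables].to_numpy()
    n = len(x)
    cols = [model.variables.index(v) for v in variables]
    if grids is not None:
        gvals = [np.asarray(grids[v], dtype=float) for v in variables]
    else:
        gvals = [pd_grid(rows[v].to_numpy(), grid_size) for v in variables]
    if len(variables) == 1:
        g = gvals[0]
        stacked = np.tile(x, (g.size, 1))
        stacked[:, cols[0]] = np.repeat(g, n)
        curve = model.predict_p_no_trauma(stacked).reshape(g.size, n).mean(axis=1)
        return g, curve
    ga, gb = gvals
    stacked = np.tile(x, (ga.size * gb.size, 1))
    aa, bb = np.meshgrid(ga, gb, indexing="ij")
    stacked[:, cols[0]] = np.repeat(aa.ravel(), n)
    stacked[:, cols[1]] = np.repeat(bb.ravel(), n)
    surface = (
        model.predict_p_no_trauma(stacked).reshape(ga.size * gb.size, n).mean(axis=1)
    ).reshape(ga.size, gb.size)
    return ga, gb, surface


def runs_to_frames(runs: list[ModelRun]) -> dict[str, pd.DataFrame]:
    """Flatten runs to plain tables (metrics / importance / PD curves / surfaces)."""
    metrics = pd.DataFrame(
        [
            {"run_id": r.run_id, "region": r.region, "draw_index": r.draw_index, **r.metrics}
            for r in runs
        ]
    )
    importance = pd.DataFrame(
        [
            {"run_id": r.run_id, "region": r.region, "variable": v, "delta_error": d}
            for r in runs
            for v, d in r.importance.items()
        ]
    )
    curves = pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "region": r.region,
                "variable": v,
                "grid_value": g,
                "p_no_trauma": c,
            }
            for r in runs
            for v, (grid, curve) in r.pd_curves.items()
            for g, c in zip(grid, curve)
        ]
    )
    surf_rows = []
    for r in runs:
        for (va, vb), (ga, gb, surf) in r.pd_surfaces.items():
            for i, a in enumerate(ga):
                for j, b in enumerate(gb):
                    surf_rows.append(
                        {
                            "run_id": r.run_id,
                            "region": r.region,
                            "variable_a": va,
                            "variable_b": vb,
                            "value_a": a,
                            "value_b": b,
                            "p_no_trauma": surf[i, j],
                        }
                    )
    surfaces = pd.DataFrame(
        surf_rows,
        columns=[
            "run_id",
            "region",
            "variable_a",
            "variable_b",
            "value_a",
            "value_b",
            "p_no_trauma",
        ],
    )
    return {
        "metrics": metrics,
        "importance": importance,
        "pd_curves": curves,
        "pd_surfaces": surfaces,
    }


def runs_from_frames(frames: dict[str, pd.DataFrame]) -> list[ModelRun]:
    """Inverse of :func:`runs_to_frames`."""
    metrics = frames["metrics"]
    importance = frames["importance"]
    curves = frames["pd_curves"]
    surfaces = frames.get("pd_surfaces")
    runs = []
    for row in metrics.itertuples():
        rid = int(row.run_id)
        imp = importance[importance["run_id"] == rid]
        cur = curves[curves["run_id"] == rid]
        pd_curves = {}
        for v, grp in cur.groupby("variable", sort=False):
            pd_curves[v] = (
                grp["grid_value"].to_numpy(),
                grp["p_no_trauma"].to_numpy(),
            )
        pd_surf = {}
        if surfaces is not None and len(surfaces):
            s = surfaces[surfaces["run_id"] == rid]
            for (va, vb), grp in s.groupby(["variable_a", "variable_b"], sort=False):
                ga = np.unique(grp["value_a"].to_numpy())
                gb = np.unique(grp["value_b"].to_numpy())
                piv = grp.pivot(index="value_a", columns="value_b", values="p_no_trauma")
                pd_surf[(va, vb)] = (ga, gb, piv.loc[ga, gb].to_numpy())
        runs.append(
            ModelRun(
                run_id=rid,
                region=str(row.region),
                draw_index=int(row.draw_index),
                metrics={
                    m: float(getattr(row, m))
                    for m in ("auc", "mse", "log_loss", "log_loss_probability")
                    if hasattr(row, m)
                },
                importance=dict(zip(imp["variable"], imp["delta_error"].astype(float))),
                pd_curves=pd_curves,
                pd_surfaces=pd_surf,
            )
        )
    return runs


def run_ensemble(
    exposure_table: pd.DataFrame,
    individuals: pd.DataFrame,
    config: ModelConfig,
    region: str,
    retained: list[str] | None = None,
) -> list[ModelRun]:
    """One region's iterated ensemble: run i uses draw index i throughout.

    ``exposure_table`` is the long table (individual_id, draw_index,
    predictors); ``individuals`` carries id, site_id, trauma, region and
    complexity. Each run: subsample sites -> stratified split -> fit ->
    evaluate -> permutation importance -> 1D partial dependence; a
    refit on all subsampled rows supplies log-loss metrics, and 2D
    surfaces are computed on every ``pd_surface_every``-th run.
    """
    n_draws = int(exposure_table["draw_index"].max()) + 1
    if config.n_models > n_draws:
        raise ValueError(
            f"n_models={config.n_models} exceeds n_draws={n_draws}"
        )
    meta = individuals.set_index("id")[["site_id", "trauma"]]
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_models)
    runs = []
    by_draw = dict(tuple(exposure_table.groupby("draw_index", sort=True)))
    variables = retained
    if variables is None:
        variables = [c for c in exposure_table.columns if c not in NON_PREDICTORS]
    # common PD grids across runs: percentiles over all draws and individuals
    fixed_grids = {
        v: pd_grid(exposure_table[v].to_numpy(), config.pd_grid_size) for v in variables
    }
    for i in range(config.n_models):
        rng = np.random.default_rng(child_seeds[i])
        table = by_draw[i].set_index("individual_id")
        table = table.join(meta, how="inner").reset_index(names="individual_id")
        rows = subsample_sites(table, cap=config.site_cap, rng=rng)
        train, test = stratified_split(rows, config.test_fraction, rng=rng)
        model = fit_probability_forest(train, variables, config, rng)
        metrics = evaluate(model, test)
        importance = permutation_importance(model, test, rng=rng)
        curves = {
            v: partial_dependence(model, rows, [v], grids=fixed_grids)
            for v in variables
        }
        # second fit on all rows for the accuracy (log-loss) measures
        full = fit_probability_forest(rows, variables, config, rng)
        p_full = full.predict_p_no_trauma(rows)
        full_metrics = _probability_metrics(p_full, 1 - rows["trauma"].to_numpy())
        metrics["log_loss"] = full_metrics["log_loss"]
        metrics["log_loss_probability"] = full_metrics["log_loss_probability"]
        surfaces = {}
        if config.pd_surface_pairs and i % config.pd_surface_every == 0:
            for pair in config.pd_surface_pairs:
                if all(v in variables for v in pair):
                    surfaces[pair] = partial_dependence(
                        model, rows, list(pair), grids=fixed_grids
                    )
        runs.append(
            ModelRun(
                run_id=i,
                region=region,
                draw_index=i,
                metrics=metrics,
                importance=importance,
                pd_curves=curves,
                pd_surfaces=surfaces,
            )
        )
    return runs
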