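"""Habitat-preference models: presence/pseudo-absence boosted regression trees.

Presences are the HMM "search" locations; for each presence three
pseudo-absences are drawn uniformly from sea cells inside a circular
colony buffer (radius 110% of the focal species' maximum colony distance)
intersected with the combined longitudinal/latitudinal range of both
species' tracks.  The binary response is modelled by stagewise gradient
boosting of small regression trees on the binomial deviance: trees are
added in blocks while fold-wise cross-validated predictive deviance is
tracked, the ensemble size minimizing mean CV deviance is selected, and
the final model is refit on all data at that size.  Relative variable
importance (summed squared-improvement over all splits, normalized to sum
to 100%) and partial-dependence curves summarize the fitted ensemble.

The base learner is a standard regression tree; the staged CV-stopping
loop, leaf Newton updates and importance accounting live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from petrelwind.geo import haversine_km
from petrelwind.synthetic import GenerationError, WorldConfig

_PMIN = 1e-6


# ---------------------------------------------------------------------------
# Pseudo-absences and synthetic covariates


def draw_pseudo_absences(
    presences: pd.DataFrame,
    colony: tuple[float, float],
    config: WorldConfig,
    ratio: int = 3,
    buffer_scale: float = 1.10,
    bounds: tuple[float, float, float, float] | None = None,
    seed: int = 0,
    max_draws: int = 500_000,
) -> pd.DataFrame:
    """Uniform at-sea background points in the colony buffer.

    The buffer is the great-circle disc around the colony with radius
    ``buffer_scale`` × the maximum presence distance from the colony,
    intersected with ``bounds`` (lon_min, lon_max, lat_min, lat_max, e.g.
    the combined range box of both species' tracks) and with the sea
    cells of the world's land mask.  Exactly ``ratio × n_presences``
    points are returned.
    """
    if len(presences) < 1:
        raise ValueError("need at least one presence")
    rng = np.random.default_rng(seed)
    r_km = buffer_scale * float(
        haversine_km(presences["lon"].values, presences["lat"].values, colony[0], colony[1]).max()
    )
    if bounds is None:
        bounds = (config.lon_min, config.lon_max, config.lat_min, config.lat_max)
    lon0, lon1, lat0, lat1 = bounds
    n_target = ratio * len(presences)
    out_lon, out_lat = [], []
    drawn = 0
    while sum(len(x) for x in out_lon) < n_target:
        n = max(4 * n_target, 1000)
        drawn += n
        if drawn > max_draws:
            raise GenerationError("pseudo-absence buffer appears to contain no sea cells")
        lo = rng.uniform(lon0, lon1, size=n)
        la = rng.uniform(lat0, lat1, size=n)
        ok = (haversine_km(lo, la, colony[0], colony[1]) <= r_km) & ~config.is_land(lo, la)
        out_lon.append(lo[ok])
        out_lat.append(la[ok])
    lon = np.concatenate(out_lon)[:n_target]
    lat = np.concatenate(out_lat)[:n_target]
    return pd.DataFrame({"lon": lon, "lat": lat, "presence": 0})


def habitat_covariates(
    points: pd.DataFrame, config: WorldConfig, windfield=None
) -> pd.DataFrame:
    """Synthetic environmental covariates at point locations.

    SST and wind speed are time-means of the world's fields at the
    location; depth is a smooth abyssal plain rising toward seamounts,
    slope its horizontal gradient magnitude; distances are great-circle
    km to the colony and the nearest seamount.
    """
    out = points.copy()
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    out["dist_colony_km"] = haversine_km(lon, lat, config.colony[0], config.colony[1])
    d_sm = np.min(
        np.stack([haversine_km(lon, lat, sx, sy) for sx, sy in config.seamounts]), axis=0
    )
    out["dist_seamount_km"] = d_sm
    sst = config.sst_field().mean("time")
    out["sst"] = sst.interp(lon=("p", lon), lat=("p", lat)).values
    if windfield is not None:
        speed = np.hypot(windfield["u10"], windfield["v10"]).mean("time")
        out["wind_speed"] = speed.interp(lon=("p", lon), lat=("p", lat)).values
    # bathymetry: -4500 m plain with Gaussian seamounts (sigma 120 km)
    depth = -4500.0 + 4200.0 * np.exp(-0.5 * (d_sm / 120.0) ** 2)
    out["depth_m"] = depth
    out["slope"] = np.abs(4200.0 * (d_sm / 120.0**2) * np.exp(-0.5 * (d_sm / 120.0) ** 2))
    return out


# ---------------------------------------------------------------------------
# Boosting core


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PMIN, 1 - _PMIN)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class _Booster:
    """Stagewise logit boosting of regression trees on binomial deviance."""

    def __init__(self, learning_rate, tree_complexity, bag_fraction, rng):
        self.lr = learning_rate
        self.depth = tree_complexity
        self.bag = bag_fraction
        self.rng = rng
        self.trees: list[DecisionTreeRegressor] = []
        self.leaf_values: list[np.ndarray] = []
        self.f0 = 0.0

    def init(self, y):
        p = np.clip(np.mean(y), _PMIN, 1 - _PMIN)
        self.f0 = float(np.log(p / (1 - p)))
        return np.full(y.shape, self.f0)

    def add_tree(self, X, y, F):
        p = 1.0 / (1.0 + np.exp(-F))
        resid = y - p
        n = len(y)
        idx = self.rng.choice(n, size=max(2, int(self.bag * n)), replace=False)
        tree = DecisionTreeRegressor(
            max_depth=self.depth, min_samples_leaf=5, random_state=int(self.rng.integers(2**31 - 1))
        )
        tree.fit(X[idx], resid[idx])
        # Newton step per terminal node: sum(resid) / sum(p(1-p))
        leaves_bag = tree.apply(X[idx])
        values = np.zeros(tree.tree_.node_count)
        w = p[idx] * (1 - p[idx])
        for leaf in np.unique(leaves_bag):
            sel = leaves_bag == leaf
            denom = max(float(w[sel].sum()), 1e-6)
            values[leaf] = float(resid[idx][sel].sum()) / denom
        self.trees.append(tree)
        self.leaf_values.append(values)
        return F + self.lr * values[tree.apply(X)]

    def raw_predict(self, X, n_trees=None):
        F = np.full(X.shape[0], self.f0)
        for tree, vals in list(zip(self.trees, self.leaf_values))[: n_trees if n_trees else len(self.trees)]:
            F += self.lr * vals[tree.apply(X)]
        return F


# ---------------------------------------------------------------------------
# Model / Results


class BoostedHabitatModel:
    """Presence / pseudo-absence boosted-tree habitat model.

    Parameters
    ----------
    data : DataFrame
        One row per point with a binary ``presence`` column (1 presence,
        0 pseudo-absence) and the covariate columns.
    covariates : list of str
        Covariate columns used as predictors.
    """

    def __init__(self, data: pd.DataFrame, covariates: list[str], label_col: str = "presence"):
        self.data = data.reset_index(drop=True)
        self.covariates = list(covariates)
        self.label_col = label_col
        y = self.data[label_col].to_numpy()
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        X = self.data[self.covariates].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        self.X, self.y = X, y.astype(float)

    def fit(
        self,
        learning_rate: float = 0.005,
        tree_complexity: int = 3,
        bag_fraction: float = 0.75,
        n_folds: int = 10,
        max_trees: int = 2000,
        step_size: int = 50,
        seed: int = 0,
    ) -> "BoostedHabitatResults":
        """Staged boosting with CV selection of the ensemble size.

        For every fold a booster grows to ``max_trees``, recording
        held-out predictions every ``step_size`` trees; the tree count
        minimizing mean CV binomial deviance is selected, and a final
        booster is refit on all data at that size.  If CV deviance never
        drops below its smallest-ensemble value, the learning rate is
        flagged as too high.
        """
        rng = np.random.default_rng(seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        grid = np.arange(step_size, max_trees + 1, step_size)
        fold_dev = np.zeros((n_folds, grid.size))
        fold_pred: list[np.ndarray] = []
        fold_idx: list[np.ndarray] = []
        for k, (tr, te) in enumerate(skf.split(self.X, self.y)):
            booster = _Booster(learning_rate, tree_complexity, bag_fraction, np.random.default_rng([seed, k]))
            F = booster.init(self.y[tr])
            Fte = np.full(te.size, booster.f0)
            preds = np.zeros((grid.size, te.size))
            g = 0
            for m in range(1, max_trees + 1):
                F = booster.add_tree(self.X[tr], self.y[tr], F)
                tree, vals = booster.trees[-1], booster.leaf_values[-1]
                Fte = Fte + learning_rate * vals[tree.apply(self.X[te])]
                if m == grid[g]:
                    p = 1.0 / (1.0 + np.exp(-Fte))
                    fold_dev[k, g] = _binomial_deviance(self.y[te], p)
                    preds[g] = p
                    g += 1
            fold_pred.append(preds)
            fold_idx.append(te)
        mean_dev = fold_dev.mean(axis=0)
        best_g = int(np.argmin(mean_dev))
        if best_g == 0 and np.all(np.diff(mean_dev) >= 0):
            warnings.warn(
                "CV deviance never decreased with ensemble size: learning rate too high "
                "(or no signal in the covariates)",
                stacklevel=2,
            )
        n_trees = int(grid[best_g])

        final = _Booster(learning_rate, tree_complexity, bag_fraction, rng)
        F = final.init(self.y)
        for _ in range(n_trees):
            F = final.add_tree(self.X, self.y, F)

        cv_rows = []
        for k in range(n_folds):
            p = fold_pred[k][best_g]
            y = self.y[fold_idx[k]]
            auc = roc_auc_score(y, p) if len(np.unique(y)) == 2 else np.nan
            cv_rows.append({"fold": k, "auc": auc, "deviance": _binomial_deviance(y, p)})
        return BoostedHabitatResults(
            model=self,
            booster=final,
            n_trees=n_trees,
            learning_rate=learning_rate,
            tree_complexity=tree_complexity,
            bag_fraction=bag_fraction,
            cv_deviance_path=pd.DataFrame({"n_trees": grid, "mean_cv_deviance": mean_dev}),
            cv_metrics=pd.DataFrame(cv_rows),
        )


@dataclass
class BoostedHabitatResults:
    """Fitted boosted habitat ensemble with importance and PD helpers."""

    model: BoostedHabitatModel
    booster: _Booster
    n_trees: int
    learning_rate: float
    tree_complexity: int
    bag_fraction: float
    cv_deviance_path: pd.DataFrame
    cv_metrics: pd.DataFrame

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted presence probability."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.covariates].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-self.booster.raw_predict(np.asarray(X, dtype=float))))

    def variable_importance(self) -> pd.Series:
        """Relative influence per covariate, summing to 100%.

        Squared-improvement of every split, accumulated per splitting
        covariate across all trees of the ensemble and normalized.
        """
        raw = np.zeros(len(self.model.covariates))
        for tree in self.booster.trees:
            raw += tree.tree_.compute_feature_importances(normalize=False)
        total = raw.sum()
        pct = raw / total * 100.0 if total > 0 else np.full_like(raw, 100.0 / raw.size)
        return pd.Series(pct, index=self.model.covariates).sort_values(ascending=False)

    def partial_dependence(self, covariate: str, grid: np.ndarray | None = None, n_grid: int = 50) -> pd.DataFrame:
        """Average prediction with one covariate swept over a grid."""
        j = self.model.covariates.index(covariate)
        if grid is None:
            lo, hi = np.percentile(self.model.X[:, j], [1, 99])
            grid = np.linspace(lo, hi, n_grid)
        vals = []
        X = self.model.X.copy()
        for g in np.asarray(grid, dtype=float):
            X[:, j] = g
            vals.append(float(self.predict(X).mean()))
        return pd.DataFrame({covariate: np.asarray(grid, dtype=float), "partial_dependence": vals})

    def summary(self) -> str:
        imp = self.variable_importance()
        cv = self.cv_metrics
        lines = [
            "Boosted habitat model (binomial deviance, staged CV stopping)",
            f"  trees: {self.n_trees}  lr: {self.learning_rate}  depth: {self.tree_complexity}  "
            f"bag: {self.bag_fraction}",
            f"  CV AUC: {cv['auc'].mean():.3f} ± {cv['auc'].std():.3f}   "
            f"CV deviance: {cv['deviance'].mean():.3f} ± {cv['deviance'].std():.3f}",
            "  relative importance (%):",
        ]
        lines += [f"    {name:<20}{val:6.1f}" for name, val in imp.items()]
        return "\n".join(lines)


def variable_importance(fit: BoostedHabitatResults) -> pd.Series:
    return fit.variable_importance()


def partial_dependence(fit: BoostedHabitatResults, covariate: str, grid=None) -> pd.DataFrame:
    return fit.partial_dependence(covariate, grid)


def cv_evaluate(fit: BoostedHabitatResults) -> pd.DataFrame:
    """Fold-wise AUC and predictive deviance at the selected ensemble size."""
    return fit.cv_metrics
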