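"""Downstream yield prediction protocols and yield unit conversion.

Three evaluation protocols, all driven by a pluggable regressor
(gradient-boosted trees by default):

1. genotype-grouped k-fold cross-validation — folds split *genotypes*, so
   scores reflect prediction for unseen genotypes in seen environments;
2. leave-one-location-out rank overlap — train on all other locations,
   predict the held-out one, and measure the percentage overlap between
   the true and predicted top-fraction genotype lists;
3. unseen-environment prediction — a single held-out environment never
   seen by the supervised model, scored by RMSE.

Yields are recorded in bushels/acre (at 15.5% moisture, 56 lb/bushel) and
converted to metric tons/hectare for cross-validation scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .training import pearson

# Unit constants: 56 lb grain per bushel, kg per lb, m^2 per acre.
BUSHEL_LB = 56.0
KG_PER_LB = 0.45359237
M2_PER_ACRE = 4046.8564
#: bu/ac -> t/ha conversion factor (~0.06277).
BU_AC_TO_T_HA = BUSHEL_LB * KG_PER_LB / M2_PER_ACRE * 10.0


def convert_yield(value):
    """Convert bu/ac (56 lb/bu) to t/ha; linear, rejects negative input."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("yield must be nonnegative")
    out = arr * BU_AC_TO_T_HA
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass
class CVResult:
    """Per-fold scores for one feature set."""

    label: str
    r2: list[float]
    rmse: list[float]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2, ddof=1)) if len(self.r2) > 1 else 0.0

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0

    def summary(self) -> dict:
        return {"label": self.label, "mean_r2": self.mean_r2, "sd_r2": self.sd_r2,
                "mean_rmse": self.mean_rmse, "sd_rmse": self.sd_rmse,
                "n_folds": len(self.r2)}


@dataclass
class RankOverlapResult:
    """Top-fraction overlap for one held-out location."""

    location: str
    fraction: float
    overlap_pct: float
    n_top: int


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot (can be negative)."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance targets")
    ss_res = float(((y - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error in the units of ``y``."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 1:
        raise ValueError("need two aligned nonempty vectors")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def grouped_kfold_split(genotypes, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Seeded genotype -> fold assignment with fold sizes differing by <= 1."""
    uniq = sorted({str(g) for g in genotypes})
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(uniq):
        raise ValueError(f"k = {k} exceeds the number of genotypes ({len(uniq)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return {uniq[idx]: int(pos % k) for pos, idx in enumerate(order)}


# Default gradient-boosted tree settings: shallow, slow boosting, which
# generalizes well for the smooth, near-additive yield targets of small
# replicated trials; deterministic and single-threaded.
DEFAULT_XGB_PARAMS: dict = dict(
    n_estimators=800, max_depth=2, learning_rate=0.05,
    subsample=0.9, colsample_bytree=0.9, tree_method="hist", n_jobs=1,
)


def _make_regressor(seed: int, params: dict | None = None):
    from xgboost import XGBRegressor

    merged = {**DEFAULT_XGB_PARAMS, **(params or {})}
    return XGBRegressor(random_state=seed, **merged)


def fit_predict(features: np.ndarray, targets: np.ndarray, train_idx, test_idx,
                seed: int = 0, regressor=None, regressor_params: dict | None = None):
    """Fit on the train rows, predict the test rows (deterministic per seed)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(x) != len(y):
        raise ValueError("features and targets must align row-wise")
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if train_idx.size == 0:
        raise ValueError("empty training set")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    model = regressor if regressor is not None else _make_regressor(seed, regressor_params)
    model.fit(x[train_idx], y[train_idx])
    return np.asarray(model.predict(x[test_idx]), dtype=float)


def _aligned(features: pd.DataFrame, yields: pd.DataFrame, metadata: pd.DataFrame):
    """Align a feature table with yields/metadata on plot_id."""
    feat = features.set_index("plot_id") if "plot_id" in features.columns else features
    merged = metadata.merge(yields, on="plot_id", validate="one_to_one")
    missing = [p for p in merged["plot_id"] if p not in feat.index]
    if missing:
        raise ValueError(f"feature rows missing for plots: {missing[:5]}...")
    x = feat.loc[merged["plot_id"]].to_numpy(dtype=float)
    return x, merged


def experiment1(feature_tables: dict[str, pd.DataFrame], yields: pd.DataFrame,
                metadata: pd.DataFrame, k: int = 5, seed: int = 0,
                regressor_params: dict | None = None,
                convert_to_t_ha: bool = True) -> list[CVResult]:
    """Genotype-grouped k-fold CV for each named feature set.

    R^2 is unitless; RMSE is reported in t/ha (``convert_to_t_ha``).
    """
    if not feature_tables:
        raise ValueError("no feature sets given")
    results = []
    for label, table in feature_tables.items():
        x, merged = _aligned(table, yields, metadata)
        y = merged["yield_bu_ac"].to_numpy(dtype=float)
        if convert_to_t_ha:
            y = convert_yield(y)
        folds = grouped_kfold_split(merged["genotype_id"], k=k, seed=seed)
        fold_of = merged["genotype_id"].astype(str).map(folds).to_numpy()
        r2s, rmses = [], []
        for f in range(k):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            pred = fit_predict(x, y, train, test, seed=seed,
                               regressor_params=regressor_params)
            r2s.append(r_squared(y[test], pred))
            rmses.append(rmse(y[test], pred))
        results.append(CVResult(label=label, r2=r2s, rmse=rmses))
    return results


def top_fraction_overlap(y_true: pd.Series, y_pred: pd.Series,
                         fraction: float) -> float:
    """Percentage overlap of the top-``fraction`` genotype sets.

    Both series are keyed by genotype. The top set holds
    ``round(fraction * G)`` (at least 1) genotypes; ties are broken by the
    stable order (descending value, then genotype id).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if len(y_true) == 0:
        raise ValueError("empty input")
    if set(y_true.index) != set(y_pred.index):
        raise ValueError("true and predicted rankings must share the genotype set")

    def top(series: pd.Series, n: int) -> set:
        df = pd.DataFrame({"v": series})
        df = df.sort_values(["v"], ascending=False, kind="stable")
        df = df.iloc[np.lexsort((df.index.astype(str), -df["v"].to_numpy()))]
        return set(df.index[:n])

    n_top = max(1, int(round(fraction * len(y_true))))
    t, p = top(y_true, n_top), top(y_pred, n_top)
    return 100.0 * len(t & p) / n_top


def experiment2(features: pd.DataFrame, yields: pd.DataFrame,
                metadata: pd.DataFrame, fraction: float = 0.25, seed: int = 0,
                regressor_params: dict | None = None) -> list[RankOverlapResult]:
    """Leave-one-location-out rank overlap of top-yielding genotypes.

    Replicate plots are averaged per genotype within the held-out location
    (for both truth and predictions) before ranking.
    """
    x, merged = _aligned(features, yields, metadata)
    y = merged["yield_bu_ac"].to_numpy(dtype=float)
    locations = sorted(merged["environment_id"].astype(str).unique())
    if len(locations) < 2:
        raise ValueError("need at least 2 locations for leave-one-location-out")
    results = []
    env = merged["environment_id"].astype(str).to_numpy()
    for loc in locations:
        test = np.flatnonzero(env == loc)
        train = np.flatnonzero(env != loc)
        pred = fit_predict(x, y, train, test, seed=seed,
                           regressor_params=regressor_params)
        sub = merged.iloc[test]
        true_by_geno = pd.Series(y[test], index=sub["genotype_id"].astype(str)) \
            .groupby(level=0).mean()
        pred_by_geno = pd.Series(pred, index=sub["genotype_id"].astype(str)) \
            .groupby(level=0).mean()
        n_top = max(1, int(round(fraction * len(true_by_geno))))
        results.append(RankOverlapResult(
            location=loc, fraction=fraction,
            overlap_pct=top_fraction_overlap(true_by_geno, pred_by_geno, fraction),
            n_top=n_top,
        ))
    return results


def experiment3(features: pd.DataFrame, yields: pd.DataFrame,
                metadata: pd.DataFrame, heldout_environment: str, seed: int = 0,
                regressor_params: dict | None = None) -> dict:
    """Unseen-environment RMSE (reported in the input yield unit).

    The supervised model never sees the held-out environment's plots;
    representation features may come from an unsupervised model fit on all
    imagery. Raises if the held-out environment is absent (nothing to
    test) — any presence of its plots in the supervised training rows is
    precluded by the split itself.
    """
    x, merged = _aligned(features, yields, metadata)
    env = merged["environment_id"].astype(str).to_numpy()
    if heldout_environment not in set(env):
        raise ValueError(f"held-out environment {heldout_environment!r} not in dataset")
    test = np.flatnonzero(env == heldout_environment)
    train = np.flatnonzero(env != heldout_environment)
    if train.size == 0:
        raise ValueError("no training environments left after holding out")
    y = merged["yield_bu_ac"].to_numpy(dtype=float)
    pred = fit_predict(x, y, train, test, seed=seed, regressor_params=regressor_params)
    return {"heldout_environment": heldout_environment,
            "rmse": rmse(y[test], pred), "unit": "bu/ac", "n_test": int(test.size)}


def feature_cross_correlation(table_a: pd.DataFrame,
                              table_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every A column against every B column.

    Rows must align (same plots in the same order); ``plot_id`` columns,
    if present, are checked and excluded from the matrix.
    """
    a, b = table_a.copy(), table_b.copy()
    if "plot_id" in a.columns and "plot_id" in b.columns:
        if not (a["plot_id"].to_numpy() == b["plot_id"].to_numpy()).all():
            raise ValueError("tables are not aligned on plot_id")
    a = a.drop(columns=[c for c in ("plot_id",) if c in a.columns])
    b = b.drop(columns=[c for c in ("plot_id",) if c in b.columns])
    if len(a) != len(b):
        raise ValueError("tables must have the same number of rows")
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            out.loc[ca, cb] = pearson(a[ca].to_numpy(float), b[cb].to_numpy(float))
    return out
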