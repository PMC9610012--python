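"""Offensive/defensive performance models and their evaluation protocol.

Rows are pooled into offensive (attack, serve) and defensive (pass,
block) sets.  Each side gets four models: a random forest and a gradient
boosting machine tuned by 10-fold cross-validation on a 70% training
split (stratified on action type and target quartile), an *action model*
that predicts the training mean target of the row's action type, and a
*naive baseline* predicting the overall training mean.  Near-zero
variance predictors are removed from the training set before fitting,
and the same retained set is applied to the test data.

Test accuracy is the mean absolute error (MAE) on the 0-10 score scale
with a 95% t-interval; each model is compared with the baseline via a
paired t-test on per-row absolute errors, percent MAE reduction, and
Cohen's d of the paired differences with a 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, ParameterGrid
from xgboost import XGBRegressor

from .features import predictor_columns
from .scoring import DEFENSE_ACTIONS, OFFENSE_ACTIONS

MODEL_KINDS = ("random_forest", "gradient_boosting", "action_only", "naive_baseline")

#: fixed reference hyperparameters (the values selected in the original
#: tuning; forest: 500 trees, 10 candidate features per split, minimum
#: node size 5, variance split rule; boosting: 50 rounds of depth-1 trees,
#: learning rate 0.3, gamma 0)
RF_DEFAULTS = {"n_estimators": 500, "max_features": 10, "min_samples_leaf": 5}
XGB_DEFAULTS = {"n_estimators": 50, "max_depth": 1, "learning_rate": 0.3, "gamma": 0.0,
                "min_child_weight": 1, "colsample_bytree": 0.6, "subsample": 0.625}

#: small default tuning grids centred on the reference values
RF_DEFAULT_GRID = {"max_features": [5, 10, 20], "min_samples_leaf": [5]}
XGB_DEFAULT_GRID = {"max_depth": [1, 2], "colsample_bytree": [0.6, 0.8], "subsample": [0.625, 1.0]}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: a model kind plus an optional hyperparameter grid."""

    kind: str
    grid: dict | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if self.kind in ("random_forest", "gradient_boosting") and self.grid is not None and not self.grid:
            raise ValueError("tuning grid must be non-empty for tunable model kinds")

    def default_grid(self) -> dict:
        if self.grid is not None:
            return self.grid
        if self.kind == "random_forest":
            return RF_DEFAULT_GRID
        if self.kind == "gradient_boosting":
            return XGB_DEFAULT_GRID
        return {}


@dataclass
class FittedModel:
    kind: str
    columns: list[str]
    estimator: object = None
    action_means: dict[str, float] | None = None
    global_mean: float = float("nan")
    chosen_params: dict = field(default_factory=dict)
    cv_mae: float = float("nan")

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        if self.kind == "naive_baseline":
            return np.full(len(matrix), self.global_mean)
        if self.kind == "action_only":
            return matrix["action_type"].map(self.action_means).fillna(self.global_mean).to_numpy()
        return np.asarray(self.estimator.predict(matrix[self.columns].to_numpy(dtype=float)))


@dataclass
class ModelEvaluation:
    """Test-set accuracy of one model against the naive baseline."""

    kind: str
    n_test: int
    mae: float
    mae_ci: tuple[float, float]
    baseline_mae: float
    mae_reduction_pct: float
    paired_p: float
    cohens_d: float
    d_ci: tuple[float, float]
    effect: str
    degenerate: bool = False


def side_matrix(matrix: pd.DataFrame, side: str) -> pd.DataFrame:
    """Restrict a feature matrix to offensive or defensive action rows."""
    actions = {"offense": OFFENSE_ACTIONS, "defense": DEFENSE_ACTIONS}[side]
    return matrix[matrix["action_type"].isin(actions)].reset_index(drop=True)


def stratified_split(matrix: pd.DataFrame, train_frac: float = 0.70,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """70/30 split stratified on action type and within-action target quartile."""
    if not len(matrix):
        raise ValueError("cannot split an empty matrix")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for action, grp in matrix.groupby("action_type", sort=True):
        try:
            bins = pd.qcut(grp["target"], q=4, labels=False, duplicates="drop")
        except ValueError:
            bins = pd.Series(0, index=grp.index)
        if bins.isna().all():
            bins = pd.Series(0, index=grp.index)
        for _, stratum in grp.groupby(bins.fillna(-1)):
            idx = stratum.index.to_numpy()
            rng.shuffle(idx)
            n_train = int(round(train_frac * len(idx)))
            n_train = min(max(n_train, 1 if len(idx) else 0), len(idx))
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
    return (matrix.loc[sorted(train_idx)].reset_index(drop=True),
            matrix.loc[sorted(test_idx)].reset_index(drop=True))


def near_zero_variance_filter(train: pd.DataFrame, columns: list[str] | None = None,
                              freq_ratio: float = 19.0, unique_pct: float = 10.0) -> list[str]:
    """Columns surviving the near-zero-variance rule on the training data.

    A column is dropped if it has a single unique value, or if the ratio
    of the most common to the second most common value exceeds
    ``freq_ratio`` while distinct values are fewer than ``unique_pct``
    percent of the rows.
    """
    if not len(train):
        raise ValueError("training set is empty")
    if columns is None:
        columns = predictor_columns(train)
    retained = []
    n = len(train)
    for c in columns:
        counts = train[c].value_counts(dropna=True)
        if len(counts) <= 1:
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = 100.0 * len(counts) / n
        if ratio > freq_ratio and pct_unique < unique_pct:
            continue
        retained.append(c)
    if not retained:
        raise ValueError("near-zero-variance filter removed every column")
    return retained


def _make_estimator(kind: str, params: dict, n_features: int, seed: int):
    if kind == "random_forest":
        p = {**RF_DEFAULTS, **params}
        p["max_features"] = min(int(p["max_features"]), n_features)
        return RandomForestRegressor(criterion="squared_error", random_state=seed,
                                     n_jobs=1, **p)
    p = {**XGB_DEFAULTS, **params}
    return XGBRegressor(objective="reg:squarederror", tree_method="hist",
                        random_state=seed, n_jobs=1, verbosity=0, **p)


def tune_and_fit(train: pd.DataFrame, spec: ModelSpec, cv_folds: int = 10,
                 seed: int = 0, columns: list[str] | None = None) -> FittedModel:
    """Grid search by K-fold cross-validated MAE, then refit on all of train.

    A single-point grid skips the search.  The action-only and baseline
    kinds have no predictors: they memorise training means.
    """
    if columns is None:
        columns = predictor_columns(train)
    y = train["target"].to_numpy(dtype=float)
    global_mean = float(y.mean())
    if spec.kind == "naive_baseline":
        return FittedModel(kind=spec.kind, columns=[], global_mean=global_mean)
    if spec.kind == "action_only":
        means = train.groupby("action_type")["target"].mean().to_dict()
        return FittedModel(kind=spec.kind, columns=[], action_means=means, global_mean=global_mean)

    X = train[columns].to_numpy(dtype=float)
    grid = list(ParameterGrid(spec.default_grid())) or [{}]
    best_params, best_mae = grid[0], float("inf")
    if len(grid) > 1:
        folds = list(KFold(n_splits=min(cv_folds, len(train)), shuffle=True,
                           random_state=seed).split(X))
        for params in grid:
            maes = []
            for tr, va in folds:
                if len(va) == 0 or len(tr) == 0:
                    raise ValueError("cross-validation fold with no data")
                est = _make_estimator(spec.kind, params, X.shape[1], seed)
                est.fit(X[tr], y[tr])
                maes.append(float(np.mean(np.abs(est.predict(X[va]) - y[va]))))
            mae = float(np.mean(maes))
            if mae < best_mae:
                best_mae, best_params = mae, params
    est = _make_estimator(spec.kind, best_params, X.shape[1], seed)
    est.fit(X, y)
    return FittedModel(kind=spec.kind, columns=list(columns), estimator=est,
                       global_mean=global_mean, chosen_params=dict(best_params),
                       cv_mae=best_mae if len(grid) > 1 else float("nan"))


def _t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = x.size
    if n < 2:
        return float("nan"), float("nan")
    se = x.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2, n - 1)
    return float(x.mean() - tq * se), float(x.mean() + tq * se)


def evaluate(model: FittedModel, test: pd.DataFrame,
             baseline_model: FittedModel) -> ModelEvaluation:
    """Test MAE with CI, paired-t comparison with the baseline, Cohen's d."""
    if not len(test):
        raise ValueError("test set is empty")
    y = test["target"].to_numpy(dtype=float)
    err_m = np.abs(model.predict(test) - y)
    err_b = np.abs(baseline_model.predict(test) - y)
    mae, mae_b = float(err_m.mean()), float(err_b.mean())
    diff = err_b - err_m
    degenerate = bool(len(test) < 2 or diff.std(ddof=1) == 0)
    if degenerate:
        p = float("nan")
        d = 0.0 if np.allclose(diff, 0) else float("nan")
        d_ci = (float("nan"), float("nan"))
    else:
        p = float(stats.ttest_rel(err_b, err_m).pvalue)
        d = float(diff.mean() / diff.std(ddof=1))
        se = np.sqrt(1 / len(diff) + d * d / (2 * len(diff)))
        d_ci = (float(d - 1.96 * se), float(d + 1.96 * se))
    from .subgroups import effect_label
    reduction = float("nan") if mae_b == 0 else (mae_b - mae) / mae_b * 100.0
    return ModelEvaluation(
        kind=model.kind, n_test=len(test), mae=mae, mae_ci=_t_ci(err_m),
        baseline_mae=mae_b, mae_reduction_pct=reduction, paired_p=p,
        cohens_d=d, d_ci=d_ci, effect=effect_label(d), degenerate=degenerate,
    )


def season_trend(targets: pd.DataFrame) -> dict[str, dict]:
    """Spearman rank correlation of performance against match index.

    The match index is the chronological rank of the match within the
    season.  Returned per side as ``{'offense': {...}, 'defense': {...}}``
    with rho, p, n and a ``degenerate`` flag for constant inputs.
    """
    out = {}
    match_rank = {d: i for i, d in enumerate(sorted(targets["match_date"].unique()))}
    for side, actions in (("offense", OFFENSE_ACTIONS), ("defense", DEFENSE_ACTIONS)):
        rows = targets[targets["action_type"].isin(actions)]
        if len(rows) < 3:
            raise ValueError(f"need at least 3 match records for the {side} trend")
        x = rows["match_date"].map(match_rank).to_numpy()
        y = rows["score"].to_numpy(dtype=float)
        if np.all(y == y[0]) or np.all(x == x[0]):
            out[side] = {"rho": float("nan"), "p": float("nan"), "n": len(rows), "degenerate": True}
            continue
        rho, p = stats.spearmanr(y, x)
        out[side] = {"rho": float(rho), "p": float(p), "n": len(rows), "degenerate": False}
    return out


def run_model_comparison(matrix: pd.DataFrame, side: str, seed: int = 0,
                         specs: list[ModelSpec] | None = None,
                         cv_folds: int = 10) -> dict[str, ModelEvaluation]:
    """Full protocol for one side: split, filter, fit all models, evaluate."""
    sm = side_matrix(matrix, side)
    train, test = stratified_split(sm, seed=seed)
    retained = near_zero_variance_filter(train)
    if specs is None:
        specs = [ModelSpec(k) for k in MODEL_KINDS]
    baseline = tune_and_fit(train, ModelSpec("naive_baseline"), seed=seed)
    out = {}
    for spec in specs:
        model = (baseline if spec.kind == "naive_baseline"
                 else tune_and_fit(train, spec, cv_folds=cv_folds, seed=seed, columns=retained))
        out[spec.kind] = evaluate(model, test, baseline)
    return out
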