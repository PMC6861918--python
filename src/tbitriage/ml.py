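"""Nested cross-validated classification of longitudinal biomarker panels.

The question: can the treated and vehicle groups be told apart from their
plasma cytokine trajectories (12 cytokines sampled at days 7, 14 and 28
post-injury), or from other longitudinal measures such as body weight?
The procedure:

* feature engineering — raw measurements per day, optionally augmented
  with successive differences and the least-squares slope of each series
  (fitted against the actual day values);
* a gradient-boosted-tree classifier evaluated by *nested* cross-validation:
  leave-one-out on the outer level, stratified k-fold grid search (over
  classifier hyperparameters and, optionally, feature-selection settings)
  on the inner level; features are standardized with outer-training
  statistics only, so the held-out animal never leaks into the fit;
* the pooled held-out class-1 probabilities give one ROC AUC per repeat;
  the whole procedure is repeated with fresh fold randomization and
  classifier initialization and the mean AUC is compared against a gate
  (default 0.75) to decide whether a panel carries signal;
* label-permutation testing with the finite-sample corrected p-value
  (1 + #{permuted AUC >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

__all__ = [
    "CYTOKINES",
    "FeatureSetSpec",
    "NestedCvConfig",
    "CvOutcome",
    "build_features",
    "select_features",
    "make_selector",
    "nested_cv_evaluate",
    "permutation_pvalue",
    "default_feature_sets",
]

CYTOKINES = (
    "GM-CSF", "IFNy", "IL-1a", "IL-1b", "IL-2", "IL-4",
    "IL-5", "IL-6", "IL-10", "IL-12p70", "IL-13", "TNFa",
)

Strategy = Literal["f_score_percentile", "embedded_forest", "pca", "none"]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which variables and days enter the feature matrix.

    ``augment`` adds, per variable series, the successive differences
    between consecutive days and the least-squares slope over the series
    (units per day, actual day values as abscissae). Single-day sets are
    raw panels and must not be augmented.
    """

    name: str
    variables: tuple[str, ...]
    days: tuple[int, ...]
    augment: bool = False

    def __post_init__(self) -> None:
        if self.augment and len(self.days) < 2:
            raise ValueError("augment requires at least two days")
        if len(self.days) != len(set(self.days)):
            raise ValueError("days must be distinct")


def default_feature_sets(days: Sequence[int] = (7, 14, 28)) -> tuple[FeatureSetSpec, ...]:
    """The shipped feature sets: each single day raw, and the full
    augmented cytokine panel."""
    singles = tuple(
        FeatureSetSpec(f"cytokines_day{d}", CYTOKINES, (d,), augment=False)
        for d in days
    )
    full = FeatureSetSpec("cytokines_all_days", CYTOKINES, tuple(days), augment=True)
    return singles + (full,)


def _series_slope(days: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope of value on day (simple regression, Sxy/Sxx)."""
    x = days - days.mean()
    return float((x * (values - values.mean())).sum() / (x * x).sum())


def build_features(
    panel: pd.DataFrame, spec: FeatureSetSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Long panel -> (animals x features matrix, 0/1 label vector).

    ``panel`` columns: animal_id, group, day, variable, value (the
    cytokine dialect ``cytokine``/``concentration`` is accepted too).
    Labels: vehicle -> 0, anything else -> 1. A missing (animal, variable,
    day) combination required by the spec is an error naming both.
    """
    df = panel.rename(
        columns={"cytokine": "variable", "concentration": "value", "measure": "variable"}
    )
    required = {"animal_id", "group", "day", "variable", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"panel missing columns: {sorted(missing_cols)}")

    df = df[df["variable"].isin(spec.variables) & df["day"].isin(spec.days)]
    wide = df.pivot_table(
        index="animal_id", columns=["variable", "day"], values="value", aggfunc="first"
    )
    groups = df.drop_duplicates("animal_id").set_index("animal_id")["group"]

    days = np.asarray(sorted(spec.days), dtype=float)
    features: dict[str, pd.Series] = {}
    for var in spec.variables:
        for d in sorted(spec.days):
            if (var, d) not in wide.columns:
                raise ValueError(f"variable {var!r} missing at day {d}")
            col = wide[(var, d)]
            if col.isna().any():
                bad = col.index[col.isna()][0]
                raise ValueError(f"animal {bad!r} missing {var!r} at day {d}")
            features[f"{var}_day{d}"] = col
        if spec.augment:
            series = wide[var][sorted(spec.days)]
            for d0, d1 in zip(sorted(spec.days)[:-1], sorted(spec.days)[1:]):
                features[f"{var}_diff_d{d1}_d{d0}"] = series[d1] - series[d0]
            features[f"{var}_slope"] = series.apply(
                lambda row: _series_slope(days, row.to_numpy(dtype=float)), axis=1
            )

    X = pd.DataFrame(features)
    y = (groups.loc[X.index] != "vehicle").astype(int).rename("label")
    return X, y


# ---------------------------------------------------------------------------
# feature-selection transformers (all guarantee at least one surviving
# feature, which sklearn's SelectPercentile / SelectFromModel do not)


class FScorePercentileSelector(BaseEstimator, TransformerMixin):
    """Keep the top ``percentile`` of features ranked by the one-way F
    statistic between classes; always keeps at least the single best."""

    def __init__(self, percentile: float = 100.0):
        self.percentile = percentile

    def fit(self, X, y):
        X = np.asarray(X)
        f, _ = f_classif(X, y)
        f = np.nan_to_num(f, nan=0.0)
        k = max(1, int(round(X.shape[1] * self.percentile / 100.0)))
        self.support_ = np.sort(np.argsort(f)[::-1][:k])
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


class AboveAverageImportanceSelector(BaseEstimator, TransformerMixin):
    """Keep features whose extremely-randomized-trees importance exceeds
    the average importance (1/p under uniformity)."""

    def __init__(self, n_estimators: int = 100, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        forest = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        ).fit(X, y)
        imp = forest.feature_importances_
        mask = imp > imp.mean()
        if not mask.any():
            mask[np.argmax(imp)] = True
        self.support_ = np.flatnonzero(mask)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


class VarianceFractionPCA(BaseEstimator, TransformerMixin):
    """Project onto leading principal components retaining a configured
    fraction of training variance."""

    def __init__(self, variance: float = 0.95):
        self.variance = variance

    def fit(self, X, y=None):
        X = np.asarray(X)
        n_max = min(X.shape)
        if self.variance >= 1 or n_max == 1:
            self.pca_ = PCA(n_components=n_max)
        else:
            self.pca_ = PCA(n_components=self.variance, svd_solver="full")
        self.pca_.fit(X)
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X))


def make_selector(strategy: Strategy, **params):
    """Instantiate the feature-selection step for a pipeline."""
    if strategy == "f_score_percentile":
        return FScorePercentileSelector(**params)
    if strategy == "embedded_forest":
        return AboveAverageImportanceSelector(**params)
    if strategy == "pca":
        return VarianceFractionPCA(**params)
    if strategy == "none":
        return "passthrough"
    raise ValueError(f"unknown feature-selection strategy {strategy!r}")


def select_features(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    strategy: Strategy,
    params: Mapping[str, Any] | None = None,
):
    """Fit a selector on training data only; returns (transformed X, fitted
    selector). ``strategy='none'`` returns the input unchanged."""
    sel = make_selector(strategy, **(params or {}))
    if sel == "passthrough":
        return np.asarray(X), None
    Xt = sel.fit(np.asarray(X), np.asarray(y)).transform(np.asarray(X))
    return Xt, sel


# ---------------------------------------------------------------------------
# nested cross-validation


DEFAULT_GRID: dict[str, tuple] = {
    "clf__max_depth": (2, 3),
    "clf__learning_rate": (0.05, 0.1),
    "clf__n_estimators": (50, 200),
}

DEFAULT_SELECTION_GRID: dict[str, tuple] = {
    "select__percentile": (10, 25, 50, 100),
}


@dataclass(frozen=True)
class NestedCvConfig:
    """Leave-one-out outer / stratified k-fold inner nested CV settings.

    The inner fold count is capped at the minority-class size of each
    outer-training set so every inner training fold contains both classes.
    """

    inner_folds: int = 10
    grid: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GRID))
    feature_selection: Strategy = "none"
    selection_grid: Mapping[str, tuple] | None = None
    n_repeats: int = 10
    auc_gate: float = 0.75
    n_permutations: int = 100
    seed: int = 0
    classifier_factory: Callable[[int], Any] | None = None

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class CvOutcome:
    aucs: tuple[float, ...]  # one pooled AUC per repeat
    mean_auc: float
    gate_passed: bool
    best_params: tuple[Mapping[str, Any], ...]  # per outer fold, first repeat
    pooled_scores: tuple[tuple[float, ...], ...]  # per repeat, per animal
    permutation_p: float | None = None


def _default_classifier(random_state: int):
    return XGBClassifier(
        n_estimators=50,
        max_depth=2,
        learning_rate=0.1,
        random_state=random_state,
        n_jobs=1,
        tree_method="exact",
        verbosity=0,
        eval_metric="logloss",
    )


def _full_grid(config: NestedCvConfig) -> dict[str, tuple]:
    grid = dict(config.grid)
    if config.feature_selection == "f_score_percentile":
        grid.update(config.selection_grid or DEFAULT_SELECTION_GRID)
    elif config.selection_grid:
        grid.update(config.selection_grid)
    return grid


def _split_params(params: Mapping[str, Any]) -> tuple[dict, dict]:
    sel = {k.removeprefix("select__"): v for k, v in params.items()
           if k.startswith("select__")}
    clf = {k.removeprefix("clf__"): v for k, v in params.items()
           if k.startswith("clf__")}
    return sel, clf


def _inner_best_params(
    X_tr: np.ndarray, y_tr: np.ndarray, config: NestedCvConfig, rs: int
) -> dict:
    """Stratified k-fold grid search on the outer-training set only,
    maximizing mean inner ROC AUC; first-best wins ties (candidate order).

    Standardization is refit inside every inner fold, so no inner
    validation row influences its own preprocessing either.
    """
    grid = _full_grid(config)
    candidates = list(ParameterGrid(grid)) if grid else [{}]
    if len(candidates) <= 1:
        return candidates[0]
    k = min(config.inner_folds, int(np.bincount(y_tr).min()))
    if k < 2:
        raise ValueError("outer-training minority class too small for inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
    factory = config.classifier_factory or _default_classifier
    prepped = []
    for tr, va in skf.split(X_tr, y_tr):
        sc = StandardScaler().fit(X_tr[tr])
        prepped.append((sc.transform(X_tr[tr]), sc.transform(X_tr[va]),
                        y_tr[tr], y_tr[va]))
    best_auc, best = -np.inf, candidates[0]
    for params in candidates:
        sel_kw, clf_kw = _split_params(params)
        aucs = []
        for Xa, Xb, ya, yb in prepped:
            sel = make_selector(config.feature_selection, **sel_kw)
            if sel != "passthrough":
                sel.fit(Xa, ya)
                Xa_s, Xb_s = sel.transform(Xa), sel.transform(Xb)
            else:
                Xa_s, Xb_s = Xa, Xb
            clf = factory(rs)
            if clf_kw:
                clf.set_params(**clf_kw)
            clf.fit(Xa_s, ya)
            aucs.append(roc_auc_score(yb, clf.predict_proba(Xb_s)[:, 1]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best = mean_auc, params
    return best


def fit_outer_fold(
    X: np.ndarray,
    y: np.ndarray,
    test_index: int,
    config: NestedCvConfig,
    repeat: int = 0,
):
    """Grid-search and refit the pipeline for one leave-one-out split.

    The held-out row takes no part in standardization, feature selection
    or fitting; returns ``(fitted model, winning params)``.
    """
    rs = (config.seed * 1_000_003 + repeat * 7919 + 17) % _SEED_MOD
    factory = config.classifier_factory or _default_classifier
    train = np.arange(len(y)) != test_index
    X_tr, y_tr = np.asarray(X, dtype=float)[train], np.asarray(y, dtype=int)[train]
    best = _inner_best_params(X_tr, y_tr, config, rs)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("select", make_selector(config.feature_selection)),
            ("clf", factory(rs)),
        ]
    )
    if best:
        pipe.set_params(**best)
    return pipe.fit(X_tr, y_tr), best


def nested_cv_evaluate(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    config: NestedCvConfig | None = None,
) -> CvOutcome:
    """LOO-outer, stratified-k-fold-inner nested CV with grid search.

    Per outer split the pipeline (standardize -> select -> boost) is
    grid-searched on the outer-training set only (maximizing inner AUC),
    refit on the full outer-training set, and scored on the held-out
    animal. The pooled held-out scores give one AUC per repeat.
    """
    config = config or NestedCvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < 2:
        raise ValueError("need at least 2 animals per class")

    n = len(y)
    aucs: list[float] = []
    all_scores: list[tuple[float, ...]] = []
    best_params: list[Mapping[str, Any]] = []
    for rep in range(config.n_repeats):
        scores = np.empty(n)
        for i in range(n):
            model, params = fit_outer_fold(X, y, i, config, repeat=rep)
            if rep == 0:
                best_params.append(params or {})
            scores[i] = model.predict_proba(X[i : i + 1])[:, 1][0]
        aucs.append(float(roc_auc_score(y, scores)))
        all_scores.append(tuple(scores))

    mean_auc = float(np.mean(aucs))
    return CvOutcome(
        aucs=tuple(aucs),
        mean_auc=mean_auc,
        gate_passed=bool(mean_auc > config.auc_gate),
        best_params=tuple(best_params),
        pooled_scores=tuple(all_scores),
    )


def permutation_pvalue(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    config: NestedCvConfig,
    observed_auc: float,
) -> float:
    """Label-permutation significance of an observed nested-CV AUC.

    Each permutation reruns the nested-CV AUC computation (one repeat per
    permutation) on shuffled labels; p carries the +1/+1 finite-sample
    correction, so the smallest attainable p is 1/(1+n_permutations).
    """
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(config.seed)
    hits = 0
    for j in range(config.n_permutations):
        y_perm = rng.permutation(y)
        perm_cfg = NestedCvConfig(
            inner_folds=config.inner_folds,
            grid=config.grid,
            feature_selection=config.feature_selection,
            selection_grid=config.selection_grid,
            n_repeats=1,
            auc_gate=config.auc_gate,
            n_permutations=config.n_permutations,
            seed=(config.seed + 7 + j * 13) % _SEED_MOD,
            classifier_factory=config.classifier_factory,
        )
        perm_auc = nested_cv_evaluate(X, y_perm, perm_cfg).mean_auc
        if perm_auc >= observed_auc - 1e-12:
            hits += 1
    return (1 + hits) / (1 + config.n_permutations)
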