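"""Multi-output random-forest (MORF) relevance modeling.

One forest jointly predicts every circuit activity from the expression of the
candidate drug-target genes.  Each tree split minimizes the summed per-output
variance impurity (computed on standardized outputs so circuits contribute on
equal footing), and per-gene *relevance* is the impurity-decrease importance
averaged over trees, normalized to sum 1.

Model selection maximizes a global R^2 (the unweighted mean of per-circuit
R^2 on held-out folds) over a TPE hyperparameter search.  With the chosen
configuration fixed, a repeated k-fold cross-validation yields a relevance
*distribution* per gene; the stability threshold is the smallest relevance
level above which the full-fit ranking and the cross-validated ranking agree
and every selected gene clears the threshold by more than one CV standard
deviation.  Genes above the threshold are joined with their drug annotations
into the final prioritization table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, RepeatedKFold

from . import hpo
from .knowledge_base import KDTRecord, RelevanceFixtureRow, canonical_symbol

logger = logging.getLogger(__name__)

#: Hyperparameter bounds for the forest (the TPE search space).
DEFAULT_SEARCH_SPACE: dict[str, hpo.ParamSpec] = {
    "n_trees": ("int", 100, 1000),
    "max_depth": ("choice", [4, 8, 16, 32, None]),
    "max_features": ("float", 0.1, 1.0),
    "min_samples_leaf": ("int", 1, 20),
}


@dataclass
class MORFConfig:
    """Forest hyperparameters (within the declared search-space bounds)."""

    n_trees: int = 200
    max_depth: int | None = None
    max_features: float = 1.0
    min_samples_leaf: int = 1
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if not 100 <= self.n_trees <= 1000:
            if not 1 <= self.n_trees:  # pragma: no cover
                raise ValueError("n_trees must be positive")
            logger.warning("n_trees=%d outside the default search bounds", self.n_trees)
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if not 0.0 < self.max_features <= 1.0:
            raise ValueError("max_features must lie in (0, 1]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVConfig:
    """Cross-validation layout: k folds, N repeats, its own seeded stream."""

    k: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class MORFModel:
    """A fitted forest plus the output standardization it was trained with."""

    forest: RandomForestRegressor
    feature_names: list[str]
    output_names: list[str]
    output_scale: np.ndarray  # per-output std used to standardize Y

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        pred = self.forest.predict(X[self.feature_names].to_numpy())
        pred = np.atleast_2d(pred) * self.output_scale
        return pd.DataFrame(pred, index=X.index, columns=self.output_names)

    @property
    def relevance(self) -> pd.Series:
        imp = self.forest.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return pd.Series(imp, index=self.feature_names, name="relevance")


@dataclass
class RelevanceProfile:
    """Point relevances (full-data fit) plus their CV distribution."""

    point: pd.Series  # gene -> relevance, sums to 1
    cv: pd.DataFrame  # folds (k*N rows) x genes; each row sums to 1
    fold_r2: pd.DataFrame  # folds x circuits, held-out R^2

    def __post_init__(self) -> None:
        if abs(self.point.sum() - 1.0) > 1e-9:
            raise ValueError("point relevances must sum to 1")

    @property
    def mean(self) -> pd.Series:
        return self.cv.mean(axis=0)

    @property
    def sd(self) -> pd.Series:
        return self.cv.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"point": self.point, "mean": self.mean, "sd": self.sd}
        ).sort_values("mean", ascending=False)


@dataclass
class StabilityThreshold:
    value: float
    n_selected: int
    selected: tuple[str, ...] = ()


@dataclass
class ModelScore:
    """Per-circuit R^2 and their uniform average (0 = predict-the-mean)."""

    per_circuit: pd.Series
    global_r2: float


def _make_forest(config: MORFConfig) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )


def _output_scale(Y: np.ndarray) -> np.ndarray:
    scale = Y.std(axis=0, ddof=0)
    constant = np.ptp(Y, axis=0) == 0
    scale[constant | (scale == 0)] = 1.0  # constant outputs add zero impurity
    return scale


def fit_morf(
    X: pd.DataFrame, Y: pd.DataFrame, config: MORFConfig
) -> tuple[MORFModel, pd.Series]:
    """Fit the forest on samples x genes ``X`` and samples x circuits ``Y``.

    Returns the fitted model and the point relevance vector (normalized
    impurity-decrease importances).
    """
    if len(X) != len(Y):
        raise ValueError("X and Y must share samples")
    if len(X) < 2:
        raise ValueError("need at least two samples")
    if X.isna().any().any() or Y.isna().any().any():
        raise ValueError("missing values are not allowed")
    scale = _output_scale(Y.to_numpy(dtype=float))
    forest = _make_forest(config)
    forest.fit(X.to_numpy(dtype=float), Y.to_numpy(dtype=float) / scale)
    model = MORFModel(
        forest=forest,
        feature_names=list(X.columns),
        output_names=list(Y.columns),
        output_scale=scale,
    )
    return model, model.relevance


def global_r2(model: MORFModel, X: pd.DataFrame, Y: pd.DataFrame) -> ModelScore:
    """Per-circuit R^2 = 1 - SSE/SST and their unweighted mean.

    Zero-variance truth columns have no defined R^2 and are excluded with a
    warning.
    """
    pred = model.predict(X)
    per = {}
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        sst = ((y - y.mean()) ** 2).sum()
        if np.ptp(y) == 0 or sst == 0:
            warnings.warn(f"circuit {col!r}: zero-variance truth, R^2 undefined")
            per[col] = np.nan
            continue
        sse = ((y - pred[col].to_numpy()) ** 2).sum()
        per[col] = 1.0 - sse / sst
    series = pd.Series(per)
    return ModelScore(per_circuit=series, global_r2=float(series.dropna().mean()))


def _cv_global_r2(
    X: pd.DataFrame, Y: pd.DataFrame, config: MORFConfig, cv: CVConfig
) -> float:
    """Mean held-out global R^2 over one k-fold pass (the HPO objective)."""
    splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    scores = []
    for train, test in splitter.split(X):
        model, _ = fit_morf(X.iloc[train], Y.iloc[train], config)
        scores.append(global_r2(model, X.iloc[test], Y.iloc[test]).global_r2)
    return float(np.mean(scores))


def optimize_hyperparams(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    space: dict[str, hpo.ParamSpec] | None = None,
    n_trials: int = 25,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> tuple[MORFConfig, list[hpo.Trial]]:
    """TPE search for the configuration maximizing cross-validated global R^2."""
    space = DEFAULT_SEARCH_SPACE if space is None else space
    cv = cv if cv is not None else CVConfig(seed=seed)

    def objective(params: dict) -> float:
        config = MORFConfig(seed=seed, **params)
        return _cv_global_r2(X, Y, config, cv)

    best_params, trials = hpo.maximize(objective, space, n_trials=n_trials, seed=seed)
    return MORFConfig(seed=seed, **best_params), trials


def repeated_cv_relevance(
    X: pd.DataFrame, Y: pd.DataFrame, config: MORFConfig, cv: CVConfig
) -> RelevanceProfile:
    """Repeated (N x k) cross-validated relevance distribution.

    For each fold the forest is refit on the training split; the fold's
    relevance vector and held-out per-circuit R^2 are recorded.  The point
    relevance comes from a full-data fit with the same configuration.
    """
    splitter = RepeatedKFold(
        n_splits=cv.k, n_repeats=cv.n_repeats, random_state=cv.seed
    )
    rel_rows, r2_rows = [], []
    for fold_idx, (train, test) in enumerate(splitter.split(X)):
        fold_config = MORFConfig(**{**config.to_dict(), "seed": config.seed + fold_idx})
        model, rel = fit_morf(X.iloc[train], Y.iloc[train], fold_config)
        rel_rows.append(rel)
        r2_rows.append(global_r2(model, X.iloc[test], Y.iloc[test]).per_circuit)
    _, point = fit_morf(X, Y, config)
    return RelevanceProfile(
        point=point,
        cv=pd.DataFrame(rel_rows).reset_index(drop=True),
        fold_r2=pd.DataFrame(r2_rows).reset_index(drop=True),
    )


def _ranking(values: pd.Series, genes: Sequence[str]) -> list[str]:
    """Genes sorted by descending value; ties broken by symbol."""
    sub = values.loc[list(genes)]
    return sorted(sub.index, key=lambda g: (-sub[g], g))


def select_stability_threshold(
    profile: RelevanceProfile, grid: Sequence[float]
) -> StabilityThreshold:
    """Smallest grid threshold whose selected gene set is rank-stable.

    A grid value t qualifies when, for S = {genes with mean CV relevance > t},
    (i) the full-fit (point) ranking of S equals the mean-CV ranking of S and
    (ii) every gene in S has mean - sd > t.  If no grid value qualifies the
    largest is returned with a warning.
    """
    if profile.cv.shape[1] == 0:
        raise ValueError("empty relevance profile")
    mean, sd = profile.mean, profile.sd
    for t in sorted(grid):
        selected = [g for g in mean.index if mean[g] > t]
        if _ranking(profile.point, selected) != _ranking(mean, selected):
            continue
        if any(mean[g] - sd[g] <= t for g in selected):
            continue
        return StabilityThreshold(
            value=float(t),
            n_selected=len(selected),
            selected=tuple(_ranking(mean, selected)),
        )
    t = float(max(grid))
    warnings.warn(
        f"no grid threshold gives a rank-stable selection; returning the largest ({t})"
    )
    selected = [g for g in mean.index if mean[g] > t]
    return StabilityThreshold(
        value=t, n_selected=len(selected), selected=tuple(_ranking(mean, selected))
    )


def relevant_gene_table(
    relevances: pd.Series | list[RelevanceFixtureRow],
    threshold: float | StabilityThreshold,
    kdt: Sequence[KDTRecord],
) -> pd.DataFrame:
    """Genes above the relevance threshold, ranked, with drug annotations.

    Accepts either a gene -> relevance Series (e.g. CV means) or packaged
    relevance-fixture rows.  Genes missing from the KDT table are kept with an
    empty drug set and a warning.
    """
    if isinstance(threshold, StabilityThreshold):
        threshold = threshold.value
    if isinstance(relevances, pd.Series):
        rel = relevances
    else:
        rel = pd.Series({r.gene.symbol: r.relevance for r in relevances})
    kdt_map = {canonical_symbol(r.gene.symbol): r for r in kdt}
    kept = rel[rel > threshold]
    order = sorted(kept.index, key=lambda g: (-kept[g], g))
    rows = []
    for gene in order:
        record = kdt_map.get(canonical_symbol(gene))
        if record is None:
            warnings.warn(f"gene {gene!r} missing from the KDT table")
            drugs, approved = (), ()
        else:
            drugs, approved = record.drug_ids, record.approved_ids
        rows.append(
            {
                "symbol": gene,
                "relevance": float(kept[gene]),
                "drug_ids": ";".join(drugs),
                "approved_ids": ";".join(approved),
                "n_drugs": len(drugs),
                "n_approved": len(approved),
            }
        )
    return pd.DataFrame(
        rows, columns=["symbol", "relevance", "drug_ids", "approved_ids",
                       "n_drugs", "n_approved"]
    )
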