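"""Per-scale random-forest ensembles scored by out-of-bag accuracy.

The scale-of-effect analysis fits, at every buffer scale, many independent
random forests on the 8 land-use area features of that scale only, and
summarises the distribution of their OOB accuracies (max / mean / min).  The
scale whose ensemble has the highest mean accuracy is the inferred scale of
effect; permutation importance of the best forest at that scale ranks the
land-use variables.

Two sampling rules are supported per tree:

``subsample70`` (default)
    Each tree trains on a ``train_fraction`` (default 70%) row subsample
    drawn *without* replacement, so its OOB set is exactly the remaining 30%.
``bootstrap``
    Classic bagging: n rows drawn with replacement, OOB ~ 36.8%.

Estimators follow the scikit-learn contract (``fit``, ``predict``,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) and compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .features import AREA_COLUMNS, BufferSpec

__all__ = [
    "ModelConfig",
    "SubsampleForestClassifier",
    "ScaleEnsembleClassifier",
    "ScaleEnsembleResult",
    "ScaleSummary",
    "fit_scale_ensemble",
    "summarize_scales",
    "variable_importance",
    "pearson_matrix",
]


@dataclass(frozen=True)
class ModelConfig:
    """Ensemble sizes and sampling rule.

    Defaults are the full study protocol (500 trees, 100 forests per scale,
    30% OOB via 70% without-replacement subsampling); reduced sizes are
    passed explicitly where runtime matters.
    """

    n_trees: int = 500
    n_models: int = 100
    oob_fraction: float = 0.30
    sampling: str = "subsample70"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_models < 1:
            raise ValueError("n_trees and n_models must be >= 1")
        if not 0 < self.oob_fraction < 1:
            raise ValueError("oob_fraction must be in (0, 1)")
        if self.sampling not in ("subsample70", "bootstrap"):
            raise ValueError("sampling must be 'subsample70' or 'bootstrap'")


class SubsampleForestClassifier(ClassifierMixin, BaseEstimator):
    """A single random forest with per-tree row subsampling and OOB scoring.

    Parameters
    ----------
    n_trees : int
        Trees per forest.
    sampling : {"subsample70", "bootstrap"}
        Row-sampling rule per tree (see module docstring).
    train_fraction : float
        Fraction of rows each tree trains on under ``subsample70``.
    max_features : str or int
        Feature subsampling per split, as in sklearn trees.
    random_state : int or None

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    oob_score_ : float
        OOB accuracy: majority vote over the trees for which each row was
        out-of-bag, scored against the true labels.
    oob_decision_counts_ : ndarray (n_samples, n_classes)
        OOB vote counts per row.
    """

    def __init__(
        self,
        n_trees: int = 500,
        sampling: str = "subsample70",
        train_fraction: float = 0.70,
        max_features="sqrt",
        random_state=None,
    ):
        self.n_trees = n_trees
        self.sampling = sampling
        self.train_fraction = train_fraction
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        X = np.ascontiguousarray(X, dtype=np.float32)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        n_sub = max(1, int(round(self.train_fraction * n)))
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)

        self.trees_ = []
        self.oob_indices_ = []
        votes = np.zeros((n, self.classes_.size), dtype=np.int32)
        all_idx = np.arange(n)
        for s in tree_seeds:
            if self.sampling == "subsample70":
                in_bag = rng.choice(n, size=n_sub, replace=False)
            elif self.sampling == "bootstrap":
                in_bag = rng.integers(0, n, size=n)
            else:
                raise ValueError(f"unknown sampling rule {self.sampling!r}")
            in_mask = np.zeros(n, dtype=bool)
            in_mask[in_bag] = True
            oob = all_idx[~in_mask]
            tree = DecisionTreeClassifier(
                max_features=self.max_features, random_state=int(s)
            )
            tree.fit(X[in_bag], y_enc[in_bag], check_input=False)
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
            if oob.size:
                pred = tree.predict(X[oob], check_input=False).astype(int)
                votes[oob, pred] += 1
        self.oob_decision_counts_ = votes
        voted = votes.sum(axis=1) > 0
        if not voted.any():
            raise RuntimeError("no sample was ever out-of-bag; increase n_trees")
        oob_pred = votes.argmax(axis=1)  # ties -> lowest class index (stable)
        self.oob_score_ = float(np.mean(oob_pred[voted] == y_enc[voted]))
        self._X_fit = X
        self._y_fit = y_enc
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "trees_")
        X = np.ascontiguousarray(check_array(X), dtype=np.float32)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=np.int32)
        for tree in self.trees_:
            pred = tree.predict(X, check_input=False).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        return self.classes_[votes.argmax(axis=1)]

    def permutation_importance_oob(
        self, random_state=None, normalize: bool = True
    ) -> np.ndarray:
        """Mean decrease in per-tree OOB accuracy when each feature is permuted.

        Breiman-style: for each tree, each feature column is shuffled among
        that tree's OOB rows and the accuracy drop recorded; importances are
        averaged over trees.  With ``normalize=True`` they are clipped at
        zero and rescaled to sum to 1 (uniform if every feature is
        uninformative) — note that this relative scale is only meaningful
        when some real signal exists; with ``normalize=False`` the raw
        accuracy-decrease scale is returned, which is the right scale for
        judging whether any variable matters at all.
        """
        check_is_fitted(self, "trees_")
        rng = np.random.default_rng(random_state)
        n_feat = self._X_fit.shape[1]
        drops = np.zeros(n_feat)
        n_used = 0
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if oob.size < 2:
                continue
            n_used += 1
            Xo = self._X_fit[oob]
            yo = self._y_fit[oob]
            base = np.mean(tree.predict(Xo, check_input=False).astype(int) == yo)
            for j in range(n_feat):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                acc = np.mean(tree.predict(Xp, check_input=False).astype(int) == yo)
                drops[j] += base - acc
        if n_used == 0:
            raise RuntimeError("no tree had an OOB set of size >= 2")
        drops = drops / n_used
        if not normalize:
            return drops
        drops = np.clip(drops, 0.0, None)
        total = drops.sum()
        if total <= 0:
            return np.full(n_feat, 1.0 / n_feat)
        return drops / total


class ScaleEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Repeated independent forests at one buffer scale.

    ``fit`` trains ``n_models`` forests with independent seed streams and
    records their OOB accuracies; prediction uses the best (max-OOB) forest.

    Attributes
    ----------
    accuracies_ : ndarray (n_models,)
        Per-forest OOB accuracy.
    best_index_ : int
        First index attaining the maximum accuracy (stable tie-break).
    best_forest_ : SubsampleForestClassifier
    feature_importances_ : ndarray (n_features,)
        Normalised OOB permutation importance of the best forest.
    model_seeds_ : ndarray (n_models,)
    """

    def __init__(
        self,
        n_models: int = 100,
        n_trees: int = 500,
        sampling: str = "subsample70",
        oob_fraction: float = 0.30,
        random_state=None,
        compute_importance: bool = True,
    ):
        self.n_models = n_models
        self.n_trees = n_trees
        self.sampling = sampling
        self.oob_fraction = oob_fraction
        self.random_state = random_state
        self.compute_importance = compute_importance

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("both labels must be present")
        if counts.min() < 10:
            raise ValueError("need at least 10 rows per class")
        ss = np.random.SeedSequence(self.random_state)
        self.model_seeds_ = ss.generate_state(self.n_models + 1) % (2**31)
        accs = np.empty(self.n_models)
        best_idx = -1
        best_acc = -np.inf
        best_forest = None
        for i in range(self.n_models):
            forest = SubsampleForestClassifier(
                n_trees=self.n_trees,
                sampling=self.sampling,
                train_fraction=1.0 - self.oob_fraction,
                random_state=int(self.model_seeds_[i]),
            ).fit(X, y)
            accs[i] = forest.oob_score_
            if accs[i] > best_acc:
                best_acc, best_idx, best_forest = accs[i], i, forest
        self.accuracies_ = accs
        self.best_index_ = int(best_idx)
        self.best_forest_ = best_forest
        self.classes_ = best_forest.classes_
        if self.compute_importance:
            raw = best_forest.permutation_importance_oob(
                random_state=int(self.model_seeds_[-1]), normalize=False
            )
            self.feature_importances_raw_ = raw
            clipped = np.clip(raw, 0.0, None)
            total = clipped.sum()
            self.feature_importances_ = (
                clipped / total if total > 0 else np.full(raw.size, 1.0 / raw.size)
            )
        else:
            self.feature_importances_raw_ = None
            self.feature_importances_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "best_forest_")
        return self.best_forest_.predict(X)


@dataclass
class ScaleEnsembleResult:
    """OOB-accuracy distribution and best-model importances at one scale."""

    spec: BufferSpec
    accuracies: np.ndarray
    best_model_importances: np.ndarray
    best_index: int
    seeds: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(AREA_COLUMNS))
    best_model_importances_raw: np.ndarray | None = None

    @property
    def max_accuracy(self) -> float:
        return float(self.accuracies.max())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def min_accuracy(self) -> float:
        return float(self.accuracies.min())


def _spec_subset(features: pd.DataFrame, spec: BufferSpec):
    sub = features[
        (features["inner_m"] == spec.inner) & (features["outer_m"] == spec.outer)
    ]
    if sub.empty:
        raise ValueError(f"feature table has no rows for buffer {spec.label}")
    X = sub[AREA_COLUMNS].to_numpy(dtype=float)
    y = sub["label"].to_numpy(dtype=int)
    ids = sub["point_id"].to_numpy()
    return X, y, ids


def fit_scale_ensemble(
    features: pd.DataFrame, spec: BufferSpec, config: ModelConfig
) -> ScaleEnsembleResult:
    """Fit the repeated-forest ensemble on one buffer scale of a feature table."""
    X, y, _ = _spec_subset(features, spec)
    est = ScaleEnsembleClassifier(
        n_models=config.n_models,
        n_trees=config.n_trees,
        sampling=config.sampling,
        oob_fraction=config.oob_fraction,
        random_state=config.seed,
    ).fit(X, y)
    return ScaleEnsembleResult(
        spec=spec,
        accuracies=est.accuracies_,
        best_model_importances=est.feature_importances_,
        best_index=est.best_index_,
        seeds=est.model_seeds_[:-1],
        best_model_importances_raw=est.feature_importances_raw_,
    )


@dataclass
class ScaleSummary:
    """Accuracy summary over scales plus the argmax-by-mean scale."""

    table: pd.DataFrame
    best_spec: BufferSpec
    tied: bool


def summarize_scales(results: list[ScaleEnsembleResult]) -> ScaleSummary:
    """Max/mean/min OOB accuracy per scale and the best-mean scale.

    Ties on mean accuracy are broken toward the smallest outer radius and
    reported via ``tied``.
    """
    if not results:
        raise ValueError("no ensemble results to summarize")
    rows = [
        {
            "scale": r.spec.label,
            "inner_m": r.spec.inner,
            "outer_m": r.spec.outer,
            "max_acc": r.max_accuracy,
            "mean_acc": r.mean_accuracy,
            "min_acc": r.min_accuracy,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    means = table["mean_acc"].to_numpy()
    best_mean = means.max()
    is_best = np.isclose(means, best_mean)
    tied = int(is_best.sum()) > 1
    cand = table[is_best].sort_values(["outer_m", "inner_m"])
    best_row = cand.iloc[0]
    best_spec = BufferSpec(outer=float(best_row["outer_m"]), inner=float(best_row["inner_m"]))
    return ScaleSummary(table=table, best_spec=best_spec, tied=tied)


def variable_importance(result: ScaleEnsembleResult) -> pd.DataFrame:
    """Best-model permutation importances with class names, ranked.

    Returns a frame in land-use code order with columns
    ``variable, importance, rank`` (rank 1 = most important).
    """
    imp = np.asarray(result.best_model_importances, dtype=float)
    if imp.size != len(result.feature_names):
        raise ValueError("importance vector does not match feature names")
    order = np.argsort(-imp, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, imp.size + 1)
    return pd.DataFrame(
        {"variable": result.feature_names, "importance": imp, "rank": rank}
    )


def pearson_matrix(features: pd.DataFrame, spec: BufferSpec | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of the 8 class-area variables at one scale.

    Zero-variance columns give missing (NaN) off-diagonal entries, never 0;
    the diagonal is 1 by convention.
    """
    if spec is not None:
        X, _, _ = _spec_subset(features, spec)
    else:
        X = features[AREA_COLUMNS].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=AREA_COLUMNS, columns=AREA_COLUMNS)
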