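"""Boosted regression trees for presence/absence data.

Stagewise gradient boosting with Bernoulli (binomial deviance) loss: the
model is an additive expansion in shallow regression trees on the log-odds
scale. Each stage fits a tree to the pointwise gradient ``y - p`` on a
random subsample (the bag), replaces terminal-node values by a single Newton
step ``sum(y - p) / sum(p (1 - p))``, shrinks by the learning rate and adds
the tree to the model. The optimal number of trees is chosen by ten-fold
cross-validation grown in fixed increments, in the spirit of ``gbm.step``
from the dismo/gbm ecology toolchain.

Single-tree fitting is delegated to :class:`sklearn.tree.DecisionTreeRegressor`
(exhaustive variance-reduction splits); the boosting recursion, Newton
terminal updates, cross-validated tree selection, relative influence and
partial dependence are implemented here.

Categorical predictors are handled by per-stage target-mean ordering: each
level is encoded by the mean boosting residual of its bagged rows, which for
the squared-error split criterion yields the same optimal binary partition
as an exhaustive subset search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "BRTConfig",
    "BoostedTreesClassifier",
    "fit_brt",
    "predict",
    "relative_influence",
    "partial_dependence",
    "compute_auc",
    "bernoulli_deviance",
]

logger = logging.getLogger(__name__)


@dataclass
class BRTConfig:
    """Hyper-parameters of a boosted-trees fit.

    learning_rate : shrinkage applied to every tree's contribution.
    tree_complexity : maximum tree depth (interaction order).
    bag_fraction : fraction of rows subsampled (without replacement) per stage.
    n_folds : cross-validation folds for tree-count selection.
    step_size : trees added per cross-validation increment.
    max_trees : hard cap on the number of trees.
    min_obs_in_node : minimum rows per terminal node.
    patience : CV increments without improvement before stopping early.
    seed : master seed for bagging and fold assignment.
    """

    learning_rate: float = 0.01
    tree_complexity: int = 5
    bag_fraction: float = 0.75
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 1000
    min_obs_in_node: int = 10
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("tree_complexity", "step_size", "max_trees", "min_obs_in_node", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, ``-2 * mean(y log p + (1-y) log(1-p))``."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def compute_auc(labels, scores) -> float:
    """ROC AUC via the Mann-Whitney rank statistic.

    ``P(score_pos > score_neg) + 0.5 * P(tie)``, exact under ties through
    midranks. Requires both classes present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# internal tree record
# ---------------------------------------------------------------------------


class _TreeRecord:
    """One boosted stage: tree topology, Newton leaf values, split records."""

    __slots__ = ("feature", "threshold", "left", "right", "leaf_value", "improvement", "encodings")

    def __init__(self, feature, threshold, left, right, leaf_value, improvement, encodings):
        self.feature = feature          # split var per node, -2 for leaves
        self.threshold = threshold
        self.left = left
        self.right = right
        self.leaf_value = leaf_value    # Newton log-odds step per node (leaves)
        self.improvement = improvement  # squared-error improvement per node
        self.encodings = encodings      # {col_index: (levels, codes, fallback)}

    def encode(self, X: np.ndarray) -> np.ndarray:
        if not self.encodings:
            return X
        X = X.copy()
        for col, (levels, codes, fallback) in self.encodings.items():
            idx = np.searchsorted(levels, X[:, col])
            idx_c = np.clip(idx, 0, len(levels) - 1)
            known = levels[idx_c] == X[:, col]
            if not known.all():
                logger.debug(
                    "%d rows with unseen level in column %d routed with the "
                    "heaviest training level", int((~known).sum()), col,
                )
            X[:, col] = np.where(known, codes[idx_c], fallback)
        return X

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Unshrunk Newton leaf value for every row (vectorized traversal)."""
        Xe = self.encode(X)
        node = np.zeros(len(Xe), dtype=np.int64)
        rows = np.arange(len(Xe))
        while True:
            feat = self.feature[node]
            internal = feat >= 0
            if not internal.any():
                break
            x = Xe[rows, np.where(internal, feat, 0)]
            go_left = x <= self.threshold[node]
            nxt = np.where(go_left, self.left[node], self.right[node])
            node = np.where(internal, nxt, node)
        return self.leaf_value[node]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_value": self.leaf_value.tolist(),
            "improvement": self.improvement.tolist(),
            "encodings": {
                str(col): {
                    "levels": levels.tolist(),
                    "codes": codes.tolist(),
                    "fallback": float(fallback),
                }
                for col, (levels, codes, fallback) in self.encodings.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_TreeRecord":
        enc = {
            int(col): (
                np.asarray(e["levels"], dtype=float),
                np.asarray(e["codes"], dtype=float),
                float(e["fallback"]),
            )
            for col, e in d["encodings"].items()
        }
        return cls(
            np.asarray(d["feature"], dtype=np.int64),
            np.asarray(d["threshold"], dtype=float),
            np.asarray(d["left"], dtype=np.int64),
            np.asarray(d["right"], dtype=np.int64),
            np.asarray(d["leaf_value"], dtype=float),
            np.asarray(d["improvement"], dtype=float),
            enc,
        )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class BoostedTreesClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted regression trees for binary presence/absence.

    Parameters mirror :class:`BRTConfig`. ``select_trees='cv'`` chooses the
    tree count by stratified k-fold cross-validation (held-out deviance
    minimum, grown in ``step_size`` increments with early stopping);
    ``select_trees='fixed'`` uses ``max_trees`` directly.

    Attributes (after :meth:`fit`)
    ------------------------------
    intercept_ : float
        Log-odds of the training prevalence.
    trees_ : list of tree records
        The boosted stages actually used for prediction (``n_trees_`` of them).
    n_trees_ : int
        Selected number of trees.
    cv_profile_ : DataFrame or None
        Mean held-out deviance per candidate tree count.
    train_deviance_path_ : ndarray
        Mean training deviance after each stage of the final fit.
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        tree_complexity: int = 5,
        bag_fraction: float = 0.75,
        n_folds: int = 10,
        step_size: int = 50,
        max_trees: int = 1000,
        min_obs_in_node: int = 10,
        patience: int = 3,
        select_trees: str = "cv",
        categorical_features: tuple | list | None = None,
        random_state: int | None = 0,
    ):
        self.learning_rate = learning_rate
        self.tree_complexity = tree_complexity
        self.bag_fraction = bag_fraction
        self.n_folds = n_folds
        self.step_size = step_size
        self.max_trees = max_trees
        self.min_obs_in_node = min_obs_in_node
        self.patience = patience
        self.select_trees = select_trees
        self.categorical_features = categorical_features
        self.random_state = random_state

    # -- configuration plumbing -------------------------------------------

    @classmethod
    def from_config(cls, config: BRTConfig, **overrides) -> "BoostedTreesClassifier":
        kw = dict(
            learning_rate=config.learning_rate,
            tree_complexity=config.tree_complexity,
            bag_fraction=config.bag_fraction,
            n_folds=config.n_folds,
            step_size=config.step_size,
            max_trees=config.max_trees,
            min_obs_in_node=config.min_obs_in_node,
            patience=config.patience,
            random_state=config.seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def _validate_X(self, X, reset: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = [f"x{i}" for i in range(arr.shape[1])]
        if reset:
            self.feature_names_in_ = np.asarray(names, dtype=object)
            self.n_features_in_ = arr.shape[1]
        elif arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} features, expected {self.n_features_in_}"
            )
        return arr

    def _resolve_categorical(self, X) -> tuple[int, ...]:
        spec = self.categorical_features
        if spec is None:
            if isinstance(X, pd.DataFrame):
                return tuple(
                    i for i, c in enumerate(X.columns)
                    if isinstance(X[c].dtype, pd.CategoricalDtype)
                )
            return ()
        names = list(self.feature_names_in_)
        out = []
        for c in spec:
            out.append(names.index(c) if isinstance(c, str) else int(c))
        return tuple(out)

    # -- boosting recursion ------------------------------------------------

    def _grow(self, X, y, n_new, F, rng, trees, tree_seeds):
        """Append ``n_new`` stages to ``trees`` updating log-odds ``F`` in place."""
        n = len(y)
        n_bag = max(2, int(round(self.bag_fraction * n)))
        for _ in range(n_new):
            p = expit(F)
            z = y - p
            w = p * (1 - p)
            if self.bag_fraction < 1:
                bag = rng.choice(n, size=n_bag, replace=False)
            else:
                bag = np.arange(n)
            Xb, zb, wb = X[bag], z[bag], w[bag]
            encodings = {}
            if self._cat_idx_:
                Xb = Xb.copy()
                for col in self._cat_idx_:
                    vals = Xb[:, col]
                    levels, inv = np.unique(vals, return_inverse=True)
                    sums = np.bincount(inv, weights=zb)
                    counts = np.bincount(inv)
                    codes = sums / counts
                    fallback = codes[int(np.argmax(counts))]
                    encodings[col] = (levels, codes, float(fallback))
                    Xb[:, col] = codes[inv]
            tree = DecisionTreeRegressor(
                max_depth=self.tree_complexity,
                min_samples_leaf=self.min_obs_in_node,
                random_state=int(tree_seeds.integers(2**31 - 1)),
            )
            tree.fit(Xb, zb)
            t = tree.tree_
            leaf_id = tree.apply(Xb)
            # Newton step per terminal node: sum(y-p) / sum(p(1-p))
            num = np.bincount(leaf_id, weights=zb, minlength=t.node_count)
            den = np.bincount(leaf_id, weights=wb, minlength=t.node_count)
            gamma = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
            # squared-error improvement of every internal split (bagged rows)
            improvement = np.zeros(t.node_count)
            internal = t.children_left >= 0
            if internal.any():
                idx = np.flatnonzero(internal)
                improvement[idx] = (
                    t.weighted_n_node_samples[idx] * t.impurity[idx]
                    - t.weighted_n_node_samples[t.children_left[idx]]
                    * t.impurity[t.children_left[idx]]
                    - t.weighted_n_node_samples[t.children_right[idx]]
                    * t.impurity[t.children_right[idx]]
                )
                improvement = np.maximum(improvement, 0.0)
            rec = _TreeRecord(
                t.feature.astype(np.int64).copy(),
                t.threshold.copy(),
                t.children_left.astype(np.int64).copy(),
                t.children_right.astype(np.int64).copy(),
                gamma,
                improvement,
                encodings,
            )
            trees.append(rec)
            F += self.learning_rate * rec.predict_raw(X)

    # -- public API --------------------------------------------------------

    def fit(self, X, y):
        arr = self._validate_X(X, reset=True)
        self._cat_idx_ = self._resolve_categorical(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        if not np.isfinite(arr).all():
            raise ValueError("covariates must be finite")
        self.classes_ = classes
        yb = (y == classes[1]).astype(float)
        if len(yb) < 2 * 1:
            raise ValueError("too few rows")
        seed_seq = np.random.SeedSequence(self.random_state)
        cv_seq, fit_seq = seed_seq.spawn(2)

        if self.select_trees == "cv":
            if len(yb) < self.n_folds:
                raise ValueError("fewer rows than folds")
            self.cv_profile_ = self._cv_select(arr, yb, cv_seq)
            self.n_trees_ = int(
                self.cv_profile_.loc[self.cv_profile_["cv_deviance"].idxmin(), "n_trees"]
            )
        elif self.select_trees == "fixed":
            self.cv_profile_ = None
            self.n_trees_ = self.max_trees
        else:
            raise ValueError("select_trees must be 'cv' or 'fixed'")

        p_bar = yb.mean()
        self.intercept_ = _logit(p_bar)
        F = np.full(len(yb), self.intercept_)
        rng = np.random.default_rng(fit_seq)
        tree_seeds = np.random.default_rng(fit_seq.spawn(1)[0])
        self.trees_: list[_TreeRecord] = []
        path = []
        # grow stage by stage, recording the training deviance path
        for _ in range(self.n_trees_):
            self._grow(arr, yb, 1, F, rng, self.trees_, tree_seeds)
            path.append(bernoulli_deviance(yb, expit(F)))
        self.train_deviance_path_ = np.asarray(path)
        self._train_means_ = np.nanmean(arr, axis=0)
        self._train_modes_ = {}
        for col in self._cat_idx_:
            levels, counts = np.unique(arr[:, col], return_counts=True)
            self._train_modes_[col] = float(levels[np.argmax(counts)])
        self._X_train_ = arr
        return self

    def _cv_select(self, X, y, seed_seq) -> pd.DataFrame:
        counts = list(range(self.step_size, self.max_trees + 1, self.step_size))
        if not counts or counts[-1] != self.max_trees:
            counts.append(self.max_trees)
        children = seed_seq.spawn(self.n_folds + 1)
        fold_seed, grow_seeds = children[0], children[1:]
        skf = StratifiedKFold(
            n_splits=self.n_folds,
            shuffle=True,
            random_state=int(fold_seed.generate_state(1)[0] % (2**31 - 1)),
        )
        state = []
        for (tr, va), gs in zip(skf.split(X, y), grow_seeds):
            gs_children = gs.spawn(2)
            icpt = _logit(y[tr].mean())
            state.append({
                "tr": tr, "va": va,
                "F_tr": np.full(len(tr), icpt),
                "F_va": np.full(len(va), icpt),
                "trees": [],
                "rng": np.random.default_rng(gs_children[0]),
                "tree_seeds": np.random.default_rng(gs_children[1]),
            })
        profile: list[tuple[int, float]] = []
        prev = 0
        for i, c in enumerate(counts):
            devs = []
            for st in state:
                self._grow(X[st["tr"]], y[st["tr"]], c - prev, st["F_tr"],
                           st["rng"], st["trees"], st["tree_seeds"])
                for rec in st["trees"][prev:]:
                    st["F_va"] += self.learning_rate * rec.predict_raw(X[st["va"]])
                devs.append(bernoulli_deviance(y[st["va"]], expit(st["F_va"])))
            prev = c
            profile.append((c, float(np.mean(devs))))
            best_i = int(np.argmin([d for _, d in profile]))
            if i - best_i >= self.patience:
                break
        return pd.DataFrame(profile, columns=["n_trees", "cv_deviance"])

    def decision_function(self, X) -> np.ndarray:
        arr = self._validate_X(X, reset=False)
        F = np.full(len(arr), self.intercept_)
        for rec in self.trees_[: self.n_trees_]:
            F += self.learning_rate * rec.predict_raw(arr)
        return F

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    # -- interpretation ----------------------------------------------------

    def relative_influence(self) -> pd.Series:
        """Per-variable percentage of total split improvement, summing to 100."""
        totals = np.zeros(self.n_features_in_)
        for rec in self.trees_[: self.n_trees_]:
            internal = rec.feature >= 0
            np.add.at(totals, rec.feature[internal], rec.improvement[internal])
        if totals.sum() <= 0:
            raise ValueError("model has no splits; relative influence undefined")
        ri = 100.0 * totals / totals.sum()
        return pd.Series(ri, index=self.feature_names_in_).sort_values(ascending=False)

    def partial_dependence(self, variable, grid=None, mode: str = "fixed") -> pd.DataFrame:
        """Model response over one covariate, on the probability scale.

        ``mode='fixed'`` holds the other covariates at their training means
        (categorical at the mode); ``mode='average'`` averages predictions
        over the training rows with the target covariate replaced.
        """
        names = list(self.feature_names_in_)
        if variable not in names:
            raise KeyError(f"unknown variable {variable!r}")
        col = names.index(variable)
        if grid is None:
            x = self._X_train_[:, col]
            if col in self._cat_idx_:
                grid = np.unique(x)
            else:
                grid = np.linspace(x.min(), x.max(), 100)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty evaluation grid")
        grid = np.sort(grid)
        if mode == "fixed":
            base = self._train_means_.copy()
            for c, m in self._train_modes_.items():
                base[c] = m
            rows = np.tile(base, (len(grid), 1))
            rows[:, col] = grid
            resp = expit(self._raw(rows))
        elif mode == "average":
            resp = np.empty(len(grid))
            for i, g in enumerate(grid):
                rows = self._X_train_.copy()
                rows[:, col] = g
                resp[i] = expit(self._raw(rows)).mean()
        else:
            raise ValueError("mode must be 'fixed' or 'average'")
        return pd.DataFrame({variable: grid, "response": resp})

    def _raw(self, arr: np.ndarray) -> np.ndarray:
        F = np.full(len(arr), self.intercept_)
        for rec in self.trees_[: self.n_trees_]:
            F += self.learning_rate * rec.predict_raw(arr)
        return F

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "params": self.get_params(),
            "intercept": self.intercept_,
            "n_trees": self.n_trees_,
            "classes": self.classes_.tolist(),
            "feature_names": list(self.feature_names_in_),
            "categorical_idx": list(self._cat_idx_),
            "train_means": self._train_means_.tolist(),
            "train_modes": {str(k): v for k, v in self._train_modes_.items()},
            "trees": [t.to_dict() for t in self.trees_],
        })

    @classmethod
    def from_json(cls, payload: str) -> "BoostedTreesClassifier":
        d = json.loads(payload)
        params = d["params"]
        if params.get("categorical_features") is not None:
            params["categorical_features"] = tuple(params["categorical_features"])
        est = cls(**params)
        est.intercept_ = float(d["intercept"])
        est.n_trees_ = int(d["n_trees"])
        est.classes_ = np.asarray(d["classes"])
        est.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        est.n_features_in_ = len(d["feature_names"])
        est._cat_idx_ = tuple(d["categorical_idx"])
        est._train_means_ = np.asarray(d["train_means"], dtype=float)
        est._train_modes_ = {int(k): float(v) for k, v in d["train_modes"].items()}
        est.trees_ = [_TreeRecord.from_dict(t) for t in d["trees"]]
        est.cv_profile_ = None
        est._X_train_ = np.tile(est._train_means_, (1, 1))
        return est


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
# thin functional wrappers (spec-level operations)
# ---------------------------------------------------------------------------


def fit_brt(table: pd.DataFrame, config: BRTConfig, feature_columns=None,
            select_trees: str = "cv") -> BoostedTreesClassifier:
    """Fit a boosted-trees model on a presence/absence cell table.

    ``table`` must carry a ``label`` column (1 = presence). Feature columns
    default to everything except bookkeeping columns; ``soil_class`` is
    treated as categorical.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("cell_id", "row", "col", "label")
        ]
    from .occurrences import CATEGORICAL_COVARIATES

    cats = tuple(c for c in feature_columns if c in CATEGORICAL_COVARIATES)
    est = BoostedTreesClassifier.from_config(
        config, select_trees=select_trees, categorical_features=cats or None
    )
    est.fit(table[feature_columns], table["label"].to_numpy())
    return est


def predict(model: BoostedTreesClassifier, covariates) -> np.ndarray:
    """Suitability probabilities for rows of covariates."""
    return model.predict_proba(covariates)[:, 1]


def relative_influence(model: BoostedTreesClassifier) -> pd.Series:
    return model.relative_influence()


def partial_dependence(model: BoostedTreesClassifier, variable, grid=None,
                       mode: str = "fixed") -> pd.DataFrame:
    return model.partial_dependence(variable, grid=grid, mode=mode)
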