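"""Bootstrapped BRT ensemble: mean suitability, per-pixel SD, AUC summaries.

Thirty (by default) boosted-tree models are fitted to independent
label-stratified 50/50 train/test splits of the presence/pseudo-absence
table. Each member reports a training AUC and a held-out test AUC and
predicts suitability over the full covariate stack; the ensemble aggregates
the per-pixel mean (the suitability map) and population standard deviation
(the uncertainty map). A with-replacement row bootstrap of the training
half is available behind ``bootstrap_rows=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split

from .brt import BRTConfig, BoostedTreesClassifier, compute_auc
from .occurrences import CATEGORICAL_COVARIATES
from .raster import EnvStack, Raster

__all__ = ["EnsembleResult", "SuitabilityEnsemble", "run_ensemble"]


@dataclass
class EnsembleResult:
    """Aggregated ensemble outputs."""

    mean_suitability: Raster
    sd_map: Raster
    train_aucs: list[float]
    test_aucs: list[float]
    n_trees: list[int]
    seed: int

    def auc_summary(self) -> dict[str, float]:
        """Mean and population SD of the per-member AUC lists."""
        return {
            "train_auc_mean": float(np.mean(self.train_aucs)),
            "train_auc_sd": float(np.std(self.train_aucs)),
            "test_auc_mean": float(np.mean(self.test_aucs)),
            "test_auc_sd": float(np.std(self.test_aucs)),
        }


class SuitabilityEnsemble(BaseEstimator):
    """Ensemble of boosted-tree suitability models (sklearn-style).

    fit(X, y) draws ``n_models`` stratified ``train_fraction`` splits, fits
    one :class:`BoostedTreesClassifier` per split and stores the members;
    ``predict_stack`` maps a raster stack to mean/SD suitability rasters.
    """

    def __init__(
        self,
        config: BRTConfig | None = None,
        n_models: int = 30,
        train_fraction: float = 0.5,
        bootstrap_rows: bool = False,
        select_trees: str = "cv",
        tile_rows: int = 256,
        random_state: int | None = 0,
    ):
        self.config = config
        self.n_models = n_models
        self.train_fraction = train_fraction
        self.bootstrap_rows = bootstrap_rows
        self.select_trees = select_trees
        self.tile_rows = tile_rows
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2 (ensemble SD undefined otherwise)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        cfg = self.config or BRTConfig()
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        cats = tuple(c for c in X.columns if c in CATEGORICAL_COVARIATES) or None
        seed_seq = np.random.SeedSequence(self.random_state)
        self.members_: list[BoostedTreesClassifier] = []
        self.train_aucs_: list[float] = []
        self.test_aucs_: list[float] = []
        self.n_trees_: list[int] = []
        for child in seed_seq.spawn(self.n_models):
            split_seed, boot_seed, fit_seed = (
                int(s.generate_state(1)[0] % (2**31 - 1)) for s in child.spawn(3)
            )
            idx_train, idx_test = train_test_split(
                np.arange(len(y)),
                train_size=self.train_fraction,
                stratify=y,
                random_state=split_seed,
            )
            if self.bootstrap_rows:
                rng = np.random.default_rng(boot_seed)
                # resample until both classes survive (logged-free fast loop)
                while True:
                    take = rng.choice(idx_train, size=len(idx_train), replace=True)
                    if len(np.unique(y[take])) == 2:
                        break
                idx_train = take
            est = BoostedTreesClassifier.from_config(
                cfg,
                select_trees=self.select_trees,
                categorical_features=cats,
                random_state=fit_seed,
            )
            est.fit(X.iloc[idx_train], y[idx_train])
            p_train = est.predict_proba(X.iloc[idx_train])[:, 1]
            p_test = est.predict_proba(X.iloc[idx_test])[:, 1]
            self.members_.append(est)
            self.train_aucs_.append(compute_auc(y[idx_train], p_train))
            self.test_aucs_.append(compute_auc(y[idx_test], p_test))
            self.n_trees_.append(est.n_trees_)
        return self

    def predict_members(self, X) -> np.ndarray:
        """(n_models, n_rows) member suitability predictions."""
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        return np.vstack([m.predict_proba(X)[:, 1] for m in self.members_])

    def predict_stack(self, stack: EnvStack) -> tuple[Raster, Raster]:
        """Mean and population-SD suitability rasters over a covariate stack.

        Prediction is streamed in blocks of ``tile_rows`` raster rows; the
        output is independent of the tiling.
        """
        missing = [n for n in self.feature_names_in_ if n not in stack]
        if missing:
            raise KeyError(f"stack is missing layers {missing}")
        grid = stack.grid
        valid = np.ones(grid.shape, dtype=bool)
        for name in self.feature_names_in_:
            valid &= stack[name].valid
        mean = np.full(grid.shape, np.nan)
        sd = np.full(grid.shape, np.nan)
        for r0 in range(0, grid.rows, self.tile_rows):
            r1 = min(r0 + self.tile_rows, grid.rows)
            vmask = valid[r0:r1]
            if not vmask.any():
                continue
            cols = {
                name: np.asarray(stack[name].values[r0:r1], dtype=float)[vmask]
                for name in self.feature_names_in_
            }
            tile = pd.DataFrame(cols)
            preds = self.predict_members(tile)
            mean[r0:r1][vmask] = preds.mean(axis=0)
            sd[r0:r1][vmask] = preds.std(axis=0, ddof=0)
        return (
            Raster(mean, grid, name="mean_suitability"),
            Raster(sd, grid, name="suitability_sd"),
        )

    def relative_influence(self) -> pd.DataFrame:
        """Per-member relative influence plus ensemble mean, sorted descending."""
        ri = pd.DataFrame([m.relative_influence() for m in self.members_])
        out = pd.DataFrame({"mean": ri.mean(), "sd": ri.std(ddof=0)})
        return out.sort_values("mean", ascending=False)


def run_ensemble(
    table: pd.DataFrame,
    stack: EnvStack,
    config: BRTConfig | None = None,
    n_models: int = 30,
    train_fraction: float = 0.5,
    seed: int = 0,
    feature_columns=None,
    select_trees: str = "cv",
) -> tuple[EnsembleResult, SuitabilityEnsemble]:
    """Fit the ensemble on a cell table and predict over the stack."""
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("cell_id", "row", "col", "label")
        ]
    ens = SuitabilityEnsemble(
        config=config,
        n_models=n_models,
        train_fraction=train_fraction,
        select_trees=select_trees,
        random_state=seed,
    )
    ens.fit(table[feature_columns], table["label"].to_numpy())
    mean, sd = ens.predict_stack(stack)
    result = EnsembleResult(
        mean_suitability=mean,
        sd_map=sd,
        train_aucs=ens.train_aucs_,
        test_aucs=ens.test_aucs_,
        n_trees=ens.n_trees_,
        seed=seed,
    )
    return result, ens
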