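"""Random-forest baseline ranker (Breiman OOB permutation importance).

The comparison algorithm: a bagged regression forest where each feature's
importance is the mean, over trees, of the increase in out-of-bag MSE
when that feature's values are permuted within the tree's OOB rows
(permuted minus untouched, so positive = informative).  Ranking proceeds
as in the boosted method: screen to the top 20 by importance, then
backward-eliminate with per-step refits.

The bagging loop is explicit (bootstrap with replacement, one sklearn
``DecisionTreeRegressor`` per tree) so per-tree OOB row sets are known
exactly.  Trees use the classical regression-forest settings mtry = p/3
and minimum node size 5.  The per-tree RNG scheme is documented and
deterministic: tree t draws its bootstrap, its split seed and its
permutations from ``default_rng(derive_seed(seed, "tree", t))``, in that
order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from ._seeds import derive_seed
from .profiles import ChromatinMatrix, FeatureMetadata, MutationProfile
from .ranking import (
    TOP_K,
    ImportanceVector,
    RankingResult,
    ReproducibilityReport,
    _argmin_feature,
    assign_origin,
    select_top_k,
)

logger = logging.getLogger(__name__)


@dataclass
class ForestParams:
    """Forest hyperparameters; n_trees defaults to the published 1000."""

    n_trees: int = 1000
    n_repeats: int = 1000
    seed: int = 0
    max_features: float = 1 / 3  # fraction of features tried per split (mtry)
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees >= 1 required")

    def to_dict(self) -> dict:
        return {
            "algorithm": "forest",
            "n_trees": self.n_trees,
            "seed": self.seed,
            "max_features": self.max_features,
            "min_samples_leaf": self.min_samples_leaf,
        }


def _rf_importance_arrays(
    Xv: np.ndarray, yv: np.ndarray, params: ForestParams, seed: int
) -> np.ndarray:
    """Raw Breiman importance per feature column.

    For each tree: bootstrap rows with replacement, fit, predict the OOB
    rows untouched and once per feature with that column permuted (one
    batched predict call per tree), accumulate MSE(permuted) - MSE(oob).
    Trees with no OOB rows are skipped with a warning.
    """
    n, p = Xv.shape
    imp = np.zeros(p)
    used = 0
    for t in range(params.n_trees):
        rng = np.random.default_rng(derive_seed(seed, "tree", t))
        boot = rng.integers(0, n, n)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = np.flatnonzero(~inbag)
        tree_seed = int(rng.integers(2**31))
        if oob.size == 0:
            warnings.warn(f"tree {t}: no out-of-bag rows; skipped for importance")
            continue
        tree = DecisionTreeRegressor(
            max_features=params.max_features,
            min_samples_leaf=params.min_samples_leaf,
            random_state=tree_seed,
        ).fit(Xv[boot], yv[boot])
        Xo = Xv[oob]
        m = oob.size
        stack = np.tile(Xo, (p + 1, 1))
        for j in range(p):
            stack[(j + 1) * m : (j + 2) * m, j] = Xo[rng.permutation(m), j]
        pred = tree.predict(stack)
        yo = yv[oob]
        base = np.mean((pred[:m] - yo) ** 2)
        for j in range(p):
            imp[j] += np.mean((pred[(j + 1) * m : (j + 2) * m] - yo) ** 2) - base
        used += 1
    if used == 0:
        raise ValueError("no tree had out-of-bag rows; increase n")
    return imp / used


def _as_xy(y: MutationProfile, X: ChromatinMatrix):
    yv = y.counts.astype(np.float32)
    Xv = X.values.to_numpy(dtype=np.float32)
    if len(yv) != Xv.shape[0]:
        raise ValueError(f"profile length {len(yv)} != matrix rows {Xv.shape[0]}")
    return yv, Xv


def rf_importance(
    y: MutationProfile, X: ChromatinMatrix, params: ForestParams, seed: int | None = None
) -> ImportanceVector:
    """Mean OOB permutation importance over the forest (may be negative)."""
    if X.values.shape[1] < 2:
        raise ValueError("need at least 2 features")
    yv, Xv = _as_xy(y, X)
    imp = _rf_importance_arrays(Xv, yv, params, params.seed if seed is None else seed)
    return ImportanceVector(
        pd.Series(imp, index=X.feature_ids), metric="oob_permutation_mse"
    )


def rf_backward_eliminate(
    y: MutationProfile,
    X: ChromatinMatrix,
    params: ForestParams,
    top_k: int = TOP_K,
    screen: bool = True,
) -> RankingResult:
    """Screen to ``top_k`` by forest importance, then backward-eliminate.

    ``screen=False`` eliminates from the full feature set instead.  The
    elimination step seed is ``derive_seed(params.seed, "rf-eliminate",
    step)`` so each step is independently reproducible.
    """
    yv, Xv = _as_xy(y, X)
    feature_ids = list(X.feature_ids)
    if not feature_ids:
        raise ValueError("empty feature set")
    if len(feature_ids) == 1:
        only = ImportanceVector(
            pd.Series([0.0], index=feature_ids), metric="oob_permutation_mse"
        )
        return RankingResult(feature_ids, params, only, [], "random_forest")
    screen_imp = rf_importance(y, X, params, seed=derive_seed(params.seed, "rf-screen"))
    # canonical ascending-id order so each step's RNG stream is reproducible
    surviving = sorted(select_top_k(screen_imp, top_k) if screen else feature_ids)
    col_of = {f: i for i, f in enumerate(feature_ids)}
    eliminated: list[str] = []
    step_importances: list[pd.Series] = []
    step = 0
    while len(surviving) > 1:
        cols = [col_of[f] for f in surviving]
        imp = _rf_importance_arrays(
            Xv[:, cols], yv, params, derive_seed(params.seed, "rf-eliminate", step)
        )
        scores = pd.Series(imp, index=surviving)
        step_importances.append(scores)
        worst = _argmin_feature(scores)
        surviving.remove(worst)
        eliminated.append(worst)
        step += 1
    ranked = [surviving[0]] + list(reversed(eliminated))
    return RankingResult(ranked, params, screen_imp, step_importances, "random_forest")


def rf_repeat_predictions(
    y: MutationProfile,
    X: ChromatinMatrix,
    meta: FeatureMetadata,
    params: ForestParams,
    n_repeats: int,
    base_seed: int,
    expected_type: str,
) -> ReproducibilityReport:
    """Repeat-run report for the forest ranker (see ranking.repeat_predictions)."""
    if n_repeats < 1:
        raise ValueError("n_repeats >= 1 required")
    predictions, rank1s = [], []
    for rep in range(n_repeats):
        p = replace(params, seed=base_seed + rep)
        result = rf_backward_eliminate(y, X, p)
        pred = assign_origin(result, meta, y.sample_id, expected_type)
        predictions.append(pred.predicted_type)
        rank1s.append(pred.rank1_feature)
    accuracy = float(np.mean([p == expected_type for p in predictions]))
    return ReproducibilityReport(
        sample_id=y.sample_id,
        expected_type=expected_type,
        n_repeats=n_repeats,
        accuracy=accuracy,
        reproducible=accuracy in (0.0, 1.0),
        predictions=predictions,
        rank1_features=rank1s,
    )
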