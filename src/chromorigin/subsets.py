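"""Region-subset robustness analyses.

How stable is the predicted origin when only a subset of the genomic
windows is used?  Two subset designs are supported: plain random subsets
of a given size, and subsets constrained to contain a fixed proportion of
enhancer-containing windows (windows overlapping at least one
tissue-specific enhancer interval by >= 1 bp).  Accuracy is measured
against the prediction obtained from the full window set with the same
ranker and parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .forest import ForestParams, rf_backward_eliminate
from .profiles import ChromatinMatrix, FeatureMetadata, MutationProfile
from .ranking import BoostParams, assign_origin, rank_features
from .windows import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class SubsetSpec:
    """One subset condition: size, optional enhancer constraint, iterations."""

    n_regions: int
    n_iterations: int = 100
    seed: int = 0
    enhancer_class: str | None = None
    enhancer_proportion: float | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_iterations < 1:
            raise ValueError("n_regions and n_iterations must be >= 1")
        if self.enhancer_proportion is not None and not (
            0.0 <= self.enhancer_proportion <= 1.0
        ):
            raise ValueError("enhancer_proportion must be in [0, 1]")


@dataclass
class SubsetAccuracyResult:
    spec: SubsetSpec
    reference_prediction: str
    predictions: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(
            np.mean([p == self.reference_prediction for p in self.predictions])
        )


def mark_enhancer_windows(ws: WindowSet, enhancers) -> np.ndarray:
    """Boolean per-window flags: True iff >= 1 bp overlap with any enhancer."""
    flags = np.zeros(len(ws), dtype=bool)
    grid: dict[str, list] = {}
    for w in ws.windows:
        grid.setdefault(w.chrom, []).append(w)
    for chrom, start, end in enhancers:
        start, end = int(start), int(end)
        for w in grid.get(str(chrom), ()):
            if start < w.end and end > w.start:
                flags[w.index] = True
    return flags


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_subset(
    ws: WindowSet,
    mask: np.ndarray | None,
    n_total: int,
    proportion: float | None,
    seed: int,
) -> np.ndarray:
    """Draw ``n_total`` distinct window indices, honouring an enhancer quota.

    With ``proportion`` set, ``round(proportion * n_total)`` indices are
    drawn without replacement from masked (enhancer-containing) windows —
    all of them if fewer exist — and the remainder from unmasked windows,
    falling back to the other stratum when one runs short.  Deterministic
    per seed; returned sorted.
    """
    n = len(ws)
    if n_total > n:
        raise ValueError(f"n_total {n_total} > number of windows {n}")
    rng = np.random.default_rng(seed)
    if proportion is None:
        return np.sort(rng.choice(n, size=n_total, replace=False))
    if mask is None:
        raise ValueError("proportion requires an enhancer mask")
    mask = np.asarray(mask, dtype=bool)
    masked = np.flatnonzero(mask)
    unmasked = np.flatnonzero(~mask)
    want_masked = min(_round_half_up(proportion * n_total), masked.size)
    want_unmasked = min(n_total - want_masked, unmasked.size)
    # shortfall in one stratum is filled from the other
    take_masked = min(masked.size, n_total - want_unmasked)
    chosen_masked = rng.choice(masked, size=take_masked, replace=False)
    chosen_unmasked = rng.choice(unmasked, size=n_total - take_masked, replace=False)
    return np.sort(np.concatenate([chosen_masked, chosen_unmasked]))


def _restrict(y: MutationProfile, X: ChromatinMatrix, rows: np.ndarray):
    y_sub = MutationProfile(y.sample_id, y.counts[rows], "")
    X_sub = ChromatinMatrix(X.values.iloc[rows].reset_index(drop=True), "")
    return y_sub, X_sub


def _run_ranker(y, X, meta, params, ranker: str):
    if ranker == "boost":
        result = rank_features(y, X, params)
    elif ranker == "forest":
        result = rf_backward_eliminate(y, X, params)
    else:
        raise ValueError(f"unknown ranker {ranker!r} (use 'boost' or 'forest')")
    return assign_origin(result, meta, y.sample_id)


def subset_accuracy(
    y: MutationProfile,
    X: ChromatinMatrix,
    meta: FeatureMetadata,
    params,
    spec: SubsetSpec,
    ranker: str = "boost",
    mask: np.ndarray | None = None,
    ws: WindowSet | None = None,
    reference_prediction: str | None = None,
) -> SubsetAccuracyResult:
    """Accuracy of subset-based predictions vs the full-region prediction.

    Iteration seeds only drive the subset draw; the ranker always runs with
    ``params.seed``, so the full-size subset reproduces the reference
    exactly.  ``ws`` defaults to a synthetic single-axis window set matching
    the matrix rows (only window count matters here).
    """
    n = X.n_windows
    if reference_prediction is None:
        reference_prediction = _run_ranker(y, X, meta, params, ranker).predicted_type
    predictions = []
    for it in range(spec.n_iterations):
        it_seed = derive_seed(spec.seed, "subset", spec.n_regions, it)
        if ws is not None:
            rows = sample_subset(ws, mask, spec.n_regions, spec.enhancer_proportion, it_seed)
        else:
            rng = np.random.default_rng(it_seed)
            rows = np.sort(rng.choice(n, size=spec.n_regions, replace=False))
        y_sub, X_sub = _restrict(y, X, rows)
        predictions.append(_run_ranker(y_sub, X_sub, meta, params, ranker).predicted_type)
    return SubsetAccuracyResult(spec, reference_prediction, predictions)


def sweep_subsets(
    y: MutationProfile,
    X: ChromatinMatrix,
    meta: FeatureMetadata,
    params,
    sizes: list[int],
    n_iterations: int,
    seed: int,
    ranker: str = "boost",
) -> list[SubsetAccuracyResult]:
    """One SubsetAccuracyResult per size (sizes must be ascending)."""
    if sorted(sizes) != list(sizes):
        raise ValueError("sizes must be ascending")
    reference = _run_ranker(y, X, meta, params, ranker).predicted_type
    results = []
    for size in sizes:
        spec = SubsetSpec(n_regions=size, n_iterations=n_iterations, seed=seed)
        results.append(
            subset_accuracy(
                y, X, meta, params, spec, ranker, reference_prediction=reference
            )
        )
    return results


def sweep_to_frames(results: list[SubsetAccuracyResult]):
    """Long-format (size, iteration, predicted_type, match) + summary frames."""
    rows = []
    for r in results:
        for it, pred in enumerate(r.predictions):
            rows.append(
                {
                    "size": r.spec.n_regions,
                    "iteration": it,
                    "predicted_type": pred,
                    "match": pred == r.reference_prediction,
                }
            )
    long = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"size": r.spec.n_regions, "accuracy": r.accuracy} for r in results]
    )
    return long, summary
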