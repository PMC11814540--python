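"""Deletion-based outlier screening for presence/pseudoabsence samples.

The screen asks whether a few influential samples depress model accuracy:
delete ``k`` randomly chosen rows (stratified so the class balance moves by
at most one), refit the full per-scale ensemble, and compare its mean OOB
accuracy to the undeleted baseline fitted with the same model seed stream.
Repeating over a grid of ``k`` and several replicates, the screen tracks
the *best* replicate at each ``k`` (the deletion group with the highest
ensemble accuracy).  Uniform stratified deletion leaves the outlier
*fraction* unchanged in expectation, so the replicate mean is flat whether
or not outliers exist; what responds to ``k`` is the best replicate, whose
advantage grows with ``k`` when deletable bad rows exist and stays within
sampling noise when they do not.  A rising ordinary-least-squares trend of
best-replicate accuracy in ``k`` therefore indicates outliers; the deleted
set of the overall best replicate is the flagged candidate outlier group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import BufferSpec
from .models import ModelConfig, ScaleEnsembleClassifier, _spec_subset

__all__ = [
    "DeletionScheduleConfig",
    "OutlierScreenResult",
    "TrendResult",
    "deletion_screen",
    "trend_test",
]


@dataclass(frozen=True)
class DeletionScheduleConfig:
    """Deletion counts, replicates per count and the screen seed.

    The default grid {1, 5, 10, 25, 50} x 5 replicates spans "one data point
    to a maximum of 50" with five repeats per count; deleting much more than
    50 of ~200 rows would no longer test the same dataset.
    """

    deletion_counts: tuple[int, ...] = (1, 5, 10, 25, 50)
    reps_per_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(self.deletion_counts)
        if any(k < 0 or k > 50 for k in ks):
            raise ValueError("deletion counts must lie in [0, 50]")
        if self.reps_per_k < 1:
            raise ValueError("reps_per_k must be >= 1")


@dataclass
class TrendResult:
    """OLS trend of the screen's accuracy response on deletion count."""

    slope: float
    intercept: float
    p_value: float
    classification: str  # "increasing" | "flat"


@dataclass
class OutlierScreenResult:
    """Screen outcome at one scale.

    ``records`` holds one row per (k, rep) with the deleted ids and the
    refitted ensemble's mean accuracy; ``delta`` is best-rep minus baseline.
    """

    spec: BufferSpec
    records: pd.DataFrame
    baseline_mean: float
    baseline_sd: float
    best_k: int
    best_rep: int
    delta: float
    flagged_ids: list = field(default_factory=list)


def _stratified_delete(y: np.ndarray, k: int, rng) -> np.ndarray:
    """Indices of k rows to delete, split across classes by proportion (+-1)."""
    classes = np.unique(y)
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    n = y.size
    # largest-remainder apportionment of k across classes
    quotas = np.array([k * idx.size / n for idx in idx_by_class])
    base = np.floor(quotas).astype(int)
    rem = k - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    out = [
        rng.choice(idx, size=b, replace=False)
        for idx, b in zip(idx_by_class, base)
        if b > 0
    ]
    return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=int)


def _mean_ensemble_accuracy(X, y, cfg: ModelConfig) -> tuple[np.ndarray, float]:
    est = ScaleEnsembleClassifier(
        n_models=cfg.n_models,
        n_trees=cfg.n_trees,
        sampling=cfg.sampling,
        oob_fraction=cfg.oob_fraction,
        random_state=cfg.seed,
        compute_importance=False,
    ).fit(X, y)
    return est.accuracies_, float(est.accuracies_.mean())


def deletion_screen(
    features: pd.DataFrame,
    spec: BufferSpec,
    schedule: DeletionScheduleConfig,
    model_cfg: ModelConfig,
) -> OutlierScreenResult:
    """Run the deletion screen at one buffer scale.

    The baseline and every refit use the same ensemble seed stream
    (``model_cfg.seed``) so accuracy differences reflect the deletions, not
    fresh sampling noise.  The best (k, rep) is the replicate with the
    highest mean accuracy; its deleted ids are flagged.
    """
    X, y, ids = _spec_subset(features, spec)
    n = y.size
    max_k = max(schedule.deletion_counts, default=0)
    _, counts = np.unique(y, return_counts=True)
    # stratified deletion removes at most floor(k*nc/n)+1 rows from a class
    worst_left = counts - (np.floor(max_k * counts / n).astype(int) + 1)
    if worst_left.min() < 10:
        raise ValueError(
            f"schedule infeasible: deleting up to {max_k} of {n} rows "
            "can leave fewer than 10 rows in a class"
        )
    rng = np.random.default_rng(schedule.seed)

    baseline_accs, baseline_mean = _mean_ensemble_accuracy(X, y, model_cfg)
    baseline_sd = float(np.std(baseline_accs, ddof=1)) if baseline_accs.size > 1 else 0.0

    rows = []
    for k in schedule.deletion_counts:
        for rep in range(schedule.reps_per_k):
            if k == 0:
                deleted = np.empty(0, dtype=int)
                mean_acc = baseline_mean
            else:
                deleted = _stratified_delete(y, k, rng)
                keep = np.setdiff1d(np.arange(n), deleted)
                _, mean_acc = _mean_ensemble_accuracy(X[keep], y[keep], model_cfg)
            rows.append(
                {
                    "scale": spec.label,
                    "k": k,
                    "rep": rep,
                    "mean_acc": mean_acc,
                    "deleted_ids": list(ids[deleted]),
                }
            )
    records = pd.DataFrame(rows)
    best = records.loc[records["mean_acc"].idxmax()]
    return OutlierScreenResult(
        spec=spec,
        records=records,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        best_k=int(best["k"]),
        best_rep=int(best["rep"]),
        delta=float(best["mean_acc"] - baseline_mean),
        flagged_ids=list(best["deleted_ids"]),
    )


def trend_test(
    result: OutlierScreenResult, alpha: float = 0.05, response: str = "excess"
) -> TrendResult:
    """OLS trend of the screen's accuracy response on deletion count k.

    ``response`` selects the regressed quantity per deletion count:

    ``"excess"`` (default)
        Best-replicate accuracy minus the replicate mean.  Deleting rows
        shrinks the training set, which depresses *every* replicate's
        accuracy as k grows and can mask the outlier signal; the replicate
        mean carries exactly that shared penalty, so the excess isolates
        how much the best deletion group beats random deletion — which
        grows with k only when deletable outliers exist.
    ``"best"``
        Raw best-replicate accuracy (the deletion group the screen keeps).
    ``"mean"``
        Replicate mean accuracy.  Flat in expectation under uniform
        deletion whether or not outliers exist; useful as a control.

    Classified "increasing" when the slope is positive and significant at
    ``alpha`` (two-sided); otherwise "flat".  Needs >= 3 distinct k values.
    """
    grouped = result.records.groupby("k")["mean_acc"]
    if response == "excess":
        per_k = grouped.max() - grouped.mean()
    elif response == "best":
        per_k = grouped.max()
    elif response == "mean":
        per_k = grouped.mean()
    else:
        raise ValueError("response must be 'excess', 'best' or 'mean'")
    if per_k.size < 3:
        raise ValueError("trend test needs at least 3 distinct deletion counts")
    ks = per_k.index.to_numpy(dtype=float)
    ys = per_k.to_numpy(dtype=float)
    if np.ptp(ys) == 0:
        return TrendResult(slope=0.0, intercept=float(ys[0]), p_value=1.0,
                           classification="flat")
    fit = sps.linregress(ks, ys)
    cls = "increasing" if (fit.slope > 0 and fit.pvalue < alpha) else "flat"
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        classification=cls,
    )
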