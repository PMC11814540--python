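"""Landscape-diversity hypothesis tests and NMDS ordination.

Per buffer scale, the Shannon diversity of presence neighborhoods is
compared with that of pseudoabsence neighborhoods.  The comparison is
normality-gated: if both groups pass a Shapiro-Wilk test (alpha = 0.05 per
group) a Welch two-sample t test is used, otherwise the Mann-Whitney U test.
Landscape composition structure across points is summarised by non-metric
multidimensional scaling (NMDS) on Bray-Curtis dissimilarities of the
row-normalised class proportions, reporting Kruskal stress-1 (< 0.2 is the
conventional rule of thumb for a usable 2-D configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .features import AREA_COLUMNS, BufferSpec

__all__ = [
    "DiversityTestResult",
    "OrdinationResult",
    "mann_whitney_u",
    "normality_test",
    "compare_diversity",
    "diversity_table",
    "nmds",
    "nmds_from_dissimilarity",
]


@dataclass
class DiversityTestResult:
    """Outcome of one per-scale presence-vs-absence diversity comparison."""

    spec: BufferSpec | None
    mean_presence: float
    mean_absence: float
    median_presence: float
    median_absence: float
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    direction: str  # "presence" | "absence" | "none"


@dataclass
class OrdinationResult:
    """NMDS embedding with Kruskal stress-1."""

    coordinates: pd.DataFrame  # columns: point_id (if known), nmds1, nmds2, ...
    stress: float
    metric: str
    converged: bool


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first group with a two-sided p value.

    U = number of (x_i, y_j) pairs with x_i > y_j, counting ties as 1/2.
    The p value is exact (permutation null) for small tie-free samples
    (n1 + n2 <= 12), otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; requires 3 <= n <= 5000 and a non-constant sample."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("normality test undefined for a constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def compare_diversity(
    shannon_presence,
    shannon_absence,
    alpha_normality: float = 0.05,
    spec: BufferSpec | None = None,
) -> DiversityTestResult:
    """Normality-gated two-sample comparison of Shannon diversities.

    Welch's t test when both groups pass Shapiro-Wilk at ``alpha_normality``;
    Mann-Whitney U otherwise (including for degenerate constant groups, with
    a warning).  Two-sided throughout.  ``direction`` reports which group is
    more diverse (by mean under t, by median under U; "none" on an exact tie).
    """
    xp = np.asarray(shannon_presence, dtype=float)
    xa = np.asarray(shannon_absence, dtype=float)
    if xp.size < 3 or xa.size < 3:
        raise ValueError("need at least 3 values per group")

    gate_ok = True
    for grp in (xp, xa):
        if np.ptp(grp) == 0:
            warnings.warn("constant group: falling back to Mann-Whitney U")
            gate_ok = False
            break
        _, p_norm = normality_test(grp)
        if p_norm <= alpha_normality:
            gate_ok = False
            break

    if gate_ok:
        res = sps.ttest_ind(xp, xa, equal_var=False)
        test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
        diff = xp.mean() - xa.mean()
    else:
        stat, p = mann_whitney_u(xp, xa)
        test_used = "mann_whitney"
        diff = np.median(xp) - np.median(xa)

    direction = "presence" if diff > 0 else ("absence" if diff < 0 else "none")
    return DiversityTestResult(
        spec=spec,
        mean_presence=float(xp.mean()),
        mean_absence=float(xa.mean()),
        median_presence=float(np.median(xp)),
        median_absence=float(np.median(xa)),
        test_used=test_used,
        statistic=stat,
        p_value=p,
        direction=direction,
    )


def diversity_table(
    features: pd.DataFrame, alpha_normality: float = 0.05
) -> tuple[pd.DataFrame, list[DiversityTestResult]]:
    """Run the gated diversity comparison at every buffer scale in a table.

    Expects a feature table with ``label`` in {0, 1} and a ``shannon``
    column; returns a per-scale summary frame plus the full results.
    """
    results = []
    rows = []
    for (inner, outer), grp in features.groupby(["inner_m", "outer_m"], sort=True):
        spec = BufferSpec(outer=float(outer), inner=float(inner))
        hp = grp.loc[grp["label"] == 1, "shannon"].dropna().to_numpy()
        ha = grp.loc[grp["label"] == 0, "shannon"].dropna().to_numpy()
        res = compare_diversity(hp, ha, alpha_normality=alpha_normality, spec=spec)
        results.append(res)
        rows.append(
            {
                "scale": spec.label,
                "inner_m": spec.inner,
                "outer_m": spec.outer,
                "mean_presence": res.mean_presence,
                "mean_absence": res.mean_absence,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p_value,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows), results


def nmds_from_dissimilarity(
    dissim: np.ndarray, n_dims: int = 2, seed=None, n_init: int = 8, max_iter: int = 300
) -> OrdinationResult:
    """Non-metric MDS on a precomputed square dissimilarity matrix.

    Multiple random starts; the best configuration's Kruskal stress-1 is
    reported (0 = perfect rank agreement).  Raises on an all-zero
    dissimilarity matrix (duplicated points carry no ordination information).
    """
    D = np.asarray(dissim, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if D.shape[0] < 4:
        raise ValueError("NMDS needs at least 4 points")
    if not np.isfinite(D).all():
        raise ValueError("dissimilarities must be finite")
    if np.allclose(D, 0):
        raise ValueError("all dissimilarities are zero; ordination undefined")
    rs = np.random.RandomState(
        int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    )
    mds = MDS(
        n_components=n_dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        random_state=rs,
        normalized_stress=True,
    )
    coords = mds.fit_transform(D)
    converged = bool(mds.n_iter_ < max_iter)
    frame = pd.DataFrame(coords, columns=[f"nmds{i + 1}" for i in range(n_dims)])
    return OrdinationResult(
        coordinates=frame,
        stress=float(mds.stress_),
        metric="precomputed",
        converged=converged,
    )


def nmds(
    features: pd.DataFrame, n_dims: int = 2, seed=None, n_init: int = 8
) -> OrdinationResult:
    """NMDS of buffer compositions: Bray-Curtis on row-normalised proportions.

    ``features`` may hold one scale or pooled scales; each row's 8 class
    areas are normalised to proportions before the dissimilarity step.
    """
    X = features[AREA_COLUMNS].to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("rows with all-zero areas cannot be ordinated")
    P = X / totals[:, None]
    D = squareform(pdist(P, metric="braycurtis"))
    res = nmds_from_dissimilarity(D, n_dims=n_dims, seed=seed, n_init=n_init)
    res.metric = "braycurtis"
    if "point_id" in features.columns:
        res.coordinates.insert(0, "point_id", features["point_id"].to_numpy())
    return res
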