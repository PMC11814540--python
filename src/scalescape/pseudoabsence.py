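"""Pseudoabsence (background) point sampling under exclusion constraints.

The negative class for a presence/pseudoabsence design: candidate points are
drawn uniformly over the part of the landscape that is (a) at least a minimum
distance from every recorded sighting, (b) outside a border-exclusion band,
and (c) outside large-town clusters.  From the candidate pool a balanced
subset is drawn, optionally many times, mirroring the
500-candidate / 100-drawn / repeated-redraw protocol of multi-scale
colony-site studies.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

from .landscape import NODATA, LanduseRaster, MaskSet, _points_frame

__all__ = [
    "ConstraintSpec",
    "InfeasibleConstraints",
    "sample_candidates",
    "draw_negatives",
    "balanced_resample",
    "subseeds",
]


@dataclass(frozen=True)
class ConstraintSpec:
    """Exclusion rules and pool sizes for pseudoabsence sampling.

    Defaults follow the study protocol scaled to the synthetic domain:
    1 km sighting exclusion (5 km analogue), border band from the mask set,
    towns avoided, 500 candidates, 100 drawn.
    """

    min_sighting_dist: float = 1000.0
    avoid_towns: bool = True
    n_candidates: int = 500
    n_draw: int = 100

    def __post_init__(self) -> None:
        if self.min_sighting_dist < 0:
            raise ValueError("min_sighting_dist must be >= 0")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if not 0 <= self.n_draw <= self.n_candidates:
            raise ValueError("n_draw must satisfy 0 <= n_draw <= n_candidates")


class InfeasibleConstraints(RuntimeError):
    """Raised when the rejection budget is exhausted before the pool fills."""


class _SightingIndex:
    """Cell-binned spatial index for exact minimum-distance queries.

    Bin side equals the query distance, so any point within ``dist`` of a
    query lies in the 3x3 neighborhood of the query's bin; the scan is exact
    (it must equal brute force) and only a speedup.
    """

    def __init__(self, xs: np.ndarray, ys: np.ndarray, dist: float) -> None:
        self.dist = dist
        self.d2 = dist * dist
        self.bins: dict[tuple[int, int], list[int]] = defaultdict(list)
        self.xs = np.asarray(xs, dtype=float)
        self.ys = np.asarray(ys, dtype=float)
        if dist > 0:
            bx = np.floor(self.xs / dist).astype(int)
            by = np.floor(self.ys / dist).astype(int)
            for i, key in enumerate(zip(bx, by)):
                self.bins[key].append(i)

    def too_close(self, x: float, y: float) -> bool:
        if self.dist <= 0 or self.xs.size == 0:
            return False
        bx, by = int(np.floor(x / self.dist)), int(np.floor(y / self.dist))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for i in self.bins.get((bx + dx, by + dy), ()):
                    if (self.xs[i] - x) ** 2 + (self.ys[i] - y) ** 2 < self.d2:
                        return True
        return False


def sample_candidates(
    raster: LanduseRaster,
    sightings: pd.DataFrame,
    masks: MaskSet,
    spec: ConstraintSpec,
    seed,
    budget_factor: int = 1000,
) -> pd.DataFrame:
    """Draw ``spec.n_candidates`` uniform points from the valid region.

    Rejection sampling: proposals are uniform over non-nodata cells (with
    within-cell jitter) and kept only if they clear the sighting-distance,
    border and town constraints, which preserves conditional uniformity on
    the valid region.  The budget is ``budget_factor * n_candidates``
    proposals; on exhaustion an :class:`InfeasibleConstraints` error reports
    the binding constraint and the rejected fraction.

    Returns a LabeledPoints frame with label 0.
    """
    rng = np.random.default_rng(seed)
    valid_rows, valid_cols = np.nonzero(raster.grid != NODATA)
    if valid_rows.size == 0:
        raise InfeasibleConstraints("raster has no valid cells")
    if masks.border_mask.shape != raster.extent:
        raise ValueError("masks do not share the raster extent")

    index = _SightingIndex(
        sightings["x"].to_numpy() if len(sightings) else np.empty(0),
        sightings["y"].to_numpy() if len(sightings) else np.empty(0),
        spec.min_sighting_dist,
    )

    xs: list[float] = []
    ys: list[float] = []
    rej = {"sighting_distance": 0, "border_band": 0, "town_avoidance": 0}
    budget = budget_factor * spec.n_candidates
    proposals = 0
    while len(xs) < spec.n_candidates and proposals < budget:
        proposals += 1
        k = rng.integers(valid_rows.size)
        r, c = valid_rows[k], valid_cols[k]
        if masks.border_mask[r, c]:
            rej["border_band"] += 1
            continue
        if spec.avoid_towns and masks.town_mask[r, c]:
            rej["town_avoidance"] += 1
            continue
        cx, cy = raster.cell_center(r, c)
        jx, jy = rng.uniform(-0.5, 0.5, 2) * raster.cell_size
        x, y = float(cx + jx), float(cy + jy)
        if index.too_close(x, y):
            rej["sighting_distance"] += 1
            continue
        xs.append(x)
        ys.append(y)
    log.info(
        "pseudoabsence sampling: %d candidates from %d proposals; rejections: %s",
        len(xs),
        proposals,
        ", ".join(f"{k}={v}" for k, v in rej.items()),
    )
    if len(xs) < spec.n_candidates:
        binding = max(rej, key=rej.get)  # type: ignore[arg-type]
        frac_rej = sum(rej.values()) / max(proposals, 1)
        raise InfeasibleConstraints(
            f"collected {len(xs)}/{spec.n_candidates} candidates in {proposals} "
            f"proposals; binding constraint: {binding}; "
            f"~{100 * frac_rej:.1f}% of the domain is excluded"
        )
    return _points_frame(xs, ys, 0, "pseudoabsence_candidate", "a")


def draw_negatives(candidates: pd.DataFrame, n_draw: int, seed) -> pd.DataFrame:
    """Simple random sample of ``n_draw`` candidates without replacement."""
    if n_draw > len(candidates):
        raise ValueError(f"n_draw={n_draw} exceeds the candidate pool ({len(candidates)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_draw, replace=False)
    out = candidates.iloc[np.sort(idx)].reset_index(drop=True)
    return out


def subseeds(seed, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit sub-seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n) % (2**31)


def balanced_resample(
    candidates: pd.DataFrame, n_draw: int, n_reps: int, seed
) -> list[pd.DataFrame]:
    """``n_reps`` independent without-replacement draws from the pool.

    The repetitions (not within-draw replacement) are the error-balancing
    mechanism: downstream consumers average model results across the reps.
    Rep ``i`` equals ``draw_negatives(candidates, n_draw, subseeds(seed, n_reps)[i])``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = subseeds(seed, n_reps)
    return [draw_negatives(candidates, n_draw, int(s)) for s in seeds]
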