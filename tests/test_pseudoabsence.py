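"""Pseudoabsence sampling: constraint exactness, uniformity, resampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import scalescape as sc
from scalescape.landscape import MaskSet
from scalescape.pseudoabsence import (
    ConstraintSpec,
    InfeasibleConstraints,
    _SightingIndex,
    subseeds,
)

from conftest import EIGHT_MIX


def _empty_sightings():
    return pd.DataFrame(columns=["id", "x", "y", "label", "source"])


def _point(x, y):
    return pd.DataFrame(
        {"id": ["s0"], "x": [x], "y": [y], "label": ["sighting"], "source": ["t"]}
    )


class TestSampleCandidates:
    def test_unconstrained_fills_pool(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=200, n_draw=50)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        assert len(cand) == 200
        assert (cand["label"] == 0).all()
        assert small_raster.contains(cand["x"], cand["y"]).all()

    def test_sighting_exclusion_exact(self, small_raster, no_masks):
        cx = small_raster.n_cols * small_raster.cell_size / 2
        cy = -small_raster.n_rows * small_raster.cell_size / 2
        sightings = _point(cx, cy)
        spec = ConstraintSpec(min_sighting_dist=2000.0, n_candidates=100, n_draw=10)
        cand = sc.sample_candidates(small_raster, sightings, no_masks, spec, 1)
        d = np.hypot(cand["x"] - cx, cand["y"] - cy)
        assert d.min() >= 2000.0

    def test_mask_constraints_respected(self, small_raster):
        import copy

        raster = copy.deepcopy(small_raster)
        masks = sc.make_masks(raster, 800.0, 3, 700.0, seed=2)
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=150, n_draw=10)
        cand = sc.sample_candidates(raster, _empty_sightings(), masks, spec, 3)
        rows, cols = raster.point_to_cell(cand["x"].to_numpy(), cand["y"].to_numpy())
        assert not masks.border_mask[rows, cols].any()
        assert not masks.town_mask[rows, cols].any()

    def test_blanket_sightings_are_infeasible(self, small_raster, no_masks):
        # sightings on a dense grid cover the whole domain within 5 km
        step = 1000.0
        xs, ys = np.meshgrid(
            np.arange(0, small_raster.n_cols * 100.0, step),
            -np.arange(0, small_raster.n_rows * 100.0, step),
        )
        sightings = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(xs.size)],
                "x": xs.ravel(),
                "y": ys.ravel(),
                "label": "sighting",
                "source": "t",
            }
        )
        spec = ConstraintSpec(min_sighting_dist=5000.0, n_candidates=10, n_draw=1)
        with pytest.raises(InfeasibleConstraints, match="sighting_distance"):
            sc.sample_candidates(
                small_raster, sightings, no_masks, spec, 0, budget_factor=20
            )

    def test_grid_index_equals_brute_force(self, small_raster):
        rng = np.random.default_rng(0)
        w = small_raster.n_cols * small_raster.cell_size
        sx = rng.uniform(0, w, 60)
        sy = -rng.uniform(0, w, 60)
        index = _SightingIndex(sx, sy, 900.0)
        for _ in range(300):
            x, y = rng.uniform(0, w), -rng.uniform(0, w)
            brute = bool((np.hypot(sx - x, sy - y) < 900.0).any())
            assert index.too_close(x, y) == brute

    def test_conditional_uniformity(self, no_masks):
        raster = sc.generate_landscape(128, 128, 100.0, EIGHT_MIX, 300.0, seed=5)
        masks = MaskSet(
            np.zeros(raster.extent, dtype=bool), np.zeros(raster.extent, dtype=bool)
        )
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=4000, n_draw=10)
        cand = sc.sample_candidates(raster, _empty_sightings(), masks, spec, 7)
        w = 128 * raster.cell_size
        bx = np.clip((cand["x"] // (w / 4)).astype(int), 0, 3)
        by = np.clip(((-cand["y"]) // (w / 4)).astype(int), 0, 3)
        counts = np.bincount(bx * 4 + by, minlength=16)
        _, p = sps.chisquare(counts)
        assert p > 0.001


class TestDrawNegatives:
    def test_full_pool_draw_is_set_equal(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=50, n_draw=50)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        drawn = sc.draw_negatives(cand, 50, seed=1)
        assert set(drawn["id"]) == set(cand["id"])

    def test_zero_draw(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=10, n_draw=0)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        assert len(sc.draw_negatives(cand, 0, seed=1)) == 0

    def test_overdraw_rejected(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=10, n_draw=5)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        with pytest.raises(ValueError):
            sc.draw_negatives(cand, 11, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        """Over many 100-of-500 draws, every candidate appears ~20% of the time."""
        pool = pd.DataFrame(
            {
                "id": [f"c{i}" for i in range(500)],
                "x": np.zeros(500),
                "y": np.zeros(500),
                "label": 0,
                "source": "t",
            }
        )
        n_reps = 2000
        counts = pd.Series(0, index=pool["id"])
        for s in subseeds(123, n_reps):
            drawn = sc.draw_negatives(pool, 100, int(s))
            counts[drawn["id"]] += 1
        freq = counts / n_reps
        assert (freq - 0.20).abs().max() <= 0.04


class TestBalancedResample:
    def test_single_rep_matches_derived_subseed(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=60, n_draw=20)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        reps = sc.balanced_resample(cand, 20, 1, seed=99)
        direct = sc.draw_negatives(cand, 20, int(subseeds(99, 1)[0]))
        assert len(reps) == 1
        assert reps[0].equals(direct)

    def test_different_seeds_differ(self, small_raster, no_masks):
        spec = ConstraintSpec(min_sighting_dist=0.0, n_candidates=200, n_draw=40)
        cand = sc.sample_candidates(small_raster, _empty_sightings(), no_masks, spec, 0)
        a = sc.balanced_resample(cand, 40, 5, seed=1)
        b = sc.balanced_resample(cand, 40, 5, seed=2)
        assert any(not x.equals(y) for x, y in zip(a, b))

    def test_rep_averaging_reduces_error(self):
        """The SE of the across-rep mean accuracy is below single-rep SD."""
        from conftest import synthetic_feature_table
        from scalescape.models import fit_scale_ensemble
        from scalescape.features import BufferSpec

        table = synthetic_feature_table(n_per_class=40, water_gap=0.05, seed=3)
        pool = table[table["label"] == 0].reset_index(drop=True)
        pres = table[table["label"] == 1]
        spec = BufferSpec(outer=1000.0)
        reps = sc.balanced_resample(pool.rename(columns={"point_id": "id"}),
                                    30, 8, seed=5)
        means, sds = [], []
        for i, neg in enumerate(reps):
            sub = pd.concat(
                [pres, neg.rename(columns={"id": "point_id"})], ignore_index=True
            )
            res = fit_scale_ensemble(
                sub, spec, sc.ModelConfig(n_trees=30, n_models=6, seed=i)
            )
            means.append(res.mean_accuracy)
            sds.append(res.accuracies.std(ddof=1))
        se_of_mean = np.std(means, ddof=1) / np.sqrt(len(means))
        assert se_of_mean < min(sds)
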