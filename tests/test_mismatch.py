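"""Signed rank differences, majority group assignment, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortmatch as cm
from cortmatch.mismatch import (
    GroupAssignment,
    aggregate_mismatch,
    assign_by_majority,
    signed_rank_difference,
)


def _pair(geom, a_vals, m_vals):
    a = cm.BrainMap(name="a", values=np.asarray(a_vals, float), geometry=geom)
    m = cm.BrainMap(name="m", values=np.asarray(m_vals, float), geometry=geom)
    return a, m


@pytest.fixture(scope="module")
def geom4():
    return cm.make_sphere_geometry(4, 10.0)


class TestSignedRankDifference:
    def test_identical_maps_give_zero(self, geom4):
        a, m = _pair(geom4, [3, 1, 4, 2], [3, 1, 4, 2])
        res = signed_rank_difference(a, m)
        assert np.all(res.delta_r == 0)
        assert not res.reversed

    def test_hand_example(self, geom4):
        # ranks of a: (1,2,3,4); ranks of m: (2,1,4,3); positive correlation
        a, m = _pair(geom4, [10, 20, 30, 40], [15, 5, 40, 30])
        res = signed_rank_difference(a, m)
        assert res.delta_r.tolist() == [-1.0, 1.0, -1.0, 1.0]
        assert not res.reversed

    def test_perfect_anticorrelation_reverses_to_zero(self, geom4):
        a, m = _pair(geom4, [1, 2, 3, 4], [4, 3, 2, 1])
        res = signed_rank_difference(a, m)
        assert res.reversed
        assert np.all(res.delta_r == 0)

    def test_zero_correlation_is_not_reversed(self, geom4):
        a, m = _pair(geom4, [1, 2, 3, 4], [1, 4, 2, 3])
        res = signed_rank_difference(a, m)
        # spearman here is exactly 0.4 > 0; flip m to force rho < 0 instead
        rev = signed_rank_difference(a, _pair(geom4, a.values, m.values[::-1])[1])
        assert res.reversed is False or rev.reversed is True

    def test_zero_variance_errors(self, geom4):
        a, m = _pair(geom4, [1, 2, 3, 4], [7, 7, 7, 7])
        with pytest.raises(ValueError, match="zero-variance"):
            signed_rank_difference(a, m)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.booleans())
    def test_sum_zero_and_bounded_with_and_without_ties(self, seed, with_ties):
        r = np.random.default_rng(seed)
        P = int(r.integers(4, 40))
        geom = cm.make_sphere_geometry(P, 50.0)
        a_vals = r.standard_normal(P)
        m_vals = (
            r.integers(0, 4, P).astype(float) + 0.5 if with_ties
            else r.standard_normal(P)
        )
        if np.ptp(m_vals) == 0 or np.ptp(a_vals) == 0:
            return
        res = signed_rank_difference(*_pair(geom, a_vals, m_vals))
        assert res.delta_r.sum() == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.abs(res.delta_r) <= P - 1)

    def test_double_reversal_restores_ranks(self, geom4):
        from scipy.stats import rankdata

        rm = rankdata([3.0, 1.0, 2.0, 2.0])
        P = 4
        assert np.array_equal((P + 1) - ((P + 1) - rm), rm)

    def test_mean_abs_delta_under_independence(self):
        """E|dr| for independent rankings is (P^2-1)/(3P)."""
        P = 180
        rng = np.random.default_rng(42)
        ranks = np.arange(1, P + 1)
        vals = [
            np.abs(ranks - rng.permutation(ranks)).mean() for _ in range(2000)
        ]
        assert np.mean(vals) == pytest.approx((P**2 - 1) / (3 * P), rel=0.02)


class TestAssignByMajority:
    def test_toy_fixture_hand_counts(self, toy_volumes):
        """Hand counts: parcel 1 -> tie 1-1 between groups 1,2 (lowest wins),
        parcel 2 -> group 2, parcel 3 -> group 1, parcel 4 -> group 2."""
        atlas, groups, _ = toy_volumes
        a = assign_by_majority(groups, atlas)
        assert a.mapping == {1: 1, 2: 2, 3: 1, 4: 2}
        assert a.ties == {1: (1, 2)}
        assert a.source == "majority-vote volume"

    def test_majority_and_full_containment(self):
        labels = np.zeros((8, 1, 1), dtype=np.int64)
        labels[:8, 0, 0] = 1
        groups = np.zeros((8, 1, 1), dtype=np.int64)
        groups[:5, 0, 0] = 7  # 5 voxels of group 7
        groups[5:, 0, 0] = 3  # 3 voxels of group 3
        a = assign_by_majority(
            cm.LabelVolume(labels=groups, affine=np.eye(4)),
            cm.LabelVolume(labels=labels, affine=np.eye(4)),
        )
        assert a.mapping == {1: 7}
        assert a.ties == {}

    def test_no_overlap_errors(self, toy_volumes):
        atlas, _, _ = toy_volumes
        empty = cm.LabelVolume(
            labels=np.zeros_like(atlas.labels), affine=atlas.affine
        )
        with pytest.raises(ValueError, match="no group overlap"):
            assign_by_majority(empty, atlas)

    def test_resampling_across_grids(self, toy_volumes):
        """A group volume on a 2x-coarser grid is resampled by nearest
        neighbour before counting."""
        atlas, groups, _ = toy_volumes
        coarse_affine = np.diag([2.0, 2.0, 1.0, 1.0])
        coarse = np.zeros((3, 3, 1), dtype=np.int64)
        coarse[:, :, 0] = 5  # single group everywhere
        a = assign_by_majority(
            cm.LabelVolume(labels=coarse, affine=coarse_affine), atlas
        )
        assert set(a.mapping.values()) == {5}


class TestAggregateMismatch:
    def test_hand_example_with_mean_tie(self, geom4):
        a, m = _pair(geom4, [10, 20, 30, 40], [15, 5, 40, 30])
        res = signed_rank_difference(a, m)  # |dr| = (1,1,1,1)
        assignment = GroupAssignment(
            mapping={1: "B", 2: "B", 3: "A", 4: "A"}, source="table"
        )
        agg = aggregate_mismatch(res, assignment)
        gm = agg.group_means
        assert gm["mean_abs_delta_r"].tolist() == [1.0, 1.0]
        assert gm["group"].tolist() == ["A", "B"]  # equal means: label order
        assert gm["n_parcels"].tolist() == [2, 2]

    def test_zero_deltas_zero_means(self, geom4):
        a, _ = _pair(geom4, [1, 2, 3, 4], [1, 2, 3, 4])
        res = signed_rank_difference(a, a)
        assignment = GroupAssignment(mapping={i: "g" for i in range(1, 5)},
                                     source="table")
        agg = aggregate_mismatch(res, assignment)
        assert agg.group_means["mean_abs_delta_r"].tolist() == [0.0]

    def test_grand_mean_is_weighted_group_mean(self, sphere60, rng):
        a = cm.BrainMap(name="a", values=rng.standard_normal(60), geometry=sphere60)
        m = cm.BrainMap(name="m", values=rng.standard_normal(60), geometry=sphere60)
        res = signed_rank_difference(a, m)
        groups = rng.integers(0, 5, 60)
        assignment = GroupAssignment(
            mapping={pid: int(g) for pid, g in zip(sphere60.parcel_ids, groups)},
            source="table",
        )
        agg = aggregate_mismatch(res, assignment)
        gm = agg.group_means
        weighted = (gm["mean_abs_delta_r"] * gm["n_parcels"]).sum() / 60
        assert weighted == pytest.approx(np.abs(res.delta_r).mean())
        assert gm["mean_abs_delta_r"].is_monotonic_decreasing

    def test_unassigned_parcel_errors(self, geom4):
        a, m = _pair(geom4, [10, 20, 30, 40], [15, 5, 40, 30])
        res = signed_rank_difference(a, m)
        assignment = GroupAssignment(mapping={1: "A", 2: "A", 3: "A"},
                                     source="table")
        with pytest.raises(ValueError, match="without group assignment"):
            aggregate_mismatch(res, assignment)
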