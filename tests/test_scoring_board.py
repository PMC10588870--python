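"""Scoring-board clustering and the cluster-based total-LA estimator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from palmleaf import (
    BoardSpec,
    LeafRecord,
    assign_cluster,
    estimate_plant_total,
    group_leaves,
    select_representatives,
    total_leaf_area,
)
from palmleaf.scoring_board import CM_PER_INCH, OVERFLOW, ClusterAssignment
from palmleaf.synthetic import generate_population


def leaf(L, W, LA=None, leaf_id="x", plant="p"):
    return LeafRecord(plant_id=plant, leaf_id=leaf_id, L=L, W=W, LA=LA)


class TestAssignCluster:
    def test_round_up_to_next_grid_line(self):
        # 10 cm = 3.937 in → 4.5; 20 cm = 7.874 in → 8.5
        assert assign_cluster(10.0, 20.0) == (4.5, 8.5)

    def test_boundary_belongs_to_its_own_line(self):
        v = 3.5 * CM_PER_INCH
        assert assign_cluster(v, v) == (3.5, 3.5)

    def test_values_below_board_clamp_to_smallest_cell(self):
        assert assign_cluster(1.0, 2.0) == (3.5, 3.5)

    def test_overflow_cell(self):
        key = assign_cluster(50.0, 10.0)
        assert math.isinf(key[0]) and key[1] == 4.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_cluster(-1.0, 5.0)

    @given(st.floats(min_value=0.1, max_value=60.0))
    def test_matches_enumerated_grid_oracle(self, value_cm):
        """Brute-force oracle: the smallest enumerated grid line ≥ value."""
        board = BoardSpec()
        inches = value_cm / CM_PER_INCH
        grid = [3.5 + i for i in range(13)]
        candidates = [g for g in grid if g >= inches - 1e-9]
        expected = min(candidates) if candidates else OVERFLOW
        assert board.cell_of(value_cm) == expected


class TestGroupLeaves:
    def test_identical_leaves_form_one_cluster(self):
        leaves = [leaf(10, 10, leaf_id=str(i)) for i in range(3)]
        clusters = group_leaves(leaves)
        assert len(clusters) == 1 and clusters[0].LN == 3

    def test_partition_preserves_leaf_count(self):
        recs = generate_population(200, seed=1)
        clusters = group_leaves(recs)
        assert sum(c.LN for c in clusters) == 200
        all_ids = sorted(i for c in clusters for i in c.member_leaf_ids)
        assert all_ids == sorted(r.leaf_id for r in recs)

    def test_cluster_count_equals_distinct_keys(self):
        recs = generate_population(300, seed=2)
        clusters = group_leaves(recs)
        keys = {assign_cluster(r.L, r.W) for r in recs}
        assert len(clusters) == len(keys)

    def test_representative_budget_realistic(self):
        # a plant of ~200 leaves occupies at least a dozen board cells
        recs = generate_population(209, seed=3)
        assert len(group_leaves(recs)) >= 13

    def test_empty_and_mixed_plants_rejected(self):
        with pytest.raises(ValueError):
            group_leaves([])
        with pytest.raises(ValueError, match="multiple plants"):
            group_leaves([leaf(5, 5, plant="a"), leaf(5, 5, plant="b")])


class TestRepresentatives:
    def cluster(self, las):
        members = [leaf(10, 10, LA=la, leaf_id=str(i)) for i, la in enumerate(las)]
        return ClusterAssignment(key=(4.5, 4.5), members=members)

    def test_singleton_cluster_selects_its_only_member(self):
        out = select_representatives(self.cluster([12.0]), k=2, seed=0)
        assert out.representative_ids == ["0"] and out.LA_rep == 12.0

    def test_seeded_selection_is_reproducible(self):
        c = self.cluster(list(range(1, 11)))
        first = select_representatives(c, k=2, seed=42)
        second = select_representatives(c, k=2, seed=42)
        assert first.representative_ids == second.representative_ids

    def test_la_rep_is_mean_of_representatives(self):
        out = select_representatives(self.cluster([10.0, 20.0]), k=2, seed=0)
        assert out.LA_rep == pytest.approx(15.0)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_representatives(self.cluster([1.0]), k=0)


class TestTotalLeafArea:
    def test_single_cluster(self):
        c = ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)] * 10, LA_rep=100.0)
        summary = total_leaf_area([c], plant_id="p")
        assert summary.total_LA == pytest.approx(1000.0)
        assert summary.total_LA_m2 == pytest.approx(0.1)

    def test_sum_over_clusters(self):
        cs = [
            ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)] * 5, LA_rep=10.0),
            ClusterAssignment(key=(4.5, 4.5), members=[leaf(9, 9)] * 2, LA_rep=20.0),
        ]
        assert total_leaf_area(cs, plant_id="p").total_LA == pytest.approx(90.0)

    def test_missing_la_rep_rejected(self):
        c = ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)])
        with pytest.raises(ValueError, match="no representative"):
            total_leaf_area([c])

    def test_monotone_in_la_rep_and_ln(self):
        base = [ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)] * 3, LA_rep=10.0)]
        t0 = total_leaf_area(base, "p").total_LA
        bigger_la = [ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)] * 3, LA_rep=11.0)]
        more_leaves = [ClusterAssignment(key=(3.5, 3.5), members=[leaf(5, 5)] * 4, LA_rep=10.0)]
        assert total_leaf_area(bigger_la, "p").total_LA >= t0
        assert total_leaf_area(more_leaves, "p").total_LA >= t0

    def test_singleton_clustering_is_exact(self):
        """With every leaf its own cluster the estimator reduces to the
        exact sum of leaf areas."""
        recs = generate_population(50, seed=7)
        clusters = [
            ClusterAssignment(key=(i, i), members=[r], LA_rep=r.LA)
            for i, r in enumerate(recs)
        ]
        total = total_leaf_area(clusters, "p").total_LA
        assert total == pytest.approx(sum(r.LA for r in recs), rel=1e-14)


class TestEstimatePlantTotal:
    def test_photo_mode_uses_measured_la(self):
        recs = generate_population(60, seed=8)
        summary, clusters = estimate_plant_total(recs, k=2, seed=0)
        assert summary.n_clusters == len(clusters)
        assert summary.total_LA > 0

    def test_hybrid_requires_model(self):
        recs = generate_population(10, seed=9)
        with pytest.raises(ValueError, match="model"):
            estimate_plant_total(recs, mode="hybrid")

    def test_board_refinement_does_not_worsen_error(self):
        """On populations where LA is monotone in (L, W), refining the
        board grid never increases the estimator's expected |error|
        (mean over representative draws)."""
        for seed in range(5):
            recs = generate_population(200, noise_sd=0.0, seed=seed)
            exact = sum(r.LA for r in recs)
            errors = []
            for step in (2.0, 1.0, 0.5):
                board = BoardSpec(step=step)
                draws = [
                    abs(estimate_plant_total(recs, board, k=2, seed=rep)[0].total_LA - exact)
                    for rep in range(20)
                ]
                errors.append(np.mean(draws))
            assert errors[0] >= errors[1] >= errors[2]
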