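"""Base-plan synthesis rules and constraint bookkeeping."""

import numpy as np
import pytest

import parotidspare as ps
from parotidspare.baseplan import BasePlanSpec

from conftest import make_box_mask


@pytest.fixture(scope="module")
def scaling(importance_table):
    return ps.scaling_factors(importance_table)


def empty_ptv_like(mask):
    return ps.BinaryMask(mask.origin, mask.spacing, np.zeros(mask.shape, dtype=bool))


class TestVariantSuite:
    def test_five_standard_variants(self):
        specs = ps.make_variant_suite()
        assert [s.name for s in specs] == ["BP_10", "BP_20", "BP_30", "BP_20,5", "BP_top5"]
        for s, d0 in zip(specs[:3], (10.0, 20.0, 30.0)):
            assert s.mode == "proportional" and s.d0 == d0
            assert s.included_ranks == frozenset(range(1, 19))
        bp205, bptop5 = specs[3], specs[4]
        assert bp205.mode == "proportional" and bp205.d0 == 20.0
        assert bp205.included_ranks == frozenset(range(1, 6))
        assert bptop5.mode == "uniform_subset" and bptop5.subset_dose == 50.0
        assert bptop5.included_ranks == frozenset(range(1, 6))

    def test_custom_linear_scale(self):
        specs = ps.make_variant_suite(d0_linear=(5.0, 15.0, 25.0))
        assert [s.d0 for s in specs[:3]] == [5.0, 15.0, 25.0]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BasePlanSpec(name="bad", mode="proportional", d0=0.0)
        with pytest.raises(ValueError):
            BasePlanSpec(name="bad", mode="uniform_subset", subset_dose=None)
        with pytest.raises(ValueError):
            BasePlanSpec(name="bad", mode="proportional", d0=10.0,
                         included_ranks=frozenset())


class TestBuildBasePlan:
    def test_top5_without_overlap(self, ranked_no_overlap, masks_no_overlap, scaling):
        _, ptv = masks_no_overlap
        spec = ps.make_variant_suite()[4]
        bp = ps.build_base_plan(ranked_no_overlap, ptv, spec, scaling)
        in_top5 = (ranked_no_overlap.labels >= 1) & (ranked_no_overlap.labels <= 5)
        assert np.all(bp.values[in_top5] == 50.0)
        assert np.all(bp.values[~in_top5] == 0.0)

    def test_bp30_max_is_d0_in_rank1(self, ranked_no_overlap, masks_no_overlap, scaling):
        _, ptv = masks_no_overlap
        spec = ps.make_variant_suite()[2]
        bp = ps.build_base_plan(ranked_no_overlap, ptv, spec, scaling)
        assert bp.values.max() == 30.0
        peak = bp.values == 30.0
        assert np.all(ranked_no_overlap.labels[peak] == 1)

    def test_support_within_gland_minus_ptv(self, ranked_default, masks_default, scaling):
        cpg, ptv = masks_default
        for spec in ps.make_variant_suite():
            bp = ps.build_base_plan(ranked_default, ptv, spec, scaling)
            support = bp.values > 0
            assert np.all(cpg.voxels[support])
            assert not np.any(support & ptv.voxels)

    def test_per_subsegment_uniformity_exact(self, ranked_default, masks_default, scaling):
        _, ptv = masks_default
        for spec in ps.make_variant_suite():
            bp = ps.build_base_plan(ranked_default, ptv, spec, scaling)
            for k in range(1, 19):
                region = (ranked_default.labels == k) & ~ptv.voxels
                if region.any():
                    vals = bp.values[region]
                    assert vals.max() == vals.min()

    def test_proportional_doses_follow_importance(self, ranked_no_overlap,
                                                  masks_no_overlap, scaling):
        _, ptv = masks_no_overlap
        spec = ps.make_variant_suite()[1]  # BP_20
        bp = ps.build_base_plan(ranked_no_overlap, ptv, spec, scaling)
        per_rank = np.array(
            [bp.values[ranked_no_overlap.labels == k].max() for k in range(1, 19)]
        )
        assert np.allclose(per_rank, 20.0 * scaling)
        assert np.all(np.diff(per_rank) <= 1e-12)

    def test_full_overlap_yields_zero_plan_with_warning(self, ranked_no_overlap,
                                                        masks_no_overlap, scaling,
                                                        caplog):
        cpg, _ = masks_no_overlap
        ptv_all = ps.BinaryMask(cpg.origin, cpg.spacing,
                                np.ones(cpg.shape, dtype=bool))
        import logging

        with caplog.at_level(logging.WARNING):
            bp = ps.build_base_plan(
                ranked_no_overlap, ptv_all, ps.make_variant_suite()[0], scaling
            )
        assert not bp.values.any()
        assert any("identically zero" in r.message for r in caplog.records)

    def test_geometry_mismatch_rejected(self, ranked_no_overlap, scaling):
        other = ps.BinaryMask((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="geometry"):
            ps.build_base_plan(ranked_no_overlap, other,
                               ps.make_variant_suite()[0], scaling)


class TestConstraintSet:
    def test_zero_base_plan(self):
        mask = make_box_mask()
        bp = ps.Grid3D(mask.origin, mask.spacing, np.zeros(mask.shape))
        cs = ps.constraint_set(bp, mask, clinical_mean_bound=20.0, dmax_margin=10.0)
        assert cs.cpg_dmax_bound == 10.0
        assert cs.cpg_mean_bound_shifted == 20.0

    def test_top5_on_exactly_equal_cells(self, importance_table):
        # box gland: 18 cells of exactly 1000 voxels; uniform 50 Gy on 5 of 18
        mask = make_box_mask()
        cells = ps.partition_equal_volume(mask)
        ranked = ps.assign_ranks(cells, importance_table, "right")
        spec = ps.make_variant_suite()[4]
        bp = ps.build_base_plan(ranked, empty_ptv_like(mask), spec,
                                ps.scaling_factors(importance_table))
        cs = ps.constraint_set(bp, mask, 20.0, 10.0)
        assert cs.cpg_mean_bound_shifted == pytest.approx(20.0 + 50.0 * 5.0 / 18.0)

    def test_dmax_bounds_differ_by_d0_difference(self, ranked_no_overlap,
                                                 masks_no_overlap, importance_table):
        cpg, ptv = masks_no_overlap
        scaling = ps.scaling_factors(importance_table)
        specs = ps.make_variant_suite()
        bounds = {}
        for spec in specs[:3]:
            bp = ps.build_base_plan(ranked_no_overlap, ptv, spec, scaling)
            bounds[spec.d0] = ps.constraint_set(bp, cpg, 20.0, 10.0).cpg_dmax_bound
        assert bounds[20.0] - bounds[10.0] == pytest.approx(10.0, abs=1e-12)
        assert bounds[30.0] - bounds[10.0] == pytest.approx(20.0, abs=1e-12)

    def test_mean_bound_additive_in_base_plan_shift(self, ranked_no_overlap,
                                                    masks_no_overlap, importance_table):
        cpg, ptv = masks_no_overlap
        scaling = ps.scaling_factors(importance_table)
        bp = ps.build_base_plan(ranked_no_overlap, ptv,
                                ps.make_variant_suite()[2], scaling)
        cs0 = ps.constraint_set(bp, cpg, 20.0, 5.0)
        shifted = bp.like(bp.values + 3.0 * cpg.voxels)
        cs1 = ps.constraint_set(shifted, cpg, 20.0, 5.0)
        assert cs1.cpg_mean_bound_shifted - cs0.cpg_mean_bound_shifted == pytest.approx(
            3.0, abs=1e-12
        )

    def test_margin_range_enforced(self, masks_no_overlap):
        cpg, _ = masks_no_overlap
        bp = ps.Grid3D(cpg.origin, cpg.spacing, np.zeros(cpg.shape))
        for bad in (-1.0, 15.1):
            with pytest.raises(ValueError, match="0, 15"):
                ps.constraint_set(bp, cpg, 20.0, bad)
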