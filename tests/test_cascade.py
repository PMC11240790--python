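import numpy as np
import pytest

from pdacdetect.cascade import (ORACLE, PancreasNotLocatedError, StageBundle,
                                ensemble_and_classify, filter_ducts_by_pancreas,
                                locate_pancreas, patient_score,
                                phantom_scale_bundle_geometry, run_pipeline)
from pdacdetect.volume_core import LabelMap, Volume
from tests.test_patch_engine import ConstModel, flood_fill_components


def oracle_bundle(shape=(48, 48, 48), **kw):
    geom = phantom_scale_bundle_geometry(shape)
    return StageBundle(coarse_pancreas=ORACLE, fine_pancreas=ORACLE,
                       ducts=ORACLE, tumor=ORACLE, **geom, **kw)


class TestDuctFilter:
    def test_attached_component_kept(self):
        pan = np.zeros((20, 20, 20), dtype=bool)
        pan[5:12, 5:12, 5:12] = True
        duct = np.zeros_like(pan)
        duct[10:16, 8, 8] = True  # crosses the pancreas boundary
        out = filter_ducts_by_pancreas(duct, pan)
        np.testing.assert_array_equal(out, duct)

    def test_isolated_blob_removed(self):
        pan = np.zeros((30, 30, 30), dtype=bool)
        pan[2:6, 2:6, 2:6] = True
        duct = np.zeros_like(pan)
        duct[20:23, 20, 20] = True  # 10+ voxels away
        assert filter_ducts_by_pancreas(duct, pan, attach_radius=2).sum() == 0

    def test_empty_pancreas_removes_everything(self):
        duct = np.ones((8, 8, 8), dtype=bool)
        assert filter_ducts_by_pancreas(duct, np.zeros_like(duct)).sum() == 0

    def test_subset_idempotent_monotone(self, rng):
        for _ in range(15):
            duct = rng.random((15, 15, 15)) < 0.2
            pan = rng.random((15, 15, 15)) < 0.05
            out2 = filter_ducts_by_pancreas(duct, pan, attach_radius=2)
            assert not (out2 & ~duct).any()  # subset of input
            np.testing.assert_array_equal(
                filter_ducts_by_pancreas(out2, pan, attach_radius=2), out2)  # idempotent
            out4 = filter_ducts_by_pancreas(duct, pan, attach_radius=4)
            assert not (out2 & ~out4).any()  # larger radius keeps more

    def test_matches_flood_fill_intersection_oracle(self, rng):
        from scipy import ndimage as ndi
        for _ in range(20):
            duct = rng.random((12, 12, 12)) < 0.25
            pan = rng.random((12, 12, 12)) < 0.08
            r = 2
            got = filter_ducts_by_pancreas(duct, pan, attach_radius=r)
            # oracle: keep components with any voxel within Chebyshev r of pancreas
            pan_idx = np.argwhere(pan)
            expect = np.zeros_like(duct)
            for comp in flood_fill_components(duct, 26):
                keep = any(
                    pan_idx.size and (np.abs(pan_idx - np.array(v)).max(axis=1) <= r).any()
                    for v in comp
                )
                if keep:
                    for v in comp:
                        expect[v] = True
            np.testing.assert_array_equal(got, expect)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            filter_ducts_by_pancreas(np.zeros((4, 4, 4), bool), np.zeros((5, 4, 4), bool))


class TestEnsemble:
    def test_mean_before_max(self):
        g = np.zeros((3, 3, 3))
        a, b, c = g.copy(), g.copy(), g.copy()
        a[1, 1, 1], b[1, 1, 1], c[1, 1, 1] = 1.0, 1.0, 0.1
        _, per_fold, score, call = ensemble_and_classify([a, b, c], threshold=0.61)
        assert score == pytest.approx(0.7)
        assert call  # 0.7 >= 0.61, even though fold c alone scores 0.1
        assert per_fold == [1.0, 1.0, pytest.approx(0.1)]

    def test_threshold_inclusive(self):
        g = np.full((2, 2, 2), 0.61)
        *_, call = ensemble_and_classify([g], threshold=0.61)
        assert call

    def test_single_fold_identity(self, rng):
        g = rng.random((4, 4, 4))
        mean, per_fold, score, _ = ensemble_and_classify([g])
        np.testing.assert_array_equal(mean, g)
        assert score == g.max()

    def test_mean_within_fold_envelope(self, rng):
        grids = [rng.random((5, 5, 5)) for _ in range(3)]
        mean, *_ = ensemble_and_classify(grids)
        lo = np.min(np.stack(grids), axis=0)
        hi = np.max(np.stack(grids), axis=0)
        assert ((mean >= lo - 1e-12) & (mean <= hi + 1e-12)).all()

    def test_voxelwise_mean_value(self, rng):
        grids = [np.full((2, 2, 2), v) for v in (0.2, 0.4, 0.9)]
        mean, *_ = ensemble_and_classify(grids)
        np.testing.assert_allclose(mean, 0.5, atol=1e-12)

    def test_empty_fold_list(self):
        with pytest.raises(ValueError):
            ensemble_and_classify([])


class TestPatientScore:
    def test_rules(self):
        assert patient_score([0.8]) == 0.8
        assert patient_score([0.2, 0.8]) == 0.8
        assert patient_score([0.2, 0.8], rule="mean") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            patient_score([])


class TestLocatePancreas:
    def test_oracle_centroid_near_truth(self, tumor_case):
        bundle = oracle_bundle()
        center = locate_pancreas(tumor_case.ct, ORACLE, bundle, gt=tumor_case.labels)
        true_c = np.argwhere(tumor_case.labels.mask("pancreas")).mean(axis=0)
        assert all(abs(center[a] - true_c[a]) <= 2 for a in range(3))

    def test_all_zero_prediction_raises(self, tumor_case):
        bundle = oracle_bundle()
        with pytest.raises(PancreasNotLocatedError):
            locate_pancreas(tumor_case.ct, [ConstModel(0.0)], bundle)

    def test_two_blob_gt_uses_largest(self):
        # pancreas annotated as one 512-voxel blob plus a 8-voxel speckle:
        # the centroid must come from the big blob only
        lab = np.zeros((48, 48, 48), dtype=np.int32)
        lab[16:24, 16:24, 16:24] = 1
        lab[40:42, 40:42, 40:42] = 1
        gt = LabelMap(lab, label_names={1: "pancreas"})
        ct = Volume(np.zeros((48, 48, 48)))
        bundle = oracle_bundle()
        center = locate_pancreas(ct, ORACLE, bundle, gt=gt)
        assert all(15 <= c <= 25 for c in center)


class TestRunPipeline:
    def test_oracle_end_to_end_tumor(self, tumor_case):
        res = run_pipeline(tumor_case.ct, oracle_bundle(), gt=tumor_case.labels)
        assert res.call
        for name, d in res.dscs.items():
            assert d == 1.0, f"{name} DSC {d}"

    def test_oracle_end_to_end_control(self, control_case):
        res = run_pipeline(control_case.ct, oracle_bundle(), gt=control_case.labels)
        assert not res.call
        assert res.case_score == 0.0

    def test_oracle_is_deterministic(self, tumor_case):
        r1 = run_pipeline(tumor_case.ct, oracle_bundle(), gt=tumor_case.labels)
        r2 = run_pipeline(tumor_case.ct, oracle_bundle(), gt=tumor_case.labels)
        np.testing.assert_array_equal(r1.tumor_prob, r2.tumor_prob)
        assert r1.summary() == r2.summary()

    def test_unlocated_pancreas_yields_flagged_negative(self, tumor_case):
        geom = phantom_scale_bundle_geometry((48, 48, 48))
        bundle = StageBundle(coarse_pancreas=[ConstModel(0.0)], fine_pancreas=ORACLE,
                             ducts=ORACLE, tumor=ORACLE, **geom)
        res = run_pipeline(tumor_case.ct, bundle, gt=tumor_case.labels)
        assert not res.call
        assert "pancreas_not_located" in res.flags


class TestSegmentDucts:
    def test_single_mode_runs_two_model_sets(self, rng):
        from pdacdetect.cascade import segment_ducts
        geom = phantom_scale_bundle_geometry((48, 48, 48))
        bundle = StageBundle(duct_mode="single", **geom)
        crop = rng.random((32, 32, 24))
        cbd, pd = segment_ducts(crop, ([ConstModel(0.2)], [ConstModel(0.8)]), bundle)
        np.testing.assert_allclose(cbd, 0.2)
        np.testing.assert_allclose(pd, 0.8)
        assert cbd.shape == crop.shape

    def test_multi_mode_requires_three_channels(self, rng):
        from pdacdetect.cascade import segment_ducts
        geom = phantom_scale_bundle_geometry((48, 48, 48))
        bundle = StageBundle(duct_mode="multi", **geom)
        with pytest.raises(ValueError, match="3 channels"):
            segment_ducts(rng.random((32, 32, 24)), [ConstModel(0.5)], bundle)


class TestStageBundle:
    def test_mismatched_fold_counts_rejected(self):
        geom = phantom_scale_bundle_geometry()
        with pytest.raises(ValueError, match="fold count"):
            StageBundle(coarse_pancreas=[ConstModel(0.5)],
                        fine_pancreas=[ConstModel(0.5), ConstModel(0.5)],
                        ducts=ORACLE, tumor=ORACLE, **geom)

    def test_bad_duct_mode(self):
        with pytest.raises(ValueError, match="duct_mode"):
            StageBundle(duct_mode="both")
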