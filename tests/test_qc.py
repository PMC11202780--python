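"""Detection and repair of segmentation errors in mask stacks."""

import copy

import numpy as np
import pytest

from lungsurv.fixtures import (
    FixtureSpec,
    inject_area_jump,
    inject_mislabel,
    inject_multi_tumor,
    make_patients,
    to_ct_series,
    to_structure_set,
)
from lungsurv.qc import (
    detect_area_jumps,
    dice,
    interpolate_mask,
    run_qc,
    select_laterality,
)
from lungsurv.roi_geometry import TumorMask, TumorMaskStack, build_mask_stack


def stack_with_areas(areas, shape=(64, 64)):
    """Masks realized as squares with the requested pixel counts."""
    masks = []
    for i, a in enumerate(areas):
        side = int(np.sqrt(a))
        m = np.zeros(shape, dtype=bool)
        m[10:10 + side, 10:10 + side] = True
        extra = a - side * side
        if extra:
            m[10 + side, 10:10 + extra] = True
        masks.append(TumorMask.from_mask(f"u{i}", m))
    return TumorMaskStack("P", masks)


def disk(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestDetectAreaJumps:
    def test_collapsed_middle_slice_flagged(self):
        s = stack_with_areas([200, 20, 210])
        assert detect_area_jumps(s, 0.5) == ["u1"]

    def test_monotone_taper_not_flagged(self):
        s = stack_with_areas([50, 100, 150])
        assert detect_area_jumps(s, 0.5) == []

    def test_two_independent_collapses(self):
        s = stack_with_areas([200, 20, 210, 15, 190])
        assert detect_area_jumps(s, 0.5) == ["u1", "u3"]

    def test_edge_slices_never_flagged(self):
        s = stack_with_areas([5, 200, 210, 190, 4])
        assert detect_area_jumps(s, 0.5) == []

    def test_tau_validated(self):
        with pytest.raises(ValueError):
            detect_area_jumps(stack_with_areas([1, 2, 3]), 1.5)


class TestInterpolateMask:
    def test_identical_neighbours_reproduced(self):
        m = TumorMask.from_mask("a", disk((64, 64), (32, 32), 10))
        out = interpolate_mask(m, m)
        np.testing.assert_array_equal(out.mask, m.mask)

    def test_concentric_disks_yield_mid_radius_disk(self):
        small = TumorMask.from_mask("a", disk((96, 96), (48, 48), 10))
        big = TumorMask.from_mask("b", disk((96, 96), (48, 48), 20))
        out = interpolate_mask(small, big)
        assert dice(out.mask, disk((96, 96), (48, 48), 15)) > 0.95

    def test_empty_neighbour_copies_other(self):
        empty = TumorMask.from_mask("a", np.zeros((32, 32), dtype=bool))
        d = TumorMask.from_mask("b", disk((32, 32), (16, 16), 6))
        np.testing.assert_array_equal(interpolate_mask(empty, d).mask, d.mask)
        np.testing.assert_array_equal(interpolate_mask(d, empty).mask, d.mask)

    def test_both_empty_errors(self):
        empty = TumorMask.from_mask("a", np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            interpolate_mask(empty, empty)


class TestSelectLaterality:
    def build_bilateral(self, left_r, right_r, n=3, shape=(64, 64)):
        masks = []
        for i in range(n):
            m = disk(shape, (32, 16), left_r) | disk(shape, (32, 48), right_r)
            masks.append(TumorMask.from_mask(f"u{i}", m))
        return TumorMaskStack("P", masks)

    def test_dominant_side_kept(self):
        stack = self.build_bilateral(left_r=5, right_r=10)
        out = select_laterality(stack.masks[0], stack)
        rows, cols = np.nonzero(out.mask)
        assert (cols >= 32).all()  # right side only

    def test_single_component_identity(self):
        m = TumorMask.from_mask("u", disk((64, 64), (32, 16), 8))
        stack = TumorMaskStack("P", [m])
        assert select_laterality(m, stack) is m

    def test_tie_keeps_side_of_largest_single_component(self):
        # equal summed areas; the largest single blob sits on the left
        shape = (64, 64)
        big_left = disk(shape, (32, 14), 8)
        two_right = disk(shape, (20, 48), 5) | disk(shape, (44, 48), 5)
        n_fill = int(big_left.sum() - two_right.sum())
        fill = np.zeros(shape, dtype=bool)
        fill[0, 33:33 + n_fill] = True  # right-side sliver to equalize areas
        m = TumorMask.from_mask("u", big_left | two_right | fill)
        stack = TumorMaskStack("P", [m])
        out = select_laterality(m, stack)
        rows, cols = np.nonzero(out.mask)
        assert (cols < 32).all()


class TestRunQC:
    def test_clean_stack_unchanged_empty_report(self, patient_pipeline):
        series, ss, _ = patient_pipeline
        stack = build_mask_stack(series, ss)
        repaired, report = run_qc(stack)
        assert report.clean
        for a, b in zip(stack.masks, repaired.masks):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_injected_jump_repaired_dice(self, small_cohort):
        patients, _ = small_cohort
        fx = copy.deepcopy(patients[0])
        gtv = fx.gtv1_slice_indices()
        target = gtv[len(gtv) // 2]
        original = copy.deepcopy(fx.rois["GTV-1"])
        inject_area_jump(fx, target, shrink_factor=0.2)
        series, ss = to_ct_series(fx), to_structure_set(fx)
        stack = build_mask_stack(series, ss)
        repaired, report = run_qc(stack)
        assert report.repaired == [fx.slice_uids[target]]
        # Dice against the pre-corruption rasterization
        from lungsurv.dicom_io import Contour
        from lungsurv.roi_geometry import rasterize_contour

        pts = dict((i, p) for i, p in original)[target]
        truth = rasterize_contour(Contour(fx.slice_uids[target], pts),
                                  series.slice_by_uid(fx.slice_uids[target]))
        i = repaired.uids.index(fx.slice_uids[target])
        assert dice(repaired.masks[i].mask, truth.mask) >= 0.9

    def test_bilateral_tumor_reduced_everywhere(self, small_cohort):
        patients, _ = small_cohort
        fx = copy.deepcopy(patients[1])
        for idx in fx.gtv1_slice_indices():
            inject_multi_tumor(fx, idx)
        stack = build_mask_stack(to_ct_series(fx), to_structure_set(fx))
        repaired, report = run_qc(stack)
        from scipy import ndimage

        assert {f[1] for f in report.flags} == {"multi_tumor"}
        for m in repaired.masks:
            _, n = ndimage.label(m.mask)
            assert n <= 1

    def test_idempotent(self, small_cohort):
        patients, _ = small_cohort
        fx = copy.deepcopy(patients[2])
        gtv = fx.gtv1_slice_indices()
        inject_area_jump(fx, gtv[len(gtv) // 2], 0.2)
        stack = build_mask_stack(to_ct_series(fx), to_structure_set(fx))
        once, _ = run_qc(stack)
        twice, second_report = run_qc(once)
        assert second_report.clean
        for a, b in zip(once.masks, twice.masks):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_repair_preserves_slice_count(self, small_cohort):
        patients, _ = small_cohort
        fx = copy.deepcopy(patients[3])
        gtv = fx.gtv1_slice_indices()
        inject_area_jump(fx, gtv[1], 0.15)
        stack = build_mask_stack(to_ct_series(fx), to_structure_set(fx))
        repaired, _ = run_qc(stack)
        assert repaired.uids == stack.uids

    def test_mislabel_flag_only(self, small_cohort):
        patients, _ = small_cohort
        fx = copy.deepcopy(patients[0])
        target = fx.gtv1_slice_indices()[0]
        inject_mislabel(fx, target)
        series, ss = to_ct_series(fx), to_structure_set(fx)
        stack = build_mask_stack(series, ss)
        lungs = {}
        from lungsurv.roi_geometry import rasterize_slice

        for uid in stack.uids:
            sm = series.slice_by_uid(uid)
            left = [c for c in ss.rois["Lung-Left"] if c.referenced_sop_uid == uid]
            right = [c for c in ss.rois["Lung-Right"] if c.referenced_sop_uid == uid]
            lungs[uid] = rasterize_slice(left, sm).mask | rasterize_slice(right, sm).mask
        repaired, report = run_qc(stack, lung_masks=lungs)
        flagged = {uid for uid, cls, _ in report.flags if cls == "mislabel"}
        assert fx.slice_uids[target] in flagged
        assert fx.slice_uids[target] not in report.repaired
        i = stack.uids.index(fx.slice_uids[target])
        np.testing.assert_array_equal(stack.masks[i].mask, repaired.masks[i].mask)

    def test_report_tsv(self, tmp_path):
        s = stack_with_areas([200, 20, 210])
        _, report = run_qc(s)
        report.to_tsv(tmp_path / "qc.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "qc.tsv", sep="\t")
        assert df.loc[0, "error_class"] == "area_jump"
        assert bool(df.loc[0, "repaired"])
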