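"""CT series / RTSTRUCT parsing and GTV-1 slice resolution."""

import shutil

import numpy as np
import pytest

from lungsurv.dicom_io import (
    DicomReadError,
    MissingROIError,
    gtv1_slice_uids,
    read_ct_series,
    read_structure_set,
    resolve_roi,
    structure_inventory,
    write_inventory_tsv,
)
from lungsurv.fixtures import (
    FixtureSpec,
    make_inventory_patient,
    make_patient,
    to_ct_series,
    to_structure_set,
    write_patient,
    write_rtstruct,
)


@pytest.fixture(scope="module")
def written_patient(tmp_path_factory):
    root = tmp_path_factory.mktemp("pat")
    rng = np.random.default_rng(21)
    fx = make_patient(FixtureSpec(n_patients=1, slices_range=(10, 10), seed=21), 0, rng)
    pdir = write_patient(fx, root)
    return fx, pdir


class TestReadCTSeries:
    def test_sorted_by_z_regardless_of_filenames(self, written_patient, tmp_path):
        fx, pdir = written_patient
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        files = sorted((pdir / "CT").glob("*.dcm"))
        rng = np.random.default_rng(0)
        for i, f in enumerate(rng.permutation(files)):
            shutil.copy(f, shuffled / f"{i:03d}.dcm")
        series = read_ct_series(shuffled)
        zs = [s.z_position for s in series.slices]
        assert len(series.slices) == 10
        assert zs == sorted(zs)
        assert series.uids == fx.slice_uids

    def test_lung1_metadata_round_trips_exactly(self, written_patient):
        fx, pdir = written_patient
        series = read_ct_series(pdir / "CT")
        s = series.slices[0]
        assert s.slice_thickness == 3.0
        assert s.pixel_spacing == (0.977, 0.977)
        assert s.rescale_intercept == -1024.0

    def test_non_dicom_file_skipped_with_warning(self, written_patient, tmp_path):
        _, pdir = written_patient
        d = tmp_path / "mixed"
        shutil.copytree(pdir / "CT", d)
        (d / "notes.txt").write_text("not a dicom")
        with pytest.warns(UserWarning, match="non-DICOM"):
            series = read_ct_series(d)
        assert len(series.slices) == 10

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(DicomReadError):
            read_ct_series(tmp_path)

    def test_duplicate_sop_uid_errors(self, written_patient, tmp_path):
        _, pdir = written_patient
        d = tmp_path / "dup"
        shutil.copytree(pdir / "CT", d)
        src = next(d.glob("*.dcm"))
        shutil.copy(src, d / "zz_copy.dcm")
        with pytest.raises(DicomReadError, match="duplicate"):
            read_ct_series(d)

    def test_pixel_payload_preserved(self, written_patient):
        fx, pdir = written_patient
        series = read_ct_series(pdir / "CT")
        np.testing.assert_array_equal(series.slices[3].pixel_array, fx.pixel_arrays[3])


class TestReadStructureSet:
    def test_roundtrip_matches_fixture_manifest(self, written_patient):
        fx, pdir = written_patient
        ss = read_structure_set(next((pdir / "RTSTRUCT").glob("*.dcm")))
        assert set(ss.rois) == set(fx.rois)
        for name, entries in fx.rois.items():
            assert len(ss.rois[name]) == len(entries)
        # contour payload round-trips to the written precision (1e-4 mm)
        got = ss.rois["GTV-1"][0].points_mm
        want = fx.rois["GTV-1"][0][1]
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_lung1_243_like_inventory(self, tmp_path):
        counts = {"Lung-Left": 113, "Lung-Right": 101, "Spinal-Cord": 94,
                  "GTV-2": 6, "GTV-1": 13}
        fx = make_inventory_patient(counts, n_slices=94, seed=1)
        write_rtstruct(fx, tmp_path / "rt.dcm")
        ss = read_structure_set(tmp_path / "rt.dcm")
        inv = structure_inventory(ss).set_index("roi_name")["contour_count"]
        assert inv.to_dict() == counts
        assert inv.sum() == 327

    def test_declared_roi_without_contours_is_empty_with_warning(self, tmp_path):
        fx = make_inventory_patient({"GTV-1": 5, "Esophagus": 0}, n_slices=10, seed=2)
        write_rtstruct(fx, tmp_path / "rt.dcm")
        with pytest.warns(UserWarning, match="Esophagus"):
            ss = read_structure_set(tmp_path / "rt.dcm")
        assert ss.rois["Esophagus"] == []

    def test_zero_roi_structure_set(self, tmp_path):
        fx = make_inventory_patient({}, n_slices=5, seed=3)
        write_rtstruct(fx, tmp_path / "rt.dcm")
        ss = read_structure_set(tmp_path / "rt.dcm")
        assert ss.rois == {}

    def test_non_rtstruct_file_rejected(self, written_patient):
        _, pdir = written_patient
        with pytest.raises(DicomReadError, match="not an RTSTRUCT"):
            read_structure_set(next((pdir / "CT").glob("*.dcm")))


class TestGtv1SliceUids:
    def test_fig4_like_window(self):
        # 94 slices, GTV-1 referencing slices 21..33 -> 13 UIDs in z order
        fx = make_inventory_patient({"GTV-1": 13}, n_slices=94, seed=5)
        fx.rois["GTV-1"] = [(20 + k, pts) for k, (_, pts) in enumerate(fx.rois["GTV-1"])]
        series, ss = to_ct_series(fx), to_structure_set(fx)
        uids = gtv1_slice_uids(series, ss)
        assert uids == fx.slice_uids[20:33]
        assert len(uids) == 13

    def test_unknown_uid_dropped_with_warning(self, patient_pipeline):
        series, ss, _ = patient_pipeline
        from lungsurv.dicom_io import Contour

        rogue = Contour("1.2.3.4.not.in.series",
                        np.array([[0, 0, 0], [5, 0, 0], [5, 5, 0]], dtype=float))
        ss.rois["GTV-1"] = ss.rois["GTV-1"] + [rogue]
        with pytest.warns(UserWarning, match="not in series"):
            uids = gtv1_slice_uids(series, ss)
        assert set(uids) <= set(series.uids)

    def test_multiple_contours_one_slice_deduplicated(self, small_cohort):
        from lungsurv.fixtures import inject_multi_tumor, to_ct_series, to_structure_set

        patients, manifest = small_cohort
        import copy

        fx = copy.deepcopy(patients[1])
        target = fx.gtv1_slice_indices()[2]
        inject_multi_tumor(fx, target)
        uids = gtv1_slice_uids(to_ct_series(fx), to_structure_set(fx))
        assert len(uids) == manifest.patients[fx.patient_id]["gtv1_slice_count"]

    def test_missing_gtv1_is_structured_error(self, small_cohort):
        patients, _ = small_cohort
        fx = patients[0]
        series, ss = to_ct_series(fx), to_structure_set(fx)
        ss.rois.pop("GTV-1")
        with pytest.raises(MissingROIError):
            gtv1_slice_uids(series, ss)

    def test_geometry_only_contours_matched_by_nearest_z(self, small_cohort):
        import copy

        patients, manifest = small_cohort
        fx = copy.deepcopy(patients[2])
        fx.geometry_only = True  # drops ContourImageSequence references
        series, ss = to_ct_series(fx), to_structure_set(fx)
        with pytest.warns(UserWarning, match="z fallback"):
            uids = gtv1_slice_uids(series, ss)
        assert len(uids) == manifest.patients[fx.patient_id]["gtv1_slice_count"]

    def test_regex_roi_matching(self, patient_pipeline):
        series, ss, _ = patient_pipeline
        ss.rois["GTV 1"] = ss.rois.pop("GTV-1")
        contours = resolve_roi(ss, regex=r"GTV[- ]?1")
        assert contours


class TestInventory:
    def test_lung1_001_like_totals(self, tmp_path):
        counts = {"Lung-Left": 139, "Lung-Right": 134, "Spinal-Cord": 84, "GTV-1": 21}
        fx = make_inventory_patient(counts, n_slices=134, seed=9)
        write_rtstruct(fx, tmp_path / "rt.dcm")
        inv = structure_inventory(read_structure_set(tmp_path / "rt.dcm"))
        assert dict(zip(inv["roi_name"], inv["contour_count"])) == counts
        assert inv["contour_count"].sum() == sum(counts.values())

    def test_counts_invariant_under_contour_permutation(self, patient_pipeline):
        _, ss, _ = patient_pipeline
        before = structure_inventory(ss).set_index("roi_name")["contour_count"]
        rng = np.random.default_rng(0)
        for name in ss.rois:
            ss.rois[name] = [ss.rois[name][i]
                             for i in rng.permutation(len(ss.rois[name]))]
        after = structure_inventory(ss).set_index("roi_name")["contour_count"]
        assert before.to_dict() == after.to_dict()

    def test_inventory_tsv_export(self, patient_pipeline, tmp_path):
        import pandas as pd

        _, ss, _ = patient_pipeline
        write_inventory_tsv({ss.patient_id: structure_inventory(ss)},
                            tmp_path / "inv.tsv")
        df = pd.read_csv(tmp_path / "inv.tsv", sep="\t")
        assert list(df.columns) == ["patient_id", "roi_name", "contour_count"]
        assert (df["patient_id"] == ss.patient_id).all()
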