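"""Dataset reading, vocabulary validation, site filtering and table export."""

import numpy as np
import pandas as pd
import pytest

from skinoverlap import colorimetry as cm
from skinoverlap.dataset import (
    DEFAULT_EXCLUDED_SITES,
    GROUPS,
    SITES,
    SkinDataset,
    filter_sites,
    read_dataset,
    write_outputs,
)
from skinoverlap.matrices import OverlapMatrix

from conftest import make_dataset


class TestReadDataset:
    def test_lab_csv_identity_read(self, lab_csv):
        ds = read_dataset(lab_csv, format="lab_csv")
        assert len(ds) == 3
        assert ds.groups == ("CA", "CN")
        np.testing.assert_allclose(ds.lab("CN"), [[58.2, 10.1, 16.2]])

    def test_unknown_group_named_in_error(self, lab_csv):
        df = pd.read_csv(lab_csv)
        df.loc[1, "group"] = "XX"
        bad = lab_csv.parent / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match=r"XX.*row\(s\) \[1\]"):
            read_dataset(bad)

    def test_xyz_white_point_row_gives_l_100(self, tmp_path):
        w = cm.white_point("D65", "1964_10deg")
        path = tmp_path / "xyz.csv"
        pd.DataFrame(
            {
                "subject_id": ["s1"], "group": ["CA"], "gender": ["female"],
                "age": [30], "body_site": ["cheek"],
                "X": [w.Xn], "Y": [w.Yn], "Z": [w.Zn],
            }
        ).to_csv(path, index=False)
        ds = read_dataset(path, format="xyz_csv")
        np.testing.assert_allclose(ds.lab()[0], (100.0, 0.0, 0.0), atol=1e-9)

    def test_spectra_csv_flat_half_reflector(self, tmp_path):
        grid = np.arange(400, 701, 10)
        row = {"subject_id": "s1", "group": "CA", "gender": "male",
               "age": 30, "body_site": "cheek"}
        row.update({str(w): 0.5 for w in grid})
        path = tmp_path / "spec.csv"
        pd.DataFrame([row]).to_csv(path, index=False)
        ds = read_dataset(path, format="spectra_csv")
        # Y/Yn = 0.5 → L* = 116 * 0.5**(1/3) - 16 = 76.0693
        assert ds.lab()[0, 0] == pytest.approx(76.0693, abs=1e-3)
        np.testing.assert_allclose(ds.lab()[0, 1:], 0.0, atol=1e-9)

    def test_spectra_csv_long_layout_pivots(self, tmp_path):
        grid = np.arange(400, 701, 10)
        rows = []
        for mid, level in (("m1", 1.0), ("m2", 0.5)):
            for w in grid:
                rows.append({"subject_id": "s1", "group": "CA", "gender": "female",
                             "age": 30, "body_site": "cheek", "measurement_id": mid,
                             "wavelength": w, "reflectance": level})
        path = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        ds = read_dataset(path, format="spectra_csv")
        assert len(ds) == 2
        assert sorted(np.round(ds.lab()[:, 0], 3)) == [76.069, 100.0]

    def test_column_mapping(self, lab_csv, tmp_path):
        df = pd.read_csv(lab_csv).rename(columns={"L": "lightness"})
        path = tmp_path / "foreign.csv"
        df.to_csv(path, index=False)
        ds = read_dataset(path, column_map={"lightness": "L"})
        assert len(ds) == 3

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("subject_id,group,gender,age,body_site,L,a,b\n")
        with pytest.raises(ValueError, match="no records"):
            read_dataset(path)


class TestFilterSites:
    def make_one_per_site(self):
        frames = []
        for i, site in enumerate(SITES[:12]):
            frames.append(make_dataset({"CA": np.array([[50.0 + i, 10, 15]])}, site=site).frame)
        return SkinDataset(pd.concat(frames, ignore_index=True))

    def test_default_exclusion_drops_two_of_twelve(self):
        ds = self.make_one_per_site()
        out = filter_sites(ds)
        assert len(out) == 10
        assert not set(DEFAULT_EXCLUDED_SITES) & set(out.frame["body_site"])

    def test_empty_exclusion_is_identity(self):
        ds = self.make_one_per_site()
        out = filter_sites(ds, excluded=())
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_retained_records_unchanged(self):
        ds = self.make_one_per_site()
        out = filter_sites(ds)
        kept = ds.frame[~ds.frame["body_site"].isin(DEFAULT_EXCLUDED_SITES)]
        pd.testing.assert_frame_equal(out.frame, kept.reset_index(drop=True))

    def test_absent_site_is_noop_with_log(self):
        ds = make_dataset({"CA": np.array([[50, 10, 15], [51, 10, 15]])}, site="cheek")
        log: list[str] = []
        out = filter_sites(ds, excluded=("palm",), log=log)
        assert len(out) == 2
        assert "removed 0" in log[0]

    def test_unknown_site_rejected(self):
        ds = make_dataset({"CA": np.array([[50, 10, 15]])})
        with pytest.raises(ValueError, match="unknown site"):
            filter_sites(ds, excluded=("elbow",))


class TestDatasetInvariants:
    def test_group_counts_match_recount(self, two_cloud_dataset):
        counts = two_cloud_dataset.group_counts()
        for g in two_cloud_dataset.groups:
            assert counts[g] == (two_cloud_dataset.frame["group"] == g).sum()

    def test_groups_in_canonical_order(self):
        ds = make_dataset({"TH": np.zeros((2, 3)), "CA": np.zeros((2, 3))})
        assert ds.groups == ("CA", "TH")
        assert set(GROUPS) >= set(ds.groups)

    def test_nonfinite_colour_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_dataset({"CA": np.array([[50.0, np.nan, 15.0]])})


class TestWriteOutputs:
    def test_round_trip_within_tolerance(self, tmp_path, rng):
        m = OverlapMatrix("individual", GROUPS, rng.uniform(0, 100, (8, 8)))
        write_outputs({"overlap": m.to_dataframe().rename_axis("reference")}, tmp_path)
        back = OverlapMatrix.from_csv(tmp_path / "overlap.csv", method="individual")
        # 6 significant digits of serialization
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5)

    def test_byte_identical_across_runs(self, tmp_path, two_cloud_dataset):
        from skinoverlap.intragroup import summarize_groups

        tbl = summarize_groups(two_cloud_dataset)
        p1 = write_outputs({"summary": tbl}, tmp_path / "a")[0]
        p2 = write_outputs({"summary": tbl}, tmp_path / "b")[0]
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_group_matrix_writes_one_by_one(self, tmp_path):
        m = OverlapMatrix("gamut", ("CA",), np.array([[100.0]]))
        m.to_csv(tmp_path / "m.csv")
        back = OverlapMatrix.from_csv(tmp_path / "m.csv", method="gamut")
        assert back.values.shape == (1, 1)
        assert back.values[0, 0] == 100.0

    def test_dataset_read_write_round_trip(self, tmp_path, two_cloud_dataset):
        path = tmp_path / "ds.csv"
        two_cloud_dataset.to_csv(path)
        back = read_dataset(path)
        np.testing.assert_allclose(back.lab(), two_cloud_dataset.lab(), rtol=1e-5)
        assert list(back.frame["subject_id"]) == list(two_cloud_dataset.frame["subject_id"])
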