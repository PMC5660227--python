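"""I/O round-trips and format error handling."""

import numpy as np
import pytest

import serumpeaks as sp
from serumpeaks.exceptions import (
    EmptyInputError,
    SpectrumParseError,
    ValidationError,
)
from serumpeaks.peakcall import PeakMatrix
from serumpeaks.spectra_io import cluster_labels


def _spec(n=50, seed=0, sample_id="a"):
    rng = np.random.default_rng(seed)
    mz = np.sort(rng.uniform(900, 10500, n))
    while np.any(np.diff(mz) <= 0):
        mz = np.sort(rng.uniform(900, 10500, n))
    return sp.RawSpectrum(sample_id=sample_id, mz=mz, intensity=rng.uniform(0, 1e4, n))


class TestRawSpectrumInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError):
            sp.RawSpectrum("x", [1.0, 2.0], [1.0])

    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValidationError):
            sp.RawSpectrum("x", [2.0, 1.0], [1.0, 1.0])

    @pytest.mark.parametrize("bad", [[np.nan, 1.0], [-1.0, 1.0]])
    def test_rejects_nonfinite_or_negative_intensity(self, bad):
        with pytest.raises(ValidationError):
            sp.RawSpectrum("x", [1.0, 2.0], bad)

    def test_rejects_single_point(self):
        with pytest.raises(ValidationError):
            sp.RawSpectrum("x", [1.0], [1.0])


class TestMzxml:
    @pytest.mark.parametrize("precision,compress", [(64, True), (32, True), (64, False)])
    def test_round_trip_six_significant_figures(self, tmp_path, precision, compress):
        s = _spec(200)
        path = tmp_path / "one.mzXML"
        sp.write_mzxml([s], path, precision=precision, compress=compress)
        (back,) = sp.read_mzxml(path)
        assert back.sample_id == "one"
        np.testing.assert_allclose(back.mz, s.mz, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-6)

    def test_multi_scan_file_order_and_ids(self, tmp_path):
        specs = [_spec(20, seed=i, sample_id=f"s{i}") for i in range(3)]
        path = tmp_path / "cohort.mzXML"
        sp.write_mzxml(specs, path)
        back = sp.read_mzxml(path)
        assert [b.sample_id for b in back] == ["cohort#1", "cohort#2", "cohort#3"]
        for orig, b in zip(specs, back):
            np.testing.assert_allclose(b.intensity, orig.intensity, rtol=1e-6)

    def test_unsorted_scan_is_sorted_consistently(self, tmp_path):
        # oracle: sort the 10 (mz, intensity) pairs by mz
        rng = np.random.default_rng(5)
        mz = rng.permutation(np.linspace(1000, 2000, 10))
        inten = rng.uniform(1, 100, 10)
        import base64, zlib

        inter = np.empty(20)
        inter[0::2], inter[1::2] = mz, inten
        b64 = base64.b64encode(zlib.compress(inter.astype(">f8").tobytes())).decode()
        xml = (
            '<?xml version="1.0"?>\n'
            '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
            ' <msRun scanCount="1"><scan num="1" msLevel="1" peaksCount="10">'
            f'<peaks compressionType="zlib" precision="64" byteOrder="network" '
            f'contentType="m/z-int">{b64}</peaks></scan></msRun></mzXML>\n'
        )
        path = tmp_path / "unsorted.mzXML"
        path.write_text(xml)
        (back,) = sp.read_mzxml(path)
        order = np.argsort(mz)
        np.testing.assert_allclose(back.mz, mz[order])
        np.testing.assert_allclose(back.intensity, inten[order])

    def test_malformed_xml_reports_location(self, tmp_path):
        path = tmp_path / "broken.mzXML"
        path.write_text("<mzXML><msRun><scan num=</mzXML>")
        with pytest.raises(SpectrumParseError):
            sp.read_mzxml(path)

    def test_no_scans_is_empty_input(self, tmp_path):
        path = tmp_path / "empty.mzXML"
        path.write_text(
            '<?xml version="1.0"?>\n<mzXML xmlns="http://sashimi.sourceforge.net/'
            'schema_revision/mzXML_3.2"><msRun scanCount="0"></msRun></mzXML>\n'
        )
        with pytest.raises(EmptyInputError):
            sp.read_mzxml(path)


class TestCsvSpectrum:
    def test_two_point_spectrum(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2084,100\n2085,50\n")
        s = sp.read_csv_spectrum(p, sample_id="x")
        assert len(s) == 2
        np.testing.assert_allclose(s.mz, [2084, 2085])
        np.testing.assert_allclose(s.intensity, [100, 50])

    def test_header_row_is_tolerated(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("mz,intensity\n2084,100\n2085,50\n")
        assert len(sp.read_csv_spectrum(p)) == 2

    def test_empty_file_is_empty_input(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            sp.read_csv_spectrum(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2084,100\noops,50\n2086,25\n")
        with pytest.raises(SpectrumParseError, match="row 2"):
            sp.read_csv_spectrum(p)

    def test_duplicate_mz_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2084,100\n2084,50\n")
        with pytest.raises(ValidationError, match="duplicate"):
            sp.read_csv_spectrum(p)

    def test_round_trip(self, tmp_path):
        s = _spec(100, seed=3)
        path = tmp_path / "rt.csv"
        sp.write_csv_spectrum(s, path)
        back = sp.read_csv_spectrum(path)
        np.testing.assert_allclose(back.mz, s.mz, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-6)


class TestManifest:
    def test_round_trip_preserves_row_order(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": ["b", "a", "c"],
                "group": ["CRC", "HC", "CRC"],
                "stage": ["II", None, "IV"],
            }
        )
        path = tmp_path / "manifest.csv"
        sp.write_manifest(df, path)
        back = sp.read_manifest(path)
        assert list(back["sample_id"]) == ["b", "a", "c"]
        assert list(back.columns) == [
            "sample_id", "group", "stage", "cea", "fobt", "surv_months", "surv_event",
        ]

    def test_duplicate_id_rejected(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"sample_id": ["a", "a"], "group": ["HC", "CRC"]})
        with pytest.raises(ValidationError, match="duplicate"):
            sp.write_manifest(df, tmp_path / "m.csv")

    def test_stage_on_hc_rejected(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"sample_id": ["a"], "group": ["HC"], "stage": ["II"]}
        )
        with pytest.raises(ValidationError, match="stage"):
            sp.write_manifest(df, tmp_path / "m.csv")


class TestPeakMatrixCsv:
    def _matrix(self, cluster_mz, n_samples=2, seed=0):
        rng = np.random.default_rng(seed)
        return PeakMatrix(
            cluster_mz=np.asarray(cluster_mz, dtype=float),
            samples=[f"s{i}" for i in range(n_samples)],
            groups=["HC", "CRC"] * (n_samples // 2) + ["HC"] * (n_samples % 2),
            values=rng.uniform(0, 1e4, (n_samples, len(cluster_mz))),
        )

    def test_shape_and_columns(self, tmp_path):
        m = self._matrix([1781.2, 2084.6, 4478.1])
        path = tmp_path / "m.csv"
        sp.write_peak_matrix(m, path)
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        assert df.shape == (2, 5)
        assert list(df.columns) == ["sample_id", "group", "1781", "2085", "4478"]

    def test_round_trip_equality(self, tmp_path):
        m = self._matrix(np.sort(np.random.default_rng(1).uniform(1000, 9000, 8)),
                         n_samples=5, seed=2)
        path = tmp_path / "m.csv"
        sp.write_peak_matrix(m, path)
        back = sp.read_peak_matrix(path)
        assert back.equals(m)

    def test_label_collision_uses_one_decimal(self):
        labels = cluster_labels(np.array([2084.2, 2084.4]))
        assert labels == ["2084.2", "2084.4"]

    def test_empty_matrix_refused(self, tmp_path):
        m = self._matrix([1000.0])
        m.values = m.values[:0]
        m.samples, m.groups = [], []
        with pytest.raises(EmptyInputError):
            sp.write_peak_matrix(m, tmp_path / "m.csv")
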