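"""Spectrum container, readers/writers, resampling and normalization."""

import numpy as np
import pytest

from pscnn.spectra import (
    NormalizationError,
    SpectralLibrary,
    Spectrum,
    SpectrumError,
    SpectrumFormatError,
    SpectrumReadError,
    default_grid,
    load_library,
    mask_regions,
    normalize_max,
    read_spectrum,
    resample,
    write_library,
    write_spectrum,
)


class TestSpectrum:
    def test_validates_length_and_finiteness(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([1.0]), np.array([0.0]))
        with pytest.raises(SpectrumError):
            Spectrum(np.array([1.0, 2.0]), np.array([0.0]))
        with pytest.raises(SpectrumError):
            Spectrum(np.array([1.0, 2.0]), np.array([np.nan, 0.0]))

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(SpectrumFormatError):
            Spectrum(np.array([0.0, 1.0, 2.5]), np.zeros(3))

    def test_ascending_axis_flipped_to_descending(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert s.ppm[0] == 2.0 and s.ppm[-1] == 0.0
        assert list(s.intensities) == [3.0, 2.0, 1.0]

    def test_default_grid_descending_uniform(self):
        g = default_grid(128, -1.0, 11.0)
        assert g.size == 128 and g[0] == 11.0 and g[-1] == -1.0
        assert np.allclose(np.diff(g), np.diff(g)[0])


class TestTableIO:
    def test_two_column_parse(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1.0 0.0\n2.0 5.0\n3.0 0.0\n")
        s = read_spectrum(f, format="table")
        assert len(s) == 3
        # stored high→low
        assert list(s.ppm) == [3.0, 2.0, 1.0]
        assert list(s.intensities) == [0.0, 5.0, 0.0]

    def test_empty_file_is_read_error(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.raises(SpectrumReadError):
            read_spectrum(f, format="table")

    def test_missing_file(self, tmp_path):
        with pytest.raises(SpectrumReadError):
            read_spectrum(tmp_path / "nope.tsv")

    def test_non_numeric_row(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("1.0 2.0\nfoo bar\n")
        with pytest.raises(SpectrumFormatError):
            read_spectrum(f)

    def test_write_read_round_trip(self, tmp_path):
        grid = default_grid(64, 0.0, 8.0)
        s = Spectrum(grid, np.sin(grid) ** 2, name="roundtrip", meta={"sf_mhz": "400"})
        f = tmp_path / "rt.tsv"
        write_spectrum(s, f)
        back = read_spectrum(f)
        assert back.name == "roundtrip"
        assert back.meta["sf_mhz"] == "400"
        np.testing.assert_allclose(back.ppm, s.ppm, atol=1e-9)
        np.testing.assert_allclose(back.intensities, s.intensities, atol=1e-9)


class TestJcamp:
    def _write(self, path, ys, firstx=10.0, lastx=0.0, yfactor=1.0):
        lines = [
            "##TITLE=demo compound",
            "##JCAMP-DX=4.24",
            "##XUNITS=PPM",
            "##YUNITS=ARBITRARY",
            f"##XFACTOR=1.0",
            f"##YFACTOR={yfactor}",
            f"##FIRSTX={firstx}",
            f"##LASTX={lastx}",
            f"##NPOINTS={len(ys)}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for i in range(0, len(ys), 4):
            chunk = ys[i : i + 4]
            lines.append(" ".join([f"{firstx}"] + [f"{v}" for v in chunk]))
        lines.append("##END=")
        path.write_text("\n".join(lines))

    def test_affn_parse(self, tmp_path):
        f = tmp_path / "c.jdx"
        ys = list(range(8))
        self._write(f, ys, firstx=7.0, lastx=0.0, yfactor=0.5)
        s = read_spectrum(f)
        assert s.name == "demo compound"
        assert len(s) == 8
        assert s.ppm[0] == 7.0 and s.ppm[-1] == 0.0
        np.testing.assert_allclose(sorted(s.intensities), np.array(ys) * 0.5)

    def test_npoints_mismatch(self, tmp_path):
        f = tmp_path / "bad.jdx"
        self._write(f, [1, 2, 3])
        text = f.read_text().replace("##NPOINTS=3", "##NPOINTS=5")
        f.write_text(text)
        with pytest.raises(SpectrumFormatError):
            read_spectrum(f)

    def test_compressed_rejected(self, tmp_path):
        f = tmp_path / "sqz.jdx"
        self._write(f, [1, 2, 3, 4])
        f.write_text(f.read_text().replace("10.0 1 2 3 4", "10.0 1J2K3"))
        with pytest.raises(SpectrumFormatError):
            read_spectrum(f)


class TestBruker:
    def _make_dir(self, root, si=64, sf=400.13, sw_p=4800.0, offset=11.0, nc_proc=-2):
        pdata = root / "10" / "pdata" / "1"
        pdata.mkdir(parents=True)
        data = (np.arange(si) % 7).astype("<i4")
        (pdata / "1r").write_bytes(data.tobytes())
        (pdata / "procs").write_text(
            "##TITLE= Parameter file\n"
            f"##$BYTORDP= 0\n##$DTYPP= 0\n##$NC_proc= {nc_proc}\n"
            f"##$OFFSET= {offset}\n##$SF= {sf}\n##$SI= {si}\n##$SW_p= {sw_p}\n"
        )
        return root / "10", data

    def test_reads_processed_real_part(self, tmp_path):
        d, data = self._make_dir(tmp_path)
        s = read_spectrum(d, format="bruker_1d")
        assert len(s) == 64
        # intensities scaled by 2**NC_proc
        np.testing.assert_allclose(s.intensities, data * 2.0**-2)
        # axis starts at OFFSET and spans SW_p/SF ppm
        assert s.ppm[0] == pytest.approx(11.0)
        assert s.ppm[0] - s.ppm[-1] == pytest.approx((4800.0 / 400.13) * 63 / 64)

    def test_missing_procs(self, tmp_path):
        d, _ = self._make_dir(tmp_path)
        (d / "pdata" / "1" / "procs").unlink()
        with pytest.raises(SpectrumReadError):
            read_spectrum(d, format="bruker_1d")

    def test_no_1r(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(SpectrumReadError):
            read_spectrum(tmp_path / "empty", format="bruker_1d")


class TestResample:
    def test_identity_on_own_grid(self):
        g = default_grid(32, 0.0, 4.0)
        s = Spectrum(g, np.random.default_rng(0).random(32))
        out = resample(s, g)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_hand_linear_interpolation(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        out = resample(s, np.array([0.0, 0.5, 1.0]))
        asc = out.intensities[::-1]  # stored high→low
        assert asc[1] == pytest.approx(1.0)

    def test_outside_range_fills_zero(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        out = resample(s, np.array([1.5, 2.0, 2.5]))
        assert np.all(out.intensities == 0.0)

    def test_short_grid_rejected(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            resample(s, np.array([0.5]))


class TestNormalize:
    def test_scales_to_unit_max(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([2.0, 4.0]))
        out = normalize_max(s)
        assert sorted(out.intensities) == [0.5, 1.0]

    def test_idempotent(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([0.2, 1.0, 0.4]))
        once = normalize_max(s)
        twice = normalize_max(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_all_zero_rejected(self):
        s = Spectrum(np.array([0.0, 1.0]), np.zeros(2))
        with pytest.raises(NormalizationError):
            normalize_max(s)


def test_mask_regions_zeroes_window():
    g = default_grid(101, 0.0, 10.0)
    s = Spectrum(g, np.ones(101))
    out = mask_regions(s, [(2.45, 2.55)])
    zeroed = out.intensities == 0.0
    assert zeroed.any()
    assert np.all((out.ppm[zeroed] >= 2.45) & (out.ppm[zeroed] <= 2.55))


class TestLibraryContainer:
    def _library(self, n=3):
        g = default_grid(32, 0.0, 4.0)
        rng = np.random.default_rng(1)
        return SpectralLibrary(
            entries=[
                Spectrum(g.copy(), rng.random(32), name=f"c{i}", meta={"k": i})
                for i in range(n)
            ]
        )

    def test_round_trip(self, tmp_path):
        lib = self._library()
        f = tmp_path / "lib.h5"
        write_library(lib, f)
        back = load_library(f)
        assert back.names == lib.names
        for a, b in zip(lib, back):
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9)
            np.testing.assert_allclose(a.ppm, b.ppm, atol=1e-9)
            assert a.meta == b.meta

    def test_empty_library_round_trip(self, tmp_path):
        f = tmp_path / "empty.h5"
        write_library(SpectralLibrary(entries=[]), f)
        assert len(load_library(f)) == 0

    def test_duplicate_names_rejected(self):
        g = default_grid(16, 0.0, 4.0)
        with pytest.raises(SpectrumFormatError):
            SpectralLibrary(
                entries=[
                    Spectrum(g.copy(), np.ones(16), name="dup"),
                    Spectrum(g.copy(), np.ones(16), name="dup"),
                ]
            )

    def test_mixed_grids_rejected(self):
        with pytest.raises(SpectrumError):
            SpectralLibrary(
                entries=[
                    Spectrum(default_grid(16, 0.0, 4.0), np.ones(16), name="a"),
                    Spectrum(default_grid(16, 0.0, 5.0), np.ones(16), name="b"),
                ]
            )

    def test_lookup_by_name_and_index(self):
        lib = self._library()
        assert lib["c1"].name == "c1"
        assert lib[0].name == "c0"
        with pytest.raises(KeyError):
            lib["missing"]
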