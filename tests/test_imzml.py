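"""imzML parsing, lazy reading, chunked iteration and writing."""

import numpy as np
import pytest

from msilazy import (
    DialectError,
    IntegrityError,
    PixelSpectrum,
    iterate_spectra_chunked,
    parse_imzml_metadata,
    read_spectrum,
    write_imzml,
)


def _write_minimal(tmp_path, dialect="continuous-profile", n=1, uuid=None):
    axis = np.array([100.0, 200.0, 300.0])
    spectra = [
        PixelSpectrum(x=i + 1, y=1, mz=axis, intensity=np.array([1.0, 2.5, 0.0]) + i)
        for i in range(n)
    ]
    return write_imzml(
        dict(image_width=n, image_height=1),
        spectra,
        dialect,
        tmp_path / "d.imzML",
        uuid=uuid,
    )


class TestParse:
    def test_minimal_continuous_file(self, tmp_path):
        meta = _write_minimal(tmp_path)
        parsed = parse_imzml_metadata(meta.imzml_path)
        assert parsed.n_spectra == 1
        assert parsed.image_width == parsed.image_height == 1
        assert parsed.depth == 3
        assert parsed.mode == "continuous"
        assert parsed.representation == "profile"

    def test_round_trip_geometry_and_offsets(self, tiny_phantom):
        meta = tiny_phantom.meta
        parsed = parse_imzml_metadata(meta.imzml_path)
        assert parsed.image_width == meta.image_width
        assert parsed.image_height == meta.image_height
        assert parsed.pixel_size_x == meta.pixel_size_x
        assert [(r.x, r.y, r.mz_offset, r.intensity_offset) for r in parsed.spectra] == [
            (r.x, r.y, r.mz_offset, r.intensity_offset) for r in meta.spectra
        ]

    def test_uuid_matches_ibd_header(self, tiny_phantom):
        meta = tiny_phantom.meta
        with open(meta.ibd_path, "rb") as fh:
            assert fh.read(16) == meta.uuid

    def test_uuid_mismatch_raises(self, tmp_path):
        meta = _write_minimal(tmp_path)
        with open(meta.ibd_path, "r+b") as fh:
            fh.write(b"\x00" * 16)
        with pytest.raises(IntegrityError, match="UUID"):
            parse_imzml_metadata(meta.imzml_path)

    def test_missing_ibd_raises(self, tmp_path):
        meta = _write_minimal(tmp_path)
        import os

        os.remove(meta.ibd_path)
        with pytest.raises(FileNotFoundError):
            parse_imzml_metadata(meta.imzml_path)

    def test_metadata_holds_records_not_arrays(self, tiny_phantom):
        """Parsing retains one record per spectrum and no spectral arrays."""
        parsed = parse_imzml_metadata(tiny_phantom.meta.imzml_path)
        assert len(parsed.spectra) == tiny_phantom.meta.n_spectra
        for value in vars(parsed).values():
            assert not isinstance(value, np.ndarray)

    def test_pyimzml_cross_check(self, tiny_phantom):
        """Independent reference parser agrees on coordinates and arrays."""
        pyimzml = pytest.importorskip("pyimzml.ImzMLParser")
        parser = pyimzml.ImzMLParser(tiny_phantom.meta.imzml_path)
        meta = tiny_phantom.meta
        assert list(parser.coordinates) == [(r.x, r.y, r.z) for r in meta.spectra]
        for idx in (0, len(meta.spectra) - 1):
            mz_ref, int_ref = parser.getspectrum(idx)
            mine = read_spectrum(meta, idx)
            np.testing.assert_array_equal(np.asarray(mz_ref), mine.mz)
            np.testing.assert_allclose(np.asarray(int_ref), mine.intensity)


class TestRead:
    def test_continuous_shares_mz_axis(self, tiny_phantom):
        meta = tiny_phantom.meta
        s0 = read_spectrum(meta, 0)
        s1 = read_spectrum(meta, 1)
        np.testing.assert_array_equal(s0.mz, s1.mz)

    def test_written_intensities_bit_identical(self, tmp_path):
        meta = _write_minimal(tmp_path)
        s = read_spectrum(meta, 0)
        np.testing.assert_array_equal(s.intensity, np.array([1.0, 2.5, 0.0], dtype="<f4"))
        assert s.intensity.dtype == np.dtype("<f4")

    def test_processed_per_spectrum_lengths(self, tmp_path):
        spectra = [
            PixelSpectrum(x=1, y=1, mz=np.array([100.0, 200.0]), intensity=np.array([1.0, 2.0])),
            PixelSpectrum(
                x=2, y=1, mz=np.linspace(100, 500, 5), intensity=np.arange(5.0)
            ),
        ]
        meta = write_imzml(
            dict(image_width=2, image_height=1), spectra, "processed-centroid",
            tmp_path / "p.imzML",
        )
        assert len(read_spectrum(meta, 0).mz) == 2
        assert len(read_spectrum(meta, 1).mz) == 5

    def test_out_of_range_index(self, tiny_phantom):
        with pytest.raises(IndexError):
            read_spectrum(tiny_phantom.meta, tiny_phantom.meta.n_spectra)

    def test_truncated_ibd(self, tmp_path):
        meta = _write_minimal(tmp_path)
        with open(meta.ibd_path, "r+b") as fh:
            fh.truncate(20)
        with pytest.raises(IOError):
            read_spectrum(meta, 0)


class TestChunkedIteration:
    @pytest.mark.parametrize("n_workers", [1, 2, 4, 8])
    def test_tic_sum_invariant_to_workers(self, tiny_phantom, n_workers):
        reference = iterate_spectra_chunked(
            tiny_phantom.meta, 1, lambda s: s.tic(), lambda a, b: a + b
        )
        value = iterate_spectra_chunked(
            tiny_phantom.meta, n_workers, lambda s: s.tic(), lambda a, b: a + b
        )
        assert value == reference  # bitwise, not approximate

    @pytest.mark.parametrize("n_workers", [1, 3, 8])
    def test_spectrum_count(self, tiny_phantom, n_workers):
        count = iterate_spectra_chunked(
            tiny_phantom.meta, n_workers, lambda s: 1, lambda a, b: a + b
        )
        assert count == tiny_phantom.meta.n_spectra

    def test_elementwise_max_equals_sequential_loop(self, tiny_phantom):
        meta = tiny_phantom.meta
        brute = read_spectrum(meta, 0).intensity.astype(float)
        for i in range(1, meta.n_spectra):
            brute = np.maximum(brute, read_spectrum(meta, i).intensity)
        chunked = iterate_spectra_chunked(
            meta, 4, lambda s: s.intensity.astype(float), np.maximum
        )
        np.testing.assert_array_equal(chunked, brute)

    def test_worker_error_surfaces(self, tiny_phantom):
        def boom(s):
            raise RuntimeError("per-spectrum failure")

        with pytest.raises(RuntimeError, match="per-spectrum failure"):
            iterate_spectra_chunked(tiny_phantom.meta, 4, boom, lambda a, b: a)


class TestWrite:
    def test_round_trip_arrays_all_dialects(self, tmp_path):
        axis = np.linspace(100, 110, 32)
        rng = np.random.default_rng(0)
        spectra = [
            PixelSpectrum(x=x + 1, y=y + 1, mz=axis, intensity=rng.random(32))
            for y in range(2)
            for x in range(2)
        ]
        for dialect in ("continuous-profile", "continuous-centroid", "processed-centroid"):
            meta = write_imzml(
                dict(image_width=2, image_height=2), list(spectra), dialect,
                tmp_path / f"{dialect}.imzML",
            )
            assert (meta.mode, meta.representation) == tuple(
                ("continuous", dialect.split("-")[1])
                if dialect.startswith("continuous")
                else ("processed", "centroid")
            )
            for i, src in enumerate(spectra):
                got = read_spectrum(meta, i)
                np.testing.assert_array_equal(got.mz, axis.astype("<f8"))
                np.testing.assert_array_equal(
                    got.intensity, src.intensity.astype("<f4")
                )

    def test_continuous_centroid_common_peak_list_width(self, tmp_path):
        centers = np.array([100.0, 150.0, 200.0, 250.0, 300.0])
        spectra = [
            PixelSpectrum(x=i + 1, y=1, mz=centers, intensity=np.full(5, float(i)))
            for i in range(3)
        ]
        meta = write_imzml(
            dict(image_width=3, image_height=1), spectra, "continuous-centroid",
            tmp_path / "cc.imzML",
        )
        for rec in meta.spectra:
            assert rec.intensity_length == 5

    def test_axis_mismatch_under_continuous_raises(self, tmp_path):
        spectra = [
            PixelSpectrum(x=1, y=1, mz=np.array([1.0, 2.0]), intensity=np.zeros(2)),
            PixelSpectrum(x=2, y=1, mz=np.array([1.0, 3.0]), intensity=np.zeros(2)),
        ]
        with pytest.raises(DialectError, match="shared m/z axis"):
            write_imzml(
                dict(image_width=2, image_height=1), spectra, "continuous-profile",
                tmp_path / "bad.imzML",
            )

    def test_write_parse_write_idempotent_bytes(self, tmp_path, tiny_phantom):
        """Re-writing a parsed dataset with the same uuid reproduces the bytes."""
        meta = tiny_phantom.meta
        spectra = [
            PixelSpectrum(
                x=r.x, y=r.y, z=r.z,
                mz=read_spectrum(meta, r.index).mz,
                intensity=read_spectrum(meta, r.index).intensity,
            )
            for r in meta.spectra
        ]
        meta2 = write_imzml(meta, spectra, "continuous-profile",
                            tmp_path / "copy.imzML", uuid=meta.uuid)
        with open(meta.ibd_path, "rb") as a, open(meta2.ibd_path, "rb") as b:
            assert a.read() == b.read()
        with open(meta.imzml_path, "rb") as a, open(meta2.imzml_path, "rb") as b:
            assert a.read() == b.read()
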