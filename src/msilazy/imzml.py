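"""Lazy imzML access.

imzML splits a mass spectrometry image into an XML metadata file (``*.imzML``)
and an external binary container (``*.ibd``) whose first 16 bytes repeat the
dataset UUID.  Metadata parsing is streaming (event-based, no DOM), so parsing
a file with N spectra allocates memory proportional to N spectrum records and
never to the size of the binary container.  Spectral arrays are only read on
demand (:func:`read_spectrum`), and multi-worker whole-image passes retain
only the reduced result (:func:`iterate_spectra_chunked`).

Two dialect axes are supported, as in the imzML 1.1 standard:

* ``continuous`` vs ``processed`` — all spectra share one m/z axis (stored
  once) vs per-spectrum m/z axes;
* ``profile`` vs ``centroid`` — raw sampled signal vs picked peaks.
"""

from __future__ import annotations

import os
import uuid as _uuidlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import BinaryIO, Callable, Iterable, Iterator, Sequence

import numpy as np
from lxml import etree

from .errors import DialectError, ImzmlParseError, IntegrityError

__all__ = [
    "DatasetMetadata",
    "SpectrumRecord",
    "Spectrum",
    "PixelSpectrum",
    "parse_imzml_metadata",
    "read_spectrum",
    "iterate_spectra_chunked",
    "write_imzml",
]

# CV accessions used by the parser/writer (imzML 1.1 / PSI-MS).
_ACC_UUID = "IMS:1000080"
_ACC_CONTINUOUS = "IMS:1000030"
_ACC_PROCESSED = "IMS:1000031"
_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_EXTERNAL_DATA = "IMS:1000101"
_ACC_MAX_X = "IMS:1000042"
_ACC_MAX_Y = "IMS:1000043"
_ACC_PIXSIZE_X = "IMS:1000046"
_ACC_PIXSIZE_Y = "IMS:1000047"
_ACC_POS_X = "IMS:1000050"
_ACC_POS_Y = "IMS:1000051"
_ACC_POS_Z = "IMS:1000052"
_ACC_EXT_ARRAY_LEN = "IMS:1000103"
_ACC_EXT_OFFSET = "IMS:1000102"
_ACC_EXT_ENCODED_LEN = "IMS:1000104"

_DTYPE_ACCESSIONS = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000519": np.dtype("<i4"),  # 32-bit integer
    "MS:1000522": np.dtype("<i8"),  # 64-bit integer
}
_DTYPE_NAMES = {
    np.dtype("<f4"): ("MS:1000521", "32-bit float"),
    np.dtype("<f8"): ("MS:1000523", "64-bit float"),
    np.dtype("<i4"): ("MS:1000519", "32-bit integer"),
    np.dtype("<i8"): ("MS:1000522", "64-bit integer"),
}

_USERPARAM_NORMFACTOR = "in-file normalization factor"

#: Canonical reduction block size (spectra).  Chunked iteration always folds
#: within fixed blocks of this size and then across blocks in index order, so
#: the floating-point reduction tree -- and hence the result, bit for bit --
#: is independent of the number of workers.
REDUCTION_BLOCK = 64


@dataclass
class SpectrumRecord:
    """Byte-level access information for one pixel's spectrum."""

    index: int
    x: int  # 1-based pixel positions, imzML convention
    y: int
    z: int = 1
    mz_offset: int = 0
    mz_length: int = 0  # element counts, not bytes
    intensity_offset: int = 0
    intensity_length: int = 0
    in_file_normalization_factor: float | None = None


@dataclass
class Spectrum:
    """One pixel's decoded spectrum: ascending m/z axis plus intensities."""

    index: int
    mz: np.ndarray
    intensity: np.ndarray

    def tic(self) -> float:
        return float(np.sum(self.intensity, dtype=np.float64))


@dataclass
class PixelSpectrum:
    """Input record for :func:`write_imzml`: pixel position plus arrays."""

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray
    z: int = 1
    normalization_factor: float | None = None


@dataclass
class DatasetMetadata:
    """Parsed imzML header: geometry, dialect flags and per-spectrum offsets.

    Holds everything needed for lazy spectral access; no spectral arrays.
    """

    image_width: int
    image_height: int
    image_depth: int
    pixel_size_x: float
    pixel_size_y: float
    pixel_size_z: float
    mode: str  # 'continuous' | 'processed'
    representation: str  # 'profile' | 'centroid'
    uuid: bytes
    mz_dtype: np.dtype
    intensity_dtype: np.dtype
    spectra: list[SpectrumRecord] = field(default_factory=list)
    imzml_path: str = ""
    ibd_path: str = ""

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def depth(self) -> int:
        """Spectral depth |S| (continuous data: shared axis length)."""
        if not self.spectra:
            return 0
        return self.spectra[0].mz_length


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_params(elem) -> Iterator[tuple[str, str, str]]:
    """Yield (kind, key, value) for cvParam/userParam children, any depth."""
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            yield "cv", child.get("accession", ""), child.get("value", "")
        elif name == "userParam":
            yield "user", child.get("name", ""), child.get("value", "")


def parse_imzml_metadata(path: str | os.PathLike, *, validate: bool = True) -> DatasetMetadata:
    """Stream-parse an imzML file's metadata without loading spectral data.

    Parameters
    ----------
    path
        Path to the ``.imzML`` file; the sibling ``.ibd`` is located by
        replacing the extension.
    validate
        Verify the XML UUID against the first 16 bytes of the ``.ibd``,
        check offsets against the file size and positions against the grid.

    Returns
    -------
    DatasetMetadata
        Geometry, dialect flags, dtypes and one :class:`SpectrumRecord` per
        spectrum, ordered as in the XML.
    """
    path = os.fspath(path)
    ibd_path = _sibling_ibd(path)

    mode: str | None = None
    representation: str | None = None
    uuid_hex: str | None = None
    width = height = 0
    pix_x = pix_y = pix_z = 1.0
    # referenceableParamGroup id -> ('mz'|'intensity', dtype)
    groups: dict[str, tuple[str | None, np.dtype | None]] = {}
    records: list[SpectrumRecord] = []
    max_z = 1

    try:
        context = etree.iterparse(path, events=("end",), remove_comments=True)
        for _event, elem in context:
            tag = _localname(elem.tag)
            if tag == "fileContent":
                for kind, key, value in _iter_params(elem):
                    if kind != "cv":
                        continue
                    if key == _ACC_UUID:
                        uuid_hex = value
                    elif key == _ACC_CONTINUOUS:
                        mode = "continuous"
                    elif key == _ACC_PROCESSED:
                        mode = "processed"
                    elif key == _ACC_PROFILE:
                        representation = "profile"
                    elif key == _ACC_CENTROID:
                        representation = "centroid"
                elem.clear()
            elif tag == "referenceableParamGroup":
                gid = elem.get("id", "")
                role: str | None = None
                dtype: np.dtype | None = None
                for kind, key, _value in _iter_params(elem):
                    if kind != "cv":
                        continue
                    if key == _ACC_MZ_ARRAY:
                        role = "mz"
                    elif key == _ACC_INT_ARRAY:
                        role = "intensity"
                    elif key in _DTYPE_ACCESSIONS:
                        dtype = _DTYPE_ACCESSIONS[key]
                groups[gid] = (role, dtype)
                elem.clear()
            elif tag == "scanSettings":
                for kind, key, value in _iter_params(elem):
                    if kind != "cv":
                        continue
                    if key == _ACC_MAX_X:
                        width = int(value)
                    elif key == _ACC_MAX_Y:
                        height = int(value)
                    elif key == _ACC_PIXSIZE_X:
                        pix_x = float(value)
                    elif key == _ACC_PIXSIZE_Y:
                        pix_y = float(value)
                for kind, key, value in _iter_params(elem):
                    if kind == "user" and key == "pixel size z":
                        pix_z = float(value)
                elem.clear()
            elif tag == "spectrum":
                rec = _parse_spectrum_element(elem, groups, len(records))
                records.append(rec)
                max_z = max(max_z, rec.z)
                # Drop the processed subtree and any exhausted siblings so
                # retained XML memory stays bounded by one spectrum element.
                elem.clear()
                parent = elem.getparent()
                if parent is not None:
                    while elem.getprevious() is not None:
                        del parent[0]
    except etree.XMLSyntaxError as exc:
        raise ImzmlParseError(f"malformed imzML XML in {path}: {exc}") from exc

    if mode is None or representation is None:
        raise ImzmlParseError(
            f"{path}: fileContent lacks continuous/processed or profile/centroid flags"
        )
    if uuid_hex is None:
        raise ImzmlParseError(f"{path}: missing universally unique identifier")

    mz_dtype = intensity_dtype = None
    for role, dtype in groups.values():
        if role == "mz":
            mz_dtype = dtype
        elif role == "intensity":
            intensity_dtype = dtype
    if mz_dtype is None or intensity_dtype is None:
        raise ImzmlParseError(f"{path}: missing m/z or intensity array param group")

    uuid_bytes = _uuidlib.UUID(uuid_hex.strip("{}")).bytes

    if width == 0:
        width = max((r.x for r in records), default=1)
    if height == 0:
        height = max((r.y for r in records), default=1)

    meta = DatasetMetadata(
        image_width=width,
        image_height=height,
        image_depth=max_z,
        pixel_size_x=pix_x,
        pixel_size_y=pix_y,
        pixel_size_z=pix_z,
        mode=mode,
        representation=representation,
        uuid=uuid_bytes,
        mz_dtype=mz_dtype,
        intensity_dtype=intensity_dtype,
        spectra=records,
        imzml_path=path,
        ibd_path=ibd_path,
    )
    if validate:
        _validate_metadata(meta)
    return meta


def _sibling_ibd(path: str) -> str:
    base, _ext = os.path.splitext(path)
    for candidate in (base + ".ibd", base + ".IBD"):
        if os.path.exists(candidate):
            return candidate
    raise FileNotFoundError(f"no .ibd container next to {path}")


def _parse_spectrum_element(elem, groups, index: int) -> SpectrumRecord:
    x = y = 0
    z = 1
    norm_factor = None
    mz_offset = mz_length = int_offset = int_length = 0

    for kind, key, value in _iter_params(elem):
        if kind == "cv":
            if key == _ACC_POS_X:
                x = int(value)
            elif key == _ACC_POS_Y:
                y = int(value)
            elif key == _ACC_POS_Z:
                z = int(value)
        elif kind == "user" and key == _USERPARAM_NORMFACTOR:
            norm_factor = float(value)

    for child in elem.iter():
        if _localname(child.tag) != "binaryDataArray":
            continue
        role = None
        offset = length = 0
        for sub in child.iter():
            name = _localname(sub.tag)
            if name == "referenceableParamGroupRef":
                role = groups.get(sub.get("ref", ""), (None, None))[0]
            elif name == "cvParam":
                acc = sub.get("accession", "")
                if acc == _ACC_EXT_OFFSET:
                    offset = int(sub.get("value", "0"))
                elif acc == _ACC_EXT_ARRAY_LEN:
                    length = int(sub.get("value", "0"))
                elif acc == _ACC_MZ_ARRAY:
                    role = "mz"
                elif acc == _ACC_INT_ARRAY:
                    role = "intensity"
        if role == "mz":
            mz_offset, mz_length = offset, length
        elif role == "intensity":
            int_offset, int_length = offset, length

    if x <= 0 or y <= 0:
        raise ImzmlParseError(f"spectrum {index}: missing or non-positive pixel position")
    return SpectrumRecord(
        index=index,
        x=x,
        y=y,
        z=z,
        mz_offset=mz_offset,
        mz_length=mz_length,
        intensity_offset=int_offset,
        intensity_length=int_length,
        in_file_normalization_factor=norm_factor,
    )


def _validate_metadata(meta: DatasetMetadata) -> None:
    with open(meta.ibd_path, "rb") as fh:
        header = fh.read(16)
        fh.seek(0, os.SEEK_END)
        ibd_size = fh.tell()
    if header != meta.uuid:
        raise IntegrityError(
            f"UUID mismatch: XML declares {meta.uuid.hex()} but .ibd header is {header.hex()}"
        )
    mz_item = meta.mz_dtype.itemsize
    int_item = meta.intensity_dtype.itemsize
    for rec in meta.spectra:
        if not (1 <= rec.x <= meta.image_width and 1 <= rec.y <= meta.image_height):
            raise IntegrityError(
                f"spectrum {rec.index}: position ({rec.x},{rec.y}) outside "
                f"{meta.image_width}x{meta.image_height} grid"
            )
        if rec.mz_offset + rec.mz_length * mz_item > ibd_size:
            raise IntegrityError(f"spectrum {rec.index}: m/z block exceeds .ibd size")
        if rec.intensity_offset + rec.intensity_length * int_item > ibd_size:
            raise IntegrityError(f"spectrum {rec.index}: intensity block exceeds .ibd size")
        if rec.mz_length != rec.intensity_length:
            raise IntegrityError(
                f"spectrum {rec.index}: m/z length {rec.mz_length} != "
                f"intensity length {rec.intensity_length}"
            )
    if meta.mode == "continuous" and meta.spectra:
        first = meta.spectra[0]
        for rec in meta.spectra:
            if rec.mz_offset != first.mz_offset or rec.mz_length != first.mz_length:
                raise IntegrityError(
                    "continuous dataset with non-shared m/z axis "
                    f"(spectrum {rec.index})"
                )


def read_spectrum(
    meta: DatasetMetadata, index: int, ibd: BinaryIO | None = None
) -> Spectrum:
    """Read exactly one spectrum's bytes from the binary container.

    For continuous data every index returns the identical shared m/z array.
    Arrays are decoded little-endian at the dtypes declared in the XML.
    """
    if not 0 <= index < len(meta.spectra):
        raise IndexError(f"spectrum index {index} out of range [0, {len(meta.spectra)})")
    rec = meta.spectra[index]
    own = ibd is None
    fh = open(meta.ibd_path, "rb") if own else ibd
    try:
        mz = _read_block(fh, rec.mz_offset, rec.mz_length, meta.mz_dtype)
        intensity = _read_block(
            fh, rec.intensity_offset, rec.intensity_length, meta.intensity_dtype
        )
    finally:
        if own:
            fh.close()
    return Spectrum(index=index, mz=mz, intensity=intensity)


def _read_block(fh: BinaryIO, offset: int, n_elements: int, dtype: np.dtype) -> np.ndarray:
    fh.seek(offset)
    nbytes = n_elements * dtype.itemsize
    buf = fh.read(nbytes)
    if len(buf) != nbytes:
        raise IOError(
            f"truncated .ibd: wanted {nbytes} bytes at offset {offset}, got {len(buf)}"
        )
    return np.frombuffer(buf, dtype=dtype)


def _worker_ranges(n: int, n_workers: int) -> list[range]:
    """Contiguous, block-aligned, near-equal index ranges (remainder last)."""
    n_blocks = -(-n // REDUCTION_BLOCK) if n else 0
    per_worker = n_blocks // n_workers
    ranges = []
    start_block = 0
    for w in range(n_workers):
        nb = per_worker if w < n_workers - 1 else n_blocks - start_block
        lo = start_block * REDUCTION_BLOCK
        hi = min(n, (start_block + nb) * REDUCTION_BLOCK)
        ranges.append(range(lo, hi))
        start_block += nb
    return ranges


def iterate_spectra_chunked(
    meta: DatasetMetadata,
    n_workers: int,
    per_spectrum_fn: Callable[[Spectrum], object],
    reducer: Callable[[object, object], object],
):
    """Map ``per_spectrum_fn`` over all spectra and fold with ``reducer``.

    Spectra are assigned to workers in contiguous, near-equal index ranges.
    The fold is performed within fixed blocks of :data:`REDUCTION_BLOCK`
    spectra and then across blocks in index order, so the result is
    bit-identical for any worker count (the reducer must be associative and
    commutative).  Spectrum data are discarded after processing; retained
    memory is proportional to the number of blocks, not to the binary size.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    n = len(meta.spectra)
    if n == 0:
        raise ValueError("dataset has no spectra")

    n_blocks = -(-n // REDUCTION_BLOCK)
    block_results: list[object] = [None] * n_blocks

    def run_range(idx_range: range) -> None:
        if len(idx_range) == 0:
            return
        with open(meta.ibd_path, "rb") as fh:
            for block_start in range(idx_range.start, idx_range.stop, REDUCTION_BLOCK):
                block_id = block_start // REDUCTION_BLOCK
                acc = None
                for i in range(block_start, min(block_start + REDUCTION_BLOCK, idx_range.stop)):
                    value = per_spectrum_fn(read_spectrum(meta, i, ibd=fh))
                    acc = value if acc is None else reducer(acc, value)
                block_results[block_id] = acc

    ranges = _worker_ranges(n, n_workers)
    if n_workers == 1:
        run_range(range(0, n))
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            futures = [pool.submit(run_range, r) for r in ranges]
            for fut in futures:
                fut.result()  # surfaces the first worker error

    result = block_results[0]
    for blk in block_results[1:]:
        result = reducer(result, blk)
    return result


def write_imzml(
    geometry: DatasetMetadata | dict,
    spectra: Iterable[PixelSpectrum] | Sequence[PixelSpectrum],
    dialect: str,
    imzml_path: str | os.PathLike,
    ibd_path: str | os.PathLike | None = None,
    *,
    mz_dtype: np.dtype | str = "<f8",
    intensity_dtype: np.dtype | str = "<f4",
    uuid: bytes | None = None,
) -> DatasetMetadata:
    """Write an imzML/.ibd pair in one of the three supported dialects.

    Parameters
    ----------
    geometry
        A :class:`DatasetMetadata` or a dict with keys ``image_width``,
        ``image_height`` and optionally ``image_depth``, ``pixel_size_x/y/z``.
    spectra
        Iterable of :class:`PixelSpectrum`; consumed once (streaming).
    dialect
        ``continuous-profile``, ``continuous-centroid`` or
        ``processed-centroid``.  Continuous dialects require all spectra to
        share one m/z axis (checked; the axis is stored once).
    uuid
        16 bytes; freshly generated when omitted.  Written to both the XML
        and the .ibd header.

    Returns
    -------
    DatasetMetadata describing the written files (re-parsed from disk).
    """
    if dialect not in ("continuous-profile", "continuous-centroid", "processed-centroid"):
        raise DialectError(f"unknown dialect {dialect!r}")
    mode, representation = dialect.rsplit("-", 1)
    mode = "continuous" if mode == "continuous" else "processed"

    mz_dtype = np.dtype(mz_dtype)
    intensity_dtype = np.dtype(intensity_dtype)
    if mz_dtype not in _DTYPE_NAMES or intensity_dtype not in _DTYPE_NAMES:
        raise ValueError("dtypes must be one of <f4, <f8, <i4, <i8")

    if uuid is None:
        uuid = _uuidlib.uuid4().bytes
    if len(uuid) != 16:
        raise ValueError("uuid must be 16 bytes")

    geo = _geometry_dict(geometry)
    imzml_path = os.fspath(imzml_path)
    if ibd_path is None:
        ibd_path = os.path.splitext(imzml_path)[0] + ".ibd"
    ibd_path = os.fspath(ibd_path)

    records: list[dict] = []
    shared_mz: np.ndarray | None = None
    shared_offset = 0

    with open(ibd_path, "wb") as fh:
        fh.write(uuid)
        for spec in spectra:
            mz = np.ascontiguousarray(spec.mz, dtype=mz_dtype)
            inten = np.ascontiguousarray(spec.intensity, dtype=intensity_dtype)
            if mz.shape != inten.shape:
                raise DialectError("m/z and intensity arrays must have equal length")
            if mode == "continuous":
                if shared_mz is None:
                    shared_mz = mz
                    shared_offset = fh.tell()
                    fh.write(mz.tobytes())
                elif len(mz) != len(shared_mz) or not np.array_equal(mz, shared_mz):
                    raise DialectError(
                        "continuous dialect requires a single shared m/z axis"
                    )
                mz_offset, mz_length = shared_offset, len(shared_mz)
            else:
                mz_offset = fh.tell()
                mz_length = len(mz)
                fh.write(mz.tobytes())
            int_offset = fh.tell()
            fh.write(inten.tobytes())
            records.append(
                dict(
                    x=spec.x,
                    y=spec.y,
                    z=spec.z,
                    mz_offset=mz_offset,
                    mz_length=mz_length,
                    intensity_offset=int_offset,
                    intensity_length=len(inten),
                    norm=spec.normalization_factor,
                )
            )

    _write_imzml_xml(
        imzml_path,
        geo,
        records,
        mode=mode,
        representation=representation,
        uuid=uuid,
        mz_dtype=mz_dtype,
        intensity_dtype=intensity_dtype,
    )
    return parse_imzml_metadata(imzml_path)


def _geometry_dict(geometry) -> dict:
    if isinstance(geometry, DatasetMetadata):
        return dict(
            image_width=geometry.image_width,
            image_height=geometry.image_height,
            image_depth=geometry.image_depth,
            pixel_size_x=geometry.pixel_size_x,
            pixel_size_y=geometry.pixel_size_y,
            pixel_size_z=geometry.pixel_size_z,
        )
    geo = dict(geometry)
    geo.setdefault("image_depth", 1)
    geo.setdefault("pixel_size_x", 1.0)
    geo.setdefault("pixel_size_y", 1.0)
    geo.setdefault("pixel_size_z", 1.0)
    return geo


def _cv(parent, accession: str, name: str, value: str | None = None, cv_ref=None):
    attrs = {
        "cvRef": cv_ref or accession.split(":")[0],
        "accession": accession,
        "name": name,
    }
    if value is not None:
        attrs["value"] = value
    return etree.SubElement(parent, "cvParam", attrs)


def _write_imzml_xml(
    path, geo, records, *, mode, representation, uuid, mz_dtype, intensity_dtype
) -> None:
    nsmap = {None: "http://psi.hupo.org/ms/mzml"}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1")

    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="IMS", fullName="Imaging MS Ontology",
        URI="https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo",
    )

    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    if representation == "profile":
        _cv(fcontent, _ACC_PROFILE, "profile spectrum")
    else:
        _cv(fcontent, _ACC_CENTROID, "centroid spectrum")
    if mode == "continuous":
        _cv(fcontent, _ACC_CONTINUOUS, "continuous")
    else:
        _cv(fcontent, _ACC_PROCESSED, "processed")
    _cv(fcontent, _ACC_UUID, "universally unique identifier",
        "{" + str(_uuidlib.UUID(bytes=uuid)) + "}")

    rpglist = etree.SubElement(root, "referenceableParamGroupList", count="2")
    mzgroup = etree.SubElement(rpglist, "referenceableParamGroup", id="mzArray")
    _cv(mzgroup, _ACC_MZ_ARRAY, "m/z array", "")
    acc, name = _DTYPE_NAMES[mz_dtype]
    _cv(mzgroup, acc, name)
    _cv(mzgroup, _ACC_EXTERNAL_DATA, "external data", "true")
    igroup = etree.SubElement(rpglist, "referenceableParamGroup", id="intensityArray")
    _cv(igroup, _ACC_INT_ARRAY, "intensity array", "")
    acc, name = _DTYPE_NAMES[intensity_dtype]
    _cv(igroup, acc, name)
    _cv(igroup, _ACC_EXTERNAL_DATA, "external data", "true")

    sslist = etree.SubElement(root, "scanSettingsList", count="1")
    ss = etree.SubElement(sslist, "scanSettings", id="scanSettings0")
    _cv(ss, _ACC_MAX_X, "max count of pixels x", str(geo["image_width"]))
    _cv(ss, _ACC_MAX_Y, "max count of pixels y", str(geo["image_height"]))
    _cv(ss, _ACC_PIXSIZE_X, "pixel size x", str(geo["pixel_size_x"]))
    _cv(ss, _ACC_PIXSIZE_Y, "pixel size y", str(geo["pixel_size_y"]))
    etree.SubElement(
        ss, "userParam", name="pixel size z", value=str(geo["pixel_size_z"])
    )

    swlist = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(swlist, "software", id="msilazy", version="0.1.0")

    iclist = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(iclist, "instrumentConfiguration", id="IC0")

    dplist = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dplist, "dataProcessing", id="export")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="msilazy")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run = etree.SubElement(
        root, "run", id="run0", defaultInstrumentConfigurationRef="IC0"
    )
    slist = etree.SubElement(run, "spectrumList", count=str(len(records)))
    mz_item = mz_dtype.itemsize
    int_item = intensity_dtype.itemsize
    for i, rec in enumerate(records):
        sp = etree.SubElement(
            slist, "spectrum", id=f"spectrum={i + 1}", index=str(i),
            defaultArrayLength=str(rec["intensity_length"]),
        )
        if rec["norm"] is not None:
            etree.SubElement(
                sp, "userParam", name=_USERPARAM_NORMFACTOR, value=repr(rec["norm"])
            )
        scanlist = etree.SubElement(sp, "scanList", count="1")
        scan = etree.SubElement(scanlist, "scan")
        _cv(scan, _ACC_POS_X, "position x", str(rec["x"]))
        _cv(scan, _ACC_POS_Y, "position y", str(rec["y"]))
        _cv(scan, _ACC_POS_Z, "position z", str(rec["z"]))
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")

        ba = etree.SubElement(balist, "binaryDataArray", encodedLength="0")
        etree.SubElement(ba, "referenceableParamGroupRef", ref="mzArray")
        _cv(ba, _ACC_EXT_ARRAY_LEN, "external array length", str(rec["mz_length"]))
        _cv(ba, _ACC_EXT_ENCODED_LEN, "external encoded length",
            str(rec["mz_length"] * mz_item))
        _cv(ba, _ACC_EXT_OFFSET, "external offset", str(rec["mz_offset"]))
        etree.SubElement(ba, "binary")

        ba = etree.SubElement(balist, "binaryDataArray", encodedLength="0")
        etree.SubElement(ba, "referenceableParamGroupRef", ref="intensityArray")
        _cv(ba, _ACC_EXT_ARRAY_LEN, "external array length",
            str(rec["intensity_length"]))
        _cv(ba, _ACC_EXT_ENCODED_LEN, "external encoded length",
            str(rec["intensity_length"] * int_item))
        _cv(ba, _ACC_EXT_OFFSET, "external offset", str(rec["intensity_offset"]))
        etree.SubElement(ba, "binary")

    tree = etree.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1", pretty_print=True)
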