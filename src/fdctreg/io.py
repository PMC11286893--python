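"""Readers and writers for MetaImage (.mha) volumes, DICOM series, landmark
point lists and rigid-transform text files.

The MetaImage dialect is the single-file, uncompressed one: an ASCII
``key = value`` header terminated by ``ElementDataFile = LOCAL``, followed by
the raw little-endian voxel payload with the x index varying fastest.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import FormatError
from .transforms import LandmarkPairSet, RigidTransform3D
from .volume import Volume3D

__all__ = [
    "read_mha",
    "write_mha",
    "parse_mha_header",
    "read_dicom_series",
    "read_points",
    "write_points",
    "read_transform",
    "write_transform",
]

# MetaImage element type <-> numpy dtype (little endian)
_MET_TO_DTYPE = {
    "MET_UCHAR": np.dtype("uint8"),
    "MET_CHAR": np.dtype("int8"),
    "MET_USHORT": np.dtype("<u2"),
    "MET_SHORT": np.dtype("<i2"),
    "MET_INT": np.dtype("<i4"),
    "MET_UINT": np.dtype("<u4"),
    "MET_FLOAT": np.dtype("<f4"),
    "MET_DOUBLE": np.dtype("<f8"),
}
_DTYPE_TO_MET = {
    np.dtype("uint8"): "MET_UCHAR",
    np.dtype("int8"): "MET_CHAR",
    np.dtype("uint16"): "MET_USHORT",
    np.dtype("int16"): "MET_SHORT",
    np.dtype("int32"): "MET_INT",
    np.dtype("uint32"): "MET_UINT",
    np.dtype("float32"): "MET_FLOAT",
    np.dtype("float64"): "MET_DOUBLE",
}


# ---------------------------------------------------------------------------
# MetaImage
# ---------------------------------------------------------------------------

def parse_mha_header(raw: bytes) -> tuple[dict[str, str], int]:
    """Parse the ASCII header of a single-file MetaImage.

    Returns the key->value mapping and the byte offset where the voxel
    payload starts.  Raises :class:`FormatError` on malformed headers.
    """
    header: dict[str, str] = {}
    offset = 0
    while True:
        nl = raw.find(b"\n", offset)
        if nl < 0:
            raise FormatError("MHA header ended before ElementDataFile")
        line = raw[offset:nl].decode("ascii", errors="replace").strip()
        offset = nl + 1
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"malformed MHA header line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        header[key] = value
        if key == "ElementDataFile":
            return header, offset


def _require(header: dict[str, str], key: str) -> str:
    if key not in header:
        raise FormatError(f"MHA header is missing required key {key!r}")
    return header[key]


def read_mha(path: str | os.PathLike) -> Volume3D:
    """Read a single-file, uncompressed 3D MetaImage volume."""
    raw = Path(path).read_bytes()
    header, payload_start = parse_mha_header(raw)

    ndims = int(_require(header, "NDims"))
    if ndims != 3:
        raise FormatError(f"only 3D volumes are supported, got NDims = {ndims}")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError("compressed MHA payloads are not supported")
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise FormatError("big-endian MHA payloads are not supported")
    if _require(header, "ElementDataFile") != "LOCAL":
        raise FormatError("only ElementDataFile = LOCAL (single-file .mha) is supported")

    size = [int(v) for v in _require(header, "DimSize").split()]
    if len(size) != ndims:
        raise FormatError(f"DimSize lists {len(size)} values but NDims = {ndims}")
    spacing = [float(v) for v in _require(header, "ElementSpacing").split()]
    if len(spacing) != 3:
        raise FormatError("ElementSpacing must list 3 values")
    origin = [float(v) for v in header.get("Offset", "0 0 0").split()]
    tm = [float(v) for v in header.get("TransformMatrix", "1 0 0 0 1 0 0 0 1").split()]
    if len(tm) != 9:
        raise FormatError("TransformMatrix must list 9 values")
    met = _require(header, "ElementType")
    if met not in _MET_TO_DTYPE:
        raise FormatError(f"unsupported ElementType {met!r}")
    dtype = _MET_TO_DTYPE[met]

    n_vox = int(np.prod(size))
    expected = n_vox * dtype.itemsize
    payload = raw[payload_start:]
    if len(payload) < expected:
        raise FormatError(
            f"MHA payload holds {len(payload)} bytes but DimSize implies {expected}"
        )
    flat = np.frombuffer(payload[:expected], dtype=dtype)
    # MetaImage stores x fastest -> Fortran order for data[ix, iy, iz]
    data = flat.reshape(size, order="F")
    # TransformMatrix rows are the axis cosines; our direction holds them as columns
    direction = np.array(tm, dtype=float).reshape(3, 3).T
    return Volume3D(data, spacing, origin, direction)


def write_mha(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as a single-file, uncompressed MetaImage."""
    dtype = vol.data.dtype.newbyteorder("<") if vol.data.dtype.byteorder == ">" else vol.data.dtype
    if dtype not in _DTYPE_TO_MET:
        raise FormatError(f"cannot store dtype {vol.data.dtype} in an MHA file")
    met = _DTYPE_TO_MET[np.dtype(dtype)]
    tm = " ".join(format(v, ".17g") for v in vol.direction.T.ravel())
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        f"TransformMatrix = {tm}",
        "Offset = " + " ".join(format(v, ".17g") for v in vol.origin),
        "CenterOfRotation = 0 0 0",
        "ElementSpacing = " + " ".join(format(v, ".17g") for v in vol.spacing),
        "DimSize = " + " ".join(str(v) for v in vol.size),
        f"ElementType = {met}",
        "ElementDataFile = LOCAL",
    ]
    payload = np.ascontiguousarray(vol.data.astype(dtype, copy=False)).tobytes(order="F")
    Path(path).write_bytes(("\n".join(lines) + "\n").encode("ascii") + payload)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | os.PathLike) -> Volume3D:
    """Load a single-frame DICOM series from a directory into a volume.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal; inter-slice spacing is inferred from consecutive positions
    and must be uniform within 1e-3 mm.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise FormatError(f"no files found in {directory}")
    slices = []
    for p in paths:
        try:
            slices.append(pydicom.dcmread(p))
        except InvalidDicomError as exc:
            raise FormatError(f"{p.name} is not a DICOM file") from exc
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise FormatError(
            f"directory mixes {len(uids)} DICOM series: {sorted(str(u) for u in uids)}"
        )

    first = slices[0]
    row = np.array(first.ImageOrientationPatient[:3], dtype=float)
    col = np.array(first.ImageOrientationPatient[3:], dtype=float)
    normal = np.cross(row, col)
    order = np.argsort([float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float)))
                        for ds in slices])
    slices = [slices[i] for i in order]
    zpos = np.array(
        [float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))) for ds in slices]
    )

    if len(slices) > 1:
        gaps = np.diff(zpos)
        dz = float(np.mean(gaps))
        bad = np.nonzero(np.abs(gaps - dz) > 1e-3)[0]
        if bad.size:
            raise FormatError(
                "non-uniform inter-slice spacing at sorted slice indices "
                f"{bad.tolist()} (gaps {gaps[bad].tolist()} vs mean {dz:.6f} mm)"
            )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    ps = [float(v) for v in first.PixelSpacing]  # (row spacing, col spacing) = (y, x)
    spacing = np.array([ps[1], ps[0], dz])
    direction = np.column_stack([row, col, normal])
    origin = np.array(slices[0].ImagePositionPatient, dtype=float)

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr.T * slope + intercept)  # (rows, cols) -> (x, y)
    data = np.stack(planes, axis=2)
    return Volume3D(data, spacing, origin, direction)


# ---------------------------------------------------------------------------
# Plain-text landmarks and transforms
# ---------------------------------------------------------------------------

def read_points(path: str | os.PathLike) -> np.ndarray:
    """Read an (N, 3) array of physical points (mm): one ``x y z`` per line,
    '#' comments allowed."""
    pts = np.loadtxt(path, comments="#", dtype=float, ndmin=2)
    if pts.size == 0:
        return np.empty((0, 3))
    if pts.shape[1] != 3:
        raise FormatError(f"point file {path} has {pts.shape[1]} columns, expected 3")
    return pts


def write_points(points: np.ndarray, path: str | os.PathLike, header: str = "") -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = [f"# {header}"] if header else []
    lines += [" ".join(format(v, ".17g") for v in p) for p in points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmark_pairs(fixed_path, moving_path, labels=None) -> LandmarkPairSet:
    """Build a :class:`LandmarkPairSet` from two point files."""
    return LandmarkPairSet(read_points(fixed_path), read_points(moving_path), labels)


def read_transform(path: str | os.PathLike) -> RigidTransform3D:
    """Read a rigid transform from text: 9 rotation entries (row-major),
    3 translation, 3 center — 15 whitespace-separated numbers."""
    tokens = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(float(t) for t in line.split())
    if len(tokens) != 15:
        raise FormatError(f"transform file {path} holds {len(tokens)} values, expected 15")
    vals = np.array(tokens)
    return RigidTransform3D(vals[:9].reshape(3, 3), vals[9:12], vals[12:15])


def write_transform(T: RigidTransform3D, path: str | os.PathLike) -> None:
    lines = [
        "# rigid transform: rotation (3x3 row-major), translation (mm), center (mm)",
        *(" ".join(format(v, ".17g") for v in row) for row in T.rotation),
        " ".join(format(v, ".17g") for v in T.translation),
        " ".join(format(v, ".17g") for v in T.center),
    ]
    Path(path).write_text("\n".join(lines) + "\n")
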