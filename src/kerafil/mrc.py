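"""Minimal MRC2014 image/volume I/O.

Supports the subset of the format this pipeline produces and consumes:
mode 2 (32-bit float) single images, image stacks and volumes, little
endian, with the voxel size carried in the cell dimensions (CELLA / M).
A hand-written reader keeps the package dependency-free for this format;
the header layout follows the MRC2014 specification.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Union

import numpy as np

from .core import Image2D, Volume

__all__ = ["read_mrc", "write_mrc", "read_image", "MrcFormatError"]

_HEADER_BYTES = 1024
_MAP_ID = b"MAP "
# little-endian machine stamp per MRC2014
_MACHST_LE = bytes((0x44, 0x44, 0x00, 0x00))


class MrcFormatError(ValueError):
    """Raised for malformed or unsupported MRC files."""


def write_mrc(path: Union[str, Path], data: np.ndarray, voxel_size_A: float) -> None:
    """Write a 2D image, image stack or 3D volume as mode-2 MRC.

    2D input is written with NZ = 1.  Arrays are interpreted as
    (sections, rows, columns) = (NZ, NY, NX).
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected 2D or 3D data, got {data.ndim}D")
    if not voxel_size_A > 0:
        raise ValueError("voxel_size_A must be positive")
    nz, ny, nx = data.shape

    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                   # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into(
        "<3f", header, 40,
        nx * voxel_size_A, ny * voxel_size_A, nz * voxel_size_A,  # CELLA (Å)
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76,
        float(data.min()), float(data.max()), float(data.mean()),
    )
    struct.pack_into("<i", header, 88, 0 if nz == 1 else 0)  # ISPG: image/stack
    struct.pack_into("<i", header, 92, 0)                    # NSYMBT
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(data.std()))   # RMS
    struct.pack_into("<i", header, 220, 1)                   # NLABL
    header[224:224 + 24] = b"kerafil mode-2 MRC2014  "

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path: Union[str, Path]) -> tuple[np.ndarray, float]:
    """Read an MRC file, returning ``(data, voxel_size_A)``.

    Only modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16) are
    accepted; data is returned as float64 with shape (NZ, NY, NX), or
    (NY, NX) when NZ == 1.

    Raises
    ------
    MrcFormatError
        On truncated files, bad magic, unsupported mode, or when the
        header carries no usable voxel size.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise MrcFormatError(f"{path}: file shorter than the 1024-byte MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    map_id = raw[208:212]

    if map_id != _MAP_ID:
        raise MrcFormatError(f"{path}: missing 'MAP ' identifier (not MRC2014?)")
    if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100_000:
        raise MrcFormatError(f"{path}: implausible dimensions {(nx, ny, nz)}")

    dtypes = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
    if mode not in dtypes:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(dtypes[mode]).newbyteorder("<")

    n_items = nx * ny * nz
    offset = _HEADER_BYTES + nsymbt
    need = offset + n_items * dtype.itemsize
    if len(raw) < need:
        raise MrcFormatError(
            f"{path}: truncated data section ({len(raw)} bytes, need {need})"
        )

    if mx <= 0 or cella[0] <= 0:
        raise MrcFormatError(
            f"{path}: header carries no voxel size (MX={mx}, CELLA_x={cella[0]}); "
            "supply the pixel size explicitly"
        )
    voxel_size = cella[0] / mx

    data = np.frombuffer(raw, dtype=dtype, count=n_items, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float64)
    if nz == 1:
        data = data[0]
    return data, float(voxel_size)


def read_image(path: Union[str, Path], pixel_size_A: float | None = None
               ) -> Union[Image2D, Volume]:
    """Read an MRC file into an :class:`Image2D` (NZ == 1) or :class:`Volume`.

    ``pixel_size_A`` overrides the header voxel size when given; it is
    required when the header carries none.
    """
    try:
        data, vox = read_mrc(path)
    except MrcFormatError as exc:
        if pixel_size_A is not None and "no voxel size" in str(exc):
            raw = Path(path).read_bytes()
            nx, ny, nz = struct.unpack_from("<3i", raw, 0)
            data = np.frombuffer(
                raw, dtype=np.dtype(np.float32).newbyteorder("<"),
                count=nx * ny * nz, offset=_HEADER_BYTES,
            ).reshape(nz, ny, nx).astype(np.float64)
            if nz == 1:
                data = data[0]
            vox = pixel_size_A
        else:
            raise
    if pixel_size_A is not None:
        vox = pixel_size_A
    if data.ndim == 2:
        return Image2D(data, vox)
    return Volume(data, vox)
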