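"""Minimal MRC2014 volume reader/writer.

Implements the subset of the MRC2014 standard this package needs: mode 2
(float32) 3D maps with voxel size carried in the CELLA header field
(angstroms) and the map origin in the ORIGIN field. Axis order on disk is
the conventional C-order (section, row, column) = (z, y, x); in memory this
package indexes volumes as (x, y, z), so reading and writing transpose.
"""

from __future__ import annotations

import struct

import numpy as np

_HEADER_BYTES = 1024
_MAP_ID = b"MAP "
# little-endian machine stamp
_MACHST = b"\x44\x44\x00\x00"


def write_mrc(path, data_xyz: np.ndarray, voxel_size_angstrom, origin_angstrom=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D float32 volume; ``data_xyz`` is indexed [x, y, z]."""
    data = np.asarray(data_xyz, dtype="<f4")
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    nx, ny, nz = data.shape
    vx, vy, vz = (float(v) for v in voxel_size_angstrom)
    ox, oy, oz = (float(v) for v in origin_angstrom)

    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                   # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into("<3f", header, 40, vx * nx, vy * ny, vz * nz)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                   # ISPG (volume)
    struct.pack_into("<i", header, 92, 0)                   # NSYMBT
    struct.pack_into("<3f", header, 196, ox, oy, oz)        # ORIGIN
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST
    struct.pack_into("<f", header, 216, float(data.std()))  # RMS
    struct.pack_into("<i", header, 220, 1)                  # NLABL
    label = b"perivasc MRC2014 writer"
    header[224 : 224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # disk order (z, y, x)
        fh.write(np.ascontiguousarray(data.T).tobytes())


def read_mrc(path):
    """Read an MRC2014 volume.

    Returns ``(data_xyz, voxel_size_angstrom, origin_angstrom)`` with data
    indexed [x, y, z].
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode = struct.unpack_from("<i", header, 12)[0]
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        origin = struct.unpack_from("<3f", header, 196)
        if header[208:212] not in (_MAP_ID, b"MAP\x00"):
            raise ValueError(f"{path}: missing MAP identifier; not an MRC2014 file")
        dtypes = {0: "i1", 1: "<i2", 2: "<f4", 6: "<u2", 12: "<f2"}
        if mode not in dtypes:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        fh.seek(_HEADER_BYTES + nsymbt)
        data = np.fromfile(fh, dtype=dtypes[mode], count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated data block")
    data = data.reshape(nz, ny, nx).T  # -> (x, y, z)
    grid = np.array([mx or nx, my or ny, mz or nz], dtype=float)
    voxel = np.asarray(cella, dtype=float) / grid
    return np.asarray(data, dtype=np.float32), voxel, np.asarray(origin, dtype=float)
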