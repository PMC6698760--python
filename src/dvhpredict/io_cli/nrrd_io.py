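"""Minimal NRRD reader/writer for 3-D volumes (raw encoding, little endian).

Covers exactly the subset this package writes: one attached-header NRRD per
volume with axis-aligned space directions.  Kept in-repo because no NRRD
library is available in the runtime environment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..errors import FormatError
from ..volumes import VolumeGrid

_MAGIC = b"NRRD0004"

_TYPE_MAP = {
    "uint8": np.uint8,
    "unsigned char": np.uint8,
    "float": np.float32,
    "double": np.float64,
}
_DTYPE_NAME = {np.dtype(np.uint8): "uint8", np.dtype(np.float32): "float",
               np.dtype(np.float64): "double"}


def write_nrrd(path: str | Path, array: np.ndarray, grid: VolumeGrid) -> None:
    """Write a 3-D array on a grid; first array axis is the fastest on disk."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise FormatError(f"array shape {array.shape} != grid shape {grid.shape}")
    if array.dtype == bool:
        array = array.astype(np.uint8)
    dtype = np.dtype(array.dtype).newbyteorder("<")
    name = _DTYPE_NAME.get(np.dtype(array.dtype))
    if name is None:
        raise FormatError(f"unsupported dtype {array.dtype}")
    sx, sy, sz = grid.spacing
    header = (
        f"{_MAGIC.decode()}\n"
        f"type: {name}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({grid.origin[0]},{grid.origin[1]},{grid.origin[2]})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(array.astype(dtype)).tobytes(order="F"))


def _parse_vector(text: str) -> tuple[float, ...]:
    return tuple(float(v) for v in text.strip().lstrip("(").rstrip(")").split(","))


def read_nrrd(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a volume written by :func:`write_nrrd`."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        data = fh.read()

    if fields.get("encoding") != "raw":
        raise FormatError(f"{path}: only raw encoding supported, got {fields.get('encoding')!r}")
    if int(fields.get("dimension", 0)) != 3:
        raise FormatError(f"{path}: only 3-D volumes supported")
    dtype = _TYPE_MAP.get(fields.get("type", ""))
    if dtype is None:
        raise FormatError(f"{path}: unsupported type {fields.get('type')!r}")
    if fields.get("endian", "little") != "little":
        raise FormatError(f"{path}: only little-endian supported")
    sizes = tuple(int(v) for v in fields["sizes"].split())
    dirs = [_parse_vector(v) for v in fields["space directions"].split(") (")]
    spacing = tuple(dirs[k][k] for k in range(3))
    origin = _parse_vector(fields.get("space origin", "(0,0,0)"))
    for k, d in enumerate(dirs):
        for j, v in enumerate(d):
            if j != k and abs(v) > 1e-9:
                raise FormatError(f"{path}: oblique space directions not supported")
    grid = VolumeGrid(shape=sizes, spacing=spacing, origin=origin)
    expected = int(np.prod(sizes)) * np.dtype(dtype).itemsize
    if len(data) < expected:
        raise FormatError(f"{path}: truncated data ({len(data)} < {expected} bytes)")
    array = np.frombuffer(data[:expected], dtype=np.dtype(dtype).newbyteorder("<"))
    return array.reshape(sizes, order="F").astype(dtype), grid
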