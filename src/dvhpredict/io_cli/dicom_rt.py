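"""Minimal DICOM-RT codec: RT Structure Set and RT Dose, explicit VR little
endian only.

No DICOM library exists in the runtime environment, so this module
implements the narrow subset the package needs: writing phantom plans as an
RTSTRUCT/RTDOSE pair and reading such pairs (or any conforming explicit-VR
little-endian files restricted to the tags used here) back into a
:class:`~dvhpredict.io_cli.portable.PlanBundle`.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from ..errors import FormatError, ModelInputError
from ..volumes import ContourSet, DoseGrid, StructureMask, VolumeGrid
from .portable import PlanBundle

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1405"  # arbitrary org root for generated UIDs

_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}

Tag = tuple[int, int]

# tags used by the writer / understood by the reader
TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_MODALITY = (0x0008, 0x0060)
TAG_FRAME_OF_REF = (0x0020, 0x0052)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_NUMBER_OF_FRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_GRID_FRAME_OFFSETS = (0x3004, 0x000C)
TAG_DOSE_GRID_SCALING = (0x3004, 0x000E)
TAG_STRUCT_SET_ROI_SEQ = (0x3006, 0x0020)
TAG_ROI_NUMBER = (0x3006, 0x0022)
TAG_ROI_NAME = (0x3006, 0x0026)
TAG_ROI_CONTOUR_SEQ = (0x3006, 0x0039)
TAG_CONTOUR_SEQ = (0x3006, 0x0040)
TAG_CONTOUR_GEOM_TYPE = (0x3006, 0x0042)
TAG_N_CONTOUR_POINTS = (0x3006, 0x0046)
TAG_CONTOUR_DATA = (0x3006, 0x0050)
TAG_REF_ROI_NUMBER = (0x3006, 0x0084)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


# ---------------------------------------------------------------------------
# element encode / decode
# ---------------------------------------------------------------------------


def _pad(value: bytes, pad_byte: bytes) -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _encode_value(vr: str, value) -> bytes:
    if vr == "UI":
        return _pad(str(value).encode("ascii"), b"\x00")
    if vr in ("CS", "LO", "SH", "ST", "DA", "TM", "PN"):
        return _pad(str(value).encode("ascii"), b" ")
    if vr in ("DS", "IS"):
        if not isinstance(value, (list, tuple, np.ndarray)):
            value = [value]
        if vr == "DS":
            text = "\\".join(f"{float(v):.10g}" for v in value)
        else:
            text = "\\".join(str(int(v)) for v in value)
        return _pad(text.encode("ascii"), b" ")
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    if vr in ("OW", "OB"):
        return bytes(value)
    raise FormatError(f"cannot encode VR {vr}")


def _encode_element(tag: Tag, vr: str, payload: bytes) -> bytes:
    head = struct.pack("<HH", tag[0], tag[1]) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    if len(payload) > 0xFFFF:
        raise FormatError(f"value too long for short VR {vr}")
    return head + struct.pack("<H", len(payload)) + payload


def _encode_dataset(elements: list[tuple[Tag, str, object]]) -> bytes:
    out = b""
    for tag, vr, value in sorted(elements, key=lambda e: e[0]):
        if vr == "SQ":
            items = b""
            for item in value:  # each item is a list of elements
                body = _encode_dataset(item)
                items += struct.pack("<HHI", 0xFFFE, 0xE000, len(body)) + body
            out += _encode_element(tag, "SQ", items)
        else:
            out += _encode_element(tag, vr, _encode_value(vr, value))
    return out


def _write_file(path: str | Path, sop_class: str, sop_instance: str,
                dataset: list[tuple[Tag, str, object]]) -> None:
    meta = _encode_dataset(
        [
            ((0x0002, 0x0002), "UI", sop_class),
            ((0x0002, 0x0003), "UI", sop_instance),
            (TAG_TRANSFER_SYNTAX, "UI", EXPLICIT_VR_LE),
        ]
    )
    group_len = _encode_element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta)))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len + meta)
        fh.write(_encode_dataset(dataset))


class _Reader:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def eof(self) -> bool:
        return self.pos >= len(self.data)

    def read_element(self):
        g, e = struct.unpack_from("<HH", self.data, self.pos)
        self.pos += 4
        if g == 0xFFFE:  # item / delimiter: implicit structure, 4-byte length
            (length,) = struct.unpack_from("<I", self.data, self.pos)
            self.pos += 4
            return (g, e), "ITEM", length
        vr = self.data[self.pos : self.pos + 2].decode("ascii")
        self.pos += 2
        if vr in _LONG_VRS:
            self.pos += 2  # reserved
            (length,) = struct.unpack_from("<I", self.data, self.pos)
            self.pos += 4
        else:
            (length,) = struct.unpack_from("<H", self.data, self.pos)
            self.pos += 2
        return (g, e), vr, length

    def read_bytes(self, n: int) -> bytes:
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out


def _decode_value(vr: str, raw: bytes):
    if vr in ("UI", "CS", "LO", "SH", "ST", "DA", "TM", "PN"):
        return raw.decode("ascii", errors="replace").strip("\x00 ").strip()
    if vr == "DS":
        text = raw.decode("ascii").strip("\x00 ")
        return [float(v) for v in text.split("\\")] if text else []
    if vr == "IS":
        text = raw.decode("ascii").strip("\x00 ")
        return [int(v) for v in text.split("\\")] if text else []
    if vr == "US":
        return list(struct.unpack(f"<{len(raw) // 2}H", raw))
    if vr == "UL":
        return list(struct.unpack(f"<{len(raw) // 4}I", raw))
    return raw  # OB/OW/unknown kept as bytes


def _parse_dataset(reader: _Reader, end: int) -> dict:
    ds: dict[Tag, object] = {}
    while reader.pos < end and not reader.eof():
        tag, vr, length = reader.read_element()
        if tag == (0xFFFE, 0xE00D):  # item delimitation
            break
        if vr == "SQ":
            ds[tag] = _parse_sequence(reader, length)
        elif length == 0xFFFFFFFF:
            raise FormatError(f"undefined length outside SQ at tag {tag}")
        else:
            ds[tag] = _decode_value(vr, reader.read_bytes(length))
    return ds


def _parse_sequence(reader: _Reader, length: int) -> list[dict]:
    items = []
    seq_end = len(reader.data) if length == 0xFFFFFFFF else reader.pos + length
    while reader.pos < seq_end and not reader.eof():
        tag, vr, ilen = reader.read_element()
        if tag == (0xFFFE, 0xE0DD):  # sequence delimitation
            break
        if tag != (0xFFFE, 0xE000):
            raise FormatError(f"expected item tag in sequence, got {tag}")
        item_end = len(reader.data) if ilen == 0xFFFFFFFF else reader.pos + ilen
        items.append(_parse_dataset(reader, item_end))
    return items


def read_dicom_file(path: str | Path) -> dict:
    """Parse one explicit-VR little-endian DICOM file into a tag dict."""
    data = Path(path).read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM preamble")
    reader = _Reader(data, 132)
    # file meta group (always explicit LE)
    tag, vr, length = reader.read_element()
    if tag != (0x0002, 0x0000):
        raise FormatError(f"{path}: missing file meta group length")
    (meta_len,) = struct.unpack("<I", reader.read_bytes(length))
    meta = _parse_dataset(_Reader(data, reader.pos), reader.pos + meta_len)
    ts = meta.get(TAG_TRANSFER_SYNTAX)
    if ts != EXPLICIT_VR_LE:
        raise FormatError(f"{path}: unsupported transfer syntax {ts!r}")
    reader.pos += meta_len
    ds = _parse_dataset(reader, len(data))
    ds.update(meta)
    return ds


# ---------------------------------------------------------------------------
# mask <-> contour conversion
# ---------------------------------------------------------------------------


def mask_to_contours(mask: StructureMask) -> ContourSet:
    """Exact rectilinear boundary polygons of a mask, slice by slice.

    Polygons trace voxel edges (centers sit strictly inside), so
    rasterizing them back reproduces the mask voxel-for-voxel; interior
    rings are emitted as separate polygons and become holes under the
    even-odd rule.
    """
    grid = mask.grid
    xs, ys, zs = (grid.axis_coords(k) for k in range(3))
    hx, hy = grid.spacing[0] / 2.0, grid.spacing[1] / 2.0
    polygons: list[tuple[float, np.ndarray]] = []
    for iz in range(grid.shape[2]):
        sl = mask.occupancy[:, :, iz]
        if not sl.any():
            continue
        ii, jj = np.nonzero(sl)
        cells = [box(xs[i] - hx, ys[j] - hy, xs[i] + hx, ys[j] + hy) for i, j in zip(ii, jj)]
        merged = unary_union(cells)
        geoms = merged.geoms if hasattr(merged, "geoms") else [merged]
        for g in geoms:
            polygons.append((float(zs[iz]), np.asarray(g.exterior.coords)[:-1]))
            for ring in g.interiors:
                polygons.append((float(zs[iz]), np.asarray(ring.coords)[:-1]))
    return ContourSet(name=mask.name, polygons=polygons)


# ---------------------------------------------------------------------------
# high-level write
# ---------------------------------------------------------------------------


def _uid(suffix: str) -> str:
    return f"{_UID_ROOT}.{suffix}"


def write_rt_dose(path: str | Path, dose: DoseGrid, frame_of_ref: str,
                  instance_suffix: str = "2.1") -> None:
    grid = dose.grid
    max_dose = float(dose.dose.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    pixels = np.round(dose.dose / scaling).astype(np.uint32)
    # frames along z, rows along y, columns along x
    raw = np.transpose(pixels, (2, 1, 0)).tobytes()
    ds = [
        (TAG_SOP_CLASS, "UI", RTDOSE_SOP_CLASS),
        (TAG_SOP_INSTANCE, "UI", _uid(instance_suffix)),
        (TAG_MODALITY, "CS", "RTDOSE"),
        (TAG_FRAME_OF_REF, "UI", frame_of_ref),
        (TAG_IMAGE_POSITION, "DS", list(grid.origin)),
        (TAG_NUMBER_OF_FRAMES, "IS", grid.shape[2]),
        (TAG_ROWS, "US", grid.shape[1]),
        (TAG_COLS, "US", grid.shape[0]),
        (TAG_PIXEL_SPACING, "DS", [grid.spacing[1], grid.spacing[0]]),
        (TAG_BITS_ALLOCATED, "US", 32),
        ((0x0028, 0x0103), "US", 0),  # unsigned pixels
        ((0x3004, 0x0002), "CS", "GY"),
        ((0x3004, 0x0004), "CS", "PHYSICAL"),
        (TAG_GRID_FRAME_OFFSETS, "DS", [k * grid.spacing[2] for k in range(grid.shape[2])]),
        (TAG_DOSE_GRID_SCALING, "DS", scaling),
        (TAG_PIXEL_DATA, "OW", raw),
    ]
    _write_file(path, RTDOSE_SOP_CLASS, _uid(instance_suffix), ds)


def write_rt_struct(path: str | Path, masks: dict[str, StructureMask], frame_of_ref: str,
                    instance_suffix: str = "3.1") -> None:
    if not masks:
        raise ModelInputError("cannot write an RT Structure Set with zero structures")
    roi_seq, contour_seq = [], []
    for number, name in enumerate(sorted(masks), start=1):
        contours = mask_to_contours(masks[name])
        roi_seq.append(
            [
                (TAG_ROI_NUMBER, "IS", number),
                ((0x3006, 0x0024), "UI", frame_of_ref),
                (TAG_ROI_NAME, "LO", name),
            ]
        )
        items = []
        for z, verts in contours.polygons:
            data = np.column_stack([verts, np.full(len(verts), z)]).ravel()
            items.append(
                [
                    (TAG_CONTOUR_GEOM_TYPE, "CS", "CLOSED_PLANAR"),
                    (TAG_N_CONTOUR_POINTS, "IS", len(verts)),
                    (TAG_CONTOUR_DATA, "DS", data.tolist()),
                ]
            )
        contour_seq.append(
            [(TAG_CONTOUR_SEQ, "SQ", items), (TAG_REF_ROI_NUMBER, "IS", number)]
        )
    ds = [
        (TAG_SOP_CLASS, "UI", RTSTRUCT_SOP_CLASS),
        (TAG_SOP_INSTANCE, "UI", _uid(instance_suffix)),
        (TAG_MODALITY, "CS", "RTSTRUCT"),
        (TAG_FRAME_OF_REF, "UI", frame_of_ref),
        (TAG_STRUCT_SET_ROI_SEQ, "SQ", roi_seq),
        (TAG_ROI_CONTOUR_SEQ, "SQ", contour_seq),
    ]
    _write_file(path, RTSTRUCT_SOP_CLASS, _uid(instance_suffix), ds)


def export_plan_dicom(plan, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a SyntheticPlan (or PlanBundle with masks) as an RTSTRUCT/RTDOSE
    pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks = plan.structures if hasattr(plan, "structures") else plan.masks
    dose = plan.dose
    frame = _uid(f"1.{abs(hash(plan.plan_id)) % 100000}")
    struct_path = out / "rtstruct.dcm"
    dose_path = out / "rtdose.dcm"
    write_rt_struct(struct_path, masks, frame)
    write_rt_dose(dose_path, dose, frame)
    return struct_path, dose_path


# ---------------------------------------------------------------------------
# high-level read
# ---------------------------------------------------------------------------


def _single(value):
    return value[0] if isinstance(value, list) else value


def read_dicom_rt(structure_set_path: str | Path, dose_path: str | Path,
                  plan_id: str = "", allow_frame_mismatch: bool = False) -> PlanBundle:
    """Read an RT Structure Set / RT Dose pair into a PlanBundle (contours +
    dose)."""
    sds = read_dicom_file(structure_set_path)
    dds = read_dicom_file(dose_path)
    s_mod = sds.get(TAG_MODALITY)
    d_mod = dds.get(TAG_MODALITY)
    if s_mod != "RTSTRUCT":
        raise FormatError(f"{structure_set_path}: expected RTSTRUCT, found modality {s_mod!r}")
    if d_mod != "RTDOSE":
        raise FormatError(f"{dose_path}: expected RTDOSE, found modality {d_mod!r}")

    s_frame = sds.get(TAG_FRAME_OF_REF) or (
        sds.get(TAG_STRUCT_SET_ROI_SEQ, [{}])[0].get((0x3006, 0x0024))
    )
    d_frame = dds.get(TAG_FRAME_OF_REF)
    if s_frame and d_frame and s_frame != d_frame and not allow_frame_mismatch:
        raise FormatError(
            f"frame-of-reference mismatch: {s_frame!r} vs {d_frame!r} "
            "(pass allow_frame_mismatch=True to override)"
        )

    if TAG_DOSE_GRID_SCALING not in dds:
        raise FormatError(f"{dose_path}: missing DoseGridScaling tag")
    scaling = _single(dds[TAG_DOSE_GRID_SCALING])
    rows = _single(dds[TAG_ROWS])
    cols = _single(dds[TAG_COLS])
    frames = int(_single(dds.get(TAG_NUMBER_OF_FRAMES, 1)))
    pos = dds[TAG_IMAGE_POSITION]
    row_sp, col_sp = dds[TAG_PIXEL_SPACING]
    offsets = dds[TAG_GRID_FRAME_OFFSETS]
    z_steps = np.diff(offsets)
    if len(offsets) > 1 and not np.allclose(z_steps, z_steps[0]):
        raise FormatError(f"{dose_path}: non-uniform frame offsets not supported")
    z_sp = float(z_steps[0]) if len(offsets) > 1 else 1.0
    bits = int(_single(dds.get(TAG_BITS_ALLOCATED, 32)))
    dtype = {16: np.uint16, 32: np.uint32}.get(bits)
    if dtype is None:
        raise FormatError(f"{dose_path}: unsupported BitsAllocated {bits}")
    raw = np.frombuffer(dds[TAG_PIXEL_DATA], dtype=np.dtype(dtype).newbyteorder("<"))
    raw = raw[: frames * rows * cols].reshape(frames, rows, cols)
    dose_arr = np.transpose(raw, (2, 1, 0)).astype(float) * float(scaling)
    grid = VolumeGrid(
        shape=(cols, rows, frames),
        spacing=(float(col_sp), float(row_sp), z_sp),
        origin=(float(pos[0]), float(pos[1]), float(pos[2])),
    )
    bundle = PlanBundle(plan_id=plan_id or Path(structure_set_path).parent.name,
                        dose=DoseGrid(grid=grid, dose=dose_arr))

    roi_names = {}
    for item in sds.get(TAG_STRUCT_SET_ROI_SEQ, []):
        roi_names[int(_single(item[TAG_ROI_NUMBER]))] = item[TAG_ROI_NAME]
    if not roi_names:
        raise FormatError(f"{structure_set_path}: structure set contains zero ROIs")
    for item in sds.get(TAG_ROI_CONTOUR_SEQ, []):
        number = int(_single(item[TAG_REF_ROI_NUMBER]))
        name = roi_names.get(number, f"ROI{number}")
        polygons = []
        for c in item.get(TAG_CONTOUR_SEQ, []):
            data = np.asarray(c[TAG_CONTOUR_DATA], dtype=float).reshape(-1, 3)
            polygons.append((float(data[0, 2]), data[:, :2]))
        bundle.contours[name] = ContourSet(name=name, polygons=polygons)
    return bundle
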