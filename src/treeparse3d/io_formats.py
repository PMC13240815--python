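"""Point-cloud and crown-annotation I/O.

Carriers
--------
``PointCloud``
    N x 3 coordinates in meters with optional per-point ``semantic`` labels
    (0 = background, 1 = crown), ``instance`` IDs (0 reserved for background /
    unassigned) and ``intensity``.
``CrownAnnotationSet``
    Top-view crown polygons in image coordinates (LabelMe-style JSON) plus an
    affine alignment mapping image XY onto point-cloud XY.

Formats
-------
* whitespace-delimited xyz: ``x y z [semantic] [instance]``
* PLY, ascii and binary_little_endian, with extra per-vertex properties
  ``semantic`` (uchar) and ``instance`` (int) when labels are present
* LabelMe-style JSON: ``{"shapes": [{"label": ..., "points": [[x, y], ...]}]}``

LAS/LAZ and CRS handling are out of scope; coordinates are plain meters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PointCloud", "CrownAnnotationSet", "NormalizationRecord",
    "read_pointcloud", "write_pointcloud", "read_crown_annotations",
    "write_crown_annotations", "normalize_coords",
    "ValidationError", "ParseError", "UnsupportedFormatError",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """File does not parse under the named standard."""


class UnsupportedFormatError(ValueError):
    """Format recognized but not supported by this build."""


@dataclass
class PointCloud:
    """Universal carrier for labeled 3D points.

    Invariants: N >= 1, finite coordinates; any point with instance > 0 must
    carry semantic = 1; instance IDs are positive for foreground objects.
    """

    coords: np.ndarray
    semantic: np.ndarray | None = None
    instance: np.ndarray | None = None
    intensity: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"coords must be Nx3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValidationError("point cloud must contain at least one point")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinate in point cloud")
        for name in ("semantic", "instance"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.shape != (len(self),):
                    raise ValidationError(f"{name} length {v.shape} != N={len(self)}")
                setattr(self, name, v)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.semantic is not None and not np.isin(self.semantic, (0, 1)).all():
            raise ValidationError("semantic labels must be in {0,1}")
        if self.instance is not None:
            if (self.instance < 0).any():
                raise ValidationError("instance IDs must be non-negative")
            if self.semantic is not None and \
                    (self.semantic[self.instance > 0] != 1).any():
                raise ValidationError(
                    "every point with instance > 0 must have semantic = 1")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def compact_instances(self) -> "PointCloud":
        """Relabel foreground instances onto the contiguous set {1..M}."""
        if self.instance is None:
            return self
        inst = self.instance.copy()
        ids = np.unique(inst[inst > 0])
        remap = {old: new for new, old in enumerate(ids, start=1)}
        for old, new in remap.items():
            inst[self.instance == old] = new
        return PointCloud(self.coords, self.semantic, inst, self.intensity)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        pick = lambda v: None if v is None else v[mask]
        return PointCloud(self.coords[mask], pick(self.semantic),
                          pick(self.instance), pick(self.intensity))


@dataclass
class CrownAnnotationSet:
    """Top-view crown polygons (the 2D modality).

    ``polygons`` maps instance_id -> closed 2D polygon (M x 2, implicitly
    closed); ``alignment`` is a 2x3 affine [A|t] taking image XY to cloud XY.
    """

    polygons: list[tuple[int, np.ndarray]] = field(default_factory=list)
    class_labels: dict[int, str] = field(default_factory=dict)
    region_bounds: tuple[float, float, float, float] | None = None
    alignment: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def __post_init__(self):
        seen: set[int] = set()
        cleaned = []
        for inst_id, poly in self.polygons:
            poly = np.asarray(poly, dtype=np.float64)
            # drop an explicit closing vertex; polygons are implicitly closed
            if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValidationError(
                    f"polygon for instance {inst_id} needs >= 3 vertices")
            if inst_id in seen:
                raise ValidationError(f"duplicate instance_id {inst_id}")
            seen.add(inst_id)
            cleaned.append((int(inst_id), poly))
        self.polygons = cleaned
        self.alignment = np.asarray(self.alignment, dtype=np.float64)
        if self.alignment.shape != (2, 3):
            raise ValidationError("alignment must be a 2x3 affine matrix")
        if abs(np.linalg.det(self.alignment[:, :2])) < 1e-12:
            raise ValidationError("alignment must be invertible")

    def __len__(self) -> int:
        return len(self.polygons)

    def to_cloud_xy(self, pts: np.ndarray) -> np.ndarray:
        """Map image-coordinate points into point-cloud XY."""
        A, t = self.alignment[:, :2], self.alignment[:, 2]
        return pts @ A.T + t


@dataclass
class NormalizationRecord:
    """Inverse transform for per-axis min-max normalization."""

    mins: np.ndarray
    scales: np.ndarray          # per-axis (max - min); 0 marks a degenerate axis

    def invert(self, coords: np.ndarray) -> np.ndarray:
        out = np.asarray(coords, dtype=np.float64).copy()
        live = self.scales > 0
        out[:, live] = out[:, live] * self.scales[live] + self.mins[live]
        out[:, ~live] = self.mins[~live]
        return out


def normalize_coords(pc: PointCloud) -> tuple[PointCloud, NormalizationRecord]:
    """Map each axis min->0, max->1; a degenerate (constant) axis maps to 0.5."""
    mins = pc.coords.min(axis=0)
    maxs = pc.coords.max(axis=0)
    scales = maxs - mins
    out = np.empty_like(pc.coords)
    for ax in range(3):
        if scales[ax] > 0:
            out[:, ax] = (pc.coords[:, ax] - mins[ax]) / scales[ax]
        else:
            out[:, ax] = 0.5
    rec = NormalizationRecord(mins=mins, scales=scales)
    return PointCloud(out, pc.semantic, pc.instance, pc.intensity), rec


# ---------------------------------------------------------------------------
# xyz dialect: "x y z [semantic] [instance]"
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> PointCloud:
    coords, sem, inst = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (3, 4, 5):
                    raise ParseError(
                        f"{path}:{lineno}: expected 3-5 columns, got {len(parts)}")
                ncols = len(parts)
            if len(parts) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            coords.append(vals[:3])
            if ncols >= 4:
                sem.append(int(vals[3]))
            if ncols == 5:
                inst.append(int(vals[4]))
    if not coords:
        raise ParseError(f"{path}: no data records")
    return PointCloud(
        np.array(coords),
        np.array(sem) if sem else None,
        np.array(inst) if inst else None,
    )


def _write_xyz(pc: PointCloud, path: Path) -> None:
    cols = [pc.coords]
    fmt = ["%.17g"] * 3
    if pc.semantic is not None:
        cols.append(pc.semantic[:, None].astype(float))
        fmt.append("%d")
        if pc.instance is not None:
            cols.append(pc.instance[:, None].astype(float))
            fmt.append("%d")
    np.savetxt(path, np.hstack(cols), fmt=" ".join(fmt))


# ---------------------------------------------------------------------------
# PLY: ascii + binary_little_endian (hand-rolled on structured arrays)
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ParseError(f"{path}: missing 'ply' magic")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: truncated header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ParseError(f"{path}: list property on vertex element")
                if tokens[1] not in _PLY_TYPES:
                    raise ParseError(f"{path}: unknown PLY type {tokens[1]!r}")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise UnsupportedFormatError(f"{path}: PLY format {fmt!r} unsupported")
        if n_vertex is None:
            raise ParseError(f"{path}: no vertex element")
        dtype = np.dtype(props)
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline()
                if not line:
                    raise ParseError(f"{path}: vertex record {i}: unexpected EOF")
                parts = line.split()
                if len(parts) != len(props):
                    raise ParseError(
                        f"{path}: vertex record {i}: expected {len(props)} "
                        f"fields, got {len(parts)}")
                rows.append(tuple(float(p) for p in parts))
            data = np.array(rows, dtype=dtype)
        else:
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) != dtype.itemsize * n_vertex:
                raise ParseError(f"{path}: truncated binary vertex data")
            data = np.frombuffer(raw, dtype=dtype)
    names = data.dtype.names
    for ax in "xyz":
        if ax not in names:
            raise ParseError(f"{path}: vertex element lacks property {ax!r}")
    coords = np.stack([data["x"], data["y"], data["z"]], axis=1).astype(np.float64)
    sem = data["semantic"].astype(np.int64) if "semantic" in names else None
    inst = data["instance"].astype(np.int64) if "instance" in names else None
    inten = data["intensity"].astype(np.float64) if "intensity" in names else None
    return PointCloud(coords, sem, inst, inten)


def _write_ply(pc: PointCloud, path: Path, binary: bool = False) -> None:
    props = [("x", "<f8", "double"), ("y", "<f8", "double"), ("z", "<f8", "double")]
    if pc.semantic is not None:
        props.append(("semantic", "u1", "uchar"))
    if pc.instance is not None:
        props.append(("instance", "<i4", "int"))
    if pc.intensity is not None:
        props.append(("intensity", "<f8", "double"))
    dtype = np.dtype([(n, t) for n, t, _ in props])
    data = np.empty(len(pc), dtype=dtype)
    data["x"], data["y"], data["z"] = pc.coords.T
    if pc.semantic is not None:
        data["semantic"] = pc.semantic
    if pc.instance is not None:
        data["instance"] = pc.instance
    if pc.intensity is not None:
        data["intensity"] = pc.intensity
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(pc)}"]
    header += [f"property {ply_t} {n}" for n, _, ply_t in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for row in data:
                fields = []
                for n, t, _ in props:
                    v = row[n]
                    fields.append(f"{int(v)}" if np.issubdtype(dtype[n], np.integer)
                                  else f"{float(v):.17g}")
                fh.write((" ".join(fields) + "\n").encode("ascii"))


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return {"ply": "ply", "las": "las", "laz": "las"}.get(suffix, "xyz")


def read_pointcloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud; format one of {ply, las, xyz} (guessed from suffix)."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "xyz":
        pc = _read_xyz(path)
    elif fmt == "ply":
        pc = _read_ply(path)
    elif fmt == "las":
        raise UnsupportedFormatError(
            "LAS/LAZ input is not supported by this build; convert to PLY or "
            "xyz (e.g. with PDAL or CloudCompare) first")
    else:
        raise UnsupportedFormatError(f"unknown point-cloud format {fmt!r}")
    log.info("read %d points from %s (dialect=%s)", len(pc), path, fmt)
    return pc


def write_pointcloud(pc: PointCloud, path: str | Path,
                     format: str | None = None, binary: bool = False) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "xyz":
        _write_xyz(pc, path)
    elif fmt == "ply":
        _write_ply(pc, path, binary=binary)
    else:
        raise UnsupportedFormatError(f"cannot write format {fmt!r}")


# ---------------------------------------------------------------------------
# LabelMe-style crown-annotation JSON
# ---------------------------------------------------------------------------
# Schema (version 1): {"version": "1", "shapes": [{"label": str,
#   "points": [[x, y], ...], "shape_type": "polygon"}],
#   "alignment": 2x3 nested list (optional, default identity),
#   "region_bounds": [xmin, ymin, xmax, ymax] (optional)}

def _label_to_id(label: str, fallback: int) -> int:
    tail = label.rsplit("_", 1)[-1]
    return int(tail) if tail.isdigit() else fallback


def read_crown_annotations(path: str | Path) -> CrownAnnotationSet:
    """Read a LabelMe-style JSON crown-annotation file."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "shapes" not in doc:
        raise ParseError(f"{path}: missing 'shapes' key")
    polygons, labels = [], {}
    for i, shape in enumerate(doc["shapes"]):
        label = shape.get("label", f"tree_{i + 1}")
        inst_id = _label_to_id(label, i + 1)
        pts = np.asarray(shape["points"], dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValidationError(
                f"{path}: shape {i} ({label!r}): polygon needs >= 3 vertices")
        polygons.append((inst_id, pts))
        labels[inst_id] = "background" if "background" in label else "crown"
    alignment = np.asarray(doc.get(
        "alignment", [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    bounds = tuple(doc["region_bounds"]) if "region_bounds" in doc else None
    return CrownAnnotationSet(polygons=polygons, class_labels=labels,
                              region_bounds=bounds, alignment=alignment)


def write_crown_annotations(ann: CrownAnnotationSet, path: str | Path) -> None:
    doc = {
        "version": "1",
        "shapes": [
            {"label": f"tree_{inst_id}", "points": poly.tolist(),
             "shape_type": "polygon"}
            for inst_id, poly in ann.polygons
        ],
        "alignment": ann.alignment.tolist(),
    }
    if ann.region_bounds is not None:
        doc["region_bounds"] = list(ann.region_bounds)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
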