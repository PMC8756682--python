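"""Reading and writing the external formats the pipeline touches.

Polygons come in as GeoJSON (RFC 7946) or ESRI Shapefile, attributes as CSV,
contiguity weights as GAL neighbor lists, and LISA cluster maps go out as
GeoJSON feature collections.  Geometry lives in memory as shapely objects;
coordinates are treated as plain planar tuples (contiguity is topological,
no projection is ever applied).

The shapefile reader/writer here is deliberately minimal: polygon shape
type only, a single character id field in the DBF, and every ring of a
record is kept as an outer ring (holes are not reconstructed from winding
order).  That is all the adjacency pipeline needs from the format.
"""

from __future__ import annotations

import csv
import datetime
import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .errors import AlignmentError, FormatError

__all__ = [
    "SpatialFrame",
    "AttributeTable",
    "read_polygons",
    "write_geojson",
    "read_attributes",
    "write_attributes",
    "align",
    "write_gal",
    "read_gal",
    "write_lisa_geojson",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpatialFrame:
    """Ordered areal units with polygon geometry.

    The unit order is load-bearing: it defines the row/column order of every
    weight matrix and variable vector downstream.
    """

    ids: list[str]
    geometries: list
    display_names: Optional[list[Optional[str]]] = None

    def __post_init__(self):
        if len(self.ids) == 0:
            raise FormatError("SpatialFrame requires at least one unit")
        if len(self.ids) != len(self.geometries):
            raise FormatError("ids and geometries length mismatch")
        seen = set()
        for uid in self.ids:
            if uid in seen:
                raise FormatError(f"duplicate unit id {uid!r}")
            seen.add(uid)
        for uid, geom in zip(self.ids, self.geometries):
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise FormatError(
                    f"unit {uid!r}: geometry must be Polygon or MultiPolygon, "
                    f"got {geom.geom_type}"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[str, int]:
        return {uid: i for i, uid in enumerate(self.ids)}


@dataclass
class AttributeTable:
    """District-level attribute table keyed by unit id.

    ``data`` is a DataFrame indexed by unit_id with purely numeric columns
    (percent variables on the 0-100 scale).
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate unit ids in attribute table: {dups}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def variable(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"unknown variable {name!r}")
        return self.data[name].to_numpy(dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# polygon input
# ---------------------------------------------------------------------------


def read_polygons(path, id_field: str, format: Optional[str] = None) -> SpatialFrame:
    """Read areal-unit polygons from GeoJSON or Shapefile, in file order.

    Parameters
    ----------
    path : path-like
        File to read.
    id_field : str
        Property (GeoJSON) or DBF field (Shapefile) holding the unit id.
    format : {"geojson", "shapefile"}, optional
        Inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = "shapefile" if ext == ".shp" else "geojson"
    if format == "geojson":
        return _read_geojson(path, id_field)
    if format == "shapefile":
        return _read_shapefile(path, id_field)
    raise FormatError(f"unknown polygon format {format!r}")


def _read_geojson(path: Path, id_field: str) -> SpatialFrame:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a FeatureCollection")
    features = doc.get("features", [])
    if not features:
        raise FormatError(f"{path}: empty FeatureCollection")
    ids, geoms, names = [], [], []
    seen = set()
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise FormatError(f"{path}: feature {k} missing id field {id_field!r}")
        uid = str(props[id_field])
        if uid in seen:
            raise FormatError(f"{path}: feature {k}: duplicate id {uid!r}")
        seen.add(uid)
        geom = feat.get("geometry")
        if geom is None:
            raise FormatError(f"{path}: feature {k} has null geometry")
        ids.append(uid)
        geoms.append(shape(geom))
        names.append(props.get("display_name"))
    display = names if any(v is not None for v in names) else None
    return SpatialFrame(ids=ids, geometries=geoms, display_names=display)


def write_geojson(frame: SpatialFrame, path, properties: Optional[dict] = None,
                  id_field: str = "unit_id") -> None:
    """Write a SpatialFrame as a GeoJSON FeatureCollection.

    ``properties`` maps property name -> sequence of per-unit values.
    """
    features = []
    for i, (uid, geom) in enumerate(zip(frame.ids, frame.geometries)):
        props = {id_field: uid}
        if frame.display_names is not None and frame.display_names[i] is not None:
            props["display_name"] = frame.display_names[i]
        if properties:
            for key, values in properties.items():
                val = values[i]
                if isinstance(val, (np.floating, np.integer)):
                    val = val.item()
                if isinstance(val, float) and not math.isfinite(val):
                    val = None
                props[key] = val
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# minimal ESRI shapefile (polygon) support
# ---------------------------------------------------------------------------

_SHP_POLYGON = 5


def _geom_rings(geom) -> list[list[tuple[float, float]]]:
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:  # pragma: no cover - guarded by SpatialFrame
        raise FormatError(f"cannot write geometry type {geom.geom_type}")
    rings = []
    for poly in polys:
        rings.append(list(poly.exterior.coords))
        for interior in poly.interiors:
            rings.append(list(interior.coords))
    return rings


def write_shapefile(frame: SpatialFrame, path, id_field: str = "unit_id") -> None:
    """Write polygons to ``path``(.shp) plus sibling .shx and .dbf files."""
    path = Path(path)
    base = path.with_suffix("")
    records = []
    for geom in frame.geometries:
        rings = _geom_rings(geom)
        parts, points = [], []
        for ring in rings:
            parts.append(len(points))
            points.extend((float(x), float(y)) for x, y in ring)
        records.append((parts, points))

    all_x = [p[0] for _, pts in records for p in pts]
    all_y = [p[1] for _, pts in records for p in pts]
    bbox = (min(all_x), min(all_y), max(all_x), max(all_y))

    shp_records = []
    offsets = []  # (offset_words, content_words)
    offset = 50  # header is 100 bytes = 50 words
    for recno, (parts, points) in enumerate(records, start=1):
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        content = struct.pack("<i4d", _SHP_POLYGON, min(xs), min(ys), max(xs), max(ys))
        content += struct.pack("<2i", len(parts), len(points))
        content += struct.pack(f"<{len(parts)}i", *parts)
        for x, y in points:
            content += struct.pack("<2d", x, y)
        words = len(content) // 2
        shp_records.append(struct.pack(">2i", recno, words) + content)
        offsets.append((offset, words))
        offset += 4 + words  # record header is 8 bytes = 4 words

    def _main_header(total_words: int) -> bytes:
        head = struct.pack(">i5ii", 9994, 0, 0, 0, 0, 0, total_words)
        head += struct.pack("<2i", 1000, _SHP_POLYGON)
        head += struct.pack("<8d", *bbox, 0.0, 0.0, 0.0, 0.0)
        return head

    shp_body = b"".join(shp_records)
    with open(base.with_suffix(".shp"), "wb") as fh:
        fh.write(_main_header(50 + len(shp_body) // 2))
        fh.write(shp_body)
    with open(base.with_suffix(".shx"), "wb") as fh:
        fh.write(_main_header(50 + 4 * len(offsets)))
        for off, words in offsets:
            fh.write(struct.pack(">2i", off, words))
    _write_dbf(base.with_suffix(".dbf"), id_field, frame.ids)


def _write_dbf(path: Path, field_name: str, values: Sequence[str]) -> None:
    width = max(1, max(len(str(v)) for v in values))
    if width > 254:
        raise FormatError("id values too long for DBF character field")
    n = len(values)
    header_size = 32 + 32 + 1
    record_size = 1 + width
    today = datetime.date(2000, 1, 1)  # fixed date keeps output byte-stable
    head = struct.pack(
        "<B3BIHH20x", 0x03, today.year - 1900, today.month, today.day,
        n, header_size, record_size,
    )
    fname = field_name.encode("ascii", "replace")[:10]
    fdesc = struct.pack("<11sc4xBB14x", fname, b"C", width, 0)
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(fdesc)
        fh.write(b"\x0d")
        for v in values:
            fh.write(b" " + str(v).ljust(width).encode("ascii", "replace"))
        fh.write(b"\x1a")


def _read_dbf(path: Path) -> tuple[list[str], list[list[str]]]:
    data = path.read_bytes()
    if len(data) < 33:
        raise FormatError(f"{path}: truncated DBF")
    n, header_size, record_size = struct.unpack_from("<IHH", data, 4)
    fields = []
    pos = 32
    while pos < header_size - 1 and data[pos] != 0x0D:
        name = data[pos:pos + 11].split(b"\x00")[0].decode("ascii", "replace")
        width = data[pos + 16]
        fields.append((name, width))
        pos += 32
    rows = []
    pos = header_size
    for _ in range(n):
        rec = data[pos:pos + record_size]
        if len(rec) < record_size:
            raise FormatError(f"{path}: truncated DBF record")
        cell_pos = 1
        row = []
        for _, width in fields:
            row.append(rec[cell_pos:cell_pos + width].decode("ascii", "replace").strip())
            cell_pos += width
        rows.append(row)
        pos += record_size
    return [f[0] for f in fields], rows


def _read_shapefile(path: Path, id_field: str) -> SpatialFrame:
    base = Path(path).with_suffix("")
    shp_path = base.with_suffix(".shp")
    dbf_path = base.with_suffix(".dbf")
    if not shp_path.exists():
        raise FormatError(f"{shp_path}: not found")
    if not dbf_path.exists():
        raise FormatError(f"{dbf_path}: not found (shapefile needs its .dbf)")

    field_names, rows = _read_dbf(dbf_path)
    if id_field not in field_names:
        raise FormatError(f"{dbf_path}: id field {id_field!r} not in {field_names}")
    id_col = field_names.index(id_field)

    data = shp_path.read_bytes()
    if len(data) < 100 or struct.unpack_from(">i", data, 0)[0] != 9994:
        raise FormatError(f"{shp_path}: not a shapefile")
    geoms = []
    pos = 100
    while pos < len(data):
        _, words = struct.unpack_from(">2i", data, pos)
        pos += 8
        shape_type = struct.unpack_from("<i", data, pos)[0]
        if shape_type != _SHP_POLYGON:
            raise FormatError(
                f"{shp_path}: record {len(geoms)}: unsupported shape type {shape_type}"
            )
        nparts, npoints = struct.unpack_from("<2i", data, pos + 36)
        parts = list(struct.unpack_from(f"<{nparts}i", data, pos + 44))
        pts_off = pos + 44 + 4 * nparts
        pts = struct.unpack_from(f"<{2 * npoints}d", data, pts_off)
        rings = []
        bounds = parts + [npoints]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rings.append([(pts[2 * k], pts[2 * k + 1]) for k in range(a, b)])
        if len(rings) == 1:
            geoms.append(Polygon(rings[0]))
        else:
            # every part kept as an outer ring; holes are not reconstructed
            geoms.append(MultiPolygon([Polygon(r) for r in rings]))
        pos += 2 * words

    if len(geoms) != len(rows):
        raise FormatError(
            f"{shp_path}: {len(geoms)} shapes but {len(rows)} DBF records"
        )
    ids = [row[id_col] for row in rows]
    return SpatialFrame(ids=ids, geometries=geoms)


# ---------------------------------------------------------------------------
# attribute CSV
# ---------------------------------------------------------------------------


def read_attributes(path, id_field: str, check_range: bool = True) -> AttributeTable:
    """Read a district attribute CSV keyed by ``id_field``.

    All non-id columns must parse as finite numbers; with ``check_range``
    (the default) every value must lie in [0, 100], catching the classic
    proportion-vs-percent unit slip early.
    """
    raw = pd.read_csv(path, dtype=str)
    if id_field not in raw.columns:
        raise FormatError(f"{path}: id column {id_field!r} not found")
    ids = raw[id_field].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate ids {dups}")
    values = {}
    for col in raw.columns:
        if col == id_field:
            continue
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise FormatError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        vec = parsed.to_numpy(dtype=float)
        if not np.all(np.isfinite(vec)):
            row = int(np.flatnonzero(~np.isfinite(vec))[0])
            raise FormatError(f"{path}: non-finite value in column {col!r}, row {row}")
        if check_range and ((vec < 0).any() or (vec > 100).any()):
            row = int(np.flatnonzero((vec < 0) | (vec > 100))[0])
            raise FormatError(
                f"{path}: value {vec[row]} in column {col!r}, row {row} outside "
                f"[0, 100]; pass check_range=False for non-percent variables"
            )
        values[col] = vec
    frame = pd.DataFrame(values, index=pd.Index(ids, name=id_field))
    return AttributeTable(data=frame)


def write_attributes(table: AttributeTable, path, id_field: str = "unit_id",
                     digits: int = 10) -> None:
    """Write an attribute table to CSV with values printed to ``digits`` decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([id_field] + table.variables)
        for uid, row in table.data.iterrows():
            writer.writerow([uid] + [f"{v:.{digits}f}" for v in row])


def align(frame: SpatialFrame, table: AttributeTable) -> AttributeTable:
    """Reorder ``table`` to the frame's unit order so vectors index-match W."""
    frame_ids = set(frame.ids)
    table_ids = set(table.ids)
    missing = sorted(frame_ids - table_ids)
    extra = sorted(table_ids - frame_ids)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"ids in frame missing from table: {missing}")
        if extra:
            parts.append(f"ids in table missing from frame: {extra}")
        raise AlignmentError("; ".join(parts))
    return AttributeTable(data=table.data.loc[frame.ids])


# ---------------------------------------------------------------------------
# GAL weights exchange
# ---------------------------------------------------------------------------


def write_gal(weights, path, layer: str = "units", id_field: str = "unit_id") -> None:
    """Write binary contiguity weights as a GAL neighbor list.

    Dialect: header line ``0 n <layer> <id_field>``, then per unit a line
    ``<id> <k>`` followed by a line of k neighbor ids (empty line for islands).
    """
    if weights.style != "binary":
        raise FormatError("GAL export requires binary-style weights")
    with open(path, "w") as fh:
        fh.write(f"0 {weights.n} {layer} {id_field}\n")
        for uid in weights.ids:
            nbrs = weights.neighbors(uid)
            fh.write(f"{uid} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n")


def read_gal(path, frame: SpatialFrame):
    """Read a GAL file back into a binary WeightMatrix in frame order."""
    from .weights import from_adjacency_pairs

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty GAL file")
    header = lines[0].split()
    if len(header) < 2:
        raise FormatError(f"{path}: malformed GAL header {lines[0]!r}")
    n = int(header[1])
    if n != frame.n:
        raise FormatError(f"{path}: GAL claims {n} units, frame has {frame.n}")
    known = set(frame.ids)
    pairs = []
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise FormatError(f"{path}: GAL body shorter than header count")
        head = lines[pos].split()
        if len(head) != 2:
            raise FormatError(f"{path}: malformed unit line {lines[pos]!r}")
        uid, k = head[0], int(head[1])
        if uid not in known:
            raise FormatError(f"{path}: unknown unit id {uid!r}")
        nbrs = lines[pos + 1].split() if pos + 1 < len(lines) else []
        if len(nbrs) != k:
            raise FormatError(
                f"{path}: unit {uid!r} declares {k} neighbors, lists {len(nbrs)}"
            )
        for nb in nbrs:
            if nb not in known:
                raise FormatError(f"{path}: neighbor id {nb!r} not in frame")
            pairs.append((uid, nb))
        pos += 2
    return from_adjacency_pairs(frame.ids, pairs)


# ---------------------------------------------------------------------------
# LISA GeoJSON export
# ---------------------------------------------------------------------------


def write_lisa_geojson(frame: SpatialFrame, stats, path) -> None:
    """Serialise LISA results as a GeoJSON map layer.

    Each feature carries exactly the five properties the cluster maps need:
    unit_id, local_i, quadrant, pseudo_p, cluster_label.
    """
    if list(stats.ids) != list(frame.ids):
        if len(stats.ids) != frame.n:
            raise FormatError(
                f"stats length {len(stats.ids)} != frame length {frame.n}"
            )
        raise FormatError("stats ids do not match frame ids/order")
    props = {
        "local_i": [float(v) for v in stats.local_i],
        "quadrant": list(stats.quadrant),
        "pseudo_p": [None if v is None or not math.isfinite(v) else float(v)
                     for v in stats.pseudo_p],
        "cluster_label": list(stats.cluster_label),
    }
    write_geojson(frame, path, properties=props, id_field="unit_id")
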