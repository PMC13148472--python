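"""Region-of-interest geometry: polygons, grids, persistence, point location.

ROIs partition the camera field into per-animal arenas.  A 96-well plate is
described by a grid (11 internal vertical lines x 7 internal horizontal lines
-> 12 x 8 rectangular cells); more complex arenas (Y-mazes) are arbitrary
simple polygons.  Coordinates are 0-based image pixels: x rightward,
y downward, stored as floats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon


class RoiError(ValueError):
    """Invalid ROI geometry or specification."""


class RoiFileError(ValueError):
    """Malformed ROI file; the message names the offending record."""


@dataclass
class PolygonRoi:
    """A closed, simple (non-self-intersecting) polygon with a string id."""

    id: str
    vertices: np.ndarray  # (n, 2) float array of (x, y)
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise RoiError(f"roi {self.id!r}: vertices must be an (n, 2) array")
        if self.closed:
            if len(self.vertices) < 3:
                raise RoiError(
                    f"roi {self.id!r}: closed polygon needs >= 3 vertices, "
                    f"got {len(self.vertices)}"
                )
            poly = _ShapelyPolygon(self.vertices)
            if not poly.is_valid:
                raise RoiError(f"roi {self.id!r}: polygon is self-intersecting or degenerate")
            if poly.area <= 0:
                raise RoiError(f"roi {self.id!r}: polygon area must be > 0")

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) axis-aligned bounding box."""
        return self.polygon.bounds

    def contains(self, point: tuple[float, float]) -> bool:
        """Membership including the boundary."""
        return bool(shapely.covers(self.polygon, shapely.points(point[0], point[1])))

    def contains_many(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
        return shapely.covers(self.polygon, pts)

    # -- transforms (all return new objects) --------------------------------

    def translated(self, dx: float, dy: float) -> "PolygonRoi":
        return replace(self, vertices=self.vertices + np.array([dx, dy]))

    def rotated(self, about_vertex, angle_deg: float) -> "PolygonRoi":
        """Rotate about one of the polygon's own vertices.

        ``about_vertex`` is either a vertex index or an (x, y) pair that must
        coincide (to 1e-9 px) with an existing vertex.
        """
        if isinstance(about_vertex, (int, np.integer)):
            if not 0 <= about_vertex < len(self.vertices):
                raise RoiError(f"roi {self.id!r}: vertex index {about_vertex} out of range")
            pivot = self.vertices[about_vertex]
        else:
            pivot = np.asarray(about_vertex, dtype=float)
            d = np.linalg.norm(self.vertices - pivot, axis=1)
            if d.min() > 1e-9:
                raise RoiError(
                    f"roi {self.id!r}: rotation pivot {tuple(pivot)} is not a vertex"
                )
        t = math.radians(angle_deg)
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        return replace(self, vertices=(self.vertices - pivot) @ rot.T + pivot)

    def copied(self, new_id: str, dx: float = 0.0, dy: float = 0.0) -> "PolygonRoi":
        return PolygonRoi(new_id, self.vertices + np.array([dx, dy]), self.closed)


def transform_roi(roi: PolygonRoi, op: str, **kwargs) -> PolygonRoi:
    """Dispatch ``translate`` / ``rotate`` / ``copy`` by name."""
    if op == "translate":
        return roi.translated(kwargs["dx"], kwargs["dy"])
    if op == "rotate":
        return roi.rotated(kwargs["about_vertex"], kwargs["angle"])
    if op == "copy":
        return roi.copied(kwargs["new_id"], kwargs.get("dx", 0.0), kwargs.get("dy", 0.0))
    raise RoiError(f"unknown transform {op!r}")


@dataclass
class GridSpec:
    """Internal grid lines subdividing an outer rectangle into cells.

    ``n_vertical`` / ``n_horizontal`` count *internal* lines, so a 96-well
    plate uses 11 vertical and 7 horizontal lines (12 columns x 8 rows).
    When offsets are omitted the lines are evenly spaced.
    """

    n_vertical: int
    n_horizontal: int
    bounds: tuple[float, float, float, float]  # x0, y0, x1, y1
    vertical_offsets: Optional[Sequence[float]] = None
    horizontal_offsets: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        if self.n_vertical < 0 or self.n_horizontal < 0:
            raise RoiError("grid line counts must be >= 0")
        if not (x0 < x1 and y0 < y1):
            raise RoiError(f"invalid grid bounds {self.bounds}")
        for name, offs, n, lo, hi in (
            ("vertical", self.vertical_offsets, self.n_vertical, x0, x1),
            ("horizontal", self.horizontal_offsets, self.n_horizontal, y0, y1),
        ):
            if offs is None:
                continue
            offs = list(offs)
            if len(offs) != n:
                raise RoiError(f"{name}_offsets must have length {n}")
            if any(not lo < v < hi for v in offs):
                raise RoiError(f"{name} line positions must lie strictly inside bounds")
            if any(b <= a for a, b in zip(offs, offs[1:])):
                raise RoiError(f"{name} line positions must be strictly increasing")

    def line_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell edges including the outer bounds: (x edges, y edges)."""
        x0, y0, x1, y1 = self.bounds
        if self.vertical_offsets is None:
            xs = np.linspace(x0, x1, self.n_vertical + 2)
        else:
            xs = np.concatenate([[x0], np.asarray(self.vertical_offsets, float), [x1]])
        if self.horizontal_offsets is None:
            ys = np.linspace(y0, y1, self.n_horizontal + 2)
        else:
            ys = np.concatenate([[y0], np.asarray(self.horizontal_offsets, float), [y1]])
        return xs, ys


@dataclass
class RoiSet:
    """An ordered collection of ROIs authored against a frame shape."""

    rois: list[PolygonRoi] = field(default_factory=list)
    frame_shape: Optional[tuple[int, int]] = None  # (height, width)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise RoiError(f"duplicate roi id {dup!r}")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, roi_id: str) -> PolygonRoi:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(roi_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rois]


def generate_grid(spec: GridSpec) -> RoiSet:
    """Tile the grid bounds into rectangular ROIs, row-major from top-left.

    Ids are ``r{row}c{col}``.  Returns (n_horizontal+1) rows by
    (n_vertical+1) columns of cells.
    """
    xs, ys = spec.line_positions()
    rois = []
    for row in range(len(ys) - 1):
        for col in range(len(xs) - 1):
            x0, x1 = xs[col], xs[col + 1]
            y0, y1 = ys[row], ys[row + 1]
            rois.append(
                PolygonRoi(f"r{row}c{col}", [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
            )
    return RoiSet(rois)


def locate_point(point: tuple[float, float], roi_set: RoiSet) -> Optional[str]:
    """Id of the first ROI (in set order) covering ``point``, else None.

    Boundary points count as inside; ties on shared edges therefore resolve
    to the earlier ROI in set order.
    """
    for roi in roi_set:
        if roi.contains(point):
            return roi.id
    return None


# -- persistence: JSON {"frame_shape": [h, w], "rois": [{"id", "vertices"}]} --


def save_rois(roi_set: RoiSet, path, extra: Optional[dict] = None) -> None:
    doc = {
        "frame_shape": list(roi_set.frame_shape) if roi_set.frame_shape else None,
        "rois": [
            {"id": r.id, "vertices": [[float(x), float(y)] for x, y in r.vertices]}
            for r in roi_set
        ],
    }
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_rois(path) -> RoiSet:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise RoiFileError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or "rois" not in doc:
        raise RoiFileError(f"{path}: missing top-level 'rois' list")
    rois = []
    for i, rec in enumerate(doc["rois"]):
        try:
            rois.append(PolygonRoi(rec["id"], np.asarray(rec["vertices"], dtype=float)))
        except (KeyError, TypeError, RoiError, ValueError) as e:
            rid = rec.get("id", f"#{i}") if isinstance(rec, dict) else f"#{i}"
            raise RoiFileError(f"{path}: bad roi record {rid!r}: {e}") from e
    shape = doc.get("frame_shape")
    return RoiSet(rois, tuple(shape) if shape else None)


def load_rois_document(path) -> dict:
    """Raw JSON document (for files carrying extra fields, e.g. maze metadata)."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
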