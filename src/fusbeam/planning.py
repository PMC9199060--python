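"""Therapy planning: turn a polygonal region of interest on a B-mode image
into an ordered grid of sonication focal points.

The grid fills the ROI's axis-aligned bounding box with rows spaced by the
focal zone's depth of field and columns by its beamwidth; alternate rows are
shifted by half a lateral step to reduce focal-zone overlap, and candidates
falling outside the ROI are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .field_sim import ArrayGeometry

__all__ = [
    "RoiPolygon",
    "PlanningParams",
    "FocalGrid",
    "bounding_box",
    "estimate_f_number",
    "grid_steps",
    "generate_focal_grid",
    "point_in_roi",
]

_EDGE_EPS = 1e-9  # meters; tie tolerance at the bounding box far edges


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-18 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass(frozen=True)
class RoiPolygon:
    """A closed, simple polygon in image coordinates (meters).

    Vertices are an ordered (n, 2) array of (x, z); the closing edge from
    the last vertex back to the first is implicit.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if v.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if np.any(v[:, 1] <= 0):
            raise ValueError("all ROI vertices must have depth z > 0")
        n = v.shape[0]
        edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if j == i + 1 or (i == 0 and j == n - 1):
                    continue  # adjacent edges share a vertex
                if _segments_intersect(*edges[i], *edges[j]):
                    raise ValueError("polygon is self-intersecting")
        if abs(self._shoelace(v)) <= 0:
            raise ValueError("degenerate polygon: zero area")
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def _shoelace(v: np.ndarray) -> float:
        x, z = v[:, 0], v[:, 1]
        return 0.5 * np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z)

    @property
    def area(self) -> float:
        return abs(self._shoelace(self.vertices))

    def translated(self, dx: float, dz: float) -> "RoiPolygon":
        return RoiPolygon(self.vertices + np.array([dx, dz]))

    # -- serialization ------------------------------------------------------

    def to_json(self, path, units: str = "m") -> None:
        scale = {"m": 1.0, "mm": 1e3}[units]
        payload = {"units": units, "vertices": (self.vertices * scale).tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "RoiPolygon":
        """Read an ROI from JSON ({"units": "mm"|"m", "vertices": [[x,z],..]})
        or a two-column CSV whose header declares the units."""
        text = open(path).read()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            payload = json.loads(text)
            units = payload.get("units", "m")
            verts = np.asarray(payload["vertices"], dtype=float)
        else:
            lines = text.splitlines()
            units = "m"
            rows = []
            for ln_no, line in enumerate(lines, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "units=" in line:
                        units = line.split("units=")[1].split()[0].strip()
                    continue
                parts = line.replace(",", " ").split()
                if parts[0].lower() in ("x", "x_m", "x_mm"):  # column header
                    units = "mm" if parts[0].lower().endswith("mm") else units
                    continue
                try:
                    rows.append([float(parts[0]), float(parts[1])])
                except (ValueError, IndexError):
                    raise ValueError(f"{path}: cannot parse ROI vertex on line {ln_no}: {line!r}")
            verts = np.asarray(rows, dtype=float)
        if units not in ("m", "mm"):
            raise ValueError(f"{path}: unknown ROI units {units!r} (use 'm' or 'mm')")
        if units == "mm":
            verts = verts * 1e-3
        return cls(verts)


@dataclass(frozen=True)
class PlanningParams:
    """Focal-zone sizes driving the grid spacing.

    The -3 dB beamwidth and depth of field of a rectangular focusing source
    under continuous-wave excitation are ``0.886 * wavelength * f_number``
    and ``7.1 * wavelength * f_number**2``.
    """

    wavelength: float
    f_number: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.f_number <= 0:
            raise ValueError("wavelength and f_number must be positive")

    @property
    def beamwidth_3db(self) -> float:
        return 0.886 * self.wavelength * self.f_number

    @property
    def dof_3db(self) -> float:
        return 7.1 * self.wavelength * self.f_number**2


@dataclass(frozen=True)
class FocalGrid:
    """Ordered focal points: row-major, top row first, left to right.

    Odd rows are shifted +0.5*dx relative to even rows.
    """

    points: np.ndarray  # (n, 2) [x, z] meters
    row_index: np.ndarray  # (n,) int
    dx: float
    dz: float
    bbox: tuple[float, float, float, float]  # x_min, z_min, x_max, z_max

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        rows = np.asarray(self.row_index, dtype=int).ravel()
        if pts.shape[0] != rows.shape[0] or pts.shape[0] == 0:
            raise ValueError("points/row_index mismatch or empty grid")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "row_index", rows)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_table(self, path, meta: dict | None = None) -> None:
        """Write ``index,row,x_m,z_m`` CSV with a commented metadata block."""
        with open(path, "w") as fh:
            fh.write(f"# fusbeam focal grid dx_m={self.dx:.9e} dz_m={self.dz:.9e}\n")
            for key, val in (meta or {}).items():
                fh.write(f"# {key}={val}\n")
            fh.write("index,row,x_m,z_m\n")
            for i, ((x, z), r) in enumerate(zip(self.points, self.row_index)):
                fh.write(f"{i},{r},{x:.9e},{z:.9e}\n")


def bounding_box(roi: RoiPolygon) -> tuple[float, float, float, float]:
    """Smallest axis-aligned rectangle enclosing the ROI: (x_min, z_min,
    x_max, z_max)."""
    v = roi.vertices
    return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())


def estimate_f_number(roi: RoiPolygon, geom: ArrayGeometry) -> float:
    """f-number = depth of the region's center / array aperture width.

    The center depth is the axial midpoint of the ROI's bounding box.
    """
    _, z_min, _, z_max = bounding_box(roi)
    return 0.5 * (z_min + z_max) / geom.aperture_width


def grid_steps(params: PlanningParams) -> tuple[float, float]:
    """Grid spacing: dx = -3 dB beamwidth, dz = half the -3 dB depth of field."""
    return params.beamwidth_3db, 0.5 * params.dof_3db


def point_in_roi(point: Sequence[float], roi: RoiPolygon, eps: float = 1e-12) -> bool:
    """Even-odd ray-casting containment test; boundary points count inside."""
    px, pz = float(point[0]), float(point[1])
    v = roi.vertices
    n = v.shape[0]
    inside = False
    for i in range(n):
        x1, z1 = v[i]
        x2, z2 = v[(i + 1) % n]
        # boundary check: distance from point to segment
        dx, dz = x2 - x1, z2 - z1
        seg2 = dx * dx + dz * dz
        t = 0.0 if seg2 == 0 else np.clip(((px - x1) * dx + (pz - z1) * dz) / seg2, 0, 1)
        if np.hypot(px - (x1 + t * dx), pz - (z1 + t * dz)) <= eps:
            return True
        # even-odd crossing of the rightward horizontal ray
        if (z1 > pz) != (z2 > pz):
            x_cross = x1 + (pz - z1) / (z2 - z1) * (x2 - x1)
            if px < x_cross:
                inside = not inside
    return inside


def generate_focal_grid(roi: RoiPolygon, dx: float, dz: float) -> FocalGrid:
    """Lay candidate rows over the bounding box and keep points inside the ROI.

    Rows sit at z = z_min + k*dz for k >= 0 while z <= z_max; even rows start
    at x_min and odd rows at x_min + 0.5*dx, stepping dx while x <= x_max
    (with a 1e-9 m tie tolerance at the far edges). Coordinates stay
    continuous — no pixel snapping.
    """
    if dx <= 0 or dz <= 0:
        raise ValueError("grid steps must be positive")
    x_min, z_min, x_max, z_max = bounding_box(roi)
    pts, rows = [], []
    k = 0
    z = z_min
    while z <= z_max + _EDGE_EPS:
        x = x_min + (0.5 * dx if k % 2 else 0.0)
        while x <= x_max + _EDGE_EPS:
            if point_in_roi((x, z), roi):
                pts.append((x, z))
                rows.append(k)
            x += dx
        k += 1
        z = z_min + k * dz
    if not pts:
        raise ValueError(
            "no focal points survive: the ROI is smaller than one focal cell "
            f"(dx={dx:g} m, dz={dz:g} m); enlarge the ROI or reduce the f-number"
        )
    return FocalGrid(
        points=np.asarray(pts), row_index=np.asarray(rows), dx=dx, dz=dz,
        bbox=(x_min, z_min, x_max, z_max),
    )
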