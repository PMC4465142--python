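"""Maximum heart distance (MHD) on a 2-D beam's-eye-view scene.

In tangential breast irradiation the posterior border of the field grazes
the chest wall; the MHD is the maximal perpendicular distance by which the
heart contour protrudes past that posterior border into the field.  It is
a simple geometric surrogate for cardiac exposure: 0 when the heart is
entirely shielded, and larger the deeper the heart sits in the beam.

The aperture is abstracted to a straight posterior edge (a point plus a
unit normal pointing into the field) with an optional axis-aligned
rectangle limiting the aperture laterally; jagged per-leaf collimator
edges are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
from shapely.geometry import Polygon, box

logger = logging.getLogger(__name__)

__all__ = ["BeamsEyeViewScene", "max_heart_distance",
           "read_scene_csv", "write_scene_csv"]


@dataclass(frozen=True)
class BeamsEyeViewScene:
    """A heart contour and a posterior field edge, coordinates in cm.

    Parameters
    ----------
    heart_contour
        (N, 2) array of polygon vertices (closed implicitly); must be a
        simple polygon with at least 3 vertices and nonzero area.
    edge_point
        Any point on the posterior field edge.
    edge_normal
        Unit vector perpendicular to the edge, pointing into the field.
    field_bounds
        Optional ``(xmin, ymin, xmax, ymax)`` rectangle limiting the
        aperture laterally.
    """

    heart_contour: np.ndarray
    edge_point: np.ndarray
    edge_normal: np.ndarray
    field_bounds: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "heart_contour",
                           np.asarray(self.heart_contour, dtype=float))
        object.__setattr__(self, "edge_point",
                           np.asarray(self.edge_point, dtype=float))
        object.__setattr__(self, "edge_normal",
                           np.asarray(self.edge_normal, dtype=float))
        c = self.heart_contour
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise ValueError("heart_contour must be an (N>=3, 2) array")
        poly = Polygon(c)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("heart contour must be a simple polygon "
                             "with positive area")
        n = self.edge_normal
        if abs(float(np.hypot(n[0], n[1])) - 1.0) > 1e-9:
            raise ValueError("edge_normal must have unit length")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.heart_contour)


def _signed_depth(points: np.ndarray, scene: BeamsEyeViewScene) -> np.ndarray:
    """Perpendicular distance past the posterior edge (positive in-field)."""
    return (points - scene.edge_point) @ scene.edge_normal


def max_heart_distance(scene: BeamsEyeViewScene) -> float:
    """Maximal penetration of the heart contour past the posterior edge, cm.

    The heart polygon is clipped to the in-field half-plane (and to the
    lateral field bounds if given); the maximum perpendicular distance from
    the edge over the clipped region is returned.  Since that distance is a
    linear function of position, its maximum over the clipped polygon is
    attained at a vertex.  Returns 0 when the heart lies entirely out of
    field; vertices exactly on the edge count as distance 0.
    """
    region = scene.polygon
    if scene.field_bounds is not None:
        xmin, ymin, xmax, ymax = scene.field_bounds
        region = region.intersection(box(xmin, ymin, xmax, ymax))
        if region.is_empty:
            return 0.0
    # in-field half-plane as a large rectangle on the normal side
    p0, n = scene.edge_point, scene.edge_normal
    t = np.array([-n[1], n[0]])  # edge direction
    coords = scene.heart_contour
    span = 10.0 * (float(np.abs(coords).max()) +
                   float(np.abs(p0).max()) + 1.0)
    half_plane = Polygon([p0 - span * t, p0 + span * t,
                          p0 + span * t + span * n,
                          p0 - span * t + span * n])
    region = region.intersection(half_plane)
    if region.is_empty:
        return 0.0
    best = 0.0
    geoms = getattr(region, "geoms", [region])
    for geom in geoms:
        if geom.is_empty or not hasattr(geom, "exterior"):
            continue
        pts = np.asarray(geom.exterior.coords)
        best = max(best, float(_signed_depth(pts, scene).max()))
    return max(best, 0.0)


# ---------------------------------------------------------------------------
# scene CSV (polygon vertices + header for the edge)
# ---------------------------------------------------------------------------

def write_scene_csv(path: Union[str, Path, TextIO],
                    scene: BeamsEyeViewScene) -> None:
    """Serialize a scene: header lines for the edge, then vertex rows."""
    angle = float(np.degrees(np.arctan2(scene.edge_normal[1],
                                        scene.edge_normal[0])))
    lines = [
        f"# edge_point_x_cm={scene.edge_point[0]:.6f}",
        f"# edge_point_y_cm={scene.edge_point[1]:.6f}",
        f"# edge_normal_angle_deg={angle:.6f}",
    ]
    if scene.field_bounds is not None:
        lines.append("# field_bounds_cm=" +
                     ",".join(f"{b:.6f}" for b in scene.field_bounds))
    lines.append("x_cm,y_cm")
    for x, y in scene.heart_contour:
        lines.append(f"{x:.6f},{y:.6f}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_scene_csv(path: Union[str, Path, TextIO]) -> BeamsEyeViewScene:
    """Read a scene written by :func:`write_scene_csv`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    meta: dict[str, str] = {}
    verts: list[tuple[float, float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif line[0].isdigit() or line[0] in "+-.":
            x, _, y = line.partition(",")
            verts.append((float(x), float(y)))
    angle = np.radians(float(meta["edge_normal_angle_deg"]))
    bounds = None
    if "field_bounds_cm" in meta:
        bounds = tuple(float(b) for b in meta["field_bounds_cm"].split(","))
    return BeamsEyeViewScene(
        heart_contour=np.asarray(verts),
        edge_point=np.array([float(meta["edge_point_x_cm"]),
                             float(meta["edge_point_y_cm"])]),
        edge_normal=np.array([np.cos(angle), np.sin(angle)]),
        field_bounds=bounds,
    )
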