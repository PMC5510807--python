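"""Ciliated-edge geometry: the operator-clicked 5-point polyline.

The ciliated edge is delimited by five operator-placed points defining four
line segments.  All physical coordinates are in micrometres, with the origin
at the top-left pixel corner of the image, x increasing along columns and y
increasing downward along rows (pixel centre of row r / column c therefore
sits at ``((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_POINTS = 5


@dataclass(frozen=True)
class EdgePolyline:
    """Five ordered points (μm) delimiting the four-segment cilia wall.

    Parameters
    ----------
    points : (5, 2) array_like
        Ordered ``(x, y)`` vertices in micrometres.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_POINTS, 2):
            raise ValueError(
                f"edge polyline needs exactly {N_POINTS} (x, y) points, "
                f"got array of shape {pts.shape}"
            )
        seg = np.diff(pts, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(lengths == 0):
            raise ValueError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)

    # -- derived geometry ---------------------------------------------------

    @property
    def segments(self) -> np.ndarray:
        """(4, 2) segment vectors."""
        return np.diff(self.points, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        seg = self.segments
        return np.hypot(seg[:, 0], seg[:, 1])

    @property
    def cumulative_abscissa(self) -> np.ndarray:
        """Curvilinear abscissa of each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_abscissa[-1])

    def reversed(self) -> "EdgePolyline":
        return EdgePolyline(self.points[::-1].copy())

    def offset(self, distance: float, side: int = -1) -> "EdgePolyline":
        """Polyline shifted ``distance`` μm towards ``side``.

        Vertices move along the mean normal of their adjacent segments
        (signed like :meth:`signed_side`); used e.g. to sample the grey
        level in the middle of the cilia band rather than exactly on the
        clicked wall line.
        """
        seg = self.segments / self.segment_lengths[:, None]
        normals = np.stack([-seg[:, 1], seg[:, 0]], axis=1)
        vertex_n = np.empty_like(self.points)
        vertex_n[0] = normals[0]
        vertex_n[-1] = normals[-1]
        for i in range(1, N_POINTS - 1):
            n = normals[i - 1] + normals[i]
            vertex_n[i] = n / np.linalg.norm(n)
        return EdgePolyline(self.points + side * distance * vertex_n)

    # -- sampling -----------------------------------------------------------

    def point_at(self, s):
        """Point(s) at curvilinear abscissa ``s`` (clipped to the polyline)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        cum = self.cumulative_abscissa
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, N_POINTS - 2)
        frac = (s - cum[idx]) / self.segment_lengths[idx]
        return self.points[idx] + frac[..., None] * self.segments[idx]

    def tangent_at(self, s):
        """Unit tangent of the segment containing abscissa ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        cum = self.cumulative_abscissa
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, N_POINTS - 2)
        t = self.segments[idx] / self.segment_lengths[idx][..., None]
        return t

    def normal_at(self, s):
        """Unit normal, the tangent rotated +90° (x→y screen convention)."""
        t = self.tangent_at(s)
        return np.stack([-t[..., 1], t[..., 0]], axis=-1)

    def resample(self, step: float) -> np.ndarray:
        """Points at uniform curvilinear steps of ``step`` μm (incl. ends)."""
        if step <= 0:
            raise ValueError("step must be positive")
        n = max(int(np.ceil(self.total_length / step)) + 1, 2)
        s = np.linspace(0.0, self.total_length, n)
        return self.point_at(s)

    # -- distances ----------------------------------------------------------

    def distance_to(self, xy):
        """Distance from point(s) to the polyline and nearest segment index.

        Returns ``(dist, seg_index)``; the distance is the minimum over the
        four point-to-segment distances.
        """
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        a = self.points[:-1]                      # (4, 2)
        d = self.segments                         # (4, 2)
        ap = p[:, None, :] - a[None, :, :]        # (n, 4, 2)
        t = np.einsum("nij,ij->ni", ap, d) / (self.segment_lengths ** 2)
        t = np.clip(t, 0.0, 1.0)
        proj = a[None] + t[..., None] * d[None]
        dist = np.linalg.norm(p[:, None, :] - proj, axis=-1)
        seg = np.argmin(dist, axis=1)
        best = dist[np.arange(len(p)), seg]
        if np.ndim(xy) == 1:
            return float(best[0]), int(seg[0])
        return best, seg

    def project(self, xy):
        """Curvilinear abscissa of the nearest point on the polyline.

        Returns ``(s, dist)`` with ``s`` in μm along the wall.
        """
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        a = self.points[:-1]
        d = self.segments
        ap = p[:, None, :] - a[None, :, :]
        t = np.einsum("nij,ij->ni", ap, d) / (self.segment_lengths ** 2)
        t = np.clip(t, 0.0, 1.0)
        proj = a[None] + t[..., None] * d[None]
        dist = np.linalg.norm(p[:, None, :] - proj, axis=-1)
        seg = np.argmin(dist, axis=1)
        rows = np.arange(len(p))
        s = self.cumulative_abscissa[seg] + t[rows, seg] * self.segment_lengths[seg]
        if np.ndim(xy) == 1:
            return float(s[0]), float(dist[0, seg[0]])
        return s, dist[rows, seg]

    def signed_side(self, xy):
        """Sign of the cross product tangent × (point − foot): +1 / −1 / 0.

        Identifies on which side of its nearest segment a point lies; the
        synthetic generator uses this to place the cilia band and the beads
        on a consistent side of the wall.
        """
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        _, seg = self.distance_to(p)
        a = self.points[:-1][seg]
        t = self.segments[seg] / self.segment_lengths[seg][:, None]
        rel = p - a
        cross = t[:, 0] * rel[:, 1] - t[:, 1] * rel[:, 0]
        out = np.sign(cross)
        if np.ndim(xy) == 1:
            return float(out[0])
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"points": self.points.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EdgePolyline":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.asarray(obj["points"], dtype=float))


def band_mask(line: EdgePolyline, shape, pixel_size: float, width: float,
              side: int = -1) -> np.ndarray:
    """Boolean mask of pixels within ``width`` μm of the wall, on one side.

    ``side`` is the sign returned by :meth:`EdgePolyline.signed_side` for the
    kept half-plane (default −1: above a left-to-right polyline in screen
    coordinates, which is where the fluid and the beads live).
    """
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xy = np.stack([(cols.ravel() + 0.5) * pixel_size,
                   (rows.ravel() + 0.5) * pixel_size], axis=1)
    dist, _ = line.distance_to(xy)
    on_side = line.signed_side(xy) == side
    return ((dist <= width) & on_side).reshape(h, w)
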