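"""Micro-bead detection, linking, kinematics and selection filters.

Beads are separated from the background by grey-level thresholding (beads
are darker), labelled as connected components, and linked frame-to-frame by
gated greedy nearest-neighbour assignment.  Each track then receives
instantaneous velocities (forward differences), their decomposition into
components parallel and perpendicular to the nearest wall segment, and
per-detection distances to the ciliated edge.  Finally tracks are filtered
to those compatible with the flow-model assumptions: straight trajectories
moving essentially parallel to the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .framestack import FrameStack
from .geometry import EdgePolyline

logger = logging.getLogger(__name__)

BEAD_DIAMETER_UM = 4.5          # polystyrene micro-beads


@dataclass(frozen=True)
class Detection:
    """One thresholded bead in one frame (centroid in μm, area in μm²)."""

    frame_index: int
    centroid: tuple
    area: float


@dataclass
class TrackFilterPolicy:
    """Gates for linking and for the straight/parallel selection filters.

    ``max_link_distance`` bounds the per-frame displacement (beads move well
    under a micrometre per frame at video rates); ``min_straightness`` is
    the floor on the fraction of positional variance explained by the best
    total-least-squares line; ``max_vertical_ratio`` bounds
    |mean u_perp| / |mean u_par| (beads with a larger perpendicular drift
    are not wall-parallel flow markers).
    """

    max_link_distance: float = 3.0        # μm
    min_track_length: int = 10            # frames
    min_straightness: float = 0.9
    max_vertical_ratio: float = 0.25

    def __post_init__(self):
        if min(self.max_link_distance, self.min_track_length,
               self.min_straightness, self.max_vertical_ratio) <= 0:
            raise ValueError("all policy fields must be positive")
        if self.max_vertical_ratio > 1:
            raise ValueError("max_vertical_ratio must not exceed 1")


@dataclass
class BeadTrack:
    """An ordered chain of detections plus derived kinematics.

    Velocities are filled by :func:`track_kinematics`: per step ``(u_x,
    u_y)`` in μm/s plus the decomposition ``u_par``/``u_perp`` relative to
    the nearest edge segment.  ``v_b`` is the norm of the mean velocity
    vector; ``y0`` the time-mean distance to the edge; ``straightness`` the
    fraction of positional variance carried by the principal axis.
    """

    detections: list = field(default_factory=list)
    velocities: np.ndarray | None = None     # (n-1, 2) μm/s
    u_par: np.ndarray | None = None
    u_perp: np.ndarray | None = None
    distances: np.ndarray | None = None      # (n,) μm
    straightness: float | None = None

    def __len__(self):
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.centroid for d in self.detections], dtype=float)

    @property
    def mean_velocity(self) -> np.ndarray:
        return self.velocities.mean(axis=0)

    @property
    def v_b(self) -> float:
        """Mean speed: norm of the mean velocity vector (μm/s)."""
        return float(np.linalg.norm(self.mean_velocity))

    @property
    def y0(self) -> float:
        """Time-mean distance to the ciliated edge (μm)."""
        return float(np.mean(self.distances))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def segment_beads(frame: np.ndarray, pixel_size: float,
                  threshold: float | None = None,
                  area_gates: tuple = (4.0, 64.0),
                  frame_index: int = 0) -> list:
    """Detect dark beads in one frame by thresholding and labelling.

    Pixels strictly darker than ``threshold`` (Otsu when ``None``) form the
    bead mask; connected components with area inside ``area_gates`` (μm²)
    become detections.  Components touching the frame border are dropped
    (a clipped disc biases the centroid).  Centroids are darkness-weighted
    — darkness relative to the frame median grey, over the component
    dilated by one pixel so the anti-aliased rim contributes — giving
    sub-pixel accuracy.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        threshold = filters.threshold_otsu(frame)
    mask = frame < threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    background = float(np.median(frame))
    nrows, ncols = frame.shape
    dets = []
    for region in measure.regionprops(labels):
        area = region.area * pixel_size ** 2
        if not area_gates[0] <= area <= area_gates[1]:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols:
            continue
        r0e, c0e = max(r0 - 1, 0), max(c0 - 1, 0)
        r1e, c1e = min(r1 + 1, nrows), min(c1 + 1, ncols)
        local = labels[r0e:r1e, c0e:c1e] == region.label
        foot = ndimage.binary_dilation(local)
        w = np.where(foot,
                     np.clip(background - frame[r0e:r1e, c0e:c1e], 0.0,
                             None), 0.0)
        total = w.sum()
        if total > 0:
            rr = (w.sum(axis=1) @ np.arange(r0e, r1e)) / total
            cc = (w.sum(axis=0) @ np.arange(c0e, c1e)) / total
        else:                         # darker than half the frame: fall
            rr, cc = region.centroid  # back to the binary centroid
        dets.append(Detection(
            frame_index=frame_index,
            centroid=((cc + 0.5) * pixel_size, (rr + 0.5) * pixel_size),
            area=float(area)))
    return dets


def detect_movie(stack: FrameStack, threshold: float | None = None,
                 area_gates: tuple = (4.0, 64.0)) -> list:
    """Run :func:`segment_beads` on every frame; one detection list each."""
    return [segment_beads(stack.data[t], stack.pixel_size, threshold,
                          area_gates, frame_index=t)
            for t in range(stack.n_frames)]


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _canonical(dets: list) -> list:
    """Detections sorted by position: makes linking independent of the
    order the detector happened to emit them."""
    return sorted(dets, key=lambda d: (d.centroid[0], d.centroid[1]))


def link_tracks(detections_per_frame: list,
                policy: TrackFilterPolicy | None = None) -> list:
    """Greedy gated nearest-neighbour linking into :class:`BeadTrack`.

    Candidate (track, detection) pairs are taken in order of increasing
    distance — ties broken by lowest detection index in canonical (x, y)
    order, logged — and accepted while within ``max_link_distance``.
    Unmatched detections open new tracks; a track not extended in a frame
    ends there (no gap closing).  Tracks shorter than ``min_track_length``
    are dropped.
    """
    policy = policy or TrackFilterPolicy()
    open_tracks: list[BeadTrack] = []
    closed: list[BeadTrack] = []
    for dets in detections_per_frame:
        dets = _canonical(dets)
        if open_tracks and dets:
            last = np.array([t.detections[-1].centroid for t in open_tracks])
            cur = np.array([d.centroid for d in dets])
            dist = np.linalg.norm(last[:, None, :] - cur[None, :, :], axis=2)
            pairs = sorted(
                ((dist[i, j], i, j)
                 for i in range(len(open_tracks))
                 for j in range(len(dets))
                 if dist[i, j] <= policy.max_link_distance),
                key=lambda p: (p[0], p[2], p[1]))
            used_t: set[int] = set()
            used_d: set[int] = set()
            seen_d = {}
            for d, i, j in pairs:
                if i in used_t or j in used_d:
                    continue
                if d in seen_d and seen_d[d] != j:
                    logger.debug(
                        "ambiguous link at distance %.3f μm resolved to "
                        "lowest detection index", d)
                used_t.add(i)
                used_d.add(j)
                seen_d[d] = j
                open_tracks[i].detections.append(dets[j])
        else:
            used_t, used_d = set(), set()
        still_open = []
        for i, t in enumerate(open_tracks):
            (still_open if i in used_t else closed).append(t)
        open_tracks = still_open
        for j, d in enumerate(dets):
            if j not in used_d:
                open_tracks.append(BeadTrack(detections=[d]))
    closed.extend(open_tracks)
    return [t for t in closed if len(t) >= policy.min_track_length]


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def track_kinematics(track: BeadTrack, edge: EdgePolyline,
                     frame_rate: float) -> BeadTrack:
    """Fill velocities, parallel/perpendicular components and distances.

    Velocities are forward differences scaled by the frame interval; each
    step velocity is decomposed along the tangent and normal of the edge
    segment nearest to the step midpoint.  The distance of each detection
    is the minimum over the four point-to-segment distances.  Straightness
    is the variance fraction of the leading principal axis of the
    positions (1 for a perfect line, 1/2 for an isotropic cloud).
    """
    if len(track) < 2:
        raise ValueError("kinematics need at least 2 detections")
    pos = track.positions
    frames = track.frames
    dt = np.diff(frames) / frame_rate
    vel = np.diff(pos, axis=0) / dt[:, None]
    mid = 0.5 * (pos[:-1] + pos[1:])
    _, seg_idx = edge.distance_to(mid)
    tangents = edge.segments[seg_idx] \
        / edge.segment_lengths[seg_idx][:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    track.velocities = vel
    track.u_par = np.einsum("ij,ij->i", vel, tangents)
    track.u_perp = np.einsum("ij,ij->i", vel, normals)
    dist, _ = edge.distance_to(pos)
    track.distances = dist
    centred = pos - pos.mean(axis=0)
    cov = centred.T @ centred
    eig = np.sort(np.linalg.eigvalsh(cov))
    total = eig.sum()
    track.straightness = float(eig[1] / total) if total > 0 else 1.0
    return track


# ---------------------------------------------------------------------------
# Selection filters
# ---------------------------------------------------------------------------

def filter_tracks(tracks: list, policy: TrackFilterPolicy | None = None):
    """Keep straight, wall-parallel tracks; label every rejection.

    Returns ``(kept, rejected)`` where ``rejected`` is a list of
    ``(track, reason)`` pairs.
    """
    policy = policy or TrackFilterPolicy()
    kept, rejected = [], []
    for t in tracks:
        if t.velocities is None:
            raise ValueError("run track_kinematics before filtering")
        if t.straightness < policy.min_straightness:
            rejected.append((t, "straightness"))
            continue
        mean_par = abs(np.mean(t.u_par))
        mean_perp = abs(np.mean(t.u_perp))
        if mean_perp > policy.max_vertical_ratio * mean_par:
            rejected.append((t, "vertical"))
            continue
        kept.append(t)
    return kept, rejected


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: list) -> pd.DataFrame:
    """Long-format table: one row per (track, step)."""
    rows = []
    for tid, t in enumerate(tracks):
        pos = t.positions
        for i, det in enumerate(t.detections):
            rows.append({
                "track_id": tid, "frame": det.frame_index,
                "x_um": pos[i, 0], "y_um": pos[i, 1],
                "ux_um_s": t.velocities[i, 0] if (
                    t.velocities is not None and i < len(t.velocities))
                else np.nan,
                "uy_um_s": t.velocities[i, 1] if (
                    t.velocities is not None and i < len(t.velocities))
                else np.nan,
                "dist_um": t.distances[i] if t.distances is not None
                else np.nan})
    return pd.DataFrame(rows)


def summarize_tracks(kept: list, rejected: list) -> pd.DataFrame:
    """Per-bead summary: mean speed, mean distance, filter outcome."""
    rows = []
    for tid, (t, reason) in enumerate(
            [(t, None) for t in kept] + list(rejected)):
        rows.append({
            "track_id": tid, "n_frames": len(t),
            "v_b_um_s": t.v_b, "y0_um": t.y0,
            "straightness": t.straightness,
            "kept": reason is None, "reason": reason or ""})
    return pd.DataFrame(rows)
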