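"""Synthetic high-speed video generator with known ground truth.

No public repository of cilia/micro-bead recordings with per-bead ground
truth exists, so every downstream stage (beat analysis, bead tracking,
profile fitting) is validated against movies built by this module.  A movie
contains three ingredients:

* a *cilia band*: pixels within one cilium length of the operator polyline,
  on the fluid side, whose grey level oscillates at the beat frequency with
  a metachronal phase gradient along the edge;
* *micro-beads*: dark anti-aliased discs advected parallel to the edge at
  the speed prescribed by a parabolic velocity profile
  ``V(y0) = Uw * (1 - y0/h)**2``;
* optional i.i.d. Gaussian pixel noise, clipped to the 8-bit grey range.

Cilia and beads are darker than the background, as in brightfield
recordings of ciliated edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .framestack import FrameStack
from .geometry import EdgePolyline, band_mask

CILIUM_LENGTH_UM = 6.0          # band depth: one cilium length
DEFAULT_PIXEL_SIZE = 0.32       # μm / pixel
DEFAULT_FRAME_RATE = 358.0      # frames / s
DEFAULT_SHAPE = (192, 256)      # rows, cols


def default_edge_polyline(width_px: int = 256,
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          y_um: float = 52.0) -> EdgePolyline:
    """A horizontal 5-point wall spanning the field of view at height y_um."""
    x = np.linspace(0.0, width_px * pixel_size, 5)
    return EdgePolyline(np.column_stack([x, np.full(5, y_um)]))


@dataclass
class SyntheticMovieSpec:
    """Everything needed to render a movie deterministically.

    Defaults mirror the reference acquisition: 358 fps, 1800 frames,
    256×192 pixels of 0.32 μm.  ``bead_entries`` is a list of
    ``(entry_frame, y0_um)`` pairs; each bead travels parallel to the edge
    at ``Uw * (1 - y0/h)**2`` where ``profile = (Uw, h)``.
    """

    edge_polyline: EdgePolyline
    n_frames: int = 1800
    frame_rate: float = DEFAULT_FRAME_RATE
    height: int = DEFAULT_SHAPE[0]
    width: int = DEFAULT_SHAPE[1]
    pixel_size: float = DEFAULT_PIXEL_SIZE
    cbf: float = 14.0
    grey_modulation_amplitude: float = 60.0
    wavelength: float = 13.0
    cilia_density: float = 0.84
    background_mean: float = 180.0
    noise_sd: float = 0.0
    bead_radius: float = 2.25
    bead_grey: float = 40.0
    bead_entries: list = field(default_factory=list)
    profile: tuple = (138.3, 87.5)
    band_width: float = CILIUM_LENGTH_UM
    side: int = -1                 # fluid side of the polyline
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.cilia_density <= 1.0:
            raise ValueError("cilia_density must lie in [0, 1]")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.cbf >= self.frame_rate / 2:
            raise ValueError("cbf must be below the Nyquist frequency")
        uw, h = self.profile
        if h <= 0:
            raise ValueError("profile height h must be positive")
        for i, (_, y0) in enumerate(self.bead_entries):
            # y0 = h is allowed: a bead sitting at the stagnant interface
            # simply does not move
            if not 0.0 < y0 <= h:
                raise ValueError(
                    f"bead {i}: y0 = {y0} μm must satisfy 0 < y0 <= h = {h}")

    @property
    def shape(self):
        return (self.height, self.width)

    def cilia_zone_mask(self) -> np.ndarray:
        """Pixels belonging to the cilia band (fluid side of the wall)."""
        return band_mask(self.edge_polyline, self.shape, self.pixel_size,
                         self.band_width, side=self.side)

    def expected_speed(self, y0: float) -> float:
        uw, h = self.profile
        return uw * (1.0 - y0 / h) ** 2


@dataclass
class GroundTruth:
    """What the generator actually put into a movie."""

    cbf: float
    wavelength: float
    cilia_density: float
    beads: list                    # dicts: entry_frame, y0, expected_speed
    parabola: tuple                # (Uw, h)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        obj["parabola"] = tuple(obj["parabola"])
        return cls(**obj)


def _render_disc(frame: np.ndarray, cx: float, cy: float, radius_px: float,
                 grey: float, subsamples: int = 6):
    """Alpha-composite an anti-aliased dark disc onto ``frame`` in place.

    Pixel coverage is estimated by ``subsamples``² area sampling, giving
    sub-pixel centroid accuracy for the velocity tests downstream.
    """
    h, w = frame.shape
    r0 = max(int(np.floor(cy - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(cy + radius_px)) + 2, h)
    c0 = max(int(np.floor(cx - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(cx + radius_px)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    sub = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    rows = np.arange(r0, r1)[:, None] + sub[None, :]          # (nr, s)
    cols = np.arange(c0, c1)[:, None] + sub[None, :]
    dr2 = (rows - cy) ** 2                                    # (nr, s)
    dc2 = (cols - cx) ** 2
    inside = (dr2[:, None, :, None] + dc2[None, :, None, :]) <= radius_px ** 2
    cover = inside.reshape(r1 - r0, c1 - c0, -1).mean(axis=2)
    patch = frame[r0:r1, c0:c1]
    patch *= 1.0 - cover
    patch += cover * grey


def generate_movie(spec: SyntheticMovieSpec):
    """Render a movie and its ground truth.

    Returns ``(FrameStack, GroundTruth)``; bit-identical output for equal
    specs (including ``rng_seed``).
    """
    rng = np.random.default_rng(spec.rng_seed)
    h_px, w_px = spec.shape
    p = spec.pixel_size
    line = spec.edge_polyline
    uw, h_chan = spec.profile

    # --- static band geometry and phase field -----------------------------
    band = spec.cilia_zone_mask()
    rows, cols = np.nonzero(band)
    xy = np.column_stack([(cols + 0.5) * p, (rows + 0.5) * p])
    s_band, _ = line.project(xy)
    # exactly round(N * rho) band pixels are cilia (seeded choice)
    n_band = len(rows)
    n_cilia = int(round(spec.cilia_density * n_band))
    order = rng.permutation(n_band)
    cilia_sel = order[:n_cilia]

    omega = 2.0 * np.pi * spec.cbf
    k = 2.0 * np.pi / spec.wavelength
    phase_x = k * s_band[cilia_sel]
    m = spec.grey_modulation_amplitude

    # --- beads ------------------------------------------------------------
    s0 = spec.bead_radius + 1.0
    beads = []
    for i, (entry_frame, y0) in enumerate(spec.bead_entries):
        speed = spec.expected_speed(y0)
        pos0 = (line.point_at(s0)
                + spec.side * y0 * line.normal_at(s0))
        inside = (0 <= pos0[0] <= w_px * p) and (0 <= pos0[1] <= h_px * p)
        if not inside:
            raise ValueError(
                f"bead {i} initial position {tuple(np.round(pos0, 2))} μm "
                "is outside the frame")
        beads.append({"index": i, "entry_frame": int(entry_frame),
                      "y0": float(y0), "expected_speed": float(speed)})

    # --- render -----------------------------------------------------------
    movie = np.empty((spec.n_frames, h_px, w_px), dtype=np.uint8)
    base = np.full((h_px, w_px), spec.background_mean, dtype=float)
    t_grid = np.arange(spec.n_frames) / spec.frame_rate
    for ti, t in enumerate(t_grid):
        frame = base.copy()
        osc = spec.background_mean - 0.5 * m * (
            1.0 + np.sin(omega * t - phase_x))
        frame[rows[cilia_sel], cols[cilia_sel]] = osc
        for b in beads:
            dt = t - b["entry_frame"] / spec.frame_rate
            if dt < 0:
                continue
            s = s0 + b["expected_speed"] * dt
            if s > line.total_length:
                continue
            centre = (line.point_at(s)
                      + spec.side * b["y0"] * line.normal_at(s))
            _render_disc(frame, centre[0] / p - 0.5, centre[1] / p - 0.5,
                         spec.bead_radius / p, spec.bead_grey)
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, frame.shape)
        movie[ti] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    stack = FrameStack(data=movie, frame_rate=spec.frame_rate,
                       pixel_size=spec.pixel_size)
    truth = GroundTruth(
        cbf=spec.cbf, wavelength=spec.wavelength,
        cilia_density=n_cilia / n_band if n_band else 0.0,
        beads=beads, parabola=(uw, h_chan))
    return stack, truth


def generate_profile_samples(parabola, y_grid, noise_sd=0.0,
                             rng_seed: int = 0):
    """Noisy samples of ``V(y) = Uw * (1 - y/h)**2`` on ``y_grid``.

    ``noise_sd`` is the Gaussian SD in μm/s, either a scalar or one value
    per altitude (per-bead velocity scatter grows with the velocity, so a
    proportional ``noise_sd = frac * V(y)`` is the realistic choice).
    Returns a :class:`~ciliaflow.profile.VelocityProfile`.
    """
    from .profile import VelocityProfile

    uw, h = parabola
    if h <= 0:
        raise ValueError("h must be positive")
    y = np.asarray(y_grid, dtype=float)
    if y.size == 0:
        raise ValueError("y_grid must not be empty")
    if np.any((y < 0) | (y > h)):
        raise ValueError("y_grid must lie within [0, h]")
    v = uw * (1.0 - y / h) ** 2
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), y.shape)
    if np.any(sd > 0):
        rng = np.random.default_rng(rng_seed)
        v = v + rng.normal(0.0, 1.0, y.shape) * sd
    return VelocityProfile(y=y, v=v)
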