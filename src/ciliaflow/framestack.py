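"""Grey-level movie container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class FrameStack:
    """A T×H×W grey-level movie with acquisition metadata.

    Parameters
    ----------
    data : (T, H, W) ndarray
        Grey levels, any numeric dtype.
    frame_rate : float
        Frames per second.
    pixel_size : float
        Micrometres per pixel (square pixels).
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("frame stack must be (T>=2, H, W)")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def field_um(self):
        """(width, height) of the field of view in μm."""
        _, h, w = self.data.shape
        return w * self.pixel_size, h * self.pixel_size

    def time_average(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def contains_um(self, xy) -> np.ndarray:
        """Whether μm positions fall inside the field of view."""
        xy = np.atleast_2d(xy)
        w_um, h_um = self.field_um
        return ((xy[:, 0] >= 0) & (xy[:, 0] <= w_um)
                & (xy[:, 1] >= 0) & (xy[:, 1] <= h_um))

    def sample_at(self, xy_um, frames=None, order: int = 1) -> np.ndarray:
        """Bilinear grey-level samples at μm positions for each frame.

        Returns an array of shape ``(T, n_points)``.
        """
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        cols = xy[:, 0] / self.pixel_size - 0.5
        rows = xy[:, 1] / self.pixel_size - 0.5
        frames = (np.arange(self.n_frames) if frames is None
                  else np.asarray(frames, dtype=int))
        out = np.empty((len(frames), xy.shape[0]), dtype=float)
        for i, t in enumerate(frames):
            out[i] = ndimage.map_coordinates(
                self.data[t].astype(float), [rows, cols],
                order=order, mode="nearest")
        return out

    # -- I/O ----------------------------------------------------------------

    def to_tiff(self, path):
        data = self.data
        if data.dtype != np.uint8:
            data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
        tifffile.imwrite(
            path, data,
            metadata={"frame_rate_hz": self.frame_rate,
                      "pixel_size_um": self.pixel_size})

    @classmethod
    def from_tiff(cls, path, frame_rate: float | None = None,
                  pixel_size: float | None = None) -> "FrameStack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata
            meta = meta[0] if meta else {}
        frame_rate = frame_rate or meta.get("frame_rate_hz")
        pixel_size = pixel_size or meta.get("pixel_size_um")
        if frame_rate is None or pixel_size is None:
            raise ValueError(
                "frame_rate and pixel_size not found in TIFF metadata; "
                "pass them explicitly")
        return cls(data=data, frame_rate=float(frame_rate),
                   pixel_size=float(pixel_size))
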