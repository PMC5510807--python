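"""Ciliary beat pattern analysis from high-speed video.

Four quantities are extracted from a grey-level movie and operator
landmarks:

* **CBF** — ciliary beat frequency, by two independent routes: the dominant
  peak of the FFT power spectrum of the mean grey level along the edge
  line, and the repeat period of the video-kymograph autocorrelation.
* **CBA** — ciliary beat amplitude, the tip travel between the extreme
  positions of the beat cycle, from three clicked points P0 (base), P1 and
  P2 (tip before the effective and recovery strokes).
* **λ** — metachronal wavelength, from the linear regression of the
  oscillation phase against curvilinear abscissa along the edge
  (λ = 2π/|slope|), the phase being read per perpendicular line segment.
* **ρc** — cilia density, the fraction of edge-zone pixels darker than the
  mean background grey level; with a cilium diameter e_c this yields the
  inter-cilia distance d_c = e_c (1 − ρc)/ρc and the uncovered fraction
  f_c = 1 − ρc.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .exceptions import (NoDominantFrequency, NoMeasurablePeriod,
                         WavelengthNotMeasurable)
from .framestack import FrameStack
from .geometry import EdgePolyline

DEFAULT_F_BAND = (0.5, 30.0)    # Hz, physiological CBF search band
CILIUM_DIAMETER_UM = 0.2


# ---------------------------------------------------------------------------
# CBF, method 1: FFT of the mean grey level along the edge line
# ---------------------------------------------------------------------------

def _line_coords(stack: FrameStack, line: EdgePolyline) -> np.ndarray:
    # the image is convex, so it suffices to check the clicked vertices
    inside = stack.contains_um(line.points)
    if not inside.all():
        idx = int(np.nonzero(~inside)[0][0])
        bad = line.points[idx]
        raise ValueError(
            f"polyline point {idx} at ({bad[0]:.2f}, {bad[1]:.2f}) μm "
            "is outside the image bounds")
    return line.resample(stack.pixel_size)


def cbf_fft(stack: FrameStack, line: EdgePolyline,
            f_min: float = DEFAULT_F_BAND[0],
            f_max: float = DEFAULT_F_BAND[1],
            peak_to_median: float = 10.0):
    """CBF as the highest-power frequency of the edge-line grey signal.

    Returns ``(cbf_hz, (freqs, power))``.  The spectral resolution is
    ``frame_rate / n_frames``.  Raises :class:`NoDominantFrequency` when the
    in-band peak does not exceed ``peak_to_median`` times the in-band
    median power (a flat spectrum).
    """
    if stack.n_frames < 64:
        raise ValueError("need at least 64 frames for a usable spectrum")
    if not 0 < f_min < f_max < stack.frame_rate / 2:
        raise ValueError("need 0 < f_min < f_max < Nyquist")
    pts = _line_coords(stack, line)
    series = stack.sample_at(pts).mean(axis=1)
    series = series - series.mean()
    power = np.abs(np.fft.rfft(series)) ** 2
    freqs = np.fft.rfftfreq(stack.n_frames, d=1.0 / stack.frame_rate)
    band = (freqs >= f_min) & (freqs <= f_max)
    if not band.any():
        raise ValueError("frequency band contains no FFT bin")
    p_band = power[band]
    floor = np.median(p_band)
    peak = p_band.max()
    if peak <= 0 or peak < peak_to_median * floor:
        raise NoDominantFrequency(
            f"no dominant frequency in [{f_min}, {f_max}] Hz "
            f"(peak/median = {peak / floor if floor else np.inf:.2f})")
    cbf = float(freqs[band][np.argmax(p_band)])
    return cbf, (freqs, power)


# ---------------------------------------------------------------------------
# CBF, method 2: video-kymography
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Space–time image: row t is the edge line resampled in frame t."""

    data: np.ndarray               # (T, S)
    abscissa_step: float           # μm
    time_step: float               # s

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def build_kymograph(stack: FrameStack, line: EdgePolyline) -> Kymograph:
    """Stack the grey level along the polyline over all frames."""
    pts = _line_coords(stack, line)
    data = stack.sample_at(pts)
    return Kymograph(data=data, abscissa_step=stack.pixel_size,
                     time_step=1.0 / stack.frame_rate)


def _parabolic_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def cbf_kymograph(kymo: Kymograph, min_peak: float = 0.2) -> float:
    """CBF from the dominant lag of the column-averaged autocorrelation.

    Each spatial column's temporal autocorrelation is averaged; the beating
    period is the base lag of the comb of autocorrelation peaks, refined by
    parabolic interpolation at the highest-order visible peak (sub-frame
    precision).  Raises :class:`NoMeasurablePeriod` when no peak exceeds
    ``min_peak`` of the zero-lag value.
    """
    x = kymo.data - kymo.data.mean(axis=0, keepdims=True)
    denom = (x ** 2).sum(axis=0)
    keep = denom > 0
    if not keep.any():
        raise NoMeasurablePeriod("kymograph has no temporal variance")
    t = x.shape[0]
    nfft = 2 * t
    spec = np.abs(np.fft.rfft(x[:, keep], n=nfft, axis=0)) ** 2
    ac = np.fft.irfft(spec, n=nfft, axis=0)[:t]
    ac = (ac / denom[keep]).mean(axis=1)
    max_lag = t // 2
    peaks, props = signal.find_peaks(ac[:max_lag], height=min_peak)
    if len(peaks) == 0:
        raise NoMeasurablePeriod(
            "no autocorrelation peak above threshold: no measurable period")
    # sub-sample base period first, then read the highest-order peak of the
    # comb for lag precision ∝ 1/order
    base = _parabolic_peak(ac, int(peaks[0]))
    last = int(peaks[-1])
    order = max(int(round(last / base)), 1)
    period = _parabolic_peak(ac, last) / order
    return float(1.0 / (period * kymo.time_step))


# ---------------------------------------------------------------------------
# CBA from the three clicked points
# ---------------------------------------------------------------------------

def measure_cba(p0, p1, p2):
    """Beat amplitude and cilium length from base/tip landmark points.

    CBA is the tip travel |P1P2|; the cilium length is the mean of |P0P1|
    and |P0P2|.  Coincident P1 and P2 yield CBA = 0 with a warning
    (degenerate beat).
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    cba = float(np.linalg.norm(p2 - p1))
    if cba == 0.0:
        warnings.warn("P1 and P2 coincide: degenerate beat, CBA = 0",
                      stacklevel=2)
    length = float(0.5 * (np.linalg.norm(p1 - p0) + np.linalg.norm(p2 - p0)))
    return cba, length


# ---------------------------------------------------------------------------
# Metachronal wavelength
# ---------------------------------------------------------------------------

WavelengthFit = namedtuple(
    "WavelengthFit", ["wavelength", "slope", "r2", "abscissa", "phase"])


def metachronal_wavelength(stack: FrameStack, line: EdgePolyline,
                           n_segments: int = 104, segment_len: int = 24,
                           f_min: float = DEFAULT_F_BAND[0],
                           f_max: float = DEFAULT_F_BAND[1],
                           r2_floor: float = 0.7,
                           max_wavelength_factor: float = 10.0):
    """Wavelength of the metachronal wave by phase regression along the edge.

    ``n_segments`` line segments of ``segment_len`` pixels, perpendicular to
    the wall and centred on it, are spread uniformly along the polyline.
    The phase of each segment's mean grey level at the CBF bin is unwrapped
    along the curvilinear abscissa x and regressed as θ(x) = p·x + c; the
    wavelength is λ = 2π/|p|.

    Returns a :class:`WavelengthFit`.  Raises
    :class:`WavelengthNotMeasurable` when the regression R² falls below
    ``r2_floor`` or when λ exceeds ``max_wavelength_factor`` edge lengths
    (segments effectively in phase).
    """
    if n_segments < 3:
        raise ValueError("need at least 3 segments")
    cbf, _ = cbf_fft(stack, line, f_min, f_max)   # may raise
    total = line.total_length
    s_centres = (np.arange(n_segments) + 0.5) * total / n_segments
    centres = line.point_at(s_centres)
    normals = line.normal_at(s_centres)
    offsets = (np.arange(segment_len) - (segment_len - 1) / 2.0) \
        * stack.pixel_size
    pts = (centres[:, None, :]
           + offsets[None, :, None] * normals[:, None, :])
    w_um, h_um = stack.field_um
    np.clip(pts[..., 0], 0.0, w_um, out=pts[..., 0])
    np.clip(pts[..., 1], 0.0, h_um, out=pts[..., 1])
    series = stack.sample_at(pts.reshape(-1, 2))
    series = series.reshape(stack.n_frames, n_segments, segment_len)
    series = series.mean(axis=2)                   # (T, n_segments)
    series = series - series.mean(axis=0, keepdims=True)
    spectrum = np.fft.rfft(series, axis=0)
    freqs = np.fft.rfftfreq(stack.n_frames, d=1.0 / stack.frame_rate)
    bin_idx = int(np.argmin(np.abs(freqs - cbf)))
    theta = np.unwrap(np.angle(spectrum[bin_idx]))
    if np.ptp(theta) == 0:
        raise WavelengthNotMeasurable(
            "all segments in phase: wavelength not measurable")
    fit = stats.linregress(s_centres, theta)
    p = float(fit.slope)
    r2 = float(fit.rvalue ** 2)
    if r2 < r2_floor:
        raise WavelengthNotMeasurable(
            f"phase regression R² = {r2:.3f} below floor {r2_floor}: "
            "wavelength not measurable")
    if p == 0 or 2.0 * np.pi / abs(p) > max_wavelength_factor * total:
        raise WavelengthNotMeasurable(
            "phase slope indistinguishable from zero: wavelength not "
            "measurable")
    lam = float(2.0 * np.pi / abs(p))
    return WavelengthFit(wavelength=lam, slope=p, r2=r2,
                         abscissa=s_centres, phase=theta)


# ---------------------------------------------------------------------------
# Cilia density
# ---------------------------------------------------------------------------

CiliaDensity = namedtuple("CiliaDensity", ["rho_c", "d_c", "f_c"])


def cilia_density(stack: FrameStack, cilia_zone: np.ndarray,
                  background_zone: np.ndarray,
                  e_c: float = CILIUM_DIAMETER_UM) -> CiliaDensity:
    """Cilia density from grey-level comparison of two image zones.

    ``rho_c`` is the fraction of time-averaged cilia-zone pixels strictly
    darker than the mean grey of the background zone.  For a homogeneous
    cilia distribution of diameter ``e_c`` this equals e_c/(e_c + d_c),
    hence ``d_c = e_c (1 − rho_c)/rho_c`` (NaN when rho_c = 0: undefined
    inter-cilia distance) and the uncovered fraction ``f_c = 1 − rho_c``.
    """
    cilia_zone = np.asarray(cilia_zone, dtype=bool)
    background_zone = np.asarray(background_zone, dtype=bool)
    if (cilia_zone & background_zone).any():
        raise ValueError("cilia and background zones must be disjoint")
    if cilia_zone.sum() < 100 or background_zone.sum() < 100:
        raise ValueError("each zone must contain at least 100 pixels")
    avg = stack.time_average()
    bg_mean = avg[background_zone].mean()
    rho = float((avg[cilia_zone] < bg_mean).mean())
    d_c = e_c * (1.0 - rho) / rho if rho > 0 else float("nan")
    return CiliaDensity(rho_c=rho, d_c=d_c, f_c=1.0 - rho)
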