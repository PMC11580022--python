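"""Tether-dragging kinematics: angle, tangential force, velocity, stalls.

A tether dragged around the cell surface slides when the tangential force
component f_par = f * sin(theta) overcomes membrane-cytoskeleton
resistance.  theta is the angle between the contour normal at the tether
base and the base-to-bead segment; the tracked cell outline is
interpolated with a periodic cubic spline and the tangent is evaluated at
the contour point nearest the base.

Base velocity comes from Gaussian-smoothed base-coordinate traces: the
coordinates are smoothed (discrete Gaussian, sigma in seconds, truncated
at 4 sigma, reflect-padded), the cumulative travelled distance is the
running sum of frame-to-frame displacements of the smoothed track, and
v_t is its central-difference derivative.  Smoothing the coordinates
rather than the raw cumulative-distance trace avoids the rectified-noise
drift that position jitter otherwise injects into the distance sum.

A stall is a maximal contiguous run with |v_t| below the noise floor
(default 0.5 um/s); each stall reports the peak tangential force it
sustained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splprep, splev
from scipy.optimize import minimize_scalar

from .exceptions import DomainError, GeometryError

__all__ = [
    "V_NOISE_DEFAULT",
    "DragFrame",
    "DragTrack",
    "StallSegment",
    "membrane_angle",
    "tangential_force",
    "gaussian_smooth",
    "base_kinematics",
    "stall_segments",
]

#: Velocity noise floor for a stationary tether base, um/s.
V_NOISE_DEFAULT = 0.5


@dataclass
class DragFrame:
    """One tracked frame: contour, tether base, bead centre, total force."""

    time: float                 # s
    contour: np.ndarray         # (N, 2) ordered points, um
    base: np.ndarray            # (2,) um
    bead_center: np.ndarray     # (2,) um
    total_force: float          # pN

    def __post_init__(self):
        self.contour = np.asarray(self.contour, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        self.bead_center = np.asarray(self.bead_center, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 \
                or self.contour.shape[0] < 5:
            raise DomainError("contour needs >= 5 ordered 2D points")
        if self.total_force < 0:
            raise DomainError("total force must be >= 0")


@dataclass(frozen=True)
class StallSegment:
    """A contiguous interval with |v_t| below the noise floor."""

    t_start: float
    t_end: float
    f_max: float        # peak tangential force sustained, pN
    short: bool         # True when shorter than 3x the smoothing width

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def membrane_angle(frame: DragFrame, base_tolerance: float = 0.5,
                   smoothing: float = 0.017**2) -> float:
    """Tether membrane angle theta at the base, folded into [0, pi/2].

    The tracked outline is fit with a periodic cubic spline; the tangent is
    taken at the spline point nearest the tether base and theta is the
    angle between the contour normal there and the base-to-bead segment
    (0: pulled along the normal, pi/2: pulled tangentially).
    ``smoothing`` is the per-point squared tracking error (um^2) used as
    the spline smoothing condition, so the tangent is not slaved to
    point-level jitter; 0 interpolates exactly.

    Raises GeometryError when the base lies farther than ``base_tolerance``
    (um) from the contour.
    """
    pts = frame.contour
    # drop a duplicated closing point, if present
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    x, y = pts[:, 0], pts[:, 1]
    tck, _ = splprep([x, y], s=smoothing * len(x), per=True)

    u_dense = np.linspace(0.0, 1.0, 20 * len(x), endpoint=False)
    xd, yd = splev(u_dense, tck)
    d2 = (xd - frame.base[0]) ** 2 + (yd - frame.base[1]) ** 2
    u0 = u_dense[int(np.argmin(d2))]

    def dist2(u):
        px, py = splev(u % 1.0, tck)
        return (px - frame.base[0]) ** 2 + (py - frame.base[1]) ** 2

    span = 1.0 / len(x)
    res = minimize_scalar(dist2, bounds=(u0 - span, u0 + span),
                          method="bounded")
    u_star = res.x % 1.0
    if np.sqrt(res.fun) > base_tolerance:
        raise GeometryError(
            f"tether base is {np.sqrt(res.fun):.3g} um from the contour "
            f"(tolerance {base_tolerance} um)")

    dx, dy = splev(u_star, tck, der=1)
    tangent = np.array([dx, dy], dtype=float)
    tnorm = np.linalg.norm(tangent)
    if tnorm == 0:
        raise GeometryError("degenerate contour tangent")
    tangent /= tnorm
    normal = np.array([-tangent[1], tangent[0]])

    bb = frame.bead_center - frame.base
    bbnorm = np.linalg.norm(bb)
    if bbnorm == 0:
        raise GeometryError("bead coincides with the tether base")
    bb /= bbnorm
    # fold: the decomposition uses |sin theta|; the normal is undirected
    cos_theta = abs(float(np.dot(normal, bb)))
    return float(np.arccos(np.clip(cos_theta, 0.0, 1.0)))


def tangential_force(total_force, theta):
    """Tangential force component f_par = f * sin(theta), theta in [0, pi/2]."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi / 2 + 1e-12):
        raise DomainError("theta must lie in [0, pi/2]")
    f = np.asarray(total_force, dtype=float) * np.sin(theta)
    return float(f) if f.ndim == 0 else f


def gaussian_smooth(values, dt: float, width: float = 1.0,
                    width_is_fwhm: bool = False):
    """Discrete Gaussian smoothing of a uniformly sampled trace.

    ``width`` is the Gaussian sigma in seconds (or the FWHM when
    ``width_is_fwhm``); the kernel is truncated at 4 sigma and the trace is
    reflect-padded at both ends.
    """
    values = np.asarray(values, dtype=float)
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0))) if width_is_fwhm \
        else width
    sigma_samp = sigma / dt
    if sigma_samp <= 0:
        return values.copy()
    half = max(int(np.ceil(4.0 * sigma_samp)), 1)
    kk = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (kk / sigma_samp) ** 2)
    kernel /= kernel.sum()
    pad = min(half, values.size - 1)
    padded = np.pad(values, pad, mode="reflect")
    sm = np.convolve(padded, kernel, mode="same")
    return sm[pad:pad + values.size] if pad else sm


def base_kinematics(times, base_xy, smoothing_width: float = 1.0,
                    width_is_fwhm: bool = False):
    """Cumulative distance and velocity of the tether base.

    Parameters
    ----------
    times : (n,) array, s
    base_xy : (n, 2) array, um
    smoothing_width : float
        Gaussian width in seconds applied to the coordinate traces
        (sigma by default, FWHM when ``width_is_fwhm``).

    Returns
    -------
    cum_distance : (n,) array, um, non-decreasing
    v_t : (n,) array, um/s (central differences of cum_distance)
    """
    times = np.asarray(times, dtype=float)
    xy = np.asarray(base_xy, dtype=float)
    if times.size < 3:
        raise DomainError("need >= 3 frames for kinematics")
    if xy.shape != (times.size, 2):
        raise DomainError("base_xy must be (n, 2)")
    dt = float(np.median(np.diff(times)))
    xs = gaussian_smooth(xy[:, 0], dt, smoothing_width, width_is_fwhm)
    ys = gaussian_smooth(xy[:, 1], dt, smoothing_width, width_is_fwhm)
    steps = np.hypot(np.diff(xs), np.diff(ys))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    v = np.gradient(cum, times)
    return cum, v


@dataclass
class DragTrack:
    """A tracked dragging experiment with derived per-frame quantities."""

    frames: list[DragFrame]
    theta: np.ndarray | None = field(default=None)
    f_parallel: np.ndarray | None = field(default=None)
    cum_distance: np.ndarray | None = field(default=None)
    v_t: np.ndarray | None = field(default=None)
    stalls: list[StallSegment] | None = field(default=None)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def base_xy(self) -> np.ndarray:
        return np.array([fr.base for fr in self.frames])

    @property
    def total_force(self) -> np.ndarray:
        return np.array([fr.total_force for fr in self.frames])

    def analyze(self, smoothing_width: float = 1.0,
                width_is_fwhm: bool = False,
                v_noise: float = V_NOISE_DEFAULT,
                base_tolerance: float = 0.5,
                contour_smoothing: float = 0.017**2) -> "DragTrack":
        """Compute theta, f_par, kinematics and stalls in place."""
        self.theta = np.array([
            membrane_angle(fr, base_tolerance=base_tolerance,
                           smoothing=contour_smoothing)
            for fr in self.frames])
        self.f_parallel = tangential_force(self.total_force, self.theta)
        self.cum_distance, self.v_t = base_kinematics(
            self.times, self.base_xy, smoothing_width, width_is_fwhm)
        self.stalls = stall_segments(
            self.times, self.v_t, self.f_parallel, v_noise=v_noise,
            min_duration=3.0 * smoothing_width)
        return self


def stall_segments(times, v_t, f_parallel,
                   v_noise: float = V_NOISE_DEFAULT,
                   min_duration: float | None = None) -> list[StallSegment]:
    """Maximal contiguous segments with |v_t| < v_noise.

    Each segment carries the peak tangential force it sustained.  Segments
    shorter than ``min_duration`` (default 3 s, three smoothing widths) are
    reported with ``short=True`` rather than silently merged or dropped.
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(v_t, dtype=float)
    f = np.asarray(f_parallel, dtype=float)
    if min_duration is None:
        min_duration = 3.0
    stalled = np.abs(v) < v_noise
    out: list[StallSegment] = []
    i = 0
    n = stalled.size
    while i < n:
        if stalled[i]:
            j = i
            while j + 1 < n and stalled[j + 1]:
                j += 1
            seg = StallSegment(
                t_start=float(times[i]), t_end=float(times[j]),
                f_max=float(np.max(f[i:j + 1])),
                short=(times[j] - times[i]) < min_duration)
            out.append(seg)
            i = j + 1
        else:
            i += 1
    return out
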