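"""Glottal main axis estimation and videokymogram (VKG) synthesis.

The glottal main axis g is modelled as a straight line through the glottal
center G0 = (mu_x, mu_y) given by the column/row TIV fits.  Among all lines
through G0 (orientations sampled every 0.5 degree over the quasi-vertical
range 30..150 degrees from the x-axis) the axis is the one whose mean
sampled intensity inside the ROI is minimal — the glottal gap is the darkest
quasi-vertical structure, so the darkest line through its center is its
axis.  The anterior (A, g = 100%) and posterior (P, g = 1%) endpoints are
the two outermost abrupt intensity transitions along the axis profile that
do not sit on the ROI border; bright peaks between them (a glottis split by
a bridge) are ignored.

Kymograms are synthesised by sampling, in every frame, the segment
perpendicular to g at a station g% of the P->A span.  The segment is
translated by the active block's ROI-center offset relative to the first
block (endoscope-motion compensation) and its orientation follows the axis
(rotation compensation), so the same anatomical line is scanned throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .roi_tracker import ROIWindow
from .video_io import VideoCube

__all__ = [
    "GlottalAxis",
    "Kymogram",
    "EndpointDetectionError",
    "fit_main_axis",
    "axis_profile",
    "axis_endpoints",
    "synthesize_vkg",
]


class EndpointDetectionError(RuntimeError):
    """Fewer than two abrupt-transition candidates along the axis."""


@dataclass
class GlottalAxis:
    g0: tuple[float, float]             # (x, y) glottal center, full-frame coords
    alpha: float                        # axis angle vs x-axis, degrees
    p_point: tuple[float, float] | None = None   # posterior end, g = 1%
    a_point: tuple[float, float] | None = None   # anterior end, g = 100%
    degenerate: bool = False

    @property
    def theta1(self) -> float:
        """Slope of the line y = theta0 + theta1 * x (inf for vertical)."""
        return float(np.tan(np.radians(self.alpha)))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector (dx, dy) along the axis."""
        a = np.radians(self.alpha)
        return np.array([np.cos(a), np.sin(a)])


@dataclass
class Kymogram:
    image: np.ndarray                   # (samples, T)
    g_position: float                   # percent along P->A
    scan_endpoints: np.ndarray = field(default=None)  # (T, 4): x0,y0,x1,y1 per frame


def _line_samples(frame: np.ndarray, x0: float, y0: float, angle_deg: float,
                  half_length: float, step: float = 0.5) -> np.ndarray:
    """Bilinear samples along a line through (x0, y0) at the given angle."""
    a = np.radians(angle_deg)
    s = np.arange(-half_length, half_length + step / 2, step)
    xs = x0 + s * np.cos(a)
    ys = y0 + s * np.sin(a)
    inside = (xs >= 0) & (xs <= frame.shape[1] - 1) & \
             (ys >= 0) & (ys <= frame.shape[0] - 1)
    if not inside.any():
        return np.array([])
    return ndimage.map_coordinates(frame.astype(float),
                                   [ys[inside], xs[inside]], order=1)


def fit_main_axis(max_open_frame_roi: np.ndarray, g0_roi: tuple[float, float],
                  angle_range: tuple[float, float] = (30.0, 150.0),
                  angle_step: float = 0.5) -> GlottalAxis:
    """Darkest line through G0: brute-force orientation search.

    ``g0_roi`` is (x, y) in ROI-local coordinates.  Ties break to the
    orientation closest to 90 degrees (vertical); a uniform ROI ties
    everywhere and returns the vertical axis with a degenerate-axis warning.
    """
    frame = np.asarray(max_open_frame_roi, dtype=float)
    x0, y0 = g0_roi
    half_length = float(np.hypot(*frame.shape))
    angles = np.arange(angle_range[0], angle_range[1] + angle_step / 2, angle_step)
    costs = np.full(angles.size, np.inf)
    for i, ang in enumerate(angles):
        samples = _line_samples(frame, x0, y0, ang, half_length)
        if samples.size:
            costs[i] = samples.mean()
    cmin = costs.min()
    near = np.nonzero(costs <= cmin + 1e-9)[0]
    best = near[np.argmin(np.abs(angles[near] - 90.0))]
    degenerate = bool(np.isclose(costs.max(), cmin))
    if degenerate:
        warnings.warn("uniform ROI: degenerate axis, returning vertical",
                      stacklevel=2)
        return GlottalAxis(g0=(x0, y0), alpha=90.0, degenerate=True)
    return GlottalAxis(g0=(x0, y0), alpha=float(angles[best]))


def axis_profile(frame_roi: np.ndarray, axis: GlottalAxis,
                 step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile along the axis, clipped to the ROI.

    Returns (samples, positions) where positions are (x, y) ROI-local
    coordinates of each sample.
    """
    frame = np.asarray(frame_roi, dtype=float)
    x0, y0 = axis.g0
    d = axis.direction
    half = float(np.hypot(*frame.shape))
    s = np.arange(-half, half + step / 2, step)
    xs, ys = x0 + s * d[0], y0 + s * d[1]
    inside = (xs >= 0) & (xs <= frame.shape[1] - 1) & \
             (ys >= 0) & (ys <= frame.shape[0] - 1)
    xs, ys = xs[inside], ys[inside]
    vals = ndimage.map_coordinates(frame, [ys, xs], order=1)
    return vals, np.column_stack([xs, ys])


def axis_endpoints(profile: np.ndarray, positions: np.ndarray | None = None,
                   border_margin: int = 2) -> tuple[int, int]:
    """Outermost abrupt-transition sample indices (posterior, anterior).

    Candidates are samples where |discrete gradient| exceeds half its
    maximum; those within ``border_margin`` samples of the profile ends (the
    ROI border) are excluded, and interior peaks between the outermost two
    are ignored.  Raises :class:`EndpointDetectionError` with fewer than two
    candidates (caller falls back to mask extremes).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 9:
        raise ValueError("profile needs at least 9 samples")
    grad = np.abs(np.gradient(profile))
    gmax = grad.max()
    if gmax <= 0:
        raise EndpointDetectionError("flat profile: no intensity transitions")
    cand = np.nonzero(grad > gmax / 2)[0]
    cand = cand[(cand >= border_margin) & (cand < profile.size - border_margin)]
    if cand.size < 2:
        raise EndpointDetectionError("fewer than two abrupt-change candidates")
    # candidates must form at least two separate transitions: a single run
    # (one sharp edge, or a uniform-gradient ramp) has no P/A pair
    if not np.any(np.diff(cand) > 3):
        raise EndpointDetectionError("all abrupt-change candidates lie on one transition")
    return int(cand[0]), int(cand[-1])


def locate_endpoints(frame_roi: np.ndarray, axis: GlottalAxis) -> GlottalAxis:
    """Fill p_point/a_point of an axis from its ROI intensity profile.

    The posterior point is the endpoint closer to the top of the frame
    (smaller y), matching the convention that P sits at g = 1%.
    """
    # half-pixel sampling so a sharp transition spans several samples and
    # survives the ROI-border exclusion even in a tight (kappa = 2) window
    vals, pos = axis_profile(frame_roi, axis, step=0.5)
    i0, i1 = axis_endpoints(vals)
    p, a = pos[i0], pos[i1]
    if p[1] > a[1]:
        p, a = a, p
    axis.p_point = (float(p[0]), float(p[1]))
    axis.a_point = (float(a[0]), float(a[1]))
    return axis


def synthesize_vkg(cube: VideoCube, roi_trace: list[ROIWindow],
                   axis: GlottalAxis, g_positions: list[float],
                   line_length_factor: float = 1.5) -> list[Kymogram]:
    """Motion- and rotation-compensated kymograms at the requested stations.

    ``axis`` must carry endpoints in *full-frame* coordinates.  Per frame,
    the scan segment is perpendicular to g at the station point, shifted by
    the active block's ROI-center offset relative to the first block.
    Samples outside the frame are edge-padded (map_coordinates nearest),
    with a single warning.
    """
    if axis.p_point is None or axis.a_point is None:
        raise ValueError("axis endpoints are required for VKG synthesis")
    if not all(1 <= g <= 100 for g in g_positions):
        raise ValueError("g positions must lie in [1, 100]")
    p = np.asarray(axis.p_point, dtype=float)
    a = np.asarray(axis.a_point, dtype=float)
    ref_win = roi_trace[0]
    ref_center = np.asarray(ref_win.center)
    width = ref_win.width
    half = line_length_factor * width / 2.0
    perp = np.radians(axis.alpha - 90.0)     # perpendicular to the axis
    step = 0.5
    s = np.arange(-half, half + step / 2, step)
    dx, dy = np.cos(perp), np.sin(perp)
    n_rows, n_cols = cube.frame_shape

    # per-frame active window
    win_of_frame: list[ROIWindow] = []
    for t in range(cube.n_frames):
        active = roi_trace[-1]
        for w in roi_trace:
            if w.t_start <= t <= w.t_end:
                active = w
                break
        win_of_frame.append(active)

    out: list[Kymogram] = []
    warned = False
    for g in g_positions:
        frac = (g - 1.0) / 99.0             # g=1% -> P, g=100% -> A
        station = p + frac * (a - p)
        img = np.zeros((s.size, cube.n_frames))
        ends = np.zeros((cube.n_frames, 4))
        for t in range(cube.n_frames):
            offset = np.asarray(win_of_frame[t].center) - ref_center
            cx, cy = station + offset
            xs = cx + s * dx
            ys = cy + s * dy
            if not warned and (xs.min() < 0 or ys.min() < 0 or
                               xs.max() > n_cols - 1 or ys.max() > n_rows - 1):
                warnings.warn("VKG scan segment exits the frame; edge-padded",
                              stacklevel=2)
                warned = True
            img[:, t] = ndimage.map_coordinates(
                cube.frame(t).astype(float), [ys, xs], order=1, mode="nearest")
            ends[t] = (xs[0], ys[0], xs[-1], ys[-1])
        out.append(Kymogram(image=img, g_position=float(g), scan_endpoints=ends))
    return out
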