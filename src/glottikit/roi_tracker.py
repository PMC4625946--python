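"""Adaptive region-of-interest localization from temporal intensity variation.

The glottal gap is the structure with the largest temporal intensity change,
so it can be located without segmenting anything: per block of N frames,

* ``S_c(x, t)`` — mean intensity of each column x in frame t,
* ``AIV_c(x)`` — time average of S_c over the block,
* ``TIV_c(x)`` — mean absolute deviation of S_c from AIV_c,

and analogously per row inside the column window (columns first, because the
glottal main axis is quasi-vertical, > 30 degrees from horizontal).  Each TIV
profile is fitted with a Gaussian ``a * exp(-(x - mu)^2 / (2 sigma^2))`` by
non-linear least squares; the ROI cut-offs are ``mu +/- kappa * sigma``
(kappa defaults to 2, the [2, 3] trade-off range).

Recomputing the window every N frames compensates slow endoscope/patient
drift (~15 Hz), which is far below the phonation rate (70–400 Hz): N must
cover at least one glottal cycle ``gc_o = round(frame_rate / f0)`` but stay
well below one endoscope cycle ``mc_e = round(frame_rate / f_e)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .video_io import VideoCube

__all__ = [
    "VariationProfile",
    "GaussianFit",
    "ROIWindow",
    "MotionParams",
    "NoSignalError",
    "column_variation",
    "row_variation",
    "fit_gaussian",
    "roi_from_fits",
    "plan_block_length",
    "estimate_cycle_frames",
    "track_roi",
    "min_intensity_frame",
    "glottal_center",
]


class NoSignalError(RuntimeError):
    """TIV profile carries no temporal variation (static block)."""


@dataclass
class VariationProfile:
    """TIV profile along one axis, with its per-frame source matrix."""

    s_matrix: np.ndarray       # (N, positions) mean intensity per frame
    aiv: np.ndarray            # time-averaged profile
    tiv: np.ndarray            # mean absolute deviation profile
    axis: str                  # "columns" or "rows"
    offset: int = 0            # first position in full-frame coordinates


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    rmse: float


@dataclass
class ROIWindow:
    """Rectangular window [x_cl, x_cr] x [y_cu, y_cd], inclusive bounds."""

    x_cl: int
    x_cr: int
    y_cu: int
    y_cd: int
    kappa_x: float = 2.0
    kappa_y: float = 2.0
    t_start: int = 0
    t_end: int = 0
    fits: tuple = ()

    @property
    def width(self) -> int:
        return self.x_cr - self.x_cl + 1

    @property
    def height(self) -> int:
        return self.y_cd - self.y_cu + 1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_cl + self.x_cr) / 2.0, (self.y_cu + self.y_cd) / 2.0)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y_cu:self.y_cd + 1, self.x_cl:self.x_cr + 1]


@dataclass
class MotionParams:
    """Block-length plan tying phonation and endoscope-motion cycles."""

    f0: float
    fe: float
    frame_rate: float
    gc_o: int = field(init=False)
    mc_e: int = field(init=False)
    n_frames: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fe < self.f0 <= self.frame_rate / 2):
            raise ValueError(
                f"need 0 < fe < f0 <= frame_rate/2, got fe={self.fe}, "
                f"f0={self.f0}, frame_rate={self.frame_rate}")
        self.gc_o = max(1, round(self.frame_rate / self.f0))
        self.mc_e = round(self.frame_rate / self.fe)
        if self.n_frames == 0:
            self.n_frames = min(3 * self.gc_o, self.mc_e)
        self.n_frames = int(np.clip(self.n_frames, self.gc_o, self.mc_e))


def column_variation(cube: VideoCube, t_start: int = 0,
                     n_frames: int | None = None) -> VariationProfile:
    """TIV over columns for the block [t_start, t_start + n_frames)."""
    if n_frames is None:
        n_frames = cube.n_frames - t_start
    if n_frames < 1 or t_start < 0 or t_start + n_frames > cube.n_frames:
        raise IndexError("block exceeds cube length")
    block = cube.intensities[t_start:t_start + n_frames].astype(float)
    s = block.mean(axis=1)                       # (N, m): mean over rows
    aiv = s.mean(axis=0)
    tiv = np.abs(s - aiv).mean(axis=0)
    return VariationProfile(s, aiv, tiv, axis="columns")


def row_variation(cube: VideoCube, x_cl: int, x_cr: int, t_start: int = 0,
                  n_frames: int | None = None) -> VariationProfile:
    """TIV over rows, restricted to columns [x_cl, x_cr] (inclusive)."""
    if n_frames is None:
        n_frames = cube.n_frames - t_start
    if n_frames < 1 or t_start < 0 or t_start + n_frames > cube.n_frames:
        raise IndexError("block exceeds cube length")
    m = cube.frame_shape[1]
    if not (0 <= x_cl < x_cr < m):
        raise IndexError(f"invalid column bounds [{x_cl}, {x_cr}] for m={m}")
    block = cube.intensities[t_start:t_start + n_frames, :, x_cl:x_cr + 1].astype(float)
    s = block.mean(axis=2)                       # (N, n): mean over window columns
    aiv = s.mean(axis=0)
    tiv = np.abs(s - aiv).mean(axis=0)
    return VariationProfile(s, aiv, tiv, axis="rows")


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian(profile: VariationProfile) -> GaussianFit:
    """Least-squares Gaussian fit of a TIV profile.

    Initialised at the profile maximum with sigma from the full width at
    half maximum; raises :class:`NoSignalError` on an all-zero profile
    (caller keeps the previous ROI or the full frame).
    """
    tiv = np.asarray(profile.tiv, dtype=float)
    if tiv.size < 5:
        raise ValueError("profile needs at least 5 samples")
    peak = float(tiv.max())
    if peak <= 0:
        raise NoSignalError("TIV profile is identically zero")
    x = np.arange(tiv.size, dtype=float)
    mu0 = float(np.argmax(tiv))
    above = np.nonzero(tiv >= peak / 2)[0]
    fwhm = max(above[-1] - above[0], 1)
    sigma0 = max(fwhm / 2.355, 1.0)
    try:
        popt, _ = curve_fit(
            _gauss, x, tiv, p0=[peak, mu0, sigma0],
            bounds=([0, 0, 1.0], [np.inf, tiv.size - 1, float(tiv.size)]),
            maxfev=10000)
    except RuntimeError:
        popt = [peak, mu0, sigma0]
    a, mu, sigma = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_gauss(x, a, mu, sigma) - tiv) ** 2)))
    return GaussianFit(mu=mu + profile.offset, sigma=sigma, amplitude=a, rmse=rmse)


def roi_from_fits(fit_x: GaussianFit, fit_y: GaussianFit,
                  kappa_x: float = 2.0, kappa_y: float = 2.0,
                  frame_shape: tuple[int, int] = (256, 256)) -> ROIWindow:
    """Cut-offs mu +/- kappa*sigma, rounded outward and clipped to the frame.

    A degenerate window (< 4 px on a side) is expanded symmetrically to the
    minimum size with a warning.
    """
    if not (1 <= kappa_x <= 5 and 1 <= kappa_y <= 5):
        raise ValueError("kappa must lie in [1, 5]")
    n, m = frame_shape
    x_cl = int(np.clip(np.floor(fit_x.mu - kappa_x * fit_x.sigma), 0, m - 1))
    x_cr = int(np.clip(np.ceil(fit_x.mu + kappa_x * fit_x.sigma), 0, m - 1))
    y_cu = int(np.clip(np.floor(fit_y.mu - kappa_y * fit_y.sigma), 0, n - 1))
    y_cd = int(np.clip(np.ceil(fit_y.mu + kappa_y * fit_y.sigma), 0, n - 1))
    x_cl, x_cr = _ensure_min_extent(x_cl, x_cr, m)
    y_cu, y_cd = _ensure_min_extent(y_cu, y_cd, n)
    return ROIWindow(x_cl, x_cr, y_cu, y_cd, kappa_x, kappa_y,
                     fits=(fit_x, fit_y))


def _ensure_min_extent(lo: int, hi: int, size: int, min_extent: int = 4) -> tuple[int, int]:
    if hi - lo + 1 >= min_extent:
        return lo, hi
    warnings.warn("degenerate ROI side expanded to minimum size", stacklevel=3)
    center = (lo + hi) // 2
    lo = max(0, center - min_extent // 2)
    hi = min(size - 1, lo + min_extent - 1)
    lo = max(0, hi - min_extent + 1)
    return lo, hi


def plan_block_length(f0: float, fe: float, frame_rate: float,
                      n_frames: int | None = None) -> MotionParams:
    """Choose the ROI-update block length N within [gc_o, mc_e].

    Default N = min(3 * gc_o, mc_e): at least one glottal cycle (a shorter
    block cannot see a full opening/closing excursion) and well below one
    endoscope-motion cycle, past which drift corrupts the TIV profiles.
    """
    return MotionParams(f0=f0, fe=fe, frame_rate=frame_rate,
                        n_frames=n_frames or 0)


def estimate_cycle_frames(cube: VideoCube, fe: float = 15.0) -> int:
    """Frames per glottal cycle from the frame-mean intensity autocorrelation.

    Used when f0 is not supplied: the dominant autocorrelation lag of the
    mean-intensity signal over the first endoscope cycle is the glottal
    period in frames.
    """
    mc_e = max(8, round(cube.frame_rate / fe))
    sig = cube.intensities[:min(mc_e, cube.n_frames)].mean(axis=(1, 2))
    sig = sig - sig.mean()
    if np.allclose(sig, 0):
        raise NoSignalError("static video: cannot estimate glottal cycle")
    ac = np.correlate(sig, sig, mode="full")[sig.size - 1:]
    ac /= ac[0]
    # first local maximum after the zero-lag peak
    lag = 1
    while lag < ac.size - 1 and ac[lag + 1] <= ac[lag]:
        lag += 1
    best = lag + int(np.argmax(ac[lag:]))
    return max(2, best)


def track_roi(cube: VideoCube, params: MotionParams,
              kappa_x: float = 2.0, kappa_y: float = 2.0) -> list[ROIWindow]:
    """One ROIWindow per consecutive block of N frames.

    Columns are fitted first (quasi-vertical axis), rows inside the column
    window.  A block with no temporal signal inherits the previous window;
    a no-signal first block falls back to the full frame.  The final partial
    block (< N frames) reuses the last full-block window.
    """
    n, m = cube.frame_shape
    # the block length can never exceed the recording itself
    N = min(params.n_frames, cube.n_frames)
    windows: list[ROIWindow] = []
    prev: ROIWindow | None = None
    n_blocks = cube.n_frames // N
    for b in range(n_blocks):
        t0 = b * N
        t1 = t0 + N - 1 if b < n_blocks - 1 else cube.n_frames - 1
        try:
            prof_c = column_variation(cube, t0, N)
            fit_x = fit_gaussian(prof_c)
            x_cl = int(np.clip(np.floor(fit_x.mu - kappa_x * fit_x.sigma), 0, m - 1))
            x_cr = int(np.clip(np.ceil(fit_x.mu + kappa_x * fit_x.sigma), 0, m - 1))
            x_cl, x_cr = _ensure_min_extent(x_cl, x_cr, m)
            prof_r = row_variation(cube, x_cl, x_cr, t0, N)
            fit_y = fit_gaussian(prof_r)
            win = roi_from_fits(fit_x, fit_y, kappa_x, kappa_y, (n, m))
        except NoSignalError:
            if prev is not None:
                win = ROIWindow(prev.x_cl, prev.x_cr, prev.y_cu, prev.y_cd,
                                kappa_x, kappa_y, fits=prev.fits)
            else:
                win = ROIWindow(0, m - 1, 0, n - 1, kappa_x, kappa_y)
        win.t_start, win.t_end = t0, t1
        windows.append(win)
        prev = win
    return windows


def min_intensity_frame(cube: VideoCube, window: ROIWindow,
                        t_start: int | None = None,
                        t_end: int | None = None) -> int:
    """Frame of maximal glottal opening: argmin of the ROI intensity sum.

    The widest-open glottis contributes the most dark pixels, so the frame
    with the smallest summed intensity inside the window is the max-opening
    frame.  Ties break to the earliest frame.
    """
    t0 = window.t_start if t_start is None else t_start
    t1 = window.t_end if t_end is None else t_end
    block = cube.intensities[t0:t1 + 1,
                             window.y_cu:window.y_cd + 1,
                             window.x_cl:window.x_cr + 1]
    sums = block.reshape(block.shape[0], -1).astype(np.int64).sum(axis=1)
    return t0 + int(np.argmin(sums))


def glottal_center(fit_x: GaussianFit, fit_y: GaussianFit) -> tuple[float, float]:
    """Approximate glottal center G0 = (mu_x, mu_y), full-frame coordinates."""
    return (fit_x.mu, fit_y.mu)
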