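"""End-to-end orchestration: enhance -> ROI -> segment -> refine -> track.

Per block of N frames the ROI is re-localised from the temporal intensity
variation; the block's max-opening frame fixes the Otsu background level and
the glottis template.  Each frame is then segmented inside the ROI:
thresholded-gradient watershed, JND merging, template-correlation merging
(an empty result means the glottis is closed in that frame) and localized
active-contour refinement, after which the mask is re-embedded in full-frame
coordinates.  A failure in any single frame yields an empty mask and a
logged warning — long recordings never abort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import axis_kymograph, roi_tracker
from .contour_refiner import ContourParams, refine_mask
from .enhance import EnhanceParams, enhance_cube
from .region_segmenter import (JNDParams, merge_by_jnd, thresholded_gradient,
                               watershed_regions)
from .roi_tracker import (MotionParams, ROIWindow, estimate_cycle_frames,
                          min_intensity_frame, plan_block_length, track_roi)
from .template_matcher import (DegenerateROIError, build_template,
                               correlation_merge, similitude)
from .video_io import GlottisTrack, VideoCube

try:
    from skimage.filters import threshold_otsu
except ImportError:  # pragma: no cover
    threshold_otsu = None

logger = logging.getLogger("glottikit")

__all__ = ["RunConfig", "segment_video", "run_vkg"]


@dataclass
class RunConfig:
    """All tunable parameters of a run, with their standard defaults."""

    enhance_beta: float = 2.0          # row-divisor contrast factor
    enhance_beta_scale: str = "divisor"  # or "paper_results" (x100)
    enhance_zeta: float = 1.8
    roi_kappa_x: float = 2.0
    roi_kappa_y: float = 2.0
    roi_n_frames: int | None = None    # override block length N
    roi_f0_hz: float | None = None     # phonation frequency if known
    roi_fe_hz: float = 15.0            # endoscope drift frequency
    segment_thr: float = 265.0
    segment_d0: float = 17.0
    segment_gamma: float = 3.0 / 128.0
    segment_gradient_floor: float = 10.0
    template_match_threshold: float = 0.45
    contour_radius: int = 5
    contour_iterations: int = 100
    contour_smoothing: float = 0.2
    vkg_g_positions: tuple[float, ...] = (50.0,)
    vkg_line_length_factor: float = 1.5
    seed: int = 0

    @property
    def enhance_params(self) -> EnhanceParams:
        if self.enhance_beta_scale == "paper_results":
            return EnhanceParams.from_results_scale(self.enhance_beta, self.enhance_zeta)
        return EnhanceParams(self.enhance_beta, self.enhance_zeta)

    @property
    def jnd_params(self) -> JNDParams:
        return JNDParams(self.segment_d0, self.segment_gamma,
                         self.segment_thr, self.segment_gradient_floor)

    @property
    def contour_params(self) -> ContourParams:
        return ContourParams(self.contour_radius, self.contour_iterations,
                             self.contour_smoothing)

    def to_manifest(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key, value in flat.items():
            name = key.replace(".", "_")
            if name not in {f.name for f in dataclasses.fields(cls)}:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[name] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)


def _plan_blocks(cube: VideoCube, config: RunConfig) -> MotionParams:
    f0 = config.roi_f0_hz
    if f0 is None:
        gc = estimate_cycle_frames(cube, config.roi_fe_hz)
        f0 = cube.frame_rate / gc
    return plan_block_length(f0, config.roi_fe_hz, cube.frame_rate,
                             n_frames=config.roi_n_frames)


def segment_video(cube: VideoCube, config: RunConfig = RunConfig()) -> GlottisTrack:
    """Segment every frame of a video; returns masks in full-frame coords."""
    enhanced = enhance_cube(cube, config.enhance_params)
    params = _plan_blocks(enhanced, config)
    windows = track_roi(enhanced, params, config.roi_kappa_x, config.roi_kappa_y)
    n, m = cube.frame_shape
    masks = np.zeros((cube.n_frames, n, m), dtype=bool)
    roi_trace: list[ROIWindow] = [None] * cube.n_frames
    jnd_params = config.jnd_params
    contour_params = config.contour_params

    for win in windows:
        t_ref = min_intensity_frame(enhanced, win)
        ref_roi = win.crop(enhanced.frame(t_ref)).astype(float)
        otsu_level = float(threshold_otsu(ref_roi)) if np.ptp(ref_roi) > 0 else 255.0
        try:
            template = build_template(win)
        except DegenerateROIError:
            logger.warning("block %d-%d: ROI too small for a template; "
                           "frames left empty", win.t_start, win.t_end)
            for t in range(win.t_start, win.t_end + 1):
                roi_trace[t] = win
            continue
        for t in range(win.t_start, win.t_end + 1):
            roi_trace[t] = win
            try:
                frame_roi = win.crop(enhanced.frame(t)).astype(float)
                grad = thresholded_gradient(frame_roi, config.segment_gradient_floor)
                regions = watershed_regions(grad, frame_roi)
                merged = merge_by_jnd(regions, jnd_params, background_floor=otsu_level)
                sim = similitude(frame_roi, template, config.template_match_threshold)
                candidate = correlation_merge(merged, sim, template)
                refined = refine_mask(frame_roi, candidate, contour_params)
                masks[t, win.y_cu:win.y_cd + 1, win.x_cl:win.x_cr + 1] = refined
            except Exception as exc:  # frame-level fault isolation
                logger.warning("frame %d failed (%s); empty mask", t, exc)
    return GlottisTrack(masks, roi_trace=roi_trace)


def estimate_axis(cube: VideoCube, track: GlottisTrack,
                  config: RunConfig = RunConfig()
                  ) -> tuple[axis_kymograph.GlottalAxis, list[ROIWindow], VideoCube]:
    """Glottal main axis from the globally max-opening frame.

    Returns the axis (endpoints in full-frame coordinates), the ordered
    block windows, and the enhanced cube used for fitting.
    """
    windows = [w for w in track.roi_trace if w is not None]
    if not windows:
        raise ValueError("track carries no ROI windows")
    enhanced = enhance_cube(cube, config.enhance_params)
    # globally max-opening frame: minimum ROI intensity over all blocks
    blocks = sorted({(w.t_start, w.t_end, id(w)): w for w in windows}.values(),
                    key=lambda w: w.t_start)
    best_t, best_sum, best_win = 0, np.inf, blocks[0]
    for w in blocks:
        t = min_intensity_frame(enhanced, w)
        s = float(w.crop(enhanced.frame(t)).sum())
        if s < best_sum:
            best_t, best_sum, best_win = t, s, w
    ref_roi = best_win.crop(enhanced.frame(best_t)).astype(float)
    fit_x, fit_y = (best_win.fits if best_win.fits
                    else (None, None))
    if fit_x is not None:
        g0_full = roi_tracker.glottal_center(fit_x, fit_y)
    else:
        g0_full = best_win.center
    g0_roi = (g0_full[0] - best_win.x_cl, g0_full[1] - best_win.y_cu)
    g0_roi = (float(np.clip(g0_roi[0], 0, ref_roi.shape[1] - 1)),
              float(np.clip(g0_roi[1], 0, ref_roi.shape[0] - 1)))
    axis = axis_kymograph.fit_main_axis(ref_roi, g0_roi)
    try:
        axis = axis_kymograph.locate_endpoints(ref_roi, axis)
    except axis_kymograph.EndpointDetectionError:
        logger.warning("axis endpoints not found; falling back to mask extremes")
        axis = _endpoints_from_mask(track, best_t, best_win, axis)
    # lift endpoints and center to full-frame coordinates
    axis.g0 = g0_full
    # lift to full-frame coordinates, then re-anchor at the first block's ROI
    # center: the scan offsets in synthesize_vkg are relative to that anchor,
    # while the endpoints were measured at the best block's drift position
    ax0, ay0 = np.asarray(blocks[0].center) - np.asarray(best_win.center)
    axis.p_point = (axis.p_point[0] + best_win.x_cl + ax0,
                    axis.p_point[1] + best_win.y_cu + ay0)
    axis.a_point = (axis.a_point[0] + best_win.x_cl + ax0,
                    axis.a_point[1] + best_win.y_cu + ay0)
    return axis, blocks, enhanced


def run_vkg(cube: VideoCube, track: GlottisTrack,
            config: RunConfig = RunConfig()) -> list[axis_kymograph.Kymogram]:
    """Axis from the globally max-opening frame, then compensated kymograms."""
    axis, blocks, enhanced = estimate_axis(cube, track, config)
    return axis_kymograph.synthesize_vkg(
        enhanced, blocks, axis, list(config.vkg_g_positions),
        config.vkg_line_length_factor)


def _endpoints_from_mask(track: GlottisTrack, t: int, win: ROIWindow,
                         axis: axis_kymograph.GlottalAxis) -> axis_kymograph.GlottalAxis:
    mask = track.masks[t, win.y_cu:win.y_cd + 1, win.x_cl:win.x_cr + 1]
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("no mask pixels to derive endpoints from")
    d = axis.direction
    proj = xs * d[0] + ys * d[1]
    i0, i1 = int(np.argmin(proj)), int(np.argmax(proj))
    p = (float(xs[i0]), float(ys[i0]))
    a = (float(xs[i1]), float(ys[i1]))
    if p[1] > a[1]:
        p, a = a, p
    axis.p_point, axis.a_point = p, a
    return axis
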