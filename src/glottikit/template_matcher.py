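"""Second merging stage: glottis-template correlation.

A canonical glottis-shaped stencil — a vertically elongated lens (two
circular arcs meeting at top and bottom vertices), black interior on a white
surround — is resized to the active ROI (12 x 42 at the 40 x 148 reference
ROI, i.e. scale factors 0.30 x 0.284) and slid over the enhanced ROI frame
with the zero-normalised cross-correlation coefficient (values in [-1, 1],
invariant to affine intensity changes).  When the best score falls below the
match threshold (default 0.45) the glottis is declared fully closed.
Otherwise, the union of template footprints at all above-threshold
placements forms the correlation zone, and every non-background region of
the first merging stage that overlaps the zone is kept; the rest is
discarded.  Keeping *all* overlapping regions is what makes a glottis split
into two dark blobs survive this stage intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.transform import resize

from .region_segmenter import BACKGROUND_LABEL, RegionLabelMap
from .roi_tracker import ROIWindow

__all__ = [
    "GlottisTemplate",
    "SimilitudeMatrix",
    "DegenerateROIError",
    "render_lens_stencil",
    "build_template",
    "similitude",
    "correlation_merge",
]

#: template size over ROI size, frozen from the 12/40 x 42/148 reference pair
WIDTH_FACTOR = 0.30
HEIGHT_FACTOR = 0.284
MIN_TEMPLATE = (7, 3)  # rows, cols

BASE_ROI = (148, 40)        # rows, cols of the reference ROI
BASE_TEMPLATE = (42, 12)    # rows, cols of the reference template


class DegenerateROIError(ValueError):
    """ROI too small to carry a meaningful template."""


@dataclass
class GlottisTemplate:
    pixels: np.ndarray          # grayscale, black lens on white, (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def footprint(self) -> np.ndarray:
        """Boolean lens interior (the dark part of the stencil)."""
        return self.pixels < 128


@dataclass
class SimilitudeMatrix:
    values: np.ndarray          # NCC per valid top-left placement
    template_shape: tuple[int, int]
    match_threshold: float = 0.45

    @property
    def best(self) -> float:
        return float(self.values.max()) if self.values.size else -1.0


def render_lens_stencil(height: int, width: int) -> np.ndarray:
    """Render the canonical lens (vesica-piscis-like) stencil.

    Two circular arcs meet at the top and bottom vertices; the interior is 0,
    the surround 255, with a 1-px white margin on every side.  Values between
    are anti-aliased so resized correlation stays smooth.
    """
    if height < MIN_TEMPLATE[0] or width < MIN_TEMPLATE[1]:
        raise ValueError(f"stencil below minimum size {MIN_TEMPLATE}")
    h2 = (height - 2) / 2.0          # half-height inside the margin
    a = (width - 2) / 2.0            # maximal half-width inside the margin
    radius = (a * a + h2 * h2) / (2.0 * a)
    yy, xx = np.mgrid[0:height, 0:width]
    y = yy - (height - 1) / 2.0
    x = np.abs(xx - (width - 1) / 2.0)
    half_width = np.sqrt(np.maximum(radius ** 2 - np.minimum(np.abs(y), h2) ** 2, 0.0)) \
        - (radius - a)
    half_width[np.abs(y) > h2] = 0.0
    # soft 1-px anti-aliased edge
    edge = np.clip(half_width - x + 0.5, 0.0, 1.0)
    out = np.clip(np.floor(255.0 * (1.0 - edge) + 0.5), 0, 255).astype(np.uint8)
    out[0, :] = out[-1, :] = 255      # enforce the 1-px white margin
    out[:, 0] = out[:, -1] = 255
    return out


def build_template(roi: ROIWindow | tuple[int, int]) -> GlottisTemplate:
    """Resize the canonical stencil to the active ROI.

    Size is (round(0.284 * roi_height), round(0.30 * roi_width)), clamped to
    at most half the ROI on each side; if the scaled size falls below the
    3 x 7 (width x height) minimum the ROI is too small and a
    :class:`DegenerateROIError` is raised.
    """
    if isinstance(roi, ROIWindow):
        rh, rw = roi.height, roi.width
    else:
        rh, rw = roi
    th = round(HEIGHT_FACTOR * rh)
    tw = round(WIDTH_FACTOR * rw)
    if th < MIN_TEMPLATE[0] or tw < MIN_TEMPLATE[1]:
        raise DegenerateROIError(
            f"ROI {rw}x{rh} yields template {tw}x{th}, below minimum 3x7")
    th = min(th, rh // 2)
    tw = min(tw, rw // 2)
    return GlottisTemplate(render_lens_stencil(th, tw))


def similitude(frame_roi: np.ndarray, template: GlottisTemplate,
               match_threshold: float = 0.45) -> SimilitudeMatrix:
    """Zero-normalised cross-correlation of the stencil at every placement.

    Placements where the image patch has zero variance are assigned 0
    (a constant patch is uncorrelated with anything).
    """
    frame_roi = np.asarray(frame_roi, dtype=float)
    th, tw = template.shape
    if th > frame_roi.shape[0] or tw > frame_roi.shape[1]:
        raise ValueError("template larger than the ROI frame")
    ncc = match_template(frame_roi, template.pixels.astype(float), pad_input=False)
    ncc = np.nan_to_num(ncc, nan=0.0, posinf=0.0, neginf=0.0)
    ncc = np.clip(ncc, -1.0, 1.0)
    # zero-variance patches: match_template can emit spurious huge values
    # before clipping; detect them explicitly via a sliding variance check
    sq = _window_sums(frame_roi ** 2, (th, tw))
    sm = _window_sums(frame_roi, (th, tw))
    var = sq - sm ** 2 / (th * tw)
    ncc[var <= 1e-9 * th * tw] = 0.0
    return SimilitudeMatrix(ncc, (th, tw), match_threshold)


def _window_sums(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Sliding-window sums over all valid placements via an integral image."""
    th, tw = shape
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    ii[1:, 1:] = img.cumsum(0).cumsum(1)
    return (ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw])


def correlation_merge(regions: RegionLabelMap, sim: SimilitudeMatrix,
                      template: GlottisTemplate) -> np.ndarray:
    """Intersect first-merge regions with the high-correlation zone.

    Returns a boolean candidate mask on the ROI frame.  If no placement
    reaches the match threshold the glottis is fully closed and the mask is
    empty.  Otherwise the correlation zone is the union of template
    footprints at every above-threshold placement, and the mask is the union
    of all non-background regions with any pixel overlap with that zone.
    """
    shape = regions.labels.shape
    if sim.best < sim.match_threshold:
        return np.zeros(shape, dtype=bool)
    th, tw = template.shape
    zone = np.zeros(shape, dtype=bool)
    foot = template.footprint
    ys, xs = np.nonzero(sim.values >= sim.match_threshold)
    for y, x in zip(ys, xs):
        zone[y:y + th, x:x + tw] |= foot
    keep = np.unique(regions.labels[zone & (regions.labels != BACKGROUND_LABEL)])
    mask = np.isin(regions.labels, keep[keep != BACKGROUND_LABEL])
    return mask & (regions.labels != BACKGROUND_LABEL)
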