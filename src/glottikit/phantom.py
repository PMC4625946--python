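"""Seeded synthetic high-speed-videoendoscopy generator with ground truth.

Real laryngeal recordings are not required anywhere in this package: the
phantom renders the phenomena that make glottis tracking hard —

* a quasi-vertical dark glottal gap opening and closing at the phonation
  rate f0 (70–400 Hz regime; frames acquired at thousands of fps),
* a posterior chink (permanent incomplete closure),
* a glottis split into two dark regions by a bright tissue bridge,
* anterior occlusion by the arytenoid cartilages,
* black corner artifacts from the endoscope tube (camera-fixed),
* random light flashes (whole-frame multiplicative gain),
* slow sinusoidal camera drift (~15 Hz), far below the phonation rate,

over a textured tissue background whose low-frequency shading plus static
grain makes an unseeded watershed over-segment realistically.  Every run is
driven by one seeded generator, so identical specs give bitwise-identical
videos, and the ground truth (masks, glottal area waveform, axis, drift
trace, max-opening frames) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .video_io import VideoCube

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "load_preset", "PRESETS"]

PRESETS = ("clean", "chink", "split", "occluded", "drift", "full")

TISSUE_LEVEL = 170.0
GLOTTIS_LEVEL = 20.0
OCCLUDER_LEVEL = 150.0
CORNER_LEVEL = 5.0


@dataclass
class PhantomSpec:
    """Scene and acquisition parameters of one synthetic recording.

    Geometry is in scene coordinates (x = column, y = row); the glottal
    midline runs through ``glottis_center`` at ``glottis_angle`` degrees
    from the x-axis, spanning ``glottis_length`` pixels.
    """

    f0: float = 120.0                 # phonation frequency, Hz
    frame_rate: float = 4000.0        # acquisition rate, fps
    n_frames: int = 200
    frame_shape: tuple[int, int] = (256, 256)
    glottis_center: tuple[float, float] = (128.0, 128.0)   # (x, y)
    glottis_angle: float = 90.0       # degrees from x-axis (90 = vertical)
    glottis_length: float = 90.0
    max_half_width: float = 9.0
    closed_fraction: float = 0.3      # fraction of each cycle fully closed
    chink: float = 0.0                # posterior minimum half-width, px
    split: bool = False               # bright bridge across the gap
    split_pos: float = 0.5            # bridge station along the axis (0..1)
    occlusion: float = 0.0            # anterior cover fraction (0..1)
    drift_freq: float = 15.0          # endoscope drift, Hz
    drift_amp: float = 0.0            # drift amplitude, px
    flash_prob: float = 0.0           # per-frame flash probability
    flash_gain: float = 1.5
    corner_artifacts: bool = True
    noise_sigma: float = 2.0          # per-frame additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.frame_rate / 2:
            raise ValueError("need 0 < f0 < frame_rate/2")
        if self.drift_freq >= self.f0:
            raise ValueError("drift frequency must be below f0")
        if not 0 <= self.closed_fraction < 1:
            raise ValueError("closed_fraction must lie in [0, 1)")
        n, m = self.frame_shape
        cx, cy = self.glottis_center
        half = self.glottis_length / 2 + self.max_half_width + self.drift_amp
        if not (half <= cx <= m - half and half <= cy <= n - half):
            raise ValueError("glottis geometry (incl. drift) exceeds the frame")


@dataclass
class PhantomTruth:
    masks: np.ndarray                 # (T, rows, cols) bool
    areas: np.ndarray                 # true glottal area waveform
    axis_angle: float
    axis_endpoints: tuple[tuple[float, float], tuple[float, float]]  # P, A at zero drift
    drift_trace: np.ndarray           # (T, 2): (dx, dy) per frame
    max_open_frames: np.ndarray       # per-cycle frame index of maximal opening
    flash_frames: np.ndarray = field(default_factory=lambda: np.array([], int))


def _oscillation(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Clipped-sinusoid opening factor in [0, 1]; zero during the closed phase.

    The clip level c = -cos(pi * closed_fraction) makes the open part of the
    cycle occupy exactly (1 - closed_fraction) of the period.
    """
    c = -np.cos(np.pi * spec.closed_fraction)
    raw = np.sin(2 * np.pi * spec.f0 * t / spec.frame_rate)
    if c >= 1.0:
        return np.zeros_like(raw)
    return np.clip((raw - c) / (1.0 - c), 0.0, None)


def _chink_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Permanent posterior half-width, tapering to zero by mid-glottis."""
    if spec.chink <= 0:
        return np.zeros_like(s)
    return spec.chink * np.clip(1.0 - s / 0.35, 0.0, 1.0) * np.clip(s * 20.0, 0.0, 1.0)


def generate(spec: PhantomSpec) -> tuple[VideoCube, PhantomTruth]:
    """Render the phantom video and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.frame_shape
    yy, xx = np.mgrid[0:n, 0:m].astype(float)

    # static scene texture: low-frequency cosine mixture + frozen grain
    grain = rng.normal(0.0, 3.0, size=(n + 32, m + 32))
    grain = ndimage.gaussian_filter(grain, 1.0) * 3.0
    cos_params = [(rng.uniform(0.004, 0.02), rng.uniform(0.004, 0.02),
                   rng.uniform(0, 2 * np.pi), rng.uniform(6, 14))
                  for _ in range(4)]

    def texture(sx: np.ndarray, sy: np.ndarray) -> np.ndarray:
        out = np.full(sx.shape, TISSUE_LEVEL)
        for fx, fy, ph, amp in cos_params:
            out = out + amp * np.cos(2 * np.pi * (fx * sx + fy * sy) + ph)
        out = out + ndimage.map_coordinates(grain, [sy + 16, sx + 16],
                                            order=1, mode="nearest")
        return out

    ang = np.radians(spec.glottis_angle)
    axis_dir = np.array([np.cos(ang), np.sin(ang)])
    perp_dir = np.array([-np.sin(ang), np.cos(ang)])
    cx, cy = spec.glottis_center
    L = spec.glottis_length
    t_idx = np.arange(spec.n_frames)
    osc = _oscillation(spec, t_idx)
    drift = np.column_stack([
        spec.drift_amp * np.sin(2 * np.pi * spec.drift_freq * t_idx / spec.frame_rate),
        0.5 * spec.drift_amp * np.sin(2 * np.pi * spec.drift_freq * t_idx
                                      / spec.frame_rate + np.pi / 3),
    ])
    flashes = rng.random(spec.n_frames) < spec.flash_prob
    noise = rng.normal(0.0, spec.noise_sigma, size=(spec.n_frames, n, m)) \
        if spec.noise_sigma > 0 else None

    frames = np.empty((spec.n_frames, n, m), dtype=np.uint8)
    masks = np.zeros((spec.n_frames, n, m), dtype=bool)
    for t in range(spec.n_frames):
        dx, dy = drift[t]
        # scene coordinates of each pixel (camera shifted by the drift)
        sx = xx - dx
        sy = yy - dy
        img = texture(sx, sy)
        # axis-aligned coordinates of the glottal midline
        rel_x = sx - (cx - L / 2 * axis_dir[0])
        rel_y = sy - (cy - L / 2 * axis_dir[1])
        s = (rel_x * axis_dir[0] + rel_y * axis_dir[1]) / L    # 0 at P, 1 at A
        d = rel_x * perp_dir[0] + rel_y * perp_dir[1]
        shape = np.sin(np.pi * np.clip(s, 0.0, 1.0))
        w = np.maximum(_chink_profile(spec, s),
                       spec.max_half_width * osc[t] * shape)
        w[(s < 0) | (s > 1)] = 0.0
        if spec.split:
            bridge = np.abs(s - spec.split_pos) < (3.0 / L)
            w[bridge] = 0.0
        if spec.occlusion > 0:
            covered = s > 1.0 - spec.occlusion
            img = np.where(covered & (np.abs(d) < spec.max_half_width + 6),
                           OCCLUDER_LEVEL + 0.3 * (img - TISSUE_LEVEL), img)
            w[covered] = 0.0
        coverage = np.clip(w - np.abs(d) + 0.5, 0.0, 1.0)
        coverage[w < 0.5] = 0.0      # fully closed: no hairline residue
        img = img * (1 - coverage) + GLOTTIS_LEVEL * coverage
        masks[t] = coverage >= 0.5
        if spec.corner_artifacts:  # camera-fixed: not drifted
            corner_r = 0.22 * min(n, m)
            for ccy, ccx in ((0, 0), (0, m - 1), (n - 1, 0), (n - 1, m - 1)):
                cd = np.hypot(yy - ccy, xx - ccx)
                img = np.where(cd < corner_r, CORNER_LEVEL, img)
        if flashes[t]:
            img = img * spec.flash_gain
        if noise is not None:
            img = img + noise[t]
        frames[t] = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    period = spec.frame_rate / spec.f0
    n_cycles = int(np.floor(spec.n_frames / period))
    max_open = []
    for c in range(max(n_cycles, 1)):
        lo = int(round(c * period))
        hi = min(int(round((c + 1) * period)), spec.n_frames)
        if hi > lo:
            max_open.append(lo + int(np.argmax(osc[lo:hi])))
    p_end = (cx - L / 2 * axis_dir[0], cy - L / 2 * axis_dir[1])
    a_end = (cx + L / 2 * axis_dir[0], cy + L / 2 * axis_dir[1])
    truth = PhantomTruth(
        masks=masks,
        areas=masks.reshape(spec.n_frames, -1).sum(axis=1),
        axis_angle=spec.glottis_angle,
        axis_endpoints=(p_end, a_end),
        drift_trace=drift,
        max_open_frames=np.array(max_open, dtype=int),
        flash_frames=np.nonzero(flashes)[0],
    )
    return VideoCube(frames, frame_rate=spec.frame_rate), truth


def load_preset(name: str, **overrides) -> PhantomSpec:
    """Load one of the frozen YAML presets shipped with the package."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    text = resources.files("glottikit").joinpath(f"presets/{name}.yaml").read_text()
    params = yaml.safe_load(text)
    params.update(overrides)
    for key in ("frame_shape", "glottis_center"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    return PhantomSpec(**params)


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> None:
    """Write an image-sequence directory plus truth masks and a truth CSV."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth_masks").mkdir(parents=True, exist_ok=True)
    cube, truth = generate(spec)
    width = max(4, len(str(spec.n_frames - 1)))
    for t in range(spec.n_frames):
        iio.imwrite(out_dir / "frames" / f"frame_{t:0{width}d}.png", cube.frame(t))
        iio.imwrite(out_dir / "truth_masks" / f"mask_{t:0{width}d}.png",
                    truth.masks[t].astype(np.uint8) * 255)
    pd.DataFrame({
        "frame": np.arange(spec.n_frames),
        "area_px": truth.areas,
        "drift_dx": truth.drift_trace[:, 0],
        "drift_dy": truth.drift_trace[:, 1],
    }).to_csv(out_dir / "truth.csv", index=False)
    with open(out_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(spec), fh)
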