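"""Watershed over-segmentation and JND-based first region merging.

The gradient magnitude of the enhanced ROI frame is normalised to [0, 255]
and floored (levels below 10 set to 0, turning texture noise into basin
interiors), then flooded with an unseeded watershed.  The resulting
over-segmentation is repaired by agglomerating adjacent regions whose mean
grey levels the human visual system could not tell apart: the merging cost

    F_c = |mR1 - mR2| - min(JND(mR1), JND(mR2)) + 255

is compared against a fixed threshold Thr = 265, i.e. two regions merge when
their mean difference is within the just-noticeable difference plus
(Thr - 255) grey levels.  The JND visibility-threshold curve is

    JND(k) = D0 * (1 - sqrt(k / 127)) + 3      for k <= 127
    JND(k) = gamma * (k - 127) + 3             for k > 127

with D0 = 17, gamma = 3/128 (continuous at k = 127, value 3).  Regions
brighter than the Otsu level of the block's max-opening frame are collapsed
into a single background region up front, which removes most of the tissue
clutter before the perceptual merging runs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.segmentation import watershed

__all__ = [
    "JNDParams",
    "RegionLabelMap",
    "thresholded_gradient",
    "watershed_regions",
    "jnd",
    "merge_by_jnd",
]

BACKGROUND_LABEL = 0


@dataclass(frozen=True)
class JNDParams:
    d0: float = 17.0
    gamma: float = 3.0 / 128.0
    thr: float = 265.0
    gradient_floor: float = 10.0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.gamma <= 0:
            raise ValueError("d0 and gamma must be positive")
        if self.thr <= 255:
            raise ValueError("thr must exceed 255 (otherwise nothing merges)")
        if not (0 <= self.gradient_floor <= 255):
            raise ValueError("gradient_floor must lie in [0, 255]")


@dataclass
class RegionLabelMap:
    """Partition of a frame into labelled regions with per-region statistics."""

    labels: np.ndarray                      # int labels, >= 1 (0 = background after merge)
    means: dict[int, float]
    counts: dict[int, int]
    adjacency: set[tuple[int, int]] = field(default_factory=set)

    def region_ids(self) -> list[int]:
        return sorted(self.means)


def thresholded_gradient(frame: np.ndarray, floor: float = 10.0) -> np.ndarray:
    """Sobel gradient magnitude normalised to [0, 255], floored.

    Values below ``floor`` are zeroed so that texture-noise micro-edges do
    not seed watershed basins; a constant frame yields an all-zero gradient.
    """
    frame = np.asarray(frame, dtype=float)
    grad = sobel(frame)
    gmax = grad.max()
    if gmax > 0:
        grad = grad * (255.0 / gmax)
    grad[grad < floor] = 0.0
    return grad


def watershed_regions(gradient: np.ndarray,
                      intensity: np.ndarray | None = None) -> RegionLabelMap:
    """Catchment basins of the gradient surface (8-connected).

    Region means/counts are taken from ``intensity`` (the enhanced frame);
    if omitted, the gradient itself is used.
    """
    gradient = np.asarray(gradient, dtype=float)
    if gradient.min() < 0:
        raise ValueError("gradient must be non-negative")
    labels = watershed(gradient, connectivity=2)
    img = gradient if intensity is None else np.asarray(intensity, dtype=float)
    ids = np.unique(labels)
    sums = ndimage.sum_labels(img, labels, ids)
    counts = ndimage.sum_labels(np.ones_like(img), labels, ids)
    means = {int(i): float(s / c) for i, s, c in zip(ids, sums, counts)}
    cnts = {int(i): int(c) for i, c in zip(ids, counts)}
    return RegionLabelMap(labels, means, cnts, _adjacency_pairs(labels))


def _adjacency_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """Unordered pairs of 8-connected neighbouring labels."""
    pairs: set[tuple[int, int]] = set()
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dy, dx in shifts:
        a = labels[max(0, -dy):labels.shape[0] - max(0, dy),
                   max(0, -dx):labels.shape[1] - max(0, dx)]
        b = labels[max(0, dy):labels.shape[0] + min(0, dy) or None,
                   max(0, dx):labels.shape[1] + min(0, dx) or None]
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((min(int(u), int(v)), max(int(u), int(v))))
    return pairs


def jnd(k: float | np.ndarray, params: JNDParams = JNDParams()) -> float | np.ndarray:
    """Just-noticeable luminance difference at background level k in [0, 255]."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0) or np.any(k_arr > 255):
        raise ValueError("luminance must lie in [0, 255]")
    low = params.d0 * (1.0 - np.sqrt(k_arr / 127.0)) + 3.0
    high = params.gamma * (k_arr - 127.0) + 3.0
    out = np.where(k_arr <= 127.0, low, high)
    return float(out) if np.isscalar(k) or out.ndim == 0 else out


def merge_cost(m1: float, m2: float, params: JNDParams = JNDParams()) -> float:
    """Perceptual merging cost F_c for two region means."""
    return abs(m1 - m2) - min(jnd(m1, params), jnd(m2, params)) + 255.0


class _RegionForest:
    """Union-find over regions carrying running means, counts and adjacency."""

    def __init__(self, regions: RegionLabelMap):
        self.parent = {i: i for i in regions.means}
        self.sums = {i: regions.means[i] * regions.counts[i] for i in regions.means}
        self.counts = dict(regions.counts)
        self.neigh: dict[int, set[int]] = {i: set() for i in regions.means}
        for u, v in regions.adjacency:
            self.neigh[u].add(v)
            self.neigh[v].add(u)

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def mean(self, i: int) -> float:
        return self.sums[i] / self.counts[i]

    def union(self, a: int, b: int) -> int:
        a, b = self.find(a), self.find(b)
        if a == b:
            return a
        if self.counts[a] < self.counts[b]:
            a, b = b, a
        self.parent[b] = a
        self.sums[a] += self.sums[b]
        self.counts[a] += self.counts[b]
        self.neigh[a] |= self.neigh[b]
        self.neigh[a].discard(a)
        self.neigh[a].discard(b)
        for k in self.neigh[b]:
            s = self.neigh[k]
            s.discard(b)
            if k != a:
                s.add(a)
        del self.neigh[b]
        return a

    def roots(self) -> list[int]:
        return [i for i in self.parent if self.parent[i] == i]


def merge_by_jnd(regions: RegionLabelMap, params: JNDParams = JNDParams(),
                 background_floor: float | None = None) -> RegionLabelMap:
    """First region merging: perceptual agglomeration plus Otsu background.

    All regions with mean grey level above ``background_floor`` (the Otsu
    threshold of the block's max-opening frame) are fused into one background
    region regardless of cost.  The remaining adjacency graph is then merged
    lowest-cost-first while the best pair's F_c stays below Thr, with means
    recomputed after every merge.  The output labelling is a coarsening of
    the input; the background region is relabelled 0.
    """
    forest = _RegionForest(regions)

    bg_root: int | None = None
    if background_floor is not None:
        bright = [i for i in regions.means if regions.means[i] > background_floor]
        for i in bright:
            bg_root = i if bg_root is None else forest.union(forest.find(bg_root), forest.find(i))

    heap: list[tuple[float, int, int]] = []

    def push_pair(a: int, b: int) -> None:
        cost = merge_cost(forest.mean(a), forest.mean(b), params)
        if cost < params.thr:
            heapq.heappush(heap, (cost, min(a, b), max(a, b)))

    for r in forest.roots():
        for nb in forest.neigh[r]:
            if r < nb:
                push_pair(r, nb)

    while heap:
        cost, a, b = heapq.heappop(heap)
        ra, rb = forest.find(a), forest.find(b)
        if ra == rb:
            continue
        # stale entry: means changed since push
        if abs(merge_cost(forest.mean(ra), forest.mean(rb), params) - cost) > 1e-9 \
                or rb not in forest.neigh.get(ra, ()):
            if rb in forest.neigh.get(ra, ()):
                push_pair(ra, rb)
            continue
        merged = forest.union(ra, rb)
        if bg_root is not None:
            bg_root = forest.find(bg_root)
        for nb in forest.neigh[merged]:
            push_pair(merged, nb)

    root_of = {i: forest.find(i) for i in regions.means}
    if bg_root is not None:
        bg_root = forest.find(bg_root)
    out_ids: dict[int, int] = {}
    next_id = 1
    for r in sorted(set(root_of.values())):
        if r == bg_root:
            out_ids[r] = BACKGROUND_LABEL
        else:
            out_ids[r] = next_id
            next_id += 1
    relabel = np.zeros(int(regions.labels.max()) + 1, dtype=np.int32)
    for i, r in root_of.items():
        relabel[i] = out_ids[r]
    new_labels = relabel[regions.labels]
    means = {out_ids[r]: forest.mean(r) for r in forest.roots()}
    counts = {out_ids[r]: forest.counts[r] for r in forest.roots()}
    return RegionLabelMap(new_labels, means, counts, _adjacency_pairs(new_labels))
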