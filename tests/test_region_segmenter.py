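import numpy as np
import pytest

from glottikit.region_segmenter import (JNDParams, RegionLabelMap,
                                        _adjacency_pairs, jnd, merge_by_jnd,
                                        merge_cost, thresholded_gradient,
                                        watershed_regions)


class TestGradient:
    def test_constant_frame_zero_gradient(self):
        assert thresholded_gradient(np.full((10, 10), 42.0)).max() == 0

    def test_hard_step_normalises_to_255(self):
        frame = np.zeros((10, 10))
        frame[:, 5:] = 255.0
        assert thresholded_gradient(frame).max() == pytest.approx(255.0)

    def test_below_floor_suppressed(self):
        # gentle ramp whose normalised gradient sits below the floor after
        # one dominant edge rescales everything
        frame = np.zeros((10, 20))
        frame[:, 10:] = 255.0                 # dominant edge -> level 255
        frame[:, :10] += np.arange(10) * 0.5  # faint ramp, normalised << 10
        grad = thresholded_gradient(frame, floor=10)
        assert grad[:, 2:7].max() == 0


class TestWatershed:
    def test_zero_gradient_single_region(self):
        regions = watershed_regions(np.zeros((8, 8)))
        assert len(regions.means) == 1

    def test_two_pools_one_ridge(self):
        grad = np.zeros((16, 16))
        grad[:, 8] = 100.0                    # bright ridge splits the plain
        regions = watershed_regions(grad)
        assert len(regions.means) == 2
        assert regions.adjacency                  # the two regions touch

    def test_partition_property(self, rng):
        frame = rng.integers(0, 256, (24, 24)).astype(float)
        grad = thresholded_gradient(frame)
        regions = watershed_regions(grad, frame)
        assert (regions.labels > 0).all()
        assert sum(regions.counts.values()) == frame.size


class TestJND:
    @pytest.mark.parametrize("k, expected", [(0, 20.0), (127, 3.0), (255, 6.0)])
    def test_reference_values(self, k, expected):
        assert jnd(k) == pytest.approx(expected)

    def test_continuity_at_127(self):
        assert jnd(127.0 - 1e-9) == pytest.approx(jnd(127.0 + 1e-9), abs=1e-6)

    def test_monotone_branches(self):
        k = np.arange(256.0)
        v = jnd(k)
        assert (np.diff(v[:128]) < 0).all()       # strictly decreasing
        assert (np.diff(v[127:]) > 0).all()       # strictly increasing

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            jnd(-1)
        with pytest.raises(ValueError):
            jnd(256)


def _toy_regions(label_img, intensity):
    label_img = np.asarray(label_img)
    intensity = np.asarray(intensity, dtype=float)
    ids = np.unique(label_img)
    means = {int(i): float(intensity[label_img == i].mean()) for i in ids}
    counts = {int(i): int((label_img == i).sum()) for i in ids}
    return RegionLabelMap(label_img, means, counts, _adjacency_pairs(label_img))


def _brute_force_merge(regions, params, background_floor=None):
    """Exhaustive agglomeration oracle: global-minimum pair each step."""
    groups = {i: {i} for i in regions.means}
    sums = {i: regions.means[i] * regions.counts[i] for i in regions.means}
    counts = dict(regions.counts)
    adj = {i: set() for i in regions.means}
    for u, v in regions.adjacency:
        adj[u].add(v)
        adj[v].add(u)

    def fuse(a, b):
        groups[a] |= groups.pop(b)
        sums[a] += sums.pop(b)
        counts[a] += counts.pop(b)
        adj[a] |= adj.pop(b)
        adj[a] -= {a, b}
        for k in adj:
            if b in adj[k]:
                adj[k].discard(b)
                if k != a:
                    adj[k].add(a)

    if background_floor is not None:
        bright = [i for i in list(groups) if sums[i] / counts[i] > background_floor]
        while len(bright) > 1:
            fuse(bright[0], bright[1])
            bright = [bright[0]] + bright[2:]
    while True:
        best = None
        for a in groups:
            for b in adj[a]:
                if b <= a:
                    continue
                c = merge_cost(sums[a] / counts[a], sums[b] / counts[b], params)
                if c < params.thr and (best is None or c < best[0]):
                    best = (c, a, b)
        if best is None:
            break
        fuse(best[1], best[2])
    return {frozenset(g) for g in groups.values()}


class TestMergeByJND:
    params = JNDParams()

    def test_equal_means_always_merge(self):
        labels = np.array([[1, 1, 2, 2]] * 4)
        frame = np.full((4, 4), 60.0)
        merged = merge_by_jnd(_toy_regions(labels, frame), self.params)
        assert len(merged.means) == 1

    def test_distinct_dark_regions_not_merged(self):
        # means 0 and 50: F_c = 50 - JND(50) + 255 = 295.7 >= 265
        labels = np.array([[1, 1, 2, 2]] * 4)
        frame = np.where(labels == 1, 0.0, 50.0)
        merged = merge_by_jnd(_toy_regions(labels, frame), self.params)
        assert len(merged.means) == 2

    def test_close_midtones_merge(self):
        # means 100 and 105: F_c = 5 - JND(105) + 255 = 255.5 < 265
        labels = np.array([[1, 1, 2, 2]] * 4)
        frame = np.where(labels == 1, 100.0, 105.0)
        merged = merge_by_jnd(_toy_regions(labels, frame), self.params)
        assert len(merged.means) == 1

    def test_merge_criterion_equivalence(self, rng):
        """F_c < Thr iff |dm| < minJND + (Thr - 255), 1000 random pairs."""
        for _ in range(1000):
            m1, m2 = rng.uniform(0, 255, 2)
            lhs = merge_cost(m1, m2, self.params) < self.params.thr
            rhs = abs(m1 - m2) < min(jnd(m1), jnd(m2)) + (self.params.thr - 255)
            assert lhs == rhs

    def test_output_is_coarsening(self, rng):
        frame = rng.integers(0, 256, (20, 20)).astype(float)
        regions = watershed_regions(thresholded_gradient(frame), frame)
        merged = merge_by_jnd(regions, self.params, background_floor=128.0)
        for i in np.unique(regions.labels):
            src = regions.labels == i
            assert len(np.unique(merged.labels[src])) == 1

    def test_bright_regions_single_background(self, rng):
        frame = rng.integers(0, 256, (20, 20)).astype(float)
        regions = watershed_regions(thresholded_gradient(frame), frame)
        merged = merge_by_jnd(regions, self.params, background_floor=100.0)
        bright = [i for i, m in merged.means.items() if m > 100.0]
        # every region whose source mean exceeded the floor carries label 0
        for i, m in regions.means.items():
            if m > 100.0:
                assert np.unique(merged.labels[regions.labels == i]) == [0]
        assert len([b for b in bright if b == 0]) <= 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        """Heap agglomeration equals brute-force merging on <=12 regions."""
        rng = np.random.default_rng(seed)
        side = 12
        labels = np.repeat(np.repeat(
            np.arange(1, 13).reshape(3, 4), side // 3, 0), side // 4, 1)
        frame = np.zeros((side, side))
        values = rng.uniform(0, 255, 12)
        for i in range(12):
            frame[labels == i + 1] = values[i]
        regions = _toy_regions(labels, frame)
        merged = merge_by_jnd(regions, self.params)
        got = {}
        for i in np.unique(labels):
            out = int(np.unique(merged.labels[labels == i])[0])
            got.setdefault(out, set()).add(int(i))
        assert {frozenset(v) for v in got.values()} == \
            _brute_force_merge(regions, self.params)


def test_jnd_params_validation():
    with pytest.raises(ValueError):
        JNDParams(thr=255.0)
    with pytest.raises(ValueError):
        JNDParams(d0=0.0)
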