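"""Spatial feature tests: DBSCAN semantics vs brute force, cluster scores."""

import numpy as np
import pytest

from sozloc import spatial as sp


def brute_force_dbscan(points: np.ndarray, epsilon: float, v_min: int) -> np.ndarray:
    """O(n^2) reference: strict more-than-v_min core rule, epsilon-linked
    core merging, border points to the nearest core (ties: lowest index)."""
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neigh_counts = (d <= epsilon).sum(axis=1) - 1  # excluding self
    core = neigh_counts > v_min
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        frontier = [i]
        labels[i] = cluster
        while frontier:
            j = frontier.pop()
            for k in range(n):
                if core[k] and labels[k] == -1 and d[j, k] <= epsilon:
                    labels[k] = cluster
                    frontier.append(k)
        cluster += 1
    for i in range(n):
        if core[i]:
            continue
        cand = [k for k in range(n) if core[k] and d[i, k] <= epsilon]
        if cand:
            best = min(cand, key=lambda k: (d[i, k], k))
            labels[i] = labels[best]
    return labels


def _canonical(labels):
    """Relabel cluster ids by first occurrence so partitions compare."""
    mapping, out = {}, []
    for lab in labels:
        if lab == -1:
            out.append(-1)
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return out


class TestDbscan:
    def test_empty_mask_gives_no_clusters(self):
        assert sp.dbscan_clusters(np.zeros((20, 20), bool)) == []

    def test_solid_block_above_threshold_is_one_cluster(self):
        mask = np.zeros((30, 30), bool)
        mask[5:17, 5:17] = True  # 144 px > 135
        clusters = sp.dbscan_clusters(mask)
        assert len(clusters) == 1
        assert clusters[0].size_px == 144

    def test_blocks_at_threshold_are_excluded(self):
        mask = np.zeros((40, 60), bool)
        mask[2:12, 2:12] = True  # 100 px
        mask[25:35, 45:55] = True  # 100 px, far apart
        assert sp.dbscan_clusters(mask) == []
        # exactly 135 px does not surpass the threshold
        mask2 = np.zeros((40, 40), bool)
        mask2[1:10, 1:16] = True  # 135 px
        assert sp.dbscan_clusters(mask2) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            h, w = rng.integers(10, 41, size=2)
            mask = rng.random((h, w)) < rng.uniform(0.05, 0.35)
            pts = np.argwhere(mask)
            eps = float(rng.uniform(1.0, 3.0))
            v_min = int(rng.integers(1, 6))
            got = sp.dbscan_labels(pts, eps, v_min)
            want = brute_force_dbscan(pts.astype(float), eps, v_min)
            assert _canonical(got) == _canonical(want)

    def test_adding_pixels_never_unqualifies_a_cluster(self):
        mask = np.zeros((30, 30), bool)
        mask[5:17, 5:17] = True
        base = sp.dbscan_clusters(mask)[0].size_px
        mask[17, 5:17] = True  # grow the cluster
        grown = sp.dbscan_clusters(mask)
        assert len(grown) == 1 and grown[0].size_px > base


class _FakeSlice:
    def __init__(self, shape=(40, 60)):
        self.pixels = np.zeros((*shape, 3), np.uint8)


def _cluster(pix, tile=0):
    return sp.ActivationCluster(pixels=np.asarray(pix), tile_index=tile)


class TestFClusters:
    def test_single_fully_one_sided_cluster_scores_one(self):
        sl = _FakeSlice()
        pix = [(r, c) for r in range(10, 20) for c in range(5, 20)]  # all left
        assert sp.f_clusters([(sl, [_cluster(pix)])]) == pytest.approx(1.0)

    def test_mirrored_pair_scores_at_most_quarter(self):
        sl = _FakeSlice()
        left = [(r, c) for r in range(10, 20) for c in range(5, 20)]
        right = [(r, 59 - c) for r, c in left]
        score = sp.f_clusters([(sl, [_cluster(left), _cluster(right)])])
        assert score <= 0.25

    def test_no_clusters_scores_zero(self):
        assert sp.f_clusters([(_FakeSlice(), [])]) == 0.0

    def test_translation_invariance(self):
        sl = _FakeSlice((80, 120))
        pix = [(r, c) for r in range(10, 20) for c in range(5, 20)]
        s1 = sp.f_clusters([(sl, [_cluster(pix)])])
        shifted = [(r + 7, c + 11) for r, c in pix]
        s2 = sp.f_clusters([(_FakeSlice((80, 120)), [_cluster(shifted)])])
        # both stay left of the (same-width) midline
        assert s1 == pytest.approx(s2)


class TestFWmVentricle:
    def _anatomy(self, shape=(40, 60), wm_col=30, vent=None):
        contour = np.array([[r, wm_col] for r in range(5, 35)], float)
        region = np.zeros(shape, bool)
        if vent is not None:
            region[vent] = True
        return sp.annotate_cluster_anatomy, contour, region

    def test_counts_fraction_with_both_flags(self):
        shape = (40, 60)

        class A:
            white_matter_contour = np.array([[r, 30] for r in range(40)], float)
            ventricle_region = np.zeros(shape, bool)
            shape_ = shape

        A.shape = shape
        A.ventricle_region[18:22, 33:37] = True
        qualifying = _cluster([(r, c) for r in range(15, 25) for c in range(28, 38)])
        ring_only = _cluster([(r, c) for r in range(2, 5) for c in range(2, 12)])
        frac = sp.f_wm_ventricle([(A, [qualifying, ring_only])])
        assert frac == pytest.approx(0.5)
        assert qualifying.overlaps_white_matter and qualifying.reaches_ventricle
        assert not ring_only.overlaps_white_matter

    def test_no_clusters_gives_zero(self):
        class A:
            white_matter_contour = None
            ventricle_region = np.zeros((40, 60), bool)
            shape = (40, 60)

        assert sp.f_wm_ventricle([(A, [])]) == 0.0
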