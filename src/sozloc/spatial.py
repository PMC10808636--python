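"""Spatial expert features from activation masks.

Two of the four expert features live here:

* ``f_clusters`` — SOZ ICs ideally show a *single* activation cluster
  confined asymmetrically to one hemisphere, while RSN ICs show two or more
  clusters mirrored across the midline.
* ``f_wm_ventricle`` — SOZ activation extends from gray matter through the
  white-matter contour into the ventricular region.

Clusters are found per slice with DBSCAN on activation-pixel coordinates.
The DBSCAN here follows the stated semantics exactly: a pixel is a core
point iff it has *strictly more than* ``v_min`` neighbors (excluding
itself) within distance ``epsilon``; core points within ``epsilon`` of each
other merge into one cluster; a non-core pixel within ``epsilon`` of a core
point is a border point assigned to the cluster of its *nearest* core point
(ties broken by lowest core-point index); all other pixels are discarded.
Only clusters strictly larger than ``min_cluster_px`` pixels are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree


@dataclass
class DbscanParams:
    epsilon: float = 2.0
    v_min: int = 4
    min_cluster_px: int = 135

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.v_min < 1:
            raise ValueError("v_min must be >= 1")
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be >= 1")


@dataclass
class ActivationCluster:
    """A retained activation cluster on one slice (pixel coords are (row, col))."""

    pixels: np.ndarray
    tile_index: int = -1
    overlaps_white_matter: bool = False
    reaches_ventricle: bool = False
    size_px: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise ValueError("pixels must be a non-empty (k, 2) array")
        self.size_px = len(self.pixels)
        self.centroid = (
            float(self.pixels[:, 0].mean()),
            float(self.pixels[:, 1].mean()),
        )


def dbscan_labels(points: np.ndarray, epsilon: float, v_min: int) -> np.ndarray:
    """Cluster id per point (-1 for discarded points), kd-tree accelerated.

    Cluster ids are assigned in order of the first core point encountered in
    input order, so the labeling is deterministic.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pts)
    neigh = tree.query_ball_point(pts, epsilon)
    # query_ball_point includes the point itself
    is_core = np.array([len(nb) - 1 > v_min for nb in neigh])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not is_core[i] or labels[i] != -1:
            continue
        # expand over core points connected within epsilon
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neigh[j]:
                if is_core[k] and labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    # border points: non-core within epsilon of a core point -> nearest core,
    # ties broken by lowest core index
    for i in range(n):
        if is_core[i]:
            continue
        best, best_d = -1, np.inf
        for k in neigh[i]:
            if k == i or not is_core[k]:
                continue
            d = np.hypot(*(pts[i] - pts[k]))
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and k < best):
                best, best_d = k, d
        if best >= 0:
            labels[i] = labels[best]
    return labels


def dbscan_clusters(
    mask: np.ndarray,
    params: DbscanParams | None = None,
    tile_index: int = -1,
) -> list[ActivationCluster]:
    """Retained activation clusters of a 2-D binary mask.

    Returns only clusters with ``size_px > min_cluster_px`` ("surpassing"
    the threshold, strictly), ordered by their first pixel in row-major
    order.
    """
    params = params or DbscanParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    points = np.argwhere(mask)
    if len(points) == 0:
        return []
    labels = dbscan_labels(points, params.epsilon, params.v_min)
    clusters = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        pix = points[labels == lab]
        if len(pix) > params.min_cluster_px:
            clusters.append(ActivationCluster(pixels=pix, tile_index=tile_index))
    clusters.sort(key=lambda c: (c.pixels[0, 0], c.pixels[0, 1]))
    return clusters


def f_clusters(
    slices_clusters: list[tuple["object", list[ActivationCluster]]],
) -> float:
    """SOZ-likeness score in [0, 1] from cluster count and asymmetry.

    With ``m`` the median per-slice retained-cluster count over slices that
    have at least one cluster, and ``a`` the fraction of retained cluster
    pixels on the dominant side of the tile's vertical midline (pooled over
    slices), the score is ``max(0, 2a - 1) / m``: 1.0 for a single fully
    one-sided cluster, 0 for mirrored symmetric activation or no clusters.
    """
    counts = []
    left = right = 0
    for sl, clusters in slices_clusters:
        if not clusters:
            continue
        counts.append(len(clusters))
        width = sl.pixels.shape[1]
        mid = width / 2.0
        for c in clusters:
            cols = c.pixels[:, 1]
            left += int(np.sum(cols < mid))
            right += int(np.sum(cols >= mid))
    if not counts:
        return 0.0
    m = float(np.median(counts))
    total = left + right
    a = max(left, right) / total
    return float(max(0.0, 2.0 * a - 1.0) / m)


def annotate_cluster_anatomy(
    anatomy: "object",
    clusters: list[ActivationCluster],
    shape: tuple[int, int],
) -> None:
    """Set the white-matter / ventricle flags of each cluster in place.

    ``overlaps_white_matter`` — cluster pixels intersect the white-matter
    contour dilated by one pixel (the contour is a 1-px path; dilation
    absorbs rasterization gaps).  ``reaches_ventricle`` — cluster pixels
    intersect the ventricular region mask.
    """
    wm = np.zeros(shape, dtype=bool)
    if anatomy.white_matter_contour is not None and len(anatomy.white_matter_contour):
        rr = np.clip(np.round(anatomy.white_matter_contour[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(anatomy.white_matter_contour[:, 1]).astype(int), 0, shape[1] - 1)
        wm[rr, cc] = True
        wm = binary_dilation(wm, iterations=1)
    vent = anatomy.ventricle_region
    if vent is None:
        vent = np.zeros(shape, dtype=bool)
    for c in clusters:
        rr, cc = c.pixels[:, 0], c.pixels[:, 1]
        inb = (rr < shape[0]) & (cc < shape[1])
        c.overlaps_white_matter = bool(wm[rr[inb], cc[inb]].any())
        c.reaches_ventricle = bool(vent[rr[inb], cc[inb]].any())


def f_wm_ventricle(
    anatomy_clusters: list[tuple["object", list[ActivationCluster]]],
) -> float:
    """Fraction of retained clusters that both overlap the white-matter
    contour and reach the ventricular region (0 when there are no clusters).

    Anatomy must come from the activation-free pass (two-pass protocol); the
    per-cluster flags are set here as a side effect.
    """
    n = 0
    hits = 0
    for anatomy, clusters in anatomy_clusters:
        if not clusters:
            continue
        shape = anatomy.shape
        annotate_cluster_anatomy(anatomy, clusters, shape)
        for c in clusters:
            n += 1
            if c.overlaps_white_matter and c.reaches_ventricle:
                hits += 1
    return hits / n if n else 0.0
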