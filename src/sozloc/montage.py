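"""IC montage processing: resizing, slice extraction, anatomy and activation.

An IC's spatial map arrives as an RGB montage of axial slice tiles rendered
on a dark background (native 709 x 1006).  The montage is resized to
270 x 470 for the convolutional network, while expert features are
extracted at native resolution: individual brain slices are located by
normalized cross-correlation against a slice template, activation pixels
are identified by a warm-color dominance rule, and slice anatomy (brain
boundary, white-matter contour, ventricular region) is derived from a
Sobel-based contour analysis of an activation-free version of each slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes, distance_transform_edt
from skimage.feature import match_template, peak_local_max
from skimage.filters import sobel
from skimage.transform import resize

NATIVE_SIZE = (709, 1006)
RESIZED_SIZE = (270, 470)

# Warm-overlay color-dominance rule: an activation pixel is strongly red,
# clearly above green, which is clearly above blue.  Grayscale anatomy
# (R == G == B) can never satisfy it.
ACT_R_MIN = 180
ACT_RG_GAP = 20
ACT_GB_GAP = 10

#: grayscale threshold separating brain tissue from background/ventricle
BRAIN_INTENSITY_THRESHOLD = 60
#: default normalized-cross-correlation score for accepting a slice tile
MATCH_THRESHOLD = 0.45
#: default level on the Sobel gradient magnitude for contour tracing
SOBEL_CONTOUR_LEVEL = 0.05

LABELS = ("NOISE", "RSN", "SOZ")


@dataclass
class ICMontage:
    """One IC's spatial map as an RGB montage image."""

    pixels: np.ndarray
    ic_id: str = ""
    patient_id: str = ""
    label: str = "unknown"
    native: bool = True
    overlay_mask: np.ndarray | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("montage must be H x W x 3")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise ValueError("montage must be non-empty")
        if self.label not in LABELS + ("unknown",):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class BrainSlice:
    """One slice tile cut from a montage (0-based, half-open extents)."""

    pixels: np.ndarray
    tile_index: int
    origin: tuple[int, int]
    brain_mask: np.ndarray
    is_base_slice: bool


@dataclass
class SliceAnatomy:
    """Contour-defined anatomy proxies of one activation-free slice."""

    boundary_contours: list[np.ndarray]
    white_matter_contour: np.ndarray | None
    ventricle_region: np.ndarray
    shape: tuple[int, int] = field(default=(0, 0))


def resize_montage(m: ICMontage) -> ICMontage:
    """Resize a native 709 x 1006 montage to 270 x 470 for the CNN."""
    if not m.native:
        raise ValueError("montage is already resized; refusing to resize twice")
    out = resize(
        m.pixels.astype(float),
        RESIZED_SIZE,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return ICMontage(
        pixels=np.clip(np.round(out), 0, 255).astype(np.uint8),
        ic_id=m.ic_id,
        patient_id=m.patient_id,
        label=m.label,
        native=False,
    )


def activation_mask_rgb(pixels: np.ndarray) -> np.ndarray:
    """Binary mask of pixels satisfying the warm-color dominance rule."""
    px = np.asarray(pixels).astype(np.int16)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (r >= ACT_R_MIN) & (r > g + ACT_RG_GAP) & (g > b + ACT_GB_GAP)


def activation_mask(s: BrainSlice) -> np.ndarray:
    return activation_mask_rgb(s.pixels)


def _grayscale_anatomy(pixels: np.ndarray) -> np.ndarray:
    """Anatomy-only grayscale estimate: the channel minimum suppresses the
    warm activation overlay (its blue channel is low) while grayscale
    anatomy is unchanged."""
    return np.asarray(pixels)[..., :3].min(axis=2)


def _group_origins(peaks: np.ndarray, tile_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Sort detected tile origins row-major (row bands, then column)."""
    if len(peaks) == 0:
        return []
    th = tile_shape[0]
    order = np.argsort(peaks[:, 0], kind="stable")
    rows_sorted = peaks[order]
    bands: list[list[np.ndarray]] = [[rows_sorted[0]]]
    for p in rows_sorted[1:]:
        if p[0] - bands[-1][0][0] > th // 2:
            bands.append([p])
        else:
            bands[-1].append(p)
    origins: list[tuple[int, int]] = []
    for band in bands:
        for p in sorted(band, key=lambda q: q[1]):
            origins.append((int(p[0]), int(p[1])))
    return origins


def _refine_origin(
    gray: np.ndarray, r: int, c: int, tile_shape: tuple[int, int]
) -> tuple[int, int]:
    """Shift a tile origin so the thresholded brain structure is centered."""
    th, tw = tile_shape
    rf, cf = float(r), float(c)
    for _ in range(2):
        r0 = int(np.clip(round(rf), 0, gray.shape[0] - th))
        c0 = int(np.clip(round(cf), 0, gray.shape[1] - tw))
        win = binary_fill_holes(
            gray[r0 : r0 + th, c0 : c0 + tw] > BRAIN_INTENSITY_THRESHOLD
        )
        if win.sum() < 50:
            break
        ys, xs = np.nonzero(win)
        rf = r0 + ys.mean() - (th - 1) / 2.0
        cf = c0 + xs.mean() - (tw - 1) / 2.0
    return (
        int(np.clip(round(rf), 0, gray.shape[0] - th)),
        int(np.clip(round(cf), 0, gray.shape[1] - tw)),
    )


def extract_brain_slices(
    m: ICMontage,
    template: np.ndarray,
    match_threshold: float = MATCH_THRESHOLD,
    coarse_factor: int = 4,
) -> list[BrainSlice]:
    """Locate slice tiles by template matching and cut them out.

    The template is correlated (normalized cross-correlation) against the
    activation-suppressed grayscale montage — at ``coarse_factor``-fold
    reduced resolution, since only approximate origins are needed before
    centroid refinement.  Correlation peaks above ``match_threshold`` are
    taken as tile origins, ordered base-to-apex (row-major).  Base slices
    are the first third of the tile order.  Returns an empty list (with a
    warning) when nothing matches.
    """
    template = np.asarray(template, dtype=float)
    gray = _grayscale_anatomy(m.pixels).astype(float)
    if template.shape[0] > gray.shape[0] or template.shape[1] > gray.shape[1]:
        raise ValueError("template larger than montage")
    f = max(1, int(coarse_factor))
    gray_c = gray[::f, ::f]
    tpl_c = template[::f, ::f]
    corr = match_template(gray_c, tpl_c, pad_input=False)
    min_dist = max(1, int(0.6 * min(tpl_c.shape)))
    peaks = peak_local_max(
        corr,
        min_distance=min_dist,
        threshold_abs=match_threshold,
        exclude_border=False,
    )
    origins = _group_origins(peaks * f, template.shape)
    if not origins:
        warnings.warn("no slice tile matched the template; non-brain image?")
        return []
    th, tw = template.shape
    # The correlation surface plateaus when a slice is smaller than the
    # template, so refine each origin by re-centering the detected brain
    # structure inside its tile window.
    origins = [
        _refine_origin(gray, r, c, (th, tw)) for (r, c) in origins
    ]
    n = len(origins)
    n_base = max(1, n // 3)
    slices = []
    for idx, (r, c) in enumerate(origins):
        tile = m.pixels[r : r + th, c : c + tw]
        mask = binary_fill_holes(_grayscale_anatomy(tile) > BRAIN_INTENSITY_THRESHOLD)
        slices.append(
            BrainSlice(
                pixels=tile,
                tile_index=idx,
                origin=(r, c),
                brain_mask=mask,
                is_base_slice=idx < n_base,
            )
        )
    return slices


def remove_activation(s: BrainSlice) -> BrainSlice:
    """Replace activation pixels by nearest-anatomy interpolation.

    Every pixel passing the color-dominance rule takes the grayscale value
    of its nearest non-activation pixel (Euclidean distance transform),
    producing an activation-free, grayscale-consistent slice for contour
    detection.  A fully saturated tile falls back to the background level.
    """
    mask = activation_mask_rgb(s.pixels)
    gray = _grayscale_anatomy(s.pixels).astype(np.uint8)
    if mask.all():
        filled = np.full_like(gray, 12)
    elif mask.any():
        _, (ir, ic) = distance_transform_edt(mask, return_indices=True)
        filled = gray.copy()
        filled[mask] = gray[ir[mask], ic[mask]]
    else:
        filled = gray
    rgb = np.repeat(filled[..., None], 3, axis=2)
    return BrainSlice(
        pixels=rgb,
        tile_index=s.tile_index,
        origin=s.origin,
        brain_mask=s.brain_mask,
        is_base_slice=s.is_base_slice,
    )


def _contour_area(contour: np.ndarray) -> float:
    """Enclosed area of a closed contour via the shoelace formula."""
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def detect_anatomy(
    s: BrainSlice,
    contour_level: float = SOBEL_CONTOUR_LEVEL,
) -> SliceAnatomy:
    """Contours and ventricle region of one activation-free slice.

    Contours are traced on the thresholded Sobel gradient magnitude.  The
    longest contour is the brain boundary; the white-matter contour is the
    most prominent interior contour (longest, ties by enclosed area).  The
    ventricular region (base slices only) is the set of dark pixels
    enclosed by brain tissue — inside the convex hull of the boundary
    contours but intersecting none of them.
    """
    from skimage.measure import find_contours

    gray = _grayscale_anatomy(s.pixels).astype(float)
    grad = sobel(gray / 255.0)
    contours = [c for c in find_contours(grad, contour_level) if len(c) >= 8]
    if not contours:
        return SliceAnatomy([], None, np.zeros(gray.shape, bool), gray.shape)
    lengths = [len(c) for c in contours]
    boundary = contours[int(np.argmax(lengths))]
    boundary_area = _contour_area(boundary)
    # Interior contours: centroid strictly inside the brain mask and enclosed
    # area well below the boundary's.  The Sobel edge band traces a nested
    # contour pair per edge, so the inner side of the brain-boundary edge
    # itself (area ~ boundary area) must not count as interior structure.
    interior = []
    for c in contours:
        if c is boundary:
            continue
        cy, cx = np.round(c.mean(axis=0)).astype(int)
        if (
            0 <= cy < gray.shape[0]
            and 0 <= cx < gray.shape[1]
            and s.brain_mask[cy, cx]
            and _contour_area(c) <= 0.8 * boundary_area
        ):
            interior.append(c)
    wm = None
    if interior:
        interior.sort(key=lambda c: (len(c), _contour_area(c)), reverse=True)
        wm = interior[0]
    vent = np.zeros(gray.shape, bool)
    if s.is_base_slice:
        tissue = gray > BRAIN_INTENSITY_THRESHOLD
        filled = binary_fill_holes(tissue)
        holes = filled & ~tissue
        # exclude pixels lying on any traced contour (ventricles do not
        # intersect brain-boundary contours)
        on_contour = np.zeros(gray.shape, bool)
        for c in contours:
            rr = np.clip(np.round(c[:, 0]).astype(int), 0, gray.shape[0] - 1)
            cc = np.clip(np.round(c[:, 1]).astype(int), 0, gray.shape[1] - 1)
            on_contour[rr, cc] = True
        vent = holes & ~on_contour
    return SliceAnatomy(
        boundary_contours=contours,
        white_matter_contour=wm,
        ventricle_region=vent,
        shape=gray.shape,
    )
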