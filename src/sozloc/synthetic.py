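"""Seeded synthetic IC cohorts emulating the three rs-fMRI IC classes.

The generator renders labeled IC montages (native 709 x 1006 RGB, 46 axial
slice tiles on a 6 x 8 grid, base-to-apex in row-major order) and matching
BOLD time courses (600 samples at TR 2 s), following the textbook sorting
rules:

* **SOZ** — a single activation cluster confined to one hemisphere on a few
  adjacent base slices, spanning from the gray-matter ring across the
  white-matter contour into the ventricular region; the time course is a
  handful of well-separated sinusoids inside 0.01-0.1 Hz (sparse spectrum).
* **RSN** — two or more clusters mirrored across the slice midline on mid
  slices, away from the ventricles; the time course densely fills the band.
* **NOISE** — rim arcs hugging the brain boundary (usually one-sided, the
  morphology of motion artifact), sub-threshold speckle and occasional
  off-brain blobs; the time course is broadband noise with drift and sharp
  spikes.

A ``separation`` knob in [0, 1] controls how cleanly the classes obey their
rules (1 = textbook); it exists so parameter-recovery experiments are
gradable and has no counterpart in real data.  Generation is a pure
function of (config, seed): identical inputs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import ICMontage, LABELS
from .temporal import BoldTimecourse

TILE_SHAPE = (118, 125)
GRID = (6, 8)
N_TILES = 46

# grayscale anatomy levels
BG_LEVEL = 12
RING_LEVEL = 150
WM_LEVEL = 95
VENT_LEVEL = 18
#: white-matter interior as a fraction of the brain ellipse axes
WM_SCALE = 0.62

# demographic marginals of the reference cohort, used purely as subgroup tags
AGE_GROUPS = ("0-<5", "5-<13", "13-18")
AGE_PROBS = (20 / 52, 18 / 52, 14 / 52)
FEMALE_FRACTION = 0.558


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_patients: int = 10
    ics_per_patient: int = 100
    class_proportions: tuple[float, float, float] = (0.51, 0.43, 0.06)
    montage_grid: tuple[int, int] = GRID
    n_tiles: int = N_TILES
    native_size: tuple[int, int] = (709, 1006)
    n_timepoints: int = 600
    tr_seconds: float = 2.0
    separation: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ConfigurationError("class_proportions must be non-negative")
        if self.n_patients > 0 and self.class_proportions[2] <= 0:
            raise ConfigurationError("SOZ proportion must be > 0")
        if not (0.0 <= self.separation <= 1.0):
            raise ConfigurationError("separation must lie in [0, 1]")
        if self.n_tiles > self.montage_grid[0] * self.montage_grid[1]:
            raise ConfigurationError("n_tiles exceeds grid capacity")

    def class_counts(self) -> tuple[int, int, int]:
        """Per-patient class counts honoring the proportions (>=1 SOZ)."""
        n = self.ics_per_patient
        raw = [p * n for p in self.class_proportions]
        if any(round(r) < 1 for r in raw):
            raise ConfigurationError(
                f"ics_per_patient={n} too small to honor proportions "
                f"{self.class_proportions}"
            )
        counts = [int(round(r)) for r in raw]
        counts[0] = n - counts[1] - counts[2]
        if min(counts) < 1:
            raise ConfigurationError(
                f"ics_per_patient={n} too small to honor proportions "
                f"{self.class_proportions}"
            )
        return tuple(counts)


@dataclass
class PatientRecord:
    patient_id: str
    age_group: str
    sex: str
    ics: list[tuple[ICMontage, BoldTimecourse, str]] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    patients: list[PatientRecord]

    def all_ics(self):
        for p in self.patients:
            for m, ts, lab in p.ics:
                yield p, m, ts, lab

    @property
    def n_ics(self) -> int:
        return sum(len(p.ics) for p in self.patients)


# ---------------------------------------------------------------------------
# anatomy rendering
# ---------------------------------------------------------------------------

def _slice_scale(i: int, n: int = N_TILES) -> float:
    """Brain size profile over the slice order: moderate at base, maximal
    mid-brain, moderate toward the apex."""
    t = (i + 1) / (n + 1)
    return 0.55 + 0.45 * np.sin(np.pi * (0.15 + 0.70 * t))


def _slice_axes(i: int, n: int = N_TILES) -> tuple[float, float]:
    s = _slice_scale(i, n)
    return 44.0 * s, 52.0 * s


def tile_center() -> tuple[float, float]:
    return (TILE_SHAPE[0] - 1) / 2.0, (TILE_SHAPE[1] - 1) / 2.0


def _tile_coords():
    cy, cx = tile_center()
    yy, xx = np.mgrid[0 : TILE_SHAPE[0], 0 : TILE_SHAPE[1]]
    return yy - cy, xx - cx


def ventricle_params(i: int, n: int = N_TILES) -> list[tuple[float, float, float, float]]:
    """(dy, dx, ry, rx) of the two ventricular holes of a base slice."""
    ar, ac = _slice_axes(i, n)
    ry, rx = 0.34 * ar, 0.20 * ac
    return [(0.0, -9.0, ry, rx), (0.0, 9.0, ry, rx)]


def draw_anatomy_tile(i: int, n: int = N_TILES, with_ventricles: bool | None = None) -> np.ndarray:
    """Grayscale pseudo-anatomy of slice ``i``: elliptical brain with a
    gray-matter ring, white-matter interior, and (on base slices) two dark
    ventricular holes."""
    if with_ventricles is None:
        with_ventricles = i < n // 3
    ar, ac = _slice_axes(i, n)
    dy, dx = _tile_coords()
    tile = np.full(TILE_SHAPE, BG_LEVEL, dtype=np.uint8)
    r2 = (dy / ar) ** 2 + (dx / ac) ** 2
    tile[r2 <= 1.0] = RING_LEVEL
    tile[r2 <= WM_SCALE**2] = WM_LEVEL
    if with_ventricles:
        for vy, vx, ry, rx in ventricle_params(i, n):
            hole = ((dy - vy) / ry) ** 2 + ((dx - vx) / rx) ** 2 <= 1.0
            tile[hole] = VENT_LEVEL
    return tile


def slice_template() -> np.ndarray:
    """Packaged synthetic single-slice template for template matching:
    a mid-size brain slice without ventricles, generated deterministically."""
    i_mid = N_TILES // 2
    return draw_anatomy_tile(i_mid, with_ventricles=False).astype(float)


def tile_origins(config: SyntheticConfig | None = None) -> list[tuple[int, int]]:
    """Top-left (row, col) of each tile, base-to-apex in row-major order."""
    rows, cols = GRID if config is None else config.montage_grid
    n = N_TILES if config is None else config.n_tiles
    th, tw = TILE_SHAPE
    out = []
    for idx in range(n):
        r, c = divmod(idx, cols)
        out.append((r * th, c * tw))
    return out


# ---------------------------------------------------------------------------
# class-conditional activation geometry
# ---------------------------------------------------------------------------

def _polar(i: int):
    ar, ac = _slice_axes(i)
    dy, dx = _tile_coords()
    r = np.sqrt((dy / ar) ** 2 + (dx / ac) ** 2)
    theta = np.arctan2(dy, dx)  # 0 points right, pi points left
    return r, theta


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + np.pi) % (2 * np.pi) - np.pi


def _sector(i: int, theta_c: float, width: float, r_lo: float, r_hi: float) -> np.ndarray:
    r, theta = _polar(i)
    return (np.abs(_wrap(theta - theta_c)) <= width / 2.0) & (r >= r_lo) & (r <= r_hi)


def _capsule(dy: np.ndarray, dx: np.ndarray, a: tuple[float, float],
             b: tuple[float, float], width: float) -> np.ndarray:
    """Pixels within ``width`` of the segment a-b (tile-center coords)."""
    ay, ax = a
    by, bx = b
    vy, vx = by - ay, bx - ax
    denom = vy * vy + vx * vx
    t = ((dy - ay) * vy + (dx - ax) * vx) / denom if denom > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    return (dy - (ay + t * vy)) ** 2 + (dx - (ax + t * vx)) ** 2 <= width**2


def _soz_tile_mask(
    i: int,
    side: int,
    rng: np.random.Generator,
    textbook: bool,
    theta_off: float = 0.0,
    width: float | None = None,
) -> np.ndarray:
    """One asymmetric activation finger: cortical wedge -> white matter ->
    ventricle, confined to one hemisphere.

    ``side`` is +1 (right hemisphere) or -1 (left); ``theta_off`` places
    the cortical focus anywhere in the hemisphere (radians from the
    horizontal axis of that side — SOZ foci vary across patients).  The
    finger covers the outer part of the ventricular hole on that side but
    leaves most of the hole uncovered, so the activation-free pass can
    still see a dark ventricular region.
    """
    axis = 0.0 if side > 0 else np.pi
    theta_c = axis + (theta_off + rng.uniform(-0.1, 0.1)) * (1 if side > 0 else -1)
    width = width if width is not None else rng.uniform(0.7, 1.1)
    ar, ac = _slice_axes(i)
    dy, dx = _tile_coords()
    mask = _sector(i, theta_c, width, 0.35, 0.93)
    hole_spec = ventricle_params(i)[1 if side > 0 else 0]
    vy, vx, ry, rx = hole_spec
    hole = ((dy - vy) / ry) ** 2 + ((dx - vx) / rx) ** 2 <= 1.0
    if textbook:
        # connector from the cortical wedge tip down to the ventricle
        tip = (0.40 * ar * np.sin(theta_c), 0.40 * ac * np.cos(theta_c))
        corridor = _capsule(dy, dx, tip, (vy, vx), 3.0)
        outer = (dx - vx) * side >= -0.2 * rx  # outer ~60% of the hole
        mask = mask | corridor | (hole & outer)
        # keep the rest of the hole visible for the anatomy pass
        mask &= ~(hole & ~outer & ~corridor)
    else:
        mask &= ~hole
    mask &= dx * side >= 0  # strictly one hemisphere
    return mask


def _rsn_tile_mask(i: int, rng: np.random.Generator, textbook: bool) -> np.ndarray:
    """One or two mirrored blob pairs in the cortical band of a mid slice."""
    mask = np.zeros(TILE_SHAPE, dtype=bool)
    for _ in range(rng.integers(1, 3)):
        theta = rng.uniform(-np.pi / 2 + 0.35, np.pi / 2 - 0.35)
        width = rng.uniform(0.5, 0.7)
        blob_r = _sector(i, theta, width, 0.55, 0.95)
        blob_l = _sector(i, np.pi - theta, width, 0.55, 0.95)
        if not textbook and rng.random() < 0.5:
            # degrade mirror symmetry: shrink one side
            blob_l &= _sector(i, np.pi - theta, width * 0.4, 0.55, 0.80)
        mask |= blob_r | blob_l
    return mask


def _noise_tile_mask(
    i: int, rng: np.random.Generator, side_bias: float | None, textbook: bool
) -> np.ndarray:
    """Rim arcs straddling the brain boundary plus sub-threshold speckle."""
    mask = np.zeros(TILE_SHAPE, dtype=bool)
    if side_bias is not None:
        theta_c = side_bias + rng.uniform(-0.5, 0.5)
    else:
        theta_c = rng.uniform(-np.pi, np.pi)
    width = rng.uniform(1.2, 2.2)
    mask |= _sector(i, theta_c, width, 0.96, 1.15)
    # speckle: small dots anywhere, each far below the retention threshold
    n_dots = rng.integers(8, 25)
    yy, xx = np.mgrid[0 : TILE_SHAPE[0], 0 : TILE_SHAPE[1]]
    for _ in range(n_dots):
        py = rng.integers(2, TILE_SHAPE[0] - 2)
        px = rng.integers(2, TILE_SHAPE[1] - 2)
        rad = rng.integers(1, 3)
        mask |= (yy - py) ** 2 + (xx - px) ** 2 <= rad**2
    if rng.random() < 0.3:
        # off-brain corner blob
        py = rng.choice([8, TILE_SHAPE[0] - 9]) + rng.integers(-3, 4)
        px = rng.choice([10, TILE_SHAPE[1] - 11]) + rng.integers(-3, 4)
        mask |= ((yy - py) / rng.uniform(6, 9)) ** 2 + (
            (xx - px) / rng.uniform(8, 12)
        ) ** 2 <= 1.0
    if not textbook and rng.random() < 0.5:
        # rule violation: interior blob
        mask |= _sector(i, rng.uniform(-np.pi, np.pi), 0.5, 0.3, 0.7)
    return mask


def draw_soz_style(rng: np.random.Generator, n_base: int = N_TILES // 3) -> dict:
    """Patient-level SOZ expression: hemisphere, cortical focus angle,
    slice range and finger width.  SOZ location is a characteristic of the
    patient — individual ICs only jitter around it — so under
    leave-one-patient-out evaluation a test patient's SOZ geometry is never
    seen in training."""
    return {
        "side": int(rng.choice([-1, 1])),
        "theta_off": float(rng.uniform(-1.2, 1.2)),
        "start": int(rng.integers(2, max(3, n_base - 3))),
        "n_slices": int(rng.integers(2, 4)),
        "width": float(rng.uniform(0.7, 1.1)),
    }


def generate_montage(
    label: str,
    rng: np.random.Generator,
    config: SyntheticConfig,
    patient_style: dict | None = None,
) -> ICMontage:
    """Render one labeled montage; the ground-truth activation mask is
    attached as ``overlay_mask``.  ``patient_style`` (SOZ only) pins the
    patient-level SOZ geometry; without it a fresh style is drawn."""
    if label not in LABELS:
        raise ValueError(f"invalid label {label!r}")
    H, W = config.native_size
    th, tw = TILE_SHAPE
    n = config.n_tiles
    n_base = n // 3
    canvas = np.full((H, W), BG_LEVEL, dtype=np.uint8)
    overlay = np.zeros((H, W), dtype=bool)
    origins = tile_origins(config)
    for idx, (r, c) in enumerate(origins):
        canvas[r : r + th, c : c + tw] = draw_anatomy_tile(idx, n)

    textbook = rng.random() < config.separation
    tile_masks: dict[int, np.ndarray] = {}
    if label == "SOZ":
        style = patient_style or draw_soz_style(rng, n_base)
        side = style["side"]
        start = int(np.clip(style["start"] + rng.integers(-1, 2), 2, n_base - 2))
        n_sl = int(np.clip(style["n_slices"] + rng.integers(-1, 2), 1, 4))
        for idx in range(start, min(start + n_sl, n_base)):
            tile_masks[idx] = _soz_tile_mask(
                idx, side, rng, textbook, style["theta_off"], style["width"]
            )
        if not textbook and rng.random() < 0.5:
            # rule violation: a mirrored ghost wedge
            ghost = int(rng.integers(start, min(start + 2, n_base)))
            tile_masks[ghost] = tile_masks.get(ghost, False) | _soz_tile_mask(
                ghost, -side, rng, textbook=False, theta_off=style["theta_off"]
            )
    elif label == "RSN":
        # resting-state networks appear at any depth, base slices included;
        # their cortical-band blobs stay clear of the ventricles
        lo, hi = 4, n - 6
        n_sl = int(rng.integers(2, 5))
        for idx in sorted(rng.choice(np.arange(lo, hi), size=n_sl, replace=False)):
            tile_masks[int(idx)] = _rsn_tile_mask(int(idx), rng, textbook)
    else:  # NOISE
        one_sided = rng.random() < 0.7
        side_bias = float(rng.choice([0.0, np.pi])) if one_sided else None
        n_sl = int(rng.integers(3, 8))
        for idx in rng.choice(np.arange(n), size=n_sl, replace=False):
            tile_masks[int(idx)] = _noise_tile_mask(int(idx), rng, side_bias, textbook)

    for idx, tm in tile_masks.items():
        r, c = origins[idx]
        overlay[r : r + th, c : c + tw] |= tm

    rgb = np.repeat(canvas[..., None], 3, axis=2)
    k = int(overlay.sum())
    if k:
        rgb[overlay, 0] = rng.integers(230, 256, size=k)
        rgb[overlay, 1] = rng.integers(100, 160, size=k)
        rgb[overlay, 2] = rng.integers(20, 50, size=k)
    return ICMontage(pixels=rgb, label=label, overlay_mask=overlay)


# ---------------------------------------------------------------------------
# class-conditional time courses
# ---------------------------------------------------------------------------

def _sparse_inband(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """2-4 well-separated sinusoids inside 0.01-0.1 Hz."""
    k = int(rng.integers(2, 5))
    freqs = []
    while len(freqs) < k:
        f = rng.uniform(0.01, 0.1)
        if all(abs(f - g) > 0.015 for g in freqs):
            freqs.append(f)
    x = np.zeros_like(t)
    for f in freqs:
        x += rng.uniform(0.7, 1.3) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x


def _dense_inband(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Many in-band components: a dense low-frequency spectrum."""
    x = np.zeros_like(t)
    for _ in range(int(rng.integers(25, 41))):
        f = rng.uniform(0.01, 0.1)
        x += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x / 3.0


def _noise_series(n: int, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """White noise + slow drift + sharp spikes (motion/scanner artifact)."""
    x = rng.normal(0.0, 1.0, size=n)
    x += rng.uniform(-1.5, 1.5) * np.linspace(-1, 1, n)
    for _ in range(int(rng.integers(5, 16))):
        pos = int(rng.integers(0, n))
        x[pos : pos + int(rng.integers(1, 3))] += rng.choice([-1, 1]) * rng.uniform(3, 6)
    return x


def generate_timecourse(
    label: str, rng: np.random.Generator, config: SyntheticConfig
) -> BoldTimecourse:
    if label not in LABELS:
        raise ValueError(f"invalid label {label!r}")
    n = config.n_timepoints
    t = np.arange(n) * config.tr_seconds
    sep = config.separation
    if label == "SOZ":
        x = sep * _sparse_inband(t, rng) + (1 - sep) * _dense_inband(t, rng)
    elif label == "RSN":
        x = sep * _dense_inband(t, rng) + (1 - sep) * _sparse_inband(t, rng)
    else:
        x = sep * _noise_series(n, t, rng) + (1 - sep) * _dense_inband(t, rng)
    x += rng.normal(0.0, 0.08, size=n)  # noise floor: output never constant
    return BoldTimecourse(samples=x, tr_seconds=config.tr_seconds)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _patient_labels(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    counts = config.class_counts()
    labels = ["NOISE"] * counts[0] + ["RSN"] * counts[1] + ["SOZ"] * counts[2]
    perm = rng.permutation(len(labels))
    return [labels[i] for i in perm]


def stream_cohort(config: SyntheticConfig):
    """Yield ``(patient_meta, ICMontage, BoldTimecourse, label)`` for every
    IC of the cohort in deterministic order without retaining pixel data.

    ``patient_meta`` is a dict with patient_id / age_group / sex.  This is
    the memory-friendly path for large cohorts; :func:`generate_cohort`
    materializes the same stream.
    """
    rng = np.random.default_rng(config.seed)
    for p in range(config.n_patients):
        meta = {
            "patient_id": f"P{p:03d}",
            "age_group": AGE_GROUPS[int(rng.choice(len(AGE_GROUPS), p=AGE_PROBS))],
            "sex": "F" if rng.random() < FEMALE_FRACTION else "M",
        }
        style = draw_soz_style(rng, config.n_tiles // 3)
        for k, label in enumerate(_patient_labels(config, rng)):
            m = generate_montage(label, rng, config, patient_style=style)
            ts = generate_timecourse(label, rng, config)
            m.ic_id = f"{meta['patient_id']}_IC{k:03d}"
            m.patient_id = meta["patient_id"]
            ts.ic_id = m.ic_id
            yield meta, m, ts, label


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Materialize a full labeled cohort (see :func:`stream_cohort`)."""
    patients: dict[str, PatientRecord] = {}
    for meta, m, ts, label in stream_cohort(config):
        pid = meta["patient_id"]
        if pid not in patients:
            patients[pid] = PatientRecord(pid, meta["age_group"], meta["sex"])
        patients[pid].ics.append((m, ts, label))
    return SyntheticCohort(config=config, patients=list(patients.values()))


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
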