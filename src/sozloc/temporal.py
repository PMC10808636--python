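"""Temporal expert features of BOLD time courses.

SOZ ICs show a *sparse* low-frequency power spectrum: a handful of dominant
components spread through the 0.01-0.1 Hz band, whereas RSN ICs fill the
band densely and scanner/motion noise is broadband and spiky.  Sparsity is
measured with the Gini index, applied to (a) coefficients of a 4-level
undecimated ("a trous") wavelet decomposition standing in for the activelet
basis, and (b) magnitudes of the in-band Fourier (sine-dictionary)
coefficients, on non-overlapping 256-sample windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: analysis frequency band in Hz (slow BOLD fluctuations)
DEFAULT_BAND = (0.01, 0.1)
#: B-spline biorthogonal wavelet used for the undecimated decomposition.
#: Activelets are exponential-spline wavelets tuned to the hemodynamic
#: response; this spline wavelet preserves the a-trous/4-level structure and
#: the sparsity-measuring role, and is swappable via the ``wavelet`` args.
ACTIVELET_WAVELET = "bior2.2"
ACTIVELET_LEVELS = 4
WINDOW_LEN = 256


@dataclass
class BoldTimecourse:
    """A single IC's BOLD time series (default 600 volumes at TR 2 s)."""

    samples: np.ndarray
    tr_seconds: float = 2.0
    ic_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("time course contains non-finite samples")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class SparsitySummary:
    activelet_gini: float
    sine_gini: float
    n_windows: int
    dominant_frequency_hz: float = field(default=np.nan)


def window_signal(ts: BoldTimecourse, window_len: int = WINDOW_LEN) -> list[np.ndarray]:
    """Split into non-overlapping, mean-centered windows; remainder dropped.

    A 600-sample series yields two 256-sample windows (88 samples dropped).
    """
    x = ts.samples
    if x.size < window_len:
        raise ValueError(
            f"time course of length {x.size} is shorter than window_len={window_len}"
        )
    n = x.size // window_len
    out = []
    for k in range(n):
        w = x[k * window_len : (k + 1) * window_len].astype(float)
        out.append(w - w.mean())
    return out


def activelet_coeffs(
    window: np.ndarray,
    wavelet: str = ACTIVELET_WAVELET,
    levels: int = ACTIVELET_LEVELS,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Undecimated (a-trous) wavelet decomposition of one window.

    Returns the stationary wavelet transform as ``levels`` pairs
    ``(approx, detail)``, coarsest first; every array has the same length as
    the input (shift-invariant), and the transform is linear.
    """
    w = np.asarray(window, dtype=float)
    if w.size % (2**levels) != 0:
        raise ValueError(
            f"window length {w.size} must be divisible by 2^{levels} for swt"
        )
    return pywt.swt(w, wavelet, level=levels)


def activelet_reconstruct(
    coeffs: list[tuple[np.ndarray, np.ndarray]],
    wavelet: str = ACTIVELET_WAVELET,
) -> np.ndarray:
    """Inverse of :func:`activelet_coeffs` (round-trip within ~1e-6)."""
    return pywt.iswt(coeffs, wavelet)


def detail_magnitudes(coeffs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Pool absolute detail coefficients across all levels into one vector."""
    return np.concatenate([np.abs(cd) for _, cd in coeffs])


def sine_coeffs(
    window: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Magnitudes of the Fourier coefficients with frequency inside ``band``.

    For a 256-sample window at TR 2 s and band (0.01, 0.1) Hz the retained
    bins are k = 6..51 (46 bins).
    """
    w = np.asarray(window, dtype=float)
    freqs = np.fft.rfftfreq(w.size, d=tr_seconds)
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < lo < hi")
    nyquist = 0.5 / tr_seconds
    if hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {nyquist} Hz")
    keep = (freqs >= lo) & (freqs <= hi)
    if not np.any(keep):
        raise ValueError("no frequency bins inside the requested band")
    return np.abs(np.fft.rfft(w))[keep]


def in_band_frequencies(
    n: int, tr_seconds: float, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return freqs[(freqs >= band[0]) & (freqs <= band[1])]


def gini_index(values: np.ndarray) -> float:
    """Rank-weighted sparsity Gini of a non-negative vector.

    With ``x`` sorted ascending, ``G = sum_i (2i - n - 1) x_(i) / (n sum x)``;
    0 for a uniform vector, ``(n-1)/n`` for a one-hot vector.  An all-zero
    input is defined as 0 (no energy, maximally dense by convention).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("gini_index requires at least one value")
    if np.any(x < 0):
        raise ValueError("gini_index requires non-negative values")
    total = x.sum()
    if total == 0:
        return 0.0
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float(np.sum((2 * ranks - n - 1) * xs) / (n * total))


def sparsity_summary(
    ts: BoldTimecourse,
    window_len: int = WINDOW_LEN,
    band: tuple[float, float] = DEFAULT_BAND,
    wavelet: str = ACTIVELET_WAVELET,
) -> SparsitySummary:
    """Mean activelet- and sine-dictionary Gini across windows.

    The activelet Gini pools absolute detail coefficients of all four levels
    of each window; the sine Gini is computed over in-band Fourier
    magnitudes.  ``dominant_frequency_hz`` (the in-band argmax frequency,
    averaged over windows) is a diagnostic only and is not part of the
    expert feature vector: at TR 2 s the Nyquist frequency is 0.25 Hz, so no
    supra-Hz dominant-frequency criterion is expressible for this data.
    """
    windows = window_signal(ts, window_len=window_len)
    freqs = in_band_frequencies(window_len, ts.tr_seconds, band)
    a_ginis, s_ginis, dom = [], [], []
    for w in windows:
        coeffs = activelet_coeffs(w, wavelet=wavelet)
        a_ginis.append(gini_index(detail_magnitudes(coeffs)))
        mags = sine_coeffs(w, ts.tr_seconds, band)
        s_ginis.append(gini_index(mags))
        dom.append(freqs[int(np.argmax(mags))] if mags.sum() > 0 else np.nan)
    return SparsitySummary(
        activelet_gini=float(np.mean(a_ginis)),
        sine_gini=float(np.mean(s_ginis)),
        n_windows=len(windows),
        dominant_frequency_hz=float(np.nanmean(dom)) if dom else np.nan,
    )
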