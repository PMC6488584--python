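"""Population synchrony: binarized traces, pairwise Pearson correlation,
and a circular-shift shuffled null.

Active cells' normalized traces are binarized (zero-phase low-pass at
0.3 Hz, 4-frame boxcar smoothing, threshold at baseline + 2 x SD of the
noise band of the original trace) and every unordered pair's Pearson r
over the entire session is computed.  The null model circularly shifts
each cell's binary trace by an independent random offset: every per-cell
marginal statistic (event count, autocovariance) is exactly preserved
while cross-cell timing is destroyed, so an excess of the actual mean r
over the shuffled distribution indicates genuine co-activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .traces import NormalizedTrace

__all__ = [
    "BinaryRaster",
    "CorrelationSet",
    "binarize",
    "pairwise_correlations",
    "shuffled_null",
]

LOWPASS_CUTOFF_HZ = 0.3
SMOOTH_FRAMES = 4
NOISE_K_SD = 2.0


@dataclass
class BinaryRaster:
    """Binarized traces of the active cells of one field of view."""

    cell_ids: list
    raster: np.ndarray  # cells x frames, {0, 1}
    fs: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("raster must be cells x frames")
        if len(self.cell_ids) != self.raster.shape[0]:
            raise ValueError("cell_ids length must match raster rows")
        if not np.all(np.isin(self.raster, (0, 1))):
            raise ValueError("raster must be binary")
        self.raster = self.raster.astype(np.uint8)


@dataclass
class CorrelationSet:
    """Pearson r for every unordered cell pair.

    ``r`` is NaN for pairs involving a constant row (undefined correlation,
    excluded from distributions).  ``shuffled``/``seed`` record provenance.
    """

    pairs: list  # [(cell_a, cell_b), ...]
    r: np.ndarray
    shuffled: bool = False
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_a": [a for a, _ in self.pairs],
            "cell_b": [b for _, b in self.pairs],
            "r": self.r,
            "shuffled": self.shuffled,
            "seed": self.seed,
        })

    def mean_r(self) -> float:
        """Mean r over pairs with defined correlation."""
        valid = self.r[np.isfinite(self.r)]
        return float(valid.mean()) if valid.size else float("nan")


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    b, a = butter(2, cutoff, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise ValueError(f"trace of {x.size} frames is shorter than the "
                         f"filter warm-up length ({padlen + 1})")
    return filtfilt(b, a, x)


def binarize(nt: NormalizedTrace, fs: float, cutoff: float = LOWPASS_CUTOFF_HZ,
             smooth_frames: int = SMOOTH_FRAMES,
             k_noise: float = NOISE_K_SD,
             noise_mode: str = "residual") -> np.ndarray:
    """Binarize one normalized trace for correlation analysis.

    Zero-phase 2nd-order Butterworth low-pass at ``cutoff``, centered
    boxcar average over ``smooth_frames``, then 1 wherever the processed
    trace exceeds ``baseline + k_noise x sd_noise``.  The noise band of the
    original trace is estimated as the SD of (original - low-passed)
    residuals (``noise_mode="residual"``); ``noise_mode="submedian"``
    instead uses the SD of the sub-median values of the original trace.
    """
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    if smooth_frames < 1:
        raise ValueError("smooth_frames must be >= 1")
    low = _lowpass(nt.g, fs, cutoff)
    kernel = np.ones(smooth_frames) / smooth_frames
    smoothed = np.convolve(low, kernel, mode="same")
    if noise_mode == "residual":
        sd_noise = float(np.std(nt.g - low))
    elif noise_mode == "submedian":
        below = nt.g[nt.g < np.median(nt.g)]
        sd_noise = float(np.std(below)) if below.size else 0.0
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    threshold = nt.baseline_level + k_noise * sd_noise
    return (smoothed > threshold).astype(np.uint8)


def _pair_correlations(raster: np.ndarray) -> np.ndarray:
    """Pearson r for all unordered row pairs; NaN where a row is constant."""
    x = raster.astype(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    iu = np.triu_indices(x.shape[0], k=1)
    return c[iu]


def pairwise_correlations(raster: BinaryRaster) -> CorrelationSet:
    """Pearson r over the full binarized traces for every unordered pair."""
    n = raster.raster.shape[0]
    if n < 2:
        raise ValueError("need at least 2 active cells")
    pairs = list(combinations(raster.cell_ids, 2))
    return CorrelationSet(pairs=pairs, r=_pair_correlations(raster.raster))


def shuffled_null(raster: BinaryRaster, seed: int) -> CorrelationSet:
    """Correlations after circularly shifting each row by a random offset.

    Offsets are drawn independently per cell, in cell order, from one
    seeded stream, uniformly from {1, ..., n_frames - 1} (zero excluded so
    every row is displaced).  Rotation preserves each row's event count and
    autocovariance exactly.
    """
    n, n_frames = raster.raster.shape
    if n < 2:
        raise ValueError("need at least 2 active cells")
    rng = np.random.default_rng(seed)
    shifted = np.empty_like(raster.raster)
    for i in range(n):
        offset = int(rng.integers(1, n_frames))
        shifted[i] = np.roll(raster.raster[i], offset)
    pairs = list(combinations(raster.cell_ids, 2))
    return CorrelationSet(pairs=pairs, r=_pair_correlations(shifted),
                          shuffled=True, seed=seed)
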