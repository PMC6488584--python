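"""Raw ROI fluorescence -> normalized traces -> detected calcium transients.

The processing chain follows the standard soma-ROI workflow for slow
calcium indicators:

1. **Neuropil compensation.** A ring around each ROI (its best-fit ellipse
   stretched by a fixed number of pixels, minus all labelled ROIs) samples
   the surrounding neuropil; the ROI trace is corrected with a fixed
   coefficient: ``F_comp = F_roi - 0.7 * (F_np - median(F_np))``.
2. **Normalization.** The trace is divided by F0, the median of all values
   smaller than its 70th percentile.  Note the convention: the trace is
   *divided* by F0 without subtraction, so baseline sits near 1 and
   transients rise above it (many pipelines use (F-F0)/F0 instead).
3. **Transient detection.** A calcium transient is a maximal run of the
   normalized trace above ``baseline + 3 x SD`` lasting at least 10
   consecutive frames (1 s at 10 Hz); a cell is "active" if it has at
   least one transient in the session.

The SD in the detection threshold is, by default, the SD of the entire
normalized trace (the literal rule); a noise-only estimate can be
substituted via ``sd_mode="residual"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "RawRoiTrace",
    "NormalizedTrace",
    "TransientSet",
    "build_neuropil_mask",
    "neuropil_compensate",
    "normalize_trace",
    "detect_transients",
    "process_trace",
]

NEUROPIL_COEFF = 0.7
BASELINE_PERCENTILE = 70.0
DETECTION_K_SD = 3.0
MIN_TRANSIENT_FRAMES = 10
NEUROPIL_STRETCH_PX = 6


@dataclass
class RawRoiTrace:
    """ROI and neuropil fluorescence of one cell in one session."""

    roi_id: str
    session_id: str
    f_roi: np.ndarray  # a.u.
    f_neuropil: np.ndarray  # a.u.
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.f_roi = np.asarray(self.f_roi, dtype=float)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=float)
        if self.f_roi.ndim != 1 or self.f_roi.size == 0:
            raise ValueError("f_roi must be a nonempty 1-D vector")
        if self.f_roi.shape != self.f_neuropil.shape:
            raise ValueError("f_roi and f_neuropil must have the same length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (np.all(np.isfinite(self.f_roi)) and np.all(np.isfinite(self.f_neuropil))):
            raise ValueError("fluorescence values must be finite")


@dataclass
class NormalizedTrace:
    """Baseline-normalized trace: g = f / F0, hovering near 1 at rest."""

    g: np.ndarray
    f0: float
    baseline_level: float  # median of sub-70th-percentile values of g (~1)
    sd_g: float  # SD of the full normalized trace


@dataclass
class TransientSet:
    """Detected supra-threshold epochs of one trace."""

    epochs: list  # [(start, end)) half-open frame intervals, disjoint, ordered
    count: int
    frequency: float  # transients/min
    is_active: bool


def build_neuropil_mask(roi_labels: np.ndarray, target_roi: int,
                        stretch_px: int = NEUROPIL_STRETCH_PX) -> np.ndarray:
    """Neuropil ring for one ROI in a label image.

    The target ROI's pixel set is fitted with an ellipse by second-order
    image moments; the ellipse's semi-axes are stretched by ``stretch_px``
    pixels, and every pixel belonging to the target or to any other
    labelled ROI is removed from the stretched ellipse.  0 is background.
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.ndim != 2:
        raise ValueError("roi_labels must be a 2-D label image")
    target = roi_labels == target_roi
    n_px = int(target.sum())
    if n_px == 0:
        raise ValueError(f"ROI {target_roi!r} not present in label image")
    if n_px < 5:
        raise ValueError(f"ROI {target_roi!r} has {n_px} px; moment fit needs >= 5")
    props = regionprops(target.astype(np.uint8))[0]
    cy, cx = props.centroid
    # regionprops orientation: angle from the row axis toward the column
    # axis; skimage.draw.ellipse rotates the column semi-axis by `rotation`
    # counterclockwise, so the conventions line up with a sign flip.
    r_rad = props.axis_minor_length / 2.0 + stretch_px
    c_rad = props.axis_major_length / 2.0 + stretch_px
    rr, cc = draw_ellipse(cy, cx, r_rad, c_rad, shape=roi_labels.shape,
                          rotation=-props.orientation)
    ring = np.zeros(roi_labels.shape, dtype=bool)
    ring[rr, cc] = True
    ring &= roi_labels == 0
    return ring


def neuropil_compensate(trace: RawRoiTrace, coeff: float = NEUROPIL_COEFF) -> np.ndarray:
    """Subtract the median-centered neuropil signal with a fixed coefficient.

    ``F_comp = F_roi - coeff * (F_np - median(F_np))``; with a constant
    neuropil trace the correction vanishes and the ROI trace is returned
    unchanged.
    """
    return trace.f_roi - coeff * (trace.f_neuropil - np.median(trace.f_neuropil))


def normalize_trace(f_comp: np.ndarray,
                    percentile: float = BASELINE_PERCENTILE) -> NormalizedTrace:
    """Divide a trace by F0 = median of values strictly below its P70.

    The percentile is computed with linear interpolation between order
    statistics.  A trace with no value strictly below the percentile (an
    all-constant trace) takes F0 = that constant, keeping the degenerate
    case total; this is logged.
    """
    f_comp = np.asarray(f_comp, dtype=float)
    if f_comp.ndim != 1 or f_comp.size == 0:
        raise ValueError("trace must be a nonempty 1-D vector")
    p = np.percentile(f_comp, percentile)
    below = f_comp[f_comp < p]
    if below.size == 0:
        f0 = float(f_comp[0])
        logger.warning("trace has no values below its P%.0f (constant?); F0 = %.4g",
                       percentile, f0)
    else:
        f0 = float(np.median(below))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0 = {f0:.4g}: corrupt input")
    g = f_comp / f0
    pg = np.percentile(g, percentile)
    below_g = g[g < pg]
    baseline_level = float(np.median(below_g)) if below_g.size else float(g[0])
    return NormalizedTrace(g=g, f0=f0, baseline_level=baseline_level,
                           sd_g=float(np.std(g)))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_transients(nt: NormalizedTrace, fs: float,
                      k_sd: float = DETECTION_K_SD,
                      min_frames: int = MIN_TRANSIENT_FRAMES,
                      sd_mode: str = "full") -> TransientSet:
    """Find calcium transients: runs of g above baseline + k_sd x SD.

    ``sd_mode="full"`` (default) uses the SD of the whole normalized trace;
    ``sd_mode="residual"`` uses the SD of the sub-baseline-percentile values
    as a noise-only estimate.  Runs shorter than ``min_frames`` are
    discarded; a run touching the end of the trace counts if long enough.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if sd_mode == "full":
        sd = nt.sd_g
    elif sd_mode == "residual":
        p = np.percentile(nt.g, BASELINE_PERCENTILE)
        below = nt.g[nt.g < p]
        sd = float(np.std(below)) if below.size else 0.0
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    threshold = nt.baseline_level + k_sd * sd
    epochs = [(s, e) for s, e in _runs_above(nt.g > threshold) if e - s >= min_frames]
    count = len(epochs)
    minutes = nt.g.size / fs / 60.0
    return TransientSet(epochs=epochs, count=count,
                        frequency=count / minutes, is_active=count >= 1)


def process_trace(trace: RawRoiTrace, coeff: float = NEUROPIL_COEFF,
                  percentile: float = BASELINE_PERCENTILE,
                  k_sd: float = DETECTION_K_SD,
                  min_frames: int = MIN_TRANSIENT_FRAMES) -> tuple[NormalizedTrace, TransientSet]:
    """Convenience chain: compensate -> normalize -> detect."""
    nt = normalize_trace(neuropil_compensate(trace, coeff), percentile)
    ts = detect_transients(nt, trace.fs, k_sd, min_frames)
    return nt, ts
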