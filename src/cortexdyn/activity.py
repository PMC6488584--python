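"""Longitudinal single-cell activity statistics.

Works on a cells x sessions table of calcium-transient frequencies for
neurons reidentified in *every* imaging session.  Provides the standard
descriptive measures of network dynamics: fraction of active cells,
four-way activity categories and their session-to-session transitions,
reoccurrence of active cells (cells staying active in every later
session), per-cell frequency changes, and locomotion-split frequencies
restricted to stationary epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import NormalizedTrace, detect_transients

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "LongitudinalTable",
    "LocomotionTrack",
    "StationaryResult",
    "categorize",
    "fraction_active",
    "transition_counts",
    "silent_conversion_fraction",
    "reoccurrence_rate",
    "per_cell_change",
    "stationary_frequency",
]

# silent: exactly 0/min; rarely active: (0, 0.5]; intermediately active:
# (0.5, 4]; highly active: > 4 transients/min.  Upper bounds inclusive so
# the four classes partition [0, inf).
CATEGORIES = ("silent", "rare", "intermediate", "high")
_RARE_MAX = 0.5
_INTERMEDIATE_MAX = 4.0

MIN_STATIONARY_FRACTION = 0.01  # sessions below 1% stationary time excluded


def categorize(frequency: float) -> str:
    """Map a transient frequency (transients/min) to its activity category."""
    if frequency < 0:
        raise ValueError("frequency must be nonnegative")
    if frequency == 0:
        return "silent"
    if frequency <= _RARE_MAX:
        return "rare"
    if frequency <= _INTERMEDIATE_MAX:
        return "intermediate"
    return "high"


@dataclass
class LongitudinalTable:
    """Cells x sessions record of transient frequencies.

    Only cells reidentified in all sessions are admitted: the frequency
    matrix must be complete.  ``active`` and ``category`` are derived.
    """

    frequency: pd.DataFrame  # index = cell ids, columns = ordered session ids

    def __post_init__(self) -> None:
        if self.frequency.empty:
            raise ValueError("empty table")
        if self.frequency.isna().any().any():
            raise ValueError("frequency table must be complete "
                             "(cells reidentified in all sessions)")
        if (self.frequency < 0).any().any():
            raise ValueError("frequencies must be nonnegative")

    @property
    def cell_ids(self) -> list:
        return list(self.frequency.index)

    @property
    def sessions(self) -> list:
        return list(self.frequency.columns)

    @property
    def active(self) -> pd.DataFrame:
        return self.frequency > 0

    @property
    def category(self) -> pd.DataFrame:
        return self.frequency.map(categorize)


@dataclass
class LocomotionTrack:
    """Per-frame running speed with a stationary flag.

    Frames with speed at or below ``speed_threshold`` count as stationary
    (default 0: only exact rest).
    """

    speed: np.ndarray
    speed_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.speed.ndim != 1 or self.speed.size == 0:
            raise ValueError("speed must be a nonempty 1-D vector")

    @property
    def stationary(self) -> np.ndarray:
        return self.speed <= self.speed_threshold

    @property
    def stationary_fraction(self) -> float:
        return float(self.stationary.mean())


def fraction_active(table: LongitudinalTable, session) -> float:
    """Fraction of cells with at least one transient in the session."""
    if session not in table.frequency.columns:
        raise KeyError(f"session {session!r} not in table")
    return float(table.active[session].mean())


def transition_counts(table: LongitudinalTable, from_session, to_session) -> pd.DataFrame:
    """4x4 category-transition counts between two sessions.

    Entry (a, b) counts cells in category ``a`` at ``from_session`` and
    ``b`` at ``to_session``; row sums equal the category counts at
    ``from_session`` and the grand total equals the number of cells.
    """
    cat = table.category
    for s in (from_session, to_session):
        if s not in cat.columns:
            raise KeyError(f"session {s!r} not in table")
    out = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    tally = pd.crosstab(cat[from_session], cat[to_session])
    for a in tally.index:
        for b in tally.columns:
            out.loc[a, b] = int(tally.loc[a, b])
    return out


def silent_conversion_fraction(table: LongitudinalTable, from_session, to_session) -> float:
    """Fraction of cells silent at ``from_session`` that are intermediately
    active at ``to_session``."""
    cat = table.category
    silent = cat[from_session] == "silent"
    n_silent = int(silent.sum())
    if n_silent == 0:
        raise ValueError(f"no silent cells at session {from_session!r}")
    return float((cat.loc[silent, to_session] == "intermediate").mean())


def reoccurrence_rate(table: LongitudinalTable, start_session) -> pd.Series:
    """Fraction of start-session-active cells still active in *every*
    session up to each later session (cumulative intersection).

    The returned series starts at 1 at ``start_session`` and is monotone
    non-increasing: a cell that skips one session is dropped for all later
    sessions.
    """
    active = table.active
    if start_session not in active.columns:
        raise KeyError(f"session {start_session!r} not in table")
    cols = list(active.columns)
    i0 = cols.index(start_session)
    base = active[start_session]
    n_base = int(base.sum())
    if n_base == 0:
        raise ValueError(f"no active cells at session {start_session!r}")
    running = base.copy()
    out = {}
    for s in cols[i0:]:
        running = running & active[s]
        out[s] = float(running.sum() / n_base)
    return pd.Series(out)


def per_cell_change(table: LongitudinalTable, baseline_session, session) -> pd.Series:
    """Per-cell frequency difference ``session - baseline_session``
    (transients/min); summarize with e.g. the median."""
    for s in (baseline_session, session):
        if s not in table.frequency.columns:
            raise KeyError(f"session {s!r} not in table")
    return table.frequency[session] - table.frequency[baseline_session]


@dataclass
class StationaryResult:
    """Transient frequency during stationary epochs of one session."""

    frequency: float  # transients per stationary minute (NaN if excluded)
    n_transients: int
    stationary_minutes: float
    included: bool  # False if the session fails the minimum-stationary rule


def stationary_frequency(nt: NormalizedTrace, track: LocomotionTrack, fs: float,
                         k_sd: float = 3.0, min_frames: int = 10,
                         min_stationary_fraction: float = MIN_STATIONARY_FRACTION,
                         ) -> StationaryResult:
    """Transient frequency restricted to stationary epochs.

    Transients are detected on the full trace; one is attributed to the
    stationary analysis if its onset frame is stationary.  The rate is the
    attributed count per stationary minute.  Sessions with less than
    ``min_stationary_fraction`` stationary time (default 1%) are excluded:
    flagged in the result, not an error.
    """
    if track.speed.size != nt.g.size:
        raise ValueError("locomotion track and trace lengths differ")
    sf = track.stationary_fraction
    stat_minutes = float(track.stationary.sum()) / fs / 60.0
    if sf < min_stationary_fraction:
        logger.warning("session excluded from stationary analysis: "
                       "stationary fraction %.4f < %.4f", sf, min_stationary_fraction)
        return StationaryResult(frequency=float("nan"), n_transients=0,
                                stationary_minutes=stat_minutes, included=False)
    if stat_minutes == 0:
        raise ValueError("zero stationary frames")
    ts = detect_transients(nt, fs, k_sd=k_sd, min_frames=min_frames)
    n = sum(1 for start, _ in ts.epochs if track.stationary[start])
    return StationaryResult(frequency=n / stat_minutes, n_transients=n,
                            stationary_minutes=stat_minutes, included=True)
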