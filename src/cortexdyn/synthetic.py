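"""Ground-truth-labelled synthetic data for every pipeline stage.

The generators emulate the statistical structure of a longitudinal awake
two-photon calcium-imaging study in mouse motor cortex, plus the histology
and proteomics that accompany it:

* ROI-level GCaMP6s-like fluorescence traces (Poisson event trains
  convolved with a rise/decay kernel, shared neuropil contamination,
  Gaussian shot noise), acquired at 10 Hz for 900 s sessions;
* a genotype-like "affected" cell population whose event rate increases by
  a configurable amount from a configurable session onward;
* locomotion speed traces with a controlled stationary fraction;
* pre/postsynaptic puncta scenes rendered as binary masks with a known
  paired fraction and pairing distance;
* two-group log2 label-free-quantification (LFQ) protein tables with a
  known set of truly regulated proteins and a synapse-annotation flag.

Every generator is deterministic given its seed, and returns the ground
truth needed to score the downstream analysis (event times and rates,
affected flags, punctum pairings, regulated proteins).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .traces import RawRoiTrace
from .synapses import PunctaMask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "calcium_kernel",
    "simulate_traces",
    "simulate_locomotion",
    "simulate_puncta_scene",
    "simulate_proteome",
    "simulate_binary_raster",
    "write_traces_csv",
    "read_traces_csv",
]

# Event-rate strata mirroring the four activity categories used downstream:
# silent (0/min), rarely active (>0-0.5), intermediately active (>0.5-4),
# highly active (>4 transients/min).
STRATUM_NAMES = ("silent", "rare", "intermediate", "high")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic imaging cohort.

    Defaults describe one field of view followed over four weekly sessions:
    150 reidentified cells, 10 Hz acquisition, 900 s per session.  The
    population rate structure is skewed toward low rates, as in
    spontaneous L2/3 activity: roughly a third of cells silent, a third
    rarely active, a third intermediately active and a small sliver highly
    active, with intermediate rates drawn from a truncated exponential so
    most intermediately active cells sit near the lower end of their band.
    ``effect_rate_shift`` is added to the rate of ``affected`` cells from
    ``effect_session`` (0-based) onward, emulating the abrupt activity
    increase of the disease model at the third imaging week.
    """

    n_cells: int = 150
    n_sessions: int = 4
    fs: float = 10.0  # Hz
    duration_s: float = 900.0  # seconds per session
    category_weights: tuple = (0.35, 0.323, 0.325, 0.002)
    # events/min intervals per stratum (silent, rare, intermediate, high)
    rate_ranges: tuple = ((0.0, 0.0), (0.05, 0.5), (0.5, 4.0), (4.0, 5.0))
    intermediate_rate_mean: float = 0.7  # events/min, truncated-exponential mean
    effect_rate_shift: float = 0.5  # events/min added to affected cells
    effect_session: int = 2  # first affected session (0-based; 3rd of 4)
    affected_fraction: float = 0.0
    kernel_tau_rise: float = 0.18  # s
    kernel_tau_decay: float = 1.8  # s
    amplitude_mean: float = 3.0  # peak dF/F of a unitary transient
    noise_sd: float = 0.1  # dF/F units
    neuropil_gain: float = 0.7  # contamination coefficient
    baseline_f: float = 100.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.n_sessions <= 0:
            raise ValueError("n_sessions must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive (zero frames)")
        n_frames = self.fs * self.duration_s
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer frame count")
        w = np.asarray(self.category_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("category_weights must be 4 nonnegative values summing to 1")
        for lo, hi in self.rate_ranges:
            if lo < 0 or hi < lo:
                raise ValueError("rate_ranges must be nonnegative intervals")
        for name in ("kernel_tau_rise", "kernel_tau_decay", "amplitude_mean",
                     "noise_sd", "neuropil_gain", "baseline_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.kernel_tau_rise >= self.kernel_tau_decay:
            raise ValueError("kernel_tau_rise must be smaller than kernel_tau_decay")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be a probability")
        if self.effect_rate_shift < 0:
            raise ValueError("effect_rate_shift must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class GroundTruth:
    """Labels the generators attach to their outputs.

    Only the fields relevant to the producing generator are populated.
    """

    # imaging: event_times[cell][session] -> array of event frame indices
    event_times: list | None = None
    true_rate: np.ndarray | None = None  # cells x sessions, events/min
    affected: np.ndarray | None = None  # bool per cell
    # puncta scenes
    paired_puncta: list | None = None  # list of (pre_id, post_id)
    pre_centroids: np.ndarray | None = None  # um, (n_pre, 2)
    post_centroids: np.ndarray | None = None  # um, (n_post, 2)
    # proteomics: protein id -> "down" | "up"
    de_proteins: dict | None = None


def calcium_kernel(fs: float, tau_rise: float = 0.18, tau_decay: float = 1.8,
                   cut: float = 1e-3) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1.

    k(t) = exp(-t/tau_decay) - exp(-t/tau_rise), truncated once the decay
    term falls below ``cut`` of its peak.  Kinetics default to slow-sensor
    (GCaMP6s-like) values.
    """
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t_end = -tau_decay * np.log(cut)
    t = np.arange(0.0, t_end, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def _draw_rates(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign each cell a stratum and a base event rate (events/min).

    The population rate distribution is strongly right-skewed, as in
    spontaneous L2/3 activity: intermediately active cells draw from a
    truncated exponential (mean ``intermediate_rate_mean``) so most sit
    near the lower end of their band; the rare and high strata draw
    log-uniformly within their ranges.
    """
    strata = rng.choice(4, size=cfg.n_cells, p=np.asarray(cfg.category_weights, float))
    rates = np.zeros(cfg.n_cells)
    for i, s in enumerate(strata):
        lo, hi = cfg.rate_ranges[s]
        if hi <= 0:
            rates[i] = 0.0
        elif hi == lo:
            rates[i] = float(hi)
        elif s == 2:
            while True:
                r = rng.exponential(cfg.intermediate_rate_mean)
                if lo < r <= hi:
                    rates[i] = float(r)
                    break
        elif lo <= 0:
            rates[i] = rng.uniform(lo, hi)
        else:
            rates[i] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return strata, rates


def simulate_traces(config: SimulationConfig) -> tuple[list[list[RawRoiTrace]], GroundTruth]:
    """Simulate ROI + neuropil fluorescence for a longitudinal cohort.

    Returns ``traces[cell][session]`` (a :class:`RawRoiTrace` each) and the
    ground truth (event frames, true rates in events/min, affected flags).

    Per cell and session, event frames are a Poisson process at the cell's
    stratum rate (plus ``effect_rate_shift`` for affected cells from the
    effect session onward).  The ROI trace is

        baseline_f * (1 + sum of events (x) kernel + noise)
                   + neuropil_gain * neuropil fluctuation,

    where the neuropil trace is a shared slow sinusoid-plus-noise per field
    of view, so that the fixed-coefficient compensation step downstream is
    exercised non-trivially.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    kernel = calcium_kernel(config.fs, config.kernel_tau_rise, config.kernel_tau_decay)
    strata, base_rates = _draw_rates(config, rng)
    affected = rng.random(config.n_cells) < config.affected_fraction

    event_times: list[list[np.ndarray]] = [[] for _ in range(config.n_cells)]
    true_rate = np.zeros((config.n_cells, config.n_sessions))
    traces: list[list[RawRoiTrace]] = [[] for _ in range(config.n_cells)]

    minutes = config.duration_s / 60.0
    t = np.arange(n_frames) / config.fs
    for s in range(config.n_sessions):
        # shared neuropil fluctuation for this session's field of view:
        # a slow drifting sinusoid plus its own noise, in dF/F-like units
        period = rng.uniform(20.0, 60.0)
        phase = rng.uniform(0, 2 * np.pi)
        np_fluct = 0.05 * np.sin(2 * np.pi * t / period + phase)
        np_trace = config.baseline_f * (
            1.0 + np_fluct + rng.normal(0.0, config.noise_sd / 2.0, n_frames)
        )
        for c in range(config.n_cells):
            rate = base_rates[c]
            if affected[c] and s >= config.effect_session:
                rate = rate + config.effect_rate_shift
            true_rate[c, s] = rate
            lam = rate * minutes
            n_ev = rng.poisson(lam) if lam > 0 else 0
            ev = np.sort(rng.integers(0, n_frames, size=n_ev)) if n_ev else np.empty(0, int)
            event_times[c].append(ev.astype(int))
            signal = np.zeros(n_frames)
            if n_ev:
                impulses = np.zeros(n_frames)
                np.add.at(impulses, ev, config.amplitude_mean)
                signal = np.convolve(impulses, kernel)[:n_frames]
            noise = rng.normal(0.0, config.noise_sd, n_frames) if config.noise_sd > 0 else 0.0
            f_roi = config.baseline_f * (1.0 + signal + noise) \
                + config.neuropil_gain * (np_trace - np.median(np_trace))
            traces[c].append(RawRoiTrace(
                roi_id=f"cell{c:04d}", session_id=f"s{s}",
                f_roi=f_roi, f_neuropil=np_trace.copy(), fs=config.fs,
            ))
    gt = GroundTruth(event_times=event_times, true_rate=true_rate, affected=affected)
    return traces, gt


def simulate_locomotion(n_frames: int, stationary_fraction: float,
                        seed: int = 0) -> np.ndarray:
    """Per-frame running speed with a controlled stationary fraction.

    The track alternates bouts of zero speed and positive speed (log-normal
    magnitudes, cm/s-like scale).  The number of stationary frames is fixed
    exactly at ``round(stationary_fraction * n_frames)`` and distributed
    over randomly placed bouts, so the empirical fraction is within one
    frame of the request.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not 0.0 <= stationary_fraction <= 1.0:
        raise ValueError("stationary_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_stat = int(round(stationary_fraction * n_frames))
    stationary = np.zeros(n_frames, dtype=bool)
    if n_stat > 0:
        # split the stationary budget into a handful of bouts and place them
        n_bouts = max(1, min(n_stat, 1 + n_frames // 600))
        cuts = np.sort(rng.choice(np.arange(1, n_stat), size=n_bouts - 1,
                                  replace=False)) if n_bouts > 1 else np.empty(0, int)
        lengths = np.diff(np.concatenate(([0], cuts, [n_stat])))
        starts = np.sort(rng.choice(n_frames, size=n_bouts, replace=False))
        pos = 0
        for start, length in zip(starts, lengths):
            start = max(start, pos)
            if start >= n_frames:
                start = n_frames - 1
            end = min(start + int(length), n_frames)
            stationary[start:end] = True
            pos = end
        # top up / trim to hit the exact budget
        deficit = n_stat - int(stationary.sum())
        if deficit > 0:
            free = np.flatnonzero(~stationary)
            stationary[free[:deficit]] = True
        elif deficit < 0:
            occ = np.flatnonzero(stationary)
            stationary[occ[:(-deficit)]] = False
    speed = rng.lognormal(mean=1.0, sigma=0.5, size=n_frames) + 0.5
    speed[stationary] = 0.0
    return speed


def _place_points(rng: np.random.Generator, n: int, field_size: float,
                  margin: float, min_sep: float,
                  existing: np.ndarray | None = None,
                  max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n points with pairwise separation >= min_sep."""
    pts: list[np.ndarray] = []
    ref = [] if existing is None else [existing]
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place puncta at the requested density without "
                "violating separation constraints")
        p = rng.uniform(margin, field_size - margin, size=2)
        others = np.concatenate(ref + [np.array(pts).reshape(-1, 2)]) \
            if (ref or pts) else np.empty((0, 2))
        if others.size and np.min(np.hypot(*(others - p).T)) < min_sep:
            continue
        pts.append(p)
    return np.array(pts).reshape(-1, 2)


def simulate_puncta_scene(n_pre: int, n_post: int, paired_fraction: float,
                          pair_distance_max: float = 1.0,
                          field_size: float = 50.0, pixel_size: float = 0.1,
                          punctum_radius_px: int = 2,
                          seed: int = 0) -> tuple[PunctaMask, PunctaMask, GroundTruth]:
    """Render a pre/postsynaptic puncta scene with known pairing.

    ``paired_fraction`` of the pre puncta receive a post partner whose
    centroid lies well inside ``pair_distance_max`` (µm); every other
    pre/post centroid pair is kept beyond 2x that distance, so re-measuring
    the rendered masks recovers the constructed pairing exactly.  Puncta are
    drawn as filled disks of ``punctum_radius_px`` pixels (>= 3 px area), on
    a ``field_size`` µm square field at ``pixel_size`` µm/px.
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must be a probability")
    if pair_distance_max >= field_size:
        raise ValueError("pair_distance_max must be smaller than field_size")
    if n_post < int(round(paired_fraction * n_pre)):
        raise ValueError("not enough post puncta for the requested paired fraction")
    rng = np.random.default_rng(seed)
    n_paired = int(round(paired_fraction * n_pre))
    sep = 2.0 * pair_distance_max + 2.0 * punctum_radius_px * pixel_size
    margin = sep

    pre = _place_points(rng, n_pre, field_size, margin, sep)
    paired_ids = rng.choice(n_pre, size=n_paired, replace=False)
    post_pts: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    for j, pid in enumerate(sorted(paired_ids)):
        # keep the partner clearly inside the pairing distance so that
        # rasterization cannot push it over the boundary
        r = rng.uniform(0.25, 0.8) * pair_distance_max
        th = rng.uniform(0, 2 * np.pi)
        post_pts.append(pre[pid] + r * np.array([np.cos(th), np.sin(th)]))
        pairs.append((int(pid), j))
    n_unpaired_post = n_post - n_paired
    if n_unpaired_post > 0:
        blockers = np.concatenate([pre, np.array(post_pts).reshape(-1, 2)])
        extra = _place_points(rng, n_unpaired_post, field_size, margin, sep,
                              existing=blockers)
        post_pts.extend(extra)
    post = np.array(post_pts).reshape(-1, 2)

    def render(points: np.ndarray, label: str) -> PunctaMask:
        n_px = int(round(field_size / pixel_size))
        img = np.zeros((n_px, n_px), dtype=bool)
        yy, xx = np.mgrid[0:n_px, 0:n_px]
        for x_um, y_um in points:
            cx, cy = x_um / pixel_size, y_um / pixel_size
            sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= punctum_radius_px ** 2
            img |= sel
        return PunctaMask(image=img, pixel_size=pixel_size, channel_label=label)

    gt = GroundTruth(paired_puncta=pairs, pre_centroids=pre, post_centroids=post)
    return render(pre, "pre"), render(post, "post"), gt


def simulate_proteome(n_proteins: int = 2000, n_synaptic: int = 160,
                      n_per_group: int = 8, frac_synaptic_down: float = 0.10,
                      frac_background_down: float = 0.04,
                      effect_log2: float = 1.0, noise_sd: float = 0.3,
                      seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-group log2 LFQ table with known regulated proteins.

    Returns a tidy protein table (rows = proteins) with per-sample log2
    intensity columns ``a1..a<n>``/``b1..b<n>`` and an ``is_synaptic``
    flag, plus the ground-truth map of truly shifted proteins.  Designated
    "down" proteins are reduced by ``effect_log2`` in group b; per-protein
    mean intensities are Gaussian around a realistic LFQ center (~25).
    """
    if n_synaptic > n_proteins:
        raise ValueError("n_synaptic cannot exceed n_proteins")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if noise_sd <= 0 and effect_log2 == 0:
        warnings.warn("degenerate proteome simulation: no noise and no effect")
    rng = np.random.default_rng(seed)
    ids = np.array([f"P{i:05d}" for i in range(n_proteins)])
    is_syn = np.zeros(n_proteins, dtype=bool)
    is_syn[rng.choice(n_proteins, size=n_synaptic, replace=False)] = True

    down = np.zeros(n_proteins, dtype=bool)
    if effect_log2 != 0:
        u = rng.random(n_proteins)
        down = np.where(is_syn, u < frac_synaptic_down, u < frac_background_down)
    means = rng.normal(25.0, 2.0, size=n_proteins)
    shift = np.where(down, -effect_log2, 0.0)
    a = means[:, None] + rng.normal(0.0, noise_sd, (n_proteins, n_per_group))
    b = (means + shift)[:, None] + rng.normal(0.0, noise_sd, (n_proteins, n_per_group))
    cols_a = [f"a{i+1}" for i in range(n_per_group)]
    cols_b = [f"b{i+1}" for i in range(n_per_group)]
    table = pd.DataFrame(np.hstack([a, b]), index=ids, columns=cols_a + cols_b)
    table.index.name = "protein_id"
    table["is_synaptic"] = is_syn
    de = {pid: "down" for pid in ids[down]}
    return table, GroundTruth(de_proteins=de)


def simulate_binary_raster(n_cells: int, n_frames: int, rate_per_min: float,
                           fs: float = 10.0, event_frames: int = 10,
                           shared_fraction: float = 0.0,
                           shared_rate_per_min: float = 0.0,
                           seed: int = 0) -> np.ndarray:
    """Binary cells x frames raster of fixed-length activity blocks.

    Each cell gets Poisson-placed 1-blocks of ``event_frames`` frames;
    the first ``shared_fraction`` of cells additionally receive blocks at
    common event times (a shared drive), producing genuinely synchronous
    rows for null-model calibration.
    """
    rng = np.random.default_rng(seed)
    minutes = n_frames / fs / 60.0
    raster = np.zeros((n_cells, n_frames), dtype=np.uint8)

    def stamp(row: np.ndarray, starts: np.ndarray) -> None:
        for st in starts:
            row[st:st + event_frames] = 1

    shared_starts = rng.integers(
        0, max(1, n_frames - event_frames),
        size=rng.poisson(shared_rate_per_min * minutes)) if shared_rate_per_min > 0 else []
    n_shared = int(round(shared_fraction * n_cells))
    for c in range(n_cells):
        n_ev = rng.poisson(rate_per_min * minutes)
        starts = rng.integers(0, max(1, n_frames - event_frames), size=n_ev)
        stamp(raster[c], starts)
        if c < n_shared and len(shared_starts):
            jitter = rng.integers(-2, 3, size=len(shared_starts))
            stamp(raster[c], np.clip(np.asarray(shared_starts) + jitter, 0,
                                     n_frames - event_frames))
    return raster


# ---------------------------------------------------------------------------
# on-disk formats: wide CSV of traces and a JSON ground-truth sidecar

def write_traces_csv(path, traces: Sequence[Sequence[RawRoiTrace]], session: int) -> None:
    """Write one session as a wide CSV: frame rows, ``<roi>`` and ``<roi>_np``
    columns per cell."""
    data = {}
    for per_cell in traces:
        tr = per_cell[session]
        data[tr.roi_id] = tr.f_roi
        data[f"{tr.roi_id}_np"] = tr.f_neuropil
    pd.DataFrame(data).to_csv(path, index_label="frame")


def read_traces_csv(path, fs: float, session_id: str = "s0") -> list[RawRoiTrace]:
    """Read the wide trace CSV back into :class:`RawRoiTrace` objects."""
    df = pd.read_csv(path, index_col=0)
    rois = [c for c in df.columns if not c.endswith("_np")]
    out = []
    for roi in rois:
        np_col = f"{roi}_np"
        if np_col not in df.columns:
            raise ValueError(f"missing neuropil column for ROI {roi!r}")
        out.append(RawRoiTrace(roi_id=roi, session_id=session_id,
                               f_roi=df[roi].to_numpy(float),
                               f_neuropil=df[np_col].to_numpy(float), fs=fs))
    return out


def write_ground_truth(path, gt: GroundTruth) -> None:
    """JSON sidecar for a generated dataset (arrays become lists)."""
    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (list, tuple)):
            return [convert(o) for o in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj
    with open(path, "w") as fh:
        json.dump({k: convert(v) for k, v in asdict(gt).items() if v is not None},
                  fh, indent=1)
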