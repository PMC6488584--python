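"""End-to-end synthetic study: two genotype-like cohorts over four sessions.

``run_study`` generates a wildtype-like cohort (no rate shift) and an
affected cohort (a configurable fraction of cells gaining
``effect_rate_shift`` transients/min from the effect session onward),
runs the full trace -> activity -> synchrony chain on both, optionally a
proteome differential analysis, and writes tidy CSV summaries plus a
machine-readable manifest of every seed and parameter, so any stage can
be re-run in isolation with identical outputs.

Randomness is organized as one seeded root stream forked into labelled
substreams (one per cohort/stage), keeping stages independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, proteome as prot
from .activity import (LongitudinalTable, fraction_active, per_cell_change,
                       reoccurrence_rate, transition_counts)
from .synchrony import BinaryRaster, binarize, pairwise_correlations, shuffled_null
from .traces import process_trace

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study"]

_STAGE_SEEDS = ("wt_traces", "hd_traces", "synchrony", "proteome")


@dataclass
class StudyConfig:
    """Everything a study run depends on.

    ``simulation`` parameterizes both cohorts; the wildtype cohort is the
    same configuration with ``affected_fraction`` forced to 0.
    """

    simulation: synthetic.SimulationConfig = field(
        default_factory=lambda: synthetic.SimulationConfig(affected_fraction=0.8))
    percentile: float = 70.0
    k_sd: float = 3.0
    min_frames: int = 10
    neuropil_coeff: float = 0.7
    cutoff_hz: float = 0.3
    smooth_frames: int = 4
    k_noise: float = 2.0
    n_shuffles: int = 20
    max_sync_cells: int = 100  # cap on cells entering the pairwise analysis
    with_proteome: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed (< 2**31)."""
        idx = _STAGE_SEEDS.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGE_SEEDS))[idx]
        return int(child.generate_state(1)[0] % (2 ** 31))


def _cohort_table(cfg: StudyConfig, sim: synthetic.SimulationConfig
                  ) -> tuple[LongitudinalTable, list, synthetic.GroundTruth]:
    traces, gt = synthetic.simulate_traces(sim)
    sessions = [f"s{j}" for j in range(sim.n_sessions)]
    freq = {}
    nts_last = []
    for per_cell in traces:
        fr = []
        for tr in per_cell:
            nt, ts = process_trace(tr, coeff=cfg.neuropil_coeff,
                                   percentile=cfg.percentile,
                                   k_sd=cfg.k_sd, min_frames=cfg.min_frames)
            fr.append(ts.frequency)
            if tr.session_id == sessions[-1]:
                nts_last.append((tr.roi_id, nt, ts.is_active))
        freq[per_cell[0].roi_id] = fr
    table = LongitudinalTable(pd.DataFrame.from_dict(freq, orient="index",
                                                     columns=sessions))
    return table, nts_last, gt


def _synchrony_summary(cfg: StudyConfig, nts_last: list, fs: float,
                       seed: int) -> dict:
    active = [(rid, nt) for rid, nt, is_act in nts_last if is_act]
    active = active[:cfg.max_sync_cells]
    if len(active) < 2:
        return {"n_cells": len(active), "mean_r": float("nan"),
                "mean_r_shuffled": float("nan")}
    rows = np.stack([binarize(nt, fs, cutoff=cfg.cutoff_hz,
                              smooth_frames=cfg.smooth_frames,
                              k_noise=cfg.k_noise) for _, nt in active])
    raster = BinaryRaster(cell_ids=[rid for rid, _ in active], raster=rows, fs=fs)
    actual = pairwise_correlations(raster)
    rng = np.random.default_rng(seed)
    shuf_means = [shuffled_null(raster, int(rng.integers(2 ** 31))).mean_r()
                  for _ in range(cfg.n_shuffles)]
    return {"n_cells": len(active), "mean_r": actual.mean_r(),
            "mean_r_shuffled": float(np.nanmean(shuf_means))}


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full synthetic study and write its report bundle.

    Writes per-cohort frequency tables, per-session summary metrics,
    category-transition matrices, the reoccurrence curve, a synchrony
    summary, optional proteome results, and ``manifest.json``.  Returns the
    summary dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = {}
    sim = config.simulation
    for name, frac, stage in (("wt", 0.0, "wt_traces"),
                              ("hd", sim.affected_fraction, "hd_traces")):
        cohort_sim = dataclasses.replace(sim, affected_fraction=frac,
                                         seed=config.stage_seed(stage))
        logger.info("simulating + processing cohort %s (%d cells, %d sessions)",
                    name, cohort_sim.n_cells, cohort_sim.n_sessions)
        table, nts_last, gt = _cohort_table(config, cohort_sim)
        cohorts[name] = (table, nts_last, gt)
        table.frequency.to_csv(out / f"{name}_frequency.csv", index_label="cell_id")

    summary: dict = {"sessions": {}, "cohorts": {}}
    for name, (table, nts_last, gt) in cohorts.items():
        sessions = table.sessions
        per_session = pd.DataFrame({
            "fraction_active": [fraction_active(table, s) for s in sessions],
            "median_frequency": table.frequency.median(axis=0).to_numpy(),
        }, index=pd.Index(sessions, name="session"))
        per_session.to_csv(out / f"{name}_session_metrics.csv")
        trans_frames = []
        for a, b in zip(sessions[:-1], sessions[1:]):
            t = transition_counts(table, a, b)
            t.insert(0, "from_session", a)
            t.insert(1, "to_session", b)
            trans_frames.append(t.rename_axis("from_category").reset_index())
        pd.concat(trans_frames).to_csv(out / f"{name}_transitions.csv", index=False)
        reocc = reoccurrence_rate(table, sessions[0])
        reocc.rename("reoccurrence").to_csv(out / f"{name}_reoccurrence.csv",
                                            index_label="session")
        pre = sessions[max(0, sim.effect_session - 1)]
        post = sessions[min(len(sessions) - 1, sim.effect_session)]
        change = per_cell_change(table, pre, post)
        sync = _synchrony_summary(config, nts_last, sim.fs,
                                  config.stage_seed("synchrony"))
        summary["cohorts"][name] = {
            "fraction_active": per_session["fraction_active"].to_dict(),
            "median_change_pre_post": float(change.median()),
            "synchrony": sync,
        }

    if config.with_proteome:
        ptable_df, pgt = synthetic.simulate_proteome(
            seed=config.stage_seed("proteome"))
        n = sum(c.startswith("a") for c in ptable_df.columns if c != "is_synaptic")
        groups = {c: ("wt" if c.startswith("a") else "hd")
                  for c in ptable_df.columns if c != "is_synaptic"}
        ptable = prot.ProteinTable.from_frame(ptable_df, groups)
        diff = prot.differential(ptable, "wt", "hd",
                                 seed=config.stage_seed("proteome"))
        diff.table.to_csv(out / "proteome_differential.csv", index_label="protein_id")
        syn_ids = set(ptable.is_synaptic.index[ptable.is_synaptic])
        n_down, n_up, n_tot, pct_down, pct_up = prot.fraction_regulated(diff, syn_ids)
        enr = prot.fisher_enrichment(n_down, n_up, n_tot)
        summary["proteome"] = {
            "n_synaptic": n_tot, "n_down": n_down, "n_up": n_up,
            "pct_down": pct_down, "pct_up": pct_up,
            "fisher_p": enr.p_value,
            "n_true_down": len(pgt.de_proteins),
        }

    manifest = {
        "config": _serializable(asdict(config)),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_SEEDS},
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".csv"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(_serializable(summary), fh, indent=1, sort_keys=True)
    return summary


def _serializable(obj):
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
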