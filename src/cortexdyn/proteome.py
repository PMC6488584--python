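"""Differential statistics for log2 LFQ proteome tables.

Implements the volcano-plot machinery of label-free quantitative
proteomics: an s0-moderated two-sample statistic with permutation-based
false-discovery-rate (FDR) control, subset regulation fractions with a
two-sided Fisher exact comparison of down- vs up-regulated proportions,
and extraction of the "main PCA drivers" — the proteins with the largest
loadings on the principal component separating a sample group.

The moderated statistic is d = (mean_b - mean_a) / (se + s0), where se is
the pooled two-sample standard error and s0 (default 0.1) damps the
significance of tiny-variance proteins.  q-values are estimated from
label permutations: at each |d| threshold, the median permuted exceedance
count over the observed exceedance count, then monotonized so q is
non-increasing in |d|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinTable",
    "DiffResult",
    "EnrichmentResult",
    "PcaDrivers",
    "differential",
    "fraction_regulated",
    "fisher_enrichment",
    "pca_drivers",
]

DEFAULT_S0 = 0.1
DEFAULT_N_PERM = 1000
DEFAULT_Q_CUTOFF = 0.05
N_DRIVERS = 25


@dataclass
class ProteinTable:
    """Proteins x samples log2 LFQ matrix with group labels and a
    synapse-annotation flag."""

    log2_lfq: pd.DataFrame  # index = protein ids, columns = sample names
    group: pd.Series  # sample -> group label
    is_synaptic: pd.Series  # protein -> bool

    def __post_init__(self) -> None:
        if not self.group.index.equals(self.log2_lfq.columns):
            self.group = self.group.reindex(self.log2_lfq.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        self.is_synaptic = self.is_synaptic.reindex(self.log2_lfq.index).fillna(False)
        counts = self.group.value_counts()
        if (counts < 2).any():
            raise ValueError("every group needs at least 2 samples")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_map: dict) -> "ProteinTable":
        """Build from a tidy frame with sample columns + an ``is_synaptic``
        column (as written by the proteome simulator)."""
        is_syn = df["is_synaptic"].astype(bool)
        lfq = df.drop(columns=["is_synaptic"])
        return cls(log2_lfq=lfq, group=pd.Series(group_map), is_synaptic=is_syn)

    def samples_of(self, label) -> list:
        return list(self.group.index[self.group == label])


@dataclass
class DiffResult:
    """Per-protein moderated statistic, q-value and direction."""

    table: pd.DataFrame  # columns: mean_diff, d_stat, q_value, direction
    group_a: str
    group_b: str
    s0: float
    q_cutoff: float
    n_dropped: int  # proteins removed for missing values

    def ids_with_direction(self, direction: str) -> set:
        return set(self.table.index[self.table["direction"] == direction])


def _moderated_d(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """s0-moderated statistic per row of two proteins x samples blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return (mb - ma) / (se + s0)


def _label_permutations(na: int, nb: int, n_perm: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays assigning na of the na+nb samples to group a.

    All distinct assignments are enumerated when there are no more than
    ``n_perm``; otherwise ``n_perm`` random assignments are drawn.
    The identity assignment is excluded from the null.
    """
    n = na + nb
    from math import comb
    total = comb(n, na)
    identity = tuple(range(na))
    perms: list[np.ndarray] = []
    if total - 1 <= n_perm:
        for c in combinations(range(n), na):
            if c == identity:
                continue
            perms.append(np.array(c))
    else:
        seen = {identity}
        while len(perms) < n_perm:
            c = tuple(sorted(rng.choice(n, size=na, replace=False)))
            if c in seen:
                continue
            seen.add(c)
            perms.append(np.array(c))
    return perms


def differential(table: ProteinTable, group_a, group_b, s0: float = DEFAULT_S0,
                 n_perm: int = DEFAULT_N_PERM, q_cutoff: float = DEFAULT_Q_CUTOFF,
                 seed: int = 0) -> DiffResult:
    """Two-group differential analysis with permutation FDR.

    ``mean_diff`` is group_b minus group_a (log2 units), so "down" means
    lower in group_b.  Proteins with any missing value in either group are
    dropped (complete-case policy) and counted in ``n_dropped``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    sa = table.samples_of(group_a)
    sb = table.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need at least 2 samples")
    sub = table.log2_lfq[sa + sb]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("dropped %d proteins with missing values", n_dropped)
    x = complete.to_numpy(float)
    na = len(sa)
    d_obs = _moderated_d(x[:, :na], x[:, na:], s0)

    rng = np.random.default_rng(seed)
    perms = _label_permutations(na, len(sb), n_perm, rng)
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs)[::-1]  # descending |d|
    thresholds = abs_obs[order]
    # observed exceedances at each protein's own |d| threshold
    obs_counts = np.arange(1, len(thresholds) + 1)
    all_idx = np.arange(x.shape[1])
    exceed = np.empty((len(perms), len(thresholds)))
    sorted_thr = thresholds[::-1]  # ascending for searchsorted
    for k, pa in enumerate(perms):
        pb = np.setdiff1d(all_idx, pa, assume_unique=True)
        d_perm = np.abs(_moderated_d(x[:, pa], x[:, pb], s0))
        # count of |d_perm| >= each threshold
        cnt = len(d_perm) - np.searchsorted(np.sort(d_perm), sorted_thr, side="left")
        exceed[k] = cnt[::-1]
    fp = np.median(exceed, axis=0)
    fdr = np.clip(fp / obs_counts, 0.0, 1.0)
    # q-value: best achievable FDR at any threshold still including the
    # protein, i.e. cumulative minimum from the small-|d| side
    q_desc = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_desc)
    q[order] = q_desc

    mean_diff = x[:, na:].mean(axis=1) - x[:, :na].mean(axis=1)
    direction = np.where(q < q_cutoff,
                         np.where(mean_diff < 0, "down", "up"), "unchanged")
    res = pd.DataFrame({"mean_diff": mean_diff, "d_stat": d_obs,
                        "q_value": q, "direction": direction},
                       index=complete.index)
    return DiffResult(table=res, group_a=str(group_a), group_b=str(group_b),
                      s0=s0, q_cutoff=q_cutoff, n_dropped=n_dropped)


def fraction_regulated(diff: DiffResult, subset: set) -> tuple[int, int, int, float, float]:
    """Counts and percentages of down-/up-regulated proteins in a subset.

    Returns ``(n_down, n_up, n_total, pct_down, pct_up)`` with percentages
    on the 0-100 scale.
    """
    subset = set(subset)
    present = subset & set(diff.table.index)
    if not present:
        raise ValueError("subset is empty or disjoint from the result table")
    missing = subset - present
    if missing:
        logger.info("%d subset proteins absent from the result table", len(missing))
    sub = diff.table.loc[sorted(present)]
    n_total = len(sub)
    n_down = int((sub["direction"] == "down").sum())
    n_up = int((sub["direction"] == "up").sum())
    return (n_down, n_up, n_total,
            100.0 * n_down / n_total, 100.0 * n_up / n_total)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2 counts
    odds_ratio: float
    p_value: float


def fisher_enrichment(n_down_in: int, n_up_in: int, n_total: int) -> EnrichmentResult:
    """Two-sided Fisher exact test comparing the down- vs up-regulated
    proportions of one protein set.

    The 2x2 table is ``[[n_down, n_total - n_down], [n_up, n_total - n_up]]``;
    the two-sided p sums the probabilities of all hypergeometric outcomes
    no more likely than the observed table.
    """
    if min(n_down_in, n_up_in, n_total) < 0:
        raise ValueError("counts must be nonnegative")
    if n_down_in > n_total or n_up_in > n_total:
        raise ValueError("class counts cannot exceed the set size")
    tab = np.array([[n_down_in, n_total - n_down_in],
                    [n_up_in, n_total - n_up_in]])
    odds, p = fisher_exact(tab, alternative="two-sided")
    return EnrichmentResult(table=tab, odds_ratio=float(odds), p_value=float(p))


@dataclass
class PcaDrivers:
    """Sample scores, protein loadings and the top-k driver lists of the
    separating component (oriented so the group of interest scores
    positively; "down" drivers have the most negative loadings)."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    component: int  # index of the separating component
    top_down: list
    top_up: list


def pca_drivers(table: ProteinTable, group_of_interest, k: int = N_DRIVERS) -> PcaDrivers:
    """PCA main drivers of a group's separation.

    Proteins are centered (not variance-scaled: LFQ intensities share a
    scale) and a full PCA is taken over samples.  The separating component
    is the one whose sample scores best discriminate the group of interest
    from the rest (largest standardized score difference); it is oriented
    so the group of interest scores positively, and the k most negative /
    most positive loadings become ``top_down`` / ``top_up``.
    """
    complete = table.log2_lfq.dropna()
    x = complete.to_numpy(float).T  # samples x proteins
    n_samples, n_proteins = x.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    if k > n_proteins:
        raise ValueError(f"k = {k} exceeds the {n_proteins} complete-case proteins")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s  # samples x components
    in_group = (table.group == group_of_interest).to_numpy()
    if in_group.sum() == 0 or in_group.sum() == n_samples:
        raise ValueError("group_of_interest must split the samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        gap = np.abs(scores[in_group].mean(axis=0) - scores[~in_group].mean(axis=0)) \
            / scores.std(axis=0)
    comp = int(np.nanargmax(gap))
    sign = 1.0 if scores[in_group, comp].mean() >= scores[~in_group, comp].mean() else -1.0
    scores = scores.copy()
    scores[:, comp] *= sign
    loadings = vt.T.copy()  # proteins x components
    loadings[:, comp] *= sign
    load = loadings[:, comp]
    asc = np.argsort(load)
    top_down = list(complete.index[asc[:k]])
    top_up = list(complete.index[asc[::-1][:k]])
    comp_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PcaDrivers(
        scores=pd.DataFrame(scores, index=complete.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=complete.index, columns=comp_names),
        component=comp, top_down=top_down, top_up=top_up)
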