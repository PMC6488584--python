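"""Differential statistics, enrichment and PCA drivers."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from cortexdyn.proteome import (
    ProteinTable,
    differential,
    fisher_enrichment,
    fraction_regulated,
    pca_drivers,
)
from cortexdyn.synthetic import simulate_proteome


def _table(a, b, ids=None, synaptic=None):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n = a.shape[0]
    ids = ids or [f"P{i}" for i in range(n)]
    cols = [f"a{i}" for i in range(a.shape[1])] + [f"b{i}" for i in range(b.shape[1])]
    lfq = pd.DataFrame(np.hstack([a, b]), index=ids, columns=cols)
    group = pd.Series({c: c[0] for c in cols})
    syn = pd.Series(synaptic if synaptic is not None else [False] * n, index=ids)
    return ProteinTable(log2_lfq=lfq, group=group, is_synaptic=syn)


class TestDifferential:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        block = rng.normal(25, 1, (50, 4))
        t = _table(block, block)
        res = differential(t, "a", "b", seed=1)
        assert np.allclose(res.table["mean_diff"], 0.0)
        assert (res.table["direction"] == "unchanged").all()

    def test_moderated_statistic_zero_variance(self):
        # means 2,2 vs 0,0: se = 0, d = -2 / s0 = -20 (b minus a)
        t = _table([[2.0, 2.0]], [[0.0, 0.0]])
        res = differential(t, "a", "b", s0=0.1, n_perm=10, seed=0)
        assert res.table["d_stat"].iloc[0] == pytest.approx(-20.0)

    def test_direction_follows_sign_and_cutoff(self):
        rng = np.random.default_rng(2)
        x = rng.normal(25, 0.3, (200, 6))
        y = x.copy()
        y[:10, :] -= 2.0  # strongly down in group b
        t = _table(x, y)
        res = differential(t, "a", "b", seed=3)
        sig = res.table.iloc[:10]
        assert (sig["q_value"] < 0.05).all()
        assert (sig["direction"] == "down").all()
        assert (res.table.iloc[10:]["direction"] == "unchanged").mean() > 0.95

    def test_label_swap_equivariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(25, 0.5, (30, 4)), rng.normal(25, 0.5, (30, 4))
        t = _table(x, y)
        ab = differential(t, "a", "b", seed=5)
        ba = differential(t, "b", "a", seed=5)
        assert np.allclose(ab.table["d_stat"], -ba.table["d_stat"])
        assert np.allclose(ab.table["q_value"], ba.table["q_value"])

    def test_missing_values_dropped(self):
        x = np.full((3, 4), 25.0)
        t = _table(x, x)
        t.log2_lfq.iloc[0, 0] = np.nan
        res = differential(t, "a", "b", n_perm=10, seed=0)
        assert res.n_dropped == 1
        assert len(res.table) == 2

    def test_too_few_permutations_rejected(self):
        t = _table(np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            differential(t, "a", "b", n_perm=5)

    def test_recovery_on_simulated_proteome(self):
        tab, gt = simulate_proteome(n_proteins=2000, n_synaptic=651,
                                    n_per_group=8, effect_log2=1.0,
                                    noise_sd=0.3, seed=7)
        groups = {c: c[0] for c in tab.columns if c != "is_synaptic"}
        pt = ProteinTable.from_frame(tab, groups)
        res = differential(pt, "a", "b", seed=8)
        truth = set(gt.de_proteins)
        called = res.ids_with_direction("down")
        assert len(truth & called) / len(truth) >= 0.9
        syn = set(pt.is_synaptic.index[pt.is_synaptic])
        n_down, n_up, n_tot, _, _ = fraction_regulated(res, syn)
        assert fisher_enrichment(n_down, n_up, n_tot).p_value < 0.01


class TestFractionRegulated:
    def test_counts_and_percentages(self):
        res_tab = pd.DataFrame({
            "mean_diff": [-1, -1, 1, 0],
            "d_stat": [-5, -4, 5, 0],
            "q_value": [0.01, 0.01, 0.01, 0.9],
            "direction": ["down", "down", "up", "unchanged"],
        }, index=["P0", "P1", "P2", "P3"])
        from cortexdyn.proteome import DiffResult
        res = DiffResult(res_tab, "a", "b", 0.1, 0.05, 0)
        n_down, n_up, n_tot, pct_down, pct_up = fraction_regulated(
            res, {"P0", "P1", "P2", "P3"})
        assert (n_down, n_up, n_tot) == (2, 1, 4)
        assert pct_down == pytest.approx(50.0)

    def test_printed_percentage_arithmetic(self):
        # 67 of 651 down -> 10.29...%
        assert 100 * 67 / 651 == pytest.approx(10.2919, abs=1e-3)

    def test_empty_subset_rejected(self):
        from cortexdyn.proteome import DiffResult
        res = DiffResult(pd.DataFrame(index=pd.Index([], name="p")),
                         "a", "b", 0.1, 0.05, 0)
        with pytest.raises(ValueError):
            fraction_regulated(res, set())


def _brute_force_fisher(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(x):
        # hypergeometric pmf for x in cell (0, 0)
        return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
                - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))

    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: np.exp(logp(x)) for x in xs}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    def test_identical_rows_p_one(self):
        assert fisher_enrichment(5, 5, 10).p_value == pytest.approx(1.0)

    def test_strong_imbalance_significant(self):
        assert fisher_enrichment(67, 26, 651).p_value < 0.001

    def test_small_table_matches_enumeration(self):
        res = fisher_enrichment(3, 0, 4)
        expected = _brute_force_fisher([[3, 1], [0, 4]])
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("n_down,n_up,n_total", [
        (0, 0, 5), (5, 5, 10), (8, 1, 12), (12, 3, 15), (1, 14, 15),
    ])
    def test_matches_enumeration_small_margins(self, n_down, n_up, n_total):
        res = fisher_enrichment(n_down, n_up, n_total)
        tab = [[n_down, n_total - n_down], [n_up, n_total - n_up]]
        assert res.p_value == pytest.approx(_brute_force_fisher(tab), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 0, 5)


class TestPcaDrivers:
    def test_shifted_protein_ranks_first(self):
        rng = np.random.default_rng(9)
        n_prot, n_per = 60, 5
        x = rng.normal(25, 0.2, (n_prot, 2 * n_per))
        x[0, n_per:] -= 4.0  # strongly down in group b
        cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        lfq = pd.DataFrame(x, index=[f"P{i}" for i in range(n_prot)], columns=cols)
        t = ProteinTable(lfq, pd.Series({c: c[0] for c in cols}),
                         pd.Series(False, index=lfq.index))
        drv = pca_drivers(t, "b", k=10)
        assert drv.top_down[0] == "P0"
        assert "P0" not in drv.top_up

    def test_orientation_invariant_lists(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (40, 8))
        x[:5, 4:] += 3
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        lfq = pd.DataFrame(x, index=[f"P{i}" for i in range(40)], columns=cols)
        t = ProteinTable(lfq, pd.Series({c: c[0] for c in cols}),
                         pd.Series(False, index=lfq.index))
        drv_b = pca_drivers(t, "b", k=5)
        # the separating component's scores must be positive for group b
        assert drv_b.scores.loc[cols[4:], f"PC{drv_b.component+1}"].mean() > 0
        assert set(drv_b.top_down).isdisjoint(drv_b.top_up)

    def test_k_larger_than_protein_count_rejected(self):
        t = _table(np.ones((5, 3)) + np.random.default_rng(0).normal(0, .1, (5, 3)),
                   np.ones((5, 3)))
        with pytest.raises(ValueError):
            pca_drivers(t, "b", k=10)
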