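"""Longitudinal activity metrics on hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from cortexdyn.activity import (
    CATEGORIES,
    LocomotionTrack,
    LongitudinalTable,
    categorize,
    fraction_active,
    per_cell_change,
    reoccurrence_rate,
    silent_conversion_fraction,
    stationary_frequency,
    transition_counts,
)
from cortexdyn.traces import normalize_trace


class TestCategorize:
    @pytest.mark.parametrize("freq,cat", [
        (0.0, "silent"),
        (0.01, "rare"),
        (0.5, "rare"),
        (0.51, "intermediate"),
        (4.0, "intermediate"),
        (4.01, "high"),
        (5.2, "high"),
    ])
    def test_boundaries(self, freq, cat):
        assert categorize(freq) == cat

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1)


class TestFractionActive:
    def test_counts(self, freq_table):
        # s0: cB, cC, cD active -> 3/4
        assert fraction_active(freq_table, "s0") == pytest.approx(0.75)

    def test_all_and_none(self):
        t = LongitudinalTable(pd.DataFrame({"s0": [1.0, 2.0], "s1": [0.0, 0.0]},
                                           index=["a", "b"]))
        assert fraction_active(t, "s0") == 1.0
        assert fraction_active(t, "s1") == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            LongitudinalTable(pd.DataFrame())

    def test_incomplete_table_rejected(self):
        df = pd.DataFrame({"s0": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="reidentified"):
            LongitudinalTable(df)


class TestTransitions:
    def test_same_session_is_diagonal(self, freq_table):
        m = transition_counts(freq_table, "s0", "s0")
        assert (np.asarray(m) == np.diag(np.diag(m))).all()
        assert int(np.asarray(m).sum()) == 4

    def test_hand_tally(self):
        freq = pd.DataFrame({"s0": [0.0, 0.0, 0.0], "s1": [1.0, 2.0, 0.0]},
                            index=["a", "b", "c"])
        m = transition_counts(LongitudinalTable(freq), "s0", "s1")
        assert list(m.loc["silent"]) == [1, 0, 2, 0]

    def test_conservation_and_row_sums(self, freq_table):
        m = transition_counts(freq_table, "s0", "s2")
        assert int(np.asarray(m).sum()) == len(freq_table.cell_ids)
        cats_s0 = freq_table.category["s0"].value_counts()
        for cat in CATEGORIES:
            assert m.loc[cat].sum() == cats_s0.get(cat, 0)


class TestSilentConversion:
    def test_fraction(self):
        freq = pd.DataFrame({"s0": [0.0] * 5, "s1": [1.0, 2.0, 0.0, 0.3, 0.0]},
                            index=list("abcde"))
        f = silent_conversion_fraction(LongitudinalTable(freq), "s0", "s1")
        assert f == pytest.approx(0.4)

    def test_no_silent_cells_signalled(self):
        freq = pd.DataFrame({"s0": [1.0, 0.5], "s1": [0.0, 2.0]},
                            index=["a", "b"])
        with pytest.raises(ValueError, match="silent"):
            silent_conversion_fraction(LongitudinalTable(freq), "s0", "s1")


class TestReoccurrence:
    def test_hand_example_cumulative_and(self):
        # A:[1,1,1], B:[1,0,1], C:[0,1,1] -> [1.0, 0.5, 0.5]
        freq = pd.DataFrame({"s0": [1.0, 1.0, 0.0],
                             "s1": [1.0, 0.0, 1.0],
                             "s2": [1.0, 1.0, 1.0]}, index=list("ABC"))
        r = reoccurrence_rate(LongitudinalTable(freq), "s0")
        assert list(r) == [1.0, 0.5, 0.5]

    def test_always_active_all_ones(self):
        freq = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                            columns=["s0", "s1", "s2"])
        assert list(reoccurrence_rate(LongitudinalTable(freq), "s0")) == [1, 1, 1]

    def test_monotone_non_increasing(self, freq_table):
        r = reoccurrence_rate(freq_table, "s0").to_numpy()
        assert (np.diff(r) <= 0).all()
        assert r[0] == 1.0

    def test_no_active_cells_signalled(self):
        freq = pd.DataFrame({"s0": [0.0], "s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="active"):
            reoccurrence_rate(LongitudinalTable(freq), "s0")


class TestPerCellChange:
    def test_same_session_zero(self, freq_table):
        assert (per_cell_change(freq_table, "s0", "s0") == 0).all()

    def test_difference_and_median(self):
        freq = pd.DataFrame({"s0": [1.0, 1.0, 1.0], "s1": [0.8, 1.1, 1.5]},
                            index=list("abc"))
        ch = per_cell_change(LongitudinalTable(freq), "s0", "s1")
        assert ch["c"] == pytest.approx(0.5)
        assert ch.median() == pytest.approx(0.1)


class TestStationaryFrequency:
    def _nt_with_transients(self, starts, n=9000):
        g = np.ones(n)
        for s in starts:
            g[s:s + 20] = 10.0
        return normalize_trace(g * 50)

    def test_all_stationary_equals_full_session(self):
        nt = self._nt_with_transients([1000, 5000])
        track = LocomotionTrack(np.zeros(9000))
        res = stationary_frequency(nt, track, fs=10.0)
        assert res.included
        assert res.frequency == pytest.approx(2 / 15.0)

    def test_below_one_percent_excluded(self):
        nt = self._nt_with_transients([1000])
        speed = np.ones(9000)
        speed[:45] = 0.0  # 0.5% stationary
        res = stationary_frequency(nt, LocomotionTrack(speed), fs=10.0)
        assert not res.included
        assert np.isnan(res.frequency)

    def test_onset_attribution_rate(self):
        # 2 transients with stationary onsets over 5 stationary minutes
        nt = self._nt_with_transients([100, 2000, 6000])
        speed = np.ones(9000)
        speed[:3000] = 0.0  # first 5 min stationary; onsets 100, 2000 inside
        res = stationary_frequency(nt, LocomotionTrack(speed), fs=10.0)
        assert res.n_transients == 2
        assert res.frequency == pytest.approx(0.4)

    def test_length_mismatch_rejected(self):
        nt = self._nt_with_transients([100], n=1000)
        with pytest.raises(ValueError):
            stationary_frequency(nt, LocomotionTrack(np.zeros(999)), fs=10.0)
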