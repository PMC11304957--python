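"""Frequencies, enrichment scores and subset selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cxxxscreen.enrichment import (
    compute_escores,
    compute_frequencies,
    escore_summary,
    export_scatter,
    select_by_threshold,
    select_top_n,
)
from cxxxscreen.library_space import enumerate_cxxx
from cxxxscreen.reads import CountTable


def _freq(d):
    s = pd.Series(d, dtype=float)
    s.index.name = "variant"
    return s


class TestFrequencies:
    def test_simple_proportions(self):
        f = compute_frequencies({"CAAA": 4, "CAAC": 6})
        assert f["CAAA"] == pytest.approx(0.4)
        assert f["CAAC"] == pytest.approx(0.6)

    def test_single_variant(self):
        f = compute_frequencies({"CVLL": 17})
        assert f["CVLL"] == 1.0

    def test_universe_fills_zeros(self):
        f = compute_frequencies({"CAAA": 4}, universe=["CAAA", "CAAC"])
        assert f["CAAC"] == 0.0
        assert f.sum() == pytest.approx(1.0)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            compute_frequencies({"CAAA": 0})

    def test_normalisation_on_simulated_table(self, small_screen):
        universe = enumerate_cxxx()[:200]
        for cond, table in small_screen.tables.items():
            f = compute_frequencies(table, universe=universe)
            assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_recount(self, small_screen):
        table = small_screen.tables["42C"]
        universe = enumerate_cxxx()[:200]
        f = compute_frequencies(table, universe=universe)
        # oracle: recount every replicate dict by hand
        raw = {}
        for rep in table.counts.values():
            for v, c in rep.items():
                raw[v] = raw.get(v, 0) + c
        grand = sum(raw.values())
        for v in universe:
            assert abs(f[v] - raw.get(v, 0) / grand) < 1e-12


class TestEScores:
    def test_self_ratio_is_one(self):
        f = _freq({"CAAA": 0.25, "CAAC": 0.75})
        df = compute_escores(f, f)
        assert (df["escore"] == 1.0).all()

    def test_zero_numerator_gives_zero(self):
        sel = _freq({"CAAA": 0.0, "CAAC": 1.0})
        naive = _freq({"CAAA": 0.5, "CAAC": 0.5})
        df = compute_escores(sel, naive)
        assert df.loc["CAAA", "escore"] == 0.0
        assert df.loc["CAAA", "status"] == "ok"

    def test_simple_ratio(self):
        sel = _freq({"CAAA": 0.2, "CAAC": 0.8})
        naive = _freq({"CAAA": 0.4, "CAAC": 0.6})
        df = compute_escores(sel, naive)
        assert df.loc["CAAA", "escore"] == pytest.approx(0.5)

    def test_zero_denominator_flagged_undefined(self):
        sel = _freq({"CAAA": 0.5, "CAAC": 0.5})
        naive = _freq({"CAAA": 1.0, "CAAC": 0.0})
        df = compute_escores(sel, naive)
        assert df.loc["CAAC", "status"] == "undefined"
        assert np.isnan(df.loc["CAAC", "escore"])

    def test_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            compute_escores(_freq({"CAAA": 1.0}), _freq({"CAAC": 1.0}))

    def test_scale_invariance_of_counts(self):
        counts = {"CAAA": 3, "CAAC": 9, "CAAD": 18}
        scaled = {v: 7 * c for v, c in counts.items()}
        f1, f2 = compute_frequencies(counts), compute_frequencies(scaled)
        naive = _freq({"CAAA": 0.1, "CAAC": 0.4, "CAAD": 0.5})
        e1 = compute_escores(f1, naive)["escore"]
        e2 = compute_escores(f2, naive)["escore"]
        assert np.allclose(e1, e2)


class TestSelection:
    def _table(self, scores):
        idx = pd.Index(list(scores), name="variant")
        return pd.DataFrame(
            {
                "freq_naive": 1.0,
                "freq_selected": list(scores.values()),
                "escore": list(scores.values()),
                "status": "ok",
            },
            index=idx,
        )

    def test_threshold_below(self):
        df = self._table({"CAAA": 0.1, "CAAC": 0.3})
        assert select_by_threshold(df, "<", 0.2) == ["CAAA"]

    def test_threshold_empty(self):
        df = self._table({"CAAA": 0.1, "CAAC": 0.3})
        assert select_by_threshold(df, "<", 0.05) == []

    def test_top_n_ordering(self):
        df = self._table({"CAAA": 2.0, "CAAC": 1.0, "CAAD": 3.0})
        assert select_top_n(df, 2, "top") == ["CAAD", "CAAA"]
        assert select_top_n(df, 3, "top") == ["CAAD", "CAAA", "CAAC"]

    def test_top_n_tie_break_lexicographic(self):
        df = self._table({"CAAD": 1.0, "CAAA": 1.0, "CAAC": 2.0})
        # tie at the boundary: lexicographically smaller variant included
        assert select_top_n(df, 2, "top") == ["CAAC", "CAAA"]

    def test_invalid_n(self):
        df = self._table({"CAAA": 1.0})
        with pytest.raises(ValueError):
            select_top_n(df, 0)
        with pytest.raises(ValueError):
            select_top_n(df, 2)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=10, allow_nan=False, width=32),
            min_size=1,
            max_size=50,
        ),
        st.integers(min_value=1, max_value=50),
    )
    def test_rank_agreement_with_full_sort_oracle(self, scores, n):
        variants = enumerate_cxxx()[: len(scores)]
        df = self._table(dict(zip(variants, scores)))
        n = min(n, len(scores))
        oracle_top = [
            v for _, v in sorted(
                zip(scores, variants), key=lambda t: (-t[0], t[1])
            )
        ][:n]
        oracle_bottom = [
            v for _, v in sorted(zip(scores, variants), key=lambda t: (t[0], t[1]))
        ][:n]
        assert select_top_n(df, n, "top") == oracle_top
        assert select_top_n(df, n, "bottom") == oracle_bottom

    def test_undefined_scores_excluded_from_rankings(self):
        df = self._table({"CAAA": 5.0, "CAAC": 1.0})
        df.loc["CAAA", "status"] = "undefined"
        assert select_top_n(df, 1, "top") == ["CAAC"]
        assert select_by_threshold(df, ">", 0.5) == ["CAAC"]


class TestScatter:
    def test_two_variant_toy(self):
        naive = _freq({"CAAA": 0.25, "CAAC": 0.75})
        other = _freq({"CAAA": 0.5, "CAAC": 0.5})
        df = export_scatter(naive, other)
        assert len(df) == 2
        assert df.loc["CAAA", "freq_naive"] == 0.25
        assert df.loc["CAAA", "freq_condition"] == 0.5
        assert df.loc["CAAA", "escore"] == pytest.approx(2.0)

    def test_identical_libraries_on_diagonal(self):
        f = _freq({"CAAA": 0.3, "CAAC": 0.7})
        df = export_scatter(f, f)
        assert np.allclose(df["freq_naive"], df["freq_condition"])

    def test_row_count_equals_universe(self, small_screen, full_universe):
        universe = full_universe[:200]
        fn = compute_frequencies(small_screen.tables["naive"], universe=universe)
        f42 = compute_frequencies(small_screen.tables["42C"], universe=universe)
        assert len(export_scatter(fn, f42)) == 200


def test_escore_summary_reports_extremes_and_threshold_count():
    idx = pd.Index(["CAAA", "CAAC", "CAAD", "CAAE"], name="variant")
    df = pd.DataFrame(
        {
            "freq_naive": 1.0,
            "freq_selected": [3.2, 0.05, 0.15, 1.0],
            "escore": [3.2, 0.05, 0.15, 1.0],
            "status": "ok",
        },
        index=idx,
    )
    s = escore_summary(df, low_cutoff=0.2)
    assert s["max"] == pytest.approx(3.2)
    assert s["min"] == pytest.approx(0.05)
    assert s["n_below_cutoff"] == 2


def test_count_scaling_leaves_frequencies_unchanged():
    t = CountTable("lib")
    t.add_replicate("r1", {"CAAA": 2, "CAAC": 6})
    t2 = CountTable("lib")
    t2.add_replicate("r1", {"CAAA": 20, "CAAC": 60})
    assert np.allclose(
        compute_frequencies(t).to_numpy(), compute_frequencies(t2).to_numpy()
    )
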