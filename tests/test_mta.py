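"""MTA-QTL chaining and subpopulation allele analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qtlome as q
from qtlome.types import GenotypeMatrix


def mta_frame(rows):
    return pd.DataFrame(
        rows, columns=["trait", "marker", "environment", "chromosome",
                       "position_cM", "neg_log10_p", "r2"]
    )


class TestChaining:
    def test_published_2b_regions(self, mta_table):
        groups = q.chain_mtas(mta_table, gap=10.0)
        regions = [g.region for g in groups if g.chromosome == "2B"]
        assert regions == [
            (2.7, 2.7), (42.2, 42.2), (133.4, 146.3), (169.5, 169.5),
            (220.5, 227.1),
        ]
        ids = [g.mtaqtl_id for g in groups if g.chromosome == "2B"]
        assert ids == [f"mtaq2B.{i}" for i in range(1, 6)]

    def test_linkage_groups_stay_separate(self, mta_table):
        groups = q.chain_mtas(mta_table, gap=10.0)
        one_a = [g for g in groups if g.chromosome.startswith("1A")]
        assert [g.mtaqtl_id for g in one_a] == ["mtaq1A.1", "mtaq1A.2"]
        assert one_a[0].chromosome == "1A.1" and one_a[1].chromosome == "1A.2"

    def test_single_mta_single_group(self):
        mtas = mta_frame([("GS", "m1", "2007", "5A", 12.0, 2.5, 0.05)])
        groups = q.chain_mtas(mtas)
        assert len(groups) == 1 and groups[0].n_mtas == 1

    def test_zero_gap_groups_identical_positions_only(self):
        mtas = mta_frame([
            ("GS", "m1", "2007", "1B", 10.0, 2.5, 0.05),
            ("TW", "m2", "2008", "1B", 10.0, 2.7, 0.05),
            ("GS", "m3", "2007", "1B", 10.1, 2.6, 0.05),
        ])
        groups = q.chain_mtas(mtas, gap=0.0)
        assert [g.n_mtas for g in groups] == [2, 1]

    def test_missing_position_rejected(self):
        mtas = mta_frame([("GS", "m1", "2007", "1B", np.nan, 2.5, 0.05)])
        with pytest.raises(ValueError):
            q.chain_mtas(mtas)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        pos=st.lists(st.floats(0, 200), min_size=1, max_size=25),
        gap=st.floats(0.5, 20),
        seed=st.integers(0, 100),
    )
    def test_partition_order_invariance_and_gap_bound(self, pos, gap, seed):
        rows = [("GS", f"m{i}", "2007", "3B", round(p, 1), 2.5, 0.05)
                for i, p in enumerate(pos)]
        mtas = mta_frame(rows)
        shuffled = mtas.sample(frac=1, random_state=seed).reset_index(drop=True)
        a = q.chain_mtas(mtas, gap=gap)
        b = q.chain_mtas(shuffled, gap=gap)
        # groups partition the MTA set regardless of input order
        assert sorted(r for g in a for r in g.members["marker"]) == sorted(
            f"m{i}" for i in range(len(pos))
        )
        assert [g.region for g in a] == [g.region for g in b]
        for g in a:
            mpos = np.sort(g.members["position_cM"].unique())
            if len(mpos) > 1:
                assert np.diff(mpos).max() <= gap + 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(pos=st.lists(st.floats(0, 100), min_size=2, max_size=15))
    def test_smaller_gap_refines(self, pos):
        rows = [("TW", f"m{i}", "2007", "6B", round(p, 1), 2.5, 0.05)
                for i, p in enumerate(pos)]
        mtas = mta_frame(rows)
        coarse = q.chain_mtas(mtas, gap=15.0)
        fine = q.chain_mtas(mtas, gap=3.0)
        assert len(fine) >= len(coarse)
        # every fine group sits inside one coarse region
        for g in fine:
            assert any(
                c.region[0] <= g.region[0] and g.region[1] <= c.region[1]
                for c in coarse
            )


class TestSummaries:
    def test_published_region_table_counts(self, mtaqtl_table):
        s = q.summarize_mtaqtls(mtaqtl_table)
        assert s["n_groups"] == 37
        assert s["n_mtas_total"] == 92
        assert s["n_single_mta"] == 14
        assert s["pct_single_trait"] == 65
        assert s["mtas_per_group"][8] == 1

    def test_empty_input(self):
        assert q.summarize_mtaqtls([])["n_groups"] == 0

    def test_chained_groups_summary(self, mta_table):
        groups = q.chain_mtas(mta_table, gap=10.0)
        s = q.summarize_mtaqtls(groups)
        assert s["n_mtas_total"] == 92


class TestAlleleDistribution:
    @staticmethod
    def _pop(freqs, n_per=50, seed=0):
        rng = np.random.default_rng(seed)
        pops = [f"SP{i}" for i in range(len(freqs))]
        calls, labels, acc = [], [], []
        for p_i, pop in zip(freqs, pops):
            for j in range(n_per):
                acc.append(f"{pop}_a{j}")
                labels.append(pop)
                calls.append([float(rng.random() < p_i)])
        G = GenotypeMatrix(acc, ["mk"], np.array(calls))
        labels = pd.Series(labels, index=acc)
        Q = pd.get_dummies(labels).astype(float)
        return G, q.SubpopAssignment(labels, Q)

    def test_all_carriers(self):
        G, sp = self._pop([1.0, 1.0])
        assert (q.carrier_frequency(G, "mk", sp) == 1.0).all()

    def test_absent_in_one_subpop(self):
        G, sp = self._pop([0.0, 1.0])
        f = q.carrier_frequency(G, "mk", sp)
        assert f["SP0"] == 0.0 and f["SP1"] == 1.0

    def test_planted_frequencies_within_binomial_ci(self):
        G, sp = self._pop([0.7, 0.1], n_per=50, seed=4)
        f = q.carrier_frequency(G, "mk", sp)
        for pop, p_true in zip(("SP0", "SP1"), (0.7, 0.1)):
            half = 1.96 * np.sqrt(p_true * (1 - p_true) / 50)
            assert abs(f[pop] - p_true) <= half + 1e-9

    def test_aggregated_frequency_matches_global(self):
        G, sp = self._pop([0.8, 0.3, 0.5], n_per=40, seed=9)
        f = q.carrier_frequency(G, "mk", sp)
        sizes = sp.labels.value_counts()
        pooled = (f * sizes.reindex(f.index)).sum() / sizes.sum()
        assert pooled == pytest.approx(np.nanmean(G.calls))


class TestPresenceEffect:
    def test_null_effect_shares_letter(self):
        rng = np.random.default_rng(1)
        n = 200
        acc = [f"a{i}" for i in range(n)]
        calls = (rng.random((n, 1)) < 0.5).astype(float)
        G = GenotypeMatrix(acc, ["mk"], calls)
        y = pd.Series(rng.standard_normal(n), index=acc)
        out = q.presence_effect(G, "mk", y)
        assert out["letter_absent"] == out["letter_present"] == "a"
        se = np.sqrt(4 / n)  # rough SE of the contrast at unit variance
        assert abs(out["relative_effect_pct"]) < np.inf
        assert abs(out["mean_present"] - out["mean_absent"]) < 3 * se * 2

    def test_planted_effect_detected(self):
        detected = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 300
            acc = [f"a{i}" for i in range(n)]
            calls = (rng.random((n, 1)) < 0.5).astype(float)
            G = GenotypeMatrix(acc, ["mk"], calls)
            y = pd.Series(0.6 * calls[:, 0] + rng.standard_normal(n), index=acc)
            out = q.presence_effect(G, "mk", y)
            detected += out["p"] < 0.05
        assert detected >= 0.9 * n_rep

    def test_empty_class_rejected(self):
        G = GenotypeMatrix(["a", "b"], ["mk"], np.array([[1.0], [1.0]]))
        y = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            q.presence_effect(G, "mk", y)


class TestPercentileCarriers:
    @staticmethod
    def _data(calls, values):
        acc = [f"a{i}" for i in range(len(calls))]
        G = GenotypeMatrix(acc, ["mk"], np.array(calls, dtype=float)[:, None])
        return G, pd.Series(values, index=acc, dtype=float)

    def test_perfect_predictor(self):
        calls = [1] * 10 + [0] * 10
        values = list(range(20, 10, -1)) + list(range(10, 0, -1))
        G, y = self._data(calls, values)
        out = q.percentile_carriers(G, "mk", y)
        assert out["upper_freq"] == 1.0 and out["lower_freq"] == 0.0

    def test_all_carriers(self):
        G, y = self._data([1] * 20, range(20))
        out = q.percentile_carriers(G, "mk", y)
        assert out["upper_freq"] == 1.0 and out["lower_freq"] == 1.0

    def test_independent_marker_near_overall_frequency(self):
        rng = np.random.default_rng(8)
        n = 200
        calls = (rng.random(n) < 0.4).astype(float)
        G, y = self._data(calls, rng.standard_normal(n))
        out = q.percentile_carriers(G, "mk", y)
        half = 1.96 * np.sqrt(0.4 * 0.6 / 20)
        assert abs(out["upper_freq"] - calls.mean()) <= half + 0.05
        assert abs(out["lower_freq"] - calls.mean()) <= half + 0.05

    def test_ties_widen_the_tail(self):
        calls = [1] * 12
        values = [0.0, 0.0, 0.0] + [float(v) for v in range(1, 10)]
        G, y = self._data(calls, values)  # three-way tie spans the low cut
        out = q.percentile_carriers(G, "mk", y, q=0.10)
        assert out["n_lower"] == 3
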