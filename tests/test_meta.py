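"""CI formulas, homothetic projection, mixture clustering and meta report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qtlome as q
from qtlome.meta import MetaConfig, MixtureFit
from qtlome.types import MarkerMap, ProjectedQtl, QtlRecord


def record(**kw):
    base = dict(qtl_id="q1", study_id="s1", trait="GPC", cross_type="RIL",
                n_progeny=150, r2=0.1, lod=3.0, chromosome="1A", position_cM=20.0)
    base.update(kw)
    return QtlRecord(**base)


class TestEstimateCi:
    @pytest.mark.parametrize(
        "cross,n,r2,expected",
        [("RIL", 163, 1.0, 1.0), ("DH", 106, 0.10, 50.0), ("F2", 200, 0.25, 10.6),
         ("BC", 100, 0.10, 53.0)],
    )
    def test_formula_values(self, cross, n, r2, expected):
        assert q.estimate_ci(cross, n, r2) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q.estimate_ci("RIL", 100, 0.0)
        with pytest.raises(ValueError):
            q.estimate_ci("NIL", 100, 0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        cross=st.sampled_from(["RIL", "DH", "BC", "F2"]),
        n=st.integers(20, 500),
        r2=st.floats(0.01, 0.9),
        dn=st.integers(1, 100),
        dr=st.floats(0.01, 0.09),
    )
    def test_strictly_decreasing_in_n_and_r2(self, cross, n, r2, dn, dr):
        base = q.estimate_ci(cross, n, r2)
        assert q.estimate_ci(cross, n + dn, r2) < base
        assert q.estimate_ci(cross, n, r2 + dr) < base


class TestProjection:
    @staticmethod
    def _map(markers, positions, chrom="1A"):
        return MarkerMap(pd.DataFrame(
            {"marker": markers, "chromosome": chrom, "position_cM": positions}
        ))

    def test_identity_maps_identity_projection(self):
        m = self._map(["a", "b", "c"], [0.0, 50.0, 100.0])
        p = q.project_qtl(record(position_cM=33.3), m, m)
        assert p.status == "projected"
        assert p.consensus_position == pytest.approx(33.3, abs=1e-9)

    def test_two_fold_stretch_midpoint(self):
        study = self._map(["a", "b"], [10.0, 30.0])
        cons = self._map(["a", "b"], [20.0, 60.0])
        p = q.project_qtl(record(position_cM=20.0), study, cons)
        assert p.consensus_position == pytest.approx(40.0)

    def test_ci_projected_by_same_transform(self):
        study = self._map(["a", "b"], [0.0, 50.0])
        cons = self._map(["a", "b"], [0.0, 100.0])
        p = q.project_qtl(record(position_cM=25.0, reported_ci=10.0), study, cons)
        assert p.ci95 == pytest.approx(20.0)  # 2x stretch doubles the width

    def test_formula_ci_when_no_reported(self):
        m = self._map(["a", "b"], [0.0, 100.0])
        p = q.project_qtl(record(position_cM=50.0, cross_type="RIL",
                                 n_progeny=163, r2=1.0), m, m)
        assert p.ci95 == pytest.approx(1.0)

    def test_reported_ci_precedence_configurable(self):
        m = self._map(["a", "b"], [0.0, 100.0])
        r = record(position_cM=50.0, reported_ci=30.0, n_progeny=163, r2=1.0)
        assert q.project_qtl(r, m, m).ci95 == pytest.approx(30.0)
        assert q.project_qtl(r, m, m, ci_precedence="formula").ci95 == pytest.approx(1.0)

    def test_fewer_than_two_common_markers_flagged(self):
        study = self._map(["x", "y"], [0.0, 50.0])
        cons = self._map(["a", "b"], [0.0, 100.0])
        p = q.project_qtl(record(), study, cons)
        assert p.status == "no_common_markers"
        assert p.consensus_position is None

    def test_coincident_study_markers_rejected(self):
        study = self._map(["a", "b"], [10.0, 10.0])
        cons = self._map(["a", "b"], [0.0, 100.0])
        with pytest.raises(ValueError):
            q.project_qtl(record(), study, cons)

    def test_order_preserved_within_interval(self):
        study = self._map(["a", "b"], [0.0, 40.0])
        cons = self._map(["a", "b"], [10.0, 90.0])
        pos = [5.0, 15.0, 35.0]
        got = [q.project_qtl(record(position_cM=p), study, cons).consensus_position
               for p in pos]
        assert got == sorted(got)

    def test_extrapolation_beyond_cap_downgraded(self):
        study = self._map(["a", "b"], [50.0, 60.0])
        cons = self._map(["a", "b"], [50.0, 60.0])
        near = q.project_qtl(record(position_cM=65.0), study, cons)
        far = q.project_qtl(record(position_cM=95.0), study, cons)
        assert near.status == "projected" and near.extrapolated
        assert far.status == "no_common_markers"


class TestMixture:
    def test_single_position_k1(self):
        fit = q.fit_mixture(np.full(5, 42.0), np.full(5, 2.0), k=1)
        assert fit.means[0] == pytest.approx(42.0)
        assert np.isfinite(fit.log_likelihood)

    def test_two_tight_clusters_recovered(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(10, 2, 15), rng.normal(90, 2, 15)]
        fit = q.fit_mixture(x, np.full(30, 2.0), k=2)
        assert sorted(np.round(fit.means)) == pytest.approx([10, 90], abs=1.0)

    def test_posteriors_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 20)
        fit = q.fit_mixture(x, np.full(20, 5.0), k=3)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_aic_counts_free_parameters(self):
        fit = MixtureFit(k=3, means=np.zeros(3), weights=np.full(3, 1 / 3),
                         posteriors=np.full((5, 3), 1 / 3), log_likelihood=-10.0,
                         n_free_parameters=5)
        assert fit.aic == pytest.approx(2 * 10 + 2 * 5)

    def test_aic_prefers_one_component_on_single_cluster(self):
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(50, 2, 20)
            sd = np.full(20, 2.0)
            f1 = q.fit_mixture(x, sd, k=1)
            f2 = q.fit_mixture(x, sd, k=2)
            wins += f1.aic < f2.aic
        assert wins >= 0.9 * n_rep

    def test_k_exceeding_distinct_positions_rejected(self):
        with pytest.raises(ValueError):
            q.fit_mixture(np.array([1.0, 1.0]), np.array([1.0, 1.0]), k=2)

    def test_loglik_nondecreasing_vs_worse_start(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(20, 1, 10), rng.normal(80, 1, 10)]
        sd = np.full(20, 1.0)
        single = q.fit_mixture(x, sd, k=2, n_starts=1)
        multi = q.fit_mixture(x, sd, k=2, n_starts=5)
        assert multi.log_likelihood >= single.log_likelihood - 1e-9


class TestSelection:
    def test_single_fit_returned(self):
        f = q.fit_mixture(np.array([1.0, 2.0, 3.0]), np.full(3, 1.0), k=1)
        assert q.select_model([f]).k == 1

    def test_tie_broken_toward_smaller_k(self):
        def fake(k, ll):
            return MixtureFit(k=k, means=np.zeros(k), weights=np.full(k, 1 / k),
                              posteriors=np.full((4, k), 1 / k),
                              log_likelihood=ll, n_free_parameters=2 * k - 1)
        f2, f3 = fake(2, -10.0), fake(3, -8.0)  # equal AIC = 26
        assert q.select_model([f3, f2]).k == 2


class TestAssignAndFilter:
    @staticmethod
    def _proj(pos, ci, lod=5.0, chrom="1A", qid="q"):
        return ProjectedQtl(
            record(qtl_id=qid, chromosome=chrom, lod=lod), pos, pos - ci / 2,
            pos + ci / 2, "projected",
        )

    def test_symmetric_members_average(self):
        qtls = [self._proj(10.0, 3.92, qid="q1"), self._proj(20.0, 3.92, qid="q2")]
        fit = q.fit_mixture(np.array([10.0, 20.0]), np.array([1.0, 1.0]), k=1)
        mqtls, singles, excluded = q.assign_and_filter(fit, qtls)
        assert len(mqtls) == 1
        assert mqtls[0].position_cM == pytest.approx(15.0)

    def test_precision_pooling_ci(self):
        qtls = [self._proj(10.0, 3.92, qid="q1"), self._proj(10.0, 3.92, qid="q2")]
        fit = q.fit_mixture(np.array([10.0, 10.0]), np.array([1.0, 1.0]), k=1)
        mqtls, _, _ = q.assign_and_filter(fit, qtls)
        assert mqtls[0].ci95_cM == pytest.approx(3.92 / np.sqrt(2))

    def test_single_member_component_is_singleton(self):
        qtls = [self._proj(10.0, 2.0, qid="q1")]
        fit = q.fit_mixture(np.array([10.0]), np.array([0.5]), k=1)
        mqtls, singles, excluded = q.assign_and_filter(fit, qtls)
        assert mqtls == [] and len(singles) == 1 and excluded == []


class TestRunMeta:
    def test_empty_input(self):
        report = q.run_meta([])
        assert report.table().empty
        assert report.conserved(0)

    def test_conservation_and_prefilter(self, consensus_1chrom):
        chrom = consensus_1chrom.chromosomes[0]
        recs, maps = q.gen_qtl_literature(
            consensus_1chrom, [(chrom, 40.0, 2.0), (chrom, 150.0, 2.0)],
            n_studies=6, seed=5, n_qtls=24,
        )
        projected = q.project_all(recs, maps, consensus_1chrom)
        # force a couple of exclusions through the pre-filter
        cfg = MetaConfig(lod_min=2.5, ci_max=60.0, seed=5)
        report = q.run_meta(projected, consensus_1chrom, cfg)
        n_proj = sum(p.status == "projected" for p in projected)
        assert report.conserved(n_proj)
        for p, reason in report.excluded:
            assert reason in {"low_lod", "large_ci", "ambiguous_membership"}

    def test_single_qtl_chromosome_is_singleton(self):
        p = ProjectedQtl(record(), 30.0, 25.0, 35.0, "projected")
        report = q.run_meta([p])
        assert len(report.singletons) == 1 and not report.mqtls

    def test_ci_reduction_positive_when_clustered(self, consensus_1chrom):
        chrom = consensus_1chrom.chromosomes[0]
        ok = 0
        for seed in range(10):
            recs, maps = q.gen_qtl_literature(
                consensus_1chrom,
                [(chrom, 30.0, 2.0), (chrom, 100.0, 2.0), (chrom, 170.0, 2.0)],
                n_studies=8, seed=seed, n_qtls=30,
            )
            projected = q.project_all(recs, maps, consensus_1chrom)
            report = q.run_meta(projected, consensus_1chrom, MetaConfig(seed=seed))
            ok += report.ci_reduction() > 0
        assert ok == 10

    def test_published_mqtl_members_sum(self, mqtl_table):
        assert int(mqtl_table["n_qtl"].sum()) == 204
        assert len(mqtl_table) == 45
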