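"""Weight aggregation, network-scale weights, covariate-adjusted group
tests, FDR correction and the report bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import adjusted_t_bruteforce, bh_bruteforce

from acupredict import reporting as rp
from acupredict.connectome import build_registry, edge_id
from acupredict.cv_engine import ConsensusSet


def _consensus(ids, trace):
    trace = np.asarray(trace, dtype=float)
    return ConsensusSet(np.arange(len(ids)), list(ids), [], trace)


class TestAggregateWeights:
    def test_constant_trace(self):
        out = rp.aggregate_weights(_consensus(["SID"], [[0.3]] * 4))
        assert out.loc[0, "weight"] == pytest.approx(0.3)
        assert out.loc[0, "mean_signed_weight"] == pytest.approx(0.3)

    def test_sign_cancellation_yields_zero(self):
        trace = [[0.3], [-0.3], [0.3], [-0.3]]
        out = rp.aggregate_weights(_consensus(["rsfc_01_02"], trace))
        assert out.loc[0, "weight"] == pytest.approx(0.0)

    def test_hand_trace_and_ranking(self):
        ids = ["a", "b", "c"]
        trace = np.array([[0.1, -0.4, 0.2],
                          [0.3, -0.2, 0.2],
                          [0.2, -0.6, 0.2],
                          [0.0, -0.4, 0.2],
                          [0.4, -0.4, 0.2]])
        out = rp.aggregate_weights(_consensus(ids, trace)).set_index("feature_id")
        assert out.loc["a", "weight"] == pytest.approx(0.2)
        assert out.loc["b", "weight"] == pytest.approx(0.4)
        assert out.loc["c", "weight"] == pytest.approx(0.2)
        assert out.loc["b", "rank"] == 1

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rp.aggregate_weights(_consensus([], np.zeros((3, 0))))


class TestNetworkWeights:
    registry = build_registry()

    def _summary(self, rows):
        return pd.DataFrame(rows)

    def test_single_between_network_edge(self):
        # components 20 (CCN) and 30 (DMN)
        s = self._summary([{"feature_id": edge_id(20, 30), "weight": 0.4}])
        mat, clin = rp.network_weights(s, self.registry)
        assert mat.loc["CCN", "DMN"] == pytest.approx(0.4)
        assert mat.loc["DMN", "CCN"] == pytest.approx(0.4)
        assert mat.values.sum() == pytest.approx(0.8)  # symmetric storage
        assert clin == 0.0

    def test_within_network_additivity(self):
        s = self._summary([{"feature_id": edge_id(17, 18), "weight": 0.2},
                           {"feature_id": edge_id(19, 23), "weight": 0.3}])
        mat, _ = rp.network_weights(s, self.registry)
        assert mat.loc["CCN", "CCN"] == pytest.approx(0.5)

    def test_conservation_and_clinical_split(self, signal_consensus,
                                             signal_report):
        summary = rp.aggregate_weights(signal_consensus)
        mat, clin = rp.network_weights(summary, self.registry)
        edge_total = summary[summary["feature_id"].str.startswith("rsfc")]["weight"].sum()
        clin_total = summary[~summary["feature_id"].str.startswith("rsfc")]["weight"].sum()
        diag = np.diag(mat.values).sum()
        off = (mat.values.sum() - diag) / 2  # off-diagonal stored twice
        assert diag + off == pytest.approx(edge_total, abs=1e-12)
        assert clin == pytest.approx(clin_total, abs=1e-12)

    def test_unknown_feature_rejected(self):
        s = self._summary([{"feature_id": "rsfc_99_99", "weight": 0.1}])
        with pytest.raises(KeyError):
            rp.network_weights(s, self.registry)


class TestAdjustedGroupTest:
    def test_reduces_to_pooled_t_when_gender_constant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            v = rng.normal(size=n)
            r = np.where(rng.random(n) < 0.5, 1, -1)
            r[:2] = [1, -1]
            t, p = rp.adjusted_group_test(v, r, np.zeros(n))
            t_ref, p_ref = stats.ttest_ind(v[r == 1], v[r == -1], equal_var=True)
            assert t == pytest.approx(t_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(10, 50))
            v = rng.normal(size=n)
            r = np.where(rng.random(n) < 0.5, 1, -1)
            r[:2] = [1, -1]
            g = (rng.random(n) < 0.5).astype(float)
            if g.min() == g.max():
                g[0] = 1 - g[0]
            t, p = rp.adjusted_group_test(v, r, g)
            t_ref, p_ref = adjusted_t_bruteforce(v, (r == 1).astype(float), g)
            assert t == pytest.approx(t_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_exactly_balanced_null_gives_zero_t(self):
        # identical value multisets in both groups, gender balanced
        v = np.tile([1.0, 2.0, 2.0, 1.0], 10)
        r = np.tile([1, 1, -1, -1], 10)
        g = np.tile([0.0, 1.0, 0.0, 1.0], 10)
        t, p = rp.adjusted_group_test(v, r, g)
        assert t == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_gender_confound_removed_by_adjustment(self):
        """Gender drives the feature; the group is correlated with gender
        but has no direct effect.  The unadjusted comparison flags a
        difference, the adjusted one does not."""
        rng = np.random.default_rng(2)
        n = 400
        g = (rng.random(n) < 0.5).astype(float)
        flip = rng.random(n) < 0.9
        r = np.where(np.where(flip, g, 1 - g) == 1, 1, -1)
        v = 1.0 * g + 0.1 * rng.normal(size=n)
        _, p_unadj = stats.ttest_ind(v[r == 1], v[r == -1])
        _, p_adj = rp.adjusted_group_test(v, r, g)
        assert p_unadj < 1e-6
        assert p_adj > 0.05

    def test_collinear_gender_rejected(self):
        v = np.arange(10.0)
        r = np.array([1, -1] * 5)
        g = (r == 1).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            rp.adjusted_group_test(v, r, g)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both responder groups"):
            rp.adjusted_group_test(np.arange(6.0), np.ones(6), np.zeros(6))


class TestFDR:
    def test_hand_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj, sig = rp.fdr_correct(p)
        assert adj == pytest.approx([0.02, 0.04, 0.04, 0.02])
        assert sig.all()

    def test_identical_pvalues_unchanged(self):
        adj, sig = rp.fdr_correct(np.full(10, 0.01))
        assert np.allclose(adj, 0.01)
        assert sig.all()

    def test_single_pvalue_passthrough(self):
        adj, _ = rp.fdr_correct([0.37])
        assert adj[0] == pytest.approx(0.37)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            adj, _ = rp.fdr_correct(p)
            assert np.allclose(adj, bh_bruteforce(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        adj, _ = rp.fdr_correct(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rp.fdr_correct([0.5, 1.2])


class TestGroupComparisonOnSignalCohort:
    def test_planted_edges_direction_matches_truth(self, signal_cohort,
                                                   signal_features,
                                                   signal_labels):
        """With positive planted effects, responders should show higher
        connectivity on nearly all planted edges after gender adjustment."""
        ids = signal_cohort.truth.planted_edge_ids
        X = signal_features.restrict(ids).values
        res = rp.group_comparison(X, ids, signal_labels.responder,
                                  signal_cohort.gender())
        frac_higher = np.mean(res["direction"] == "responders_higher")
        assert frac_higher >= 0.95
        assert res["significant"].mean() > 0.9
        assert np.all(res["p_fdr"] >= res["p"] - 1e-15)


class TestReportBundle:
    def test_roundtrip_bit_exact(self, tmp_path):
        qc = pd.DataFrame({"subject_id": ["a", "b"], "excluded": [False, True]})
        cvs = pd.DataFrame({"threshold": [0.15], "accuracy_mean": [0.875]})
        consensus = pd.DataFrame({"feature_id": ["SID"], "weight": [0.3]})
        net = pd.DataFrame(np.zeros((4, 4)),
                           index=list("ABCD"), columns=list("ABCD"))
        out = rp.write_report(tmp_path / "run", qc=qc, cv_summary=cvs,
                              consensus_features=consensus, network_matrix=net,
                              operating_threshold=0.15,
                              permutation={"p_accuracy": 1 / 1001},
                              config={"seed": 5})
        back = rp.read_report(out)
        assert back["meta"]["operating_threshold"] == 0.15
        assert back["meta"]["permutation"]["p_accuracy"] == 1 / 1001
        pd.testing.assert_frame_equal(back["cv_summary"], cvs)
        pd.testing.assert_frame_equal(back["consensus_features"], consensus)

    def test_partial_report_marks_missing_sections(self, tmp_path):
        out = rp.write_report(tmp_path / "run", qc=None, cv_summary=None)
        back = rp.read_report(out)
        assert back["meta"]["sections_present"]["qc"] is False
        assert "qc" not in back
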