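"""Signature procedures: t-test calls, consensus, correlation, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emtnet.signatures import (
    MIR200_FAMILY,
    ExpressionMatrix,
    differential_signature,
    family_correlation_rank,
    intersect_signatures,
    merge_replicates,
    timepoint_de_filter,
)
from oracles import pearson_oracle, welch_t_oracle


def _matrix(values, n_e, n_m, features=None):
    n = n_e + n_m
    features = features or [f"mir{i}" for i in range(len(values))]
    samples = [f"s{i}" for i in range(n)]
    labels = pd.Series(["epithelial"] * n_e + ["mesenchymal"] * n_m, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples),
                            labels)


class TestDifferentialSignature:
    def test_identical_groups_not_significant(self):
        m = _matrix([[10, 10, 10, 10, 10, 10]], 3, 3)
        sig = differential_signature(m)
        assert not sig.table.significant.iloc[0]

    def test_down_direction(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(10, 0.1, 5), rng.normal(5, 0.1, 5)])
        sig = differential_signature(_matrix([vals], 5, 5))
        row = sig.table.iloc[0]
        assert row.direction == "DOWN" and row.significant

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 12))
        m = _matrix(vals, 6, 6)
        sig = differential_signature(m)
        for i in range(20):
            t = welch_t_oracle(vals[i, 6:], vals[i, :6])
            assert sig.table.t.iloc[i] == pytest.approx(t, abs=1e-10)
            p = 2 * stats.t.sf(abs(t), df=stats.ttest_ind(
                vals[i, 6:], vals[i, :6], equal_var=False).df)
            assert sig.table.p.iloc[i] == pytest.approx(p, abs=1e-10)

    def test_small_group_marked_untested(self):
        vals = np.ones((1, 5))
        vals[0, 0] = np.nan  # epithelial group left with 1 value
        m = _matrix(vals, 2, 3)
        sig = differential_signature(m)
        assert not sig.table.tested.iloc[0]
        assert not sig.table.significant.iloc[0]

    def test_pooled_option_matches_scipy(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 10))
        m = _matrix(vals, 5, 5)
        sig = differential_signature(m, equal_var=True)
        for i in range(5):
            t, _ = stats.ttest_ind(vals[i, 5:], vals[i, :5], equal_var=True)
            assert sig.table.t.iloc[i] == pytest.approx(float(t), abs=1e-10)

    def test_permutation_null_calibration(self):
        """Random relabelling produces significant calls at roughly the
        nominal alpha."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 16))
        hits = total = 0
        for _ in range(100):
            perm = rng.permutation(16)
            m = _matrix(vals[:, perm], 8, 8)
            sig = differential_signature(m, alpha=0.01)
            hits += int(sig.table.significant.sum())
            total += 40
        rate = hits / total
        assert 0.0005 < rate < 0.03  # loose binomial band around 0.01


class TestIntersectSignatures:
    def _sig(self, down=(), up=()):
        ids = sorted(set(down) | set(up)) or ["x"]
        table = pd.DataFrame({
            "t": 0.0, "p": 0.0001,
            "direction": ["DOWN" if i in down else "UP" for i in ids],
            "significant": [i in down or i in up for i in ids],
            "tested": True,
        }, index=pd.Index(ids, name="feature_id"))
        from emtnet.signatures import StudySignature
        return StudySignature(table, alpha=0.01)

    def test_single_study_identity(self):
        s = self._sig(down=("a", "b"))
        meta = intersect_signatures([s], "DOWN", min_studies=1)
        assert meta.consensus == {"a", "b"}

    def test_three_of_five(self):
        sigs = [self._sig(down=("a",)) if i in (0, 2, 4) else self._sig(up=("a",))
                for i in range(5)]
        meta = intersect_signatures(sigs, "DOWN", min_studies=3)
        assert "a" in meta.consensus
        assert meta.counts.loc["a", "down_count"] == 3
        assert meta.counts.loc["a", "up_count"] == 2

    def test_split_directions_excluded(self):
        sigs = [self._sig(down=("a",))] * 2 + [self._sig(up=("a",))] * 2
        meta = intersect_signatures(sigs, "DOWN", min_studies=3)
        assert "a" not in meta.consensus

    def test_order_invariance(self):
        sigs = [self._sig(down=("a", "b")), self._sig(down=("b",)),
                self._sig(down=("a",))]
        m1 = intersect_signatures(sigs, "DOWN", 2)
        m2 = intersect_signatures(sigs[::-1], "DOWN", 2)
        assert m1.consensus == m2.consensus
        assert m1.counts.equals(m2.counts)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            intersect_signatures([], "DOWN", 1)


class TestMergeReplicates:
    def test_probe_rows_averaged(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[1, 3], [3, 5]], index=["p1", "p2"], columns=["s1", "s2"]))
        out = merge_replicates(m, {"p1": "mirX", "p2": "mirX"})
        assert list(out.feature_ids) == ["mirX"]
        assert out.values.loc["mirX"].tolist() == [2.0, 4.0]

    def test_unmapped_passthrough(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["p1"],
                                          columns=["a", "b"]))
        out = merge_replicates(m, {})
        assert out.values.equals(m.values)

    def test_missing_ignored_in_mean(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[1, np.nan], [3, 5]], index=["p1", "p2"], columns=["s1", "s2"]))
        out = merge_replicates(m, {"p1": "x", "p2": "x"})
        assert out.values.loc["x"].tolist() == [2.0, 5.0]


class TestFamilyCorrelation:
    def test_identical_feature_ranks_first(self):
        rng = np.random.default_rng(5)
        fam = rng.normal(size=10)
        vals = pd.DataFrame(
            [fam, fam, rng.normal(size=10)],
            index=["hsa-miR-200a", "twin", "noise"],
            columns=[f"s{i}" for i in range(10)],
        )
        rep = family_correlation_rank(ExpressionMatrix(vals), ["hsa-miR-200a"])
        assert rep.table.loc["twin", "avg_correlation"] == pytest.approx(1.0)
        assert rep.table.loc["twin", "rank"] == 1

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(6, 20))
        ids = list(MIR200_FAMILY) + ["hsa-miR-203"]
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=ids, columns=[f"s{i}" for i in range(20)]))
        rep = family_correlation_rank(m)
        expected = np.mean([pearson_oracle(vals[5], vals[j]) for j in range(5)])
        assert rep.table.loc["hsa-miR-203", "avg_correlation"] == pytest.approx(
            expected, abs=1e-10)

    def test_family_self_correlation_excluded(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 30))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=list(MIR200_FAMILY), columns=[f"s{i}" for i in range(30)]))
        rep = family_correlation_rank(m)
        a = rep.table.loc["hsa-miR-200a", "avg_correlation"]
        expected = np.mean([pearson_oracle(vals[0], vals[j]) for j in range(1, 5)])
        assert a == pytest.approx(expected, abs=1e-10)

    def test_pure_noise_feature_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(7, 50))
        ids = list(MIR200_FAMILY) + ["hsa-miR-203", "noise"]
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=ids, columns=[f"s{i}" for i in range(50)]))
        rep = family_correlation_rank(m)
        assert abs(rep.table.loc["noise", "avg_correlation"]) < 0.2

    def test_zero_variance_ranks_last(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(
            [rng.normal(size=8), rng.normal(size=8), np.ones(8)],
            index=["hsa-miR-200a", "hsa-miR-200b", "flat"],
            columns=[f"s{i}" for i in range(8)])
        rep = family_correlation_rank(
            ExpressionMatrix(vals), ["hsa-miR-200a", "hsa-miR-200b"])
        assert np.isnan(rep.table.loc["flat", "avg_correlation"])
        assert rep.table.loc["flat", "rank"] == 3

    def test_invariance_to_sample_order_and_affine_rescaling(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(8, 25))
        ids = list(MIR200_FAMILY) + [f"m{i}" for i in range(3)]
        cols = [f"s{i}" for i in range(25)]
        m = ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=cols))
        base = family_correlation_rank(m).table["rank"]
        perm = rng.permutation(25)
        scaled = vals * rng.uniform(0.5, 3.0, size=(8, 1)) + rng.normal(size=(8, 1))
        m2 = ExpressionMatrix(pd.DataFrame(scaled[:, perm], index=ids,
                                           columns=[cols[i] for i in perm]))
        assert family_correlation_rank(m2).table["rank"].equals(base)


class TestTimepointFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["mirna", "time_point", "replicate",
                                           "log_ratio", "p_value"])

    def test_both_replicates_pass(self):
        t = self._table([("a", "72h", 1, -1.2, 0.001), ("a", "72h", 2, -0.9, 0.001)])
        out = timepoint_de_filter(t)
        row = out.loc[("a", "72h")]
        assert row.average == pytest.approx(-1.05)
        assert row.present and row.n_pass == 2

    def test_below_threshold_absent(self):
        t = self._table([("a", "72h", 1, -0.3, 0.001), ("a", "72h", 2, -0.2, 0.001)])
        row = timepoint_de_filter(t).loc[("a", "72h")]
        assert not row.present and np.isnan(row.average)

    def test_filter_then_average(self):
        t = self._table([("a", "72h", 1, -1.0, 0.001), ("a", "72h", 2, -0.1, 0.5)])
        row = timepoint_de_filter(t).loc[("a", "72h")]
        assert row.average == pytest.approx(-1.0)
        assert row.n_pass == 1

    def test_single_replicate_untestable(self):
        t = self._table([("a", "72h", 1, -1.0, 0.001)])
        row = timepoint_de_filter(t).loc[("a", "72h")]
        assert not row.testable

    def test_probe_level_p_values(self):
        probes = [[-1.0, -1.1, -0.9, -1.05], [0.01, -0.02, 0.03, 0.0]]
        t = pd.DataFrame({
            "mirna": ["a", "a"], "time_point": ["72h"] * 2, "replicate": [1, 2],
            "log_ratio": [float(np.mean(p)) for p in probes],
            "probe_ratios": probes,
        })
        row = timepoint_de_filter(t).loc[("a", "72h")]
        # replicate 1 passes (strong, consistent), replicate 2 fails |lr| filter
        assert row.n_pass == 1
        assert row.average == pytest.approx(np.mean(probes[0]))
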