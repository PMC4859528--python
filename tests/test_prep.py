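"""qPCR and microarray preprocessing."""

import numpy as np
import pandas as pd
import pytest

from mirindex import (
    ArrayFilterRule,
    CtMatrix,
    DetectionRule,
    ExpressionMatrix,
    QuantileNormalizer,
    collapse_probe_replicates,
    delta_ct_normalize,
    filter_array_probes,
    filter_detected_mirs,
    quantile_normalize,
)


def ct_matrix(rows: dict, controls=()):
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    return CtMatrix(frame, control_ids=list(controls))


class TestDetectionFilter:
    def test_exclusion_requires_strictly_more_than_the_fraction(self):
        n = 50
        rows = {
            "m62pct": [39.0] * 31 + [30.0] * 19,  # 62% undetected -> out
            "m60pct": [39.0] * 30 + [30.0] * 20,  # exactly 60% -> kept
            "m_at_limit": [38.0] * 50,  # CT == limit counts as detected
        }
        retained, excluded = filter_detected_mirs(ct_matrix(rows))
        assert excluded == ["m62pct"]
        assert list(retained.values.index) == ["m60pct", "m_at_limit"]
        assert len(excluded) + len(retained.values) == len(rows)

    def test_controls_survive_but_are_reported(self):
        rows = {"ctrl": [39.5] * 10, "m1": [30.0] * 10}
        retained, excluded = filter_detected_mirs(ct_matrix(rows, ["ctrl"]))
        assert "ctrl" in retained.values.index
        assert excluded == ["ctrl"]

    def test_rerun_on_retained_output_is_identity(self, rng):
        values = rng.uniform(20, 42, (30, 20))
        ct = CtMatrix(pd.DataFrame(values,
                                   index=[f"m{i}" for i in range(30)],
                                   columns=[f"s{i}" for i in range(20)]))
        once, _ = filter_detected_mirs(ct)
        twice, excluded2 = filter_detected_mirs(once)
        assert excluded2 == []
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestDeltaCt:
    def test_stated_arithmetic(self):
        rows = {"c1": [20.0], "c2": [22.0], "c3": [24.0], "m": [25.0]}
        expr = delta_ct_normalize(ct_matrix(rows, ["c1", "c2", "c3"]))
        # reference = median(20, 22, 24) = 22; dCT = 3; 2^-3 = 0.125
        assert expr.values.loc["m", "s0"] == pytest.approx(0.125)
        assert expr.scale == "linear" and expr.platform == "qpcr"

    def test_undetected_control_dropped_from_reference(self):
        rows = {"c1": [20.0], "c2": [39.5], "c3": [24.0], "m": [25.0]}
        expr = delta_ct_normalize(ct_matrix(rows, ["c1", "c2", "c3"]))
        assert expr.values.loc["m", "s0"] == pytest.approx(2.0 ** -(25 - 22))

    def test_monotone_decreasing_in_ct(self):
        rows = {"c1": [20.0, 20.0], "lo": [26.0, 26.0], "hi": [25.0, 25.0]}
        expr = delta_ct_normalize(ct_matrix(rows, ["c1"]))
        assert (expr.values.loc["lo"] < expr.values.loc["hi"]).all()

    def test_sample_wide_ct_shift_cancels(self, rng):
        base = rng.uniform(22, 34, (6, 4))
        ids = ["c1", "c2", "c3", "m1", "m2", "m3"]
        cols = list("abcd")
        ct1 = CtMatrix(pd.DataFrame(base, index=ids, columns=cols), ids[:3])
        shifted = base.copy()
        shifted[:, 2] += 1.7  # everything in one sample shifts together
        ct2 = CtMatrix(pd.DataFrame(shifted, index=ids, columns=cols), ids[:3])
        e1 = delta_ct_normalize(ct1)
        e2 = delta_ct_normalize(ct2)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_undetected_mirs_floor_imputed_at_limit(self):
        rows = {"c1": [30.0], "m": [41.0]}
        expr = delta_ct_normalize(ct_matrix(rows, ["c1"]))
        assert expr.values.loc["m", "s0"] == pytest.approx(2.0 ** -(38 - 30))

    def test_all_controls_undetected_names_the_sample(self):
        rows = {"c1": [39.0, 25.0], "m": [30.0, 30.0]}
        with pytest.raises(ValueError, match="s0"):
            delta_ct_normalize(ct_matrix(rows, ["c1"]))

    def test_strictly_positive_output(self, rng):
        values = rng.uniform(18, 42, (10, 8))
        ids = [f"m{i}" for i in range(7)] + ["c1", "c2", "c3"]
        ct = CtMatrix(pd.DataFrame(values, index=ids,
                                   columns=[f"s{i}" for i in range(8)]),
                      ["c1", "c2", "c3"])
        expr = delta_ct_normalize(ct)
        assert (expr.values.to_numpy() > 0).all()


class TestArrayProbeFilter:
    def make(self, flag_rows, groups):
        probes = pd.DataFrame(
            np.full((len(flag_rows), len(groups)), 8.0),
            index=list(flag_rows), columns=[f"s{i}" for i in range(len(groups))],
        )
        flags = pd.DataFrame(
            list(flag_rows.values()), index=list(flag_rows), columns=probes.columns
        )
        return probes, flags, pd.Series(groups, index=probes.columns)

    def test_per_group_strict_threshold(self):
        groups = ["g1"] * 10 + ["g2"] * 10
        probes, flags, gs = self.make(
            {
                "p40pct_one_group": [1] * 4 + [0] * 6 + [0] * 10,  # 40% in g1
                "p30pct_both": [1] * 3 + [0] * 7 + [1] * 3 + [0] * 7,  # exactly 30%
                "p_clean": [0] * 20,
            },
            groups,
        )
        kept = filter_array_probes(probes, flags, gs)
        assert list(kept.index) == ["p30pct_both", "p_clean"]

    def test_no_flags_is_identity(self):
        probes, flags, gs = self.make({"a": [0] * 6, "b": [0] * 6},
                                      ["g1"] * 3 + ["g2"] * 3)
        kept = filter_array_probes(probes, flags, gs)
        pd.testing.assert_frame_equal(kept, probes)

    def test_missing_group_label_rejected(self):
        probes, flags, gs = self.make({"a": [0] * 4}, ["g1", "g1", "g2", "g2"])
        gs = gs.drop("s3")
        with pytest.raises(ValueError, match="s3"):
            filter_array_probes(probes, flags, gs)


class TestProbeCollapse:
    def test_mean_of_replicates(self):
        probes = pd.DataFrame(
            {"s0": [6.0, 8.0, 5.0]}, index=["g1_p1", "g1_p2", "g2_p1"]
        )
        p2g = pd.Series({"g1_p1": "g1", "g1_p2": "g1", "g2_p1": "g2"})
        genes, dropped = collapse_probe_replicates(probes, p2g)
        assert genes.loc["g1", "s0"] == pytest.approx(7.0)
        assert genes.loc["g2", "s0"] == pytest.approx(5.0)  # single probe
        assert dropped == []

    def test_fully_filtered_gene_listed_as_dropped(self):
        probes = pd.DataFrame({"s0": [6.0]}, index=["g1_p1"])
        p2g = pd.Series({"g1_p1": "g1", "g2_p1": "g2"})
        genes, dropped = collapse_probe_replicates(probes, p2g)
        assert "g2" not in genes.index and dropped == ["g2"]

    def test_conflicting_mapping_rejected(self):
        probes = pd.DataFrame({"s0": [6.0]}, index=["p1"])
        p2g = pd.Series(["g1", "g2"], index=["p1", "p1"])
        with pytest.raises(ValueError, match="p1"):
            collapse_probe_replicates(probes, p2g)


class TestQuantileNormalize:
    def as_matrix(self, arr, groups=None):
        frame = pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=[f"g{i}" for i in range(len(arr))],
            columns=[f"s{i}" for i in range(np.asarray(arr).shape[1])],
        )
        gs = pd.Series(groups or ["x"] * frame.shape[1], index=frame.columns)
        return ExpressionMatrix(frame, "log2", "array", gs)

    def test_order_statistic_means(self):
        m = self.as_matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(m)
        expected = np.array([2.5, 3.5, 4.5])
        for col in out.values.columns:
            assert np.sort(out.values[col].to_numpy()) == pytest.approx(expected)

    def test_columns_share_sorted_vector_and_ranks_kept(self, rng):
        m = self.as_matrix(rng.normal(8, 1.5, (40, 6)))
        out = quantile_normalize(m)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for c in range(arr.shape[1]):
            assert np.sort(arr[:, c]) == pytest.approx(ref)
            before = m.values.iloc[:, c].rank().to_numpy()
            after = out.values.iloc[:, c].rank().to_numpy()
            assert (before == after).all()

    def test_idempotent(self, rng):
        m = self.as_matrix(rng.normal(size=(30, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_sample_warns_and_passes_through(self):
        m = self.as_matrix([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_sklearn_transformer_maps_ranks_to_reference(self, rng):
        X = rng.normal(size=(5, 30))
        qn = QuantileNormalizer().fit(X)
        out = qn.transform(X)
        ref = np.sort(X, axis=1).mean(axis=0)
        for r in range(out.shape[0]):
            assert np.sort(out[r]) == pytest.approx(ref)
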