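"""Probe-to-gene preprocessing stages, each against a hand-checkable oracle."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from rpewound import (SimulationConfig, average_replicate_probes,
                      collapse_probes_to_genes, detection_filter,
                      lowess_normalize, preprocess_array, quantile_normalize,
                      simulate_array_experiment, subtract_background)
from rpewound.arrays import PreprocessError


def annot_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "gene_symbol",
                                       "is_negative_control", "replicate_group"])


class TestBackgroundSubtraction:
    @pytest.fixture
    def fixture(self):
        raw = pd.DataFrame(
            {"s1": [100.0, 30.0, 200.0, 40.0, 40.0],
             "s2": [90.0, 75.0, 300.0, 55.0, 65.0]},
            index=["p1", "p2", "p3", "nc1", "nc2"])
        raw.index.name = "probe_id"
        annot = annot_frame([
            ("p1", "A", False, ""), ("p2", "B", False, ""),
            ("p3", "C", False, ""), ("nc1", "", True, ""), ("nc2", "", True, "")])
        return raw, annot

    def test_net_is_raw_minus_control_mean_per_sample(self, fixture):
        raw, annot = fixture
        net, background = subtract_background(raw, annot)
        # control means: s1 -> 40, s2 -> 60
        assert background["s1"] == 40.0 and background["s2"] == 60.0
        assert net.loc["p1", "s1"] == 60.0
        assert net.loc["p3", "s2"] == 240.0

    def test_values_below_floor_are_floored(self, fixture):
        raw, annot = fixture
        net, _ = subtract_background(raw, annot)
        assert net.loc["p2", "s1"] == 1.0  # 30 - 40 -> floored

    def test_no_negative_controls_is_an_error(self, fixture):
        raw, annot = fixture
        annot["is_negative_control"] = False
        with pytest.raises(PreprocessError, match="negative-control"):
            subtract_background(raw, annot)


class TestLowess:
    def _channels(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(4, 14, n)
        ch1 = pd.DataFrame({"s": 2.0 ** a}, index=[f"p{i}" for i in range(n)])
        return a, ch1

    def test_identical_channels_unchanged(self):
        _, ch1 = self._channels()
        out1, out2 = lowess_normalize(ch1, ch1.copy())
        np.testing.assert_allclose(out1.to_numpy(), ch1.to_numpy(), rtol=1e-10)
        np.testing.assert_allclose(out2.to_numpy(), ch1.to_numpy(), rtol=1e-10)

    def test_constant_dye_gain_removed(self):
        _, ch1 = self._channels()
        ch2 = ch1 * 2.0
        out1, out2 = lowess_normalize(ch1, ch2)
        m = np.log2(out2.to_numpy() / out1.to_numpy())
        assert np.abs(m).max() < 1e-6

    def test_smooth_intensity_dependent_bias_removed(self):
        # planted M(A) = 0.5*sin(A); oracle: independent local regression of
        # the residual should be ~flat and residual |M| small for most probes
        a, ch1 = self._channels(n=1000, seed=1)
        bias = 0.5 * np.sin(a)
        ch2 = pd.DataFrame({"s": 2.0 ** (a + bias)}, index=ch1.index)
        out1, out2 = lowess_normalize(ch1, ch2)
        m_resid = np.log2(out2["s"] / out1["s"]).to_numpy()
        assert np.quantile(np.abs(m_resid), 0.95) < 0.1

    def test_residual_trend_flat_for_bias_within_bandwidth(self):
        # bias varying slower than the smoother window: refit of the
        # corrected M on A should be ~0 everywhere
        a, ch1 = self._channels(n=1000, seed=1)
        bias = 0.5 * np.sin(a / 2.0)
        ch2 = pd.DataFrame({"s": 2.0 ** (a + bias)}, index=ch1.index)
        out1, out2 = lowess_normalize(ch1, ch2)
        m_resid = np.log2(out2["s"] / out1["s"]).to_numpy()
        refit = sm_lowess(m_resid, a, frac=0.3, return_sorted=False)
        assert np.abs(refit).max() < 0.05

    def test_nonpositive_intensity_names_probe(self):
        _, ch1 = self._channels(n=10)
        ch2 = ch1.copy()
        ch2.iloc[3, 0] = -5.0
        with pytest.raises(PreprocessError, match="p3"):
            lowess_normalize(ch1, ch2)


class TestReplicateAveraging:
    def test_group_mean_per_sample(self):
        net = pd.DataFrame({"s1": [1.0, 3.0, 7.0], "s2": [10.0, 30.0, 5.0]},
                           index=["r1", "r2", "solo"])
        annot = annot_frame([("r1", "A", False, "G1"), ("r2", "A", False, "G1"),
                             ("solo", "B", False, "")])
        out, out_annot = average_replicate_probes(net, annot)
        assert out.loc["r1", "s1"] == 2.0 and out.loc["r1", "s2"] == 20.0
        assert out.loc["solo", "s1"] == 7.0 and out.loc["solo", "s2"] == 5.0

    def test_identical_replicates_collapse_to_value(self):
        net = pd.DataFrame({"s": [5.0] * 10}, index=[f"r{i}" for i in range(10)])
        annot = annot_frame([(f"r{i}", "A", False, "G") for i in range(10)])
        out, _ = average_replicate_probes(net, annot)
        assert len(out) == 1 and out.iloc[0, 0] == 5.0

    def test_200_groups_of_10_collapse_to_200_rows(self):
        rng = np.random.default_rng(0)
        rows, annot_rows = [], []
        for g in range(200):
            for r in range(10):
                rows.append((f"g{g:03d}_r{r}", rng.uniform(10, 100)))
                annot_rows.append((f"g{g:03d}_r{r}", f"GENE{g}", False, f"grp{g:03d}"))
        net = pd.DataFrame({"s": [v for _, v in rows]},
                           index=[p for p, _ in rows])
        out, out_annot = average_replicate_probes(net, annot_frame(annot_rows))
        assert len(out) == 200
        assert len(out_annot) == 200

    def test_singleton_group_is_identity(self):
        net = pd.DataFrame({"s": [4.0]}, index=["only"])
        annot = annot_frame([("only", "A", False, "G1")])
        out, _ = average_replicate_probes(net, annot)
        assert out.loc["only", "s"] == 4.0


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 6.0, 8.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out["b"], [2.5, 4.0, 5.5])

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_idempotence(self, rng):
        m = pd.DataFrame(rng.lognormal(3, 1, (50, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)

    def test_rank_preservation_and_equal_distributions(self, rng):
        m = pd.DataFrame(rng.normal(size=(100, 5)))
        out = quantile_normalize(m)
        for j in m.columns:
            assert (np.argsort(m[j].to_numpy()) ==
                    np.argsort(out[j].to_numpy())).all()
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.ptp(sorted_cols, axis=1).max() < 1e-12

    def test_ties_get_mean_of_spanned_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(
            0.5 * (ref[0] + ref[1]))


class TestDetectionFilter:
    def test_boundary_is_inclusive(self):
        net = pd.DataFrame({"s1": [20.0], "s2": [5.0]}, index=["p"])
        bg = pd.Series({"s1": 10.0, "s2": 10.0})
        assert "p" in detection_filter(net, bg).kept

    def test_below_twice_background_everywhere_discarded(self):
        net = pd.DataFrame({"s1": [19.9], "s2": [19.9]}, index=["p"])
        bg = pd.Series({"s1": 10.0, "s2": 10.0})
        assert len(detection_filter(net, bg).kept) == 0

    def test_ten_probe_enumeration(self):
        # oracle: hand enumeration against per-sample backgrounds {10, 20}
        net = pd.DataFrame(
            {"s1": [25, 19, 5, 20, 1, 100, 15, 19.99, 39, 2],
             "s2": [10, 41, 39, 10, 1, 5, 40, 39.99, 41, 80]},
            index=[f"p{i}" for i in range(10)], dtype=float)
        bg = pd.Series({"s1": 10.0, "s2": 20.0})
        kept = set(detection_filter(net, bg).kept)
        assert kept == {"p0", "p1", "p3", "p5", "p6", "p8", "p9"}

    def test_flags_match_kept(self):
        net = pd.DataFrame({"s1": [25.0, 5.0]}, index=["a", "b"])
        bg = pd.Series({"s1": 10.0})
        res = detection_filter(net, bg)
        assert res.flags.loc["a", "s1"] and not res.flags.loc["b", "s1"]


class TestCollapseProbes:
    def test_single_probe_gene_passes_through(self):
        net = pd.DataFrame({"s": [7.0]}, index=["p1"])
        annot = annot_frame([("p1", "A", False, "")])
        out = collapse_probes_to_genes(net, annot)
        assert out.loc["A", "s"] == 7.0

    def test_highest_mean_probe_selected(self):
        net = pd.DataFrame({"s1": [10.0, 50.0, 20.0], "s2": [10.0, 50.0, 20.0]},
                           index=["p1", "p2", "p3"])
        annot = annot_frame([("p1", "A", False, ""), ("p2", "A", False, ""),
                             ("p3", "A", False, "")])
        out = collapse_probes_to_genes(net, annot)
        assert out.loc["A", "s1"] == 50.0

    def test_tie_breaks_to_smallest_probe_id(self):
        net = pd.DataFrame({"s1": [30.0, 30.0], "s2": [31.0, 31.0]},
                           index=["pB", "pA"])
        annot = annot_frame([("pB", "A", False, ""), ("pA", "A", False, "")])
        out = collapse_probes_to_genes(net, annot)
        pd.testing.assert_series_equal(out.loc["A"], net.loc["pA"],
                                       check_names=False)

    def test_unannotated_probes_dropped_and_rows_unique(self):
        net = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["p1", "p2", "nc"])
        annot = annot_frame([("p1", "A", False, ""), ("p2", "B", False, ""),
                             ("nc", "", True, "")])
        out = collapse_probes_to_genes(net, annot)
        assert set(out.index) == {"A", "B"}
        assert out.index.is_unique


class TestPipeline:
    def test_end_to_end_deterministic_and_traceable(self, small_config):
        probes, annot, sheet, _ = simulate_array_experiment(small_config)
        r1 = preprocess_array(probes, annot)
        r2 = preprocess_array(probes, annot)
        pd.testing.assert_frame_equal(r1["gene_matrix"], r2["gene_matrix"])
        assert r1["n_genes"] <= small_config.n_genes
        # collapse never increases rows
        assert r1["n_genes"] <= r1["n_probes_detected"]

    def test_replicate_block_absent_after_averaging(self, small_config):
        probes, annot, _, _ = simulate_array_experiment(small_config)
        result = preprocess_array(probes, annot)
        # detection flags are on the averaged probe set: one row per group
        rep_probes = annot.loc[annot["replicate_group"] != "", "probe_id"]
        flagged = result["detection_flags"].index
        assert len(set(rep_probes) & set(flagged)) == small_config.n_replicate_probes
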