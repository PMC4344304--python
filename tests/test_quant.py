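"""RPM normalization and threshold calling."""

import numpy as np
import pandas as pd
import pytest

from mirmeth.quant import (DiffParams, RipParams, call_differential,
                           call_methylated, filter_expressed,
                           log2_fold_changes, normalize_rpm)


def matrix(data, samples=None):
    return pd.DataFrame(data).T if samples is None else \
        pd.DataFrame(data, columns=samples)


class TestNormalize:
    def test_single_reference_gets_the_whole_million(self):
        counts = pd.DataFrame({"s1": [5]}, index=["A"])
        norm = normalize_rpm(counts)
        assert norm.loc["A", "s1"] == pytest.approx(1e6)

    def test_proportional_split(self):
        counts = pd.DataFrame({"s1": [3, 1]}, index=["A", "B"])
        norm = normalize_rpm(counts)
        assert norm["s1"].tolist() == pytest.approx([750000.0, 250000.0])

    def test_spikes_share_denominator_but_do_not_contribute(self):
        counts = pd.DataFrame({"s1": [3, 97]}, index=["A", "siRNA"])
        norm = normalize_rpm(counts, spike_names=["siRNA"])
        assert norm.loc["A", "s1"] == pytest.approx(1e6)
        assert norm.loc["siRNA", "s1"] == pytest.approx(97 / 3 * 1e6)

    def test_zero_sample_yields_zero_column(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["A", "B"])
        with caplog.at_level("WARNING"):
            norm = normalize_rpm(counts)
        assert (norm["s1"] == 0).all()
        assert "zero mapped" in caplog.text

    def test_non_spike_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 6)),
            index=[f"m{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(6)],
        )
        counts.iloc[0, :] += 1  # ensure non-zero samples
        spikes = ["m0", "m1"]
        norm = normalize_rpm(counts, spikes)
        sums = norm.drop(index=spikes).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)


class TestExpressed:
    def test_boundary_is_inclusive(self):
        norm = pd.DataFrame({"a": [15.0], "b": [15.0], "c": [15.0]},
                            index=["m"])
        assert filter_expressed(norm, ["a", "b", "c"], 15.0) == ["m"]

    def test_all_samples_rule(self):
        norm = pd.DataFrame({"a": [14.9], "b": [100.0], "c": [100.0]},
                            index=["m"])
        assert filter_expressed(norm, ["a", "b", "c"], 15.0) == []

    def test_equals_bruteforce_row_scan(self, rng):
        norm = pd.DataFrame(rng.uniform(0, 40, size=(30, 3)),
                            index=[f"m{i}" for i in range(30)],
                            columns=["a", "b", "c"])
        got = set(filter_expressed(norm, ["a", "b", "c"], 15.0))
        want = {i for i in norm.index
                if all(norm.loc[i, s] >= 15.0 for s in ["a", "b", "c"])}
        assert got == want

    def test_raising_threshold_shrinks_the_set(self, rng):
        norm = pd.DataFrame(rng.uniform(0, 200, size=(50, 3)),
                            columns=["a", "b", "c"])
        sets = [set(filter_expressed(norm, ["a", "b", "c"], t))
                for t in (10, 50, 100)]
        assert sets[2] <= sets[1] <= sets[0]


def kd_matrix(control, treated):
    data = {}
    for i, v in enumerate(control):
        data[f"scr_{i}"] = [v]
    for i, v in enumerate(treated):
        data[f"kd_{i}"] = [v]
    return pd.DataFrame(data, index=["m"])


KD_PAIRS = [(f"kd_{i}", f"scr_{i}") for i in range(3)]


class TestDifferential:
    def test_downregulated_call(self):
        norm = kd_matrix(control=(20, 18, 30), treated=(5, 6, 9))
        out = call_differential(norm, KD_PAIRS)
        # mean of per-pair ratios: (5/20 + 6/18 + 9/30)/3
        assert out.loc["m", "mean_fc"] == pytest.approx(0.29444, abs=1e-4)
        assert out.loc["m", "status_fold2"] == "down"

    def test_exact_half_is_not_down(self):
        norm = kd_matrix(control=(15, 15, 15), treated=(7.5, 7.5, 7.5))
        out = call_differential(norm, KD_PAIRS)
        assert out.loc["m", "mean_fc"] == pytest.approx(0.5)
        assert out.loc["m", "status_fold2"] == "none"
        assert out.loc["m", "status_fold1_5"] == "down"  # 0.5 < 1/1.5

    def test_upregulated_call(self):
        norm = kd_matrix(control=(10, 10, 10), treated=(40, 40, 40))
        out = call_differential(norm, KD_PAIRS)
        assert out.loc["m", "mean_fc"] == pytest.approx(4.0)
        assert out.loc["m", "status_fold2"] == "up"

    def test_low_expression_blocks_calls(self):
        norm = kd_matrix(control=(14, 100, 100), treated=(5, 6, 9))
        out = call_differential(norm, KD_PAIRS)
        assert out.loc["m", "status_fold2"] == "none"

    def test_zero_control_uses_pseudocount(self):
        norm = kd_matrix(control=(0, 10, 10), treated=(5, 5, 5))
        out = call_differential(norm, KD_PAIRS)
        assert np.isfinite(out.loc["m", "mean_fc"])
        assert out.loc["m", "fc_1"] == pytest.approx(6.0)  # (5+1)/(0+1)

    def test_unknown_sample_rejected(self):
        norm = kd_matrix(control=(1, 1, 1), treated=(1, 1, 1))
        with pytest.raises(ValueError, match="nope"):
            call_differential(norm, [("nope", "scr_0")])


def rip_matrices(ip, ctrl):
    idx = ["m"]
    return (pd.DataFrame({f"m6A_{i}": [v] for i, v in enumerate(ip)},
                         index=idx),
            pd.DataFrame({f"IgG_{i}": [v] for i, v in enumerate(ctrl)},
                         index=idx))


class TestMethylated:
    def test_enriched_and_abundant_is_methylated(self):
        ip, ctrl = rip_matrices((250, 300, 260), (50, 60, 70))
        out = call_methylated(ip, ctrl)
        expected = np.mean([251 / 51, 301 / 61, 261 / 71])
        assert out.loc["m", "mean_enrichment"] == pytest.approx(expected)
        assert bool(out.loc["m", "methylated"])

    def test_cutoff_applies_to_every_ip_replicate(self):
        ip, ctrl = rip_matrices((99, 300, 300), (10, 10, 10))
        out = call_methylated(ip, ctrl)
        assert not bool(out.loc["m", "methylated"])

    def test_pseudocount_handles_zero_controls(self):
        ip, ctrl = rip_matrices((500, 500, 500), (0, 0, 0))
        out = call_methylated(ip, ctrl)
        assert out.loc["m", "mean_enrichment"] == pytest.approx(501.0)
        assert bool(out.loc["m", "methylated"])

    def test_unpaired_replicates_rejected(self):
        ip, ctrl = rip_matrices((1, 1, 1), (1, 1))
        with pytest.raises(ValueError, match="unpaired"):
            call_methylated(ip, ctrl)

    def test_sorted_by_mean_enrichment_descending(self, rng):
        n = 20
        ip = pd.DataFrame(rng.uniform(50, 500, size=(n, 3)),
                          index=[f"m{i}" for i in range(n)])
        ctrl = pd.DataFrame(rng.uniform(1, 100, size=(n, 3)),
                            index=ip.index)
        out = call_methylated(ip, ctrl)
        assert (out["mean_enrichment"].diff().dropna() <= 1e-12).all()

    def test_monotone_in_thresholds(self, rng):
        n = 50
        ip = pd.DataFrame(rng.uniform(0, 400, size=(n, 3)),
                          index=[f"m{i}" for i in range(n)])
        ctrl = pd.DataFrame(rng.uniform(0, 200, size=(n, 3)), index=ip.index)
        base = call_methylated(ip, ctrl, RipParams())
        stricter_rpm = call_methylated(ip, ctrl, RipParams(min_rpm=200))
        stricter_fold = call_methylated(ip, ctrl, RipParams(min_fold=4))
        s0 = set(base.index[base["methylated"]])
        assert set(stricter_rpm.index[stricter_rpm["methylated"]]) <= s0
        assert set(stricter_fold.index[stricter_fold["methylated"]]) <= s0


class TestLog2Table:
    def test_log2_values_and_exclusions(self, caplog):
        enr = pd.DataFrame({"mean_enrichment": [485.21, 0.0]},
                           index=["hi", "zero"])
        diff = pd.DataFrame({"mean_fc": [0.5, 1.0]}, index=["hi", "zero"])
        with caplog.at_level("WARNING"):
            out = log2_fold_changes(enr, diff)
        assert list(out.index) == ["hi"]
        assert out.loc["hi", "log2_enrichment"] == pytest.approx(8.92256,
                                                                 abs=1e-4)
        assert out.loc["hi", "log2_kd_fc"] == pytest.approx(-1.0)

    def test_unit_fold_change_maps_to_zero(self):
        enr = pd.DataFrame({"mean_enrichment": [1.0]}, index=["m"])
        diff = pd.DataFrame({"mean_fc": [1.0]}, index=["m"])
        out = log2_fold_changes(enr, diff)
        assert out.loc["m", "log2_enrichment"] == 0.0
        assert out.loc["m", "log2_kd_fc"] == 0.0
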