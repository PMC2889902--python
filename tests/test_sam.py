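"""SAM statistic, filtering, aggregation, and the tissue-dilution model."""

import numpy as np
import pandas as pd
import pytest

from teleoarray.sam import (
    SamParameters,
    aggregate_to_transcripts,
    dilution_adjusted_fc,
    fold_change,
    impute_missing,
    missing_value_filter,
    sam_two_class,
    signed_fold_change,
)

from conftest import make_dataset


class TestMissingValueFilter:
    def test_three_missing_of_four_removed(self):
        flags = np.ones((2, 8), dtype=int)
        flags[0, 4:7] = 0  # three missing in the deformed condition
        ds = make_dataset(
            np.full((2, 8), 100.0), flags,
            conditions=["normal"] * 4 + ["deformed"] * 4,
        )
        filtered, removed = missing_value_filter(ds)
        assert removed == [ds.probe_ids[0]]
        assert list(filtered.probe_ids) == [ds.probe_ids[1]]

    def test_two_and_two_missing_retained(self):
        flags = np.ones((1, 8), dtype=int)
        flags[0, [0, 1, 4, 5]] = 0  # exactly two per condition: boundary kept
        ds = make_dataset(
            np.full((1, 8), 100.0), flags,
            conditions=["normal"] * 4 + ["deformed"] * 4,
        )
        filtered, removed = missing_value_filter(ds)
        assert removed == []
        assert len(filtered.probe_ids) == 1

    def test_all_present_removes_nothing(self):
        ds = make_dataset(np.full((5, 8), 10.0), conditions=["normal"] * 4 + ["deformed"] * 4)
        _filtered, removed = missing_value_filter(ds)
        assert removed == []

    def test_imputation_uses_within_condition_mean(self):
        intensities = np.array([[10.0, 20.0, 999.0, 40.0, 40.0, 40.0]])
        flags = np.array([[1, 1, 0, 1, 1, 1]])
        ds = make_dataset(
            intensities, flags, conditions=["normal"] * 3 + ["deformed"] * 3
        )
        imputed = impute_missing(ds)
        assert imputed.intensities.iloc[0, 2] == pytest.approx(15.0)  # mean(10, 20)


class TestSamStatistic:
    def test_hand_computed_pooled_d(self):
        # reference class mean 5 with squared deviations summing to 2, the
        # deformed class mean 2 likewise; s0 = 0
        values = pd.DataFrame(
            [[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]],
            index=["p1"], columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series(
            ["normal"] * 3 + ["deformed"] * 3, index=values.columns
        )
        result = sam_two_class(values, labels, SamParameters(s0=0.0))
        s_expected = np.sqrt((2 + 2) * (1 / 3 + 1 / 3) / 4)
        assert s_expected == pytest.approx(0.8165, abs=1e-4)
        assert result.table.loc["p1", "d"] == pytest.approx(-3 / s_expected)
        assert result.table.loc["p1", "d"] == pytest.approx(-3.674, abs=1e-3)

    def test_no_signal_no_noise_gives_zero_d(self):
        values = pd.DataFrame(
            np.tile([5.0, 6.0, 7.0, 5.0, 6.0, 7.0], (4, 1)),
            index=[f"p{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series(["normal"] * 3 + ["deformed"] * 3, index=values.columns)
        result = sam_two_class(values, labels, SamParameters(s0=1.0))
        assert np.allclose(result.table["d"], 0.0)
        assert not result.table["significant"].any()

    def test_label_swap_negates_d_and_preserves_calls(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(8, 1, size=(50, 8)),
            index=[f"p{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(8)],
        )
        values.iloc[:5, 4:] += 3.0
        labels = pd.Series(["normal"] * 4 + ["deformed"] * 4, index=values.columns)
        params = SamParameters(seed=1)
        forward = sam_two_class(values, labels, params, classes=("normal", "deformed"))
        backward = sam_two_class(values, labels, params, classes=("deformed", "normal"))
        assert np.allclose(forward.table["d"], -backward.table["d"])
        assert forward.table["significant"].sum() == backward.table["significant"].sum()

    def test_null_data_yields_almost_no_calls(self):
        # single-probe call sets can slip through with an estimated FDR of 0
        # (median false-call quantization), so the bound is on the typical case
        n_calls = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(
                rng.normal(8, 1, size=(500, 8)),
                columns=[f"s{i}" for i in range(8)],
            )
            labels = pd.Series(["normal"] * 4 + ["deformed"] * 4, index=values.columns)
            result = sam_two_class(values, labels, SamParameters(seed=seed))
            assert result.exhaustive and result.n_permutations == 70
            n_calls.append(int(result.table["significant"].sum()))
        assert np.median(n_calls) <= 1
        assert max(n_calls) <= 0.05 * 500

    def test_too_few_replicates_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        labels = pd.Series(["normal", "normal", "deformed"], index=values.columns)
        with pytest.raises(ValueError):
            sam_two_class(values, labels)

    def test_zero_variance_probe_with_zero_s0_rejected(self):
        values = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0]], columns=["a", "b", "c", "d"]
        )
        labels = pd.Series(["n", "n", "d", "d"], index=values.columns)
        with pytest.raises(ValueError):
            sam_two_class(values, labels, SamParameters(s0=0.0))


class TestFoldChange:
    def test_signed_convention(self):
        assert signed_fold_change(0.25) == pytest.approx(-4.0)
        assert signed_fold_change(1.0) == 1.0
        assert signed_fold_change(4.0) == 4.0
        # an 0.08 ratio reads as -12.5-fold down-regulation
        assert signed_fold_change(0.08) == pytest.approx(-12.5)

    def test_group_mean_ratio(self):
        ds = make_dataset(
            np.array([[100.0, 100.0, 25.0, 25.0]]),
            conditions=["normal", "normal", "deformed", "deformed"],
        )
        fc = fold_change(ds.intensities, ds.samples["condition"], ("normal", "deformed"))
        assert fc["ratio_fc"].iloc[0] == pytest.approx(0.25)
        assert fc["signed_fc"].iloc[0] == pytest.approx(-4.0)

    def test_nonpositive_mean_flagged(self):
        frame = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], columns=list("abcd"))
        labels = pd.Series(["n", "n", "d", "d"], index=frame.columns)
        with pytest.raises(ValueError):
            fold_change(frame, labels, ("n", "d"))


class TestAggregation:
    platform = ["T1_1", "T1_2", "T2_1", "T2_2", "T3_1", "T3_2", "T4_1"]

    def test_both_probe_category(self):
        calls = aggregate_to_transcripts(["T1_1", "T1_2"], self.platform)
        assert calls.table.loc["T1", "category"] == "both-probe"
        assert calls.counts["n_transcripts"] == 1

    def test_filtered_second_probe_category(self):
        calls = aggregate_to_transcripts(
            ["T2_1"], self.platform, filtered_probe_ids=["T2_2"]
        )
        assert calls.table.loc["T2", "category"] == "single-filtered"

    def test_exhaustive_bookkeeping_on_toy_call_set(self):
        sig = ["T1_1", "T1_2", "T2_1", "T3_2", "T4_1"]
        calls = aggregate_to_transcripts(
            sig, self.platform, filtered_probe_ids=["T3_1"]
        )
        assert calls.table.loc["T1", "category"] == "both-probe"
        assert calls.table.loc["T2", "category"] == "single-not-significant"
        assert calls.table.loc["T3", "category"] == "single-filtered"
        assert calls.table.loc["T4", "category"] == "single-on-platform"
        # conservation: 2 x both + singles = significant probes
        n_both = calls.counts.get("both-probe", 0)
        n_single = calls.counts["n_transcripts"] - n_both
        assert 2 * n_both + n_single == len(sig)

    def test_orphan_probe_raises(self):
        with pytest.raises(KeyError):
            aggregate_to_transcripts(["TX_9"], self.platform)


class TestDilutionModel:
    def test_tenth_of_tissue(self):
        assert dilution_adjusted_fc(1 / 10, 10.0) == pytest.approx(1.9)

    def test_thirtieth_of_tissue(self):
        assert dilution_adjusted_fc(1 / 30, 10.0) == pytest.approx(1.3)

    def test_whole_tissue_identity(self):
        assert dilution_adjusted_fc(1.0, 7.3) == pytest.approx(7.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dilution_adjusted_fc(0.0, 10.0)
        with pytest.raises(ValueError):
            dilution_adjusted_fc(0.5, -1.0)
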