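import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromcut.io_tracks import CountMatrix
from chromcut.screen_counts import (
    SamplePair,
    chromosome_summary,
    control_size_factors,
    log2_fold_change,
    pairs_from_metadata,
    region_dose_comparison,
    total_count_normalize,
)


def make_cm(counts: dict, controls=(), sample_info=None) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="guide")
    if controls:
        df.index = pd.Index(
            [f"CTRL_{i:03d}" if i in controls else f"g{i}" for i in range(len(df))],
            name="guide",
        )
    is_control = pd.Series(
        [i in controls for i in range(len(df))], index=df.index
    )
    return CountMatrix(counts=df, is_control=is_control, sample_info=sample_info)


class TestTotalCountNormalize:
    def test_hand_computed_rpm(self):
        cm = make_cm({"s1": [10, 30], "s2": [1, 3]})
        rpm = total_count_normalize(cm)
        assert rpm["s1"].tolist() == [250_000.0, 750_000.0]
        assert rpm["s2"].tolist() == [250_000.0, 750_000.0]

    def test_every_sample_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        cm = make_cm({f"s{j}": rng.integers(0, 500, size=50) for j in range(4)})
        rpm = total_count_normalize(cm)
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_zero_total_sample_rejected(self):
        cm = make_cm({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            total_count_normalize(cm)


class TestControlSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_cm({"s1": [10, 20, 30], "s2": [10, 20, 30]}, controls={0, 1, 2})
        assert np.allclose(control_size_factors(cm), 1.0)

    def test_doubled_sample_gets_sqrt2_vs_inverse_sqrt2(self):
        # geometric mean sits between the two samples, so a uniform 2x
        # depth difference splits symmetrically in ratio space
        cm = make_cm({"s1": [10, 20, 40], "s2": [20, 40, 80]}, controls={0, 1, 2})
        sf = control_size_factors(cm)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))

    def test_hand_computed_median_of_ratios(self):
        counts = {
            "s1": [100, 10, 50, 7, 3],
            "s2": [200, 10, 60, 7, 3],
            "s3": [100, 40, 55, 7, 3],
        }
        cm = make_cm(counts, controls={0, 1, 2, 3, 4})
        arr = np.array(list(zip(*counts.values())), dtype=float)
        geo = np.exp(np.log(arr).mean(axis=1))
        expected = np.median(arr / geo[:, None], axis=0)
        assert np.allclose(control_size_factors(cm), expected)

    def test_zero_count_controls_are_excluded(self):
        cm = make_cm(
            {"s1": [10, 0, 10], "s2": [10, 500, 10]}, controls={0, 1, 2}
        )
        # the zero-containing control would otherwise drag s2's factor up
        assert np.allclose(control_size_factors(cm), 1.0)

    def test_targeting_guides_are_ignored(self):
        cm = make_cm({"s1": [10, 999], "s2": [10, 1]}, controls={0})
        assert np.allclose(control_size_factors(cm), 1.0)

    def test_no_controls_rejected(self):
        cm = make_cm({"s1": [1, 2], "s2": [3, 4]})
        with pytest.raises(ValueError, match="no control"):
            control_size_factors(cm)


class TestLog2FoldChange:
    def _sf(self, samples):
        return pd.Series(1.0, index=pd.Index(samples), name="size_factor")

    def test_equal_counts_give_zero(self):
        cm = make_cm({"d4_r1": [7, 80], "d16_r1": [7, 80]})
        fc = log2_fold_change(
            cm, self._sf(cm.counts.columns), [SamplePair("r1", "d4_r1", "d16_r1")]
        )
        assert np.allclose(fc.mean, 0.0)

    def test_pseudocount_arithmetic(self):
        cm = make_cm({"d4_r1": [100], "d16_r1": [25]})
        fc = log2_fold_change(
            cm, self._sf(cm.counts.columns), [SamplePair("r1", "d4_r1", "d16_r1")]
        )
        assert fc.mean.iloc[0] == pytest.approx(np.log2(25.5 / 100.5))

    def test_size_factor_rescaling_cancels_depth(self):
        # target has uniformly twice the depth; factor 2 must cancel it
        cm = make_cm({"d4_r1": [100, 10], "d16_r1": [200, 20]})
        sf = pd.Series({"d4_r1": 1.0, "d16_r1": 2.0}, name="size_factor")
        fc = log2_fold_change(cm, sf, [SamplePair("r1", "d4_r1", "d16_r1")])
        assert np.allclose(fc.mean, 0.0)

    def test_mean_over_replicates(self):
        cm = make_cm({"d4_r1": [100], "d16_r1": [100], "d4_r2": [100], "d16_r2": [25]})
        pairs = [SamplePair("r1", "d4_r1", "d16_r1"), SamplePair("r2", "d4_r2", "d16_r2")]
        fc = log2_fold_change(cm, self._sf(cm.counts.columns), pairs)
        assert fc.per_replicate.shape == (1, 2)
        assert fc.mean.iloc[0] == pytest.approx(np.log2(25.5 / 100.5) / 2)

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.integers(min_value=0, max_value=10_000),
        b=st.integers(min_value=0, max_value=10_000),
    )
    def test_swapping_reference_and_target_negates(self, a, b):
        cm = make_cm({"x": [a], "y": [b]})
        sf = self._sf(["x", "y"])
        fwd = log2_fold_change(cm, sf, [SamplePair("r1", "x", "y")]).mean.iloc[0]
        rev = log2_fold_change(cm, sf, [SamplePair("r1", "y", "x")]).mean.iloc[0]
        assert fwd == pytest.approx(-rev)

    def test_sample_shared_between_pairs_rejected(self):
        cm = make_cm({"a": [1], "b": [2], "c": [3]})
        with pytest.raises(ValueError, match="more than one pair"):
            log2_fold_change(
                cm, self._sf(["a", "b", "c"]),
                [SamplePair("r1", "a", "b"), SamplePair("r2", "a", "c")],
            )

    def test_nonpositive_pseudocount_rejected(self):
        cm = make_cm({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(
                cm, self._sf(["a", "b"]), [SamplePair("r1", "a", "b")], pseudocount=0
            )


class TestPairsFromMetadata:
    def _cm(self, rows):
        info = pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"])
        info = info.set_index("sample")
        counts = pd.DataFrame(
            {s: [1, 2] for s in info.index},
            index=pd.Index(["g0", "g1"], name="guide"),
        )
        return CountMatrix(
            counts=counts,
            is_control=pd.Series([False, False], index=counts.index),
            sample_info=info,
        )

    def test_one_pair_per_replicate(self):
        cm = self._cm(
            [("d4_r1", 4, "r1"), ("d16_r1", 16, "r1"),
             ("d4_r2", 4, "r2"), ("d16_r2", 16, "r2"),
             ("d8_r1", 8, "r1"), ("d8_r2", 8, "r2")]
        )
        pairs = pairs_from_metadata(cm, reference_day=4, target_day=16)
        assert [(p.replicate, p.reference, p.target) for p in pairs] == [
            ("r1", "d4_r1", "d16_r1"), ("r2", "d4_r2", "d16_r2")
        ]
        day8 = pairs_from_metadata(cm, reference_day=4, target_day=8)
        assert [p.target for p in day8] == ["d8_r1", "d8_r2"]

    def test_missing_target_day_rejected(self):
        cm = self._cm([("d4_r1", 4, "r1"), ("d16_r1", 16, "r1"), ("d4_r2", 4, "r2")])
        with pytest.raises(ValueError, match="r2"):
            pairs_from_metadata(cm, reference_day=4, target_day=16)

    def test_no_metadata_rejected(self):
        cm = make_cm({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="metadata"):
            pairs_from_metadata(cm)


def _guide_frame(n, chrom_of, cut_of):
    return pd.DataFrame(
        {
            "id": [f"g{i}" for i in range(n)],
            "chrom": [chrom_of(i) for i in range(n)],
            "cut_pos": [cut_of(i) for i in range(n)],
            "is_control": [False] * n,
        }
    )


class TestRegionDoseComparison:
    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(1)
        n = 60
        guides = _guide_frame(
            n, lambda i: "chr1" if i < 20 else "chr2", lambda i: 1000 * i
        )
        fc = pd.Series(rng.normal(0, 0.1, size=n), index=[f"g{i}" for i in range(n)])
        fc.iloc[:20] -= 2.0  # chr1 guides strongly depleted
        res = region_dose_comparison(fc, guides, ("chr1", 0, 100_000))
        assert res["n_inside"] == 20 and res["n_outside"] == 40
        assert res["median_difference"] == pytest.approx(-2.0, abs=0.2)
        assert res["pvalue"] < 1e-6

    def test_null_shift_is_not_significant(self):
        rng = np.random.default_rng(2)
        n = 60
        guides = _guide_frame(
            n, lambda i: "chr1" if i < 20 else "chr2", lambda i: 1000 * i
        )
        fc = pd.Series(rng.normal(0, 0.1, size=n), index=[f"g{i}" for i in range(n)])
        res = region_dose_comparison(fc, guides, ("chr1", 0, 100_000))
        assert res["pvalue"] > 0.01
        assert abs(res["median_difference"]) < 0.1

    def test_boundary_is_half_open_on_cut_position(self):
        guides = _guide_frame(4, lambda i: "chr1", lambda i: [0, 999, 1000, 2000][i])
        fc = pd.Series([0.0, 0.1, 0.2, 0.3], index=[f"g{i}" for i in range(4)])
        res = region_dose_comparison(fc, guides, ("chr1", 0, 1000))
        assert res["n_inside"] == 2 and res["n_outside"] == 2

    def test_everything_inside_rejected(self):
        guides = _guide_frame(5, lambda i: "chr1", lambda i: i)
        fc = pd.Series(0.0, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="each side"):
            region_dose_comparison(fc, guides, ("chr1", 0, 100))


class TestChromosomeSummary:
    def _inputs(self):
        rng = np.random.default_rng(3)
        chroms = ["chr1"] * 10 + ["chr2"] * 10 + ["chr3"] * 10
        guides = _guide_frame(30, lambda i: chroms[i], lambda i: 100 * i)
        fc = pd.Series(
            np.concatenate(
                [rng.normal(-1, 0.05, 10), rng.normal(0, 0.05, 10),
                 rng.normal(2, 0.05, 10)]
            ),
            index=[f"g{i}" for i in range(30)],
        )
        return fc, guides

    def test_one_row_per_chromosome_with_correct_median(self):
        fc, guides = self._inputs()
        summary = chromosome_summary(fc, guides)
        assert summary["chrom"].tolist() == ["chr1", "chr2", "chr3"]
        assert summary["n"].tolist() == [10, 10, 10]
        assert summary["median"].tolist() == pytest.approx(
            [fc.iloc[:10].median(), fc.iloc[10:20].median(), fc.iloc[20:].median()]
        )
        assert (summary["mad"] < 0.2).all()

    def test_guide_order_does_not_matter(self):
        fc, guides = self._inputs()
        shuffled = guides.sample(frac=1, random_state=0).reset_index(drop=True)
        a = chromosome_summary(fc, guides)
        b = chromosome_summary(fc, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_controls_are_excluded(self):
        fc, guides = self._inputs()
        guides.loc[0, "is_control"] = True
        summary = chromosome_summary(fc, guides)
        assert summary.loc[summary["chrom"] == "chr1", "n"].iloc[0] == 9
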