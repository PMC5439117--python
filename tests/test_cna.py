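import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcnaclass.cna import (
    AMPLIFIED,
    FLAG_NAMES,
    GAIN,
    HOMODEL,
    LOSS,
    MISSING,
    NEUTRAL,
    Thresholds,
    baseline_correct,
    call_gene_focal,
    call_state,
    callsets_frame,
    cna_frequency,
    make_callset,
    make_callsets,
    region_median,
    weighted_median,
)
from gcnaclass.regions import Region


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2"])


class TestThresholds:
    def test_defaults(self):
        t = Thresholds()
        assert (t.gistic_gain, t.gistic_loss) == (0.5, -0.5)
        assert (t.seg_gain, t.seg_loss) == (0.1, -0.1)
        assert (t.amp, t.homodel) == (0.6, -0.6)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(gistic_gain=-0.1)
        with pytest.raises(ValueError):
            Thresholds(amp=0.4)


class TestCallState:
    # documented inclusive boundary behavior at all three regimes
    @pytest.mark.parametrize(
        "value,gain,loss,expected",
        [
            (0.6, 0.5, -0.5, GAIN),
            (0.5, 0.5, -0.5, GAIN),
            (-0.5, 0.5, -0.5, LOSS),
            (0.49, 0.5, -0.5, NEUTRAL),
            (0.0, 0.5, -0.5, NEUTRAL),
            (0.1, 0.1, -0.1, GAIN),
            (-0.1, 0.1, -0.1, LOSS),
            (0.0999, 0.1, -0.1, NEUTRAL),
        ],
    )
    def test_boundaries(self, value, gain, loss, expected):
        assert call_state(value, gain, loss) == expected

    def test_nan_is_missing(self):
        assert call_state(float("nan"), 0.5, -0.5) == MISSING

    @given(st.floats(-3, 3), st.floats(0.05, 1.0))
    def test_monotone_in_gain_threshold(self, value, delta):
        # raising the gain threshold never converts neutral → gain
        lo = call_state(value, 0.5, -0.5)
        hi = call_state(value, 0.5 + delta, -0.5)
        if lo == NEUTRAL:
            assert hi in (NEUTRAL,)
        if hi == GAIN:
            assert lo == GAIN


class TestCallGeneFocal:
    def test_paper_thresholds(self):
        assert call_gene_focal(0.9) == AMPLIFIED
        assert call_gene_focal(-1.4) == HOMODEL
        assert call_gene_focal(0.5) == NEUTRAL  # above broad gain, below focal
        assert call_gene_focal(0.6) == AMPLIFIED
        assert call_gene_focal(-0.6) == HOMODEL


class TestWeightedMedian:
    def test_equal_weights_midpoint(self):
        # two equal-length segments at +0.1 and +0.3 → 0.2 (brute-force
        # per-bp expansion gives the same: mean of the two middle values)
        assert weighted_median(np.array([0.1, 0.3]), np.array([10.0, 10.0])) == pytest.approx(0.2)

    def test_dominant_weight(self):
        assert weighted_median(np.array([0.0, 5.0]), np.array([99.0, 1.0])) == 0.0

    def test_brute_force_expansion(self):
        # integer weights: expand each value w times and take np.median
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = rng.integers(1, 6)
            values = rng.normal(size=k).round(3)
            weights = rng.integers(1, 8, size=k)
            expanded = np.repeat(values, weights)
            assert weighted_median(values, weights.astype(float)) == pytest.approx(
                np.median(expanded)
            )

    def test_empty_is_nan(self):
        assert np.isnan(weighted_median(np.array([]), np.array([])))


class TestBaselineCorrect:
    def test_constant_shift(self):
        seg = seg_frame([("S1", "1", 1, 100, 0.2), ("S1", "2", 1, 100, 0.2)])
        out = baseline_correct(seg)
        np.testing.assert_allclose(out["log2"], 0.0)

    def test_idempotent_exact(self):
        rng = np.random.default_rng(0)
        rows = [("S1", str(c), 1, int(rng.integers(10, 1000)), float(rng.normal()))
                for c in range(1, 10)]
        seg = seg_frame(rows)
        once = baseline_correct(seg)
        twice = baseline_correct(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_per_sample_independence(self):
        seg_a = seg_frame([("A", "1", 1, 100, 0.5)])
        seg_b = seg_frame([("B", "1", 1, 100, -0.3)])
        both = pd.concat([seg_a, seg_b], ignore_index=True)
        out = baseline_correct(both)
        out_b_alone = baseline_correct(seg_b)
        np.testing.assert_allclose(
            out[out["sample_id"] == "B"]["log2"].to_numpy(),
            out_b_alone["log2"].to_numpy(),
        )

    def test_no_autosomes_errors(self):
        seg = seg_frame([("S1", "X", 1, 100, 0.1)])
        with pytest.raises(ValueError, match="S1"):
            baseline_correct(seg)


class TestRegionMedian:
    def test_single_segment_identity(self):
        region = Region("r", "arm", "1", 1, 1000, ())
        seg = seg_frame([("S1", "1", 1, 1000, -0.35)])
        assert region_median(seg, region)["S1"] == pytest.approx(-0.35)

    def test_two_equal_overlaps_midpoint(self):
        region = Region("r", "arm", "1", 1, 200, ())
        seg = seg_frame([("S1", "1", 1, 100, 0.1), ("S1", "1", 101, 200, 0.3)])
        assert region_median(seg, region)["S1"] == pytest.approx(0.2)

    def test_no_overlap_missing(self):
        region = Region("r", "arm", "X", 1, 1000, ())
        seg = seg_frame([("S1", "1", 1, 1000, 0.4)])
        assert np.isnan(region_median(seg, region)["S1"])

    def test_partial_overlap_weighting(self):
        # region covers 50 bp of the first segment and 100 of the second
        region = Region("r", "arm", "1", 51, 200, ())
        seg = seg_frame([("S1", "1", 1, 100, -1.0), ("S1", "1", 101, 200, 1.0)])
        expanded = np.repeat([-1.0, 1.0], [50, 100])
        assert region_median(seg, region)["S1"] == pytest.approx(np.median(expanded))


class TestMakeCallset:
    def test_codel_from_forced_arms(self, region_map, small_clean_cohort):
        c = small_clean_cohort
        truth = c.truth.set_index("sample_id")
        callsets = make_callsets(gistic=c.gistic, regions=region_map)
        for cs in callsets:
            assert cs.flags["codel_1p19q"] == bool(truth.loc[cs.sample_id, "codel_1p19q"])

    def test_coamp_requires_both(self, region_map):
        import gcnaclass.io as io

        genes = ["CDK4", "MDM2", "CDKN2A"]
        m = io.GisticMatrix(genes=genes, samples=["S1"], scores=np.array([[0.9], [0.7], [0.0]]))
        cs = make_callset("S1", gistic=m, regions=region_map)
        assert cs.flags["cdk4_amp"] and cs.flags["mdm2_amp"] and cs.flags["cdk4_mdm2_coamp"]

    def test_all_zero_burden_counts_mutations_only(self, region_map):
        import gcnaclass.io as io
        from gcnaclass.regions import synthetic_gene_panel

        panel = synthetic_gene_panel()
        m = io.GisticMatrix(
            genes=list(panel["gene"]), samples=["S1"],
            scores=np.zeros((len(panel), 1)),
        )
        cs = make_callset("S1", gistic=m, regions=region_map, mutated_genes={"IDH1", "TP53"})
        assert all(v == "neutral" for v in cs.region_states.values())
        assert cs.alteration_burden == 2

    def test_flag_invariants(self, region_map, small_clean_cohort):
        callsets = make_callsets(gistic=small_clean_cohort.gistic, regions=region_map)
        for cs in callsets:
            assert cs.flags["cdk4_mdm2_coamp"] == (cs.flags["cdk4_amp"] and cs.flags["mdm2_amp"])
            assert cs.flags["codel_1p19q"] == (
                cs.region_states["1p"] == LOSS and cs.region_states["19q"] == LOSS
            )

    def test_requires_exactly_one_source(self, region_map):
        with pytest.raises(ValueError):
            make_callset("S1", regions=region_map)


class TestRouteAgreement:
    def test_gistic_and_segment_flags_agree_noise_free(self, region_map, small_clean_cohort):
        c = small_clean_cohort
        via_gistic = callsets_frame(make_callsets(gistic=c.gistic, regions=region_map))
        via_seg = callsets_frame(make_callsets(segments=c.segments, regions=region_map))
        merged = via_gistic.merge(via_seg, on="sample_id", suffixes=("_g", "_s"))
        for flag in FLAG_NAMES:
            assert (merged[f"{flag}_g"] == merged[f"{flag}_s"]).all(), flag


class TestCnaFrequency:
    def test_all_gain(self, region_map, small_clean_cohort):
        cfg_samples = small_clean_cohort.truth
        callsets = make_callsets(gistic=small_clean_cohort.gistic, regions=region_map)
        clusters = dict(zip(cfg_samples["sample_id"], cfg_samples["cluster"]))
        freq = cna_frequency(callsets, clusters, region_map)
        oligo = freq[(freq["cluster"] == "OLIGO_IDHmut_CODEL") & (freq["region"] == "1p")]
        assert oligo["loss_freq"].iloc[0] == 1.0  # codel prevalence 1.0 by default

    def test_direct_count(self, region_map):
        from gcnaclass.cna import CnaCallSet

        callsets = []
        states = [GAIN] * 3 + [LOSS] * 1 + [NEUTRAL] * 6
        for i, s in enumerate(states):
            callsets.append(CnaCallSet(f"S{i}", {"chr7": s}, {}, {}, 0))
        clusters = {f"S{i}": "c" for i in range(10)}
        freq = cna_frequency(callsets, clusters, Region7Map())
        row = freq.iloc[0]
        assert (row["gain_freq"], row["loss_freq"]) == (0.3, 0.1)
        assert row["gain_freq"] + row["loss_freq"] + row["neutral_freq"] == 1.0

    def test_empty_cluster_errors(self, region_map):
        with pytest.raises(ValueError):
            cna_frequency([], {}, region_map)

    def test_frequencies_sum_to_one(self, region_map, small_clean_cohort):
        callsets = make_callsets(gistic=small_clean_cohort.gistic, regions=region_map)
        clusters = dict(zip(small_clean_cohort.truth["sample_id"], small_clean_cohort.truth["cluster"]))
        freq = cna_frequency(callsets, clusters, region_map)
        np.testing.assert_allclose(
            freq["gain_freq"] + freq["loss_freq"] + freq["neutral_freq"], 1.0
        )


class Region7Map:
    """Minimal stand-in region map exposing only chr7."""

    def __init__(self):
        self.regions = {"chr7": Region("chr7", "chrom", "7", 1, 159138663, ())}

    def __getitem__(self, name):
        return self.regions[name]

    def names(self):
        return list(self.regions)
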