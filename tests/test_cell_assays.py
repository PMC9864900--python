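"""Assay quantification: G/F ratio, puncta counting, stats, wound metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedcascade import (
    BandConfig,
    PunctaConfig,
    WoundConfig,
    WoundSeries,
    contact_time,
    count_puncta,
    coverage_timecourse,
    dunn_posthoc,
    generate_band_table,
    generate_puncta_image,
    generate_timepoint_counts,
    generate_wound_series,
    gf_ratio,
    recovery_analysis,
    significance_mark,
)
from pedcascade.cell_assays import AssayInvalidError, InputError
from pedcascade.synthetic_data import PATIENT_WOUND


class TestGFRatio:
    def test_zero_noise_quotient_exact(self):
        table = generate_band_table(BandConfig(noise_cv=0.0), 3, seed=7)
        result = gf_ratio(table)
        assert result.ratio_quotient == pytest.approx(0.5)
        assert result.excluded == []

    def test_gapdh_in_pellet_excluded(self):
        table = generate_band_table(BandConfig(noise_cv=0.0), 3, seed=0)
        table.loc[0, "GAPDH_pellet"] = table.loc[0, "GAPDH_supernatant"]
        result = gf_ratio(table)
        assert ("CONTROL", 1, "gapdh_in_pellet") in result.excluded
        assert len(result.per_replicate) == 5

    def test_zero_f_flagged_not_fatal(self):
        table = generate_band_table(BandConfig(noise_cv=0.0), 3, seed=0)
        table.loc[1, "F"] = 0.0
        result = gf_ratio(table)
        assert ("CONTROL", 2, "zero_F") in result.excluded

    def test_all_replicates_failing_qc_is_invalid(self):
        table = generate_band_table(
            BandConfig(noise_cv=0.0, separation_failure=True), 3, seed=0)
        with pytest.raises(AssayInvalidError):
            gf_ratio(table)

    def test_patient_below_control_significant_one_sided(self):
        table = generate_band_table(BandConfig(), 6, seed=7)
        result = gf_ratio(table, alternative="greater")  # control > patient
        assert result.group_means["PATIENT"] < result.group_means["CONTROL"]
        assert result.p_value < 0.05

    def test_ttest_option(self):
        table = generate_band_table(BandConfig(), 6, seed=7)
        assert gf_ratio(table, test="ttest").p_value < 0.05


class TestCountPuncta:
    @pytest.mark.parametrize("rate,seed", [(10, 1), (50, 3), (120, 5)])
    def test_exact_recovery_at_zero_noise(self, rate, seed):
        img, truth = generate_puncta_image(rate, (512, 512), seed=seed)
        assert count_puncta(img) == truth

    def test_exact_recovery_with_background_noise(self):
        img, truth = generate_puncta_image(50, (512, 512), seed=3,
                                           background_noise_sd=5.0)
        assert count_puncta(img) == truth

    def test_blank_image_counts_zero(self):
        assert count_puncta(np.zeros((64, 64))) == 0
        assert count_puncta(np.full((64, 64), 7.0)) == 0

    def test_size_gate(self):
        img, _ = generate_puncta_image(30, (256, 256), seed=2)
        # discs of radius 3 cover 29 px; a gate below that removes them all
        assert count_puncta(img, size_range=(1, 3)) == 0

    def test_monotone_in_rate_across_seeds(self):
        """Mean planted (and counted) puncta increase with the Poisson rate."""
        rates = [5, 15, 30]
        means = []
        for rate in rates:
            counts = [count_puncta(generate_puncta_image(rate, (160, 160),
                                                         seed=s)[0])
                      for s in range(100)]
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]

    def test_non_2d_rejected(self):
        with pytest.raises(InputError):
            count_puncta(np.zeros((4, 4, 3)))


class TestKruskalDunn:
    def test_hand_computed_h(self):
        """Three tie-free groups of three: rank sums 6/15/24 give H = 7.2."""
        result = recovery_analysis({0: {"a": [1, 2, 3], "b": [4, 5, 6],
                                        "c": [7, 8, 9]}})
        assert result.per_timepoint[0].H == pytest.approx(7.2)

    def test_identical_groups_h_zero_p_one(self):
        result = recovery_analysis({0: {"a": [1, 2, 3], "b": [1, 2, 3]}})
        cmp = result.per_timepoint[0]
        assert cmp.H == pytest.approx(0.0, abs=1e-12)
        assert cmp.p == pytest.approx(1.0)
        assert not cmp.significant

    def test_all_tied_flagged(self):
        result = recovery_analysis({0: {"a": [5, 5, 5], "b": [5, 5, 5]}})
        assert result.per_timepoint[0].all_tied
        assert result.per_timepoint[0].H is None

    def test_invariance_under_monotone_transform(self):
        groups = {"a": [1.0, 4.0, 2.0], "b": [9.0, 7.0, 5.0], "c": [3.0, 8.0, 6.0]}
        h_raw, _ = stats.kruskal(*groups.values())
        transformed = {k: np.exp(np.asarray(v) / 3.0) for k, v in groups.items()}
        h_t, _ = stats.kruskal(*transformed.values())
        assert h_t == pytest.approx(h_raw)

    def test_dunn_hand_oracle(self):
        """Dunn z for two tie-free groups matches the explicit formula."""
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        table = dunn_posthoc(groups, adjust="none")
        # pooled ranks 1..6: mean ranks 2 and 5; Var base = 6*7/12 = 3.5
        z_expected = (2.0 - 5.0) / np.sqrt(3.5 * (1 / 3 + 1 / 3))
        assert table.loc[0, "z"] == pytest.approx(z_expected)
        assert table.loc[0, "p_raw"] == pytest.approx(
            2 * stats.norm.sf(abs(z_expected)))

    def test_dunn_adjustment_and_pair_count(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(i, 1, size=6) for i, g in enumerate("abcd")}
        table = dunn_posthoc(groups)
        assert len(table) == 4 * 3 // 2
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_too_few_observations_rejected(self):
        with pytest.raises(InputError):
            recovery_analysis({0: {"a": [1, 2], "b": [3, 4, 5]}})

    def test_significance_marks(self):
        assert significance_mark(0.0004) == "***"
        assert significance_mark(0.0009) == "**"
        assert significance_mark(0.004) == "*"
        assert significance_mark(0.2) == "ns"
        assert significance_mark(0.03, conventional=True) == "*"

    def test_patient_above_control_at_all_timepoints(self):
        counts = generate_timepoint_counts(PunctaConfig(), seed=11)
        result = recovery_analysis(counts)
        for cmp, t in zip(result.per_timepoint, sorted(counts)):
            assert np.mean(counts[t]["PATIENT"]) > np.mean(counts[t]["CONTROL"])
            assert cmp.significant


class TestContactTime:
    def _series(self, speed, seed=0, noise=0.0, n_frames=15):
        config = WoundConfig(frame_shape=(40, 200), gap_px=100,
                             speed_px_per_frame=speed, speed_noise_sd=noise)
        masks, truth = generate_wound_series(config, n_frames, seed=seed)
        return WoundSeries(masks, frame_interval_min=20.0), truth

    def test_matches_kinematic_truth(self):
        series, truth = self._series(5.0)
        assert truth == 10
        assert contact_time(series) == pytest.approx(10 * 20 / 60.0)

    def test_zero_speed_returns_none(self):
        series, truth = self._series(0.0)
        assert truth is None
        assert contact_time(series) is None

    def test_patient_config_slower_than_control(self):
        control = WoundConfig()
        patient = WoundConfig(**{**control.__dict__, **PATIENT_WOUND})
        n = 201  # 67 h at 20-min frames
        c_masks, c_truth = generate_wound_series(control, n, seed=5)
        p_masks, p_truth = generate_wound_series(patient, n, seed=5)
        c_time = contact_time(WoundSeries(c_masks))
        p_time = (contact_time(WoundSeries(p_masks))
                  if p_truth is not None else None)
        assert c_time is not None
        assert p_time is None or p_time > c_time

    def test_antitone_in_speed(self):
        times = []
        for speed in (2.0, 4.0, 8.0):
            series, _ = self._series(speed, n_frames=40)
            times.append(contact_time(series))
        assert times[0] > times[1] > times[2]

    def test_wrong_initial_region_count_rejected(self):
        masks = np.zeros((3, 20, 60), dtype=bool)
        masks[:, :, :10] = True  # single region only
        with pytest.raises(InputError):
            contact_time(WoundSeries(masks))


class TestCoverage:
    def test_full_mask_everywhere_one(self):
        masks = np.ones((2, 30, 30), dtype=bool)
        table = coverage_timecourse(WoundSeries(masks))
        squares = [c for c in table.columns if c.startswith("square_")]
        assert len(squares) == 9
        assert (table[squares] == 1.0).all().all()
        assert (table["mean_coverage"] == 1.0).all()

    def test_half_covered_clean_split(self):
        masks = np.zeros((1, 30, 30), dtype=bool)
        masks[:, :, :15] = True
        table = coverage_timecourse(WoundSeries(masks))
        assert table.loc[0, "mean_coverage"] == pytest.approx(0.5)
        values = {table.loc[0, f"square_{i}"] for i in range(1, 10)}
        assert values == {0.0, 0.5, 1.0}

    def test_mean_of_squares_conserves_whole_frame_fraction(self):
        rng = np.random.default_rng(3)
        masks = rng.random((1, 33, 33)) > 0.4  # 33 divisible by 3
        table = coverage_timecourse(WoundSeries(masks))
        assert table.loc[0, "mean_coverage"] == pytest.approx(masks[0].mean())

    def test_remainder_pixels_area_conserving(self):
        rng = np.random.default_rng(4)
        masks = rng.random((1, 32, 35)) > 0.5  # not divisible by 3
        table = coverage_timecourse(WoundSeries(masks))
        assert table.loc[0, "mean_coverage"] == pytest.approx(masks[0].mean())

    def test_control_closes_before_patient(self):
        n = 201
        control_masks, _ = generate_wound_series(WoundConfig(), n, seed=5)
        patient = WoundConfig(**{**WoundConfig().__dict__, **PATIENT_WOUND})
        patient_masks, _ = generate_wound_series(patient, n, seed=5)
        c = coverage_timecourse(WoundSeries(control_masks))
        p = coverage_timecourse(WoundSeries(patient_masks))
        assert c["mean_coverage"].iloc[-1] == pytest.approx(1.0)
        assert p["mean_coverage"].iloc[-1] < 1.0
        closure = c.loc[c["mean_coverage"] >= 1.0, "time_h"].min()
        assert closure < 67.0

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            WoundSeries(np.zeros((0, 10, 10), dtype=bool))
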