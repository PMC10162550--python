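"""Generator contracts: pulse waveform, video rendering, cohort structure."""

import numpy as np
import pytest

from retppg.paa import paa_single_pulse, PulseWindow
from retppg.patterns import rnfl_sector_mean
from retppg.stats import GROUPS, partial_correlation
from retppg.synthetic import (
    AGE_MEAN_SD,
    CouplingParams,
    GROUP_SIZES,
    PulseShape,
    RNFL_GROUP_STATS,
    SceneParams,
    generate_cohort,
    generate_eye_video,
    pulse_waveform,
    rnfl_angular_template,
)


class TestPulseWaveform:
    def test_range_and_extremes_over_one_period(self):
        t = np.linspace(0, 60 / 72, 2000, endpoint=False)
        g = pulse_waveform(t, 72)
        assert g.min() == 0.0
        assert g.max() == 1.0
        assert np.all((g >= 0) & (g <= 1))

    def test_periodicity(self):
        period = 60 / 72
        t = np.linspace(0, 3, 500)
        assert np.allclose(
            pulse_waveform(t, 72), pulse_waveform(t + 5 * period, 72), atol=1e-12
        )

    def test_value_at_trough_frame_is_one(self):
        # maximal blood volume = intensity trough; g is exactly 1 there
        shape = PulseShape()
        t_peak = (shape.rise + shape.peak_hold / 2) * (60 / 72)
        assert pulse_waveform(t_peak, 72) == 1.0

    def test_twelve_full_periods_in_ten_seconds_at_72_bpm(self):
        t = np.arange(0, 10, 0.001)
        g = pulse_waveform(t, 72)
        # count systolic plateaus (g == 1 runs)
        runs = np.diff((g == 1.0).astype(int))
        assert (runs == 1).sum() == 12

    @pytest.mark.parametrize("hr", [0, -10, 30, 200])
    def test_heart_rate_validation(self, hr):
        with pytest.raises(ValueError):
            pulse_waveform(np.arange(10) / 25, hr)

    def test_flat_shape_is_degenerate_and_flagged(self):
        with pytest.warns(UserWarning, match="flat"):
            g = pulse_waveform(np.arange(10) / 25, 72, PulseShape(0.0, 0.0, 0.0))
        assert np.all(g == 0)


class TestGenerateEyeVideo:
    def test_no_modulation_reproduces_baseline(self):
        params = SceneParams(
            height=128, width=128,
            amplitude_map=np.zeros((128, 128)),
            noise_sigma=0.0, motion_max_shift=0.0, motion_max_rot=0.0,
        )
        stack, truth = generate_eye_video(params, seed=3)
        assert np.array_equal(stack.data[0], truth.baseline_image)
        assert np.all(stack.data == stack.data[0])

    def test_uniform_amplitude_direct_formula(self, still_noiseless_stack):
        # per-pixel (max - min) / max over a full pulse equals the planted A
        stack, truth = still_noiseless_stack
        s, e = truth.pulse_windows[0]
        seg = stack.data[s:e]
        ratio = (seg.max(axis=0) - seg.min(axis=0)) / seg.max(axis=0)
        assert np.allclose(ratio, 0.03, atol=1e-12)

    def test_generative_identity_every_window(self, still_noiseless_stack):
        # raw min/max recovers the amplitude map exactly, each pulse
        stack, truth = still_noiseless_stack
        for s, e in truth.pulse_windows:
            amp = paa_single_pulse(stack, PulseWindow(s, e), smooth_window=0)
            assert np.nanmax(np.abs(amp - 0.03)) < 1e-9

    def test_seed_determinism(self):
        params = SceneParams(height=128, width=128, duration=2.0)
        a, _ = generate_eye_video(params, seed=11)
        b, _ = generate_eye_video(params, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_excessive_amplitude_rejected(self):
        params = SceneParams(
            height=128, width=128, amplitude_map=np.full((128, 128), 1.2)
        )
        with pytest.raises(ValueError, match="non-positive"):
            generate_eye_video(params, seed=0)

    def test_minimum_scene_size_enforced(self):
        with pytest.raises(ValueError):
            generate_eye_video(SceneParams(height=64, width=64), seed=0)

    def test_truth_invariants(self, still_noiseless_stack):
        stack, truth = still_noiseless_stack
        assert np.all(truth.amplitude_map >= 0)
        windows = truth.pulse_windows
        assert all(0 <= s < e <= stack.n_frames for s, e in windows)
        assert all(e0 <= s1 for (_, e0), (s1, _) in zip(windows, windows[1:]))


class TestRNFLTemplate:
    def test_double_hump_ordering(self):
        angles = np.arange(0, 360)
        t = rnfl_angular_template(angles)
        superior, inferior = t[85], t[275]
        temporal, nasal = t[0], t[180]
        assert superior > temporal > nasal
        assert inferior > temporal > nasal
        assert np.isclose(t.mean(), 1.0)


class TestGenerateCohort:
    def test_default_group_sizes_give_111_records(self, default_cohort):
        assert len(default_cohort.records) == sum(GROUP_SIZES.values()) == 111
        counts = default_cohort.records["group"].value_counts().to_dict()
        assert counts == GROUP_SIZES

    def test_n_eyes_inconsistent_with_groups_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            generate_cohort(seed=0, n_eyes=100)

    def test_cohort_moments_match_configured_means(self):
        # n = 1000 per group: empirical group means within 3 SE
        sizes = {g: 1000 for g in GROUPS}
        coh = generate_cohort(seed=5, group_sizes=sizes, make_maps=False)
        for g in GROUPS:
            mu, sd = RNFL_GROUP_STATS[g]
            sub = coh.records.loc[coh.records["group"] == g, "rnfl_mean"]
            se = sd / np.sqrt(len(sub))
            assert abs(sub.mean() - mu) < 3 * se

    def test_null_coupling_gives_null_partial_correlation(self):
        # alpha = beta = 0: planted annulus amplitude is pure noise, so its
        # partial correlation with RNFL stays within the Monte-Carlo null band
        null = CouplingParams(alpha_temporal=0.0, alpha_nasal=0.0, beta_age=0.0)
        for seed in range(20):
            coh = generate_cohort(seed=seed, coupling=null, make_maps=False)
            r, _ = partial_correlation(
                coh.truth["c_temporal"],
                coh.records["rnfl_temp"].to_numpy(),
                coh.records["age"].to_numpy(),
            )
            assert abs(r) < 3 / np.sqrt(len(coh.records))

    def test_noiseless_linear_link_gives_unit_correlation(self):
        from retppg.patterns import AnnulusSpec, annulus_mask, pattern_mean_paa

        noiseless = CouplingParams(
            beta_age=0.0, noise_sd=0.0, background_sd=0.0, map_noise_sd=0.0
        )
        coh = generate_cohort(
            seed=2,
            group_sizes={"G_norm": 6, "G_per": 6},
            coupling=noiseless,
            map_shape=(128, 128),
            onh_radius_mean=24.0,
        )
        # the planted coupling coefficient is exactly linear in sector RNFL
        r, _ = partial_correlation(
            coh.truth["c_temporal"],
            coh.records["rnfl_temp"].to_numpy(),
            coh.records["age"].to_numpy(),
        )
        assert r > 1 - 1e-9
        # the rasterized pattern mean inherits it up to per-eye annulus
        # discretization (radius/center jitter modulates the bump average)
        means, rnfl, ages = [], [], []
        for eye, rec in zip(coh.eyes, coh.records.itertuples()):
            spec = AnnulusSpec(0.5, 0.05, sector="temporal",
                               laterality=eye.laterality)
            mask = annulus_mask(eye.geometry, spec, eye.paa_map.data.shape)
            means.append(
                pattern_mean_paa(eye.paa_map, mask, eye.vessel_mask).value
            )
            rnfl.append(rnfl_sector_mean(eye.rnfl_profile, "temporal"))
            ages.append(rec.age)
        r_map, _ = partial_correlation(
            np.array(means), np.array(rnfl), np.array(ages)
        )
        assert r_map > 0.97

    def test_cohort_determinism(self):
        a = generate_cohort(seed=9, group_sizes={"G_norm": 5, "G_per": 5},
                            map_shape=(128, 128))
        b = generate_cohort(seed=9, group_sizes={"G_norm": 5, "G_per": 5},
                            map_shape=(128, 128))
        assert a.records.equals(b.records)
        for ea, eb in zip(a.eyes, b.eyes):
            assert np.array_equal(ea.paa_map.data, eb.paa_map.data)

    def test_temporal_coupling_must_dominate(self):
        with pytest.raises(ValueError, match="temporal"):
            CouplingParams(alpha_temporal=0.001, alpha_nasal=0.002)

    def test_age_distribution_plausible(self, default_cohort):
        ages = default_cohort.records["age"]
        assert abs(ages.mean() - AGE_MEAN_SD[0]) < 5
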