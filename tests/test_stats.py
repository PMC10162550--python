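"""Partial correlation, landscape search, optimum, group summaries."""

import numpy as np
import pandas as pd
import pytest

from retppg.patterns import AnnulusSpec, annulus_mask, pattern_mean_paa, rnfl_sector_mean
from retppg.stats import (
    GROUPS,
    CorrelationLandscape,
    correlation_landscape,
    group_summary,
    landscape_optimum,
    partial_correlation,
)


def residual_regression_partial(x, y, z):
    """Independent oracle: correlate the residuals of x~z and y~z."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialCorrelation:
    def test_identical_variables_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        z = rng.random(50)
        r, p = partial_correlation(x, x, z)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12

    def test_control_equal_to_outcome_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.random(60)
        y = rng.random(60)
        r, _ = partial_correlation(x, y, y)
        assert abs(r) < 1e-12

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y, z = rng.random((3, 111))
            r, _ = partial_correlation(x, y, z)
            assert abs(r - residual_regression_partial(x, y, z)) < 1e-10

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x, y, z = rng.random((3, 80))
        r, p = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert abs(r - ref["r"].iloc[0]) < 1e-10
        assert abs(p - ref["p_val"].iloc[0]) < 1e-8

    def test_missing_rows_dropped_pairwise_complete(self):
        rng = np.random.default_rng(4)
        x, y, z = rng.random((3, 40))
        x2 = x.copy()
        x2[5] = np.nan
        keep = np.ones(40, bool)
        keep[5] = False
        r1, _ = partial_correlation(x2, y, z)
        r2, _ = partial_correlation(x[keep], y[keep], z[keep])
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_zero_variance_errors_and_fallback(self):
        rng = np.random.default_rng(5)
        y, z = rng.random((2, 30))
        with pytest.raises(ValueError, match="variance"):
            partial_correlation(np.ones(30), y, z)
        x = rng.random(30)
        with pytest.warns(UserWarning, match="Pearson"):
            r, _ = partial_correlation(x, y, np.full(30, 2.0))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y, z = rng.random((3, 50))
        r_xy, _ = partial_correlation(x, y, z)
        r_yx, _ = partial_correlation(y, x, z)
        assert r_xy == pytest.approx(r_yx, abs=1e-14)
        r_scaled, _ = partial_correlation(3 * x - 1, 0.5 * y + 4, -2 * z + 7)
        assert r_scaled == pytest.approx(r_xy, abs=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.arange(3.0), np.arange(3.0), np.arange(3.0))


class TestCorrelationLandscape:
    def test_single_cell_equals_direct_partial_correlation(self, default_cohort):
        eyes = default_cohort.eyes[:30]
        L = correlation_landscape(
            eyes, d_r_values=np.array([0.5]), w_r_values=np.array([0.05]),
            sector="temporal",
        )
        means, rnfl, ages = [], [], []
        for eye in eyes:
            spec = AnnulusSpec(0.5, 0.05, "temporal", eye.laterality)
            mask = annulus_mask(eye.geometry, spec, eye.paa_map.data.shape)
            means.append(pattern_mean_paa(eye.paa_map, mask, eye.vessel_mask).value)
            rnfl.append(rnfl_sector_mean(eye.rnfl_profile, "temporal"))
            ages.append(eye.age)
        r, _ = partial_correlation(np.array(means), np.array(rnfl), np.array(ages))
        assert L.R[0, 0] == pytest.approx(r, abs=1e-10)

    def test_planted_coupling_found_and_region95_connected(self, default_cohort):
        from scipy import ndimage

        L = correlation_landscape(default_cohort.eyes, sector="full")
        opt = landscape_optimum(L)
        assert abs(opt.d_r - default_cohort.truth["planted_d_r"]) <= 0.01 + 1e-9
        # the 95% region contains the argmax and the planted cell, connected
        i_d = int(np.argmin(np.abs(L.d_r_values - opt.d_r)))
        i_w = int(np.argmin(np.abs(L.w_r_values - opt.w_r)))
        assert opt.region95[i_d, i_w]
        labels, _ = ndimage.label(opt.region95)
        planted_d = int(np.argmin(
            np.abs(L.d_r_values - default_cohort.truth["planted_d_r"])
        ))
        assert labels[planted_d, 0] == labels[i_d, i_w]

    def test_landscape_invariant_to_common_map_rescaling(self, default_cohort):
        from dataclasses import replace

        from retppg.paa import PAAMap

        eyes = default_cohort.eyes[:20]
        grid_d = np.array([0.4, 0.5, 0.6])
        grid_w = np.array([0.02, 0.05])
        L1 = correlation_landscape(eyes, grid_d, grid_w)
        scaled = [
            replace(e, paa_map=PAAMap(e.paa_map.data * 2.5, e.paa_map.n_pulses))
            for e in eyes
        ]
        L2 = correlation_landscape(scaled, grid_d, grid_w)
        assert np.allclose(L1.R, L2.R, atol=1e-10)

    def test_empty_grid_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="grid"):
            correlation_landscape(
                default_cohort.eyes[:10], np.array([]), np.array([0.05])
            )

    def test_n_reported_per_cell(self, default_cohort):
        eyes = default_cohort.eyes[:12]
        L = correlation_landscape(
            eyes, np.array([0.5]), np.array([0.05]), sector="full"
        )
        assert L.n[0, 0] == 12


class TestLandscapeOptimum:
    @staticmethod
    def _landscape(R):
        R = np.asarray(R, dtype=float)
        return CorrelationLandscape(
            d_r_values=np.arange(R.shape[0]) * 0.1,
            w_r_values=np.arange(R.shape[1]) * 0.01,
            R=R, p=np.zeros_like(R), n=np.full(R.shape, 10),
        )

    def test_unique_maximum(self):
        opt = landscape_optimum(self._landscape([[0.1, 0.2], [0.5, 0.3]]))
        assert (opt.d_r, opt.w_r, opt.R_max) == (0.1, 0.0, 0.5)

    def test_tie_breaks_toward_smaller_d_r_then_w_r(self):
        opt = landscape_optimum(self._landscape([[0.2, 0.5], [0.5, 0.1]]))
        assert (opt.d_r, opt.w_r) == (0.0, 0.01)
        opt2 = landscape_optimum(self._landscape([[0.5, 0.5], [0.1, 0.1]]))
        assert (opt2.d_r, opt2.w_r) == (0.0, 0.0)

    def test_region95_contains_argmax(self):
        opt = landscape_optimum(self._landscape([[0.96, 0.5], [1.0, 0.2]]))
        assert opt.region95[1, 0] and opt.region95[0, 0]
        assert not opt.region95[0, 1]

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            landscape_optimum(self._landscape([[np.nan, np.nan]]))


class TestGroupSummary:
    def test_group_rnfl_median_ordering(self, default_cohort):
        s = group_summary(default_cohort.records, value_columns=["rnfl_mean"])
        med = {g: s.loc[(g, "rnfl_mean"), "median"] for g in GROUPS}
        assert min(med["G_norm"], med["G_OHT"]) > med["G_pre"] > med["G_per"]

    def test_planted_severity_link_shows_in_paa(self, default_cohort):
        # pattern-mean PAA at the planted annulus declines with severity
        vals = []
        for eye in default_cohort.eyes:
            spec = AnnulusSpec(0.5, 0.05, "full", eye.laterality)
            mask = annulus_mask(eye.geometry, spec, eye.paa_map.data.shape)
            vals.append(pattern_mean_paa(eye.paa_map, mask, eye.vessel_mask).value)
        df = default_cohort.records.assign(paa=vals)
        s = group_summary(df, value_columns=["paa"])
        med = {g: s.loc[(g, "paa"), "median"] for g in GROUPS}
        assert min(med["G_norm"], med["G_OHT"]) > med["G_per"]
        assert med["G_pre"] > med["G_per"]

    def test_single_group_cohort_reports_others_with_zero_n(self):
        df = pd.DataFrame({"group": ["G_norm"] * 5, "v": np.arange(5.0)})
        s = group_summary(df, value_columns=["v"])
        assert s.loc[("G_norm", "v"), "n"] == 5
        for g in ("G_OHT", "G_pre", "G_per"):
            assert s.loc[(g, "v"), "n"] == 0
            assert np.isnan(s.loc[(g, "v"), "median"])

    def test_unknown_group_label_rejected(self):
        df = pd.DataFrame({"group": ["G_bad"], "v": [1.0]})
        with pytest.raises(ValueError, match="unknown"):
            group_summary(df)
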