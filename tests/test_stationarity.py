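"""Nested model forms, comparison tests, and per-slice coefficients."""

import numpy as np
import pandas as pd
import pytest

from paleopcs.spatial import fit_ols
from paleopcs.stationarity import (
    FORMS,
    StationarityModel,
    build_design,
    compare_nested,
    equalize_sample_sizes,
    exclude_sparse_periods,
    extract_time_coefficients,
    fit_model_set,
    geographic_trend,
    select_form,
    select_weight_distance,
)


def make_panel(slopes: dict[int, float], intercepts: dict[int, float],
               n_per_slice: int = 40, sigma: float = 1.0,
               seed: int = 0) -> pd.DataFrame:
    """Synthetic PCS panel with a known per-slice linear PCS-climate law."""
    rng = np.random.default_rng(seed)
    rows = []
    for t, b in slopes.items():
        x = rng.normal(size=n_per_slice)
        y = intercepts[t] + b * x + rng.normal(scale=sigma, size=n_per_slice)
        lon = rng.uniform(-90, -80, size=n_per_slice)
        lat = rng.uniform(38, 44, size=n_per_slice)
        for xi, yi, lo, la in zip(x, y, lon, lat):
            rows.append((lo, la, t, yi, xi))
    return pd.DataFrame(rows, columns=["cell_lon", "cell_lat", "time_ka",
                                       "nri", "tmin"])


class TestExcludeSparse:
    def test_threshold_is_strict_less_than(self):
        df = pd.DataFrame({
            "time_ka": [0] * 10 + [1] * 9,
            "nri": np.random.default_rng(0).normal(size=19),
        })
        out = exclude_sparse_periods(df, 10, value_col="nri")
        assert set(out["time_ka"]) == {0}

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame({"time_ka": [0, 1], "nri": [0.1, 0.2]})
        out = exclude_sparse_periods(df, 0, value_col="nri")
        assert len(out) == 2

    def test_all_dropped_rejected(self):
        df = pd.DataFrame({"time_ka": [0], "nri": [0.1]})
        with pytest.raises(ValueError):
            exclude_sparse_periods(df, 5, value_col="nri")


class TestDesign:
    def test_column_counts_for_each_form(self):
        df = make_panel({0: 1, 1: 1, 2: 1}, {0: 0, 1: 0, 2: 0})
        k = 3
        _, X1 = build_design(df, "tmin", "stable_relationship")
        _, X2 = build_design(df, "tmin", "stable_slope")
        _, X3 = build_design(df, "tmin", "changed_relationship")
        assert X1.shape[1] == 2
        assert X2.shape[1] == 1 + k
        assert X3.shape[1] == 2 * k

    def test_stable_form_ignores_time(self):
        df = make_panel({0: 1, 1: 1}, {0: 0, 1: 0})
        y1, X1 = build_design(df, "tmin", "stable_relationship")
        shuffled = df.copy()
        shuffled["time_ka"] = shuffled["time_ka"].sample(
            frac=1, random_state=3).to_numpy()
        y2, X2 = build_design(shuffled, "tmin", "stable_relationship")
        np.testing.assert_allclose(X1.to_numpy(), X2.to_numpy())

    def test_single_time_level_rejected_for_changed(self):
        df = make_panel({0: 1}, {0: 0})
        with pytest.raises(ValueError):
            build_design(df, "tmin", "changed_relationship")


class TestChangedFormEquivalence:
    def test_per_slice_lines_equal_independent_fits(self):
        """Full-interaction fits decouple the slices: per-slice intercepts
        and slopes equal separate per-slice simple regressions."""
        df = make_panel({0: 2.0, 3: -1.0, 7: 0.5},
                        {0: 1.0, 3: -1.0, 7: 0.0}, seed=4)
        res = StationarityModel(df, "nri", "tmin",
                                "changed_relationship", "ols").fit()
        tc = extract_time_coefficients(res).set_index("time_ka")
        for t, sl in df.groupby("time_ka"):
            X = pd.DataFrame({"const": np.ones(len(sl)),
                              "tmin": sl["tmin"].to_numpy()})
            sep = fit_ols(sl["nri"].to_numpy(), X)
            assert tc.loc[t, "intercept"] == pytest.approx(sep.params["const"],
                                                           abs=1e-8)
            assert tc.loc[t, "slope"] == pytest.approx(sep.params["tmin"],
                                                       abs=1e-8)

    def test_two_slice_toy_exact_recovery(self):
        # y = 1 + 2x at t=0 and y = -1 + 0.5x at t=1, no noise
        x = np.linspace(-2, 2, 9)
        rows = []
        for xi in x:
            rows.append((-85.0, 40.0, 0, 1 + 2 * xi, xi))
            rows.append((-85.0, 40.0, 1, -1 + 0.5 * xi, xi))
        df = pd.DataFrame(rows, columns=["cell_lon", "cell_lat", "time_ka",
                                         "nri", "tmin"])
        res = StationarityModel(df, "nri", "tmin",
                                "changed_relationship", "ols").fit()
        tc = extract_time_coefficients(res).set_index("time_ka")
        assert tc.loc[0, "intercept"] == pytest.approx(1.0)
        assert tc.loc[0, "slope"] == pytest.approx(2.0)
        assert tc.loc[1, "intercept"] == pytest.approx(-1.0)
        assert tc.loc[1, "slope"] == pytest.approx(0.5)

    def test_slope_form_has_constant_slopes(self):
        df = make_panel({0: 1.0, 1: 1.0, 2: 1.0}, {0: 0, 1: 1, 2: 2}, seed=5)
        res = StationarityModel(df, "nri", "tmin", "stable_slope", "ols").fit()
        tc = extract_time_coefficients(res)
        assert tc["slope"].nunique() == 1


class TestNesting:
    def test_rss_monotone_over_nesting(self):
        df = make_panel({0: 1.0, 1: 0.5, 2: -0.5}, {0: 0, 1: 1, 2: 0}, seed=6)
        fits = {f: StationarityModel(df, "nri", "tmin", f, "ols").fit()
                for f in FORMS}
        rss = [fits[f].fit.ssr for f in FORMS]
        assert rss[0] >= rss[1] >= rss[2]
        llf = [fits[f].llf for f in FORMS]
        assert llf[0] <= llf[1] <= llf[2]

    def test_identical_fits_give_zero_statistic(self):
        df = make_panel({0: 1.0, 1: 1.0}, {0: 0.0, 1: 0.0}, seed=7,
                        sigma=0.0)
        fits = {f: StationarityModel(df, "nri", "tmin", f, "ols").fit()
                for f in FORMS}
        # noise-free constant law: extra parameters explain nothing
        c = compare_nested(fits["stable_slope"], fits["changed_relationship"])
        assert c.statistic == pytest.approx(0.0, abs=1e-6)

    def test_type_one_error_calibrated(self):
        """Constant-slope generator: the changed-vs-slope test rejects at
        about the nominal 5% rate."""
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            slopes = {t: 0.8 for t in range(5)}
            intercepts = {t: 0.1 * t for t in range(5)}
            df = make_panel(slopes, intercepts, n_per_slice=25, seed=1000 + rep)
            fits = {f: StationarityModel(df, "nri", "tmin", f, "ols").fit()
                    for f in ("stable_slope", "changed_relationship")}
            c = compare_nested(fits["stable_slope"],
                               fits["changed_relationship"])
            rejections += c.p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08

    def test_power_against_sign_flip(self):
        """Slope flipping from +0.5 to -0.5 mid-series is detected."""
        detected = 0
        n_rep = 100
        for rep in range(n_rep):
            slopes = {t: (0.5 if t < 3 else -0.5) for t in range(6)}
            intercepts = {t: 0.0 for t in range(6)}
            df = make_panel(slopes, intercepts, n_per_slice=30,
                            seed=2000 + rep)
            fits = {f: StationarityModel(df, "nri", "tmin", f, "ols").fit()
                    for f in ("stable_slope", "changed_relationship")}
            c = compare_nested(fits["stable_slope"],
                               fits["changed_relationship"])
            detected += c.p < 0.05
        assert detected / n_rep >= 0.8

    def test_stable_slope_estimate_unbiased(self):
        b = 0.6
        est = []
        for rep in range(100):
            df = make_panel({t: b for t in range(4)},
                            {t: 0.0 for t in range(4)}, n_per_slice=30,
                            seed=3000 + rep)
            res = StationarityModel(df, "nri", "tmin",
                                    "stable_relationship", "ols").fit()
            est.append(res.params["tmin"])
        assert abs(np.mean(est) - b) < 0.02 * abs(b) + 0.01

    def test_non_nested_rejected(self):
        df = make_panel({0: 1.0, 1: 0.5}, {0: 0, 1: 1}, seed=8)
        fits = {f: StationarityModel(df, "nri", "tmin", f, "ols").fit()
                for f in FORMS}
        with pytest.raises(ValueError):
            compare_nested(fits["changed_relationship"],
                           fits["stable_relationship"])


class TestSarPath:
    def test_fit_model_set_selects_distance_and_fits_all_forms(self):
        df = make_panel({0: 1.0, 1: 0.5, 2: 0.0}, {0: 0, 1: 0.5, 2: 1},
                        n_per_slice=35, seed=9)
        out = fit_model_set(df, "nri", "tmin", "sar",
                            distances_km=[120.0, 360.0, 480.0])
        assert out["distance_km"] in (120.0, 360.0, 480.0)
        assert set(out["fits"]) == set(FORMS)
        sel, comps = select_form(out["fits"])
        assert sel in FORMS
        assert all(c.statistic >= 0 for c in comps)

    def test_select_weight_distance_argmin_and_tie(self):
        class Stub:
            def __init__(self, I):
                self.moran = type("M", (), {"I": I})()

        assert select_weight_distance(
            {120.0: Stub(0.30), 360.0: Stub(0.05), 480.0: Stub(0.08)}) == 360.0
        assert select_weight_distance(
            {120.0: Stub(0.1), 360.0: Stub(0.1), 480.0: Stub(0.1)}) == 120.0

    def test_sar_llf_monotone_over_nesting(self):
        df = make_panel({0: 1.0, 1: -0.5}, {0: 0, 1: 1}, n_per_slice=40,
                        seed=10)
        out = fit_model_set(df, "nri", "tmin", "sar")
        llf = [out["fits"][f].llf for f in FORMS]
        assert llf[0] <= llf[1] + 1e-6 and llf[1] <= llf[2] + 1e-6


class TestGeography:
    def test_constant_pcs_zero_slope(self):
        df = make_panel({0: 0.0}, {0: 0.0}, sigma=0.0, seed=11)
        df["nri"] = 1.5
        # constant response: slope is exactly 0
        fit = geographic_trend(df, "nri", "lon")
        assert fit.params["cell_lon"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_synthetic_gradient(self):
        rng = np.random.default_rng(12)
        lon = rng.uniform(-95, -55, size=3000)
        df = pd.DataFrame({
            "cell_lon": lon, "cell_lat": 40.0,
            "nri": 0.01 * lon + rng.normal(scale=0.3, size=3000),
            "time_ka": 0,
        })
        fit = geographic_trend(df, "nri", "lon")
        ci = fit.conf_int()
        lo, hi = ci.loc["cell_lon"] if hasattr(ci, "loc") else ci[1]
        assert lo <= 0.01 <= hi


class TestEqualize:
    def test_row_counts_and_determinism(self):
        df = make_panel({t: 0.5 for t in range(5)}, {t: 0 for t in range(5)},
                        n_per_slice=30, seed=13)
        out1 = equalize_sample_sizes(df, 12, seed=1)
        out2 = equalize_sample_sizes(df, 12, seed=1)
        assert len(out1) == 12 * 5
        pd.testing.assert_frame_equal(out1, out2)

    def test_n_equal_to_slice_size_is_identity(self):
        df = make_panel({0: 0.5}, {0: 0.0}, n_per_slice=12, seed=14)
        out = equalize_sample_sizes(df, 12, seed=0)
        assert len(out) == 12

    def test_small_slice_modes(self):
        df = make_panel({0: 0.5, 1: 0.5}, {0: 0, 1: 0}, n_per_slice=8,
                        seed=15)
        with pytest.raises(ValueError):
            equalize_sample_sizes(df, 12, seed=0)
        out = equalize_sample_sizes(df, 12, seed=0, on_small="drop")
        assert out.empty
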