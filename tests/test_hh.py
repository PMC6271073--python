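"""Semilog Henderson–Hasselbalch stage: transforms, fits, conversions."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrtitrate import (
    NOISELESS,
    DegenerateDataError,
    FitError,
    HHTable,
    LimitingShifts,
    NoiseSpec,
    NoTransitionError,
    SiteModel,
    TitrationPoint,
    TitrationSeries,
    default_grid,
    extract_limits,
    fit_pka,
    hh_transform,
    ka_to_pka,
    pka_to_ka,
    simulate_monoprotic,
)


class TestKaConversions:
    @pytest.mark.parametrize(
        "Ka, pKa_1dp",
        [(15.1e-9, 7.8), (1.44e-9, 8.8), (1.23e-9, 8.9), (1e-7, 7.0)],
    )
    def test_ka_to_pka_reference_values(self, Ka, pKa_1dp):
        assert round(ka_to_pka(Ka), 1) == pKa_1dp

    def test_pka_to_ka(self):
        assert pka_to_ka(7.0) == pytest.approx(1e-7)
        assert pka_to_ka(0.0) == 1.0

    @given(st.floats(min_value=-10, max_value=-4))
    @settings(max_examples=30, derandomize=True)
    def test_round_trip(self, log_ka):
        Ka = 10.0 ** log_ka
        assert pka_to_ka(ka_to_pka(Ka)) == pytest.approx(Ka, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ka_to_pka(0.0)
        with pytest.raises(ValueError):
            ka_to_pka(-1.0)
        with pytest.raises(ValueError):
            pka_to_ka(float("nan"))


class TestExtractLimits:
    def test_recovers_generating_endpoints(self, mono_site):
        # plateau window must sit >= 3 pH units from the transition for
        # sub-0.1% endpoint contamination
        s = simulate_monoprotic(mono_site, default_grid(8.5, span=3.5), NOISELESS)
        limits = extract_limits(s, "H9", 3)
        rng = 8.9 - 8.1
        assert abs(limits.delta_min - 8.1) < 1e-3 * rng
        assert abs(limits.delta_max - 8.9) < 1e-3 * rng
        assert not limits.truncated

    def test_constant_series_refused(self):
        points = [
            TitrationPoint(i, "initial" if i == 0 else "base", 6.0 + i, {"H9": 5.0})
            for i in range(8)
        ]
        series = TitrationSeries(points=points)
        with pytest.raises(ValueError, match="delta_min"):
            extract_limits(series, "H9", 3)

    def test_truncated_titration_flagged(self, mono_site):
        # stop half a unit past the pKa: the basic plateau never develops
        s = simulate_monoprotic(mono_site, np.arange(6.0, 9.01, 0.25), NOISELESS)
        assert extract_limits(s, "H9", 3).truncated

    def test_too_few_points(self, mono_site):
        s = simulate_monoprotic(mono_site, [7.0, 8.0, 9.0], NOISELESS)
        with pytest.raises(DegenerateDataError):
            extract_limits(s, "H9", 3)


class TestTransform:
    def test_midpoint_maps_to_zero(self, mono_site):
        s = simulate_monoprotic(mono_site, [8.5, 9.5], NOISELESS)
        limits = LimitingShifts(8.1, 8.9, "H9", 0)
        table = hh_transform(s, "H9", limits)
        assert table.y[0] == pytest.approx(0.0, abs=1e-12)

    def test_points_at_limits_excluded_not_fatal(self):
        points = [
            TitrationPoint(0, "initial", 6.0, {"H9": 8.9}),   # at delta_max
            TitrationPoint(1, "base", 8.0, {"H9": 8.5}),
            TitrationPoint(2, "base", 9.0, {"H9": 8.3}),
            TitrationPoint(3, "base", 12.0, {"H9": 8.1}),     # at delta_min
        ]
        series = TitrationSeries(points=points)
        table = hh_transform(series, "H9", LimitingShifts(8.1, 8.9, "H9", 0))
        assert table.n_excluded == 2
        assert table.pH.tolist() == [8.0, 9.0]

    def test_exact_linearity_on_noiseless_data(self, mono_site):
        s = simulate_monoprotic(mono_site, default_grid(8.5, span=2.0), NOISELESS)
        limits = LimitingShifts(8.1, 8.9, "H9", 0)
        table = hh_transform(s, "H9", limits)
        # two-state algebra: y = pKa - pH up to sign per endpoint orientation
        assert np.allclose(np.abs(table.y), np.abs(8.5 - table.pH), atol=1e-9)


class TestFitPka:
    def test_collinear_points_exact(self):
        table = HHTable(np.array([8.0, 9.0, 10.0]), np.array([1.0, 0.0, -1.0]),
                        0, "H9")
        fit = fit_pka(table)
        assert fit.pKa == pytest.approx(9.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert not fit.slope_deviation

    @pytest.mark.parametrize("increasing", [True, False])
    def test_noiseless_recovery_both_orientations(self, increasing):
        da, db = (8.1, 8.9) if increasing else (8.9, 8.1)
        site = SiteModel(8.5, {"H9": da}, {"H9": db})
        s = simulate_monoprotic(site, default_grid(8.5), NOISELESS)
        limits = LimitingShifts(8.1, 8.9, "H9", 0)
        fit = fit_pka(hh_transform(s, "H9", limits))
        assert fit.pKa == pytest.approx(8.5, abs=1e-6)
        assert abs(fit.slope) == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared > 1 - 1e-12

    def test_min_max_swap_leaves_pka_flips_slope(self, mono_series):
        limits = extract_limits(mono_series, "H9", 3)
        fit = fit_pka(hh_transform(mono_series, "H9", limits))
        # relabelling which end is min/max == reflecting the shifts
        reflected = dataclasses.replace(
            mono_series,
            points=[
                dataclasses.replace(p, shifts={"H9": -p.shifts["H9"]})
                for p in mono_series.points
            ],
        )
        limits2 = extract_limits(reflected, "H9", 3)
        fit2 = fit_pka(hh_transform(reflected, "H9", limits2))
        assert fit2.pKa == pytest.approx(fit.pKa, abs=1e-9)
        assert fit2.slope == pytest.approx(-fit.slope, abs=1e-9)

    def test_monte_carlo_noisy_recovery(self, mono_site):
        grid = default_grid(8.5)
        errors = []
        for seed in range(1, 201):
            noise = NoiseSpec(sigma_shift=0.002, sigma_pH=0.02, seed=seed)
            s = simulate_monoprotic(mono_site, grid, noise)
            limits = extract_limits(s, "H9", 3)
            fit = fit_pka(hh_transform(s, "H9", limits))
            errors.append(abs(fit.pKa - 8.5))
        assert float(np.mean(errors)) < 0.05

    def test_leave_one_out_within_stderr(self, mono_site):
        noise = NoiseSpec(sigma_shift=0.002, sigma_pH=0.02, seed=7)
        s = simulate_monoprotic(mono_site, default_grid(8.5), noise)
        limits = extract_limits(s, "H9", 3)
        full = fit_pka(hh_transform(s, "H9", limits))
        for drop in range(5, 20):   # interior points
            sub = dataclasses.replace(
                s, points=[p for i, p in enumerate(s.points) if i != drop]
            )
            fit = fit_pka(hh_transform(sub, "H9", limits))
            assert abs(fit.pKa - full.pKa) < full.pKa_stderr

    def test_all_ph_equal_is_singular(self):
        table = HHTable(np.array([8.0, 8.0, 8.0]), np.array([1.0, 0.0, -1.0]),
                        0, "H9")
        with pytest.raises(FitError, match="singular"):
            fit_pka(table)

    def test_flat_response_refused(self):
        rng = np.random.default_rng(0)
        table = HHTable(np.linspace(6, 11, 12), rng.normal(0, 0.01, 12), 0, "H9")
        with pytest.raises(NoTransitionError):
            fit_pka(table)
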