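"""δ-diagram stage: construction, breakpoint classes, Perrin, Gibbs triangle."""

import dataclasses
import math

import numpy as np
import pytest

from nmrtitrate import (
    NOISELESS,
    DegenerateDataError,
    DegenerateTriangleError,
    TautomerSystemSpec,
    build_diagram,
    default_grid,
    linearity_check,
    perrin_fit,
    polster_lachmann,
    simulate_tautomeric,
)
from tests.conftest import make_diprotic_ratio


def tautomer_diagram(pKa_HO, pKa_HN, true_anchors=True):
    spec = TautomerSystemSpec(
        pKa_HO, pKa_HN, {"H6": 6.9, "H9": 4.8}, {"H6": 6.3, "H9": 4.3}
    )
    lo, hi = min(pKa_HO, pKa_HN), max(pKa_HO, pKa_HN)
    series = simulate_tautomeric(spec, default_grid(lo, hi), NOISELESS)
    kwargs = {}
    if true_anchors:
        kwargs = {"start_anchor": (6.9, 4.8), "end_anchor": (6.3, 4.3)}
    return spec, build_diagram(series, "H6", "H9", **kwargs)


class TestBuildDiagram:
    def test_completeness_filter(self, mono_series):
        points = list(mono_series.points)
        p = points[5]
        points[5] = dataclasses.replace(
            p, shifts={k: v for k, v in p.shifts.items() if k != "H6"}
        )
        series = dataclasses.replace(mono_series, points=points)
        d = build_diagram(series, "H6", "H9")
        assert len(d) == len(mono_series) - 1
        assert 5 not in d.source_index.tolist()

    def test_anchors_default_to_first_last(self, mono_series):
        d = build_diagram(mono_series, "H6", "H9")
        assert d.start_anchor == tuple(d.points[0])
        assert d.end_anchor == tuple(d.points[-1])

    def test_monoprotic_diagram_is_collinear(self, mono_series):
        d = build_diagram(mono_series, "H6", "H9")
        a = np.asarray(d.start_anchor)
        c = np.asarray(d.end_anchor)
        chord = (c - a) / np.hypot(*(c - a))
        normal = np.array([-chord[1], chord[0]])
        deviation = np.abs((d.points - a) @ normal)
        assert deviation.max() < 1e-10

    def test_too_few_complete_points(self, mono_series):
        series = dataclasses.replace(mono_series, points=mono_series.points[:2])
        with pytest.raises(DegenerateDataError):
            build_diagram(series, "H6", "H9")


class TestLinearityCheck:
    def test_collinear_zero_breaks(self, mono_series):
        d = build_diagram(mono_series, "H6", "H9")
        assert linearity_check(d).selected == 0

    def test_smooth_two_site_curvature_is_not_a_breakpoint(self, tautomer_series):
        # overlapping equilibria curve the diagram smoothly: no corner
        d = build_diagram(tautomer_series, "H6", "H9")
        assert linearity_check(d).selected == 0

    def test_diprotic_one_break_near_intermediate(self, diprotic_series):
        d = build_diagram(diprotic_series, "H6", "H9")
        result = linearity_check(d)
        assert result.selected == 1
        v = result.model.vertices[0]
        # vertex within 2 grid steps of the pure-intermediate coordinates
        step = np.abs(np.diff(d.points, axis=0)).max()
        assert np.hypot(*(d.points[v] - np.array([6.5, 4.75]))) < 2.5 * step

    def test_four_state_two_breaks(self, four_state_series):
        d = build_diagram(four_state_series, "H6", "H5")
        assert linearity_check(d).selected == 2

    def test_subset_stability(self, diprotic_series):
        d = build_diagram(diprotic_series, "H6", "H9")
        full = linearity_check(d).selected
        sub = dataclasses.replace(
            diprotic_series, points=diprotic_series.points[2:-2]
        )
        dsub = build_diagram(sub, "H6", "H9")
        assert linearity_check(dsub).selected <= full + 1

    def test_too_few_points_for_breaks(self, mono_series):
        series = dataclasses.replace(mono_series, points=mono_series.points[:5])
        d = build_diagram(series, "H6", "H9")
        with pytest.raises(ValueError):
            linearity_check(d, max_breaks=2)
        assert linearity_check(d, max_breaks=1).selected in (0, 1)


class TestPerrin:
    def test_recovery_and_zero_intercept(self):
        spec, d = tautomer_diagram(8.0, 8.3)
        fit = perrin_fit(d)
        assert fit.delta_K == pytest.approx(10 ** (-0.3), rel=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert abs(fit.r) > 1 - 1e-9

    def test_equal_constants_unity_slope(self):
        spec, d = tautomer_diagram(8.0, 8.0)
        fit = perrin_fit(d)
        assert fit.delta_K == pytest.approx(1.0, abs=1e-12)
        assert fit.near_unity
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("dpk", np.round(np.linspace(-1.0, 1.0, 9), 3))
    def test_ratio_sweep_recovery(self, dpk):
        # ratios 0.1 .. 10: slope equals the generating site-constant quotient
        spec, d = tautomer_diagram(8.0, 8.0 + dpk)
        fit = perrin_fit(d)
        assert fit.delta_K == pytest.approx(spec.delta_K_true, rel=1e-6)

    def test_probe_swap_inverts_slope(self):
        spec, d = tautomer_diagram(8.0, 8.3)
        k_xy = perrin_fit(d).delta_K
        k_yx = perrin_fit(d.swapped()).delta_K
        assert k_xy * k_yx == pytest.approx(1.0, abs=1e-9)

    def test_direction_reversal_inverts_slope(self):
        # swapping the start/end anchor roles exchanges u and v exactly
        spec, d = tautomer_diagram(8.0, 8.3)
        k_fwd = perrin_fit(d).delta_K
        k_rev = perrin_fit(d.reversed()).delta_K
        assert k_fwd * k_rev == pytest.approx(1.0, abs=1e-9)

    def test_coincident_anchor_coordinate_rejected(self, mono_series):
        d = build_diagram(mono_series, "H6", "H9")
        bad = dataclasses.replace(d, end_anchor=(d.start_anchor[0], 4.0))
        with pytest.raises(DegenerateDataError):
            perrin_fit(bad)


class TestPolsterLachmann:
    @pytest.mark.parametrize("ratio", [2, 5, 10])
    def test_stepwise_quotient_recovery(self, ratio):
        series = make_diprotic_ratio(ratio)
        d = build_diagram(series, "H6", "H9")
        result = linearity_check(d)
        # overlapping steps may not raise a corner; the analyst posits the
        # two-step model explicitly
        model = result.model if result.selected >= 1 else result.models[1]
        pl = polster_lachmann(d, model)
        assert abs(pl.delta_K - ratio) / ratio <= 0.10
        assert pl.delta_K > 0
        assert pl.distance_ratio > 0

    def test_collinear_diagram_refused(self, mono_series):
        d = build_diagram(mono_series, "H6", "H9")
        result = linearity_check(d)
        assert result.selected == 0
        with pytest.raises(DegenerateTriangleError):
            polster_lachmann(d, result)
        # forcing the 1-vertex model on collinear data collapses the triangle
        with pytest.raises(DegenerateTriangleError):
            polster_lachmann(d, result.models[1])

    def test_triangle_vertices_sane(self, diprotic_series):
        d = build_diagram(diprotic_series, "H6", "H9")
        pl = polster_lachmann(d, linearity_check(d))
        tri = pl.triangle
        assert tri.A == d.start_anchor
        assert tri.C == d.end_anchor
        # B approximates the pure-intermediate coordinates
        assert np.hypot(*(np.array(tri.B) - np.array([6.5, 4.75]))) < 0.05
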