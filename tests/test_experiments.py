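"""End-to-end experiments: compression, insulation, matching, scrambling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgeint import experiments as ex
from edgeint.integration import ModelConfig


class TestFitPowerLaw:
    def test_unit_and_third_slopes(self):
        x = np.geomspace(1.0, 100.0, 6)
        assert ex.fit_power_law(x, np.log(x)).slope == pytest.approx(1.0)
        fit = ex.fit_power_law(x, np.log(x) / 3.0 + 2.0)
        assert fit.slope == pytest.approx(1.0 / 3.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.rss < 1e-12

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_slope_invariant_to_rescaling_x(self, c):
        x = np.geomspace(2.0, 50.0, 5)
        y = 0.4 * np.log(x) - 1.0
        assert math.isclose(
            ex.fit_power_law(x * c, y).slope, 0.4, rel_tol=1e-9, abs_tol=1e-9
        )

    def test_needs_two_distinct_x(self):
        with pytest.raises(ValueError):
            ex.fit_power_law([5.0, 5.0], [1.0, 2.0])


class TestGelbSeries:
    def test_plain_wide_exponent_is_w_inc(self):
        res = ex.run_gelb_series()
        assert res.fit.slope == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert res.fit.rss < 1e-12

    def test_insulated_wide_exponent_is_w_dec(self):
        res = ex.run_gelb_series(insulated=True)
        assert res.fit.slope == pytest.approx(1.0, abs=1e-12)
        assert res.fit.rss < 1e-12

    def test_ideal_observer_is_veridical(self):
        res = ex.run_gelb_series(config=ModelConfig(ideal_observer=True))
        assert res.fit.slope == pytest.approx(1.0, abs=1e-9)

    @given(
        w_inc=st.floats(min_value=0.2, max_value=0.8),
        w_dec=st.floats(min_value=0.8, max_value=1.5),
        illum=st.floats(min_value=400.0, max_value=4000.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=8, deadline=None)
    def test_exponents_equal_weights_for_any_series(self, w_inc, w_dec, illum, seed):
        """Closed-form consequence: the fitted Gelb exponent equals w_inc
        (plain) / w_dec (insulated) for any paper set and illuminant."""
        rng = np.random.default_rng(seed)
        refl = np.sort(rng.uniform(0.02, 0.85, size=4))
        if np.min(np.diff(np.log(refl))) < 1e-3:
            refl = np.geomspace(0.02, 0.85, 4)
        config = ModelConfig(w_inc=w_inc, w_dec=w_dec)
        plain = ex.run_gelb_series(refl, illum=illum, config=config)
        assert plain.fit.slope == pytest.approx(w_inc, rel=1e-9)
        ins = ex.run_gelb_series(refl, illum=illum, config=config, insulated=True)
        assert ins.fit.slope == pytest.approx(w_dec, rel=1e-9)

    def test_insulation_requires_reflective_frame(self):
        with pytest.raises(ValueError, match="frame"):
            ex.run_gelb_series([0.1, 0.95], insulated=True, frame_reflectance=0.5)


class TestIdealObserverMatching:
    def test_reflectance_interpretation_luminance_match_slope_zero(self):
        res = ex.run_ideal_observer_matching(interpretation="reflectance")
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.fit.rss < 1e-12
        # luminance matching: the match equals the test disk luminance
        assert all(
            math.isclose(m.matched_disk_lum, 60.0, rel_tol=1e-9) for m in res.matches
        )

    def test_illumination_interpretation_ratio_match_slope_minus_one(self):
        res = ex.run_ideal_observer_matching(interpretation="illumination")
        assert res.slope == pytest.approx(-1.0, abs=1e-9)
        assert res.fit.rss < 1e-12
        # ratio matching: disk/annulus ratio preserved
        for m in res.matches:
            assert math.isclose(
                m.matched_disk_lum / 40.0, 60.0 / m.annulus_lum, rel_tol=1e-9
            )

    def test_full_illumination_gain_reproduces_reflectance_case(self):
        """g_illum = 1 makes the illumination interpretation act like the
        reflectance one."""
        from edgeint.contrast import extract_edges
        from edgeint.integration import path_lightness
        from edgeint.selection import (
            SpotlightSpec,
            apply_gain_field,
            build_region_graph,
            select_paths,
        )
        from edgeint.stimuli import make_disk_annulus

        image, regions = make_disk_annulus(60.0, 90.0, 10.0)
        config = ModelConfig(ideal_observer=True)
        lams = {}
        for tag, spot in [
            ("refl", SpotlightSpec()),
            ("illum_g1", SpotlightSpec(default_interpretation="illumination", g_illum=1.0)),
        ]:
            edges = apply_gain_field(extract_edges(image, regions), spot)
            graph = build_region_graph(regions, edges)
            paths = select_paths(graph, 2, spot)
            lams[tag] = path_lightness(paths, edges, config, regions)
        assert lams["refl"] == pytest.approx(lams["illum_g1"], abs=1e-12)


class TestWeightRecovery:
    def test_default_ratio_is_one_third_exact(self):
        res = ex.run_weight_recovery()
        assert res["ratio"] == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert res["residual"] < 1e-9

    def test_ideal_observer_ratio_is_one(self):
        res = ex.run_weight_recovery(config=ModelConfig(ideal_observer=True))
        assert res["ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_one_sided_design_rejected(self):
        with pytest.raises(ValueError, match="polarit"):
            ex.run_weight_recovery(disk_lums=[150.0, 200.0, 300.0])


class TestScrambling:
    def test_identity_permutation_changes_nothing(self):
        for mode in ("wide", "narrow"):
            table = ex.run_scrambling(permutation=[0, 1, 2, 3, 4], spotlight_mode=mode)
            assert table["delta"].abs().max() == 0.0

    def test_wide_mode_invariant_under_any_permutation(self):
        for perm in ([4, 3, 2, 1, 0], [1, 3, 0, 4, 2]):
            table = ex.run_scrambling(permutation=perm, spotlight_mode="wide")
            assert table["delta"].abs().max() < 1e-12

    def test_narrow_mode_sensitive_to_neighbour_swap(self):
        table = ex.run_scrambling(permutation=[0, 2, 1, 3, 4], spotlight_mode="narrow")
        assert table["delta"].abs().max() > 1e-3

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            ex.run_scrambling(permutation=[0, 0, 1, 2, 3])


class TestAnnulusWidth:
    def test_equal_widths_equal_ac(self):
        res = ex.run_annulus_width_demo(widths=(2.0, 2.0))
        assert res[0][1] == res[1][1]

    def test_wider_annulus_gives_lower_disk_ac(self):
        res = ex.run_annulus_width_demo(widths=(1.0, 4.0))
        assert res[1][1] < res[0][1]

    def test_uniform_kernel_removes_the_effect(self):
        res = ex.run_annulus_width_demo(
            widths=(1.0, 4.0), config=ModelConfig(ideal_observer=True)
        )
        assert res[0][1] == pytest.approx(res[1][1], abs=1e-9)

    def test_incremental_disk_rejected(self):
        with pytest.raises(ValueError):
            ex.run_annulus_width_demo(disk_lum=120.0, annulus_lum=90.0)


class TestContourMasking:
    def test_masking_gain_zero_edge_changes_nothing(self, decremental_disk):
        from edgeint.contrast import extract_edges
        from edgeint.selection import SpotlightSpec, apply_gain_field, mask_edge
        from edgeint.integration import compute_channel_maps

        image, regions = decremental_disk
        edges = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
        outer = edges.between(0, 1)[0].id
        pre_masked = mask_edge(edges, outer)
        res_before = compute_channel_maps(pre_masked, regions, ModelConfig())
        res_after = compute_channel_maps(
            mask_edge(pre_masked, outer), regions, ModelConfig()
        )
        assert np.array_equal(res_before.L, res_after.L)
        assert np.array_equal(res_before.D, res_after.D)
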