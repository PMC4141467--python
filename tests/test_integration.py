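"""Spatial integration: kernels, path sums, channel maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from edgeint.contrast import extract_edges
from edgeint.integration import (
    DEFAULT_TAU,
    ModelConfig,
    compute_channel_maps,
    distance_weight,
    path_lightness,
)
from edgeint.selection import SpotlightSpec, apply_gain_field, build_region_graph, select_paths
from edgeint.stimuli import LuminanceImage, make_disk_annulus

lum = st.floats(min_value=1.0, max_value=1000.0)


def disk_lightness(image, regions, config, spotlight=None):
    spotlight = spotlight or SpotlightSpec()
    edges = apply_gain_field(extract_edges(image, regions), spotlight)
    graph = build_region_graph(regions, edges)
    paths = select_paths(graph, 2, spotlight)
    return path_lightness(paths, edges, config, regions)


class TestDistanceWeight:
    def test_unit_weight_at_zero(self):
        for kernel in ("exponential", "linear", "log_linear", "uniform"):
            assert distance_weight(0.0, ModelConfig(kernel=kernel)) == 1.0

    def test_default_kernel_negligible_at_range_limit(self):
        g10 = distance_weight(10.0, ModelConfig())
        assert g10 <= 0.05 + 1e-12
        assert math.isclose(g10, 0.05, rel_tol=1e-9)

    @pytest.mark.parametrize("kernel", ["exponential", "linear", "log_linear"])
    def test_monotone_non_increasing(self, kernel):
        config = ModelConfig(kernel=kernel)
        d = np.linspace(0.0, 15.0, 301)
        g = distance_weight(d, config)
        assert np.all(np.diff(g) <= 1e-12)
        assert np.all((g >= 0) & (g <= 1))
        assert np.all(g[d > config.range_cutoff] == 0.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_weight(-1.0, ModelConfig())

    def test_default_tau_calibration(self):
        assert math.isclose(DEFAULT_TAU, 10.0 / math.log(20.0), rel_tol=1e-12)


class TestPathLightness:
    @given(bg=lum, ann=lum, disk=lum)
    @settings(max_examples=15, deadline=None)
    def test_telescoping_oracle_for_ideal_observer(self, bg, ann, disk):
        """With unit weights and a uniform kernel the path sum telescopes
        to ln(L_target / L_background) for any disk-annulus stimulus."""
        image, regions = make_disk_annulus(disk, ann, bg, shape=(128, 128))
        lam = disk_lightness(image, regions, ModelConfig(ideal_observer=True))
        assert math.isclose(lam, math.log(disk / bg), rel_tol=1e-9, abs_tol=1e-9)

    def test_default_weights_manual_oracle(self):
        """bg 1, annulus 100, disk 10 with kernel ≡ 1:
        Λ = (1/3)·ln 100 + 1·ln(1/10) = −(1/3)·ln 10."""
        image, regions = make_disk_annulus(10.0, 100.0, 1.0)
        config = ModelConfig(kernel="uniform")
        lam = disk_lightness(image, regions, config)
        assert math.isclose(lam, -math.log(10.0) / 3.0, rel_tol=1e-9)

    def test_zero_contrast_step_contributes_nothing(self):
        image, regions = make_disk_annulus(30.0, 10.0, 10.0)  # annulus == bg
        lam = disk_lightness(image, regions, ModelConfig(kernel="uniform"))
        assert math.isclose(lam, ModelConfig().w_inc * math.log(3.0), rel_tol=1e-9)

    @given(c=st.floats(min_value=1e-2, max_value=1e2))
    @settings(max_examples=15, deadline=None)
    def test_scaling_invariance(self, c):
        """Multiplying all luminances by c > 0 leaves Λ unchanged."""
        image, regions = make_disk_annulus(30.0, 90.0, 10.0, shape=(128, 128))
        scaled = LuminanceImage(image.values * c, image.pitch)
        lam0 = disk_lightness(image, regions, ModelConfig())
        lam1 = disk_lightness(scaled, regions, ModelConfig())
        assert math.isclose(lam0, lam1, rel_tol=1e-9, abs_tol=1e-9)

    def test_polarity_asymmetry_ratio(self):
        """Mirrored contrasts: |Λ| for the decrement is w_dec/w_inc = 3×
        the increment's."""
        k, L = 4.0, 50.0
        config = ModelConfig(kernel="uniform")
        img_inc, reg = make_disk_annulus(L * k, L, L)
        img_dec, _ = make_disk_annulus(L / k, L, L)
        lam_inc = disk_lightness(img_inc, reg, config)
        lam_dec = disk_lightness(img_dec, reg, config)
        assert math.isclose(abs(lam_dec), 3.0 * abs(lam_inc), rel_tol=1e-9)

    def test_gain_scales_contribution(self, decremental_disk):
        image, regions = decremental_disk
        edges = extract_edges(image, regions)
        outer = edges.between(0, 1)[0]
        spot = SpotlightSpec(edge_interpretation={outer.id: "illumination"}, g_illum=0.0)
        config = ModelConfig(kernel="uniform")
        lam = disk_lightness(image, regions, config, spot)
        # only the inner decremental edge survives
        assert math.isclose(lam, math.log(30.0 / 90.0), rel_tol=1e-9)


class TestChannelMaps:
    def test_uniform_image_gives_zero_channels(self):
        image, regions = make_disk_annulus(50.0, 50.0, 50.0)
        edges = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
        maps = compute_channel_maps(edges, regions, ModelConfig())
        assert np.all(maps.L == 0.0) and np.all(maps.D == 0.0)

    def test_decremental_disk_gets_both_inductions(self, decremental_disk, decremental_edges):
        image, regions = decremental_disk
        maps = compute_channel_maps(decremental_edges, regions, ModelConfig())
        disk = regions.labels == 2
        assert np.all(maps.D[disk] > 0)  # darkness from the inner edge
        assert np.all(maps.L[disk] > 0)  # lightness reaching in from the outer edge

    def test_double_increment_disk_has_no_darkness(self):
        image, regions = make_disk_annulus(120.0, 60.0, 20.0)
        edges = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
        maps = compute_channel_maps(edges, regions, ModelConfig())
        disk = regions.labels == 2
        assert np.all(maps.D[disk] == 0.0)
        assert np.all(maps.L[disk] > 0.0)

    def test_meniscus_exponential_peak_linear_flat(self):
        """Exponential kernel: the decremental disk's AC has a strict
        maximum at the disk centre with real curvature; linear kernel:
        the interior profile is affine in the edge distances (flat
        second derivative, no meniscus)."""
        image, regions = make_disk_annulus(
            30.0, 90.0, 10.0, disk_radius=2.0, annulus_outer_radius=4.0
        )
        edges = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
        disk = regions.labels == 2
        # interior, clear of the pixelated boundary
        rr = ndimage.distance_transform_edt(disk) * image.pitch
        interior = disk & (rr > 0.3)
        center = np.unravel_index(np.argmax(rr), rr.shape)

        def residual_of_affine_in_distances(config):
            maps = compute_channel_maps(edges, regions, config)
            ac = maps.L - maps.D
            dists = []
            for e in edges:
                mask = np.zeros(regions.shape, dtype=bool)
                pix = e.boundary_pixels()
                mask[pix[:, 0], pix[:, 1]] = True
                dists.append(ndimage.distance_transform_edt(~mask)[interior] * image.pitch)
            A = np.stack([np.ones(interior.sum())] + dists, axis=1)
            coef, _, _, _ = np.linalg.lstsq(A, ac[interior], rcond=None)
            return ac, float(np.max(np.abs(A @ coef - ac[interior])))

        ac_exp, res_exp = residual_of_affine_in_distances(ModelConfig(kernel="exponential"))
        ac_lin, res_lin = residual_of_affine_in_distances(ModelConfig(kernel="linear"))
        # exponential: strict central maximum, genuinely curved profile
        assert ac_exp[center] > ac_exp[interior].mean()
        assert ac_exp[center] >= ac_exp[interior].max() - 1e-12
        assert res_exp > 1e-3
        # linear: profile is affine in the edge distances to float precision
        assert res_lin < 1e-9

    def test_distance_monotonicity_wider_annulus_darker_disk(self):
        """Moving the outer border farther away strictly lowers disk AC."""
        acs = []
        for outer_r in (2.0, 3.5, 5.0):
            image, regions = make_disk_annulus(
                30.0, 90.0, 10.0, disk_radius=1.0, annulus_outer_radius=outer_r
            )
            edges = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
            maps = compute_channel_maps(edges, regions, ModelConfig())
            disk = regions.labels == 2
            acs.append((maps.L - maps.D)[disk].mean())
        assert acs[0] > acs[1] > acs[2]

    def test_channel_maps_scaling_invariance(self, decremental_disk):
        image, regions = decremental_disk
        scaled = LuminanceImage(image.values * 7.5, image.pitch)
        e0 = apply_gain_field(extract_edges(image, regions), SpotlightSpec())
        e1 = apply_gain_field(extract_edges(scaled, regions), SpotlightSpec())
        m0 = compute_channel_maps(e0, regions, ModelConfig())
        m1 = compute_channel_maps(e1, regions, ModelConfig())
        assert np.allclose(m0.L, m1.L, rtol=1e-9, atol=1e-12)
        assert np.allclose(m0.D, m1.D, rtol=1e-9, atol=1e-12)
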