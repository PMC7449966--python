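import dataclasses

import numpy as np
import pytest

from liverspec.photon_mc import (EmptyMapError, GeometryError, PhotonState,
                                 ProbeGeometry, SimulationConfig,
                                 absorb_and_roulette, boundary_interaction,
                                 fresnel_reflectance, launch,
                                 penetration_depth, run_simulation,
                                 sample_step, scatter_hg, sensing_depth)
from liverspec.tissue_optics import OpticalProperties, \
    liver_reference_properties


def props(mu_a=1.0, mu_s=100.0, g=0.9, n=1.38, wavelength=800.0):
    return OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n,
                             wavelength=wavelength)


class TestElementaryOps:
    def test_fresnel_normal_incidence_closed_form(self):
        # ((n1-n2)/(n1+n2))^2 at normal incidence
        assert fresnel_reflectance(1.0, 1.4, 1.0) == pytest.approx(
            (0.4 / 2.4) ** 2, abs=1e-12)

    def test_fresnel_matched_and_total_internal(self):
        assert fresnel_reflectance(0.3, 1.5, 1.5) == pytest.approx(0.0)
        critical = np.sqrt(1 - (1.0 / 1.5) ** 2)
        assert fresnel_reflectance(critical * 0.9, 1.5, 1.0) == 1.0

    def test_step_exponential_mean(self, rng):
        steps = sample_step(10.0, rng, size=1_000_000)
        assert steps.mean() == pytest.approx(0.1, rel=0.01)
        assert np.isfinite(steps).all()

    def test_step_scaling_and_validation(self, rng):
        s1 = sample_step(5.0, np.random.default_rng(7), size=200_000)
        s2 = sample_step(10.0, np.random.default_rng(7), size=200_000)
        assert s1.mean() == pytest.approx(2 * s2.mean(), rel=1e-9)
        with pytest.raises(ValueError):
            sample_step(0.0, rng)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_hg_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(11)
        ct = scatter_hg(g, rng, size=1_000_000)
        se = ct.std() / np.sqrt(ct.size)
        assert abs(ct.mean() - g) < 3 * se

    def test_hg_isotropic_variance(self):
        rng = np.random.default_rng(3)
        ct = scatter_hg(0.0, rng, size=500_000)
        assert ct.var() == pytest.approx(1.0 / 3.0, rel=0.02)

    def test_hg_invalid_g(self, rng):
        with pytest.raises(ValueError):
            scatter_hg(1.0, rng)


class TestLaunch:
    def test_positions_inside_source_disk_and_centered(self):
        geo = ProbeGeometry()
        rng = np.random.default_rng(0)
        states = launch(geo, 1.38, rng, n=100_000)
        pos = np.array([s.position for s in states])
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(r <= geo.source_radius + 1e-12)
        se = geo.source_radius / np.sqrt(len(states))
        assert abs(pos[:, 0].mean()) < 3 * se
        assert abs(pos[:, 1].mean()) < 3 * se

    def test_directions_within_cone(self):
        geo = ProbeGeometry()
        rng = np.random.default_rng(1)
        states = launch(geo, 1.38, rng, n=20_000)
        uz = np.array([s.direction[2] for s in states])
        assert np.all(uz >= geo.cone_cosine(1.38) - 1e-12)

    def test_degenerate_cone_limit(self):
        geo = ProbeGeometry(numerical_aperture=1e-9)
        state = launch(geo, 1.38, np.random.default_rng(0))
        assert state.direction[2] == pytest.approx(1.0, abs=1e-9)

    def test_na_exceeding_index_is_geometry_error(self):
        geo = ProbeGeometry(numerical_aperture=0.9)
        with pytest.raises(GeometryError):
            launch(geo, 0.8, np.random.default_rng(0))


class TestRouletteAndBoundary:
    def test_albedo_one_keeps_weight(self, rng):
        p = PhotonState(position=[0, 0, 0.1], direction=[0, 0, 1],
                        weight=0.5)
        absorb_and_roulette(p, 1.0, SimulationConfig(), rng)
        assert p.weight == 0.5

    def test_three_interactions_arithmetic(self, rng):
        p = PhotonState(position=[0, 0, 0.1], direction=[0, 0, 1])
        for _ in range(3):
            absorb_and_roulette(p, 0.9, SimulationConfig(), rng)
        assert p.weight == pytest.approx(0.729)

    def test_roulette_is_unbiased(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(5)
        w0 = 5e-5  # below threshold
        total = 0.0
        n = 100_000
        for _ in range(n):
            p = PhotonState(position=[0, 0, 0.1], direction=[0, 0, 1],
                            weight=w0)
            absorb_and_roulette(p, 1.0, cfg, rng)
            total += p.weight
        mean = total / n
        se = w0 * np.sqrt((1 / cfg.roulette_survival - 1) / n)
        assert abs(mean - w0) < 3 * se

    def test_boundary_matched_always_transmits(self, rng):
        p = PhotonState(position=[0, 0, 0.0], direction=[0, 0, -1])
        assert boundary_interaction(p, 1.4, 1.4, rng) == "transmitted"

    def test_boundary_total_internal_reflection(self, rng):
        # incidence beyond the critical angle asin(n2/n1)
        uz = -0.1
        d = np.array([np.sqrt(1 - uz ** 2), 0, uz])
        p = PhotonState(position=[0, 0, 0.0], direction=d)
        assert boundary_interaction(p, 1.5, 1.0, rng) == "reflected"
        assert p.direction[2] == pytest.approx(0.1)


@pytest.fixture(scope="module")
def liver450_run():
    cfg = SimulationConfig(n_photons=1_000_000, seed=7, slab_half=0.0025,
                           roulette_threshold=1e-5)
    return run_simulation(ProbeGeometry(), liver_reference_properties(450.0),
                          cfg)


class TestRunSimulation:
    def test_weight_conservation(self, liver450_run):
        led = liver450_run.ledger
        total = sum(v for k, v in led.items() if k != "launched")
        assert total == pytest.approx(led["launched"], rel=1e-6)

    def test_zero_absorption_matched_boundary_escape(self):
        cfg = SimulationConfig(n_photons=50_000, seed=2, track_map=False,
                               max_path=5000.0)
        res = run_simulation(ProbeGeometry(ambient_index=1.46),
                             props(mu_a=0.0, mu_s=50.0, g=0.0, n=1.46), cfg)
        led = res.ledger
        escape = (led["detected"] + led["escaped"]) / led["launched"]
        assert escape == pytest.approx(1.0, abs=0.005)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_photons=100_000, seed=9, track_map=False)
        geo = ProbeGeometry()
        r1 = run_simulation(geo, props(), cfg)
        r2 = run_simulation(geo, props(), cfg)
        assert r1.detected_fraction == r2.detected_fraction
        assert np.array_equal(r1.fluence.values, r2.fluence.values)

    def test_detected_fraction_decreases_with_absorption(self):
        geo = ProbeGeometry()
        fractions = []
        for mu_a in (5.0, 15.0, 40.0):
            cfg = SimulationConfig(n_photons=250_000, seed=4,
                                   track_map=False)
            fractions.append(run_simulation(
                geo, props(mu_a=mu_a, mu_s=130.0, g=0.89), cfg
            ).detected_fraction)
        assert fractions[0] > fractions[1] > fractions[2]

    def test_similarity_scaling_halves_depths(self):
        """Rescaling (mu_a, mu_s) by k with geometry and grids scaled by
        1/k must rescale sensing and penetration depth by 1/k."""
        k = 2.0
        geo = ProbeGeometry()
        cfg = SimulationConfig(n_photons=1_000_000, seed=13,
                               slab_half=0.0025, roulette_threshold=1e-5)
        base_props = liver_reference_properties(450.0)
        base = run_simulation(geo, base_props, cfg)
        geo2 = ProbeGeometry(source_radius=geo.source_radius / k,
                             detector_radius=geo.detector_radius / k,
                             separation=geo.separation / k)
        cfg2 = dataclasses.replace(
            cfg, voxel_size=cfg.voxel_size / k,
            x_extent=(cfg.x_extent[0] / k, cfg.x_extent[1] / k),
            z_extent=cfg.z_extent / k, slab_half=cfg.slab_half / k,
            fluence_depth=cfg.fluence_depth / k,
            fluence_bin=cfg.fluence_bin / k,
            fluence_radius=cfg.fluence_radius / k, max_path=cfg.max_path / k)
        scaled_props = dataclasses.replace(base_props,
                                           mu_a=k * base_props.mu_a,
                                           mu_s=k * base_props.mu_s)
        scaled = run_simulation(geo2, scaled_props, cfg2)
        assert sensing_depth(scaled.sampling_map) == pytest.approx(
            sensing_depth(base.sampling_map) / k, rel=0.05)
        assert penetration_depth(scaled.fluence) == pytest.approx(
            penetration_depth(base.fluence) / k, rel=0.05)

    def test_penetration_shrinks_with_absorption(self):
        geo = ProbeGeometry()
        cfg = SimulationConfig(n_photons=150_000, seed=6, track_map=False)
        shallow = run_simulation(geo, props(mu_a=3.0, mu_s=80.0), cfg)
        deep = run_simulation(geo, props(mu_a=0.8, mu_s=80.0), cfg)
        assert penetration_depth(shallow.fluence) < \
            penetration_depth(deep.fluence)

    def test_reciprocity_area_weighted(self):
        """Swapping fibers conserves throughput: f_SD * A_src = f_DS * A_det
        within 3 pooled MC standard errors."""
        geo = ProbeGeometry()
        swapped = geo.swapped()
        p = liver_reference_properties(450.0)
        fwd, rev = [], []
        for seed in range(4):
            cfg = SimulationConfig(n_photons=250_000, seed=seed,
                                   track_map=False)
            fwd.append(run_simulation(geo, p, cfg).detected_fraction
                       * geo.source_radius ** 2)
            rev.append(run_simulation(swapped, p, cfg).detected_fraction
                       * swapped.source_radius ** 2)
        fwd, rev = np.array(fwd), np.array(rev)
        se = np.sqrt(fwd.var(ddof=1) / 4 + rev.var(ddof=1) / 4)
        assert abs(fwd.mean() - rev.mean()) < 3 * se


class TestDepthExtraction:
    def test_threshold_one_returns_peak_voxel_depth(self, liver450_run):
        smap = liver450_run.sampling_map
        d = sensing_depth(smap, threshold=1.0)
        iz = np.argwhere(smap.values == 1.0)
        assert d == pytest.approx(smap.z[iz[:, 1].max()])

    def test_depth_non_increasing_in_threshold(self, liver450_run):
        smap = liver450_run.sampling_map
        depths = [sensing_depth(smap, t)
                  for t in (1e-3, 1e-2, 1e-1, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(depths, depths[1:]))

    def test_penetration_threshold_one_is_near_surface(self, liver450_run):
        fl = liver450_run.fluence
        assert penetration_depth(fl, threshold=1.0) == \
            fl.z[int(np.argmax(fl.values))]

    def test_empty_map_raises(self):
        # separation far beyond any plausible photon migration
        geo = ProbeGeometry(separation=5.0)
        cfg = SimulationConfig(n_photons=2_000, seed=1)
        res = run_simulation(geo, props(mu_a=20.0, mu_s=100.0), cfg)
        assert res.sampling_map.empty
        with pytest.raises(EmptyMapError):
            sensing_depth(res.sampling_map)

    def test_geometry_validation(self):
        with pytest.raises(GeometryError):
            ProbeGeometry(numerical_aperture=1.5)
        with pytest.raises(GeometryError):
            ProbeGeometry(source_radius=-1.0)
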