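"""Monte Carlo transport: geometry, Fresnel physics and detection optics."""

import numpy as np
import pytest

from confocyl.mc import (
    OpticalSystem,
    Photon,
    _launch_batch,
    fresnel_interact,
    fresnel_reflectance,
    intersect_ray_cylinder,
    launch_photon,
    lens_diameter,
    simulate_pixel,
    trace,
)
from confocyl.phantom import Phantom, single_cylinder_phantom


class TestLensDiameter:
    def test_printed_configurations(self):
        assert lens_diameter(0.6, 2.0, 1.0) == pytest.approx(6.0, rel=1e-12)
        assert lens_diameter(1.4, 0.3, 1.518) == pytest.approx(2.8631, abs=2e-4)

    def test_small_aperture_limit(self):
        na, f, ns = 1e-6, 2.0, 1.0
        assert lens_diameter(na, f, ns) == pytest.approx(4 * f * na / ns, rel=1e-9)

    def test_na_exceeding_medium_index_rejected(self):
        with pytest.raises(ValueError):
            lens_diameter(1.1, 2.0, 1.0)
        with pytest.raises(ValueError):
            OpticalSystem(na=1.6, focal_length=0.3, pinhole_radius=0.7, n_surround=1.518)


class TestLaunch:
    def test_direction_unit_and_downward(self, air_optics, rng):
        for _ in range(50):
            ph = launch_photon(air_optics, (0.0, 0.0, 5.0), rng)
            assert np.linalg.norm(ph.direction) == pytest.approx(1.0, abs=1e-12)
            assert ph.direction[2] < 0

    def test_area_sampling_mean_radius(self, air_optics):
        """Uniform-over-area start positions have mean radius 2/3 r_lens."""
        rng = np.random.default_rng(7)
        pos, _ = _launch_batch(
            air_optics, np.zeros(3), 1_000_000, rng, "3d", "area"
        )
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r.mean() == pytest.approx(
            2 / 3 * air_optics.lens_radius_um, rel=0.002
        )

    def test_literal_sampling_mean_radius(self, air_optics):
        """The literal uniform-in-radius mode has mean radius r_lens / 2."""
        rng = np.random.default_rng(7)
        pos, _ = _launch_batch(
            air_optics, np.zeros(3), 500_000, rng, "3d", "literal"
        )
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r.mean() == pytest.approx(air_optics.lens_radius_um / 2, rel=0.005)

    def test_2d_mode_confined_to_plane(self, air_optics):
        rng = np.random.default_rng(7)
        pos, d = _launch_batch(air_optics, np.zeros(3), 1000, rng, "2d", "area")
        assert np.all(pos[:, 0] == 0.0)
        assert np.all(d[:, 0] == 0.0)


class TestIntersection:
    def test_head_on_hit(self):
        hit = intersect_ray_cylinder(
            np.array([0.0, 0.0, 30.0]), np.array([0.0, 0.0, -1.0]), 0.0, 0.0, 10.0
        )
        assert hit is not None
        t, normal = hit
        assert t == pytest.approx(20.0, abs=1e-9)
        np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)

    def test_tangent_ray_misses(self):
        hit = intersect_ray_cylinder(
            np.array([0.0, 10.0, 30.0]), np.array([0.0, 0.0, -1.0]), 0.0, 0.0, 10.0
        )
        assert hit is None

    def test_axis_parallel_ray_misses(self):
        hit = intersect_ray_cylinder(
            np.array([0.0, 3.0, 3.0]), np.array([1.0, 0.0, 0.0]), 0.0, 0.0, 10.0
        )
        assert hit is None

    def test_against_surface_marching_oracle(self):
        """Brute-force oracle: march along each ray in 1e-3 um steps and
        record the first step crossing the cylinder surface."""
        rng = np.random.default_rng(99)
        r = 10.0
        for _ in range(300):
            pos = rng.uniform(-30, 30, 3)
            if np.hypot(pos[1], pos[2]) <= r + 0.1:
                continue
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts = np.arange(0.0, 80.0, 1e-3)
            pts_y = pos[1] + ts * d[1]
            pts_z = pos[2] + ts * d[2]
            inside = pts_y**2 + pts_z**2 < r * r
            first = np.argmax(inside) if inside.any() else None
            hit = intersect_ray_cylinder(pos, d, 0.0, 0.0, r)
            if first is None or first == 0:
                if hit is not None:  # marching can miss grazing hits
                    chord_y = pos[1] + hit[0] * d[1]
                    chord_z = pos[2] + hit[0] * d[2]
                    assert np.hypot(chord_y, chord_z) == pytest.approx(r, abs=1e-6)
            else:
                assert hit is not None
                assert hit[0] == pytest.approx(ts[first], abs=2e-3)


class TestFresnel:
    def test_normal_incidence_reflectance(self):
        assert fresnel_reflectance(1.0, 1.0, 1.6285) == pytest.approx(
            (0.6285 / 2.6285) ** 2, rel=1e-12
        )

    def test_matched_media_pass_through(self, rng):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, -1.0]), 1.5)
        out = fresnel_interact(ph, np.array([0.0, 0.0, 1.0]), 1.5, 1.5, rng)
        np.testing.assert_allclose(out.direction, [0, 0, -1], atol=1e-12)
        assert out.n_events == 1

    def test_total_internal_reflection(self, rng):
        # from the denser resin toward oil beyond the critical angle
        n1, n2 = 1.6285, 1.518
        crit = np.arcsin(n2 / n1)
        ang = crit + 0.05
        d = np.array([0.0, np.sin(ang), -np.cos(ang)])
        for _ in range(50):
            ph = Photon(np.zeros(3), d.copy(), n1)
            out = fresnel_interact(ph, np.array([0.0, 0.0, 1.0]), n1, n2, rng)
            assert out.medium_index == n1  # always reflected
            assert out.direction[2] > 0

    def test_branch_frequency_matches_reflectance(self):
        """Empirical reflect frequency equals the Fresnel reflectance within
        3 sigma (binomial)."""
        rng = np.random.default_rng(5)
        n1, n2, cos_i = 1.0, 1.6285, np.cos(0.4)
        r_expected = fresnel_reflectance(cos_i, n1, n2)
        n = 20_000
        d = np.array([0.0, np.sin(0.4), -np.cos(0.4)])
        reflected = 0
        for _ in range(n):
            ph = Photon(np.zeros(3), d.copy(), n1)
            out = fresnel_interact(ph, np.array([0.0, 0.0, 1.0]), n1, n2, rng)
            reflected += out.medium_index == n1
        sigma = np.sqrt(r_expected * (1 - r_expected) / n)
        assert reflected / n == pytest.approx(r_expected, abs=3 * sigma)

    def test_energy_conservation_of_coefficients(self):
        for cos_i in (1.0, 0.9, 0.5, 0.2):
            r = fresnel_reflectance(cos_i, 1.0, 1.6285)
            assert 0.0 <= r <= 1.0

    def test_misoriented_normal_rejected(self, rng):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, -1.0]), 1.0)
        with pytest.raises(ValueError):
            fresnel_interact(ph, np.array([0.0, 0.0, -1.0]), 1.0, 1.5, rng)


class TestDetectionOptics:
    def test_ray_from_focal_point_maps_to_pinhole_centre(self, air_optics, rng):
        """The 4f ABCD mapping sends any ray through the focus to the
        pinhole centre."""
        focal = np.array([3.0, -2.0, 5.0])
        empty = Phantom(cylinders=(), n_surround=1.0)
        for ang in (0.05, 0.2, 0.5):
            d = np.array([np.sin(ang), 0.2 * np.sin(ang), np.cos(ang)])
            d /= np.linalg.norm(d)
            ph = Photon(focal.copy(), d, 1.0)
            rec = trace(ph, empty, air_optics, focal, rng=rng)
            assert rec.detected
            assert np.hypot(*rec.pinhole_pos) < 1e-9

    def test_lateral_displacement_maps_at_unit_magnification(self, air_optics, rng):
        focal = np.array([0.0, 0.0, 5.0])
        empty = Phantom(cylinders=(), n_surround=1.0)
        delta = 0.9
        d = np.array([0.1, 0.0, 1.0])
        d /= np.linalg.norm(d)
        ph = Photon(np.array([delta, 0.0, 5.0]), d, 1.0)
        rec = trace(ph, empty, air_optics, focal, rng=rng)
        assert np.hypot(*rec.pinhole_pos) == pytest.approx(delta, rel=1e-9)

    def test_ray_missing_aperture_terminated(self, air_optics, rng):
        focal = np.array([0.0, 0.0, 0.0])
        empty = Phantom(cylinders=(), n_surround=1.0)
        d = np.array([np.sin(1.2), 0.0, np.cos(1.2)])  # far outside the cone
        ph = Photon(focal.copy(), d, 1.0)
        rec = trace(ph, empty, air_optics, focal, rng=rng)
        assert not rec.detected
        assert rec.lens_hit is None


class TestSimulatePixel:
    def test_empty_phantom_detects_nothing(self, air_optics):
        empty = Phantom(cylinders=(), n_surround=1.0)
        assert simulate_pixel(air_optics, empty, (0, 0, 0), 5000, 1) == 0.0

    def test_determinism(self, air_optics, cylinder_air):
        a = simulate_pixel(air_optics, cylinder_air, (0, 0, 10.0), 20_000, 3)
        b = simulate_pixel(air_optics, cylinder_air, (0, 0, 10.0), 20_000, 3)
        assert a == b

    def test_detected_fraction_bounded(self, air_optics, cylinder_air):
        f = simulate_pixel(air_optics, cylinder_air, (0, 0, 10.0), 20_000, 3)
        assert 0.0 < f < 1.0

    def test_apex_focus_matches_fresnel_expectation(self, air_optics, cylinder_air):
        """Oracle: with the focus on the cylinder apex every launched ray is
        retro-reflected through the focus, so the detected fraction equals
        the Fresnel reflectance averaged over the launch-angle
        distribution."""
        f_um = air_optics.focal_length_um
        r_lens = air_optics.lens_radius_um
        r = np.linspace(0, r_lens, 4001)[1:]
        cos_theta = 2 * f_um / np.hypot(r, 2 * f_um)
        R = np.array([fresnel_reflectance(c, 1.0, 1.6285) for c in cos_theta])
        expected = np.sum(R * r) / np.sum(r)  # area-weighted over the disc
        n = 100_000
        frac = simulate_pixel(air_optics, cylinder_air, (0, 0, 10.0), n, 17)
        sigma = np.sqrt(expected * (1 - expected) / n)
        # small extra contributions (multi-bounce) allowed above the pure
        # single-reflection estimate
        assert frac == pytest.approx(expected, abs=max(5 * sigma, 0.1 * expected))

    def test_apex_focus_is_axial_maximum(self, air_optics, cylinder_air):
        near = [
            simulate_pixel(air_optics, cylinder_air, (0, 0, z), 30_000, 21)
            for z in (8.0, 10.0, 12.0)
        ]
        assert near[1] == max(near)

    def test_pinhole_monotonicity(self, cylinder_air):
        """Enlarging the pinhole never loses a detected photon (same photon
        stream, nested acceptance discs)."""
        fracs = []
        for r_pin in (0.4, 0.8, 1.68, 3.5):
            opt = OpticalSystem(
                na=0.6, focal_length=2.0, pinhole_radius=r_pin, n_surround=1.0
            )
            fracs.append(
                simulate_pixel(opt, cylinder_air, (0, 0, 4.0), 30_000, 11)
            )
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_mirror_symmetry(self, air_optics):
        """Mirroring the phantom about y=0 mirrors the scan within MC
        error."""
        from confocyl.phantom import Cylinder

        ph_left = Phantom(cylinders=(Cylinder(-6.0, 0.0, 5.0, 1.6285),))
        ph_right = Phantom(cylinders=(Cylinder(6.0, 0.0, 5.0, 1.6285),))
        n = 40_000
        for y in (-6.0, -3.0, 0.0):
            a = simulate_pixel(air_optics, ph_left, (0, y, 5.0), n, 31)
            b = simulate_pixel(air_optics, ph_right, (0, -y, 5.0), n, 32)
            p = (a + b) / 2
            sigma = np.sqrt(max(2 * p * (1 - p) / n, 1e-12))
            assert abs(a - b) <= 3 * sigma + 1e-9

    def test_scalar_trace_agrees_with_batch_engine(self, air_optics, cylinder_air):
        """The per-photon reference implementation and the vectorised batch
        engine sample the same physics."""
        rng = np.random.default_rng(8)
        focal = np.array([0.0, 0.0, 10.0])
        n = 3000
        hits = 0
        for _ in range(n):
            ph = launch_photon(air_optics, focal, rng)
            hits += trace(ph, cylinder_air, air_optics, focal, rng=rng).detected
        frac_scalar = hits / n
        frac_batch = simulate_pixel(air_optics, cylinder_air, focal, 50_000, 9)
        sigma = np.sqrt(
            frac_batch * (1 - frac_batch) * (1 / n + 1 / 50_000)
        )
        assert frac_scalar == pytest.approx(frac_batch, abs=3.5 * sigma)

    def test_deep_signal_rises_as_na_shrinks(self, cylinder_oil):
        """Reducing the aperture from NA 1.4 to 0.9 makes the deep
        focus-like signal below the cylinder rise relative to the
        underside reflex."""
        ratios = {}
        for na in (1.4, 0.9):
            opt = OpticalSystem(
                na=na, focal_length=0.3, pinhole_radius=0.72, n_surround=1.518
            )
            deep = simulate_pixel(opt, cylinder_oil, (0, 0, -20.0), 150_000, 41)
            ref = simulate_pixel(opt, cylinder_oil, (0, 0, -12.0), 150_000, 42)
            ratios[na] = deep / max(ref, 1e-12)
        assert ratios[0.9] > ratios[1.4]

    def test_record_path_vertices_on_cylinder(self, oil_optics, cylinder_oil):
        rng = np.random.default_rng(2)
        focal = np.array([0.0, 0.0, -12.0])
        found = None
        for _ in range(3000):
            ph = launch_photon(oil_optics, focal, rng)
            rec = trace(
                ph, cylinder_oil, oil_optics, focal, rng=rng, record_path=True
            )
            if rec.detected:
                found = rec
                break
        assert found is not None, "no detected path found"
        interior = found.path[1:]
        for v in interior:
            assert np.hypot(v[1], v[2]) == pytest.approx(10.0, abs=1e-6)
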