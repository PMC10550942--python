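"""Geometric water construction: circle, midpoint, oxygen, hydrogens."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from aquabridge.chemistry import GeometryParams
from aquabridge.energy import HBondModel
from aquabridge.fixtures import FixtureSpec, make_bridge_fixture
from aquabridge.waterbuild import (GeometryError, bridge_circle,
                                   closest_approach_midpoint,
                                   construct_water, merge_waters,
                                   orient_hydrogens, pair_eligible,
                                   place_water_oxygen, solvate_structure)
from conftest import make_site, random_eligible_pair, unit

PARAMS = GeometryParams()


def two_sphere_oracle(Xi, Xj, d_i, d_j):
    """Numerically solve |P-Xi|=d_i, |P-Xj|=d_j in the axis plane."""
    Xi, Xj = np.asarray(Xi, float), np.asarray(Xj, float)

    def eqs(v):
        a, h = v  # along-axis offset and altitude
        n = (Xj - Xi) / np.linalg.norm(Xj - Xi)
        perp = np.array([-n[1], n[0], 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        p = Xi + a * n + h * perp
        return (np.linalg.norm(p - Xi) - d_i,
                np.linalg.norm(p - Xj) - d_j)

    a, h = fsolve(eqs, [np.linalg.norm(Xj - Xi) / 2, 1.0], full_output=False)
    return float(a), abs(float(h))


class TestEligibility:
    def test_expected_separation_is_eligible(self):
        si = make_site([0, 0, 0])
        sj = make_site([4.61, 0, 0])
        assert pair_eligible(si, sj, PARAMS)

    def test_boundary_is_strict(self):
        si = make_site([0, 0, 0])
        sj = make_site([3.65, 0, 0])
        assert not pair_eligible(si, sj, PARAMS)

    def test_strict_window(self):
        si = make_site([0, 0, 0])
        sj = make_site([5.00, 0, 0])
        assert pair_eligible(si, sj, PARAMS, strict=True)
        sk = make_site([4.00, 0, 0])
        assert not pair_eligible(si, sk, PARAMS, strict=True)

    def test_same_residue_ineligible(self):
        si = make_site([0, 0, 0], res_id=77)
        sj = make_site([4.61, 0, 0], res_id=77)
        assert not pair_eligible(si, sj, PARAMS)


class TestBridgeCircle:
    @pytest.mark.parametrize("sep,di,dj", [
        (4.61, 2.73, 2.73),
        (4.61, 2.73, 2.87),
        (3.70, 2.87, 2.87),
        (5.40, 2.73, 2.73),
    ])
    def test_against_two_sphere_oracle(self, sep, di, dj):
        Xi, Xj = np.zeros(3), np.array([sep, 0.0, 0.0])
        c = bridge_circle(Xi, Xj, di, dj)
        a_ref, h_ref = two_sphere_oracle(Xi, Xj, di, dj)
        assert np.linalg.norm(c.center - Xi) == pytest.approx(a_ref,
                                                              abs=1e-8)
        assert c.radius == pytest.approx(h_ref, abs=1e-8)
        # every circle point is at the ideal distances
        perp = np.array([0.0, 1.0, 0.0])
        p = c.center + c.radius * perp
        assert np.linalg.norm(p - Xi) == pytest.approx(di, abs=1e-9)
        assert np.linalg.norm(p - Xj) == pytest.approx(dj, abs=1e-9)

    def test_degenerate_tangency(self):
        c = bridge_circle([0, 0, 0], [5.46, 0, 0], 2.73, 2.73)
        assert c.radius == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(c.center, [2.73, 0, 0], atol=1e-9)

    def test_triangle_violation(self):
        with pytest.raises(GeometryError):
            bridge_circle([0, 0, 0], [6.0, 0, 0], 2.73, 2.73)

    def test_center_on_segment(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            si, sj = random_eligible_pair(rng)
            c = bridge_circle(si.position, sj.position,
                              si.ideal_water_distance,
                              sj.ideal_water_distance)
            axis = sj.position - si.position
            t = np.dot(c.center - si.position, axis) / np.dot(axis, axis)
            assert 0.0 < t < 1.0


class TestClosestApproach:
    def test_skew_lines(self):
        m, par = closest_approach_midpoint([0, 0, 0], [1, 0, 0],
                                           [0, 1, 1], [0, 1, 0])
        assert not par
        np.testing.assert_allclose(m, [0, 0, 0.5], atol=1e-12)

    def test_intersecting_lines(self):
        m, par = closest_approach_midpoint([-1, -1, 0], [1, 1, 0],
                                           [-1, 1, 0], [1, -1, 0])
        assert not par
        np.testing.assert_allclose(m, [0, 0, 0], atol=1e-12)

    def test_parallel_fallback(self):
        m, par = closest_approach_midpoint([0, 0, 0], [1, 0, 0],
                                           [0, 0, 1], [1, 0, 0])
        assert par
        np.testing.assert_allclose(m, [0, 0, 0.5], atol=1e-12)

    def test_minimises_squared_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p1, p2 = rng.normal(size=3), rng.normal(size=3)
            u, v = unit(rng.normal(size=3)), unit(rng.normal(size=3))
            m, par = closest_approach_midpoint(p1, u, p2, v)
            if par:
                continue
            # oracle: dense grid over both line parameters
            t = np.linspace(-10, 10, 4001)
            A = p1[None, :] + t[:, None] * u[None, :]
            B = p2[None, :] + t[:, None] * v[None, :]
            d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            np.testing.assert_allclose(m, 0.5 * (A[i] + B[j]), atol=0.02)


class TestOxygenPlacement:
    def test_zero_radius_returns_center(self):
        c = bridge_circle([0, 0, 0], [5.46, 0, 0], 2.73, 2.73)
        np.testing.assert_allclose(
            place_water_oxygen(c, [9.0, 9.0, 9.0]), c.center, atol=1e-9)

    def test_scaling_along_center_ray(self):
        c = bridge_circle([0, 0, 0], [4.0, 0, 0], 2.73, 2.73)
        m = c.center + 2 * c.radius * np.array([0.0, 1.0, 0.0])
        o = place_water_oxygen(c, m)
        np.testing.assert_allclose(
            o, c.center + c.radius * np.array([0, 1.0, 0]), atol=1e-9)

    def test_perimeter_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            si, sj = random_eligible_pair(rng)
            c = bridge_circle(si.position, sj.position,
                              si.ideal_water_distance,
                              sj.ideal_water_distance)
            m = rng.normal(scale=4.0, size=3)
            o = place_water_oxygen(c, m)
            # oracle: dense perimeter grid, nearest point to the midpoint
            ref = np.array([1.0, 0, 0])
            if abs(np.dot(ref, c.normal)) > 0.9:
                ref = np.array([0, 1.0, 0])
            e1 = unit(ref - np.dot(ref, c.normal) * c.normal)
            e2 = np.cross(c.normal, e1)
            ang = np.linspace(0, 2 * math.pi, 36000, endpoint=False)
            pts = c.center + c.radius * (
                np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            best = pts[np.argmin(np.linalg.norm(pts - m, axis=1))]
            assert np.linalg.norm(o - best) < 1e-3

    def test_degenerate_projection_uses_tiebreak(self):
        c = bridge_circle([0, 0, 0], [4.0, 0, 0], 2.73, 2.73)
        o1 = place_water_oxygen(c, c.center,
                                tiebreak_dirs=[([0, 0, 0], [0.5, 1, 0])])
        assert np.linalg.norm(o1 - c.center) == pytest.approx(c.radius,
                                                              abs=1e-9)
        # tie-break follows the supplied direction
        assert np.dot(o1 - c.center, [0, 1, 0]) > 0


def water_geometry_ok(p, params=PARAMS):
    for h in p.hydrogens:
        assert np.linalg.norm(h - p.oxygen) == pytest.approx(
            params.OH_length, abs=1e-6)
    u1 = unit(p.hydrogens[0] - p.oxygen)
    u2 = unit(p.hydrogens[1] - p.oxygen)
    ang = math.degrees(math.acos(np.clip(np.dot(u1, u2), -1, 1)))
    assert ang == pytest.approx(params.HOH_angle, abs=1e-4)


class TestOrientation:
    def test_two_acceptors_single_variant_symmetric(self):
        si = make_site([2.3, 0, 0], orbital=[-1, 0, 0])
        sj = make_site([-2.3, 0, 0], orbital=[1, 0, 0])
        out = orient_hydrogens([0, 0.9, 0], si, sj, PARAMS)
        assert len(out) == 1
        p = out[0]
        water_geometry_ok(p)
        a1 = np.dot(unit(p.hydrogens[0] - p.oxygen),
                    unit(si.position - p.oxygen))
        a2 = np.dot(unit(p.hydrogens[1] - p.oxygen),
                    unit(sj.position - p.oxygen))
        assert a1 == pytest.approx(a2, abs=1e-9)  # symmetric deviations

    def test_two_donors_hydrogens_face_away(self):
        si = make_site([2.3, 0, 0], role="donor",
                       hydrogen_toward=[0, 0.9, 0])
        sj = make_site([-2.3, 0, 0], role="donor",
                       hydrogen_toward=[0, 0.9, 0])
        out = orient_hydrogens([0, 0.9, 0], si, sj, PARAMS)
        assert len(out) == 1
        p = out[0]
        water_geometry_ok(p)
        for site in (si, sj):
            for h in p.hydrogens:
                cosang = np.dot(unit(h - p.oxygen),
                                unit(site.position - p.oxygen))
                assert cosang < 0  # angle > 90 deg

    def test_mixed_pair_two_variants(self):
        si = make_site([2.3, 0, 0], role="both", orbital=[-1, 0, 0],
                       hydrogen_toward=[0, 0.9, 0])
        sj = make_site([-2.3, 0, 0], role="acceptor", orbital=[1, 0, 0])
        out = orient_hydrogens([0, 0.9, 0], si, sj, PARAMS)
        assert len(out) == 2
        assert {p.orientation_variant for p in out} == {1, 2}
        for p in out:
            water_geometry_ok(p)


class TestConstruction:
    def test_exactness_invariants_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            si, sj = random_eligible_pair(rng)
            for p in construct_water(si, sj, PARAMS):
                assert np.linalg.norm(p.oxygen - si.position) == \
                    pytest.approx(si.ideal_water_distance, abs=1e-6)
                assert np.linalg.norm(p.oxygen - sj.position) == \
                    pytest.approx(sj.ideal_water_distance, abs=1e-6)
                water_geometry_ok(p)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            si, sj = random_eligible_pair(rng)
            o1 = construct_water(si, sj, PARAMS)[0].oxygen
            o2 = construct_water(sj, si, PARAMS)[0].oxygen
            assert np.linalg.norm(o1 - o2) < 1e-9


class TestSolvation:
    def test_planted_fixture_recovery(self):
        s, truth = make_bridge_fixture(FixtureSpec(seed=42, n_bridges=2))
        waters = solvate_structure(s, PARAMS, HBondModel())
        assert len(waters) >= len(truth)
        for t in truth:
            dev = min(np.linalg.norm(w.oxygen - t.oxygen) for w in waters)
            assert dev < 0.05

    def test_no_polar_sites_yields_nothing(self):
        s, _ = make_bridge_fixture(
            FixtureSpec(seed=0, n_bridges=0, decoy_atoms=12))
        waters = solvate_structure(s, PARAMS, HBondModel())
        assert waters == []

    def test_pair_outside_window_yields_nothing(self):
        from aquabridge.structure import Structure
        from aquabridge.fixtures import _carbonyl_fragment
        rng = np.random.default_rng(0)
        w = np.zeros(3)
        frag = (_carbonyl_fragment(np.array([3.0, 0, 0]), w, rng, 1)
                + _carbonyl_fragment(np.array([-3.0, 0, 0]), w, rng, 2))
        # polar separation 6.0 A: outside the 2-sigma window
        waters = solvate_structure(Structure(atoms=frag), PARAMS,
                                   HBondModel())
        assert waters == []

    def test_merge_keeps_lower_energy(self):
        from aquabridge.waterbuild import WaterPlacement
        w1 = WaterPlacement(oxygen=np.zeros(3), hydrogens=[],
                            energy_i=-3, energy_j=-3)
        w2 = WaterPlacement(oxygen=np.array([0.4, 0, 0]), hydrogens=[],
                            energy_i=-1, energy_j=-1)
        w3 = WaterPlacement(oxygen=np.array([5.0, 0, 0]), hydrogens=[],
                            energy_i=-1, energy_j=-1)
        kept = merge_waters([w2, w1, w3], 1.0)
        assert len(kept) == 2
        assert any(k is w1 for k in kept) and any(k is w3 for k in kept)
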