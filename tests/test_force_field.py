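"""Potential-energy terms: finite-difference force consistency, weight
interpolation, cutoff construction, presets and invariances."""

import numpy as np
import pytest

from pacsab import (ForceFieldParams, build_pacsab_model, make_polypeptide,
                    pair_weights, preset, total_energy_forces)
from pacsab.errors import SingularityError
from pacsab.force_field import (go_energy_force, hbond_energy_force,
                                solvation_energy_force, vdw_energy_force)


@pytest.fixture(scope="module")
def params():
    return preset("default")


class TestPairWeights:
    def test_short_plateau(self, params):
        assert pair_weights(3, 5, 0, 0, params) == \
            (params.w_vdw_short, params.w_solv_short)

    def test_intermolecular_uses_long_range(self, params):
        assert pair_weights(0, 0, 0, 1, params) == \
            (params.w_vdw_long, params.w_solv_long)

    def test_linear_midpoint(self, params):
        mid = (params.delta_short + params.delta_long) // 2
        wv, ws = pair_weights(0, mid, 0, 0, params)
        assert wv == pytest.approx((params.w_vdw_short + params.w_vdw_long) / 2)
        assert ws == pytest.approx((params.w_solv_short + params.w_solv_long) / 2)

    def test_long_plateau(self, params):
        assert pair_weights(0, params.delta_long + 5, 0, 0, params) == \
            (params.w_vdw_long, params.w_solv_long)


class TestVdw:
    def test_minimum_at_2_1_6_sigma(self, params):
        sig, epsv = 3.0, 0.2
        rmin = 2.0 ** (1.0 / 6.0) * sig
        e, de = vdw_energy_force(rmin, sig, epsv, params)
        qc6 = (sig / params.cutoff) ** 6
        shift = 4.0 * epsv * (qc6 * qc6 - qc6)
        assert e == pytest.approx(-epsv - shift, rel=1e-12)
        assert de == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_cutoff(self, params):
        e, de = vdw_energy_force(params.cutoff, 3.0, 0.2, params)
        assert e == 0.0 and de == 0.0

    def test_force_matches_finite_difference(self, params, rng):
        h = 1e-6
        for _ in range(20):
            r = rng.uniform(2.5, params.cutoff - 0.05)
            e, de = vdw_energy_force(r, 3.1, 0.17, params)
            ep, _ = vdw_energy_force(r + h, 3.1, 0.17, params)
            em, _ = vdw_energy_force(r - h, 3.1, 0.17, params)
            fd = (ep - em) / (2 * h)
            assert de == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestSolvation:
    def test_zero_beyond_cutoff(self, params):
        e, de = solvation_energy_force(params.cutoff + 0.1, 3.0, 0.5, 0.5, params)
        assert e == 0.0 and de == 0.0

    def test_hydrophobic_pair_monotonic_attraction(self, params):
        grid = np.linspace(params.cutoff - 1e-6, 3.0, 200)
        vals = [solvation_energy_force(r, 3.0, 0.5, 0.6, params)[0] for r in grid]
        diffs = np.diff(vals)
        assert vals[-1] < vals[0] <= 0.0
        assert (diffs <= 1e-12).all()  # decreases as r decreases

    def test_hydrophilic_burial_penalised(self, params):
        e, _ = solvation_energy_force(3.5, 3.0, -0.4, -0.3, params)
        assert e > 0.0

    def test_force_matches_finite_difference(self, params, rng):
        h = 1e-6
        for _ in range(20):
            r = rng.uniform(3.05, params.cutoff - 0.05)
            e, de = solvation_energy_force(r, 3.0, 0.4, -0.2, params)
            ep, _ = solvation_energy_force(r + h, 3.0, 0.4, -0.2, params)
            em, _ = solvation_energy_force(r - h, 3.0, 0.4, -0.2, params)
            assert de == pytest.approx((ep - em) / (2 * h), rel=1e-6, abs=1e-9)


class TestHbond:
    def ideal_geometry(self, params, r=None, theta_deg=180.0):
        r = params.hb_r0 if r is None else r
        h = np.zeros(3)
        n = np.array([-1.01, 0.0, 0.0])
        # theta is the N-H-O angle at H; N sits along -x
        ang = np.deg2rad(theta_deg)
        o = r * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
        return n, h, o

    def test_ideal_geometry_gives_minus_eps(self, params):
        n, h, o = self.ideal_geometry(params)
        e, _ = hbond_energy_force(n, h, o, params)
        assert e == pytest.approx(-params.eps_hb, rel=1e-12)

    def test_right_angle_gives_zero(self, params):
        n, h, o = self.ideal_geometry(params, theta_deg=90.0)
        e, f = hbond_energy_force(n, h, o, params)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_helix_i_i4_pairs_are_strong(self, params, helix10):
        for i in range(2, 5):
            o = helix10.coords[helix10.atom_index(i, "O")]
            nn = helix10.coords[helix10.atom_index(i + 4, "N")]
            hh = helix10.coords[helix10.atom_index(i + 4, "H")]
            e, _ = hbond_energy_force(nn, hh, o, params)
            assert e < -0.5 * params.eps_hb

    def test_forces_match_finite_difference(self, params, rng):
        h = 1e-6
        for _ in range(10):
            pts = [np.array([-1.0, 0.1, 0]) + rng.normal(scale=0.05, size=3),
                   np.zeros(3),
                   np.array([1.2, 0.9, 0.3]) + rng.normal(scale=0.2, size=3)]
            e0, f = hbond_energy_force(*pts, params)
            for a in range(3):
                for d in range(3):
                    pp = [p.copy() for p in pts]
                    pm = [p.copy() for p in pts]
                    pp[a][d] += h
                    pm[a][d] -= h
                    fd = -(hbond_energy_force(*pp, params)[0]
                           - hbond_energy_force(*pm, params)[0]) / (2 * h)
                    assert f[a][d] == pytest.approx(fd, rel=2e-5, abs=1e-7)


class TestGo:
    def test_all_contacts_at_r0(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0], [0, 7.0, 0], [6.0, 7.0, 0]])
        pairs = [(0, 1), (2, 3)]
        r0 = [6.0, 6.0]
        e, f = go_energy_force(coords, pairs, r0, eps_go=1.3)
        assert e == pytest.approx(-1.3 * 2, rel=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_stretched_contact_nearly_free(self):
        coords = np.array([[0.0, 0, 0], [18.0, 0, 0]])
        e, _ = go_energy_force(coords, [(0, 1)], [6.0], eps_go=1.0)
        assert abs(e) < 0.05

    def test_forces_vanish_at_native_structure(self, helix10, params):
        from pacsab import extract_native_contacts
        from pacsab.model_builder import apply_native_contacts

        m = apply_native_contacts(build_pacsab_model(helix10),
                                  extract_native_contacts(helix10))
        e, f = go_energy_force(m.coords, m.go_pairs, m.go_r0, params.eps_go,
                               m.go_weight)
        # r0 is measured from this structure, so it is the term's minimum
        assert e == pytest.approx(-params.eps_go * len(m.go_pairs), rel=1e-9)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)


class TestTotal:
    def test_isolated_particles_have_zero_nonbonded(self, params):
        m = build_pacsab_model(make_polypeptide("A", "extended")).with_box(500.0)
        rep = total_energy_forces(m, params)
        # a single tiny residue: all pairs are bonded-excluded or 1-4;
        # move instead two single-residue copies far apart
        from pacsab import replicate_with_offset

        sys2 = replicate_with_offset(m, offset=(200.0, 0, 0), L=500.0)
        rep = total_energy_forces(sys2, params)
        rep1 = total_energy_forces(m, params)
        assert rep.vdw == pytest.approx(2 * rep1.vdw, abs=1e-12)
        assert rep.solvation == pytest.approx(2 * rep1.solvation, abs=1e-12)

    def test_omega_linearity(self, small_coil_model, params):
        rep1 = total_energy_forces(small_coil_model, params)
        alpha = 1.7
        scaled = params.replace(w_vdw_short=params.w_vdw_short * alpha,
                                w_vdw_long=params.w_vdw_long * alpha)
        rep2 = total_energy_forces(small_coil_model, scaled)
        assert rep2.vdw == pytest.approx(alpha * rep1.vdw, rel=1e-12)
        assert rep2.solvation == pytest.approx(rep1.solvation, rel=1e-12)
        assert rep2.hbond == pytest.approx(rep1.hbond, rel=1e-12)
        beta = 0.31
        scaled = params.replace(w_solv_short=params.w_solv_short * beta,
                                w_solv_long=params.w_solv_long * beta)
        rep3 = total_energy_forces(small_coil_model, scaled)
        assert rep3.solvation == pytest.approx(beta * rep1.solvation, rel=1e-12)
        assert rep3.vdw == pytest.approx(rep1.vdw, rel=1e-12)

    def test_full_force_finite_difference(self, small_coil_model, params, rng):
        m = small_coil_model
        pos0 = m.coords + rng.normal(scale=0.1, size=m.coords.shape)
        rep = total_energy_forces(m, params, coords=pos0)
        scale = np.abs(rep.forces).max()
        h = 1e-5
        for i in range(m.n_particles):
            for d in range(3):
                pp = pos0.copy()
                pm = pos0.copy()
                pp[i, d] += h
                pm[i, d] -= h
                fd = -(total_energy_forces(m, params, coords=pp).total
                       - total_energy_forces(m, params, coords=pm).total) / (2 * h)
                assert abs(fd - rep.forces[i, d]) <= 1e-5 * scale

    def test_rigid_motion_invariance(self, small_coil_model, params):
        from scipy.spatial.transform import Rotation

        m = small_coil_model
        rep0 = total_energy_forces(m, params)
        rot = Rotation.from_euler("xyz", [20, -35, 70], degrees=True)
        moved = rot.apply(m.coords - m.coords.mean(axis=0)) \
            + m.coords.mean(axis=0) + np.array([3.0, -2.0, 5.0])
        rep1 = total_energy_forces(m, params, coords=moved)
        assert abs(rep1.total - rep0.total) <= 1e-9
        assert np.abs(rep1.forces.sum(axis=0)).max() <= 1e-8  # net force
        torque = np.cross(moved - moved.mean(axis=0), rep1.forces).sum(axis=0)
        assert np.abs(torque).max() <= 1e-8

    def test_decomposition_sums_to_total(self, small_coil_model, params):
        rep = total_energy_forces(small_coil_model, params)
        s = rep.bonded + rep.vdw + rep.solvation + rep.hbond + rep.go
        assert rep.total == pytest.approx(s, rel=1e-10)

    def test_overlap_raises_singularity(self, two_copy_system, params):
        bad = two_copy_system.coords.copy()
        n = two_copy_system.n_particles // 2
        bad[n] = bad[0] + 1e-3
        with pytest.raises(SingularityError):
            total_energy_forces(two_copy_system, params, coords=bad)


class TestPresets:
    def test_server_2024_is_3pct_less_vdw(self):
        d = preset("default")
        s = preset("server_2024")
        assert s.w_vdw_long / d.w_vdw_long == pytest.approx(0.97, rel=1e-12)
        assert s.w_vdw_short / d.w_vdw_short == pytest.approx(0.97, rel=1e-12)
        assert s.w_solv_long == d.w_solv_long

    def test_unfolding_is_hydrophilic_and_weak_hb(self):
        d = preset("default")
        u = preset("unfolding")
        assert u.eps_hb < d.eps_hb
        assert u.w_vdw_long < d.w_vdw_long
        assert u.w_solv_long > d.w_solv_long

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="default"):
            preset("nonsense")

    def test_param_file_round_trip(self, tmp_path):
        p = preset("unfolding").replace(cutoff=9.5)
        path = tmp_path / "ff.txt"
        p.save(path)
        assert ForceFieldParams.load(path) == p

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(w_vdw_short=-1.0)
        with pytest.raises(ValueError):
            ForceFieldParams(delta_short=8, delta_long=8)
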