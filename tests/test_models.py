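import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucsas as ns
from nucsas.models import CoreShellCylinderParams


Q = np.geomspace(0.01, 0.3, 40)


class TestCoreShellCylinder:
    PARAMS = CoreShellCylinderParams(19.0, 23.0, 60.0, 2.3, 3.4, -0.56)

    def test_matches_high_order_quadrature_oracle(self):
        i_std = ns.core_shell_cylinder_intensity(self.PARAMS, Q, n_quad=76)
        i_ref = ns.core_shell_cylinder_intensity(self.PARAMS, Q, n_quad=760)
        assert np.max(np.abs(i_std / i_ref - 1.0)) < 1e-4

    def test_equal_slds_reduce_to_uniform_cylinder(self):
        p = CoreShellCylinderParams(19.0, 23.0, 60.0, 3.4, 3.4, -0.56)
        i_cs = ns.core_shell_cylinder_intensity(p, Q)
        # uniform cylinder of the outer dimensions via a vanishing shell
        pu = CoreShellCylinderParams(19.0 + 23.0 - 1e-9, 1e-9, 60.0 + 46.0 - 2e-9,
                                     3.4, 3.4, -0.56)
        i_u = ns.core_shell_cylinder_intensity(pu, Q)
        np.testing.assert_allclose(i_cs, i_u, rtol=1e-6)

    def test_forward_scattering_limit(self):
        p = self.PARAMS
        i0 = ns.core_shell_cylinder_intensity(p, np.array([1e-7]))[0]
        v_shell = p.v_outer - p.v_core
        expect = (p.v_core * (p.sld_core - p.sld_solvent)
                  + v_shell * (p.sld_shell - p.sld_solvent)) ** 2
        assert i0 == pytest.approx(p.scale * expect + p.background, rel=1e-8)

    def test_low_quadrature_order_rejected(self):
        with pytest.raises(ValueError):
            ns.core_shell_cylinder_intensity(self.PARAMS, Q, n_quad=8)


class TestCylinderRg:
    def test_rod_limit(self):
        p = CoreShellCylinderParams(1e-6, 1e-6, 100.0, 2.0, 2.0, 0.0)
        assert ns.cylinder_rg(p) == pytest.approx(100.0 / math.sqrt(12), rel=1e-4)

    def test_disc_limit(self):
        p = CoreShellCylinderParams(50.0, 1e-6, 1e-5, 2.0, 2.0, 0.0)
        assert ns.cylinder_rg(p) == pytest.approx(50.0 / math.sqrt(2), rel=1e-4)

    def test_two_phase_against_monte_carlo_second_moment(self):
        p = CoreShellCylinderParams(19.0, 23.0, 60.0, 2.3, 3.4, -0.56)
        rng = np.random.default_rng(12)
        n = 400_000
        r_out = p.core_radius + p.shell_thickness
        l_out = p.length + 2 * p.shell_thickness
        # sample uniformly in the outer cylinder, weight by local contrast
        r = r_out * np.sqrt(rng.random(n))
        phi = 2 * math.pi * rng.random(n)
        z = l_out * (rng.random(n) - 0.5)
        in_core = (r <= p.core_radius) & (np.abs(z) <= p.length / 2)
        w = np.where(in_core, p.sld_core - p.sld_solvent,
                     p.sld_shell - p.sld_solvent)
        d2 = r**2 + z**2
        rg_mc = math.sqrt(np.sum(w * d2) / np.sum(w))
        assert ns.cylinder_rg(p) == pytest.approx(rg_mc, rel=0.005)

    def test_zero_net_contrast_is_an_error(self):
        p = CoreShellCylinderParams(20.0, 10.0, 50.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ns.cylinder_rg(p)

    def test_reciprocity_with_guinier_of_own_curve(self):
        """cylinder_rg must agree with the Guinier Rg of the model's own
        noise-free curve within 1% (low-q window to stay in the Guinier
        regime of this anisotropic body)."""
        p = CoreShellCylinderParams(19.0, 23.0, 60.0, 2.0, 3.4, 0.0)
        q = np.geomspace(0.003, 0.05, 120)
        i = ns.core_shell_cylinder_intensity(p, q)
        prof = ns.ScatteringProfile(q, i, 0.01 * np.sqrt(i * i[0]))
        g = ns.guinier_fit(prof, qrg_max=0.8)
        assert ns.cylinder_rg(p) == pytest.approx(g.rg, rel=0.01)


class TestDebye:
    def test_single_bead_constant(self):
        bm = ns.BeadModel(np.zeros((1, 3)), np.array([3.0]),
                          np.array(["protein"]))
        np.testing.assert_allclose(ns.debye_intensity(bm, Q, method="direct"), 9.0)

    def test_two_beads_closed_form(self):
        d = 25.0
        bm = ns.BeadModel(np.array([[0, 0, 0], [0, 0, d]]),
                          np.array([2.0, 2.0]), np.array(["protein"] * 2))
        expect = 2 * 4.0 * (1 + np.sinc(Q * d / np.pi))
        np.testing.assert_allclose(ns.debye_intensity(bm, Q, method="direct"),
                                   expect, rtol=1e-12)

    def test_histogram_agrees_with_direct_on_500_random_beads(self):
        rng = np.random.default_rng(8)
        bm = ns.BeadModel(rng.uniform(-50, 50, (500, 3)),
                          rng.uniform(0.5, 2.0, 500),
                          np.array(["protein"] * 250 + ["dna"] * 250))
        i_d = ns.debye_intensity(bm, Q, method="direct")
        i_h = ns.debye_intensity(bm, Q, method="histogram", bin_width=0.25)
        assert np.max(np.abs(i_h / i_d - 1.0)) < 1e-3

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(0.1, 3.0), st.floats(-40, 40), st.floats(-40, 40),
           st.floats(-40, 40))
    def test_rigid_motion_invariance(self, angle, tx, ty, tz):
        rng = np.random.default_rng(3)
        xyz = rng.uniform(-30, 30, (60, 3))
        b = rng.uniform(0.5, 2.0, 60)
        tags = np.array(["protein"] * 60)
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        bm1 = ns.BeadModel(xyz, b, tags)
        bm2 = ns.BeadModel(xyz @ rot.T + [tx, ty, tz], b, tags)
        i1 = ns.debye_intensity(bm1, Q, method="direct")
        i2 = ns.debye_intensity(bm2, Q, method="direct")
        np.testing.assert_allclose(i1, i2, rtol=1e-9)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            ns.BeadModel(np.zeros((0, 3)), np.array([]), np.array([]))


class TestGaussianCoil:
    def test_forward_limit(self):
        i = ns.gaussian_coil_intensity(40.0, 7.0, np.array([1e-9]))
        assert i[0] == pytest.approx(7.0, rel=1e-6)

    def test_x_equal_one_closed_form(self):
        i = ns.gaussian_coil_intensity(1.0, 1.0, np.array([1.0]))
        assert i[0] == pytest.approx(2.0 / math.e, rel=1e-12)

    def test_nonpositive_rg_rejected(self):
        with pytest.raises(ValueError):
            ns.gaussian_coil_intensity(0.0, 1.0, Q)


def simulate_cv_series(true_params, rng, noise=0.03, n_q=40):
    """SAXS + 4 SANS contrasts from shared geometry (generator truth)."""
    q = np.geomspace(0.01, 0.25, n_q)
    slds = [(430.0, 527.0, 334.0),          # X-ray electron-density-like
            (1.77, 3.10, -0.56), (2.02, 3.22, 0.83),
            (2.64, 3.53, 4.29), (2.83, 3.62, 5.32)]
    series = []
    for sc, ss, sv in slds:
        from dataclasses import replace
        p = replace(true_params, sld_core=sc, sld_shell=ss, sld_solvent=sv)
        i = ns.core_shell_cylinder_intensity(p, q)
        sig = noise * np.sqrt(np.abs(i) * np.abs(i[0]))
        series.append((ns.ScatteringProfile(
            q, i + rng.normal(size=q.size) * sig, sig), sc, ss, sv))
    return series


class TestGlobalFit:
    TRUE = CoreShellCylinderParams(19.0, 23.0, 60.0, 0.0, 0.0, 0.0, scale=1e-9)
    START = CoreShellCylinderParams(25.0, 18.0, 75.0, 0.0, 0.0, 0.0)

    def test_geometry_recovered_on_noisy_series(self):
        rng = np.random.default_rng(17)
        series = simulate_cv_series(self.TRUE, rng)
        fit = ns.global_cv_fit(series, self.START, seed=1, n_starts=2)
        for name, truth in (("core_radius", 19.0), ("shell_thickness", 23.0),
                            ("length", 60.0)):
            got = getattr(fit.params, name)
            sig = max(fit.uncertainties[name], 1e-6)
            assert abs(got - truth) < max(3 * sig, 0.05 * truth), name

    def test_fixing_shell_reduces_recovery_variance(self):
        """Recovery spread of core_radius/length must shrink when the
        shell thickness is fixed at truth (information argument)."""
        free_r, fixed_r = [], []
        for k in range(8):
            rng = np.random.default_rng(100 + k)
            series = simulate_cv_series(self.TRUE, rng, noise=0.05)
            f_all = ns.global_cv_fit(series, self.START, seed=k, n_starts=1)
            f_fix = ns.global_cv_fit(
                series, ns.CoreShellCylinderParams(
                    25.0, 23.0, 75.0, 0.0, 0.0, 0.0),
                fixed={"shell_thickness"}, seed=k, n_starts=1)
            free_r.append((f_all.params.core_radius, f_all.params.length))
            fixed_r.append((f_fix.params.core_radius, f_fix.params.length))
        var_free = np.var(np.array(free_r), axis=0)
        var_fixed = np.var(np.array(fixed_r), axis=0)
        assert np.all(var_fixed < var_free)

    def test_single_noise_free_curve_all_free_is_flagged(self):
        rng = np.random.default_rng(2)
        series = simulate_cv_series(self.TRUE, rng, noise=1e-6)[:1]
        fit = ns.global_cv_fit(series, self.START, seed=0, n_starts=1)
        assert fit.degenerate

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ns.global_cv_fit([], self.START)


class TestBeadPdbIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        bm = ns.BeadModel(rng.uniform(-40, 40, (20, 3)).round(3),
                          rng.uniform(0.5, 9.9, 20).round(2),
                          np.array(["protein"] * 12 + ["dna"] * 8))
        path = tmp_path / "beads.pdb"
        ns.write_bead_pdb(bm, path)
        back = ns.read_bead_pdb(path)
        np.testing.assert_allclose(back.xyz, bm.xyz, atol=1e-3)
        np.testing.assert_allclose(back.b, bm.b, atol=1e-2)
        assert list(back.tags) == list(bm.tags)
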