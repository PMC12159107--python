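import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucsas as ns
from conftest import sphere_intensity, sphere_pr_mc


class TestGuinier:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(rg=st.floats(10.0, 120.0), i0=st.floats(0.01, 1e3))
    def test_exact_guinier_law_recovered_to_machine_precision(self, rg, i0):
        q = np.geomspace(0.005, 1.0 / rg, 60)
        i = i0 * np.exp(-((q * rg) ** 2) / 3.0)
        prof = ns.ScatteringProfile(q, i, 1e-6 * i)
        g = ns.guinier_fit(prof)
        assert g.rg == pytest.approx(rg, rel=1e-9)
        assert g.i0 == pytest.approx(i0, rel=1e-9)

    def test_sphere_rg_within_known_window_bias(self, sphere_profile):
        """Guinier on a hard sphere at qRg <= 1.2 carries a ~1.7% positive
        bias from the quartic term in ln I; assert recovery within 2%."""
        prof, R = sphere_profile
        g = ns.guinier_fit(prof)
        assert g.rg == pytest.approx(math.sqrt(3.0 / 5.0) * R, rel=0.02)
        assert g.qrg_window[1] <= 1.2 * 1.02

    def test_qrg_window_reported(self, sphere_profile):
        prof, _ = sphere_profile
        g = ns.guinier_fit(prof, qrg_max=1.0)
        assert g.qrg_window[1] <= 1.0 * 1.02
        assert g.n_points >= 3

    def test_truncated_curve_raises(self):
        rg = 40.0
        q = np.linspace(1.5 / rg, 3.0 / rg, 30)  # no points below qRg=1.2
        i = np.exp(-((q * rg) ** 2) / 3.0)
        with pytest.raises(ValueError):
            ns.guinier_fit(ns.ScatteringProfile(q, i, 0.01 * i))


class TestIft:
    def test_sphere_pr_matches_mc_oracle_within_2pct(self, sphere_profile):
        prof, R = sphere_profile
        res = ns.ift_pr(prof, 2 * R)
        centers, p_true = sphere_pr_mc(R)
        p_est = np.interp(centers, res.r, res.p)
        p_est /= np.trapezoid(p_est, centers)
        nrms = np.sqrt(np.mean((p_est - p_true) ** 2)) / p_true.max()
        assert nrms < 0.02

    def test_forward_transform_self_consistency(self, sphere_profile,
                                                noisy_sphere_profile):
        # noise-free input: the forward transform must sit far inside sigma
        prof, R = sphere_profile
        res = ns.ift_pr(prof, 2 * R)
        fwd = res.forward(prof.q)
        assert np.mean(np.abs(fwd - prof.intensity) <= 1.5 * prof.sigma) >= 0.95
        # noisy input: residuals are the noise itself, so the right check
        # is a reduced chi^2 near 1, not a 1.5-sigma point count
        nprof, R = noisy_sphere_profile
        nres = ns.ift_pr(nprof, 2 * R)
        assert 0.5 < nres.chi2_reduced < 1.5

    def test_rg_and_i0_from_moments(self, sphere_profile):
        prof, R = sphere_profile
        res = ns.ift_pr(prof, 2 * R)
        assert res.rg_real == pytest.approx(math.sqrt(0.6) * R, rel=0.01)
        assert res.i0_real == pytest.approx(541.0, rel=0.02)

    def test_half_dmax_degrades_quality_with_structured_residuals(
            self, noisy_sphere_profile):
        prof, R = noisy_sphere_profile
        good = ns.ift_pr(prof, 2 * R)
        bad = ns.ift_pr(prof, R)
        assert bad.quality < 0.5 * good.quality
        assert bad.chi2_reduced > 5 * good.chi2_reduced

    def test_infeasible_dmax_flagged(self, sphere_profile):
        prof, _ = sphere_profile
        res = ns.ift_pr(prof, 0.5 * math.pi / prof.q[0])
        assert res.feasibility_warning

    def test_boundary_conditions_enforced(self, sphere_profile):
        prof, R = sphere_profile
        res = ns.ift_pr(prof, 2 * R)
        assert res.p[0] == 0.0 and res.p[-1] == 0.0

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        i = np.exp(-((q * 40) ** 2) / 3)
        with pytest.raises(ValueError):
            ns.ift_pr(ns.ScatteringProfile(q, i, 0.01 * i), 100.0)


class TestDmaxScan:
    def test_sphere_scan_recommends_true_diameter(self, noisy_sphere_profile):
        prof, R = noisy_sphere_profile
        tab = ns.dmax_scan(prof, (R, 4 * R), steps=13)
        assert tab.attrs["recommended_dmax"] == pytest.approx(2 * R, rel=0.10)

    def test_plateau_tie_breaks_to_smallest(self):
        # quality is monotone-ish flat above the true dmax: the smallest
        # candidate within 2% of the max must be chosen
        prof_q = np.geomspace(0.009, 0.3, 120)
        i = sphere_intensity(prof_q, 40.0)
        prof = ns.ScatteringProfile(prof_q, i, 0.01 * np.sqrt(i * i[0]))
        tab = ns.dmax_scan(prof, (80.0, 160.0), steps=9)
        ok = tab[tab["quality"] >= 0.98 * tab["quality"].max()]
        assert tab.attrs["recommended_dmax"] == ok["dmax"].iloc[0]

    def test_degenerate_inputs_rejected(self, sphere_profile):
        prof, _ = sphere_profile
        with pytest.raises(ValueError):
            ns.dmax_scan(prof, (100.0, 120.0), steps=1)
        with pytest.raises(ValueError):
            ns.dmax_scan(prof, (120.0, 100.0), steps=5)


class TestKratky:
    def test_guinier_law_peak_at_sqrt3(self):
        q = np.linspace(1e-4, 0.12, 3000)[1:]
        rg = 41.9
        i = np.exp(-((q * rg) ** 2) / 3.0)
        prof = ns.ScatteringProfile(q, i, np.full(q.size, 1e-6))
        g = ns.GuinierResult(rg, 0, 1.0, 0, (0, 0), (0, 0), 0, 1, np.array([]))
        k = ns.kratky_transform(prof, "normalized", g)
        assert k.peak_x == pytest.approx(math.sqrt(3.0), abs=1e-3)
        assert k.peak_y == pytest.approx(3.0 / math.e, abs=1e-3)

    def test_sphere_peak_near_compact_reference(self):
        """Analytic sphere: dimensionless Kratky peak at x*sqrt(3/5) with
        x the root of x^2 sin x + 2x cos x - 2 sin x, i.e. qRg ~ 1.61,
        in the ~1.7 region characteristic of compact particles."""
        R = 54.0
        q = np.linspace(1e-4, 0.12, 4000)[1:]
        prof = ns.ScatteringProfile(q, sphere_intensity(q, R),
                                    np.full(q.size, 1e-6))
        rg = math.sqrt(0.6) * R
        g = ns.GuinierResult(rg, 0, 1.0, 0, (0, 0), (0, 0), 0, 1, np.array([]))
        k = ns.kratky_transform(prof, "normalized", g)
        assert k.peak_x == pytest.approx(1.612, abs=0.01)

    def test_constant_intensity_has_no_interior_maximum(self):
        q = np.linspace(0.01, 0.3, 100)
        prof = ns.ScatteringProfile(q, np.ones(q.size), np.full(q.size, 0.01))
        k = ns.kratky_transform(prof, "standard")
        assert k.peak_x is None
        assert np.all(np.diff(k.y) > 0)

    def test_normalized_mode_requires_guinier(self, sphere_profile):
        with pytest.raises(ValueError):
            ns.kratky_transform(sphere_profile[0], "normalized")

    def test_coil_plateaus_without_return_to_baseline(self):
        q = np.geomspace(0.001, 0.5, 400)
        rg = 144.0
        i = ns.gaussian_coil_intensity(rg, 1.0, q)
        prof = ns.ScatteringProfile(q, i, np.full(q.size, 1e-6))
        g = ns.GuinierResult(rg, 0, 1.0, 0, (0, 0), (0, 0), 0, 1, np.array([]))
        k = ns.kratky_transform(prof, "normalized", g)
        assert k.peak_x is None           # monotone rise to the plateau
        assert k.y[-1] > 1.8              # ~2 asymptote, no decay


class TestPrDifference:
    def test_identical_inputs_give_zero(self, sphere_profile):
        prof, R = sphere_profile
        a = ns.ift_pr(prof, 2 * R)
        r, d = ns.pr_difference(a, a)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_unit_area_difference_integrates_to_zero(self, sphere_profile):
        prof, R = sphere_profile
        a = ns.ift_pr(prof, 2 * R)
        q = prof.q
        rod = ns.ScatteringProfile(q, ns.gaussian_coil_intensity(
            math.sqrt(0.6) * R, 541.0, q), prof.sigma)
        b = ns.ift_pr(rod, 3.5 * R)
        r, d = ns.pr_difference(a, b, normalization="unit-area")
        assert np.sum(np.gradient(r) * d) == pytest.approx(0.0, abs=1e-9)

    def test_unwrapping_shifts_mass_to_large_r(self):
        """Compact vs end-unwrapped synthetic nucleosome: the difference
        (unwrapped - native) must be positive at large r."""
        q = ns.default_q_grid(80)
        native = ns.build_nucleosome_beads(ns.NucleosomeGeometry())
        unwrapped = ns.build_nucleosome_beads(
            ns.NucleosomeGeometry(unwrap_bp_each_end=25))
        w = {"protein": 1.0, "dna": 3.0}
        profs = []
        for bm in (unwrapped, native):
            i = ns.debye_intensity(bm, q, contrast_per_tag=w)
            profs.append(ns.ScatteringProfile(q, i, 0.01 * np.sqrt(i * i[0])))
        pa = ns.ift_pr(profs[0], 220.0)
        pb = ns.ift_pr(profs[1], 115.0)
        r, d = ns.pr_difference(pa, pb, normalization="unit-area")
        tail = r > 100.0
        assert np.sum(np.gradient(r)[tail] * d[tail]) > 0


class TestReferenceGeometry:
    def test_147bp_rod_matches_flory_reference(self):
        L, rg, dmax = ns.rigid_rod_metrics(147)
        assert L == pytest.approx(500, abs=1)
        assert rg == pytest.approx(144, abs=1)
        assert dmax == L

    def test_single_bp_closed_form(self):
        L, rg, dmax = ns.rigid_rod_metrics(1)
        assert L == pytest.approx(3.4)
        assert rg == pytest.approx(3.4 / math.sqrt(12))

    def test_zero_bp_rejected(self):
        with pytest.raises(ValueError):
            ns.rigid_rod_metrics(0)

    def test_stokes_einstein_inversion(self):
        kb = 1.380649e-16
        T, eta, rh = 298.15, 0.0089, 50.0e-8  # cm
        d = kb * T / (6 * math.pi * eta * rh)
        assert ns.stokes_einstein_radius(d, T, eta) == pytest.approx(50.0, rel=1e-9)
        # R_h = kT/(6 pi eta D): at fixed D, doubling eta halves R_h
        assert ns.stokes_einstein_radius(d, T, 2 * eta) == pytest.approx(
            25.0, rel=1e-9)

    def test_stokes_einstein_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ns.stokes_einstein_radius(1e-7, 298.0, 0.0)

    @pytest.mark.parametrize(
        "rpm,rm,rb,rho",
        [(40000, 6.0, 7.2, 1.0), (26000, 6.9, 7.2, 1.01)],
    )
    def test_auc_pressure_matches_numeric_integral(self, rpm, rm, rb, rho):
        omega = 2 * math.pi * rpm / 60.0
        r = np.linspace(rm, rb, 20001) * 1e-2
        p_pa = np.trapezoid(rho * 1000.0 * omega**2 * r, r)
        expected = 0.1013 + p_pa / 1e6
        got = ns.auc_cell_pressure(rpm, rm, rb, rho)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_auc_pressure_at_rest_is_ambient(self):
        assert ns.auc_cell_pressure(0, 6.0, 7.2) == pytest.approx(0.1013)

    def test_auc_geometry_must_be_ordered(self):
        with pytest.raises(ValueError):
            ns.auc_cell_pressure(40000, 7.2, 6.0)


class TestAnalyzeSeries:
    def test_identical_return_profile_has_zero_hysteresis(self):
        q = np.geomspace(0.009, 0.3, 100)
        i = sphere_intensity(q, 54.0, 541.0)
        s = 0.01 * np.sqrt(i * i[0])
        a = ns.ScatteringProfile(q, i, s, {"pressure": 5.0, "label": "base"})
        b = ns.ScatteringProfile(q, i, s, {"pressure": 5.0, "label": "return"})
        summ = ns.analyze_series([a, b], baseline_label="base")
        assert len(summ.hysteresis) == 1
        assert summ.hysteresis["delta_rg"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ns.analyze_series([])

    def test_monotone_unwrapping_gives_nondecreasing_rg(self):
        """Generator-truth ordering: a monotone native->extended schedule
        must produce a non-decreasing recovered Rg sequence."""
        maps = [{"native": 1.0},
                {"native": 0.8, "unwrapped": 0.2},
                {"native": 0.4, "unwrapped": 0.5, "extended": 0.1},
                {"unwrapped": 0.7, "extended": 0.3}]
        profs, man = ns.simulate_pressure_series(
            pressures=(5.0, 100.0, 200.0, 300.0), state_maps=maps, seed=9)
        summ = ns.analyze_series(profs)
        rg = summ.table["rg_guinier"].to_numpy()
        sig = summ.table["rg_guinier_sigma"].to_numpy()
        assert np.all(np.diff(rg) > -3 * np.hypot(sig[:-1], sig[1:]))
        assert rg[-1] > rg[0]
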