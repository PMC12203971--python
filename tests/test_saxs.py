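"""Debye scattering, Guinier/Kratky/p(r)/fractal analysis, chi-square fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sahens.forward import (
    SAXSCurve,
    chi2_fit,
    debye_curve,
    debye_from_distances,
    dimensionless_kratky,
    ensemble_metrics,
    fractal_fit,
    guinier_fit,
    pr_from_coords,
    radius_of_gyration,
)

S = np.linspace(0.05, 3.0, 150)


def sphere_curve(R=3.0, s=None):
    s = S if s is None else s
    sr = s * R
    F = 3.0 * (np.sin(sr) - sr * np.cos(sr)) / sr ** 3
    return SAXSCurve(s, F ** 2)


class TestDebye:
    def test_two_scatterers_closed_form(self):
        d = 1.3
        curve = debye_curve(None, S, coords=np.array([[0, 0, 0], [0, 0, d]]))
        np.testing.assert_allclose(curve.I, 2 + 2 * np.sin(S * d) / (S * d))

    def test_forward_intensity_is_squared_total_factor(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(15, 3))
        f = rng.uniform(1, 8, 15)
        curve = debye_curve(None, np.array([0.0, 0.5]), coords=coords, f=f)
        assert curve.I[0] == pytest.approx(np.sum(f) ** 2, rel=1e-12)

    def test_matches_brute_force_double_loop(self):
        """Vectorized Debye equals the naive O(n^2) double sum."""
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=1.5, size=(20, 3))
        f = rng.uniform(1, 8, 20)
        curve = debye_curve(None, S, coords=coords, f=f)
        brute = np.zeros_like(S)
        for k, s in enumerate(S):
            total = 0.0
            for i in range(20):
                for j in range(20):
                    r = np.linalg.norm(coords[i] - coords[j])
                    x = s * r
                    total += f[i] * f[j] * (np.sin(x) / x if x > 0 else 1.0)
            brute[k] = total
        np.testing.assert_allclose(curve.I, brute, rtol=1e-10)

    def test_ensemble_curve_is_member_mean(self, tiny_pool):
        sub = tiny_pool.subset([0, 1, 2])
        ens_curve = debye_curve(sub, S[:30])
        members = np.stack([debye_curve(c, S[:30]).I for c in sub])
        np.testing.assert_allclose(ens_curve.I, members.mean(axis=0))

    def test_binned_distance_route_approximates_exact(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=2.0, size=(60, 3))
        exact = debye_curve(None, S, coords=coords)
        from scipy.spatial.distance import pdist
        r = pdist(coords)
        hist, edges = np.histogram(r, bins=2000)
        centers = 0.5 * (edges[:-1] + edges[1:])
        approx = debye_from_distances(S, centers, hist)
        np.testing.assert_allclose(60 + 2 * approx.I, exact.I, rtol=2e-3)


class TestGuinier:
    def test_exact_guinier_curve_inverts(self):
        rg = 3.0
        curve = SAXSCurve(S, 7.5 * np.exp(-(S * rg) ** 2 / 3.0))
        g = guinier_fit(curve)
        assert g.rg == pytest.approx(rg, rel=1e-3)
        assert g.i0 == pytest.approx(7.5, rel=1e-3)
        assert np.all(curve.s[g.window[0]:g.window[1] + 1] * g.rg < 1.2 + 1e-9)

    def test_sphere_gives_sqrt_three_fifths_radius(self):
        R = 3.0
        s = np.linspace(0.01, 2.0, 300)
        g = guinier_fit(sphere_curve(R, s))
        assert g.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.02)

    def test_noisy_sphere_within_five_percent(self):
        R = 3.0
        s = np.linspace(0.01, 2.0, 300)
        curve = sphere_curve(R, s)
        rng = np.random.default_rng(11)
        noisy = SAXSCurve(s, curve.I * (1 + rng.normal(0, 0.01, len(s))))
        g = guinier_fit(noisy)
        assert g.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.05)

    def test_no_guinier_regime_rejected(self):
        rising = SAXSCurve(S, 1.0 + S ** 2)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(rising)


class TestKratky:
    def test_ideal_curve_peaks_at_sqrt3_and_3_over_e(self):
        rg = 2.0
        s = np.linspace(0.01, 2.5, 2000)
        curve = SAXSCurve(s, np.exp(-(s * rg) ** 2 / 3.0))
        g = guinier_fit(curve)
        x, y = dimensionless_kratky(curve, g)
        assert x[np.argmax(y)] == pytest.approx(np.sqrt(3.0), abs=0.02)
        assert y.max() == pytest.approx(3.0 / np.e, abs=0.005)

    def test_rod_transform_increases_at_high_srg(self):
        """A thin rod's dimensionless Kratky transform keeps rising over
        sRg in [2, 8], the extended-structure signature."""
        line = np.zeros((150, 3))
        line[:, 2] = np.linspace(0, 12.0, 150)
        s = np.linspace(0.02, 3.0, 400)
        curve = debye_curve(None, s, coords=line)
        g = guinier_fit(curve)
        x, y = dimensionless_kratky(curve, g)
        sel = (x >= 2.0) & (x <= 8.0)
        xs, ys = x[sel], y[sel]
        # increasing trend: positive slope and last > first
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope > 0
        assert ys[-1] > ys[0]

    def test_globular_sphere_is_bell_shaped(self):
        s = np.linspace(0.01, 3.0, 500)
        curve = sphere_curve(3.0, s)
        g = guinier_fit(curve)
        x, y = dimensionless_kratky(curve, g)
        peak = np.argmax(y[x < 4])
        assert 1.0 < x[peak] < 2.5      # bell-shaped maximum
        assert y[x < 4][peak] > y[(x > 3) & (x < 4)].mean()


class TestFractal:
    @pytest.mark.parametrize("dm", [0.5, 1.0, 1.36, 2.0, 4.0])
    def test_exact_on_pure_power_laws(self, dm):
        curve = SAXSCurve(S, S ** -dm)
        fit = fractal_fit(curve)
        assert fit.dm == pytest.approx(dm, abs=1e-12)
        assert fit.flory_nu * fit.dm == pytest.approx(1.0, abs=1e-12)

    def test_thin_rod_approaches_one(self):
        line = np.zeros((200, 3))
        line[:, 2] = np.linspace(0, 30.0, 200)
        curve = debye_curve(None, np.linspace(0.1, 3.0, 200), coords=line)
        assert fractal_fit(curve).dm == pytest.approx(1.0, abs=0.1)

    def test_random_walk_chains_approach_two(self):
        """Ensemble-averaged freely-jointed chains scatter with Dm ~ 2."""
        rng = np.random.default_rng(2024)
        s = np.linspace(0.3, 2.0, 60)
        from scipy.spatial.distance import pdist
        bins = np.linspace(0, 120.0, 3000)
        centers = 0.5 * (bins[:-1] + bins[1:])
        acc = np.zeros(len(centers))
        n_chains, n_seg, bond = 60, 800, 0.38
        for _ in range(n_chains):
            steps = rng.normal(size=(n_seg, 3))
            steps /= np.linalg.norm(steps, axis=1)[:, None]
            chain = np.cumsum(steps * bond, axis=0)
            acc += np.histogram(pdist(chain), bins=bins)[0]
        curve = debye_from_distances(s, centers, acc)
        curve = SAXSCurve(s, curve.I + n_chains * n_seg / 2)  # self terms
        fit = fractal_fit(curve, s_range=(0.5, 1.5))
        assert fit.dm == pytest.approx(2.0, abs=0.2)

    def test_too_few_points_rejected(self):
        curve = SAXSCurve(np.array([0.6, 0.7, 0.8]), np.array([1.0, 0.9, 0.8]))
        with pytest.raises(ValueError):
            fractal_fit(curve)


class TestChi2:
    def test_doubled_model_fits_exactly(self):
        curve = sphere_curve()
        data = SAXSCurve(S, 2 * curve.I, sigma=0.1 * curve.I + 1e-6)
        fit = chi2_fit(curve, data)
        assert fit.scale == pytest.approx(2.0, rel=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_matched_noise_gives_unit_chi2(self):
        curve = sphere_curve()
        sig = 0.05 * curve.I
        rng = np.random.default_rng(4)
        chis = []
        for _ in range(10):
            data = SAXSCurve(S, curve.I + rng.normal(0, sig), sigma=sig)
            chis.append(chi2_fit(curve, data).chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.3)

    def test_wrong_shape_is_strongly_rejected(self):
        line = np.zeros((100, 3))
        line[:, 2] = np.linspace(0, 15, 100)
        rod = debye_curve(None, S, coords=line)
        rod = SAXSCurve(S, rod.I / rod.I[0])
        glob = sphere_curve(2.0)
        data = SAXSCurve(S, rod.I, sigma=0.02 * rod.I)
        assert chi2_fit(glob, data).chi2 > 3.0

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_joint_rescaling(self, a, b):
        curve = sphere_curve()
        sig = 0.05 * curve.I
        rng = np.random.default_rng(0)
        data_I = curve.I + rng.normal(0, sig)
        base = chi2_fit(SAXSCurve(S, a * curve.I),
                        SAXSCurve(S, b * data_I, sigma=b * sig))
        ref = chi2_fit(curve, SAXSCurve(S, data_I, sigma=sig))
        assert base.chi2 == pytest.approx(ref.chi2, rel=1e-9)

    def test_nonpositive_sigma_rejected(self):
        curve = sphere_curve()
        with pytest.raises(ValueError):
            chi2_fit(curve, SAXSCurve(S, curve.I))


class TestPofR:
    def test_two_points_single_bin(self):
        p = pr_from_coords(None, bin_width=0.1,
                           coords=np.array([[0, 0, 0], [0, 0, 1.0]]))
        assert p.dmax == pytest.approx(1.0)
        occupied = p.r[p.p > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(1.05, abs=0.051)

    def test_three_collinear_points_weighting(self):
        coords = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        p = pr_from_coords(None, bin_width=0.2, coords=coords)
        w1 = p.p[(p.r > 0.8) & (p.r < 1.2)].sum()
        w2 = p.p[(p.r > 1.8) & (p.r < 2.2)].sum()
        assert w1 == pytest.approx(2.0)
        assert w2 == pytest.approx(1.0)

    def test_histogram_matches_brute_force(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(scale=1.2, size=(50, 3))
        p = pr_from_coords(None, bin_width=0.05, coords=coords)
        dists = [np.linalg.norm(coords[i] - coords[j])
                 for i in range(50) for j in range(i + 1, 50)]
        brute, _ = np.histogram(dists, bins=len(p.r),
                                range=(0, len(p.r) * 0.05))
        np.testing.assert_allclose(p.p, brute)
        assert p.dmax == pytest.approx(max(dists))

    def test_ensemble_dmax_is_member_maximum(self, tiny_pool):
        sub = tiny_pool.subset([0, 5, 11])
        p_ens = pr_from_coords(sub)
        singles = [pr_from_coords(c) for c in sub]
        assert p_ens.dmax == pytest.approx(max(s.dmax for s in singles))
        half = 0.5 * (p_ens.r[1] - p_ens.r[0])
        assert np.all(p_ens.p[p_ens.r > p_ens.dmax + half] == 0)


class TestEnsembleMetrics:
    def test_two_unit_masses(self):
        assert radius_of_gyration(np.array([[0, 0, 0], [0, 0, 2.0]])) == \
            pytest.approx(1.0)

    def test_straight_helix_end_to_end_rise(self):
        from tests.conftest import uniform_dihedrals
        from sahens.conformers import build_conformer
        conf = build_conformer("A" * 74, uniform_dihedrals(74, -57.0, -47.0))
        e2e = ensemble_metrics(conf)["end_to_end"].iloc[0]
        assert e2e == pytest.approx(0.15 * 73, rel=0.10)

    def test_coordinate_rg_matches_guinier_of_own_debye_curve(self, tiny_pool):
        """With a conservative window (sRg < 0.8, where the quadratic
        Guinier expansion is accurate for elongated bodies) the fitted Rg
        reproduces the coordinate Rg within 2%."""
        conf = tiny_pool[3]
        ca = conf.ca_coords()
        rg_coord = radius_of_gyration(ca)
        s = np.linspace(0.02, 2.0, 300)
        g = guinier_fit(debye_curve(conf, s, granularity="ca"), srg_limit=0.8)
        assert g.rg == pytest.approx(rg_coord, rel=0.02)
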