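"""Scattering stack: Debye oracles, Guinier, p(r), IFT, Dmax, NSD."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdccore.assembly import BeadModel
from pdccore.scattering import (AggregationError, ScatteringCurve,
                                debye_intensity, estimate_dmax, guinier_fit,
                                ift, nsd_superpose, pair_distance_histogram,
                                sphere_form_factor)

Q_BALL = np.linspace(0.0, 0.25, 300)
Q_CORE = np.linspace(0.0, 0.08, 200)


def sphere_pr_closed_form(r: np.ndarray, R: float) -> np.ndarray:
    """Pair-distance distribution of a uniform sphere of radius R.

    p(r) ∝ r² (1 − 3x/4 + x³/16) with x = r/R on 0 ≤ r ≤ 2R — the
    textbook self-correlation of a ball, used as an independent oracle.
    """
    x = r / R
    p = r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
    return np.where(x <= 2.0, np.maximum(p, 0.0), 0.0)


class TestDebyeIntensity:
    def test_single_bead_is_sphere_form_factor(self):
        R = 30.0
        model = BeadModel([[5.0, -3.0, 1.0]], R)
        curve = debye_intensity(model, Q_BALL)
        expected = sphere_form_factor(Q_BALL, R) ** 2
        assert np.allclose(curve.I / curve.I[0], expected, atol=1e-12)

    def test_two_point_beads(self):
        d = 40.0
        model = BeadModel([[0, 0, 0], [0, 0, d]], 1.0)
        curve = debye_intensity(model, Q_BALL, form="point")
        qd = Q_BALL * d
        expected = np.where(qd > 0, 0.5 * (1 + np.sin(qd) / np.where(
            qd > 0, qd, 1.0)), 1.0)
        assert np.allclose(curve.I / curve.I[0], expected, atol=1e-12)

    def test_forward_intensity_is_squared_total_amplitude(self, core_model):
        curve = debye_intensity(core_model, np.array([0.0, 0.01]))
        total = (core_model.weights * core_model.volumes).sum()
        assert curve.I[0] == pytest.approx(total**2, rel=1e-12)

    def test_rigid_motion_invariance(self, core_model, rng):
        R = Rotation.random(random_state=7).as_matrix()
        moved = core_model.transformed(rotation=R, translation=[120, -50, 3])
        a = debye_intensity(core_model, Q_CORE)
        b = debye_intensity(moved, Q_CORE)
        assert np.allclose(a.I, b.I, rtol=1e-9)

    def test_invalid_q_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ScatteringCurve(np.array([0.0, 0.0, 0.1]), np.ones(3))


class TestGuinier:
    def test_exact_exponential_recovers_rg(self):
        Rg = 147.0
        q = np.linspace(0.0, 0.02, 120)
        curve = ScatteringCurve(q, 7.5 * np.exp(-q**2 * Rg**2 / 3.0))
        fit = guinier_fit(curve)
        assert fit.Rg == pytest.approx(Rg, rel=1e-9)
        assert fit.I0 == pytest.approx(7.5, rel=1e-9)

    def test_solid_sphere_rg(self):
        # single uniform sphere: Rg = sqrt(3/5)·R
        R = 50.0
        curve = debye_intensity(BeadModel([[0, 0, 0]], R), Q_BALL)
        fit = guinier_fit(curve)
        assert fit.Rg == pytest.approx(np.sqrt(0.6) * R, rel=0.01)

    def test_window_respects_q_rg_cutoff(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        fit = guinier_fit(curve, qRg_max=1.3)
        assert fit.q_range[1] * fit.Rg <= 1.3 + 1e-9

    def test_aggregated_curve_raises(self):
        q = np.linspace(0.0, 0.05, 60)
        curve = ScatteringCurve(q, 1.0 + 40.0 * q**2)
        with pytest.raises(AggregationError):
            guinier_fit(curve)

    def test_consistency_with_direct_rg(self, ball_model, core_model):
        for model, q in ((ball_model, Q_BALL), (core_model, Q_CORE)):
            fit = guinier_fit(debye_intensity(model, q))
            assert fit.Rg == pytest.approx(model.radius_of_gyration(),
                                           rel=0.02)


class TestPairDistance:
    def test_rg_matches_direct_second_moment(self, core_model):
        pr = pair_distance_histogram(core_model, bin_width=1.0)
        direct = core_model.radius_of_gyration(include_bead_size=False)
        assert pr.rg() == pytest.approx(direct, rel=0.005)

    def test_uniform_ball_matches_closed_form(self, ball_model):
        pr = pair_distance_histogram(ball_model, bin_width=2.0)
        expected = sphere_pr_closed_form(pr.r, 50.0)
        # normalize both to unit area before comparing shapes
        p1 = pr.p / np.trapezoid(pr.p, pr.r)
        p2 = expected / np.trapezoid(expected, pr.r)
        assert np.max(np.abs(p1 - p2)) < 0.05 * p2.max()

    def test_single_bead_point_mode_mass_at_origin(self):
        model = BeadModel([[1.0, 2.0, 3.0]], 10.0)
        pr = pair_distance_histogram(model, bin_width=1.0, mode="point")
        assert pr.p[0] > 0
        assert np.all(pr.p[1:] == 0)

    def test_sphere_mode_extends_dmax_by_bead_radii(self, shell_model):
        # furthest pair gains one bead radius at each end
        point = pair_distance_histogram(shell_model, 1.0, mode="point")
        sphere = pair_distance_histogram(shell_model, 1.0, mode="sphere")
        assert sphere.Dmax == pytest.approx(point.Dmax + 2 * 5.0, rel=0.01)

    def test_rigid_motion_invariance(self, shell_model):
        R = Rotation.random(random_state=3).as_matrix()
        moved = shell_model.transformed(rotation=R, translation=[9, 9, -4])
        a = pair_distance_histogram(shell_model, 2.0)
        b = pair_distance_histogram(moved, 2.0)
        assert np.allclose(a.p, b.p, rtol=1e-9, atol=1e-9 * a.p.max())

    def test_forward_intensity_proportionality(self, core_model):
        # Parseval-type check: total p(r) mass equals I(0) in point mode
        bw = 1.0
        pr = pair_distance_histogram(core_model, bw)
        I0 = debye_intensity(core_model, np.array([0.0])).I[0]
        assert pr.p.sum() * bw == pytest.approx(I0, rel=1e-9)


class TestIFT:
    def test_round_trip_core(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        dist = ift(curve, Dmax=core_model.dmax(), n_r=70)
        assert dist.rg() == pytest.approx(core_model.radius_of_gyration(),
                                          rel=0.02)

    def test_noise_free_sphere_matches_closed_form(self):
        R = 50.0
        curve = debye_intensity(BeadModel([[0, 0, 0]], R), Q_BALL)
        dist = ift(curve, Dmax=2 * R, n_r=80)
        expected = sphere_pr_closed_form(dist.r, R)
        p1 = dist.p / np.trapezoid(dist.p, dist.r)
        p2 = expected / np.trapezoid(expected, dist.r)
        assert np.max(np.abs(p1 - p2)) < 0.03 * p2.max()

    def test_misfit_monotone_in_regularization(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        lams = [1e-5, 1e-3, 1e-1, 10.0]
        chis = [ift(curve, core_model.dmax(), lambda_reg=l,
                    misfit_warn_factor=np.inf).chi2 for l in lams]
        assert all(a <= b * (1 + 1e-9) for a, b in zip(chis, chis[1:]))

    def test_endpoints_pinned(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        dist = ift(curve, core_model.dmax())
        assert dist.p[0] == 0.0 and dist.p[-1] == 0.0
        assert np.all(dist.p >= 0)

    def test_undersized_dmax_warns(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        with pytest.warns(RuntimeWarning, match="Dmax"):
            ift(curve, Dmax=0.5 * core_model.dmax(), misfit_warn_factor=1.0)


class TestEstimateDmax:
    def test_sphere_diameter(self, ball_model):
        curve = debye_intensity(ball_model, np.linspace(0.0, 0.12, 150))
        est = estimate_dmax(curve)
        assert est == pytest.approx(ball_model.dmax(), rel=0.03)

    def test_core_model(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        est = estimate_dmax(curve)
        assert est == pytest.approx(core_model.dmax(), rel=0.05)

    def test_armed_core(self, armed_model):
        curve = debye_intensity(armed_model, Q_CORE)
        est = estimate_dmax(curve)
        assert est == pytest.approx(armed_model.dmax(), rel=0.05)

    def test_undersized_candidates_fit_worse(self, core_model):
        curve = debye_intensity(core_model, Q_CORE)
        true_d = core_model.dmax()
        chi_small = ift(curve, 0.7 * true_d,
                        misfit_warn_factor=np.inf).chi2
        chi_true = ift(curve, true_d, misfit_warn_factor=np.inf).chi2
        assert chi_small > 10 * chi_true


class TestNSD:
    def test_identity_is_zero(self, shell_model):
        res = nsd_superpose(shell_model, shell_model, n_orientations=0)
        assert res.nsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, core_model, shell_model):
        scaled = shell_model.transformed(translation=[10, 0, 0])
        ab = nsd_superpose(core_model, scaled, n_orientations=40)
        ba = nsd_superpose(scaled, core_model, n_orientations=40)
        assert ab.nsd == pytest.approx(ba.nsd, rel=0.02, abs=1e-6)

    def test_rotated_copy_recovered(self, core_model):
        # a dense enough orientation grid plus ICP polish recovers an
        # arbitrary rigid rotation essentially exactly
        R = Rotation.from_euler("zyx", [40.0, 25.0, -70.0],
                                degrees=True).as_matrix()
        moved = core_model.transformed(rotation=R, translation=[50, -20, 10])
        res = nsd_superpose(core_model, moved, n_orientations=500)
        assert res.nsd < 0.05

    def test_more_orientations_do_not_hurt(self, core_model):
        R = Rotation.from_euler("zyx", [15.0, 80.0, 5.0],
                                degrees=True).as_matrix()
        moved = core_model.transformed(rotation=R)
        coarse = nsd_superpose(core_model, moved, n_orientations=10,
                               refine=False)
        fine = nsd_superpose(core_model, moved, n_orientations=200,
                             refine=False)
        assert fine.nsd <= coarse.nsd + 1e-12

    def test_armed_vs_core_exceeds_jitter(self, core_model, armed_model, rng):
        jittered = BeadModel(core_model.coords
                             + rng.normal(0, 1.0, core_model.coords.shape),
                             core_model.radii)
        d_arm = nsd_superpose(core_model, armed_model, n_orientations=20)
        d_jit = nsd_superpose(core_model, jittered, n_orientations=20)
        assert d_arm.nsd > d_jit.nsd > 0
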