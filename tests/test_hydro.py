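"""Hydrodynamics: Svedberg relations, friction oracles, coarse-graining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdccore.assembly import (AssemblySpec, BeadModel, build_core_model,
                              particle_volume, TABLE1_CORES)
from pdccore.constants import (AVOGADRO, CM_PER_ANGSTROM, SVEDBERG,
                               WATER4_DENSITY, WATER4_VISCOSITY)
from pdccore.hydro import (BuoyancyError, MolecularParams, SolventConditions,
                           WATER_20C, anhydrous_radius, bead_friction,
                           coarse_grain, extrapolate_s0, hydration_factor,
                           model_sedimentation, standardize_s,
                           svedberg_params)


class TestAnhydrousRadius:
    @pytest.mark.parametrize("name,expected", [
        ("rE2/E3BP", 102.0), ("rE2", 103.0), ("tE2/E3BP", 79.1)])
    def test_published_radii(self, name, expected):
        row = TABLE1_CORES[name]
        r0 = anhydrous_radius(MolecularParams(row["M"], row["vbar"]))
        assert r0 == pytest.approx(expected, abs=1.0)

    def test_cube_root_scaling(self):
        r1 = anhydrous_radius(MolecularParams(1e6, 0.73))
        r8 = anhydrous_radius(MolecularParams(8e6, 0.73))
        assert r8 == pytest.approx(2 * r1, rel=1e-12)


class TestSvedbergParams:
    @pytest.mark.parametrize("name,ff0", [
        ("rE2/E3BP", 2.69), ("rE2", 2.79), ("tE2/E3BP", 1.73)])
    def test_frictional_ratios(self, name, ff0):
        row = TABLE1_CORES[name]
        res = svedberg_params(MolecularParams(row["M"], row["vbar"]),
                              row["s20w0"])
        assert res.f_over_f0 == pytest.approx(ff0, rel=0.01)

    def test_truncated_core_stokes_diameter(self):
        row = TABLE1_CORES["tE2/E3BP"]
        res = svedberg_params(MolecularParams(row["M"], row["vbar"]),
                              row["s20w0"])
        assert res.Ds / 10.0 == pytest.approx(27.4, rel=0.01)  # Å → nm
        assert res.Ds == pytest.approx(2 * res.Rs, rel=1e-14)

    def test_sphere_limit_gives_unit_ratio(self):
        p = MolecularParams(1e6, 0.73)
        r0_cm = anhydrous_radius(p) * CM_PER_ANGSTROM
        f0 = 6 * np.pi * WATER_20C.eta * r0_cm
        s_sphere = p.M * (1 - p.vbar * WATER_20C.rho) / (AVOGADRO * f0)
        res = svedberg_params(p, s_sphere / SVEDBERG)
        assert res.f_over_f0 == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_dimensional_consistency(self):
        p = MolecularParams(2.5e6, 0.74)
        res = svedberg_params(p, 20.0)
        s_back = p.M * (1 - p.vbar * WATER_20C.rho) / (AVOGADRO * res.f)
        assert s_back / SVEDBERG == pytest.approx(20.0, rel=1e-12)

    def test_floating_particle_rejected(self):
        with pytest.raises(BuoyancyError):
            svedberg_params(MolecularParams(1e6, 0.9999999),
                            10.0, SolventConditions(rho=1.2, eta=0.01))


class TestStandardizeS:
    def test_identity_at_standard_conditions(self):
        assert standardize_s(29.3, WATER_20C, 0.744) == pytest.approx(29.3)

    def test_linear_in_viscosity_ratio(self):
        cond = SolventConditions(T=293.15, rho=WATER_20C.rho,
                                 eta=2 * WATER_20C.eta)
        assert standardize_s(10.0, cond, 0.744) == pytest.approx(20.0)

    def test_cold_water_factor_matches_hand_evaluation(self):
        cond = SolventConditions(T=277.15, rho=WATER4_DENSITY,
                                 eta=WATER4_VISCOSITY)
        vbar = 0.744
        expected = 10.0 * (WATER4_VISCOSITY / WATER_20C.eta) * (
            (1 - vbar * WATER_20C.rho) / (1 - vbar * WATER4_DENSITY))
        assert standardize_s(10.0, cond, vbar) == pytest.approx(
            expected, rel=1e-12)


class TestExtrapolateS0:
    def test_constant_s(self):
        s0, err = extrapolate_s0([0.1, 0.4, 0.8, 1.5], [27.5] * 4)
        assert s0 == pytest.approx(27.5)

    def test_exact_linear_concentration_dependence(self):
        c = np.array([0.2, 0.5, 1.0, 2.0])
        s = 29.3 * (1 - 0.02 * c)
        s0, _ = extrapolate_s0(c, s)
        assert s0 == pytest.approx(29.3, rel=1e-10)

    def test_monte_carlo_unbiased(self, rng):
        c = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        truth = 29.3
        est = []
        for _ in range(500):
            s = truth * (1 - 0.015 * c) + rng.normal(0, 0.05, c.shape)
            est.append(extrapolate_s0(c, s)[0])
        est = np.asarray(est)
        sem = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - truth) < 3 * sem

    def test_single_point_warns(self):
        with pytest.warns(UserWarning, match="single concentration"):
            s0, err = extrapolate_s0([1.0], [27.5])
        assert s0 == 27.5 and np.isinf(err)

    def test_reciprocal_variant(self):
        c = np.array([0.2, 0.6, 1.2])
        s = 1.0 / (1 / 29.3 + 0.001 * c)
        s0, _ = extrapolate_s0(c, s, reciprocal=True)
        assert s0 == pytest.approx(29.3, rel=1e-10)


class TestHydrationFactor:
    def test_published_value(self):
        assert hydration_factor(0.744, 0.4, 1.002) == pytest.approx(
            0.87, abs=0.005)
        assert hydration_factor(0.746, 0.4, 1.002) == pytest.approx(
            0.87, abs=0.005)

    def test_anhydrous_limit(self):
        assert hydration_factor(0.73, 0.0, 1.0) == 1.0

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_hydration(self, d1, d2):
        lo, hi = sorted([d1, d2])
        if hi - lo < 1e-9:
            return
        assert hydration_factor(0.744, hi, 1.002) < hydration_factor(
            0.744, lo, 1.002)


def two_body_rpy_oracle(r: float, a: float, eta: float) -> float:
    """Independent two-equal-sphere RPY friction via an explicit 6×6 solve."""
    zeta = 6 * np.pi * eta * a
    rij = np.array([0.0, 0.0, r])
    rr = np.outer(rij, rij) / r**2
    T = (1 / (8 * np.pi * eta * r)) * (
        (1 + 2 * a**2 / (3 * r**2)) * np.eye(3)
        + (1 - 2 * a**2 / r**2) * rr)
    M = np.block([[np.eye(3) / zeta, T], [T, np.eye(3) / zeta]])
    f = 0.0
    for axis in np.eye(3):
        u = np.concatenate([axis, axis])
        forces = np.linalg.solve(M, u)
        f += forces @ u
    return f / 3.0


class TestBeadFriction:
    def test_single_bead_stokes_law(self):
        R = 25.0
        model = BeadModel([[4.0, 4.0, 4.0]], R)
        expected = 6 * np.pi * WATER_20C.eta * R * CM_PER_ANGSTROM
        for method in ("supermatrix", "kirkwood"):
            assert bead_friction(model, method=method) == pytest.approx(
                expected, rel=1e-12)

    def test_two_touching_spheres_match_oracle(self):
        a = 20.0
        model = BeadModel([[0, 0, 0], [0, 0, 2 * a]], a)
        f = bead_friction(model, method="supermatrix")
        expected = two_body_rpy_oracle(2 * a * CM_PER_ANGSTROM,
                                       a * CM_PER_ANGSTROM, WATER_20C.eta)
        assert f == pytest.approx(expected, rel=1e-10)

    def test_kirkwood_close_to_supermatrix(self, shell_model, core_model):
        for model in (shell_model, core_model):
            fs = bead_friction(model, method="supermatrix")
            fk = bead_friction(model, method="kirkwood")
            assert fk == pytest.approx(fs, rel=0.10)

    def test_rigid_motion_invariance(self, shell_model):
        from scipy.spatial.transform import Rotation
        moved = shell_model.transformed(
            rotation=Rotation.random(random_state=5).as_matrix(),
            translation=[100, 2, -30])
        for method in ("supermatrix", "kirkwood"):
            assert bead_friction(moved, method=method) == pytest.approx(
                bead_friction(shell_model, method=method), rel=1e-9)

    def test_overlap_policies(self):
        model = BeadModel([[0, 0, 0], [0, 0, 10.0]], 8.0)
        with pytest.raises(ValueError, match="overlapping"):
            bead_friction(model, overlap_policy="reject")
        with pytest.warns(UserWarning, match="overlapping"):
            bead_friction(model, overlap_policy="shrink")


class TestCoarseGrain:
    def test_total_volume_exact(self, core_model):
        target = 2.07e6
        cg = coarse_grain(core_model, 15.0, target)
        assert cg.volumes.sum() == pytest.approx(target, rel=1e-9)

    def test_bead_count_bounded_by_cells(self, core_model):
        cg = coarse_grain(core_model, 30.0, 1e6)
        assert cg.n_beads <= core_model.n_beads

    def test_degenerate_grid_single_bead(self, core_model):
        V = 1e6
        cg = coarse_grain(core_model, 1e4, V)
        assert cg.n_beads == 1
        assert cg.radii[0] == pytest.approx((3 * V / (4 * np.pi)) ** (1 / 3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coarse_grain(np.empty((0, 3)), 5.0, 1e6)

    def test_grid_convergence_on_dense_core(self):
        # friction varies < 5% between 7 Å and 5.7 Å grids
        dense = build_core_model(AssemblySpec(seed=1, beads_per_monomer=24,
                                              bead_radius=4.0))
        V = particle_volume(1_671_348.0, 0.746)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f7 = bead_friction(coarse_grain(dense, 7.0, V))
            f57 = bead_friction(coarse_grain(dense, 5.7, V))
        assert abs(f7 / f57 - 1) < 0.05


class TestModelSedimentation:
    def test_sphere_limit_matches_closed_form(self):
        p = MolecularParams(1_671_348.0, 0.746)
        r0 = anhydrous_radius(p)
        model = BeadModel([[0.0, 0.0, 0.0]], r0)
        s_anh, s_hyd = model_sedimentation(model, p)
        f0 = 6 * np.pi * WATER_20C.eta * r0 * CM_PER_ANGSTROM
        expected = p.M * (1 - p.vbar * WATER_20C.rho) / (AVOGADRO * f0)
        assert s_anh == pytest.approx(expected / SVEDBERG, rel=1e-9)

    def test_hydration_ratio_exact(self, core_model):
        p = MolecularParams(1_671_348.0, 0.746, delta1=0.4)
        s_anh, s_hyd = model_sedimentation(core_model, p)
        F = hydration_factor(p.vbar, p.delta1, WATER_20C.v1_0)
        assert s_hyd / s_anh == pytest.approx(F, rel=1e-12)

    def test_frictional_ratio_at_least_one(self, core_model):
        # any extended shape has more friction than its anhydrous sphere
        p = MolecularParams(1_671_348.0, 0.746)
        f = bead_friction(core_model)
        f0 = 6 * np.pi * WATER_20C.eta * anhydrous_radius(p) * CM_PER_ANGSTROM
        assert f / f0 > 1.0 - 0.005
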