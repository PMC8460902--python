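import numpy as np
import pytest

from scolprog.cohort import CohortConfig, cohort_to_frame, generate_cohort, sample_spine_geometry
from scolprog.geometry import LEVELS
from scolprog.msk import (
    GRAVITY, InfeasibleError, MskModel, MuscleFascicle, RecruitmentConfig,
    ScalingConfig, build_model, fit_height_weight_model, joint_force_local,
    muscle_activity_sum, predict_height_weight, solve_inverse_statics,
)
from scolprog.msk import _equilibrium_system, _vertebra_rotation


class TestHeightWeightSurrogate:
    def test_intercept_only_model(self, subject):
        h, w = predict_height_weight(
            subject, height_coeffs={"intercept": 165.0},
            weight_coeffs={"intercept": 52.0})
        assert (h, w) == (165.0, 52.0)

    def test_three_predictor_dot_product(self, subject):
        # age 12, sex F: 100 + 4*12 + 2*1 = 150; 10 + 3*12 = 46
        h, w = predict_height_weight(
            subject,
            height_coeffs={"intercept": 100.0, "age": 4.0, "sex_F": 2.0},
            weight_coeffs={"intercept": 10.0, "age": 3.0})
        assert h == pytest.approx(150.0)
        assert w == pytest.approx(46.0)

    def test_unknown_coefficient_raises(self, subject):
        with pytest.raises(ValueError):
            predict_height_weight(subject, height_coeffs={"nope": 1.0})

    def test_fitted_surrogate_rmse_comparable_to_radiographic_models(self):
        df = cohort_to_frame(generate_cohort(
            CohortConfig(n_stable=180, n_progressive=120, seed=21)))
        _, _, rmse_h, rmse_w = fit_height_weight_model(df)
        assert 3.0 < rmse_h < 6.0       # reference fit quality ~4.3 cm
        assert 3.0 < rmse_w < 6.5       # ~3.9 kg plus propagated stature error


class TestModelBuild:
    def test_straight_spine_fascicles_mirror_symmetric(self, subject, scaling,
                                                       straight_geometry):
        model = build_model(subject, straight_geometry, scaling)
        left = {(f.group, f.crossed_joints): f for f in model.fascicles
                if f.side == "left"}
        for f in model.fascicles:
            if f.side != "right":
                continue
            mate = left[(f.group, f.crossed_joints)]
            assert np.allclose(f.insertion * [1, -1, 1], mate.insertion)
            assert np.allclose(f.origin * [1, -1, 1], mate.origin)
            assert f.pcsa == mate.pcsa

    def test_doubling_weight_doubles_masses_and_loads(self, subject,
                                                      straight_geometry):
        m1 = build_model(subject, straight_geometry,
                         ScalingConfig(height=158, weight=45, age=12))
        m2 = build_model(subject, straight_geometry,
                         ScalingConfig(height=158, weight=90, age=12))
        for lvl in LEVELS:
            assert m2.masses[lvl] == pytest.approx(2 * m1.masses[lvl])
        assert np.allclose(m2.external_loads[0][1],
                           2 * np.asarray(m1.external_loads[0][1]))

    def test_pcsa_follows_age_table(self, subject, straight_geometry):
        cfg = ScalingConfig(height=158, weight=45, age=12,
                            pcsa_age_nodes=((8.0, 0.75), (18.0, 1.35)))
        expected_factor = 0.75 + (1.35 - 0.75) * (12 - 8) / 10
        model = build_model(subject, straight_geometry, cfg)
        es = next(f for f in model.fascicles if f.group == "ES")
        assert es.pcsa == pytest.approx(cfg.es_pcsa_cm2 * expected_factor)

    def test_supported_mass_fraction_monotone(self, scaling):
        fracs = [scaling.cumulative_fraction(i) for i in range(17)]
        assert np.all(np.diff(fracs) >= 0)
        assert fracs[0] == pytest.approx(0.14)
        assert fracs[-1] == pytest.approx(0.57)


class TestLocalFrame:
    def test_ninety_degree_coronal_rotation_moves_axial_to_lateral(self):
        R = _vertebra_rotation(0.0, 90.0, 0.0)
        local = R.T @ np.array([0.0, 0.0, -1.0])
        assert abs(local[1]) == pytest.approx(1.0, abs=1e-12)
        assert abs(local[2]) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_level_raises(self, solved_straight):
        with pytest.raises(KeyError):
            joint_force_local(solved_straight, "C7")


class TestStaticsStraightSpine:
    def test_lateral_shear_vanishes_by_symmetry(self, solved_straight):
        for lvl in LEVELS:
            f_ap, f_lat, f_ax = joint_force_local(solved_straight, lvl)
            assert abs(f_lat) < 1e-6
            assert f_ax > 0 or f_ax < 0  # finite

    def test_axial_compression_accumulates_caudally(self, solved_straight):
        _, _, ax_t1 = joint_force_local(solved_straight, "T1")
        _, _, ax_l5 = joint_force_local(solved_straight, "L5")
        assert abs(ax_l5) >= abs(ax_t1)

    def test_bilateral_activations_equal(self, solved_straight):
        for lvl in ("T3", "T8", "L2", "L5"):
            for group in ("ES", "MF"):
                left = muscle_activity_sum(solved_straight, group, lvl, "left")
                right = muscle_activity_sum(solved_straight, group, lvl, "right")
                assert left == pytest.approx(right, abs=1e-6)

    def test_moment_residuals_below_tolerance(self, solved_straight):
        A, b = _equilibrium_system(solved_straight.model)
        scale = np.abs(b).max()
        assert max(solved_straight.residual.values()) < 1e-6 * scale

    def test_global_force_balance(self, solved_straight):
        """Reaction at the lumbosacral junction balances the supported
        weight, arm loads, and the pull of every muscle crossing it."""
        model = solved_straight.model
        f_ext = np.zeros(3)
        for lvl in LEVELS:
            f_ext += [0.0, 0.0, -model.masses[lvl] * GRAVITY]
        for _, force in model.external_loads:
            f_ext += force
        f_musc = np.zeros(3)
        for k, f in enumerate(model.fascicles):
            if 16 in f.crossed_joints:
                f_musc += (solved_straight.activation[k] * f.max_force
                           * f.line_of_action())
        total = solved_straight.joint_force["L5S1"] + f_ext + f_musc
        assert np.linalg.norm(total) < 1e-6 * np.linalg.norm(f_ext)


class TestStaticsScolioticSpine:
    def test_lateral_shear_grows_with_cobb(self, subject, scaling):
        rng = np.random.default_rng(0)
        f_upper = []
        for cobb in (0.0, 12.0, 20.0, 28.0):
            geom = sample_spine_geometry(
                dict(tk=44, ll=59, ss=39.6, pi=47.8, cobb=cobb,
                     largest_axial_rotation=8.0,
                     n_curves=1 if cobb > 10 else 0, apex="T9", side=1), rng)
            sol = solve_inverse_statics(build_model(subject, geom, scaling))
            f_upper.append(abs(joint_force_local(sol, "T6")[1]))
        assert all(b > a for a, b in zip(f_upper, f_upper[1:]))

    def test_mirrored_geometry_flips_lateral_shear_and_swaps_sides(
            self, solved_scoliotic, solved_scoliotic_mirror):
        for lvl in ("T6", "T9", "T12"):
            f = joint_force_local(solved_scoliotic, lvl)
            fm = joint_force_local(solved_scoliotic_mirror, lvl)
            assert fm[1] == pytest.approx(-f[1], abs=1e-4 * (1 + abs(f[1])))
            assert fm[2] == pytest.approx(f[2], rel=1e-3)
            for group in ("ES", "MF"):
                l = muscle_activity_sum(solved_scoliotic, group, lvl, "left")
                r = muscle_activity_sum(solved_scoliotic_mirror, group, lvl, "right")
                assert l == pytest.approx(r, abs=1e-4)

    def test_load_scale_equivariance(self, subject, scoliotic_geometry):
        base = ScalingConfig(height=158, weight=40, age=12)
        heavy = ScalingConfig(height=158, weight=60, age=12)
        s1 = solve_inverse_statics(build_model(subject, scoliotic_geometry, base))
        s2 = solve_inverse_statics(build_model(subject, scoliotic_geometry, heavy))
        k = 60.0 / 40.0
        active = s1.activation > 1e-4
        assert np.allclose(s2.activation[active], k * s1.activation[active],
                           rtol=1e-2)

    def test_overload_raises_infeasibility_with_joint_name(
            self, subject, scoliotic_geometry):
        crushing = ScalingConfig(height=158, weight=4500, age=12)
        with pytest.raises(InfeasibleError) as err:
            solve_inverse_statics(build_model(subject, scoliotic_geometry, crushing))
        assert err.value.joint in {f"{a}{b}" for a, b in
                                   zip(LEVELS, LEVELS[1:])} | {"L5S1"}


def _toy_single_joint_model(fascicles, mass=0.0, com_offset=(0.0, 0.0, 0.0)):
    """One spherical joint at the origin carrying one segment."""
    eye = np.eye(3)
    return MskModel(
        levels=["SEG"],
        positions={"SEG": np.array([0.0, 0.0, 100.0])},
        rotations={"SEG": eye},
        masses={"SEG": mass},
        com={"SEG": np.array([0.0, 0.0, 100.0]) + np.asarray(com_offset)},
        joint_positions={"J": np.zeros(3)},
        joint_frames={"J": eye},
        fascicles=fascicles,
        external_loads=[],
        config=None,
        joint_order=["J"],
        cranial_levels={"J": ["SEG"]},
    )


def _fascicle(side, y, pcsa=1.0):
    return MuscleFascicle(
        group="ES", side=side,
        origin=np.array([0.0, y, -100.0]),
        insertion=np.array([0.0, y, 100.0]),
        crossed_joints=(0,), crossed_levels=(0,), pcsa=pcsa, _stress=90.0)


class TestRecruitmentOptimality:
    def test_antagonist_pair_pure_moment(self):
        """External moment about the anteroposterior axis: the agonist
        carries M / lever arm, the antagonist stays silent."""
        left = _fascicle("left", +50.0)
        right = _fascicle("right", -50.0)
        # gravity on a mass offset toward +y creates a -x moment, balanced
        # only by the fascicle on the -y side (its pull gives +x moment)
        m = _toy_single_joint_model([left, right], mass=2.0,
                                    com_offset=(0.0, 30.0, 0.0))
        sol = solve_inverse_statics(m)
        needed = 2.0 * GRAVITY * 30.0 / 50.0 / right.max_force
        assert sol.activation[1] == pytest.approx(needed, rel=1e-4)
        assert sol.activation[0] == pytest.approx(0.0, abs=1e-6)

    def test_objective_matches_grid_search_on_three_fascicles(self):
        """Cubic-criterion optimum vs exhaustive grid (step 1e-3) on a
        redundant two-agonist + one-antagonist toy."""
        f1 = _fascicle("left", +40.0, pcsa=1.0)
        f2 = _fascicle("left", +80.0, pcsa=0.5)
        f3 = _fascicle("right", -50.0, pcsa=1.0)
        m = _toy_single_joint_model([f1, f2, f3], mass=1.5,
                                    com_offset=(0.0, 40.0, 0.0))
        sol = solve_inverse_statics(m)
        A, b = _equilibrium_system(m)
        # the only binding scalar equation is the moment about x
        row = A[0]
        target = b[0]
        best = np.inf
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        for a1 in grid:
            # solve a2 from the equality, a3 = 0 at optimum (antagonist)
            a2 = (target - row[0] * a1) / row[1]
            if not (0.0 <= a2 <= 1.0):
                continue
            best = min(best, a1 ** 3 + a2 ** 3)
        achieved = float(np.sum(sol.activation ** 3))
        assert achieved <= best + 1e-5
        assert max(sol.residual.values()) < 1e-6 * abs(target)


class TestActivitySums:
    def test_no_crossing_fascicles_gives_zero(self, solved_straight):
        # abdominal fascicles never enter the ES/MF activity sums
        assert muscle_activity_sum(solved_straight, "XX", "T8", "left") == 0.0

    def test_summation_of_crossing_activations(self):
        f1 = _fascicle("left", +50.0)
        f2 = _fascicle("left", +80.0)
        m = _toy_single_joint_model([f1, f2], mass=1.0,
                                    com_offset=(0.0, -20.0, 0.0))
        sol = solve_inverse_statics(m)
        total = muscle_activity_sum(sol, "ES", "SEG", "left")
        assert total == pytest.approx(float(sol.activation.sum()))
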