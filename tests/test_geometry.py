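import numpy as np
import pytest

from scolprog.cohort import sample_spine_geometry
from scolprog.geometry import (
    LEVELS, LEVEL_INDEX, CurveDescriptor, NoCurveError, SpineGeometry,
    classify_lenke, cobb_angle, curve_sagittal_angle, detect_curves,
    geometrical_params, lateral_offsets, sagittal_profiles, torsion_index,
)


def make_geometry(sag=None, cor=None, ax=None, ss=39.0, pt=8.0):
    sag = np.zeros(17) if sag is None else np.asarray(sag, float)
    cor = np.zeros(17) if cor is None else np.asarray(cor, float)
    ax = np.zeros(17) if ax is None else np.asarray(ax, float)
    ori = {lvl: (sag[i], cor[i], ax[i]) for i, lvl in enumerate(LEVELS)}
    return SpineGeometry(ori, sacral_slope=ss, pelvic_tilt=pt)


def make_curve(upper="T6", apex="T9", lower="T12", side="left_convex",
               cobb=18.0):
    return CurveDescriptor(upper_end=upper, apex=apex, lower_end=lower,
                           side=side, cobb=cobb, sagittal_angle=0.0,
                           max_axial_rotation=0.0)


class TestCobbAngle:
    def test_end_vertebra_inclination_difference(self):
        cor = np.zeros(17)
        cor[LEVEL_INDEX["T6"]] = 10.0
        cor[LEVEL_INDEX["T12"]] = -8.0
        geom = make_geometry(cor=cor)
        assert cobb_angle(geom, make_curve()) == pytest.approx(18.0)

    def test_zero_tilts_give_zero_angle(self):
        assert cobb_angle(make_geometry(), make_curve()) == 0.0


class TestSagittalDescriptors:
    def test_flat_profile_gives_zero_tk_and_ll(self):
        # all sagittal tilts equal zero and L1 matching the sacral endplate
        geom = make_geometry(ss=0.0, pt=47.0)
        assert sagittal_profiles(geom) == (0.0, 0.0)

    def test_tk_is_t1_t12_angle(self):
        sag = np.zeros(17)
        sag[LEVEL_INDEX["T1"]] = -20.0
        sag[LEVEL_INDEX["T12"]] = 24.0
        tk, _ = sagittal_profiles(make_geometry(sag=sag))
        assert tk == pytest.approx(44.0)

    def test_curve_sagittal_angle_between_end_vertebrae(self):
        sag = np.zeros(17)
        sag[LEVEL_INDEX["T6"]] = -8.0
        sag[LEVEL_INDEX["T12"]] = 8.0
        geom = make_geometry(sag=sag)
        assert curve_sagittal_angle(geom, make_curve()) == pytest.approx(16.0)
        sag[LEVEL_INDEX["T12"]] = -8.0
        assert curve_sagittal_angle(make_geometry(sag=sag), make_curve()) == 0.0

    def test_pelvic_incidence_identity(self):
        gp = geometrical_params(_single_curve_geometry())
        assert gp.pi == pytest.approx(gp.ss + 8.0)


def _single_curve_geometry(peak=9.0, up="T7", lo="T11"):
    """Sinusoidal coronal lobe peaking +/-peak at the end vertebrae."""
    cor = np.zeros(17)
    a, b = LEVEL_INDEX[up], LEVEL_INDEX[lo]
    for i in range(a, b + 1):
        cor[i] = peak * np.cos(np.pi * (i - a) / (b - a))
    return make_geometry(cor=cor)


class TestCurveDetection:
    def test_straight_spine_has_no_curves(self):
        assert detect_curves(make_geometry()) == []

    def test_single_sinusoidal_lobe_ends_at_most_tilted_vertebrae(self):
        curves = detect_curves(_single_curve_geometry(peak=9.0, up="T7", lo="T11"))
        assert len(curves) == 1
        assert (curves[0].upper_end, curves[0].lower_end) == ("T7", "T11")
        assert curves[0].cobb == pytest.approx(18.0)

    def test_two_opposite_lobes_detected_as_two_curves(self):
        rng = np.random.default_rng(0)
        geom = sample_spine_geometry(
            dict(tk=40, ll=58, ss=39, pi=47, cobb=22.0,
                 largest_axial_rotation=8.0, n_curves=2, apex="T8", side=1),
            rng)
        assert len(detect_curves(geom)) == 2

    def test_detection_agrees_with_brute_force_oracle(self):
        """Oracle: within each same-sign run of lateral offset, the curve
        ends are the pair of vertebrae maximizing the tilt difference."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            geom = sample_spine_geometry(
                dict(tk=float(rng.uniform(30, 55)), ll=float(rng.uniform(45, 65)),
                     ss=39.6, pi=47.8, cobb=float(rng.uniform(12, 25)),
                     largest_axial_rotation=5.0,
                     n_curves=int(rng.integers(1, 3)),
                     apex=str(rng.choice(["T8", "T9", "T10"])),
                     side=int(rng.choice([-1, 1]))), rng)
            y = lateral_offsets(geom)
            cor = geom.coronal
            # brute force: split into same-sign offset runs (ignoring
            # near-zero offsets), take max pairwise tilt difference per run
            active = np.abs(y) > 2.0
            oracle = []
            i = 0
            while i < 17:
                if not active[i]:
                    i += 1
                    continue
                j = i
                while j < 17 and active[j] and np.sign(y[j]) == np.sign(y[i]):
                    j += 1
                run = list(range(max(i - 1, 0), min(j + 1, 17)))
                best = max(((a, b) for a in run for b in run if a < b),
                           key=lambda p: abs(cor[p[0]] - cor[p[1]]))
                if abs(cor[best[0]] - cor[best[1]]) > 10.0:
                    oracle.append((LEVELS[best[0]], LEVELS[best[1]]))
                i = j
            found = {(c.upper_end, c.lower_end) for c in detect_curves(geom)}
            assert found == set(oracle)

    def test_mirror_symmetry_preserves_magnitudes(self):
        geom = _single_curve_geometry()
        mirrored = geom.mirrored()
        c, cm = detect_curves(geom)[0], detect_curves(mirrored)[0]
        assert c.side != cm.side
        assert c.cobb == pytest.approx(cm.cobb)
        assert sagittal_profiles(geom) == sagittal_profiles(mirrored)
        assert torsion_index(geom, c) == pytest.approx(
            torsion_index(mirrored, cm))


class TestTorsionIndex:
    def test_zero_rotations_give_zero(self):
        assert torsion_index(make_geometry(), make_curve()) == 0.0

    def test_mean_of_partial_sums(self):
        # intervertebral rotations sum to 8 from T6 up to the T9 apex and
        # to 6 from T9 down to T12 (8 - 2); the index is their mean, 7
        ax = np.zeros(17)
        for lvl, v in [("T7", 5.0), ("T8", 7.0), ("T9", 8.0),
                       ("T10", 4.0), ("T11", 2.5), ("T12", 2.0)]:
            ax[LEVEL_INDEX[lvl]] = v
        geom = make_geometry(ax=ax)
        curve = make_curve(upper="T6", apex="T9", lower="T12")
        assert torsion_index(geom, curve) == pytest.approx(7.0)

    def test_direct_summation_oracle_on_random_profiles(self):
        rng = np.random.default_rng(3)
        curve = make_curve(upper="T6", apex="T9", lower="T12")
        for _ in range(25):
            ax = rng.normal(0, 5, 17)
            geom = make_geometry(ax=ax)
            iu, ia, il = 5, 8, 11
            lower = sum(ax[i] - ax[i + 1] for i in range(ia, il))
            upper = sum(ax[i + 1] - ax[i] for i in range(iu, ia))
            expected = (abs(lower) + abs(upper)) / 2
            assert torsion_index(geom, curve) == pytest.approx(expected)


class TestLenke:
    def test_single_main_thoracic_is_type_1(self):
        assert classify_lenke([make_curve(apex="T9")]) == 1

    def test_single_thoracolumbar_is_type_5(self):
        assert classify_lenke([make_curve(upper="T11", apex="L1", lower="L3")]) == 5

    def test_lumbar_dominant_with_thoracic_minor_is_type_6(self):
        lumbar = make_curve(upper="T11", apex="L2", lower="L4", cobb=24.0)
        thoracic = make_curve(apex="T8", cobb=14.0)
        assert classify_lenke([lumbar, thoracic]) == 6

    def test_no_curves_raises(self):
        with pytest.raises(NoCurveError):
            classify_lenke([])


class TestGeometricalParams:
    def test_straight_spine_is_flagged(self):
        with pytest.raises(NoCurveError):
            geometrical_params(make_geometry())

    def test_nine_finite_descriptors(self, scoliotic_geometry):
        gp = geometrical_params(scoliotic_geometry)
        d = gp.as_dict()
        assert len(d) == 9
        assert all(np.isfinite(list(d.values())))

    def test_descriptors_invariant_to_uniform_height_scaling(self, scoliotic_geometry):
        import dataclasses
        taller = SpineGeometry(
            dict(scoliotic_geometry.orientation),
            scoliotic_geometry.sacral_slope, scoliotic_geometry.pelvic_tilt,
            {k: v * 1.3 for k, v in scoliotic_geometry.vertebral_heights.items()})
        a = geometrical_params(scoliotic_geometry).as_dict()
        b = geometrical_params(taller).as_dict()
        assert a == pytest.approx(b)
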