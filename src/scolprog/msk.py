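"""Simplified subject-specific inverse-statics model of the thoracolumbar
spine in relaxed upright stance.

The spine is a chain of rigid vertebral segments T1-L5 stacked on a sacrum
that is rigidly fixed to the ground through the pelvis.  Vertebral
orientations replicate the reconstructed spinal alignment; intervertebral
joints are ideal spherical joints with zero passive moment (neutral upright
position).  Trunk muscles are straight-line fascicles of two bilateral
groups — erector spinae (long, sacrum to every vertebra) and multifidus
(short, spanning two levels) — with maximum force PCSA x 90 N/cm^2 and PCSA
scaled with age.  Gravity acts on per-level lumped masses (a cumulative
supported-mass fraction of body weight) and the raised arms load the upper
thorax.

The muscle recruitment problem minimises the cubic sum of activations
subject to the three moment-equilibrium equations of every spherical joint,
with activations bounded in [0, 1]; intervertebral reaction forces follow
by force balance of everything cranial to each joint and are reported in
the local (anteroposterior, lateral, axial) frame of the caudal vertebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, minimize
from scipy.spatial.transform import Rotation

from .geometry import LEVEL_INDEX, LEVELS, SpineGeometry

__all__ = [
    "GRAVITY", "ScalingConfig", "RecruitmentConfig", "MuscleFascicle",
    "MskModel", "EquilibriumSolution", "InfeasibleError",
    "predict_height_weight", "fit_height_weight_model", "build_model",
    "solve_inverse_statics", "joint_force_local", "muscle_activity_sum",
]

GRAVITY = 9.81          # m/s^2
REFERENCE_HEIGHT_CM = 165.0

JOINTS = [f"{LEVELS[i]}{LEVELS[i + 1]}" for i in range(16)] + ["L5S1"]


class InfeasibleError(RuntimeError):
    """The required joint moments exceed the muscle capacity."""

    def __init__(self, joint: str, residual: float):
        self.joint = joint
        self.residual = residual
        super().__init__(
            f"moment equilibrium infeasible at joint {joint} "
            f"(residual {residual:.3g} N*mm)")


@dataclass
class RecruitmentConfig:
    exponent: float = 3.0          # polynomial recruitment criterion
    min_activation: float = 0.0    # optional co-activation floor
    tol: float = 1e-8              # relative moment residual tolerance
    # small quadratic term: the cubic criterion alone is not strictly
    # convex at zero activation, leaving barely recruited fascicles with
    # arbitrary left/right splits; the ridge makes the optimum unique
    ridge: float = 1e-6


@dataclass
class ScalingConfig:
    height: float                  # cm
    weight: float                  # kg
    age: float                     # years
    # cumulative supported body-mass fraction, linear T1 -> L5
    mass_fraction_t1: float = 0.14
    mass_fraction_l5: float = 0.57
    # PCSA vs age reference: linear interpolation nodes (years -> factor)
    pcsa_age_nodes: tuple = ((8.0, 0.75), (18.0, 1.35))
    es_pcsa_cm2: float = 1.0       # per ES fascicle at factor 1
    mf_pcsa_cm2: float = 0.8       # per MF fascicle at factor 1
    muscle_stress: float = 90.0    # N/cm^2
    arm_load_fraction: float = 0.05  # of body weight, per arm, at T1
    com_anterior_offset_mm: float = 50.0
    # fascicle lever-arm offsets (mm, at reference stature)
    es_lateral_lumbar_mm: float = 35.0
    es_lateral_thoracic_mm: float = 25.0
    es_posterior_mm: float = 40.0
    mf_lateral_insertion_mm: float = 15.0
    mf_lateral_origin_mm: float = 30.0
    mf_posterior_mm: float = 30.0
    # lumped anterior flexors (psoas / abdominal wall / ribcage load path,
    # actuation only, never predictors): short fascicles mirroring the
    # multifidus span on the anterior side
    ab_pcsa_cm2: float = 2.5
    ab_anterior_mm: float = 40.0
    ab_lateral_mm: float = 30.0

    def pcsa_factor(self, age: float) -> float:
        xs, ys = zip(*self.pcsa_age_nodes)
        return float(np.interp(age, xs, ys))

    def cumulative_fraction(self, i: int) -> float:
        return self.mass_fraction_t1 + (
            self.mass_fraction_l5 - self.mass_fraction_t1) * i / 16.0


@dataclass
class MuscleFascicle:
    group: str                    # 'ES' | 'MF'
    side: str                     # 'left' | 'right'
    origin: np.ndarray            # mm, global
    insertion: np.ndarray         # mm, global
    crossed_joints: tuple         # joint indices it spans
    crossed_levels: tuple         # vertebral mid-planes it crosses
    pcsa: float                   # cm^2

    @property
    def max_force(self) -> float:
        return self.pcsa * self._stress

    _stress: float = 90.0

    def line_of_action(self) -> np.ndarray:
        d = self.origin - self.insertion
        return d / np.linalg.norm(d)


@dataclass
class MskModel:
    levels: list
    positions: dict               # level -> centre (mm)
    rotations: dict               # level -> 3x3 rotation (local->global)
    masses: dict                  # level -> kg (lumped, incl. head at T1)
    com: dict                     # level -> centre of mass (mm)
    joint_positions: dict         # joint name -> mm
    joint_frames: dict            # joint name -> 3x3 (caudal vertebra frame)
    fascicles: list
    external_loads: list          # (point mm, force N) pairs
    config: ScalingConfig
    joint_order: list = None      # joint names; fascicle crossed_joints index it
    cranial_levels: dict = None   # joint name -> levels supported above it

    def __post_init__(self):
        if self.joint_order is None:
            self.joint_order = list(self.joint_positions)
        if self.cranial_levels is None:
            self.cranial_levels = {
                j: self.levels[: i + 1] for i, j in enumerate(self.joint_order)}


def _vertebra_rotation(sag: float, cor: float, ax: float) -> np.ndarray:
    """Intrinsic sagittal (lateral Y axis), coronal (anteroposterior X),
    axial (cranial Z) rotation sequence, degrees.

    Positive sagittal tilt is a posterior inclination, hence the sign flip
    about Y (+Y rotation tips the cranial axis anteriorly in the global
    X-anterior frame); positive coronal tilt tips the vertebral top toward
    the subject's right (-Y).
    """
    return Rotation.from_euler("YXZ", [-sag, cor, ax], degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# anthropometric surrogates

DEFAULT_HEIGHT_COEFFS = {"intercept": 102.0, "age": 4.3, "sex_F": -2.5}
DEFAULT_WEIGHT_COEFFS = {"intercept": -0.64, "age": 3.72, "sex_F": -1.7}


def _predictor_value(name, anthro, geom_params):
    if name == "intercept":
        return 1.0
    if name == "sex_F":
        return 1.0 if anthro.sex == "F" else 0.0
    for source in (anthro, geom_params):
        if source is not None and hasattr(source, name):
            return float(getattr(source, name))
    raise KeyError(name)


def predict_height_weight(anthro, geom_params=None,
                          height_coeffs=None, weight_coeffs=None):
    """Stature and body mass from linear surrogate models on the
    anthropometric (and optionally geometrical) predictors.

    Radiographic archives rarely store height and weight, so the body model
    is scaled with regression-predicted values.  The coefficient tables are
    fully configurable; the defaults are a simple age/sex surrogate.
    """
    hw = []
    for coeffs in (height_coeffs or DEFAULT_HEIGHT_COEFFS,
                   weight_coeffs or DEFAULT_WEIGHT_COEFFS):
        try:
            hw.append(sum(c * _predictor_value(k, anthro, geom_params)
                          for k, c in coeffs.items()))
        except KeyError as e:
            raise ValueError(f"no value available for coefficient {e}") from e
    return float(hw[0]), float(hw[1])


def fit_height_weight_model(df):
    """Fit the height/weight regressions on a cohort table with known
    values; returns (height_coeffs, weight_coeffs, rmse_height, rmse_weight).
    """
    from sklearn.linear_model import LinearRegression

    X = np.column_stack([df["age"].to_numpy(float),
                         (df["sex"] == "F").to_numpy(float)])
    out = []
    for target in ("height", "weight"):
        y = df[target].to_numpy(float)
        fit = LinearRegression().fit(X, y)
        coeffs = {"intercept": float(fit.intercept_),
                  "age": float(fit.coef_[0]), "sex_F": float(fit.coef_[1])}
        rmse = float(np.sqrt(np.mean((fit.predict(X) - y) ** 2)))
        out.append((coeffs, rmse))
    return out[0][0], out[1][0], out[0][1], out[1][1]


# ---------------------------------------------------------------------------
# model construction

def build_model(subject, geom: SpineGeometry, cfg: ScalingConfig) -> MskModel:
    """Stack the rigid chain in the replicated posture and attach muscle
    fascicles and gravitational/external loads."""
    scale = cfg.height / REFERENCE_HEIGHT_CM
    heights = {lvl: geom.vertebral_heights[lvl] * scale for lvl in LEVELS}

    R_sac = Rotation.from_euler("Y", geom.sacral_slope, degrees=True).as_matrix()
    rotations = {"sacrum": R_sac}
    for lvl in LEVELS:
        s, c, a = geom.orientation[lvl]
        rotations[lvl] = _vertebra_rotation(s, c, a)

    positions, joint_positions, joint_frames = {}, {}, {}
    z = np.array([0.0, 0.0, 1.0])
    # L5S1 joint sits at the sacral endplate (global origin)
    joint = np.zeros(3)
    joint_positions["L5S1"] = joint.copy()
    joint_frames["L5S1"] = R_sac
    for i in range(16, -1, -1):
        lvl = LEVELS[i]
        centre = joint + rotations[lvl] @ z * (heights[lvl] / 2.0)
        positions[lvl] = centre
        if i > 0:
            joint = centre + rotations[lvl] @ z * (heights[lvl] / 2.0)
            jname = JOINTS[i - 1]
            joint_positions[jname] = joint.copy()
            joint_frames[jname] = rotations[lvl]

    for i in range(16):
        lower = positions[LEVELS[i + 1]]
        upper = positions[LEVELS[i]]
        if upper[2] <= lower[2]:
            raise ValueError(
                f"non-physiologic geometry: segment {LEVELS[i]} does not "
                "stack cranially")

    masses, com = {}, {}
    for i, lvl in enumerate(LEVELS):
        frac = cfg.cumulative_fraction(i) - (
            cfg.cumulative_fraction(i - 1) if i > 0 else 0.0)
        masses[lvl] = frac * cfg.weight
        com[lvl] = positions[lvl] + rotations[lvl] @ np.array(
            [cfg.com_anterior_offset_mm * scale, 0.0, 0.0])

    arm_force = np.array([0.0, 0.0, -cfg.arm_load_fraction * cfg.weight * GRAVITY])
    external_loads = [(positions["T1"].copy(), arm_force.copy()),
                      (positions["T1"].copy(), arm_force.copy())]

    factor = cfg.pcsa_factor(cfg.age)
    fascicles = []
    for side, s in (("left", 1.0), ("right", -1.0)):
        for i, lvl in enumerate(LEVELS):
            lat = (cfg.es_lateral_lumbar_mm if lvl.startswith("L")
                   else cfg.es_lateral_thoracic_mm) * scale
            insertion = positions[lvl] + rotations[lvl] @ np.array(
                [-cfg.es_posterior_mm * scale, s * lat, 0.0])
            origin = joint_positions["L5S1"] + R_sac @ np.array(
                [-cfg.es_posterior_mm * scale,
                 s * cfg.es_lateral_lumbar_mm * scale, -40.0 * scale])
            fascicles.append(MuscleFascicle(
                group="ES", side=side, origin=origin, insertion=insertion,
                crossed_joints=tuple(range(i, 17)),
                crossed_levels=tuple(range(i, 17)),
                pcsa=cfg.es_pcsa_cm2 * factor, _stress=cfg.muscle_stress))
        for i in range(15):                      # MF spans two levels
            lvl, caudal = LEVELS[i], LEVELS[i + 2]
            insertion = positions[lvl] + rotations[lvl] @ np.array(
                [-cfg.mf_posterior_mm * scale,
                 s * cfg.mf_lateral_insertion_mm * scale, 0.0])
            origin = positions[caudal] + rotations[caudal] @ np.array(
                [-cfg.mf_posterior_mm * scale,
                 s * cfg.mf_lateral_origin_mm * scale, 0.0])
            fascicles.append(MuscleFascicle(
                group="MF", side=side, origin=origin, insertion=insertion,
                crossed_joints=(i, i + 1),
                crossed_levels=(i, i + 1),
                pcsa=cfg.mf_pcsa_cm2 * factor, _stress=cfg.muscle_stress))
        # lumbosacral multifidus: deepest fascicles anchor on the sacrum,
        # giving the L4L5/L5S1 joints the same short-fascicle actuation
        for ins_lvl, joints, lat_ins, lat_org in (
                ("L4", (15, 16), cfg.mf_lateral_insertion_mm, cfg.mf_lateral_origin_mm),
                ("L5", (16,), cfg.mf_lateral_insertion_mm, cfg.mf_lateral_origin_mm),
                ("L4", (15, 16), cfg.mf_lateral_origin_mm, cfg.mf_lateral_insertion_mm),
                ("L5", (16,), cfg.mf_lateral_origin_mm, cfg.mf_lateral_insertion_mm)):
            group = "MF" if lat_ins == cfg.mf_lateral_insertion_mm else "RT"
            insertion = positions[ins_lvl] + rotations[ins_lvl] @ np.array(
                [-cfg.mf_posterior_mm * scale, s * lat_ins * scale, 0.0])
            origin = joint_positions["L5S1"] + R_sac @ np.array(
                [-cfg.mf_posterior_mm * scale, s * lat_org * scale,
                 -30.0 * scale])
            pcsa = cfg.mf_pcsa_cm2 * (1.0 if group == "MF" else 0.5) * factor
            fascicles.append(MuscleFascicle(
                group=group, side=side, origin=origin, insertion=insertion,
                crossed_joints=joints, crossed_levels=joints,
                pcsa=pcsa, _stress=cfg.muscle_stress))
        # rotatores-like short fascicles: opposite medio-lateral slant to the
        # multifidus, so both signs of axial torque are available per side
        for i in range(15):
            lvl, caudal = LEVELS[i], LEVELS[i + 2]
            insertion = positions[lvl] + rotations[lvl] @ np.array(
                [-cfg.mf_posterior_mm * scale,
                 s * cfg.mf_lateral_origin_mm * scale, 0.0])
            origin = positions[caudal] + rotations[caudal] @ np.array(
                [-cfg.mf_posterior_mm * scale,
                 s * cfg.mf_lateral_insertion_mm * scale, 0.0])
            fascicles.append(MuscleFascicle(
                group="RT", side=side, origin=origin, insertion=insertion,
                crossed_joints=(i, i + 1), crossed_levels=(i, i + 1),
                pcsa=cfg.mf_pcsa_cm2 * factor, _stress=cfg.muscle_stress))
        # lumped anterior flexors: short two-level fascicles anterior of the
        # vertebral bodies, so a flexion moment is available at every joint
        # (a lordotic or swayed posture is infeasible with extensors alone)
        for i in range(15):
            lvl, caudal = LEVELS[i], LEVELS[i + 2]
            # alternating oblique slant (external/internal oblique analogue)
            # provides both signs of axial torque on the anterior side
            lat_ins = cfg.ab_lateral_mm * (1.0 if i % 2 == 0 else 0.5)
            lat_org = cfg.ab_lateral_mm * (0.5 if i % 2 == 0 else 1.0)
            insertion = positions[lvl] + rotations[lvl] @ np.array(
                [cfg.ab_anterior_mm * scale, s * lat_ins * scale, 0.0])
            origin = positions[caudal] + rotations[caudal] @ np.array(
                [cfg.ab_anterior_mm * scale, s * lat_org * scale, 0.0])
            fascicles.append(MuscleFascicle(
                group="AB", side=side, origin=origin, insertion=insertion,
                crossed_joints=(i, i + 1), crossed_levels=(i, i + 1),
                pcsa=cfg.ab_pcsa_cm2 * factor, _stress=cfg.muscle_stress))
        for ins_lvl, joints in (("L4", (15, 16)), ("L5", (16,))):
            insertion = positions[ins_lvl] + rotations[ins_lvl] @ np.array(
                [cfg.ab_anterior_mm * scale, s * cfg.ab_lateral_mm * scale, 0.0])
            origin = joint_positions["L5S1"] + R_sac @ np.array(
                [cfg.ab_anterior_mm * scale, s * cfg.ab_lateral_mm * scale,
                 -30.0 * scale])
            fascicles.append(MuscleFascicle(
                group="AB", side=side, origin=origin, insertion=insertion,
                crossed_joints=joints, crossed_levels=joints,
                pcsa=cfg.ab_pcsa_cm2 * factor, _stress=cfg.muscle_stress))

    return MskModel(
        levels=list(LEVELS), positions=positions, rotations=rotations,
        masses=masses, com=com, joint_positions=joint_positions,
        joint_frames=joint_frames, fascicles=fascicles,
        external_loads=external_loads, config=cfg,
        joint_order=list(JOINTS))


# ---------------------------------------------------------------------------
# inverse statics

@dataclass
class EquilibriumSolution:
    model: MskModel
    activation: np.ndarray        # per fascicle, 0-1
    joint_force: dict             # joint name -> global reaction (N)
    residual: dict                # joint name -> moment residual (N*mm)

    def activation_of(self, fascicle) -> float:
        return float(self.activation[self.model.fascicles.index(fascicle)])


def _equilibrium_system(model: MskModel):
    """Moment-equilibrium matrix (3 rows per joint) over fascicle forces and
    the gravity/external right-hand side."""
    nf = len(model.fascicles)
    joints = model.joint_order
    A = np.zeros((3 * len(joints), nf))
    b = np.zeros(3 * len(joints))
    for ji, jname in enumerate(joints):
        rj = model.joint_positions[jname]
        m_ext = np.zeros(3)
        for lvl in model.cranial_levels[jname]:  # everything cranial to joint
            w = np.array([0.0, 0.0, -model.masses[lvl] * GRAVITY])
            m_ext += np.cross(model.com[lvl] - rj, w)
        for point, force in model.external_loads:
            m_ext += np.cross(point - rj, force)
        b[3 * ji: 3 * ji + 3] = -m_ext
        for k, f in enumerate(model.fascicles):
            if ji in f.crossed_joints:
                arm = np.cross(f.insertion - rj, f.line_of_action())
                A[3 * ji: 3 * ji + 3, k] = arm * f.max_force
    return A, b


def solve_inverse_statics(model: MskModel,
                          criterion: RecruitmentConfig = None) -> EquilibriumSolution:
    """Solve the muscle recruitment problem and the joint reactions.

    Minimises sum(activation^p) subject to the three moment-equilibrium
    equations per spherical joint and activations in [min_activation, 1].
    Raises :class:`InfeasibleError` when no admissible activation pattern
    balances the posture.
    """
    criterion = criterion or RecruitmentConfig()
    A, b = _equilibrium_system(model)
    joints = model.joint_order
    scale = max(np.abs(b).max(), 1.0)
    lo = criterion.min_activation

    # feasibility: bounded least squares on the equality system
    ls = lsq_linear(A, b, bounds=(lo, 1.0), method="bvls",
                    tol=1e-14, max_iter=200)
    res_per_joint = np.linalg.norm((A @ ls.x - b).reshape(-1, 3), axis=1)
    if res_per_joint.max() > 1e-6 * scale * 10:
        j = joints[int(np.argmax(res_per_joint))]
        raise InfeasibleError(j, float(res_per_joint.max()))

    p = criterion.exponent
    ridge = criterion.ridge
    As, bs = A / scale, b / scale

    def objective(a):
        return float(np.sum(a ** p) + ridge * np.sum(a ** 2))

    def gradient(a):
        return p * a ** (p - 1.0) + 2.0 * ridge * a

    result = minimize(
        objective, ls.x, jac=gradient, method="SLSQP",
        bounds=[(lo, 1.0)] * A.shape[1],
        constraints=[{"type": "eq", "fun": lambda a: As @ a - bs,
                      "jac": lambda a: As}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    a = np.clip(result.x, lo, 1.0)
    res_per_joint = np.linalg.norm((A @ a - b).reshape(-1, 3), axis=1)
    if res_per_joint.max() > 1e-6 * scale * 10:
        # fall back to the feasible least-squares point
        a = ls.x
        res_per_joint = np.linalg.norm((A @ a - b).reshape(-1, 3), axis=1)

    forces = a * np.array([f.max_force for f in model.fascicles])
    joint_force, residual = {}, {}
    for ji, jname in enumerate(joints):
        f_ext = np.zeros(3)
        for lvl in model.cranial_levels[jname]:
            f_ext += np.array([0.0, 0.0, -model.masses[lvl] * GRAVITY])
        for _, force in model.external_loads:
            f_ext += force
        f_musc = np.zeros(3)
        for k, f in enumerate(model.fascicles):
            if ji in f.crossed_joints:
                f_musc += forces[k] * f.line_of_action()
        joint_force[jname] = -(f_ext + f_musc)
        residual[jname] = float(res_per_joint[ji])
    return EquilibriumSolution(model=model, activation=a,
                               joint_force=joint_force, residual=residual)


def joint_force_local(solution: EquilibriumSolution, level: str):
    """Reaction at the joint caudal to ``level``, expressed in the caudal
    vertebra's local (ap, lat, ax) frame."""
    if level not in LEVEL_INDEX:
        raise KeyError(f"unknown vertebral level {level!r}")
    jname = JOINTS[LEVEL_INDEX[level]]
    frame = solution.model.joint_frames[jname]
    local = frame.T @ solution.joint_force[jname]
    return float(local[0]), float(local[1]), float(local[2])


def muscle_activity_sum(solution: EquilibriumSolution, group: str,
                        level: str, side: str) -> float:
    """Sum of activations of the group/side fascicles whose span crosses
    the vertebral mid-plane of ``level``."""
    li = solution.model.levels.index(level)
    total = 0.0
    for k, f in enumerate(solution.model.fascicles):
        if f.group == group and f.side == side and li in f.crossed_levels:
            total += float(solution.activation[k])
    return total
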