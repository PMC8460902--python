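"""The eleven biomechanical predictors of a solved upright posture.

Three lateral-shear magnitudes (upper end, apex, lower end of the most
severe curve) and eight normalized muscle-asymmetry ratios: erector spinae
(ES) and multifidus (MF) at the same three levels, plus along-curve ratios
obtained from the activation totals summed over every level from the upper
to the lower end vertebra inclusive.

The normalized activity ratio (convex - concave)/(convex + concave) is near
zero for balanced bilateral activation and approaches +1 / -1 when the
convex / concave side dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import CurveDescriptor
from .msk import EquilibriumSolution, joint_force_local, muscle_activity_sum

__all__ = ["BiomechParams", "normalized_activity_ratio", "extract_biomech_params"]


@dataclass
class BiomechParams:
    f_lat_upper: float
    f_lat_apex: float
    f_lat_lower: float
    nes_upper: float
    nes_apex: float
    nes_lower: float
    nmf_upper: float
    nmf_apex: float
    nmf_lower: float
    nes_curve: float
    nmf_curve: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def normalized_activity_ratio(convex_sum: float, concave_sum: float,
                              atol: float = 1e-8) -> float:
    """(convex - concave)/(convex + concave); total activity at or below
    ``atol`` counts as balanced (0) — the solver resolves activations to
    finite precision, so a ratio of two vanishing sums is noise."""
    if convex_sum < 0 or concave_sum < 0:
        raise ValueError("activity sums must be non-negative")
    total = convex_sum + concave_sum
    if total <= atol:
        return 0.0
    return (convex_sum - concave_sum) / total


def extract_biomech_params(solution: EquilibriumSolution,
                           curve: CurveDescriptor) -> BiomechParams:
    """Reduce an equilibrium solution plus the most severe curve to the
    eleven biomechanical predictors."""
    convex = "left" if curve.side == "left_convex" else "right"
    concave = "right" if convex == "left" else "left"

    def f_lat(level):
        return abs(joint_force_local(solution, level)[1])

    def ratio(group, level):
        return normalized_activity_ratio(
            muscle_activity_sum(solution, group, level, convex),
            muscle_activity_sum(solution, group, level, concave))

    def curve_ratio(group):
        cx = sum(muscle_activity_sum(solution, group, lvl, convex)
                 for lvl in curve.levels())
        cc = sum(muscle_activity_sum(solution, group, lvl, concave)
                 for lvl in curve.levels())
        return normalized_activity_ratio(cx, cc)

    u, a, l = curve.upper_end, curve.apex, curve.lower_end
    return BiomechParams(
        f_lat_upper=f_lat(u), f_lat_apex=f_lat(a), f_lat_lower=f_lat(l),
        nes_upper=ratio("ES", u), nes_apex=ratio("ES", a), nes_lower=ratio("ES", l),
        nmf_upper=ratio("MF", u), nmf_apex=ratio("MF", a), nmf_lower=ratio("MF", l),
        nes_curve=curve_ratio("ES"), nmf_curve=curve_ratio("MF"),
    )
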