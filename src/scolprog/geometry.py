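"""Geometrical descriptors of the scoliotic thoracolumbar spine.

A spine is described by the 3D orientation of each vertebra from T1 to L5
(sagittal tilt, coronal tilt, axial rotation, in degrees) plus the sacral
slope and pelvic tilt.  From these the module derives the nine standard
descriptors used as predictors of curve progression — thoracic kyphosis,
lumbar lordosis, sacral slope, pelvic incidence, number of scoliotic curves,
Cobb angle of the most severe curve, curve sagittal angle, largest vertebral
axial rotation inside the curve, and an approximate Lenke type — plus the
torsion index of a curve.

Conventions
-----------
Global frame: right-handed, X anterior, Y subject-left, Z cranial.
Coronal tilt is the frontal-plane inclination of a vertebra (positive tilts
the vertebral top toward the subject's right); sagittal tilt is positive
for a posterior (extension-direction) inclination, so a normal alignment
runs from an anteriorly tilted T1 (negative) to a posteriorly tilted
thoracolumbar junction (positive).  Thoracic kyphosis and lumbar lordosis
are both reported with positive magnitudes.  Pelvic incidence obeys the
geometric identity PI = SS + pelvic tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEVELS", "LEVEL_INDEX", "DEFAULT_SEGMENT_HEIGHTS",
    "SpineGeometry", "CurveDescriptor", "GeometricalParams",
    "DegenerateCurveError", "NoCurveError",
    "detect_curves", "cobb_angle", "sagittal_profiles", "curve_sagittal_angle",
    "torsion_index", "classify_lenke", "geometrical_params", "lateral_offsets",
]

LEVELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}

# Cranio-caudal segment heights (vertebral body + disc, mm) for a reference
# adolescent stature; scaled linearly with subject height by the builder.
DEFAULT_SEGMENT_HEIGHTS = {
    "T1": 22.0, "T2": 23.0, "T3": 23.0, "T4": 24.0, "T5": 24.0, "T6": 25.0,
    "T7": 25.0, "T8": 26.0, "T9": 26.0, "T10": 27.0, "T11": 28.0, "T12": 29.0,
    "L1": 30.0, "L2": 31.0, "L3": 32.0, "L4": 33.0, "L5": 33.0,
}

COBB_THRESHOLD_DEG = 10.0  # scoliotic curve: Cobb angle larger than 10 degrees


class DegenerateCurveError(ValueError):
    """Raised when a curve's end vertebrae coincide."""


class NoCurveError(ValueError):
    """Raised when descriptors of the main curve are requested on a spine
    without any scoliotic curve (Cobb > 10 degrees)."""


@dataclass
class SpineGeometry:
    """Per-vertebra orientation triples T1..L5 plus pelvic parameters.

    ``orientation`` maps level name -> (sagittal_tilt, coronal_tilt,
    axial_rotation) in degrees.
    """

    orientation: dict
    sacral_slope: float
    pelvic_tilt: float
    vertebral_heights: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_HEIGHTS))

    def __post_init__(self):
        missing = [lvl for lvl in LEVELS if lvl not in self.orientation]
        if missing:
            raise ValueError(f"missing vertebral orientations: {missing}")
        arr = np.array([self.orientation[lvl] for lvl in LEVELS], dtype=float)
        if arr.shape != (17, 3) or not np.all(np.isfinite(arr)):
            raise ValueError("orientations must be 17 finite (sag, cor, ax) triples")
        if any(self.vertebral_heights.get(lvl, 0) <= 0 for lvl in LEVELS):
            raise ValueError("vertebral heights must be positive")

    def angles(self) -> np.ndarray:
        """(17, 3) array of (sagittal, coronal, axial) in degrees, T1 first."""
        return np.array([self.orientation[lvl] for lvl in LEVELS], dtype=float)

    @property
    def sagittal(self) -> np.ndarray:
        return self.angles()[:, 0]

    @property
    def coronal(self) -> np.ndarray:
        return self.angles()[:, 1]

    @property
    def axial(self) -> np.ndarray:
        return self.angles()[:, 2]

    def heights(self) -> np.ndarray:
        return np.array([self.vertebral_heights[lvl] for lvl in LEVELS], dtype=float)

    def mirrored(self) -> "SpineGeometry":
        """Left-right reflection: negates coronal tilts and axial rotations."""
        ori = {
            lvl: (s, -c, -a) for lvl, (s, c, a) in self.orientation.items()
        }
        return SpineGeometry(ori, self.sacral_slope, self.pelvic_tilt,
                             dict(self.vertebral_heights))


@dataclass
class CurveDescriptor:
    upper_end: str
    apex: str
    lower_end: str
    side: str                     # left_convex | right_convex
    cobb: float
    sagittal_angle: float
    max_axial_rotation: float

    def __post_init__(self):
        iu, ia, il = (LEVEL_INDEX[self.upper_end], LEVEL_INDEX[self.apex],
                      LEVEL_INDEX[self.lower_end])
        if not (iu < ia < il):
            raise ValueError("curve levels must be ordered upper < apex < lower")

    def levels(self):
        """All levels from upper to lower end, inclusive."""
        return LEVELS[LEVEL_INDEX[self.upper_end]: LEVEL_INDEX[self.lower_end] + 1]


@dataclass
class GeometricalParams:
    tk: float
    ll: float
    ss: float
    pi: float
    n_curves: int
    cobb_main: float
    curve_sagittal_angle: float
    largest_axial_rotation: float
    lenke_type: int

    def as_dict(self) -> dict:
        return {
            "tk": self.tk, "ll": self.ll, "ss": self.ss, "pi": self.pi,
            "n_curves": self.n_curves, "cobb": self.cobb_main,
            "curve_sagittal_angle": self.curve_sagittal_angle,
            "largest_axial_rotation": self.largest_axial_rotation,
            "lenke_type": self.lenke_type,
        }


def lateral_offsets(geom: SpineGeometry) -> np.ndarray:
    """Frontal-plane lateral position (mm, +Y subject-left) of each
    vertebral centre, stacking the chain from the fixed pelvis upward.

    Positive coronal tilt rotates the local cranial axis toward -Y, so a
    curve convex to the left accumulates positive offset below its apex.
    """
    cor = np.deg2rad(geom.coronal)
    h = geom.heights()
    y = np.zeros(17)
    acc = 0.0
    for i in range(16, -1, -1):           # caudal (L5) to cranial (T1)
        acc += -h[i] * np.sin(cor[i])
        y[i] = acc
    return y


def _offset_runs(y, dead_band):
    """Contiguous same-sign runs of lateral deviation (index ranges),
    ignoring offsets within the dead band."""
    runs = []
    i, n = 0, len(y)
    while i < n:
        if abs(y[i]) <= dead_band:
            i += 1
            continue
        j = i
        while j < n and abs(y[j]) > dead_band and np.sign(y[j]) == np.sign(y[i]):
            j += 1
        runs.append((i, j - 1))
        i = j
    return runs


def detect_curves(geom: SpineGeometry, min_offset_mm: float = 2.0,
                  min_apex_deviation_mm: float = 2.0) -> list:
    """Scoliotic curves (Cobb > 10 deg), most severe first.

    The stacked chain is split into contiguous same-sign runs of lateral
    deviation; within each run (extended by one transition vertebra at each
    boundary, which adjacent curves may share) the end vertebrae are the
    most-tilted vertebrae in either direction, and the apex is the vertebra
    of maximal lateral deviation from the chord between the ends.  Runs
    whose end-tilt difference stays below the 10-degree Cobb threshold, or
    whose apex deviates less than ``min_apex_deviation_mm`` from the chord,
    are transition zones rather than curves.
    """
    cor = geom.coronal
    y = lateral_offsets(geom)
    curves = []
    for lo, hi in _offset_runs(y, min_offset_mm):
        a, b = max(lo - 1, 0), min(hi + 1, 16)
        window = np.arange(a, b + 1)
        i_max = int(window[np.argmax(cor[window])])
        i_min = int(window[np.argmin(cor[window])])
        iu, il = min(i_max, i_min), max(i_max, i_min)
        cobb = abs(cor[iu] - cor[il])
        if cobb <= COBB_THRESHOLD_DEG or il - iu < 2:
            continue
        # apex: maximal lateral deviation from the chord between the ends
        span = np.arange(iu, il + 1)
        chord = y[iu] + (y[il] - y[iu]) * (span - iu) / (il - iu)
        dev = y[span] - chord
        k = int(span[np.argmax(np.abs(dev))])
        if k == iu or k == il:   # no interior apex -> not a lateral curve
            continue
        if np.max(np.abs(dev)) < min_apex_deviation_mm:
            continue
        side = "left_convex" if dev[k - iu] > 0 else "right_convex"
        curves.append(CurveDescriptor(
            upper_end=LEVELS[iu], apex=LEVELS[k], lower_end=LEVELS[il],
            side=side, cobb=float(cobb),
            sagittal_angle=float(geom.sagittal[il] - geom.sagittal[iu]),
            max_axial_rotation=float(np.max(np.abs(geom.axial[iu:il + 1]))),
        ))
    curves.sort(key=lambda c: -c.cobb)
    return curves


def cobb_angle(geom: SpineGeometry, curve: CurveDescriptor) -> float:
    """Frontal-plane Cobb angle: absolute difference of the coronal
    inclinations of the curve's end vertebrae."""
    if curve.upper_end == curve.lower_end:
        raise DegenerateCurveError("end vertebrae coincide")
    iu, il = LEVEL_INDEX[curve.upper_end], LEVEL_INDEX[curve.lower_end]
    return float(abs(geom.coronal[iu] - geom.coronal[il]))


def sagittal_profiles(geom: SpineGeometry):
    """(TK, LL): thoracic kyphosis T1-T12 and lumbar lordosis L1-S1.

    TK is the signed sagittal angle between the T1 and T12 orientations
    (kyphosis positive); LL is measured between L1 and the sacral endplate,
    whose anterior-down inclination is the sacral slope (lordosis
    positive).
    """
    sag = geom.sagittal
    tk = sag[LEVEL_INDEX["T12"]] - sag[LEVEL_INDEX["T1"]]
    ll = geom.sacral_slope + sag[LEVEL_INDEX["L1"]]
    return float(tk), float(ll)


def curve_sagittal_angle(geom: SpineGeometry, curve: CurveDescriptor) -> float:
    """Signed sagittal-plane angle between the curve's end vertebrae
    (kyphosis-positive, like TK)."""
    iu, il = LEVEL_INDEX[curve.upper_end], LEVEL_INDEX[curve.lower_end]
    return float(geom.sagittal[il] - geom.sagittal[iu])


def torsion_index(geom: SpineGeometry, curve: CurveDescriptor) -> float:
    """Mean of the two summed intervertebral axial rotations: lower end to
    apex, and apex to upper end of the curve (magnitudes averaged)."""
    ax = geom.axial
    iu, ia, il = (LEVEL_INDEX[curve.upper_end], LEVEL_INDEX[curve.apex],
                  LEVEL_INDEX[curve.lower_end])
    lower_sum = sum(ax[i] - ax[i + 1] for i in range(ia, il))
    upper_sum = sum(ax[i + 1] - ax[i] for i in range(iu, ia))
    return float((abs(lower_sum) + abs(upper_sum)) / 2.0)


_THORACIC_APICES = {f"T{i}" for i in range(2, 12)}          # T2..T11
_TL_LUMBAR_APICES = {"T12", "L1", "L2", "L3", "L4"}


def classify_lenke(curves: list) -> int:
    """Rule-based approximation of the six Lenke types from apex locations
    and curve count.

    Single thoracic curve -> 1; two thoracic curves -> 2; thoracic main with
    a lumbar minor -> 3; three or more curves with thoracic main -> 4;
    single thoracolumbar/lumbar -> 5; lumbar dominant with thoracic minor
    -> 6.  Side-bending films and sagittal modifiers of the clinical scheme
    are not available from a single standing acquisition and are ignored.
    """
    if not curves:
        raise NoCurveError("Lenke type undefined without a scoliotic curve")
    main = curves[0]
    thoracic = [c for c in curves if c.apex in _THORACIC_APICES]
    lumbar = [c for c in curves if c.apex in _TL_LUMBAR_APICES]
    if main.apex in _THORACIC_APICES:
        if len(curves) >= 3:
            return 4
        if lumbar:
            return 3
        return 2 if len(thoracic) >= 2 else 1
    # main curve thoracolumbar / lumbar
    return 6 if thoracic else 5


def geometrical_params(geom: SpineGeometry) -> GeometricalParams:
    """Assemble the nine geometrical descriptors; the curve-specific ones
    come from the most severe curve."""
    curves = detect_curves(geom)
    if not curves:
        raise NoCurveError("no scoliotic curve with Cobb angle > 10 degrees")
    main = curves[0]
    tk, ll = sagittal_profiles(geom)
    return GeometricalParams(
        tk=tk, ll=ll,
        ss=float(geom.sacral_slope),
        pi=float(geom.sacral_slope + geom.pelvic_tilt),
        n_curves=len(curves),
        cobb_main=cobb_angle(geom, main),
        curve_sagittal_angle=curve_sagittal_angle(geom, main),
        largest_axial_rotation=main.max_axial_rotation,
        lenke_type=classify_lenke(curves),
    )
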