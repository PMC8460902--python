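"""Synthetic AIS cohort generation.

Emulates a baseline cohort of adolescents with mild idiopathic scoliosis
(Cobb 10-25 degrees, Risser 0-2, age 10-18 at first examination) labelled
stable or progressive at follow-up.  Two sampling modes are provided:

``feature_level``
    Draw complete 23-dimensional predictor vectors directly from the
    group-conditional calibrated distributions, coupled by a Gaussian
    copula with configurable rank correlations.
``geometry_level``
    Draw per-subject geometrical targets from the same calibration and
    realize them as full per-vertebra orientation chains (T1-L5), so that
    the descriptor computations and the musculoskeletal solver can be run
    end to end.  The realized geometry reproduces the sampled targets
    within 1 degree when pushed back through the descriptor module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import (
    ANTHRO_COLUMNS,
    BIOMECH_COLUMNS,
    FEATURE_COLUMNS,
    GEOM_COLUMNS,
    TruncNormMargin,
    default_margins,
    default_rank_correlation,
    solve_biomech_coupling,
)
from .geometry import LEVELS, LEVEL_INDEX, SpineGeometry

__all__ = [
    "SubjectRecord", "FollowupRecord", "CohortConfig", "ConfigurationError",
    "GenerationError", "apply_progression_criteria", "sample_feature_vector",
    "sample_spine_geometry", "generate_cohort", "cohort_to_frame",
    "geometry_columns", "frame_to_geometries",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration (e.g. infeasible correlation matrix)."""


class GenerationError(RuntimeError):
    """A requested geometry target cannot be realized."""


@dataclass
class SubjectRecord:
    id: str
    age: float                   # years
    sex: str                     # 'F' | 'M'
    risser: int                  # 0-2 at baseline (inclusion rule)
    group: str                   # 'stable' | 'progressive'
    height: float                # cm
    weight: float                # kg
    followup_months: float

    def __post_init__(self):
        if not (10.0 <= self.age <= 18.0):
            raise ValueError(f"age {self.age} outside inclusion range [10, 18]")
        if self.risser not in (0, 1, 2):
            raise ValueError(f"baseline Risser {self.risser} outside 0-2")
        if self.followup_months < 6.0:
            raise ValueError("follow-up shorter than 6 months")


@dataclass
class FollowupRecord:
    risser_fu: int               # 0-5
    delta_cobb: float            # degrees of Cobb-angle increase


@dataclass
class CohortConfig:
    n_stable: int = 60
    n_progressive: int = 40
    seed: int = 0
    mode: str = "feature_level"            # or "geometry_level"
    # 'redundant': biomechanical predictors are group-independent functions
    # of Cobb and age plus shared noise (calibrated to the published group
    # means), so they add no outcome information beyond the reduced set.
    # 'margins': sample them directly from the group-conditional margins
    # through the copula.
    biomech_coupling: str = "redundant"
    margins: dict = field(default_factory=default_margins)
    rank_correlation_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("feature_level", "geometry_level"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.biomech_coupling not in ("redundant", "margins"):
            raise ConfigurationError(
                f"unknown biomech coupling {self.biomech_coupling!r}")
        if self.n_stable < 0 or self.n_progressive < 0:
            raise ConfigurationError("group sizes must be non-negative")
        self._couplings = None

    def biomech_couplings(self) -> dict:
        if self._couplings is None:
            self._couplings = solve_biomech_coupling(self.margins)
        return self._couplings


# ---------------------------------------------------------------------------
# follow-up labelling

def apply_progression_criteria(baseline: SubjectRecord, fu: FollowupRecord) -> str:
    """Outcome label from the follow-up examination.

    Stable: skeletally mature enough (Risser > 2) with Cobb increase below
    10 degrees.  Progressive: still immature (Risser 0-2) with Cobb increase
    above 10 degrees.  Any other combination is indeterminate and excluded
    from labelled cohorts.
    """
    if fu.risser_fu > 2 and fu.delta_cobb < 10.0:
        return "stable"
    if fu.risser_fu <= 2 and fu.delta_cobb > 10.0:
        return "progressive"
    return "indeterminate"


_FOLLOWUP_MONTHS = {"stable": (27.0, 13.0), "progressive": (25.0, 12.0)}


def _sample_followup(group: str, baseline_risser: int, rng: np.random.Generator) -> FollowupRecord:
    """Follow-up consistent with the group label; indeterminate draws are
    regenerated until a labelled case results."""
    for _ in range(1000):
        if group == "stable":
            fu = FollowupRecord(
                risser_fu=int(rng.integers(3, 6)),
                delta_cobb=float(np.clip(rng.normal(3.0, 3.0), -5.0, 9.5)),
            )
        else:
            fu = FollowupRecord(
                risser_fu=int(np.clip(baseline_risser + rng.integers(0, 2), 0, 2)),
                delta_cobb=float(np.clip(rng.normal(14.0, 3.0), 10.5, 30.0)),
            )
        label = "stable" if (fu.risser_fu > 2 and fu.delta_cobb < 10) else (
            "progressive" if (fu.risser_fu <= 2 and fu.delta_cobb > 10) else "indeterminate")
        if label == group:
            return fu
    raise GenerationError("could not realize a labelled follow-up")


def _sample_followup_months(group: str, rng: np.random.Generator) -> float:
    m, s = _FOLLOWUP_MONTHS[group]
    for _ in range(1000):
        v = rng.normal(m, s)
        if v >= 6.0:
            return float(v)
    return 6.0


# True stature/mass used to scale the body model.  Linear in age and sex
# with residual scatter matching the reported goodness of fit of the
# radiographic height/weight predictors (4.3 cm, 3.9 kg RMSE).
HEIGHT_MODEL = {"intercept": 102.0, "age": 4.3, "sex_F": -2.5, "resid_sd": 4.3}
WEIGHT_MODEL = {"intercept": -70.0, "height": 0.68, "age": 0.8, "resid_sd": 3.9}


def _sample_height_weight(age: float, sex: str, rng: np.random.Generator):
    h = (HEIGHT_MODEL["intercept"] + HEIGHT_MODEL["age"] * age
         + HEIGHT_MODEL["sex_F"] * (sex == "F")
         + rng.normal(0.0, HEIGHT_MODEL["resid_sd"]))
    w = (WEIGHT_MODEL["intercept"] + WEIGHT_MODEL["height"] * h
         + WEIGHT_MODEL["age"] * age
         + rng.normal(0.0, WEIGHT_MODEL["resid_sd"]))
    return float(h), float(max(w, 25.0))


# ---------------------------------------------------------------------------
# feature-level sampling

def _latent_correlation(config: CohortConfig, columns) -> np.ndarray:
    """Latent Gaussian correlation from the target rank correlations
    (Pearson of the latent normal r = 2 sin(pi * rho_s / 6))."""
    R_rank = default_rank_correlation(columns, config.rank_correlation_overrides)
    R = 2.0 * np.sin(np.pi * R_rank / 6.0)
    np.fill_diagonal(R, 1.0)
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise ConfigurationError(
            "correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})")
    return R


def _copula_uniforms(n: int, R: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    z = rng.standard_normal((n, len(R))) @ L.T
    return norm.cdf(z)


REDUCED_FEATURES = ANTHRO_COLUMNS + GEOM_COLUMNS


def sample_feature_vector(group: str, config: CohortConfig,
                          rng: np.random.Generator, n: int = 1) -> pd.DataFrame:
    """Draw ``n`` complete 23-dimensional predictor vectors for a group.

    The anthropometric and geometrical predictors are drawn from the
    group-conditional calibrated margins through the Gaussian copula.  The
    biomechanical block follows the configured coupling: by default a
    group-independent size/severity mechanism on Cobb and age (see
    :func:`scolprog.calibration.solve_biomech_coupling`); alternatively
    direct margin sampling through the copula.

    Columns follow :data:`scolprog.calibration.FEATURE_COLUMNS`; sex is
    'F'/'M', Risser/Lenke/curve counts are integers, everything else float.
    """
    margins = config.margins[group]
    if config.biomech_coupling == "margins":
        copula_cols = FEATURE_COLUMNS
    else:
        copula_cols = REDUCED_FEATURES
    U = _copula_uniforms(n, _latent_correlation(config, copula_cols), rng)
    data = {}
    for j, col in enumerate(copula_cols):
        vals = margins[col].ppf(U[:, j])
        if col == "sex":
            vals = np.where(np.asarray(vals) == 1, "F", "M")
        data[col] = vals
    if config.biomech_coupling == "redundant":
        couplings = config.biomech_couplings()
        # residuals share a subject-level factor: every biomechanical output
        # comes from the same simulation of the same reconstructed geometry
        # scaled by the same predicted height/weight, so simulation error is
        # common across features (each marginal stays standard normal)
        eps_common = rng.standard_normal(n)
        w = np.sqrt(0.5)
        for col in BIOMECH_COLUMNS:
            eps = w * eps_common + w * rng.standard_normal(n)
            data[col] = couplings[col].realize(data["cobb"], data["age"], eps)
    df = pd.DataFrame(data)[list(FEATURE_COLUMNS)]
    for col in ("risser", "n_curves", "lenke_type"):
        df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# geometry-level sampling

def sample_spine_geometry(targets: dict, rng: np.random.Generator) -> SpineGeometry:
    """Realize per-subject geometrical targets as a smooth per-vertebra
    orientation chain.

    ``targets`` must provide tk, ll, ss, pi, cobb, largest_axial_rotation
    and n_curves; optional: apex (level name), side (+1 left convex / -1),
    and span (half-width of the curve in vertebral levels, default 3).
    The descriptors recomputed from the output reproduce the targets within
    1 degree (round-trip contract).
    """
    tk, ll, ss, pi = (float(targets[k]) for k in ("tk", "ll", "ss", "pi"))
    cobb = float(targets["cobb"])
    lar = float(targets.get("largest_axial_rotation", 0.0))
    n_curves = int(targets.get("n_curves", 1))

    # sagittal channel: piecewise-linear through the control vertebrae that
    # define TK (T1, T12) and LL (L1 against the sacral endplate); posterior
    # tilt positive, so T1 leans anteriorly and L5 follows the sacrum
    idx = np.arange(17)
    sag = np.interp(
        idx,
        [0, LEVEL_INDEX["T12"], LEVEL_INDEX["L1"], 16],
        [-tk / 2.0, tk / 2.0, ll - ss, 0.2 * ll - 0.8 * ss],
    )

    coronal = np.zeros(17)
    axial = np.zeros(17)

    def place_curve(apex_i: int, span_u: int, span_l: int, c: float,
                    s: float, rot: float):
        iu, il = apex_i - span_u, apex_i + span_l
        if iu < 0 or il > 16 or span_u < 1 or span_l < 1 or il - iu < 2:
            raise GenerationError(
                f"curve spanning levels {iu}..{il} is not realizable")
        if np.any(coronal[iu:il + 1] != 0.0):
            raise GenerationError("curve placement overlaps an existing curve")
        for i in range(iu, apex_i + 1):
            coronal[i] = s * (c / 2.0) * math.sin(
                math.pi / 2.0 * (apex_i - i) / span_u)
            axial[i] = s * rot * math.sin(
                math.pi / 2.0 * (i - iu) / span_u)
        for i in range(apex_i, il + 1):
            coronal[i] = -s * (c / 2.0) * math.sin(
                math.pi / 2.0 * (i - apex_i) / span_l)
            axial[i] = s * rot * math.sin(
                math.pi / 2.0 * (il - i) / span_l)
        axial[apex_i] = s * rot

    if cobb <= 10.0:
        if n_curves > 0 and cobb > 0:
            raise GenerationError("main-curve Cobb target must exceed 10 degrees")
    side = float(targets.get("side", 1 if rng.random() < 0.5 else -1))
    span = int(targets.get("span", 3))
    apex = targets.get("apex")
    if apex is None:
        lenke = int(targets.get("lenke_type", 1))
        pool = ["T8", "T9", "T10"] if lenke in (1, 2, 3, 4) else ["L1", "L2"]
        apex = pool[int(rng.integers(0, len(pool)))]
    apex_i = LEVEL_INDEX[apex]
    span_u = min(span, apex_i)
    span_l = min(span, 16 - apex_i)
    if cobb > 10.0:
        place_curve(apex_i, span_u, span_l, cobb, side, lar)

    if n_curves >= 2 and cobb > 10.0:
        # compensatory curve on the opposite side, smaller than the main one
        c2 = 10.5 + 0.5 * (cobb - 10.5)
        if apex_i <= LEVEL_INDEX["T10"]:
            apex2 = min(apex_i + span_l + 4, 14)     # caudal lobe, apex <= L3
        else:
            apex2 = max(apex_i - span_u - 4, 2)      # cranial lobe
        span2 = 2
        try:
            place_curve(apex2, span2, span2, c2, -side, lar * c2 / cobb * 0.8)
        except GenerationError:
            pass  # no room for a secondary lobe on this spine

    orientation = {
        lvl: (float(sag[i]), float(coronal[i]), float(axial[i]))
        for i, lvl in enumerate(LEVELS)
    }
    return SpineGeometry(orientation, sacral_slope=ss, pelvic_tilt=pi - ss)


# ---------------------------------------------------------------------------
# cohort assembly

def generate_cohort(config: CohortConfig):
    """Generate the full labelled cohort.

    Returns a list of ``(SubjectRecord, payload)`` where the payload is a
    :class:`pandas.Series` of the 23 predictors (feature mode) or a
    :class:`SpineGeometry` (geometry mode).  Reproducible under a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    counter = 0
    for group, n in (("stable", config.n_stable),
                     ("progressive", config.n_progressive)):
        if n == 0:
            continue
        feats = sample_feature_vector(group, config, rng, n=n)
        for _, row in feats.iterrows():
            counter += 1
            height, weight = _sample_height_weight(row["age"], row["sex"], rng)
            rec = SubjectRecord(
                id=f"S{counter:04d}",
                age=float(row["age"]), sex=str(row["sex"]),
                risser=int(row["risser"]), group=group,
                height=height, weight=weight,
                followup_months=_sample_followup_months(group, rng),
            )
            fu = _sample_followup(group, rec.risser, rng)
            assert apply_progression_criteria(rec, fu) == group
            if config.mode == "feature_level":
                payload = row.copy()
            else:
                payload = sample_spine_geometry(row.to_dict(), rng)
            out.append((rec, payload))
    return out


def geometry_columns() -> list:
    cols = []
    for lvl in LEVELS:
        cols += [f"sag_{lvl}", f"cor_{lvl}", f"ax_{lvl}"]
    return cols + ["sacral_slope", "pelvic_tilt"]


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Flatten a generated cohort into one row per subject (CSV-ready)."""
    rows = []
    for rec, payload in cohort:
        row = {
            "id": rec.id, "group": rec.group, "age": rec.age, "sex": rec.sex,
            "risser": rec.risser, "height": rec.height, "weight": rec.weight,
            "followup_months": rec.followup_months,
        }
        if isinstance(payload, SpineGeometry):
            for lvl in LEVELS:
                s, c, a = payload.orientation[lvl]
                row[f"sag_{lvl}"] = s
                row[f"cor_{lvl}"] = c
                row[f"ax_{lvl}"] = a
            row["sacral_slope"] = payload.sacral_slope
            row["pelvic_tilt"] = payload.pelvic_tilt
        else:
            row.update({c: payload[c] for c in FEATURE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_geometries(df: pd.DataFrame):
    """Rebuild ``(SubjectRecord, SpineGeometry)`` pairs from a cohort table
    written by :func:`cohort_to_frame` in geometry mode."""
    out = []
    for _, row in df.iterrows():
        rec = SubjectRecord(
            id=row["id"], age=row["age"], sex=row["sex"],
            risser=int(row["risser"]), group=row["group"],
            height=row["height"], weight=row["weight"],
            followup_months=row["followup_months"],
        )
        ori = {lvl: (row[f"sag_{lvl}"], row[f"cor_{lvl}"], row[f"ax_{lvl}"])
               for lvl in LEVELS}
        geom = SpineGeometry(ori, sacral_slope=row["sacral_slope"],
                             pelvic_tilt=row["pelvic_tilt"])
        out.append((rec, geom))
    return out
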