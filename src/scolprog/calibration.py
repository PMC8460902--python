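"""Group-conditional calibration targets for the synthetic AIS cohort.

The generator is calibrated to the published descriptive statistics of a
100-subject mild-scoliosis cohort (60 stable, 40 progressive at follow-up):
per-group mean (SD) for the continuous predictors, count proportions for the
categorical ones, and the handful of strong rank correlations observed
between curve severity and the lateral intervertebral shear.

Bounded quantities are modelled as truncated normals whose *underlying*
parameters are solved by moment matching so that the truncated distribution
itself reproduces the printed mean, and the printed SD as far as the family
allows.  Integer-valued scores (Risser grade, number of curves) use discrete
distributions on their support solved from the first two moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "Margin",
    "TruncNormMargin",
    "DiscreteMargin",
    "BernoulliMargin",
    "CategoricalMargin",
    "FEATURE_COLUMNS",
    "ANTHRO_COLUMNS",
    "GEOM_COLUMNS",
    "BIOMECH_COLUMNS",
    "default_margins",
    "default_rank_correlation",
    "discrete_from_moments",
    "solve_truncnorm_params",
    "BiomechCoupling",
    "solve_biomech_coupling",
    "COBB_CORR_TARGETS",
]

# Ordered predictor list: 3 anthropometric + 9 geometrical + 11 biomechanical.
ANTHRO_COLUMNS = ["age", "sex", "risser"]
GEOM_COLUMNS = [
    "tk", "ll", "ss", "pi", "n_curves", "cobb",
    "curve_sagittal_angle", "largest_axial_rotation", "lenke_type",
]
BIOMECH_COLUMNS = [
    "f_lat_upper", "f_lat_apex", "f_lat_lower",
    "nes_upper", "nes_apex", "nes_lower",
    "nmf_upper", "nmf_apex", "nmf_lower",
    "nes_curve", "nmf_curve",
]
FEATURE_COLUMNS = ANTHRO_COLUMNS + GEOM_COLUMNS + BIOMECH_COLUMNS


@lru_cache(maxsize=256)
def solve_truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) of a truncated normal on [lo, hi] whose
    truncated mean equals ``mean`` and truncated SD is as close as possible
    to ``sd``.

    The truncated mean is strictly increasing in mu at fixed sigma, so the
    inner solve is a bracketed root find; the outer 1-D search adjusts sigma
    for the SD.  When the requested SD exceeds what the family can attain on
    the interval (its variance is capped near the uniform limit), the result
    matches the mean exactly and delivers the closest attainable SD.
    """
    if not np.isfinite(lo) and not np.isfinite(hi):
        return float(mean), float(sd)

    def stats_for(mu, sigma):
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def mu_for_sigma(sigma):
        span = 8 * sigma + (hi - lo if np.isfinite(hi) and np.isfinite(lo) else 0)
        f = lambda mu: stats_for(mu, sigma)[0] - mean
        lo_mu, hi_mu = mean - span, mean + span
        # widen the bracket if needed (very asymmetric truncation)
        for _ in range(60):
            if f(lo_mu) < 0 < f(hi_mu):
                break
            lo_mu -= span
            hi_mu += span
        return optimize.brentq(f, lo_mu, hi_mu, xtol=1e-10)

    def sd_err(log_sigma):
        sigma = float(np.exp(log_sigma))
        mu = mu_for_sigma(sigma)
        return (stats_for(mu, sigma)[1] - sd) ** 2

    res = optimize.minimize_scalar(
        sd_err, bounds=(np.log(sd / 10), np.log(sd * 40)), method="bounded",
        options={"xatol": 1e-8},
    )
    sigma = float(np.exp(res.x))
    return mu_for_sigma(sigma), sigma


def discrete_from_moments(support, mean, sd):
    """Probabilities on an ordered integer support matching a target mean
    and SD in least squares, with exact-match solutions preferred.

    For a 3-point support the two moment equations plus normalisation have a
    unique solution; when it leaves the simplex it is projected back
    (clipped and renormalised, then mean re-centred by a small least-squares
    correction).
    """
    support = np.asarray(support, dtype=float)
    k = len(support)
    A = np.vstack([np.ones(k), support, support ** 2])
    b = np.array([1.0, mean, sd ** 2 + mean ** 2])
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(p < -1e-9):
        # project to simplex while keeping normalisation + mean exact
        res = optimize.linprog(
            c=np.zeros(k),
            A_eq=A[:2], b_eq=b[:2],
            bounds=[(0, 1)] * k,
        )
        if not res.success:
            raise ValueError(
                f"no distribution on support {support} with mean {mean}"
            )
        p = res.x
    p = np.clip(p, 0, None)
    return p / p.sum()


@dataclass(frozen=True)
class Margin:
    """Base class: a marginal distribution addressed through its quantile
    function, so a Gaussian copula can drive all margins uniformly."""

    def ppf(self, u):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class TruncNormMargin(Margin):
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def ppf(self, u):
        mu, sigma = solve_truncnorm_params(self.mean, self.sd, self.lo, self.hi)
        a, b = (self.lo - mu) / sigma, (self.hi - mu) / sigma
        return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


@dataclass(frozen=True)
class DiscreteMargin(Margin):
    support: tuple
    probs: tuple

    @classmethod
    def from_moments(cls, support, mean, sd):
        p = discrete_from_moments(support, mean, sd)
        return cls(tuple(support), tuple(p))

    def ppf(self, u):
        edges = np.cumsum(self.probs)
        idx = np.searchsorted(edges, np.asarray(u), side="right")
        idx = np.clip(idx, 0, len(self.support) - 1)
        return np.asarray(self.support)[idx]


@dataclass(frozen=True)
class BernoulliMargin(Margin):
    """Two-level categorical; returns 1 with probability p_one."""

    p_one: float

    def ppf(self, u):
        return (np.asarray(u) < self.p_one).astype(int)


@dataclass(frozen=True)
class CategoricalMargin(Margin):
    levels: tuple
    counts: tuple

    def ppf(self, u):
        p = np.asarray(self.counts, dtype=float)
        p = p / p.sum()
        edges = np.cumsum(p)
        idx = np.searchsorted(edges, np.asarray(u), side="right")
        idx = np.clip(idx, 0, len(self.levels) - 1)
        return np.asarray(self.levels)[idx]


def default_margins() -> dict:
    """Per-group marginal calibration for all 23 predictors.

    Values are the published group mean (SD) / counts.  Sex is coded as the
    probability of female; Lenke type by per-type case counts.
    """
    stable = {
        "age": TruncNormMargin(13.2, 1.1, 10.0, 18.0),
        "sex": BernoulliMargin(36 / 60),          # 36 F / 24 M
        "risser": DiscreteMargin.from_moments((0, 1, 2), 1.1, 0.9),
        "tk": TruncNormMargin(44.0, 13.4, 0.0, 90.0),
        "ll": TruncNormMargin(59.2, 9.8, 20.0, 90.0),
        "ss": TruncNormMargin(39.6, 7.3, 10.0, 70.0),
        "pi": TruncNormMargin(47.8, 7.8, 20.0, 85.0),
        "n_curves": DiscreteMargin.from_moments((1, 2, 3), 1.7, 0.6),
        "cobb": TruncNormMargin(18.9, 6.1, 10.0, 25.0),
        "curve_sagittal_angle": TruncNormMargin(22.1, 14.7),
        "largest_axial_rotation": TruncNormMargin(9.9, 5.6, 0.0, np.inf),
        "lenke_type": CategoricalMargin((1, 2, 3, 4, 5, 6), (11, 2, 10, 4, 14, 19)),
        "f_lat_upper": TruncNormMargin(57.8, 41.2, 0.0, np.inf),
        "f_lat_apex": TruncNormMargin(26.4, 22.2, 0.0, np.inf),
        "f_lat_lower": TruncNormMargin(46.3, 23.4, 0.0, np.inf),
        "nes_upper": TruncNormMargin(0.11, 0.22, -1.0, 1.0),
        "nes_apex": TruncNormMargin(0.12, 0.21, -1.0, 1.0),
        "nes_lower": TruncNormMargin(0.06, 0.19, -1.0, 1.0),
        "nmf_upper": TruncNormMargin(0.00, 0.19, -1.0, 1.0),
        "nmf_apex": TruncNormMargin(0.20, 0.29, -1.0, 1.0),
        "nmf_lower": TruncNormMargin(0.04, 0.25, -1.0, 1.0),
        "nes_curve": TruncNormMargin(0.11, 0.20, -1.0, 1.0),
        "nmf_curve": TruncNormMargin(0.11, 0.22, -1.0, 1.0),
    }
    progressive = {
        "age": TruncNormMargin(11.5, 1.3, 10.0, 18.0),
        "sex": BernoulliMargin(31 / 40),          # 31 F / 9 M
        "risser": DiscreteMargin.from_moments((0, 1, 2), 0.2, 0.5),
        "tk": TruncNormMargin(41.4, 11.5, 0.0, 90.0),
        "ll": TruncNormMargin(58.5, 9.9, 20.0, 90.0),
        "ss": TruncNormMargin(39.6, 5.4, 10.0, 70.0),
        "pi": TruncNormMargin(46.9, 7.5, 20.0, 85.0),
        "n_curves": DiscreteMargin.from_moments((1, 2, 3), 1.6, 0.5),
        "cobb": TruncNormMargin(15.9, 5.1, 10.0, 25.0),
        "curve_sagittal_angle": TruncNormMargin(16.4, 11.7),
        "largest_axial_rotation": TruncNormMargin(8.3, 5.0, 0.0, np.inf),
        "lenke_type": CategoricalMargin((1, 2, 3, 4, 5, 6), (13, 0, 9, 0, 5, 13)),
        "f_lat_upper": TruncNormMargin(35.0, 21.4, 0.0, np.inf),
        "f_lat_apex": TruncNormMargin(14.2, 11.6, 0.0, np.inf),
        "f_lat_lower": TruncNormMargin(37.9, 20.2, 0.0, np.inf),
        "nes_upper": TruncNormMargin(0.09, 0.19, -1.0, 1.0),
        "nes_apex": TruncNormMargin(0.10, 0.20, -1.0, 1.0),
        "nes_lower": TruncNormMargin(0.06, 0.18, -1.0, 1.0),
        "nmf_upper": TruncNormMargin(0.02, 0.11, -1.0, 1.0),
        "nmf_apex": TruncNormMargin(0.14, 0.22, -1.0, 1.0),
        "nmf_lower": TruncNormMargin(-0.03, 0.25, -1.0, 1.0),
        "nes_curve": TruncNormMargin(0.08, 0.19, -1.0, 1.0),
        "nmf_curve": TruncNormMargin(0.07, 0.18, -1.0, 1.0),
    }
    return {"stable": stable, "progressive": progressive}


# Rank (Spearman) correlation targets.  Only the strong, published couplings
# are non-zero by default: skeletal maturity tracks age, and the lateral
# shear at the curve end/apex levels tracks the Cobb angle.
DEFAULT_RANK_CORRELATIONS = {
    ("age", "risser"): 0.6,
    ("cobb", "f_lat_upper"): 0.63,
    ("cobb", "f_lat_apex"): 0.29,
    ("cobb", "f_lat_lower"): 0.67,
}

# Correlation of each biomechanical predictor with the Cobb angle, used as
# the loading target of the redundant (geometry/size-driven) coupling.
COBB_CORR_TARGETS = {
    "f_lat_upper": 0.63, "f_lat_apex": 0.29, "f_lat_lower": 0.67,
    "nes_upper": -0.01, "nes_apex": 0.01, "nes_lower": 0.02,
    "nmf_upper": 0.12, "nmf_apex": 0.36, "nmf_lower": 0.11,
    "nes_curve": 0.02, "nmf_curve": 0.3,
}


@dataclass(frozen=True)
class BiomechCoupling:
    """Group-independent linear mechanism for one biomechanical predictor:
    value = clip(alpha + b*cobb + c*age + sigma*eps, lo, hi)."""

    alpha: float
    b_cobb: float
    c_age: float
    sigma: float
    lo: float
    hi: float

    def realize(self, cobb, age, eps):
        raw = self.alpha + self.b_cobb * cobb + self.c_age * age + self.sigma * eps
        return np.clip(raw, self.lo, self.hi)


def _margin_moments(margin: TruncNormMargin):
    """Achieved mean/SD of a moment-matched truncated-normal margin."""
    mu, sigma = solve_truncnorm_params(margin.mean, margin.sd, margin.lo, margin.hi)
    a, b = (margin.lo - mu) / sigma, (margin.hi - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def solve_biomech_coupling(margins: dict, n_calib: int = 200000,
                           calib_seed: int = 12345) -> dict:
    """Coefficients of the redundant biomechanical mechanism.

    The biomechanical predictors of the upright-posture simulation reflect
    curve severity and body size, so they are modelled as group-independent
    linear functions of the Cobb angle and age plus noise: the slope on
    Cobb is set by the published Cobb correlation, and the intercept and
    age slope are solved (by Monte-Carlo moment matching on the bounded,
    clipped value) so that the per-group means reproduce the published
    group statistics exactly.  The noise SD is group-independent, so the
    biomechanical block carries no outcome information beyond what the
    anthropometric and geometrical predictors already contain.
    """
    rng = np.random.default_rng(calib_seed)
    samples = {}
    for grp in ("stable", "progressive"):
        u = rng.random((n_calib, 2))
        samples[grp] = {
            "cobb": margins[grp]["cobb"].ppf(u[:, 0]),
            "age": margins[grp]["age"].ppf(u[:, 1]),
            "eps": rng.standard_normal(n_calib),
        }
    s_cobb = np.mean([_margin_moments(margins[g]["cobb"])[1]
                      for g in ("stable", "progressive")])
    s_age = {g: _margin_moments(margins[g]["age"])[1]
             for g in ("stable", "progressive")}
    m_cobb = {g: _margin_moments(margins[g]["cobb"])[0]
              for g in ("stable", "progressive")}
    m_age = {g: _margin_moments(margins[g]["age"])[0]
             for g in ("stable", "progressive")}

    couplings = {}
    for col in BIOMECH_COLUMNS:
        tgt = {g: margins[g][col] for g in ("stable", "progressive")}
        lo, hi = tgt["stable"].lo, tgt["stable"].hi
        s_mean = 0.5 * (tgt["stable"].sd + tgt["progressive"].sd)
        b = COBB_CORR_TARGETS.get(col, 0.0) * s_mean / s_cobb
        # first-pass age slope from the unclipped mean difference
        dm = tgt["stable"].mean - tgt["progressive"].mean
        dcobb = m_cobb["stable"] - m_cobb["progressive"]
        dage = m_age["stable"] - m_age["progressive"]
        c0 = (dm - b * dcobb) / dage
        resid = [max(tgt[g].sd ** 2 - (b * _margin_moments(margins[g]["cobb"])[1]) ** 2
                     - (c0 * s_age[g]) ** 2, (0.1 * s_mean) ** 2)
                 for g in ("stable", "progressive")]
        sigma = float(np.sqrt(np.mean(resid)))
        if lo == 0.0:            # keep clipping mild for non-negative loads
            sigma = min(sigma, min(tgt[g].mean for g in tgt) / 2.0)

        def group_means(params, _b=b, _sig=sigma, _lo=lo, _hi=hi):
            alpha, c = params
            out = []
            for g in ("stable", "progressive"):
                s = samples[g]
                raw = alpha + _b * s["cobb"] + c * s["age"] + _sig * s["eps"]
                out.append(np.mean(np.clip(raw, _lo, _hi)))
            return np.array(out)

        target = np.array([tgt["stable"].mean, tgt["progressive"].mean])
        alpha0 = tgt["stable"].mean - b * m_cobb["stable"] - c0 * m_age["stable"]
        sol = optimize.least_squares(
            lambda p: group_means(p) - target, x0=[alpha0, c0],
            xtol=1e-12, ftol=1e-12)
        couplings[col] = BiomechCoupling(
            alpha=float(sol.x[0]), b_cobb=b, c_age=float(sol.x[1]),
            sigma=sigma, lo=lo, hi=hi)
    return couplings


def default_rank_correlation(columns=FEATURE_COLUMNS, overrides=None) -> np.ndarray:
    """Target rank-correlation matrix over the predictor columns."""
    pairs = dict(DEFAULT_RANK_CORRELATIONS)
    if overrides:
        for (a, b), r in overrides.items():
            pairs[(a, b)] = r
    n = len(columns)
    R = np.eye(n)
    index = {c: i for i, c in enumerate(columns)}
    for (a, b), r in pairs.items():
        if a in index and b in index:
            i, j = index[a], index[b]
            R[i, j] = R[j, i] = r
    return R
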