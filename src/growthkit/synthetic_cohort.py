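"""Synthetic pediatric cohort generator with a planted obesity effect.

Emulates the statistical structure the analysis pipeline assumes: a mixed
cross-sectional/longitudinal cohort ages 0-18 with normal-weight and obese
strata, reference-anchored height trajectories, an obesity height-offset
curve D(t) planted in centimetres (rise in early childhood to a maximum
D_max at age A_max, plateau, pubertal catch-down calibrated so the obese
stratum's mean growth velocity in the pubertal window is a fixed fraction
of the normal stratum's, and near-convergence of final height),
cross-lagged BMI-height dynamics gamma(t) operating on within-stratum BMI
deviations, and endocrine age profiles with stratum multipliers.

The synthetic reference set (`default_reference`) plays the role of
national growth references: height-for-age with L=1 and S=0.042 around a
monotone median curve, a velocity-for-age reference equal to the median
curve's derivative with SD 1 cm/y, a BMI-for-age reference under which the
generator's latent BMI SDS is recovered exactly, and linear-in-gestational-
age birth-size references.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm, truncnorm

from .reference_engine import (
    BIRTH_LENGTH, BIRTH_WEIGHT, BMI, HEIGHT, VELOCITY,
    ReferenceSet, ReferenceTable, SEXES,
)

logger = logging.getLogger("growthkit")

NORMAL, OBESE = "normal", "obese"
UNDERWEIGHT, OVERWEIGHT = "underweight", "overweight"


# ---------------------------------------------------------------------------
# synthetic reference set
# ---------------------------------------------------------------------------

_HEIGHT_KNOTS = {
    "male": [(0, 50.0), (1, 76.0), (2, 88.0), (4, 104.0), (6, 116.0),
             (8, 128.0), (10, 139.0), (12, 149.0), (14, 163.0), (16, 174.0),
             (18, 177.0)],
    "female": [(0, 49.5), (1, 74.5), (2, 86.5), (4, 103.0), (6, 115.5),
               (8, 128.0), (10, 139.0), (12, 152.0), (14, 160.0),
               (16, 163.5), (18, 164.0)],
}

_BMI_KNOTS = {
    "male": [(0, 13.4), (0.75, 17.2), (2, 16.2), (4, 15.8), (6, 15.6),
             (8, 16.2), (10, 17.2), (12, 18.3), (14, 19.5), (16, 20.6),
             (18, 21.5)],
    "female": [(0, 13.3), (0.75, 16.9), (2, 16.0), (4, 15.6), (6, 15.5),
               (8, 16.2), (10, 17.3), (12, 18.6), (14, 19.8), (16, 20.6),
               (18, 21.3)],
}

HEIGHT_S = 0.042        # coefficient of variation of height-for-age
BMI_S = 0.11
VELOCITY_SD = 1.0       # cm/y, constant across age
_AGE_GRID = np.round(np.arange(0.0, 18.0 + 1e-9, 0.1), 10)


def _height_median(sex: str) -> PchipInterpolator:
    knots = _HEIGHT_KNOTS[sex]
    return PchipInterpolator([k[0] for k in knots], [k[1] for k in knots])


def default_reference() -> ReferenceSet:
    """Synthetic LMS reference set (height, BMI, velocity, birth size).

    Height: L=1, S=0.042, median by monotone cubic interpolation through
    sex-specific knots, tabulated every 0.1 y (so the package's linear
    table interpolation reproduces the smooth curve to <0.01 cm).
    Velocity: median = d(height median)/dt, SD 1 cm/y (S = 1/M), L=1.
    BMI: L=1, S=0.11 around a plausible median curve, so the generator's
    latent BMI SDS round-trips exactly. Birth size: linear in gestational
    age, SD 2 cm / 450 g.
    """
    rows = []
    for sex in SEXES:
        m = _height_median(sex)
        M = m(_AGE_GRID)
        rows.append(pd.DataFrame({
            "measure": HEIGHT, "sex": sex, "age": _AGE_GRID,
            "L": 1.0, "M": M, "S": HEIGHT_S, "units": "cm"}))
        Mv = np.maximum(m.derivative()(_AGE_GRID), 0.1)
        rows.append(pd.DataFrame({
            "measure": VELOCITY, "sex": sex, "age": _AGE_GRID,
            "L": 1.0, "M": Mv, "S": VELOCITY_SD / Mv, "units": "cm/y"}))
        knots = _BMI_KNOTS[sex]
        bm = PchipInterpolator([k[0] for k in knots], [k[1] for k in knots])
        rows.append(pd.DataFrame({
            "measure": BMI, "sex": sex, "age": _AGE_GRID,
            "L": 1.0, "M": bm(_AGE_GRID), "S": BMI_S, "units": "kg/m2"}))
        ga = np.arange(24.0, 43.0 + 1e-9, 0.5)
        Ml = 50.0 + 0.9 * (ga - 40.0)
        Mw = 3400.0 + 170.0 * (ga - 40.0)
        rows.append(pd.DataFrame({
            "measure": BIRTH_LENGTH, "sex": sex, "age": ga,
            "L": 1.0, "M": Ml, "S": 2.0 / Ml, "units": "cm"}))
        rows.append(pd.DataFrame({
            "measure": BIRTH_WEIGHT, "sex": sex, "age": ga,
            "L": 1.0, "M": Mw, "S": 450.0 / Mw, "units": "g"}))
    df = pd.concat(rows, ignore_index=True)
    tables = []
    for measure, sub in df.groupby("measure", sort=False):
        tables.append(ReferenceTable(
            measure=str(measure),
            records=sub[["sex", "age", "L", "M", "S"]].reset_index(drop=True),
            units=str(sub["units"].iloc[0])))
    return ReferenceSet(tables)


# ---------------------------------------------------------------------------
# planted effect profile
# ---------------------------------------------------------------------------

def _default_cross_lag():
    # (age, gamma): peak +0.18/SDS at age 1, zero crossing near 10-11,
    # trough -0.10 at boys 14 / girls 11, fading to 0 by late adolescence
    return {
        "male": [(0.5, 0.18), (1.0, 0.18), (10.75, 0.0), (14.0, -0.10),
                 (17.0, 0.0)],
        "female": [(0.5, 0.18), (1.0, 0.18), (10.25, 0.0), (11.0, -0.10),
                   (16.0, 0.0)],
    }


@dataclass
class EffectProfile:
    """The planted obesity effect: height offset curve, pubertal velocity
    blunting, cross-lag coefficients and endocrine multipliers.

    With all offsets 0, ratios 1 and multipliers 1 (``EffectProfile.null()``)
    the generator is an exact A/A null.
    """
    birth_length_offset: dict = field(
        default_factory=lambda: {"male": 0.5, "female": 0.5})  # cm
    d_max: dict = field(
        default_factory=lambda: {"male": 6.8, "female": 7.6})  # cm
    a_max: dict = field(
        default_factory=lambda: {"male": 6.0, "female": 8.0})  # years
    delta_v_peak: float = 1.2        # cm/y excess velocity plateau
    ramp_start: float = 0.5          # years
    preferred_ramp: float = 1.0      # years; shortened if infeasible
    decline_start: float = 11.0      # years
    convergence_age: float = 17.0
    convergence_residual: float = 0.3  # cm left at convergence_age (<= 0.5)
    pubertal_window: dict = field(
        default_factory=lambda: {"male": (13, 14), "female": (12, 13)})
    pubertal_velocity_ratio: dict = field(
        default_factory=lambda: {"male": 0.75, "female": 0.78})
    cross_lag: dict = field(default_factory=_default_cross_lag)
    igf1_prepubertal: float = 1.10
    igf1_prepubertal_window: tuple = (6, 9)   # age-group labels
    igf1_pubertal: float = 0.83               # applied in pubertal_window
    testosterone_pubertal: float = 0.38       # boys, pubertal_window
    testosterone_recovery: float = 0.9        # by convergence_age
    testosterone_girls: float = 1.3           # obese girls, age >= 10
    estradiol_late: float = 0.63
    estradiol_window: tuple = (15, 16)        # girls, age-group labels
    insulin_obese: float = 2.5
    leptin_obese: float = 4.0

    @classmethod
    def null(cls) -> "EffectProfile":
        """Exact A/A profile: no offsets, ratios 1, multipliers 1, gamma 0."""
        zero_cl = {sx: [(a, 0.0) for a, _ in pts]
                   for sx, pts in _default_cross_lag().items()}
        return cls(
            birth_length_offset={"male": 0.0, "female": 0.0},
            d_max={"male": 0.0, "female": 0.0},
            delta_v_peak=0.0,
            convergence_residual=0.0,
            pubertal_velocity_ratio={"male": 1.0, "female": 1.0},
            cross_lag=zero_cl,
            igf1_prepubertal=1.0, igf1_pubertal=1.0,
            testosterone_pubertal=1.0, testosterone_recovery=1.0,
            testosterone_girls=1.0,
            estradiol_late=1.0, insulin_obese=1.0, leptin_obese=1.0,
        )

    def gamma(self, sex: str, age):
        """Cross-lag coefficient gamma(age): height-SDS change next year per
        within-stratum BMI SDS deviation."""
        pts = self.cross_lag[sex]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        out = np.interp(np.asarray(age, dtype=float), xs, ys)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pubertal_window"] = {k: list(v) for k, v in
                                d["pubertal_window"].items()}
        d["cross_lag"] = {k: [list(p) for p in v]
                          for k, v in d["cross_lag"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectProfile":
        d = dict(d)
        if "pubertal_window" in d:
            d["pubertal_window"] = {k: tuple(v) for k, v in
                                    d["pubertal_window"].items()}
        if "cross_lag" in d:
            d["cross_lag"] = {k: [tuple(p) for p in v]
                              for k, v in d["cross_lag"].items()}
        for key in ("igf1_prepubertal_window", "estradiol_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def window_span(window: tuple) -> tuple[float, float]:
    """Age span covered by a pair of age-group labels: [w0-0.5, w1+0.5)."""
    w0, w1 = window
    return (w0 - 0.5, w1 + 0.5)


# ---------------------------------------------------------------------------
# obesity height-offset curve
# ---------------------------------------------------------------------------

class InfeasibleProfileError(ValueError):
    """Planted-offset constraints cannot all hold (D_max unreachable)."""


@dataclass
class OffsetCurve:
    """D(t): obese-minus-normal mean height offset in cm, with its rate
    dv(t) = D'(t) (the planted excess velocity in cm/y)."""
    sex: str
    grid: np.ndarray
    d_values: np.ndarray
    dv_values: np.ndarray
    meta: dict = field(default_factory=dict)

    def d(self, age):
        out = np.interp(np.asarray(age, dtype=float), self.grid, self.d_values)
        return out if out.ndim else float(out)

    def dv(self, age):
        out = np.interp(np.asarray(age, dtype=float), self.grid,
                        self.dv_values)
        return out if out.ndim else float(out)


def _cos_rise(t, t0, t1):
    """0 -> 1 smoothly on [t0, t1]."""
    x = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def build_obese_offset_curve(profile: EffectProfile, sex: str,
                             references: ReferenceSet) -> OffsetCurve:
    """Construct the planted cm offset D(t) for the obese stratum.

    Shape: D(0) = birth offset; excess velocity ramps up from
    ``ramp_start``, holds a plateau at ``delta_v_peak`` and ramps down so
    that D(A_max) = D_max (ramp lengths solved; infeasible combinations
    raise with the attainable maximum); D is flat to ``decline_start``;
    the pubertal decline is a two-component smooth bump solved so that the
    obese stratum's mean velocity over the pubertal window is
    ``pubertal_velocity_ratio`` times the normal stratum's and
    D(convergence_age) equals the convergence residual.
    """
    d0 = float(profile.birth_length_offset[sex])
    d_max = float(profile.d_max[sex])
    a_max = float(profile.a_max[sex])
    vpeak = float(profile.delta_v_peak)
    rs = float(profile.ramp_start)
    ds = float(profile.decline_start)
    ca = float(profile.convergence_age)
    ratio = float(profile.pubertal_velocity_ratio[sex])
    residual = float(profile.convergence_residual)

    grid = np.arange(0.0, 18.0 + 1e-9, 0.005)
    dv = np.zeros_like(grid)
    meta = {"sex": sex}

    if abs(d_max) < 1e-12 and abs(d0) < 1e-12:
        return OffsetCurve(sex, grid, np.zeros_like(grid), dv,
                           {"null": True, "sex": sex})

    if vpeak <= 0 and d_max > d0 + 1e-12:
        raise InfeasibleProfileError(
            f"D_max={d_max} unreachable with delta_v_peak={vpeak}")

    # --- rise phase: solve trapezoid/triangle so D(a_max) = d_max ---------
    q = (d_max - d0) / vpeak if vpeak > 0 else 0.0
    attainable = d0 + vpeak * (a_max - rs)
    if q > (a_max - rs) + 1e-9:
        raise InfeasibleProfileError(
            f"D_max={d_max} cm by age {a_max} exceeds the attainable maximum "
            f"{attainable:.2f} cm for delta_v_peak={vpeak} cm/y")
    d_up = float(profile.preferred_ramp)
    t_e = 2.0 * q + d_up + 2.0 * rs - a_max
    if t_e > a_max:
        d_up = 2.0 * (a_max - rs - q)
        t_e = a_max
    if t_e < rs + d_up - 1e-9:
        # small D_max: triangular profile with a lower peak
        v_star = 2.0 * vpeak * q / (a_max - rs)
        mid = 0.5 * (rs + a_max)
        up = _cos_rise(grid, rs, mid)
        down = 1.0 - _cos_rise(grid, mid, a_max)
        dv = np.where(grid < mid, v_star * up, v_star * down)
        dv[grid < rs] = 0.0
        dv[grid >= a_max] = 0.0
        meta["shape"] = "triangle"
        meta["v_star"] = v_star
    else:
        up = _cos_rise(grid, rs, rs + d_up)
        dv = vpeak * up
        if a_max > t_e:
            down = 1.0 - _cos_rise(grid, t_e, a_max)
            dv = np.where(grid > t_e, vpeak * down, dv)
        dv[grid < rs] = 0.0
        dv[grid >= a_max] = 0.0
        meta["shape"] = "trapezoid"
        meta["ramp_up"] = d_up
        meta["plateau_end"] = t_e

    # --- pubertal decline -------------------------------------------------
    # The velocity-blunting constraint is planted per age group of the
    # pubertal window (the analysis averages per-group percent reductions):
    # one smooth bump per window group plus a wide parabola, solved so that
    # the obese mean velocity over each group's age span equals
    # ratio * (normal mean velocity there) and the total decline area
    # brings D down to the convergence residual.
    if ratio < 1.0 or d_max - residual > 1e-12:
        w0, w1 = profile.pubertal_window[sex]
        groups = list(range(int(w0), int(w1) + 1))
        in_dec = (grid >= ds) & (grid <= ca)
        vel_ref = references[VELOCITY]

        def _bump(center, half_width):
            lo = max(ds, center - half_width)
            hi = min(ca, center + half_width)
            up = _cos_rise(grid, lo, center)
            down = 1.0 - _cos_rise(grid, center, hi)
            b = np.where(grid < center, up, down)
            return np.where((grid >= lo) & (grid <= hi) & in_dec, b, 0.0)

        basis = [_bump(float(g), 2.0) for g in groups]
        basis.append(np.where(
            in_dec, (grid - ds) * (ca - grid) * 4.0 / (ca - ds) ** 2, 0.0))
        k = len(basis)

        def _interval_avg(values):
            # what a velocity record centred at t measures: the mean of the
            # curve over a one-year visit interval [t-0.5, t+0.5]
            anti = np.concatenate(([0.0], np.cumsum(
                0.5 * (values[1:] + values[:-1]) * np.diff(grid))))
            return (np.interp(grid + 0.5, grid, anti)
                    - np.interp(grid - 0.5, grid, anti))

        rows, targets = [], []
        rows.append([float(np.trapezoid(b, grid)) for b in basis])
        targets.append(d_max - residual)           # total decline area
        spans = {}
        smoothed = [_interval_avg(b) for b in basis]
        for g in groups:
            span = (grid >= g - 0.5) & (grid <= g + 0.5)
            _, mv, _ = vel_ref.interpolate(
                sex, np.clip(grid, *vel_ref.age_range(sex)))
            mv_smooth = _interval_avg(mv)
            mean_vn = float(np.mean(mv_smooth[span]))
            spans[g] = mean_vn
            rows.append([float(np.mean(b[span])) for b in smoothed])
            targets.append((1.0 - ratio) * mean_vn)
        if ratio >= 1.0:
            coef = np.zeros(k)
            coef[-1] = targets[0] / rows[0][-1]
        else:
            A = np.array(rows)
            coef, *_ = np.linalg.lstsq(A, np.array(targets), rcond=None)
            if A.shape[0] == A.shape[1]:
                coef = np.linalg.solve(A, np.array(targets))
        decline = sum(c * b for c, b in zip(coef, basis))
        dv = dv - decline
        meta["decline"] = {"coefficients": [float(c) for c in coef],
                           "group_mean_vn": spans,
                           "window_groups": groups}

    d_values = d0 + np.concatenate(
        ([0.0], np.cumsum(0.5 * (dv[1:] + dv[:-1]) * np.diff(grid))))
    curve = OffsetCurve(sex, grid, d_values, dv, meta)

    achieved = curve.d(a_max)
    if abs(achieved - d_max) > 0.02:
        raise InfeasibleProfileError(
            f"offset construction failed: D({a_max}) = {achieved:.3f} "
            f"!= {d_max}")
    return curve


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

_BMI_STRATA = {
    # stratum: (mean, sd, lower, upper) of the truncated-normal BMI SDS
    NORMAL: (0.0, 0.65, -1.28, 1.28),
    OBESE: (2.4, 0.35, 1.88, 5.0),
    UNDERWEIGHT: (-1.7, 0.3, -3.2, -1.28),
    OVERWEIGHT: (1.55, 0.17, 1.28, 1.88),
}


@dataclass
class GeneratorConfig:
    """Cohort shape, noise levels and the random seed.

    The visit schedule mimics a registry: first visit uniform in
    ``first_visit_age``, then roughly annual visits (jitter +/-0.15 y) with
    per-visit retention 0.8 until age 18.
    """
    n_normal: int = 1000
    n_obese: int = 1000
    n_underweight: int = 0
    n_overweight: int = 0
    seed: int = 0
    first_visit_age: tuple = (0.5, 4.0)
    max_age: float = 18.0
    visit_jitter: float = 0.15
    retention: float = 0.8
    premature_fraction: float = 0.08
    premature_ga: tuple = (32.0, 37.0)
    term_ga: tuple = (38.0, 42.0)
    intercept_sd: float = 0.95        # SDS, between-child height intercept
    latent_reversion: float = 0.92    # per-year AR coefficient of the wiggle
    # innovation sized so the annual velocity noise (~2*s_w^2*(1-rho) in SDS,
    # times M*S in cm) matches the velocity reference SD of 1 cm/y
    latent_innovation_sd: float = 0.15  # SDS per sqrt(year)
    measurement_error_cm: float = 0.3
    bmi_ar: float = 0.9               # per-year persistence of the BMI path
    analyte_cv: float = 0.35
    include_analytes: bool = True
    analyte_min_age: float = 5.0
    parental_coupling: float = 0.5    # parent SDS loading on child intercept
    parental_sd: float = 0.7

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("first_visit_age", "premature_ga", "term_ga"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("first_visit_age", "premature_ga", "term_ga"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# analyte curves
# ---------------------------------------------------------------------------

ANALYTE_UNITS = {
    "igf1": "ng/mL", "igfbp3": "ug/mL", "testosterone": "nmol/L",
    "estradiol": "pmol/L", "insulin": "pmol/L", "glucose": "mmol/L",
    "leptin": "ug/L",
}

_ANALYTE_CURVES: dict[tuple[str, str], Callable] = {}


def _pchip_curve(knots):
    interp = PchipInterpolator([k[0] for k in knots], [k[1] for k in knots])
    return lambda age: interp(np.clip(age, knots[0][0], knots[-1][0]))


def _logistic(lo, hi, midpoint, scale):
    return lambda age: lo + (hi - lo) / (1.0 + np.exp(-(np.asarray(age, float)
                                                        - midpoint) / scale))


def _init_curves():
    c = _ANALYTE_CURVES
    c[("igf1", "male")] = _pchip_curve(
        [(0, 30), (5, 150), (10, 250), (12, 340), (13.5, 380), (15, 350),
         (17, 300), (18, 290)])
    c[("igf1", "female")] = _pchip_curve(
        [(0, 35), (5, 160), (10, 290), (11.5, 390), (12.5, 420), (14, 380),
         (16, 320), (18, 300)])
    for sx in SEXES:
        c[("igfbp3", sx)] = _pchip_curve(
            [(0, 1.8), (5, 3.5), (10, 4.5), (13, 5.2), (16, 5.4), (18, 5.3)])
        c[("insulin", sx)] = _pchip_curve(
            [(0, 25), (5, 35), (8, 45), (11, 65), (13, 80), (15, 75),
             (18, 60)])
        c[("glucose", sx)] = lambda age: np.full_like(
            np.asarray(age, float), 4.8)
    c[("testosterone", "male")] = _logistic(0.5, 18.0, 13.5, 0.8)
    c[("testosterone", "female")] = _logistic(0.7, 1.2, 12.0, 1.0)
    c[("estradiol", "female")] = _logistic(20.0, 350.0, 12.5, 0.9)
    c[("estradiol", "male")] = _logistic(30.0, 60.0, 14.0, 1.0)
    c[("leptin", "male")] = _pchip_curve(
        [(0, 3.0), (5, 2.5), (10, 3.5), (13, 3.0), (18, 2.5)])
    c[("leptin", "female")] = _pchip_curve(
        [(0, 3.0), (5, 3.5), (10, 6.0), (14, 9.0), (18, 11.0)])


_init_curves()


def analyte_mean(analyte: str, sex: str, age):
    """Reference (normal-weight) mean serum level by sex and age."""
    return _ANALYTE_CURVES[(analyte, sex)](np.asarray(age, dtype=float))


def analyte_multiplier(profile: EffectProfile, analyte: str, sex: str, age,
                       stratum):
    """Obese-stratum multiplier on the analyte mean (1 elsewhere)."""
    age = np.asarray(age, dtype=float)
    stratum = np.asarray(stratum)
    mult = np.ones_like(age)
    ob = stratum == OBESE
    if not ob.any():
        return mult
    pw_lo, pw_hi = window_span(profile.pubertal_window[sex])
    if analyte == "igf1":
        pre_lo, pre_hi = window_span(profile.igf1_prepubertal_window)
        mult = np.where(ob & (age >= pre_lo) & (age < pre_hi),
                        profile.igf1_prepubertal, mult)
        mult = np.where(ob & (age >= pw_lo) & (age < pw_hi),
                        profile.igf1_pubertal, mult)
    elif analyte == "testosterone" and sex == "male":
        mult = np.where(ob & (age >= pw_lo) & (age < pw_hi),
                        profile.testosterone_pubertal, mult)
        rec = (age - pw_hi) / max(profile.convergence_age - pw_hi, 1e-9)
        rec_mult = (profile.testosterone_pubertal
                    + np.clip(rec, 0, 1) * (profile.testosterone_recovery
                                            - profile.testosterone_pubertal))
        mult = np.where(ob & (age >= pw_hi), rec_mult, mult)
    elif analyte == "testosterone" and sex == "female":
        mult = np.where(ob & (age >= 10.0), profile.testosterone_girls, mult)
    elif analyte == "estradiol" and sex == "female":
        e_lo, e_hi = window_span(profile.estradiol_window)
        mult = np.where(ob & (age >= e_lo) & (age < e_hi),
                        profile.estradiol_late, mult)
    elif analyte == "insulin":
        mult = np.where(ob, profile.insulin_obese, mult)
    elif analyte == "leptin":
        mult = np.where(ob, profile.leptin_obese, mult)
    elif analyte == "glucose":
        mult = np.where(ob, 1.05, mult)
    return mult


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Generated tables plus provenance (seed, profile, config)."""
    children: pd.DataFrame
    observations: pd.DataFrame
    analytes: pd.DataFrame
    provenance: dict

    def write(self, outdir):
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.children.to_csv(out / "children.csv", index=False,
                             float_format=fmt)
        self.observations.to_csv(out / "observations.csv", index=False,
                                 float_format=fmt)
        self.analytes.to_csv(out / "analytes.csv", index=False,
                             float_format=fmt)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        return out


def _truncated_bmi(z_std, stratum_arr):
    """Map standard-normal latents to truncated-normal BMI SDS per stratum."""
    out = np.empty_like(z_std)
    u = norm.cdf(z_std)
    for stratum, (mu, sd, lo, hi) in _BMI_STRATA.items():
        m = stratum_arr == stratum
        if not np.any(m):
            continue
        a, b = (lo - mu) / sd, (hi - mu) / sd
        out[m] = truncnorm.ppf(np.clip(u[m], 1e-12, 1 - 1e-12), a, b,
                               loc=mu, scale=sd)
    return out


def _stratum_bmi_mean(stratum_arr):
    out = np.empty(stratum_arr.shape)
    for stratum, (mu, sd, lo, hi) in _BMI_STRATA.items():
        m = stratum_arr == stratum
        if np.any(m):
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[m] = truncnorm.mean(a, b, loc=mu, scale=sd)
    return out


def generate_cohort(config: GeneratorConfig,
                    profile: EffectProfile | None = None,
                    references: ReferenceSet | None = None) -> Cohort:
    """Simulate children.csv / observations.csv / analytes.csv tables.

    Per child: sex ~ Bernoulli(0.5); a latent height-SDS intercept u;
    an Ornstein-Uhlenbeck wiggle around u (reversion ``latent_reversion``
    per year, stationary SD ~0.5 SDS) carrying the cross-lag kick
    gamma(t) * (BMI SDS - stratum mean) * dt; a truncated-normal AR BMI-SDS
    path per stratum.  Heights are emitted through the height reference
    (L=1), plus the obese offset D(t) in cm and measurement error.
    Analytes come from sex/age mean curves x stratum multipliers x
    mean-preserving log-normal noise.
    """
    profile = profile if profile is not None else EffectProfile()
    refs = references if references is not None else default_reference()
    rng = np.random.default_rng(config.seed)

    strata = ([NORMAL] * config.n_normal + [OBESE] * config.n_obese
              + [UNDERWEIGHT] * config.n_underweight
              + [OVERWEIGHT] * config.n_overweight)
    n = len(strata)
    if n == 0:
        empty_children = pd.DataFrame(columns=[
            "child_id", "sex", "stratum", "gestational_age_weeks",
            "birth_length_cm", "birth_weight_g", "mother_height_cm",
            "father_height_cm", "flags"])
        empty_obs = pd.DataFrame(columns=[
            "child_id", "age_years", "height_cm", "weight_kg"])
        empty_ana = pd.DataFrame(columns=[
            "child_id", "age_years", "analyte", "value", "units"])
        return Cohort(empty_children, empty_obs, empty_ana,
                      {"seed": config.seed, "n_children": 0})
    stratum_arr = np.array(strata)
    child_id = np.array([f"C{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    u = rng.normal(0.0, config.intercept_sd, n)

    premature = rng.random(n) < config.premature_fraction
    ga = np.where(premature,
                  rng.uniform(*config.premature_ga, n),
                  rng.uniform(*config.term_ga, n))

    bl_sds = 0.3 * u / max(config.intercept_sd, 1e-9) + rng.normal(0, 0.95, n)
    bw_sds = 0.6 * bl_sds + rng.normal(0, 0.8, n)
    obese = stratum_arr == OBESE
    offset_cm = np.array([profile.birth_length_offset[s] for s in sex])
    birth_length = refs[BIRTH_LENGTH].value(sex, ga, bl_sds) \
        + np.where(obese, offset_cm, 0.0)
    birth_weight = refs[BIRTH_WEIGHT].value(sex, ga, bw_sds)

    height_ref = refs[HEIGHT]
    adult_age = {sx: height_ref.age_range(sx)[1] for sx in SEXES}
    mother_sds = config.parental_coupling * u + rng.normal(
        0, config.parental_sd, n)
    father_sds = config.parental_coupling * u + rng.normal(
        0, config.parental_sd, n)
    mother_cm = height_ref.value(np.full(n, "female"),
                                 np.full(n, adult_age["female"]), mother_sds)
    father_cm = height_ref.value(np.full(n, "male"),
                                 np.full(n, adult_age["male"]), father_sds)

    children = pd.DataFrame({
        "child_id": child_id, "sex": sex, "stratum": stratum_arr,
        "gestational_age_weeks": ga,
        "birth_length_cm": birth_length, "birth_weight_g": birth_weight,
        "mother_height_cm": mother_cm, "father_height_cm": father_cm,
        "flags": "",
    })

    # --- visit schedule ---------------------------------------------------
    lo, hi = config.first_visit_age
    k_max = int(np.ceil(config.max_age - lo)) + 1
    increments = 1.0 + rng.uniform(-config.visit_jitter, config.visit_jitter,
                                   (n, k_max - 1))
    ages = np.empty((n, k_max))
    ages[:, 0] = rng.uniform(lo, hi, n)
    ages[:, 1:] = increments
    ages = np.cumsum(ages, axis=1)
    kept = rng.random((n, k_max)) < config.retention
    kept[:, 0] = True
    visit_mask = kept & (ages <= config.max_age)

    # --- latent BMI path --------------------------------------------------
    z = np.empty((n, k_max))
    z[:, 0] = rng.normal(0, 1, n)
    dt = np.diff(ages, axis=1)
    rho_b = config.bmi_ar ** dt
    innov_b = rng.normal(0, 1, (n, k_max - 1))
    for k in range(1, k_max):
        z[:, k] = rho_b[:, k - 1] * z[:, k - 1] \
            + np.sqrt(1 - rho_b[:, k - 1] ** 2) * innov_b[:, k - 1]
    stratum_mat = np.repeat(stratum_arr[:, None], k_max, axis=1)
    bmi_sds = _truncated_bmi(z.ravel(), stratum_mat.ravel()).reshape(n, k_max)
    bmi_dev = bmi_sds - _stratum_bmi_mean(stratum_mat.ravel()).reshape(n, k_max)

    # --- latent height path (OU wiggle + cross-lag kick) ------------------
    rho_w = config.latent_reversion
    s_w = config.latent_innovation_sd / np.sqrt(max(1 - rho_w ** 2, 1e-9))
    w = np.empty((n, k_max))
    w[:, 0] = rng.normal(0, s_w, n)
    innov_w = rng.normal(0, 1, (n, k_max - 1))
    gamma_by_sex = {sx: profile.gamma(sx, ages[:, :-1][sex == sx])
                    for sx in SEXES}
    gamma_mat = np.zeros((n, k_max - 1))
    for sx in SEXES:
        gamma_mat[sex == sx] = gamma_by_sex[sx]
    for k in range(1, k_max):
        rho_k = rho_w ** dt[:, k - 1]
        kick = gamma_mat[:, k - 1] * bmi_dev[:, k - 1] * dt[:, k - 1]
        w[:, k] = rho_k * w[:, k - 1] + kick \
            + s_w * np.sqrt(1 - rho_k ** 2) * innov_w[:, k - 1]
    h_latent = u[:, None] + w

    # --- emission ---------------------------------------------------------
    curves = {sx: build_obese_offset_curve(profile, sx, refs) for sx in SEXES}
    sex_mat = np.repeat(sex[:, None], k_max, axis=1)
    age_flat = ages.ravel()
    sex_flat = sex_mat.ravel()
    age_clip = np.clip(age_flat, 0.0, 18.0)
    height = height_ref.value(sex_flat, age_clip, h_latent.ravel())
    d_offset = np.zeros_like(height)
    ob_flat = np.repeat(obese[:, None], k_max, axis=1).ravel()
    for sx in SEXES:
        m = ob_flat & (sex_flat == sx)
        if m.any():
            d_offset[m] = curves[sx].d(age_clip[m])
    height = height + d_offset + rng.normal(
        0, config.measurement_error_cm, height.shape)

    bmi_val = refs[BMI].value(sex_flat, age_clip, bmi_sds.ravel())
    weight = bmi_val * (height / 100.0) ** 2

    mask_flat = visit_mask.ravel()
    observations = pd.DataFrame({
        "child_id": np.repeat(child_id, k_max)[mask_flat],
        "age_years": age_flat[mask_flat],
        "height_cm": height[mask_flat],
        "weight_kg": weight[mask_flat],
    }).reset_index(drop=True)

    # --- analytes ---------------------------------------------------------
    if config.include_analytes:
        a_mask = mask_flat & (age_flat >= config.analyte_min_age)
        a_child = np.repeat(child_id, k_max)[a_mask]
        a_age = age_flat[a_mask]
        a_sex = sex_flat[a_mask]
        a_stratum = np.repeat(stratum_arr[:, None], k_max, axis=1).ravel()[a_mask]
        frames = []
        for analyte in ANALYTE_UNITS:
            mean = np.empty_like(a_age)
            mult = np.empty_like(a_age)
            for sx in SEXES:
                m = a_sex == sx
                if not m.any():
                    continue
                mean[m] = analyte_mean(analyte, sx, a_age[m])
                mult[m] = analyte_multiplier(profile, analyte, sx, a_age[m],
                                             a_stratum[m])
            cv = 0.06 if analyte == "glucose" else config.analyte_cv
            sigma = np.sqrt(np.log(1 + cv ** 2))
            noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, a_age.shape))
            frames.append(pd.DataFrame({
                "child_id": a_child, "age_years": a_age,
                "analyte": analyte, "value": mean * mult * noise,
                "units": ANALYTE_UNITS[analyte]}))
        analytes = pd.concat(frames, ignore_index=True)
    else:
        analytes = pd.DataFrame(columns=[
            "child_id", "age_years", "analyte", "value", "units"])

    profile_json = json.dumps(profile.to_dict(), sort_keys=True)
    provenance = {
        "seed": config.seed,
        "n_children": n,
        "n_observations": int(len(observations)),
        "n_analyte_rows": int(len(analytes)),
        "config": config.to_dict(),
        "profile": profile.to_dict(),
        "profile_sha256": hashlib.sha256(profile_json.encode()).hexdigest(),
    }
    logger.info("generated cohort: %d children, %d observations",
                n, len(observations))
    return Cohort(children, observations, analytes, provenance)
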