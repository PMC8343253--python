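"""Smooth LMS curve estimation from cross-sectional measurement-vs-age data.

Fits age curves L(t), M(t), S(t) of the Box-Cox-normal reference model by
penalized maximum likelihood (Cole-Green style): each curve is a cubic
B-spline expansion, the fit maximizes

    sum_i l_i(L(t_i), M(t_i), S(t_i))  -  1/2 sum_c alpha_c Int c''(t)^2 dt

with the per-observation Box-Cox log-likelihood

    l = L ln(x/M) - ln S - z^2 / 2,     z = ((x/M)^L - 1) / (L S).

Optimization alternates penalized Newton (scoring) updates of the three
coefficient vectors with step-halving, which makes the penalized
log-likelihood non-decreasing across iterations.  Smoothness is specified
as target effective degrees of freedom (EDF) per curve, internally
converted to penalty weights.  L and M are linear in the basis; S is
fitted on the log scale to stay positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline

from .reference_engine import (
    GrowthReferenceError, ReferenceTable, sds as lms_sds, value_from_sds,
    z_from_centile,
)

logger = logging.getLogger("growthkit")


class FitError(ValueError):
    """Raised for invalid fitting inputs."""


def loglik_boxcox(x, L, M, S):
    """Per-observation Box-Cox-normal log-likelihood (additive constant
    dropped): ``L*ln(x/M) - ln(S) - z**2/2``."""
    x = np.asarray(x, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise FitError("x, M and S must be positive")
    z = lms_sds(x, L, M, S)
    out = np.asarray(L, dtype=float) * np.log(x / M) - np.log(S) \
        - 0.5 * np.asarray(z) ** 2
    return out if out.ndim else float(out)


@dataclass
class FitConfig:
    """Hyperparameters of the penalized LMS fit.

    ``edf`` are the target effective degrees of freedom for (L, M, S); the
    M curve needs the most flexibility (the height median runs 50 to 180 cm
    over 0-18 y with a steep infancy segment and a pubertal inflection),
    L and S are near-constant for height.  Interior knots sit at empirical
    quantiles of sqrt(age), which places them densely where infant growth
    curves bend hardest.
    """
    n_interior_knots: int = 15
    edf: tuple = (4.0, 14.0, 4.0)       # (L, M, S)
    age_grid_step: float = 0.25
    age_grid: np.ndarray | None = None  # default: data range at the step
    max_iter: int = 200
    tol: float = 1e-7
    min_points: int = 50
    min_distinct_ages: int = 5


@dataclass
class LMSFit:
    """Fitted L(t), M(t), S(t) curves for one sex."""
    sex: str
    age_grid: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    penalized_loglik: float
    loglik: float
    edf: dict
    alphas: dict
    n_obs: int
    converged: bool
    n_iter: int
    knots: np.ndarray = field(default=None, repr=False)
    coefs: dict = field(default_factory=dict, repr=False)

    def curves_at(self, ages):
        """(L, M, S) arrays interpolated onto ``ages``."""
        ages = np.asarray(ages, dtype=float)
        return (np.interp(ages, self.age_grid, self.L),
                np.interp(ages, self.age_grid, self.M),
                np.interp(ages, self.age_grid, self.S))

    def to_reference_records(self, measure: str = "height-for-age"
                             ) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": measure, "sex": self.sex, "age": self.age_grid,
            "L": self.L, "M": self.M, "S": self.S})


# ---------------------------------------------------------------------------
# basis and penalty construction
# ---------------------------------------------------------------------------

def _knot_vector(ages: np.ndarray, n_interior: int) -> np.ndarray:
    # quantile knots on the sqrt(age) scale: denser in infancy where
    # growth curves carry most of their curvature
    lo, hi = float(ages.min()), float(ages.max())
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(np.sqrt(ages), qs) ** 2)
    interior = interior[(interior > lo) & (interior < hi)]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _design(ages: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(ages, knots, 3).toarray()


def _penalty(knots: np.ndarray) -> np.ndarray:
    """Exact integral of products of basis second derivatives.

    Second derivatives of cubic B-splines are piecewise linear, so 2-point
    Gauss-Legendre per knot span integrates their products exactly.
    """
    p = len(knots) - 4
    d2 = BSpline(knots, np.eye(p), 3).derivative(2)
    spans = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    P = np.zeros((p, p))
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for gp in gauss:
            vals = d2(mid + half * gp)            # (p,)
            P += half * np.outer(vals, vals)
    return P


def _edf_to_alpha(BtWB: np.ndarray, P: np.ndarray, target: float) -> float:
    """Penalty weight whose smoother trace matches the target EDF."""
    p = BtWB.shape[0]
    target = float(np.clip(target, 2.05, p - 0.05))

    def edf(log_alpha):
        alpha = 10.0 ** log_alpha
        A = BtWB + alpha * P
        try:
            return float(np.trace(np.linalg.solve(A, BtWB)))
        except np.linalg.LinAlgError:
            return float(np.trace(np.linalg.lstsq(A, BtWB, rcond=None)[0]))

    lo, hi = -10.0, 16.0
    if edf(lo) < target:
        return 10.0 ** lo
    if edf(hi) > target:
        return 10.0 ** hi
    root = optimize.brentq(lambda la: edf(la) - target, lo, hi, xtol=1e-4)
    return 10.0 ** root


# ---------------------------------------------------------------------------
# likelihood derivatives
# ---------------------------------------------------------------------------

_L_FLOOR = 1e-5


def _safe_L(L):
    return np.where(np.abs(L) < _L_FLOOR, np.where(L < 0, -_L_FLOOR,
                                                   _L_FLOOR), L)


def _grad(x, L, M, S, which: str):
    """Analytic d(loglik)/d(curve value); for S the curve value is ln S."""
    L = _safe_L(L)
    r = np.log(x / M)
    t_pow = np.exp(L * r)
    z = (t_pow - 1.0) / (L * S)
    if which == "L":
        dz = (r * t_pow) / (L * S) - z / L
        return r - z * dz
    if which == "M":
        return -L / M + z * t_pow / (M * S)
    if which == "S":                       # wrt ln S
        return z * z - 1.0
    raise ValueError(which)


def _loglik_vec(x, L, M, S):
    L = _safe_L(L)
    r = np.log(x / M)
    z = (np.exp(L * r) - 1.0) / (L * S)
    return L * r - np.log(S) - 0.5 * z * z


def _curvature(x, L, M, S, which: str):
    """-d2 loglik / d(curve value)^2 by central difference of the gradient."""
    if which == "L":
        h = 1e-4
        gp = _grad(x, L + h, M, S, which)
        gm = _grad(x, L - h, M, S, which)
    elif which == "M":
        h = 1e-4 * M
        gp = _grad(x, L, M + h, S, which)
        gm = _grad(x, L, M - h, S, which)
    else:
        h = 1e-4
        gp = _grad(x, L, M, S * np.exp(h), which)
        gm = _grad(x, L, M, S * np.exp(-h), which)
    w = -(gp - gm) / (2 * h)
    return np.maximum(w, 1e-8)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_curves(ages, values, B):
    """L = 1; M = binned running median; S = binned running CV."""
    n_bins = max(5, min(20, len(ages) // 25))
    qs = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    idx = np.clip(np.searchsorted(qs, ages, side="right") - 1, 0, n_bins - 1)
    centers, med, cv = [], [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() < 3:
            continue
        centers.append(ages[m].mean())
        med.append(np.median(values[m]))
        sd = values[m].std(ddof=1)
        cv.append(np.clip(sd / max(np.median(values[m]), 1e-9), 1e-3, 1.0))
    centers, med, cv = map(np.asarray, (centers, med, cv))
    M0 = np.interp(ages, centers, med)
    lnS0 = np.log(np.interp(ages, centers, cv))
    coef_L = np.linalg.lstsq(B, np.ones(len(ages)), rcond=None)[0]
    coef_M = np.linalg.lstsq(B, M0, rcond=None)[0]
    coef_S = np.linalg.lstsq(B, lnS0, rcond=None)[0]
    return {"L": coef_L, "M": coef_M, "S": coef_S}


def _curve_values(B, coefs):
    return {"L": B @ coefs["L"], "M": B @ coefs["M"],
            "S": np.exp(B @ coefs["S"])}


def _penalized_ll(x, B, coefs, alphas, P):
    cv = _curve_values(B, coefs)
    if np.any(cv["M"] <= 0):
        return -np.inf
    ll = float(np.sum(_loglik_vec(x, cv["L"], cv["M"], cv["S"])))
    pen = sum(alphas[c] * float(coefs[c] @ P @ coefs[c]) for c in coefs)
    return ll - 0.5 * pen


def fit_lms(points, sex: str, config: FitConfig | None = None) -> LMSFit:
    """Fit L(t), M(t), S(t) to (age, value) points for one sex.

    Deterministic given data and config.  Raises on too few points;
    non-convergence within ``max_iter`` is returned with
    ``converged=False``, not raised.
    """
    cfg = config or FitConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be an (n, 2) array of (age, value)")
    ages, values = pts[:, 0], pts[:, 1]
    if len(ages) < cfg.min_points:
        raise FitError(f"need >= {cfg.min_points} points, got {len(ages)}")
    if len(np.unique(np.round(ages, 6))) < cfg.min_distinct_ages:
        raise FitError(f"need >= {cfg.min_distinct_ages} distinct ages")
    if np.any(values <= 0):
        raise FitError("measurement values must be positive")

    knots = _knot_vector(ages, cfg.n_interior_knots)
    B = _design(ages, knots)
    P = _penalty(knots)
    coefs = _initial_curves(ages, values, B)
    cv = _curve_values(B, coefs)

    edf_targets = dict(zip(("L", "M", "S"), cfg.edf))
    alphas = {}
    for c in ("L", "M", "S"):
        w = _curvature(values, cv["L"], cv["M"], cv["S"], c)
        BtWB = B.T @ (B * w[:, None])
        alphas[c] = _edf_to_alpha(BtWB, P, edf_targets[c])

    pll = _penalized_ll(values, B, coefs, alphas, P)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        for c in ("M", "S", "L"):
            cv = _curve_values(B, coefs)
            g = _grad(values, cv["L"], cv["M"], cv["S"], c)
            w = _curvature(values, cv["L"], cv["M"], cv["S"], c)
            grad_coef = B.T @ g - alphas[c] * (P @ coefs[c])
            H = B.T @ (B * w[:, None]) + alphas[c] * P
            try:
                delta = np.linalg.solve(H, grad_coef)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, grad_coef, rcond=None)[0]
            step = 1.0
            base = _penalized_ll(values, B, coefs, alphas, P)
            while step > 1e-6:
                trial = dict(coefs)
                trial[c] = coefs[c] + step * delta
                if _penalized_ll(values, B, trial, alphas, P) > base:
                    coefs = trial
                    break
                step *= 0.5
        new_pll = _penalized_ll(values, B, coefs, alphas, P)
        if abs(new_pll - pll) <= cfg.tol * (abs(pll) + 1.0):
            pll = new_pll
            converged = True
            break
        pll = new_pll

    cv = _curve_values(B, coefs)
    edf_actual = {}
    for c in ("L", "M", "S"):
        w = _curvature(values, cv["L"], cv["M"], cv["S"], c)
        BtWB = B.T @ (B * w[:, None])
        edf_actual[c] = float(np.trace(np.linalg.solve(
            BtWB + alphas[c] * P, BtWB)))

    if cfg.age_grid is not None:
        grid = np.asarray(cfg.age_grid, dtype=float)
    else:
        grid = np.arange(float(ages.min()), float(ages.max()) + 1e-9,
                         cfg.age_grid_step)
    Bg = _design(np.clip(grid, ages.min(), ages.max()), knots)
    gv = _curve_values(Bg, coefs)
    ll = float(np.sum(_loglik_vec(values, cv["L"], cv["M"], cv["S"])))
    if not converged:
        logger.warning("LMS fit (%s): not converged in %d iterations",
                       sex, cfg.max_iter)
    return LMSFit(
        sex=sex, age_grid=grid, L=gv["L"], M=gv["M"], S=gv["S"],
        penalized_loglik=pll, loglik=ll, edf=edf_actual, alphas=alphas,
        n_obs=len(ages), converged=converged, n_iter=it,
        knots=knots, coefs=coefs)


def centile_table(fit: LMSFit, centiles=(3, 10, 25, 50, 75, 90, 97),
                  ages=None) -> pd.DataFrame:
    """Measurement values at the requested centiles along the age grid."""
    if not fit.converged:
        raise FitError("fit did not converge; refusing to tabulate centiles")
    for p in centiles:
        if not (0 < p < 100):
            raise GrowthReferenceError(
                f"centile {p} outside the open interval (0, 100)")
    ages = fit.age_grid if ages is None else np.asarray(ages, dtype=float)
    L, M, S = fit.curves_at(ages)
    out = {"sex": np.repeat(fit.sex, ages.size), "age": ages}
    for p in centiles:
        out[f"P{p:g}"] = value_from_sds(z_from_centile(p), L, M, S)
    return pd.DataFrame(out)


def roughness(fit: LMSFit, curve: str = "M") -> float:
    """Int c''(t)^2 dt of a fitted curve (smoothing diagnostics)."""
    P = _penalty(fit.knots)
    c = fit.coefs[curve]
    return float(c @ P @ c)


def select_one_per_child(observations: pd.DataFrame, value_col: str,
                         seed: int) -> pd.DataFrame:
    """One randomly selected observation per child (seeded, logged)."""
    rng = np.random.default_rng(seed)
    obs = observations.reset_index(drop=True)
    picks = obs.groupby("child_id", sort=True).apply(
        lambda g: g.index[rng.integers(0, len(g))], include_groups=False)
    out = obs.loc[np.sort(picks.to_numpy())].reset_index(drop=True)
    logger.info("reference fit input: %d children, one visit each (seed=%d)",
                len(out), seed)
    return out


def fit_reference(observations: pd.DataFrame, seed: int = 0,
                  value_col: str = "height_cm",
                  config: FitConfig | None = None) -> dict:
    """Per-sex LMS fits from a cohort table (one random visit per child)."""
    picked = select_one_per_child(observations, value_col, seed)
    fits = {}
    for sex, chunk in picked.groupby("sex", sort=True):
        pts = np.column_stack([chunk["age_years"].to_numpy(float),
                               chunk[value_col].to_numpy(float)])
        fits[sex] = fit_lms(pts, sex, config)
    return fits
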