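"""Regression machinery for longitudinal growth analyses.

Three estimators:

* mid-parental height adjustment in SDS space (familial height expectation
  as the mean of the parents' adult height SDS);
* the cross-lagged effect of BMI SDS at age t on height SDS at t+1 year,
  adjusted for height SDS at t, estimated per one-year age group by OLS;
* a random-intercept linear mixed model fitted by REML with a 1-D profile
  over the variance ratio theta = sigma2_b / sigma2_e, used for piecewise
  age-interval trend contrasts between weight groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_pipeline import AGE_GROUP_ADULT, PipelineError, dedup_first_per_group
from .reference_engine import HEIGHT, ReferenceSet, SEXES

logger = logging.getLogger("growthkit")


class ModelError(ValueError):
    """Raised for singular designs or invalid model inputs."""


# ---------------------------------------------------------------------------
# mid-parental height
# ---------------------------------------------------------------------------

def midparental_height_sds(mother_cm, father_cm, references: ReferenceSet):
    """Mid-parental height SDS: mean of the parents' adult height SDS.

    Each parent is referenced against the adult end (maximum tabulated age)
    of the sex-specific height reference.  A missing parent (NaN) leaves
    the other parent's SDS; both missing yields NaN.
    """
    height = references[HEIGHT]
    mother = np.asarray(mother_cm, dtype=float)
    father = np.asarray(father_cm, dtype=float)
    mother, father = np.broadcast_arrays(mother, father)

    def _adult_sds(values, sex):
        out = np.full(values.shape, np.nan)
        ok = np.isfinite(values)
        if np.any(ok & ((values < 120) | (values > 220))):
            raise ModelError("parental height outside plausible 120-220 cm")
        if ok.any():
            age = height.age_range(sex)[1]
            out[ok] = height.sds(sex, np.full(ok.sum(), age), values[ok])
        return out

    m_sds = _adult_sds(mother, "female")
    f_sds = _adult_sds(father, "male")
    both = np.isfinite(m_sds) & np.isfinite(f_sds)
    mid = np.where(both, 0.5 * (m_sds + f_sds),
                   np.where(np.isfinite(m_sds), m_sds, f_sds))
    return mid if mid.ndim else float(mid)


def adjust_height(child_height_sds, midparental_sds):
    """Height SDS relative to the familial expectation (child - mid-parent)."""
    out = np.asarray(child_height_sds, dtype=float) \
        - np.asarray(midparental_sds, dtype=float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# cross-lagged BMI -> height effect
# ---------------------------------------------------------------------------

def build_cross_lag_pairs(observations: pd.DataFrame,
                          predictor: str = "bmi_sds",
                          outcome: str = "height_sds") -> pd.DataFrame:
    """One pair per child per consecutive age-group transition (g, g+1).

    Uses the first observation of the child in each age group; children
    without an observation in group g+1 contribute nothing at g.  The
    open-ended adult group is never a starting point.
    """
    first = dedup_first_per_group(observations)
    cols = ["child_id", "age_group", predictor, outcome]
    cur = first[cols].rename(columns={
        predictor: f"{predictor}_t", outcome: f"{outcome}_t"})
    nxt = first[["child_id", "age_group", outcome]].copy()
    nxt["age_group"] = nxt["age_group"] - 1
    nxt = nxt.rename(columns={outcome: f"{outcome}_t1"})
    pairs = cur.merge(nxt, on=["child_id", "age_group"], how="inner")
    pairs = pairs[pairs["age_group"] < AGE_GROUP_ADULT - 1]
    return pairs.rename(columns={"age_group": "age_t"}).reset_index(drop=True)


@dataclass
class CrossLagResult:
    """Per-age-group effect of the predictor at t on the outcome at t+1,
    adjusted for the outcome at t."""
    predictor: str
    outcome: str
    table: pd.DataFrame  # age, beta, se, p, n, significant
    alpha: float = 0.05


def cross_lag_effect(pairs: pd.DataFrame, min_n: int = 3,
                     alpha: float = 0.05,
                     predictor: str = "bmi_sds",
                     outcome: str = "height_sds",
                     adjusted: bool = False) -> CrossLagResult:
    """OLS of outcome_t1 on {1, predictor_t, outcome_t} per age group.

    Returns the predictor coefficient (height SDS next year per unit of the
    predictor), its standard error and two-sided p-value.  Significance is
    judged at ``alpha`` uncorrected by default (``adjusted=True`` applies
    Holm-Sidak across the fitted ages).
    """
    xcol, ycol_t, ycol = f"{predictor}_t", f"{outcome}_t", f"{outcome}_t1"
    rows = []
    for age_t, chunk in pairs.groupby("age_t", sort=True):
        chunk = chunk.dropna(subset=[xcol, ycol_t, ycol])
        n = len(chunk)
        if n < min_n:
            continue
        X = np.column_stack([np.ones(n),
                             chunk[xcol].to_numpy(float),
                             chunk[ycol_t].to_numpy(float)])
        y = chunk[ycol].to_numpy(float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ModelError(
                f"singular design at age group {age_t}: predictor and "
                "adjustor are collinear")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        if dof <= 0:
            continue
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[1, 1]))
        t_stat = beta[1] / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t_stat), dof)
        rows.append({"age": int(age_t), "beta": float(beta[1]), "se": se,
                     "p": float(p), "n": n})
    table = pd.DataFrame(rows)
    if len(table):
        if adjusted:
            from .cohort_pipeline import holm_sidak
            table["p_adj"] = holm_sidak(table["p"].to_numpy())
            table["significant"] = table["p_adj"] < alpha
        else:
            table["significant"] = table["p"] < alpha
    return CrossLagResult(predictor=predictor, outcome=outcome, table=table,
                          alpha=alpha)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (REML)
# ---------------------------------------------------------------------------

@dataclass
class MixedFit:
    """REML fit of y = X beta + b_subject + e with b ~ N(0, sigma2_b)."""
    beta: np.ndarray
    se: np.ndarray
    sigma2_b: float
    sigma2_e: float
    theta: float            # sigma2_b / sigma2_e
    reml_loglik: float
    n_subjects: int
    n_obs: int
    columns: list = field(default_factory=list)

    @property
    def cov_beta(self):
        return self._cov_beta

    _cov_beta: np.ndarray | None = None


def _reml_pieces(y, X, starts, counts, theta):
    """Sufficient statistics of the GLS problem under V_i = I + theta J.

    V_i^{-1} = I - c_i J with c_i = theta / (1 + theta n_i); returns
    (XtVX, XtVy, ytVy, logdetV).
    """
    n_obs, p = X.shape
    c = theta / (1.0 + theta * counts)
    XtVX = X.T @ X
    XtVy = X.T @ y
    ytVy = float(y @ y)
    sum_x = np.add.reduceat(X, starts, axis=0)      # per-subject column sums
    sum_y = np.add.reduceat(y, starts)
    XtVX = XtVX - (sum_x * c[:, None]).T @ sum_x
    XtVy = XtVy - (sum_x * c[:, None]).T @ sum_y
    ytVy = ytVy - float((c * sum_y) @ sum_y)
    logdetV = float(np.sum(np.log1p(theta * counts)))
    return XtVX, XtVy, ytVy, logdetV


def _reml_criterion(y, X, starts, counts, theta):
    n_obs, p = X.shape
    XtVX, XtVy, ytVy, logdetV = _reml_pieces(y, X, starts, counts, theta)
    try:
        L = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return -np.inf, None
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    dof = n_obs - p
    if rss <= 0:
        return -np.inf, None
    sigma2_e = rss / dof
    logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (logdetV + logdet_XtVX + dof * (1.0 + np.log(2.0 * np.pi))
                 + dof * np.log(sigma2_e))
    return ll, (beta, sigma2_e, XtVX)


def fit_random_intercept_lm(y, X, subject_ids,
                            columns: list | None = None) -> MixedFit:
    """REML random-intercept fit via a 1-D profile over theta = s2_b/s2_e.

    Given theta, beta has the closed GLS form; the profiled REML criterion
    is maximized over log-theta by bounded scalar search (deterministic).
    theta at the zero boundary reduces to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ModelError("X must be (n_obs, p) matching y")
    subject_ids = np.asarray(subject_ids)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [i for i in range(X.shape[1])
                   if abs(R[i, i] if i < R.shape[0] else 0.0) < 1e-8]
        names = ([columns[i] for i in aliased] if columns else aliased)
        raise ModelError(f"rank-deficient design; aliased columns: {names}")

    order = np.argsort(subject_ids, kind="stable")
    y_s, X_s, ids_s = y[order], X[order], subject_ids[order]
    uniq, starts, counts = np.unique(ids_s, return_index=True,
                                     return_counts=True)
    if len(uniq) < 2:
        raise ModelError("need at least 2 subjects")

    def neg(log_theta):
        ll, _ = _reml_criterion(y_s, X_s, starts, counts, np.exp(log_theta))
        return -ll

    # coarse deterministic grid then local refinement
    grid = np.linspace(np.log(1e-8), np.log(1e4), 61)
    vals = np.array([neg(g) for g in grid])
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(np.exp(res.x))
    ll0, _ = _reml_criterion(y_s, X_s, starts, counts, 1e-12)
    llh, fit = _reml_criterion(y_s, X_s, starts, counts, theta)
    if ll0 >= llh:   # boundary: no subject-level variance
        theta = 0.0
        llh, fit = _reml_criterion(y_s, X_s, starts, counts, 1e-12)
    beta, sigma2_e, XtVX = fit
    cov_beta = sigma2_e * np.linalg.inv(XtVX)
    out = MixedFit(
        beta=beta, se=np.sqrt(np.diag(cov_beta)),
        sigma2_b=theta * sigma2_e, sigma2_e=sigma2_e, theta=theta,
        reml_loglik=float(llh), n_subjects=len(uniq), n_obs=len(y),
        columns=list(columns) if columns else [])
    out._cov_beta = cov_beta
    return out


# ---------------------------------------------------------------------------
# piecewise age-interval trend contrasts
# ---------------------------------------------------------------------------

@dataclass
class AgeIntervals:
    """Ordered, non-overlapping age intervals per sex (closed-open except
    the last, which includes its upper bound)."""
    boundaries: dict = field(default_factory=lambda: {
        "male": (2.0, 5.0, 11.0, 17.0),
        "female": (2.0, 8.25, 11.0, 17.0),
    })

    def intervals(self, sex: str):
        b = self.boundaries[sex]
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def membership(self, sex: str, age):
        """Interval index (0-based) per age; -1 outside all intervals."""
        age = np.asarray(age, dtype=float)
        b = self.boundaries[sex]
        idx = np.searchsorted(b, age, side="right") - 1
        idx = np.where((age < b[0]) | (age > b[-1]), -1, idx)
        idx = np.where(age == b[-1], len(b) - 2, idx)  # close the last
        return idx


def piecewise_trend_analysis(observations: pd.DataFrame,
                             intervals: AgeIntervals | None = None,
                             covariates: list | None = None,
                             group_a: str = "obese",
                             group_b: str = "normal",
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per sex x age interval: height SDS ~ age * weight group (+ covariates)
    with a random intercept per child.

    Uses the multiple-observations data set.  Reports the group-specific
    age slopes, their difference (the age x group interaction) with Wald SE
    and p, and the variance components.  ``covariates`` names child-level
    columns (e.g. midparental_sds, birth_length_sds) already merged onto
    the observation rows.
    """
    iv = intervals or AgeIntervals()
    covariates = covariates or []
    sub = observations[
        observations["weight_category"].isin([group_a, group_b])]
    rows = []
    for sex in SEXES:
        s = sub[sub["sex"] == sex]
        member = iv.membership(sex, s["age_years"].to_numpy(float))
        for j, (lo, hi) in enumerate(iv.intervals(sex)):
            chunk = s[member == j].dropna(
                subset=["height_sds"] + covariates)
            is_a = (chunk["weight_category"] == group_a).to_numpy(float)
            n_subj_a = chunk.loc[is_a == 1, "child_id"].nunique()
            n_subj_b = chunk.loc[is_a == 0, "child_id"].nunique()
            if n_subj_a < 2 or n_subj_b < 2:
                logger.warning("interval %s [%s, %s): <2 subjects per group, "
                               "skipped", sex, lo, hi)
                continue
            age = chunk["age_years"].to_numpy(float) - lo
            cols = ["intercept", "age", "group", "age:group"] + covariates
            X = np.column_stack(
                [np.ones(len(chunk)), age, is_a, age * is_a]
                + [chunk[c].to_numpy(float) for c in covariates])
            fit = fit_random_intercept_lm(
                chunk["height_sds"].to_numpy(float), X,
                chunk["child_id"].to_numpy(), columns=cols)
            slope_b = fit.beta[1]
            interaction = fit.beta[3]
            se = fit.se[3]
            dof = fit.n_obs - X.shape[1]
            p = 2.0 * stats.t.sf(abs(interaction / se), dof) if se > 0 else np.nan
            rows.append({
                "sex": sex, "interval": f"{lo:g}-{hi:g}",
                "age_lo": lo, "age_hi": hi,
                "slope_nw": float(slope_b),
                "slope_ob": float(slope_b + interaction),
                "interaction": float(interaction), "se": float(se),
                "p": float(p), "significant": bool(p < alpha),
                "sigma2_b": fit.sigma2_b, "sigma2_e": fit.sigma2_e,
                "n_obs": fit.n_obs, "n_subjects": fit.n_subjects,
            })
    return pd.DataFrame(rows)
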