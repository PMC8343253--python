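"""Cohort preparation and two-group contrast machinery.

Implements the observational pipeline for a mixed cross-sectional/
longitudinal pediatric cohort: SDS annotation, inclusion filters,
age-group allocation by rounded age, first-observation de-duplication,
consecutive-visit growth velocities with plausibility filters, and
per-age-group two-group contrasts (Welch t-tests with step-down
Holm-Sidak multiple-comparison correction and small-stratum suppression).

Input tables are plain pandas DataFrames:

``children``:      child_id, sex, gestational_age_weeks, birth_length_cm,
                   birth_weight_g, mother_height_cm, father_height_cm, flags
``observations``:  child_id, age_years, height_cm, weight_kg

``flags`` is a semicolon-separated subset of {disease, medication,
metformin, thyroxin}; the first two exclude a child from all analyses, the
last two only from insulin/HOMA-IR and thyroid analyses respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference_engine as ref
from .reference_engine import (
    BMI, HEIGHT, VELOCITY, DEFAULT_WEIGHT_CUTOFFS, ReferenceSet,
    WeightCutoffs, classify_weight, compute_bmi,
)

logger = logging.getLogger("growthkit")

AGE_GROUP_ADULT = 18  # label for "18+" (ages >= 17.5)

FLAG_DISEASE = "disease"
FLAG_MEDICATION = "medication"
FLAG_METFORMIN = "metformin"
FLAG_THYROXIN = "thyroxin"


class PipelineError(ValueError):
    """Raised for contract violations in the cohort pipeline."""


# ---------------------------------------------------------------------------
# age groups
# ---------------------------------------------------------------------------

def assign_age_group(age):
    """Age-group label by rounded age.

    Group ``g`` covers [g-0.5, g+0.5) for g = 1..17, ages in [0, 0.5) form
    group 0, and ages >= 17.5 form the open-ended group 18 ("18+").
    """
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise PipelineError("age must be non-negative")
    group = np.floor(arr + 0.5).astype(int)
    group = np.minimum(group, AGE_GROUP_ADULT)
    return group if group.ndim else int(group)


def age_group_label(group):
    """Human-readable label: the integer, or '18+' for the adult group."""
    return "18+" if int(group) == AGE_GROUP_ADULT else str(int(group))


# ---------------------------------------------------------------------------
# SDS annotation
# ---------------------------------------------------------------------------

def annotate_observations(children: pd.DataFrame, observations: pd.DataFrame,
                          references: ReferenceSet,
                          cutoffs: WeightCutoffs = DEFAULT_WEIGHT_CUTOFFS,
                          ) -> pd.DataFrame:
    """Join sex onto visits and add bmi, height_sds, bmi_sds, weight_category
    and age_group columns.

    Ages outside a reference table's range yield NaN SDS (the pipeline's
    tables span 0-18; adult visits are referenced at the table edge up to
    the 18+ convention) -- here we clip lookup ages into the table range so
    the open-ended 18+ group stays referenceable.
    """
    obs = observations.merge(children[["child_id", "sex"]], on="child_id",
                             how="left", validate="many_to_one")
    if obs["sex"].isna().any():
        missing = obs.loc[obs["sex"].isna(), "child_id"].iloc[0]
        raise PipelineError(f"observation for unknown child {missing!r}")
    obs = obs.copy()
    obs["bmi"] = compute_bmi(obs["weight_kg"].to_numpy(),
                             obs["height_cm"].to_numpy())

    height = references[HEIGHT]
    bmi_ref = references[BMI]
    sex = obs["sex"].to_numpy()
    age = obs["age_years"].to_numpy(dtype=float)

    def _clipped(table, sex_arr, age_arr):
        out = np.empty(age_arr.shape)
        for sx in ref.SEXES:
            m = sex_arr == sx
            if not m.any():
                continue
            lo, hi = table.age_range(sx)
            out[m] = np.clip(age_arr[m], lo, hi)
        return out

    obs["height_sds"] = height.sds(sex, _clipped(height, sex, age),
                                   obs["height_cm"].to_numpy())
    obs["bmi_sds"] = bmi_ref.sds(sex, _clipped(bmi_ref, sex, age),
                                 obs["bmi"].to_numpy())
    obs["weight_category"] = classify_weight(obs["bmi_sds"].to_numpy(), cutoffs)
    obs["age_group"] = assign_age_group(obs["age_years"].to_numpy())
    return obs


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    height_sds_min: float = -2.5
    height_sds_max: float = 4.0
    bmi_sds_min: float = -3.5
    premature_ga_weeks: float = 38.0
    premature_min_age: float = 2.0


def _flag_set(flags) -> set:
    if flags is None or (isinstance(flags, float) and np.isnan(flags)):
        return set()
    return {f.strip() for f in str(flags).split(";") if f.strip()}


def apply_inclusion_filters(children: pd.DataFrame, observations: pd.DataFrame,
                            config: FilterConfig | None = None,
                            analytes: pd.DataFrame | None = None):
    """Apply the cohort inclusion rules; returns (observations, log) or
    (observations, analytes, log) when an analyte table is supplied.

    Observation-level rules (each an independent predicate; removal is the
    union): height SDS outside [-2.5, 4.0]; BMI SDS < -3.5; visits before
    age 2.0 of children born before gestational week 38; all visits of
    children flagged with a growth-affecting disease or medication.
    Children flagged ``metformin`` (``thyroxin``) are retained here but
    their insulin/glucose/HOMA-IR (TSH/FT4) analyte rows are removed.
    """
    cfg = config or FilterConfig()
    for col in ("height_sds", "bmi_sds"):
        if col not in observations.columns:
            raise PipelineError(
                f"missing {col!r}: reference the cohort first "
                "(annotate_observations)")
    obs = observations

    flags = children.set_index("child_id")["flags"].map(_flag_set) \
        if "flags" in children.columns else pd.Series(dtype=object)
    ga = children.set_index("child_id").get("gestational_age_weeks")

    child_flags = obs["child_id"].map(flags) if len(flags) else pd.Series(
        [set()] * len(obs), index=obs.index)
    child_flags = child_flags.map(lambda s: s if isinstance(s, set) else set())
    child_ga = obs["child_id"].map(ga) if ga is not None else pd.Series(
        np.nan, index=obs.index)

    h = obs["height_sds"].to_numpy(dtype=float)
    b = obs["bmi_sds"].to_numpy(dtype=float)
    age = obs["age_years"].to_numpy(dtype=float)

    m_height_high = h > cfg.height_sds_max
    m_height_low = h < cfg.height_sds_min
    m_bmi_low = b < cfg.bmi_sds_min
    m_premature = (child_ga.to_numpy(dtype=float) < cfg.premature_ga_weeks) \
        & (age < cfg.premature_min_age)
    m_disease = child_flags.map(lambda s: FLAG_DISEASE in s).to_numpy(bool)
    m_medication = child_flags.map(
        lambda s: FLAG_MEDICATION in s).to_numpy(bool)

    drop = (m_height_high | m_height_low | m_bmi_low | m_premature
            | m_disease | m_medication)
    log = {
        "height_sds_above_max": int(m_height_high.sum()),
        "height_sds_below_min": int(m_height_low.sum()),
        "bmi_sds_below_min": int(m_bmi_low.sum()),
        "premature_below_age_2": int(m_premature.sum()),
        "disease_flag": int(m_disease.sum()),
        "medication_flag": int(m_medication.sum()),
        "observations_in": int(len(obs)),
        "observations_removed": int(drop.sum()),
        "observations_out": int(len(obs) - drop.sum()),
    }
    filtered = obs.loc[~drop].reset_index(drop=True)

    if analytes is None:
        logger.info("inclusion filters: %s", log)
        return filtered, log

    a_flags = analytes["child_id"].map(flags) if len(flags) else pd.Series(
        [set()] * len(analytes), index=analytes.index)
    a_flags = a_flags.map(lambda s: s if isinstance(s, set) else set())
    name = analytes["analyte"].str.lower()
    insulin_rows = name.isin(["insulin", "glucose", "homa-ir", "homa_ir"])
    thyroid_rows = name.isin(["tsh", "ft4"])
    m_metformin = a_flags.map(
        lambda s: FLAG_METFORMIN in s).to_numpy(bool) & insulin_rows.to_numpy()
    m_thyroxin = a_flags.map(
        lambda s: FLAG_THYROXIN in s).to_numpy(bool) & thyroid_rows.to_numpy()
    # analyte rows of globally excluded children are removed as well
    excluded_children = set(obs.loc[m_disease | m_medication, "child_id"])
    m_global = analytes["child_id"].isin(excluded_children).to_numpy()
    a_drop = m_metformin | m_thyroxin | m_global
    log["metformin_analyte_rows"] = int(m_metformin.sum())
    log["thyroxin_analyte_rows"] = int(m_thyroxin.sum())
    analytes_out = analytes.loc[~a_drop].reset_index(drop=True)
    logger.info("inclusion filters: %s", log)
    return filtered, analytes_out, log


# ---------------------------------------------------------------------------
# de-duplication
# ---------------------------------------------------------------------------

def dedup_first_per_group(observations: pd.DataFrame) -> pd.DataFrame:
    """Keep one observation per (child, age_group): the youngest, ties by
    input order.  Stable and idempotent."""
    if "age_group" not in observations.columns:
        raise PipelineError("observations need an age_group column")
    obs = observations.reset_index(drop=True)
    order = obs.sort_values("age_years", kind="stable")
    keep = order.drop_duplicates(["child_id", "age_group"], keep="first").index
    return obs.loc[obs.index.isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# growth velocities
# ---------------------------------------------------------------------------

@dataclass
class VelocityConfig:
    min_interval: float = 0.25
    max_interval: float = 2.0
    min_mean_age: float = 1.5
    min_gv: float = 0.0            # gv < 0 always excluded
    min_gv_under_14: float = 1.0   # gv < 1 for mean age < 14
    max_gv_sds: float = 10.0
    weight_rule: str = "pair-first"  # or "child-first"


def compute_velocities(observations: pd.DataFrame,
                       velocity_reference=None,
                       config: VelocityConfig | None = None):
    """Growth velocities from consecutive visit pairs, with the
    plausibility filters; returns (velocity records, exclusion log).

    For each child's consecutive visits (t1, h1), (t2, h2):
    gv = (h2 - h1)/(t2 - t1) assigned to the mean age.  Pairs are dropped
    when the interval falls outside [0.25, 2] years or the mean age is
    below 1.5; velocities are dropped when gv < 0, when gv < 1 cm/y under
    mean age 14, or when the velocity SDS exceeds 10.  The weight category
    comes from the earlier observation of the pair (``pair-first``) or the
    child's first visit overall (``child-first``).
    """
    cfg = config or VelocityConfig()
    required = {"child_id", "age_years", "height_cm", "weight_category"}
    missing = required - set(observations.columns)
    if missing:
        raise PipelineError(f"observations missing columns {sorted(missing)}")
    obs = observations
    grouped = obs.groupby("child_id", sort=False)["age_years"]
    if (grouped.diff().dropna() < 0).any():
        raise PipelineError("observations must be time-sorted per child")

    g = obs.groupby("child_id", sort=False)
    nxt_age = g["age_years"].shift(-1)
    nxt_height = g["height_cm"].shift(-1)
    has_next = nxt_age.notna()

    pair = pd.DataFrame({
        "child_id": obs["child_id"],
        "age1": obs["age_years"],
        "age2": nxt_age,
        "h1": obs["height_cm"],
        "h2": nxt_height,
        "weight_category_pair_first": obs["weight_category"],
    })
    if "sex" in obs.columns:
        pair["sex"] = obs["sex"]
    pair = pair.loc[has_next].reset_index(drop=True)

    interval = (pair["age2"] - pair["age1"]).to_numpy(dtype=float)
    mean_age = ((pair["age1"] + pair["age2"]) / 2.0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gv = ((pair["h2"] - pair["h1"]) / (pair["age2"] - pair["age1"])
              ).to_numpy(dtype=float)

    m_interval_short = interval < cfg.min_interval
    m_interval_long = interval > cfg.max_interval
    m_young = mean_age < cfg.min_mean_age
    structural = m_interval_short | m_interval_long | m_young

    m_negative = ~structural & (gv < cfg.min_gv)
    m_slow_young = ~structural & (gv >= cfg.min_gv) & (
        gv < cfg.min_gv_under_14) & (mean_age < 14.0)

    gv_sds = np.full_like(gv, np.nan)
    if velocity_reference is not None:
        sex = pair["sex"].to_numpy() if "sex" in pair.columns else None
        if sex is None:
            raise PipelineError("velocity SDS needs a sex column")
        clip_age = np.empty_like(mean_age)
        for sx in ref.SEXES:
            m = sex == sx
            if m.any():
                lo, hi = velocity_reference.age_range(sx)
                clip_age[m] = np.clip(mean_age[m], lo, hi)
        # SDS only defined for positive velocities under the Box-Cox form;
        # negative velocities are excluded anyway
        pos = gv > 0
        gv_sds[pos] = velocity_reference.sds(
            sex[pos] if sex is not None else None, clip_age[pos], gv[pos])
        m_sds_high = ~structural & pos & (gv_sds > cfg.max_gv_sds)
    else:
        logger.warning("no velocity reference supplied: gv_sds omitted and "
                       "the SDS-based plausibility filter skipped")
        m_sds_high = np.zeros_like(m_negative)

    drop = structural | m_negative | m_slow_young | m_sds_high
    log = {
        "pairs_in": int(len(pair)),
        "interval_too_short": int(m_interval_short.sum()),
        "interval_too_long": int(m_interval_long.sum()),
        "mean_age_below_1_5": int(m_young.sum()),
        "gv_negative": int(m_negative.sum()),
        "gv_below_1_under_14": int(m_slow_young.sum()),
        "gv_sds_above_10": int(m_sds_high.sum()),
        "records_out": int((~drop).sum()),
        "sds_filter_applied": velocity_reference is not None,
    }

    out = pd.DataFrame({
        "child_id": pair["child_id"],
        "mean_age": mean_age,
        "interval": interval,
        "gv": gv,
        "gv_sds": gv_sds,
    })
    if "sex" in pair.columns:
        out["sex"] = pair["sex"]
    out["age_group"] = assign_age_group(np.maximum(mean_age, 0.0))
    if cfg.weight_rule == "pair-first":
        out["weight_category"] = pair["weight_category_pair_first"]
    elif cfg.weight_rule == "child-first":
        first = obs.groupby("child_id", sort=False)["weight_category"].first()
        out["weight_category"] = out["child_id"].map(first)
    else:
        raise PipelineError(f"unknown weight_rule {cfg.weight_rule!r}")
    out = out.loc[~drop].reset_index(drop=True)
    logger.info("velocity computation: %s", log)
    return out, log


def dedup_first_velocity_per_group(velocities: pd.DataFrame) -> pd.DataFrame:
    """First velocity record per child per age group (for charts/statistics)."""
    vel = velocities.reset_index(drop=True)
    order = vel.sort_values("mean_age", kind="stable")
    keep = order.drop_duplicates(["child_id", "age_group"], keep="first").index
    return vel.loc[vel.index.isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple-comparison correction
# ---------------------------------------------------------------------------

def holm_sidak(pvals):
    """Step-down Holm-Sidak adjusted p-values, in the original order.

    Sort ascending; the i-th smallest (1-based) gets
    ``1 - (1 - p_(i))**(m - i + 1)``; enforce the running maximum; cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise PipelineError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise PipelineError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    exponents = m - np.arange(m)
    adj = 1.0 - np.power(1.0 - sorted_p, exponents)
    adj = np.maximum.accumulate(adj)
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# two-group contrasts
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Per-age-group two-group contrast for one outcome.

    ``table`` columns: age_group, n_a, n_b, mean_a, sem_a, mean_b, sem_b,
    diff, pct_diff, p_raw, p_adj, significant, suppressed.
    The correction family consists of the non-suppressed age groups.
    """
    outcome: str
    group_a: str
    group_b: str
    table: pd.DataFrame
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)


def compare_groups(data: pd.DataFrame, value_col: str,
                   group_a: str, group_b: str,
                   category_col: str = "weight_category",
                   age_group_col: str = "age_group",
                   min_n: int = 6, alpha: float = 0.05,
                   equal_var: bool = False,
                   outcome: str | None = None) -> ComparisonResult:
    """Welch (default) two-sample t-tests of ``group_a`` vs ``group_b`` per
    age group, Holm-Sidak corrected across the non-suppressed groups.

    Strata with fewer than ``min_n`` in either group are suppressed: no
    p-value, excluded from the correction family.  Strata with zero variance
    in both groups get p = NaN and a ``degenerate`` note.
    """
    sub = data[data[category_col].isin([group_a, group_b])]
    sub = sub.dropna(subset=[value_col])
    rows = []
    for grp, chunk in sub.groupby(age_group_col, sort=True):
        a = chunk.loc[chunk[category_col] == group_a, value_col].to_numpy(float)
        b = chunk.loc[chunk[category_col] == group_b, value_col].to_numpy(float)
        n_a, n_b = a.size, b.size
        suppressed = (n_a < min_n) or (n_b < min_n)
        mean_a = a.mean() if n_a else np.nan
        mean_b = b.mean() if n_b else np.nan
        sem_a = a.std(ddof=1) / np.sqrt(n_a) if n_a > 1 else np.nan
        sem_b = b.std(ddof=1) / np.sqrt(n_b) if n_b > 1 else np.nan
        diff = mean_a - mean_b
        pct = (100.0 * diff / mean_b
               if np.isfinite(mean_b) and mean_b != 0 else np.nan)
        degenerate = False
        if suppressed:
            p = np.nan
        elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p, degenerate = np.nan, True
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows.append({
            "age_group": grp, "n_a": n_a, "n_b": n_b,
            "mean_a": mean_a, "sem_a": sem_a,
            "mean_b": mean_b, "sem_b": sem_b,
            "diff": diff, "pct_diff": pct,
            "p_raw": p, "suppressed": suppressed, "degenerate": degenerate,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = np.nan
        family = ~table["suppressed"] & table["p_raw"].notna()
        if family.any():
            table.loc[family, "p_adj"] = holm_sidak(
                table.loc[family, "p_raw"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    else:
        table = pd.DataFrame(columns=[
            "age_group", "n_a", "n_b", "mean_a", "sem_a", "mean_b", "sem_b",
            "diff", "pct_diff", "p_raw", "suppressed", "degenerate", "p_adj",
            "significant"])
    return ComparisonResult(
        outcome=outcome or value_col, group_a=group_a, group_b=group_b,
        table=table, alpha=alpha,
        meta={"min_n": min_n, "equal_var": equal_var})


def max_group_difference(result: ComparisonResult,
                         metric: str = "absolute",
                         window: tuple[float, float] | None = None,
                         largest: bool = True):
    """(age_group, value) of the extreme group difference.

    ``metric``: ``absolute`` (or its alias ``sds`` for SDS outcomes) uses the
    mean difference; ``percent`` uses 100*(mean_a-mean_b)/mean_b.  Suppressed
    strata are ignored; ties resolve to the youngest group.  ``largest=False``
    returns the minimum (e.g. the deepest reduction).
    """
    tab = result.table
    tab = tab[~tab["suppressed"]]
    if window is not None:
        lo, hi = window
        tab = tab[(tab["age_group"] >= lo) & (tab["age_group"] <= hi)]
    col = {"absolute": "diff", "sds": "diff", "percent": "pct_diff"}.get(metric)
    if col is None:
        raise PipelineError(f"unknown metric {metric!r}")
    tab = tab.dropna(subset=[col])
    if not len(tab):
        raise PipelineError("all strata suppressed or empty in the window")
    vals = tab[col].to_numpy(dtype=float)
    idx = int(np.argmax(vals)) if largest else int(np.argmin(vals))
    # ties -> youngest: argmax/argmin already return the first (youngest,
    # since groups are sorted ascending)
    return int(tab["age_group"].iloc[idx]), float(vals[idx])
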