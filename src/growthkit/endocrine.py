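"""Hormone and metabolic analyte computations and age-profile contrasts.

HOMA-IR from fasting insulin and glucose, and per-analyte obese-vs-normal
contrasts by sex and age group, reusing the cohort pipeline's Welch-t /
Holm-Sidak comparison machinery with the analyte-specific medication
exclusions (metformin -> insulin & HOMA-IR, thyroxin -> TSH & FT4).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort_pipeline import (
    ComparisonResult, PipelineError, assign_age_group, compare_groups,
    dedup_first_per_group, max_group_difference,
)

logger = logging.getLogger("growthkit")

#: insulin unit conversion: 1 mU/l = 6.945 pmol/L
PMOL_PER_MUL = 6.945

#: analyte -> medication flag whose takers are excluded from its contrasts
MEDICATION_RULES = {
    "insulin": "metformin", "glucose": "metformin", "homa-ir": "metformin",
    "tsh": "thyroxin", "ft4": "thyroxin",
}


def homa_ir(insulin_mU_l=None, glucose_mmol_l=None, *, insulin_pmol_l=None):
    """HOMA-IR = insulin[mU/l] x glucose[mmol/l] / 22.5.

    Insulin may be given in pmol/L via the keyword ``insulin_pmol_l``; it is
    then converted by / 6.945 (and the conversion logged).
    """
    if (insulin_mU_l is None) == (insulin_pmol_l is None):
        raise PipelineError(
            "provide exactly one of insulin_mU_l / insulin_pmol_l")
    if insulin_pmol_l is not None:
        logger.info("HOMA-IR: converting insulin pmol/L -> mU/l (/ %.3f)",
                    PMOL_PER_MUL)
        insulin = np.asarray(insulin_pmol_l, dtype=float) / PMOL_PER_MUL
    else:
        insulin = np.asarray(insulin_mU_l, dtype=float)
    glucose = np.asarray(glucose_mmol_l, dtype=float)
    if np.any(glucose <= 0):
        raise PipelineError("glucose must be positive")
    if np.any(insulin < 0):
        raise PipelineError("insulin must be non-negative")
    out = insulin * glucose / 22.5
    return out if out.ndim else float(out)


def add_homa_ir(analytes: pd.DataFrame) -> pd.DataFrame:
    """Append derived homa-ir rows from matched insulin (pmol/L) and glucose
    (mmol/L) rows sharing (child_id, age_years)."""
    ins = analytes[analytes["analyte"] == "insulin"]
    glu = analytes[analytes["analyte"] == "glucose"]
    merged = ins.merge(glu, on=["child_id", "age_years"],
                       suffixes=("_ins", "_glu"))
    if not len(merged):
        return analytes
    homa = pd.DataFrame({
        "child_id": merged["child_id"],
        "age_years": merged["age_years"],
        "analyte": "homa-ir",
        "value": homa_ir(glucose_mmol_l=merged["value_glu"].to_numpy(),
                         insulin_pmol_l=merged["value_ins"].to_numpy()),
        "units": "index",
    })
    return pd.concat([analytes, homa], ignore_index=True)


def prepare_analyte_table(analytes: pd.DataFrame, children: pd.DataFrame,
                          observations: pd.DataFrame) -> pd.DataFrame:
    """Join sex, weight category and age group onto analyte rows.

    Weight category and age group come from the anthropometric observation
    at the same (child_id, age_years) visit; ages are matched to 0.001 y
    so tables written at different float precisions still join.
    """
    meta = observations[["child_id", "age_years", "weight_category"]].copy()
    meta["age_key"] = (meta["age_years"] * 1000).round().astype(np.int64)
    out = analytes.copy()
    out["age_key"] = (out["age_years"] * 1000).round().astype(np.int64)
    out = out.merge(meta.drop(columns="age_years"),
                    on=["child_id", "age_key"], how="inner")
    out = out.drop(columns="age_key")
    out = out.merge(children[["child_id", "sex"]], on="child_id", how="left")
    out["age_group"] = assign_age_group(out["age_years"].to_numpy(float))
    return out


def _apply_medication_rule(table: pd.DataFrame, children: pd.DataFrame,
                           analyte: str):
    flag = MEDICATION_RULES.get(analyte.lower())
    if flag is None or "flags" not in children.columns:
        return table, 0
    flagged = children.loc[
        children["flags"].fillna("").str.contains(flag), "child_id"]
    m = table["child_id"].isin(set(flagged))
    if m.any():
        logger.info("%s contrast: excluded %d rows of %s takers",
                    analyte, int(m.sum()), flag)
    return table.loc[~m], int(m.sum())


def analyte_contrast(analyte_table: pd.DataFrame, children: pd.DataFrame,
                     analyte: str,
                     group_a: str = "obese", group_b: str = "normal",
                     min_n: int = 6, alpha: float = 0.05,
                     log_scale: bool = False) -> dict:
    """Per-sex obese-vs-normal contrast of one analyte across age groups.

    Returns ``{sex: ComparisonResult}``.  The correction family is the
    analyte x sex panel.  One observation per child per age group; the
    analyte-specific medication exclusion is applied first.  ``log_scale``
    compares log-concentrations (for heavily skewed analytes), off by
    default since raw means are the convention here.
    """
    sub = analyte_table[analyte_table["analyte"].str.lower()
                        == analyte.lower()].copy()
    if not len(sub):
        raise PipelineError(f"analyte {analyte!r} absent from the table")
    sub, n_excluded = _apply_medication_rule(sub, children, analyte)
    value_col = "value"
    if log_scale:
        sub["log_value"] = np.log(sub["value"])
        value_col = "log_value"
    results = {}
    for sex, chunk in sub.groupby("sex", sort=True):
        first = dedup_first_per_group(chunk)
        res = compare_groups(first, value_col, group_a, group_b,
                             min_n=min_n, alpha=alpha,
                             outcome=f"{analyte} ({sex})")
        res.meta["medication_excluded_rows"] = n_excluded
        results[sex] = res
    return results


def max_percent_reduction(result: ComparisonResult,
                          window: tuple[float, float]) -> tuple[int, float]:
    """(age_group, percent) of the strongest reduction of group A relative
    to group B within the age-group window; percent is positive for a
    reduction."""
    group, pct = max_group_difference(result, metric="percent",
                                      window=window, largest=False)
    return group, -pct


def window_mean_reduction(result: ComparisonResult,
                          window: tuple[float, float]) -> float:
    """Percent reduction of group A vs group B averaged over the window's
    age groups (positive for a reduction).

    For an effect that is constant across the window this estimates the
    window's maximum reduction without the upward bias of taking the
    extremum of noisy per-group cells.
    """
    tab = result.table
    tab = tab[~tab["suppressed"]]
    win = tab[(tab["age_group"] >= window[0])
              & (tab["age_group"] <= window[1])].dropna(subset=["pct_diff"])
    if not len(win):
        raise PipelineError("no usable age groups in the window")
    return float(-win["pct_diff"].mean())
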