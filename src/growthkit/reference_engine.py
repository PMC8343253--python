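"""LMS (Box-Cox) growth referencing.

A pediatric reference distribution is summarized by three age- and
sex-specific curves: the Box-Cox power ``L(t)``, the median ``M(t)`` and the
coefficient of variation ``S(t)`` (Cole's LMS method).  A measurement ``x``
taken at age ``t`` maps to a standard deviation score (SDS, z-score)

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                     for L == 0

and back via the exact inverse.  This module holds the scalar transforms,
tabulated reference tables with linear age interpolation, and the BMI-SDS
weight-category and birth-size classifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("growthkit")

SEXES = ("male", "female")

# canonical measure names used across the package
HEIGHT = "height-for-age"
BMI = "bmi-for-age"
VELOCITY = "velocity-for-age"
BIRTH_LENGTH = "birth-length-for-GA"
BIRTH_WEIGHT = "birth-weight-for-GA"

_L_ZERO_TOL = 1e-9


class GrowthReferenceError(ValueError):
    """Raised for invalid reference tables or out-of-range lookups."""


# ---------------------------------------------------------------------------
# scalar LMS transforms
# ---------------------------------------------------------------------------

def sds(x, L, M, S):
    """Standard deviation score of measurement ``x`` under (L, M, S).

    All arguments broadcast; ``x``, ``M`` and ``S`` must be positive.
    """
    x, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float)
                                       for a in (x, L, M, S)))
    if np.any(x <= 0):
        raise GrowthReferenceError("measurement x must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("M and S must be positive")
    ratio = x / M
    L_safe = np.where(np.abs(L) < _L_ZERO_TOL, 1.0, L)
    with np.errstate(invalid="ignore"):
        z = np.where(
            np.abs(L) < _L_ZERO_TOL,
            np.log(ratio) / S,
            (np.power(ratio, L_safe) - 1.0) / (L_safe * S),
        )
    return z if z.ndim else float(z)


def value_from_sds(z, L, M, S):
    """Measurement value at SDS ``z`` under (L, M, S); inverse of :func:`sds`.

    For ``L != 0`` the Box-Cox support requires ``1 + L*S*z > 0``; a value
    outside raises (the requested centile does not exist under the model).
    """
    z, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float)
                                       for a in (z, L, M, S)))
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("M and S must be positive")
    base = 1.0 + L * S * z
    nonzero = np.abs(L) >= _L_ZERO_TOL
    if np.any(nonzero & (base <= 0)):
        raise GrowthReferenceError(
            "centile outside Box-Cox support: 1 + L*S*z <= 0")
    L_safe = np.where(nonzero, L, 1.0)
    with np.errstate(invalid="ignore"):
        x = np.where(nonzero,
                     M * np.power(np.where(base > 0, base, 1.0), 1.0 / L_safe),
                     M * np.exp(S * z))
    return x if x.ndim else float(x)


def centile(z):
    """Percent of the reference population below SDS ``z`` (Phi(z) * 100)."""
    out = norm.cdf(np.asarray(z, dtype=float)) * 100.0
    return out if out.ndim else float(out)


def z_from_centile(p):
    """Inverse of :func:`centile`; ``p`` in percent, open interval (0, 100)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise GrowthReferenceError("centile must lie strictly in (0, 100)")
    out = norm.ppf(p / 100.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# weight and birth-size categories
# ---------------------------------------------------------------------------

UNDERWEIGHT = "underweight"
NORMAL = "normal"
OVERWEIGHT = "overweight"
OBESE = "obese"

WEIGHT_CATEGORIES = (UNDERWEIGHT, NORMAL, OVERWEIGHT, OBESE)


@dataclass(frozen=True)
class WeightCutoffs:
    """BMI-SDS boundaries of the weight categories.

    Defaults follow the German pediatric consensus scheme:
    underweight < -1.28 <= normal <= 1.28 < overweight <= 1.88 < obese.
    """
    underweight: float = -1.28
    overweight: float = 1.28
    obese: float = 1.88


DEFAULT_WEIGHT_CUTOFFS = WeightCutoffs()


def classify_weight(bmi_sds, cutoffs: WeightCutoffs = DEFAULT_WEIGHT_CUTOFFS):
    """Weight category from BMI SDS; boundaries per the half-open scheme.

    -1.28 and 1.28 are ``normal``; 1.88 is ``overweight``; above is ``obese``.
    """
    arr = np.asarray(bmi_sds, dtype=float)
    if np.any(np.isnan(arr)):
        raise GrowthReferenceError("BMI SDS contains NaN")
    cat = np.select(
        [arr < cutoffs.underweight, arr <= cutoffs.overweight,
         arr <= cutoffs.obese],
        [UNDERWEIGHT, NORMAL, OVERWEIGHT],
        default=OBESE,
    )
    return cat if cat.ndim else str(cat)


SGA, AGA, LGA = "SGA", "AGA", "LGA"
UNCLASSIFIED = "unclassified"


def classify_birth_size(birth_sds, lower: float = -1.28, upper: float = 1.28):
    """SGA/AGA/LGA from a gestational-age-referenced birth-size SDS.

    Default cutoffs are +/-1.28 SDS (~10th/90th centile).  Missing values
    (NaN, e.g. unknown gestational age) yield ``unclassified`` rather than an
    error.
    """
    arr = np.asarray(birth_sds, dtype=float)
    cat = np.select(
        [np.isnan(arr), arr < lower, arr > upper],
        [UNCLASSIFIED, SGA, LGA],
        default=AGA,
    )
    return cat if cat.ndim else str(cat)


# ---------------------------------------------------------------------------
# tabulated reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """A tabulated (sex, age) -> (L, M, S) reference for one measure.

    ``records`` holds columns ``sex, age, L, M, S`` with ages strictly
    increasing within sex.  Lookups linearly interpolate each of L, M, S in
    age; ages outside the tabulated range raise.  For birth-size references
    the "age" axis is gestational age in weeks.
    """

    measure: str
    records: pd.DataFrame
    units: str = ""
    _by_sex: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self):
        required = {"sex", "age", "L", "M", "S"}
        missing = required - set(self.records.columns)
        if missing:
            raise GrowthReferenceError(
                f"reference table {self.measure!r} missing columns {sorted(missing)}")
        rec = self.records.copy()
        rec["age"] = rec["age"].astype(float)
        for sex in SEXES:
            sub = rec[rec["sex"] == sex]
            if len(sub) < 2:
                raise GrowthReferenceError(
                    f"reference {self.measure!r} needs >=2 records for {sex}")
            ages = sub["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise GrowthReferenceError(
                    f"reference {self.measure!r}/{sex}: ages must be strictly increasing")
            if np.any(ages < 0):
                raise GrowthReferenceError("ages must be non-negative")
            if np.any(sub["M"].to_numpy() <= 0) or np.any(sub["S"].to_numpy() <= 0):
                raise GrowthReferenceError(
                    f"reference {self.measure!r}/{sex}: M and S must be positive")
            self._by_sex[sex] = {
                "age": ages,
                "L": sub["L"].to_numpy(dtype=float),
                "M": sub["M"].to_numpy(dtype=float),
                "S": sub["S"].to_numpy(dtype=float),
            }
        self.records = rec.sort_values(["sex", "age"], kind="stable").reset_index(drop=True)

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self._sex(sex)["age"]
        return float(ages[0]), float(ages[-1])

    def _sex(self, sex: str):
        try:
            return self._by_sex[sex]
        except KeyError:
            raise GrowthReferenceError(
                f"sex must be one of {SEXES}, got {sex!r}") from None

    def interpolate(self, sex, age):
        """(L, M, S) at ``age`` for ``sex``; exact at nodes, linear between."""
        ages = np.asarray(age, dtype=float)
        if np.ndim(sex) == 0:
            node = self._sex(sex)
            lo, hi = node["age"][0], node["age"][-1]
            out_of_range = (ages < lo) | (ages > hi)
            if np.any(out_of_range):
                bad = float(np.atleast_1d(ages[out_of_range])[0])
                raise GrowthReferenceError(
                    f"age {bad:g} outside {self.measure!r} "
                    f"range [{lo:g}, {hi:g}] for sex {sex!r}")
            L = np.interp(ages, node["age"], node["L"])
            M = np.interp(ages, node["age"], node["M"])
            S = np.interp(ages, node["age"], node["S"])
            if np.ndim(age) == 0:
                return float(L), float(M), float(S)
            return L, M, S
        sex_arr = np.asarray(sex)
        ages, sex_arr = np.broadcast_arrays(ages, sex_arr)
        unknown = ~np.isin(sex_arr, SEXES)
        if unknown.any():
            raise GrowthReferenceError(
                f"unknown sex value {sex_arr[unknown][0]!r}")
        L = np.empty(ages.shape)
        M = np.empty(ages.shape)
        S = np.empty(ages.shape)
        for sx in SEXES:
            mask = sex_arr == sx
            if mask.any():
                L[mask], M[mask], S[mask] = self.interpolate(sx, ages[mask])
        return L, M, S

    def sds(self, sex, age, value):
        """SDS of ``value`` at (sex, age) under this reference."""
        L, M, S = self.interpolate(sex, age)
        return sds(value, L, M, S)

    def value(self, sex, age, z):
        """Measurement value at SDS ``z`` for (sex, age)."""
        L, M, S = self.interpolate(sex, age)
        return value_from_sds(z, L, M, S)

    def centile_values(self, sex, ages, centiles: Iterable[float]) -> pd.DataFrame:
        """Table of measurement values at the requested centiles."""
        ages = np.asarray(ages, dtype=float)
        out = {"sex": np.repeat(sex, ages.size), "age": ages}
        for p in centiles:
            out[f"P{p:g}"] = self.value(sex, ages, z_from_centile(p))
        return pd.DataFrame(out)


class ReferenceSet(Mapping):
    """A collection of :class:`ReferenceTable` keyed by measure name."""

    def __init__(self, tables: Iterable[ReferenceTable]):
        self._tables = {t.measure: t for t in tables}

    def __getitem__(self, measure: str) -> ReferenceTable:
        try:
            return self._tables[measure]
        except KeyError:
            raise GrowthReferenceError(
                f"no reference table for measure {measure!r}; "
                f"available: {sorted(self._tables)}") from None

    def __iter__(self):
        return iter(self._tables)

    def __len__(self):
        return len(self._tables)

    @classmethod
    def from_csv(cls, path) -> "ReferenceSet":
        """Read an LMS reference CSV: columns ``measure,sex,age,L,M,S[,units]``."""
        df = pd.read_csv(path)
        required = {"measure", "sex", "age", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise GrowthReferenceError(
                f"LMS CSV {path} missing columns {sorted(missing)}")
        tables = []
        for measure, sub in df.groupby("measure", sort=False):
            units = ""
            if "units" in sub.columns and sub["units"].notna().any():
                units = str(sub["units"].dropna().iloc[0])
            tables.append(ReferenceTable(
                measure=str(measure),
                records=sub[["sex", "age", "L", "M", "S"]].reset_index(drop=True),
                units=units,
            ))
        return cls(tables)

    def to_csv(self, path):
        frames = []
        for t in self._tables.values():
            f = t.records.copy()
            f.insert(0, "measure", t.measure)
            f["units"] = t.units
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.6g")


def interpolate_lms(table: ReferenceTable, sex, age):
    """Functional alias for :meth:`ReferenceTable.interpolate`."""
    return table.interpolate(sex, age)


def compute_bmi(weight_kg, height_cm):
    """BMI in kg/m^2 from weight in kg and height in cm."""
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(height_cm <= 0):
        raise GrowthReferenceError("height must be positive")
    out = np.asarray(weight_kg, dtype=float) / (height_cm / 100.0) ** 2
    return out if out.ndim else float(out)
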