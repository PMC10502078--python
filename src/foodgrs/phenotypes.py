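"""Phenotype and dietary-exposure preparation.

Covers four jobs: recoding 7-point food-frequency ratings to weekly
consumption frequencies, computing the two summary dietary indices (sweet
treat index, plant consumption index), converting BMI to age- and
sex-specific z-scores with the LMS method, and producing descriptive
two-group comparisons (t-test / chi-square) of cohort characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, FormatError
from .items import (
    DEFAULT_RATING_TO_WEEKLY,
    FFQ_ITEMS,
    PLANT_ITEMS,
    SWEET_TREAT_ITEMS,
)

# ---------------------------------------------------------------------------
# FFQ recoding and summary indices


def validate_rating_mapping(mapping: Mapping[int, float]) -> None:
    """Check a rating -> times/week mapping: defined on 1..7, monotone
    non-decreasing, anchored at 1 -> 0 and 7 -> 14."""
    keys = sorted(mapping)
    if keys != list(range(1, 8)):
        raise ConfigurationError(
            f"mapping must be defined exactly on ratings 1..7, got {keys}"
        )
    vals = [mapping[k] for k in range(1, 8)]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ConfigurationError("rating mapping must be non-decreasing")
    if mapping[1] != 0.0 or mapping[7] != 14.0:
        raise ConfigurationError(
            "rating mapping must anchor 1 -> 0.0 and 7 -> 14.0 times/week"
        )


def recode_ffq(
    records: pd.DataFrame,
    mapping: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Recode 1-7 FFQ ratings to weekly frequencies (0-14 times/week).

    Missing ratings stay missing.  Ratings outside 1..7 raise DomainError.
    """
    if mapping is None:
        mapping = DEFAULT_RATING_TO_WEEKLY
    validate_rating_mapping(mapping)
    vals = records.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, np.arange(1.0, 8.0))
    if not ok.all():
        raise DomainError("FFQ ratings must be integers 1..7 or missing")
    lut = {float(k): float(v) for k, v in mapping.items()}
    return records.apply(lambda col: col.astype(float).map(lut))


def _index(weekly: pd.DataFrame, items: Sequence[str], name: str) -> pd.Series:
    unknown = [i for i in items if i not in weekly.columns]
    if unknown:
        raise ConfigurationError(f"unknown food item(s) for {name}: {unknown}")
    # skipna=False: any missing component makes the index missing
    out = weekly[list(items)].sum(axis=1, skipna=False)
    out.name = name
    return out


def sweet_treat_index(
    weekly: pd.DataFrame, items: Sequence[str] | None = None
) -> pd.Series:
    """Sweet treat index (STI): summed weekly frequency of sugary items."""
    return _index(weekly, items or SWEET_TREAT_ITEMS, "sweet_treat_index")


def plant_consumption_index(
    weekly: pd.DataFrame, items: Sequence[str] | None = None
) -> pd.Series:
    """Plant consumption index (PCI): summed weekly frequency of
    vegetables, fruit and berries."""
    return _index(weekly, items or PLANT_ITEMS, "plant_consumption_index")


# ---------------------------------------------------------------------------
# LMS BMI z-scores


@dataclass(frozen=True)
class LMSReference:
    """LMS (skewness L, median M, coefficient of variation S) growth
    reference, one row per (sex, age)."""

    table: pd.DataFrame

    def __post_init__(self):
        req = ["sex", "age", "L", "M", "S"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise FormatError(f"LMS reference missing column(s): {missing}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise FormatError("LMS reference requires M > 0 and S > 0")
        for sex, grp in self.table.groupby("sex"):
            a = grp["age"].to_numpy()
            if not (np.diff(a) > 0).all():
                raise FormatError(
                    f"ages must be strictly increasing within sex {sex!r}"
                )

    def age_range(self, sex: int) -> tuple[float, float]:
        grp = self.table[self.table["sex"] == sex]
        if grp.empty:
            raise DomainError(f"no LMS rows for sex {sex!r}")
        return float(grp["age"].min()), float(grp["age"].max())

    def interpolate(
        self, age: np.ndarray, sex: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linearly interpolate (L, M, S) in age, separately per sex."""
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex)
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for s in np.unique(sex):
            grp = self.table[self.table["sex"] == s]
            if grp.empty:
                raise DomainError(f"no LMS rows for sex {s!r}")
            lo, hi = grp["age"].min(), grp["age"].max()
            mask = sex == s
            if (age[mask] < lo).any() or (age[mask] > hi).any():
                raise DomainError(
                    f"age outside LMS reference range [{lo}, {hi}] "
                    f"for sex {s!r}"
                )
            a = grp["age"].to_numpy()
            L[mask] = np.interp(age[mask], a, grp["L"].to_numpy())
            M[mask] = np.interp(age[mask], a, grp["M"].to_numpy())
            S[mask] = np.interp(age[mask], a, grp["S"].to_numpy())
        return L, M, S


def load_lms_reference(path: str | Path) -> LMSReference:
    """Read an LMS reference CSV with columns sex, age, L, M, S."""
    return LMSReference(pd.read_csv(path))


def synthetic_lms_reference(
    ages: np.ndarray | None = None,
) -> LMSReference:
    """A smooth synthetic LMS reference for testing and simulation.

    The curves are plausible for school-age children (median BMI rising from
    ~15.5 at age 5 to ~20 at 18, mild left skewness, CV around 0.10) but are
    NOT a published growth standard; supply a real IOTF/WHO coefficient file
    for substantive use.  Sex coding: 0 = boy, 1 = girl.
    """
    if ages is None:
        ages = np.arange(2.0, 18.5, 0.5)
    rows = []
    for sex in (0, 1):
        for a in ages:
            t = a - 5.0
            m = 15.2 + 0.11 * t + 0.021 * t * t + (0.10 if sex == 1 else 0.0)
            l = -1.35 - 0.035 * t
            s = 0.082 + 0.0040 * t
            rows.append((sex, float(a), l, m, s))
    return LMSReference(
        pd.DataFrame(rows, columns=["sex", "age", "L", "M", "S"])
    )


def bmi_zscore(
    bmi,
    age,
    sex,
    ref: LMSReference,
):
    """BMI -> z-score via the LMS transformation.

    z = ((bmi/M)^L - 1) / (L*S) when L != 0, else ln(bmi/M)/S, with (L, M, S)
    linearly interpolated in age within sex.  Accepts scalars or arrays.
    """
    bmi_arr = np.asarray(bmi, dtype=float)
    scalar = bmi_arr.ndim == 0
    bmi_arr = np.atleast_1d(bmi_arr)
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    sex_arr = np.atleast_1d(np.asarray(sex))
    if (bmi_arr <= 0).any():
        raise DomainError("BMI must be positive")
    L, M, S = ref.interpolate(age_arr, sex_arr)
    with np.errstate(all="ignore"):
        z = np.where(
            L != 0,
            ((bmi_arr / M) ** L - 1.0) / (L * S),
            np.log(bmi_arr / M) / S,
        )
    return float(z[0]) if scalar else z


def bmi_from_zscore(z, age, sex, ref: LMSReference):
    """Inverse LMS transform: z-score -> BMI (kg/m^2)."""
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    sex_arr = np.atleast_1d(np.asarray(sex))
    L, M, S = ref.interpolate(age_arr, sex_arr)
    with np.errstate(all="ignore"):
        bmi = np.where(
            L != 0,
            M * (1.0 + L * S * z_arr) ** (1.0 / L),
            M * np.exp(S * z_arr),
        )
    return float(bmi[0]) if scalar else bmi


# ---------------------------------------------------------------------------
# Two-group descriptive comparisons


@dataclass(frozen=True)
class GroupComparison:
    """One variable's two-group comparison (descriptives + test)."""

    variable: str
    test: str  # "t-test" or "chi-square"
    statistic: float
    p: float
    summary: pd.DataFrame  # per-group mean/sd or counts/%

    def __post_init__(self):
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise DomainError(f"p-value out of [0, 1]: {self.p}")


def compare_groups(
    cohort: pd.DataFrame,
    groups: pd.Series,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    equal_var: bool = True,
    correction: bool = False,
) -> list[GroupComparison]:
    """Compare variables between two groups, complete-case per variable.

    Continuous variables use an independent-samples t-test (pooled variance
    by default, Welch with ``equal_var=False``); categorical variables use a
    Pearson chi-square on the contingency table (Yates continuity correction
    off by default).
    """
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise DomainError(f"exactly two groups required, got {list(labels)}")
    g1, g2 = sorted(labels)
    out: list[GroupComparison] = []
    for var in continuous:
        x = cohort.loc[groups == g1, var].dropna()
        y = cohort.loc[groups == g2, var].dropna()
        if x.empty or y.empty:
            raise DomainError(f"empty group for variable {var!r}")
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        summary = pd.DataFrame(
            {
                "group": [g1, g2],
                "n": [len(x), len(y)],
                "mean": [x.mean(), y.mean()],
                "sd": [x.std(ddof=1), y.std(ddof=1)],
            }
        )
        out.append(
            GroupComparison(var, "t-test", float(res.statistic),
                            float(res.pvalue), summary)
        )
    for var in categorical:
        sub = pd.DataFrame({"g": groups, "v": cohort[var]}).dropna()
        table = pd.crosstab(sub["v"], sub["g"])
        if table.shape[1] != 2 or (table.sum(axis=0) == 0).any():
            raise DomainError(f"empty group for variable {var!r}")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
        pct = table / table.sum(axis=0)
        summary = pd.concat(
            {"count": table, "fraction": pct}, axis=1
        ).reset_index()
        out.append(
            GroupComparison(var, "chi-square", float(chi2), float(p), summary)
        )
    return out


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison objects into a tidy one-row-per-variable
    DataFrame for reporting."""
    rows = []
    for c in comparisons:
        row: dict = {"variable": c.variable, "test": c.test,
                     "statistic": c.statistic, "p": c.p}
        if c.test == "t-test":
            for _, r in c.summary.iterrows():
                row[f"mean_{r['group']}"] = r["mean"]
                row[f"sd_{r['group']}"] = r["sd"]
                row[f"n_{r['group']}"] = r["n"]
        rows.append(row)
    return pd.DataFrame(rows)
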