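"""Gene-diet interaction regression and the two-level screening cascade.

The analytic core of the package:

1. ``fit_interaction`` — ordinary least squares for
   ``BMIz ~ score + food + score:food + covariates`` with complete-case
   handling and both unstandardized (b) and standardized (Beta)
   coefficients.
2. ``screen_whole_grs`` — level one of the cascade: test every food against
   every whole-panel GRS scheme at p < 0.15, refitting borderline results
   with a median-dichotomized score.
3. ``screen_snps`` — level two: for a flagged food, test each SNP's dosage
   individually and keep SNPs whose interaction coefficient has the same
   sign as the whole-GRS interaction ("same direction") and p < 0.2.
4. ``build_food_grs`` / ``validate_food_grs`` — combine the selected SNPs
   into an unweighted food-specific GRS and refit the interaction under two
   covariate models.
5. ``stratified_effects`` — per-stratum food effect below/above the median
   food-specific score, plus the joint interaction model.
6. ``shared_snp_analysis`` — exact set algebra over the food-specific SNP
   selections (Venn regions, union, full intersection).

Interaction p-value thresholds are deliberately liberal (0.15 for whole-GRS
screens, 0.2 for per-SNP screens): power for interactions is far below
power for main effects, so the type-I error rate is raised at the screening
stage and no multiple-testing correction is applied by default.  An
optional Benjamini-Hochberg column can be added for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .errors import (
    BuildError,
    ConfigurationError,
    DomainError,
    SingularDesignError,
)
from .grs_engine import (
    GenotypeMatrix,
    SNPPanel,
    ScoreVector,
    median_split,
    subset_score,
)

#: Covariate set of the screening stage (includes ancestry PCs).
SCREEN_COVARIATES = ("sex", "ltpa", "sleep", "pc1", "pc2")

#: Covariate sets of the two validation models (no ancestry PCs).
VALIDATION_MODELS: dict[int, tuple[str, ...]] = {
    1: ("sex",),
    2: ("sex", "ltpa", "sleep"),
}

MIN_EXTRA_CASES = 10  # complete cases required beyond the parameter count


# ---------------------------------------------------------------------------
# OLS interaction fit


@dataclass(frozen=True)
class InteractionResult:
    """A fitted interaction model.

    ``table`` has one row per term (const, score, food, interaction,
    covariates) and columns ``b`` (unstandardized coefficient), ``se``,
    ``beta`` (standardized coefficient), ``t``, ``p`` (two-sided, from the
    t distribution with residual df) and the 95% CI bounds.
    """

    table: pd.DataFrame
    n_used: int
    df_resid: int

    def __post_init__(self):
        t = self.table
        if not ((t["ci_low"] <= t["b"] + 1e-12) & (t["b"] <= t["ci_high"] + 1e-12)).all():
            raise DomainError("CI must bracket the coefficient")
        if not t["p"].between(0.0, 1.0).all():
            raise DomainError("p-values must lie in [0, 1]")

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def interaction(self) -> pd.Series:
        return self.term("interaction")


def _diagnose_rank(X: pd.DataFrame) -> list[str]:
    """Columns that a pivoted QR identifies as linearly dependent."""
    A = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(A)
    if r == A.shape[1]:
        return []
    _, _, piv = qr(A, mode="economic", pivoting=True)
    return [X.columns[j] for j in piv[r:]]


def fit_interaction(
    outcome: pd.Series,
    g: pd.Series,
    e: pd.Series,
    covariates: Mapping[str, pd.Series] | pd.DataFrame | None = None,
    g_name: str = "score",
    e_name: str = "food",
) -> InteractionResult:
    """Fit ``outcome ~ const + g + e + g*e + covariates`` by OLS.

    Complete-case: rows missing any variable are dropped.  ``Beta`` is the
    coefficient times SD(term)/SD(outcome) on the analysis sample; for the
    interaction term the product variable itself is standardized.

    Raises
    ------
    SingularDesignError
        Constant predictor or rank-deficient design (the offending term is
        named).
    DomainError
        Fewer than ``n_params + 10`` complete cases.
    """
    if covariates is None:
        covariates = {}
    if isinstance(covariates, pd.DataFrame):
        covariates = {c: covariates[c] for c in covariates.columns}

    cols = {g_name: g, e_name: e}
    cols["interaction"] = g * e
    for name, v in covariates.items():
        if name in cols:
            raise ConfigurationError(f"duplicate term name {name!r}")
        cols[name] = v
    df = pd.DataFrame(cols)
    df["_y"] = outcome
    df = df.dropna()
    n_used = len(df)
    k = len(cols) + 1  # + intercept
    if n_used < k + MIN_EXTRA_CASES:
        raise DomainError(
            f"insufficient complete cases: n={n_used} for {k} parameters"
        )

    y = df.pop("_y")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        raise SingularDesignError(f"constant predictor term(s): {constant}")
    X = sm.add_constant(df, prepend=True)
    offenders = _diagnose_rank(X)
    if offenders:
        raise SingularDesignError(
            f"rank-deficient design; dependent term(s): {offenders}"
        )

    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    sd_y = y.std(ddof=1)
    sd_x = X.std(ddof=1)
    beta = res.params * sd_x.to_numpy() / sd_y
    beta[0] = np.nan  # intercept has no standardized coefficient
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "b": res.params,
            "se": res.bse,
            "beta": beta,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=names,
    )
    return InteractionResult(
        table=table, n_used=n_used, df_resid=int(res.df_resid)
    )


# ---------------------------------------------------------------------------
# Level 1: whole-GRS x food screen


@dataclass(frozen=True)
class ScreeningReport:
    """Per (food x scheme) interaction p-values and the flagged foods.

    ``table`` columns: food, scheme, p_continuous, p_dichotomized (NaN when
    the borderline fallback was not triggered), n_used.
    """

    table: pd.DataFrame
    alpha: float
    flagged: list[str]

    def __post_init__(self):
        tested = set(self.table["food"])
        if not set(self.flagged) <= tested:
            raise DomainError("flagged foods must be a subset of tested foods")


def flag_foods(
    pvalues: pd.DataFrame, alpha: float = 0.15, food_column: str = "food"
) -> list[str]:
    """Apply the screening flag rule to a p-value table.

    A food is flagged when *any* scheme's continuous-score p-value, or its
    dichotomized-score p-value where available, is below ``alpha``.  Works
    both on reports produced by :func:`screen_whole_grs` and on published
    p-value tables.
    """
    flagged = []
    for food, grp in pvalues.groupby(food_column, sort=False):
        hit = (grp["p_continuous"] < alpha).any()
        if "p_dichotomized" in grp:
            hit = hit or (grp["p_dichotomized"] < alpha).any()
        if hit:
            flagged.append(food)
    return flagged


def screen_whole_grs(
    cohort: pd.DataFrame,
    scores: Mapping[str, ScoreVector],
    foods: Sequence[str],
    outcome: str = "bmiz",
    covariates: Sequence[str] = SCREEN_COVARIATES,
    alpha: float = 0.15,
    borderline_band: tuple[float, float] = (0.15, 0.25),
) -> ScreeningReport:
    """Level-one screen: every food against every whole-GRS scheme.

    For each (food, scheme) the continuous-score interaction model is
    fitted; when the p-value is borderline (within ``borderline_band``) the
    model is refitted with the scheme's score dichotomized at its median
    (low = 0, high = 1) and both p-values are reported.
    """
    if len(foods) == 0:
        raise DomainError("empty food list")
    lo, hi = borderline_band
    if not (0.0 <= lo < hi <= 1.0):
        raise DomainError(f"invalid borderline band {borderline_band}")
    covs = cohort[list(covariates)]
    rows = []
    for food in foods:
        for scheme, sv in scores.items():
            s = sv.values.reindex(cohort.index)
            fit = fit_interaction(
                cohort[outcome], s, cohort[food], covs,
                g_name="score", e_name=food,
            )
            p_cont = float(fit.interaction["p"])
            p_dich = np.nan
            if lo <= p_cont < hi:
                labels, _ = median_split(s)
                binary = labels.map({"low": 0.0, "high": 1.0})
                dfit = fit_interaction(
                    cohort[outcome], binary, cohort[food], covs,
                    g_name="score_group", e_name=food,
                )
                p_dich = float(dfit.interaction["p"])
            rows.append(
                {
                    "food": food,
                    "scheme": scheme,
                    "b_continuous": float(fit.interaction["b"]),
                    "p_continuous": p_cont,
                    "p_dichotomized": p_dich,
                    "n_used": fit.n_used,
                }
            )
    table = pd.DataFrame(rows)
    return ScreeningReport(
        table=table, alpha=alpha, flagged=flag_foods(table, alpha)
    )


# ---------------------------------------------------------------------------
# Level 2: per-SNP screen and food-specific GRS


@dataclass(frozen=True)
class FoodSpecificGRS:
    """A food item plus the SNP subset selected by the cascade."""

    food: str
    rsids: list[str]
    reference_direction: int  # +1 or -1: sign of the whole-GRS interaction

    def __post_init__(self):
        if len(self.rsids) == 0:
            raise BuildError(f"empty SNP selection for {self.food!r}")
        if len(set(self.rsids)) != len(self.rsids):
            raise BuildError(f"duplicate rsIDs in selection for {self.food!r}")
        if self.reference_direction not in (-1, 1):
            raise DomainError("reference_direction must be +1 or -1")


def screen_snps(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    food: str,
    reference_direction: int,
    outcome: str = "bmiz",
    covariates: Sequence[str] = SCREEN_COVARIATES,
    alpha: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Level-two screen: per-SNP dosage x food interactions.

    Selects SNPs with ``sign(interaction b) == reference_direction`` and
    two-sided p < ``alpha``; panel order is preserved.  Returns the
    selection plus the full per-SNP results table.  An empty selection is
    returned with a warning (building a food GRS from it will refuse).
    """
    if reference_direction not in (-1, 1):
        raise DomainError("reference_direction must be +1 or -1")
    covs = cohort[list(covariates)]
    rows = []
    for rsid in panel.rsids:
        d = genotypes.dosage[rsid].reindex(cohort.index)
        fit = fit_interaction(
            cohort[outcome], d, cohort[food], covs,
            g_name=rsid, e_name=food,
        )
        b = float(fit.interaction["b"])
        p = float(fit.interaction["p"])
        selected = (np.sign(b) == reference_direction) and (p < alpha)
        rows.append(
            {"rsid": rsid, "food": food, "b": b, "p": p,
             "selected": bool(selected), "n_used": fit.n_used}
        )
    table = pd.DataFrame(rows)
    selection = list(table.loc[table["selected"], "rsid"])
    if not selection:
        warnings.warn(
            f"no SNP passed the screen for {food!r} "
            f"(direction {reference_direction:+d}, p < {alpha})",
            UserWarning,
            stacklevel=2,
        )
    return selection, table


def build_food_grs(
    panel: SNPPanel,
    selected: Sequence[str],
    food: str,
    reference_direction: int,
) -> FoodSpecificGRS:
    """Combine a screened SNP selection into a food-specific GRS
    (scored downstream as an unweighted risk-allele count)."""
    if len(selected) == 0:
        raise BuildError(f"cannot build a food GRS for {food!r}: no SNPs selected")
    unknown = [r for r in selected if r not in set(panel.rsids)]
    if unknown:
        raise ConfigurationError(f"selected rsID(s) not in panel: {unknown}")
    return FoodSpecificGRS(
        food=food, rsids=list(selected), reference_direction=reference_direction
    )


def validate_food_grs(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    fgrs: FoodSpecificGRS,
    models: Mapping[int, Sequence[str]] | None = None,
    outcome: str = "bmiz",
) -> dict[int, InteractionResult]:
    """Refit the interaction with the food-specific score under the two
    validation covariate models (1: sex; 2: sex + physical activity +
    sleep).  Returns one InteractionResult per model; the focal rows are
    ``score``, the food term and ``interaction``."""
    models = dict(models or VALIDATION_MODELS)
    sv = subset_score(genotypes, panel, fgrs.rsids, scheme="unweighted")
    s = sv.values.reindex(cohort.index)
    out: dict[int, InteractionResult] = {}
    for model_id, covariates in models.items():
        out[model_id] = fit_interaction(
            cohort[outcome], s, cohort[fgrs.food], cohort[list(covariates)],
            g_name="score", e_name=fgrs.food,
        )
    return out


# ---------------------------------------------------------------------------
# Stratified effects


@dataclass(frozen=True)
class StratifiedEffects:
    """Food effect on BMIz within low/high strata of a food-specific GRS.

    ``per_group`` maps 'low'/'high' to dicts with keys b, ci_low, ci_high,
    p, n; ``interaction_b``/``interaction_p`` come from the joint
    group x food model.
    """

    food: str
    per_group: dict[str, dict[str, float]]
    interaction_b: float
    interaction_p: float
    cutoff: float
    joint: InteractionResult = field(repr=False)

    def __post_init__(self):
        if set(self.per_group) != {"low", "high"}:
            raise DomainError("strata labels must be exactly {'low', 'high'}")


def stratified_effects(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    fgrs: FoodSpecificGRS,
    outcome: str = "bmiz",
    covariates: Sequence[str] = VALIDATION_MODELS[2],
) -> StratifiedEffects:
    """Estimate the food effect separately in the low and high strata of
    the food-specific score (median rule, median to 'low'), plus the joint
    group x food interaction model with the same covariates."""
    sv = subset_score(genotypes, panel, fgrs.rsids, scheme="unweighted")
    s = sv.values.reindex(cohort.index)
    labels, cutoff = median_split(s)
    covs = list(covariates)

    per_group: dict[str, dict[str, float]] = {}
    for grp in ("low", "high"):
        sub = cohort[labels == grp]
        X = pd.DataFrame({fgrs.food: sub[fgrs.food]})
        for c in covs:
            X[c] = sub[c]
        df = X.copy()
        df["_y"] = sub[outcome]
        df = df.dropna()
        k = df.shape[1]  # terms + intercept (y replaced by const)
        if len(df) < k + MIN_EXTRA_CASES:
            raise DomainError(
                f"stratum {grp!r} has too few complete cases ({len(df)})"
            )
        y = df.pop("_y")
        Xc = sm.add_constant(df, prepend=True)
        res = sm.OLS(y.to_numpy(), Xc.to_numpy()).fit()
        idx = list(Xc.columns).index(fgrs.food)
        ci = res.conf_int(alpha=0.05)
        per_group[grp] = {
            "b": float(res.params[idx]),
            "ci_low": float(ci[idx, 0]),
            "ci_high": float(ci[idx, 1]),
            "p": float(res.pvalues[idx]),
            "n": int(len(df)),
        }

    binary = labels.map({"low": 0.0, "high": 1.0})
    joint = fit_interaction(
        cohort[outcome], binary, cohort[fgrs.food],
        cohort[covs] if covs else None,
        g_name="risk_group", e_name=fgrs.food,
    )
    return StratifiedEffects(
        food=fgrs.food,
        per_group=per_group,
        interaction_b=float(joint.interaction["b"]),
        interaction_p=float(joint.interaction["p"]),
        cutoff=cutoff,
        joint=joint,
    )


# ---------------------------------------------------------------------------
# Shared-SNP set analysis


@dataclass(frozen=True)
class SharedSNPReport:
    """Set relations between food-specific SNP selections.

    ``membership`` is a boolean rsID x food DataFrame; ``venn_counts`` maps
    an '&'-joined food combination to the number of rsIDs belonging to
    exactly that combination (exclusive Venn regions).
    """

    foods: list[str]
    membership: pd.DataFrame
    union: list[str]
    intersection: list[str]
    venn_counts: dict[str, int]

    def intersection_of(self, foods: Sequence[str]) -> list[str]:
        """rsIDs present in *all* of the given foods (inclusive)."""
        m = self.membership[list(foods)]
        return list(self.membership.index[m.all(axis=1)])


def shared_snp_analysis(
    fgrs_list: Sequence[FoodSpecificGRS],
) -> SharedSNPReport:
    """Exact set algebra over food-specific SNP selections.

    Reports the union, the full intersection, the membership matrix and the
    cardinality of every exclusive Venn region (non-empty combinations).
    """
    if len(fgrs_list) == 0:
        raise DomainError("need at least one food-specific GRS")
    foods = [f.food for f in fgrs_list]
    if len(set(foods)) != len(foods):
        raise ConfigurationError("duplicate food in shared-SNP analysis")
    sets = {f.food: set(f.rsids) for f in fgrs_list}

    order: list[str] = []
    for f in fgrs_list:
        for r in f.rsids:
            if r not in order:
                order.append(r)
    membership = pd.DataFrame(
        {food: [r in sets[food] for r in order] for food in foods},
        index=pd.Index(order, name="rsid"),
    )

    union = list(order)
    inter = [r for r in order if all(r in sets[f] for f in foods)]

    venn: dict[str, int] = {}
    patterns = membership.apply(
        lambda row: "&".join(sorted(f for f in foods if row[f])), axis=1
    )
    for key, grp in patterns.groupby(patterns):
        venn[key] = int(len(grp))
    return SharedSNPReport(
        foods=foods,
        membership=membership,
        union=union,
        intersection=inter,
        venn_counts=venn,
    )


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional reporting add-on)."""
    from statsmodels.stats.multitest import multipletests

    mask = pvalues.notna()
    adj = pd.Series(np.nan, index=pvalues.index)
    if mask.any():
        adj[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return adj
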