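"""Genetic risk score (GRS) engine.

Houses the SNP panel used for the BMI genetic risk score and computes
whole-panel and subset (food-specific) risk scores under four weighting
schemes:

``unweighted``
    Plain count of risk alleles over the non-missing SNPs.
``speliotes``
    Published GWAS per-allele effect sizes as weights, averaged per
    non-missing SNP (PLINK ``--score`` convention).
``finhit``
    Cohort-specific re-estimated effect sizes as weights, same averaging.
``ratio``
    Weight for SNP *j* is ``beta_finhit_j / beta_speliotes_j``, expressing
    the cohort-specific effect relative to the discovery GWAS.

Missing genotypes are handled PLINK-style: weighted scores are averages over
the non-missing SNPs of an individual, so individuals with different
missingness patterns remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FormatError

SCHEMES = ("unweighted", "speliotes", "finhit", "ratio")

_PANEL_COLUMNS = [
    "rsid",
    "risk_allele",
    "other_allele",
    "beta_speliotes",
    "beta_finhit",
    "gene",
]

#: Strand-ambiguous allele pairs (indistinguishable from their reverse
#: complement); orientation against such panel entries is not guessed.
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class SNPPanel:
    """Ordered catalogue of risk SNPs with risk alleles and effect sizes.

    Parameters
    ----------
    entries : pandas.DataFrame
        One row per SNP with columns ``rsid``, ``risk_allele``,
        ``other_allele``, ``beta_speliotes``, ``beta_finhit`` and ``gene``.
        Row order is preserved everywhere downstream.
    """

    entries: pd.DataFrame

    def __post_init__(self):
        df = self.entries
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"panel is missing column(s): {missing}")
        if df["rsid"].duplicated().any():
            dupes = sorted(df.loc[df["rsid"].duplicated(), "rsid"])
            raise FormatError(f"duplicated rsID(s) in panel: {dupes}")
        same = df["risk_allele"] == df["other_allele"]
        if same.any():
            raise FormatError(
                "risk and other allele identical for "
                f"{sorted(df.loc[same, 'rsid'])}"
            )
        if (df["beta_speliotes"] <= 0).any():
            bad = sorted(df.loc[df["beta_speliotes"] <= 0, "rsid"])
            raise FormatError(
                f"beta_speliotes must be positive (risk alleles): {bad}"
            )
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    @property
    def rsids(self) -> list[str]:
        return list(self.entries["rsid"])

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, rsids: Sequence[str]) -> "SNPPanel":
        """Return a panel restricted to ``rsids``, keeping panel order."""
        unknown = [r for r in rsids if r not in set(self.rsids)]
        if unknown:
            raise ConfigurationError(f"rsID(s) not in panel: {unknown}")
        keep = self.entries["rsid"].isin(set(rsids))
        return SNPPanel(self.entries.loc[keep])

    def weights(self, scheme: str) -> pd.Series:
        """Per-SNP weights for a scoring scheme, indexed by rsid."""
        e = self.entries.set_index("rsid")
        if scheme == "unweighted":
            return pd.Series(1.0, index=e.index)
        if scheme == "speliotes":
            return e["beta_speliotes"].astype(float)
        if scheme == "finhit":
            return e["beta_finhit"].astype(float)
        if scheme == "ratio":
            return (e["beta_finhit"] / e["beta_speliotes"]).astype(float)
        raise ConfigurationError(
            f"unknown scheme {scheme!r}; expected one of {SCHEMES}"
        )

    def ambiguous_rsids(self) -> list[str]:
        """rsIDs whose allele pair is strand-ambiguous (A/T or C/G)."""
        out = []
        for _, row in self.entries.iterrows():
            if {row["risk_allele"], row["other_allele"]} in AMBIGUOUS_PAIRS:
                out.append(row["rsid"])
        return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x SNPs risk-allele dosage matrix.

    ``dosage`` is a float DataFrame indexed by individual ID with one column
    per rsID; entries are 0, 1, 2 (risk-allele count) or NaN (missing).
    """

    dosage: pd.DataFrame

    def __post_init__(self):
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DomainError("dosages must be 0, 1, 2 or missing")
        if self.dosage.index.duplicated().any():
            raise FormatError("duplicated individual IDs")
        if self.dosage.columns.duplicated().any():
            raise FormatError("duplicated rsIDs in genotype matrix")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]


@dataclass(frozen=True)
class ScoreVector:
    """Per-individual risk score under one weighting scheme."""

    values: pd.Series
    scheme: str
    n_nonmissing: pd.Series = field(repr=False)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)


def default_panel_path() -> Path:
    """Path of the packaged 30-SNP panel file.

    The rsID and gene columns list the 30 well-replicated BMI loci used for
    the childhood BMI risk score; the allele and effect-size columns are
    synthetic, plausible stand-ins (the original per-allele weights are not
    redistributed with this package) and can be replaced by a user file.
    """
    return Path(
        str(resources.files("foodgrs.data") / "panel30_synthetic_weights.tsv")
    )


def load_panel(path: str | Path | None = None) -> SNPPanel:
    """Read a SNP panel from a TSV file.

    Parameters
    ----------
    path : str or Path, optional
        TSV with columns rsid / risk_allele / other_allele / beta_speliotes /
        beta_finhit / gene.  When omitted, the packaged default 30-SNP panel
        is loaded.

    Returns
    -------
    SNPPanel
        Panel with file row order preserved.
    """
    if path is None:
        path = default_panel_path()
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    return SNPPanel(df)


def _check_alignment(genotypes: GenotypeMatrix, panel: SNPPanel) -> None:
    absent = [r for r in panel.rsids if r not in set(genotypes.rsids)]
    if absent:
        raise ConfigurationError(
            f"panel rsID(s) absent from genotype matrix: {absent}"
        )


def score(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    scheme: str = "unweighted",
    per_allele: bool = False,
) -> ScoreVector:
    """Compute a whole-panel genetic risk score.

    Unweighted: sum of risk-allele dosages over the individual's non-missing
    SNPs (an integer count when nothing is missing).  Weighted schemes:
    ``sum_j w_j * dosage_ij / n_nonmissing_i`` — the average score per
    non-missing SNP.  With ``per_allele=True`` the divisor becomes
    ``2 * n_nonmissing`` (strict PLINK ``--score`` per-allele averaging).

    Individuals with every panel SNP missing cannot be scored; they are
    dropped with a warning.

    Raises
    ------
    ConfigurationError
        If a panel rsID is absent from the genotype matrix or the scheme is
        unknown.
    """
    _check_alignment(genotypes, panel)
    D = genotypes.dosage[panel.rsids].astype(float)
    n_nonmissing = D.notna().sum(axis=1)

    all_missing = n_nonmissing == 0
    if all_missing.any():
        dropped = list(D.index[all_missing])
        warnings.warn(
            f"excluding {len(dropped)} individual(s) with all panel SNPs "
            f"missing: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            UserWarning,
            stacklevel=2,
        )
        D = D.loc[~all_missing]
        n_nonmissing = n_nonmissing.loc[~all_missing]

    w = panel.weights(scheme)
    if scheme == "unweighted":
        values = D.sum(axis=1)  # count of risk alleles, skipping missing
    else:
        denom = n_nonmissing * (2 if per_allele else 1)
        values = (D * w).sum(axis=1) / denom
    return ScoreVector(values=values, scheme=scheme, n_nonmissing=n_nonmissing)


def subset_score(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    rsids: Sequence[str],
    scheme: str = "unweighted",
    per_allele: bool = False,
) -> ScoreVector:
    """Risk score restricted to a SNP subset (food-specific GRS scoring).

    ``rsids`` must be a subset of the panel; panel order is preserved.
    """
    if len(rsids) == 0:
        raise DomainError("rsid subset must be non-empty")
    return score(genotypes, panel.subset(rsids), scheme, per_allele)


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Split values at their median: value <= median -> ``low``, else
    ``high``.  Returns (labels, cutoff).  A constant vector yields all-low
    with a warning."""
    if len(values) < 2:
        raise DomainError("need at least two individuals to dichotomize")
    v = values.dropna()
    if v.empty:
        raise DomainError("cannot dichotomize an all-missing score vector")
    cutoff = float(v.median())
    if v.nunique() == 1:
        warnings.warn(
            "score vector is constant; all individuals labelled 'low'",
            UserWarning,
            stacklevel=2,
        )
    labels = pd.Series(
        np.where(values <= cutoff, "low", "high"), index=values.index
    )
    labels[values.isna()] = np.nan
    return labels, cutoff


def dichotomize(scores: ScoreVector) -> tuple[pd.Series, float]:
    """Dichotomize an unweighted risk-allele count at the cohort median.

    The median value itself goes to the ``low`` group, so e.g. with a median
    count of 27 the low-risk group spans counts <= 27 and the high-risk
    group counts >= 28.
    """
    return median_split(scores.values)
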