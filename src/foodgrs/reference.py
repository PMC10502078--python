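"""Packaged reference tables from the published childhood BMI gene-diet
interaction study this pipeline operationalizes.

Two plain-CSV fixtures ship with the package:

* the whole-GRS x food interaction screening p-values (continuous score,
  plus the dichotomized-score p-value where the borderline fallback was
  run), and
* the seven food-specific SNP selections that passed the per-SNP screen.

These are *published result tables*, usable as worked-example inputs; they
are not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Foods whose food-specific GRS interaction was validated in stratified
#: analysis (opposite-direction food effects in low vs high risk groups).
VALIDATED_FOODS = [
    "pizza",
    "sweets_and_chocolate",
    "sugary_juice_drink",
    "hamburger_and_hotdog",
]


def _data_path(name: str):
    return resources.files("foodgrs.data") / name


def load_published_screen_pvalues() -> pd.DataFrame:
    """Whole-GRS screening p-values: columns variable, kind (summary|food),
    scheme, p_continuous, p_dichotomized (NaN where not run)."""
    with resources.as_file(_data_path("published_screen_pvalues.csv")) as p:
        return pd.read_csv(p)


def load_published_food_grs() -> dict[str, list[str]]:
    """The published food-specific SNP selections, food -> ordered rsIDs."""
    with resources.as_file(_data_path("published_food_grs.csv")) as p:
        df = pd.read_csv(p)
    return {
        row["food"]: row["rsids"].split(";") for _, row in df.iterrows()
    }
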