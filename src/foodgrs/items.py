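"""Registry of the 16 food-frequency questionnaire items and the default
conventions attached to them.

The questionnaire asks how often each item was consumed, on a 7-point scale
from 1 ("not at all") to 7 ("several times a day").  During analysis the
ratings are recoded to weekly consumption frequencies on a 0-14 times/week
scale; only the two endpoints of that recoding are fixed by convention
(1 -> 0, 7 -> 14), the interior values are an explicit, overridable mapping.
"""

from __future__ import annotations

# Order matters: it is the presentation order used in cohort tables.
FFQ_ITEMS: list[str] = [
    "dark_bread",
    "sweet_pastry",
    "biscuits_and_cookies",
    "ice_cream",
    "sugary_juice_drink",
    "sugary_soft_drink",
    "sweets_and_chocolate",
    "pizza",
    "hamburger_and_hotdog",
    "milk_and_sourmilk",
    "cooked_vegetables",
    "fresh_and_grated_vegetables",
    "fruit_and_berries",
    "juice",
    "salty_snacks",
    "water",
]

DISPLAY_NAMES: dict[str, str] = {
    "dark_bread": "Dark bread",
    "sweet_pastry": "Sweet pastry",
    "biscuits_and_cookies": "Biscuits and cookies",
    "ice_cream": "Ice cream",
    "sugary_juice_drink": "Sugary juice drink",
    "sugary_soft_drink": "Sugary soft drink",
    "sweets_and_chocolate": "Sweets and chocolate",
    "pizza": "Pizza",
    "hamburger_and_hotdog": "Hamburger and hotdog",
    "milk_and_sourmilk": "Milk and sourmilk",
    "cooked_vegetables": "Cooked vegetables",
    "fresh_and_grated_vegetables": "Fresh and grated vegetables",
    "fruit_and_berries": "Fruit and berries",
    "juice": "Juice",
    "salty_snacks": "Salty snacks",
    "water": "Water",
}

#: Sweet treat index (STI): sugary/energy-dense snack items.
SWEET_TREAT_ITEMS: list[str] = [
    "sweet_pastry",
    "biscuits_and_cookies",
    "ice_cream",
    "sugary_juice_drink",
    "sugary_soft_drink",
    "sweets_and_chocolate",
]

#: Plant consumption index (PCI): vegetables, fruit and berries.
PLANT_ITEMS: list[str] = [
    "cooked_vegetables",
    "fresh_and_grated_vegetables",
    "fruit_and_berries",
]

#: Default 7-point rating -> times/week recoding.  Endpoints are the
#: contractual anchors (1 = never = 0/week, 7 = several times a day =
#: 14/week); the interior values are a documented convention.
DEFAULT_RATING_TO_WEEKLY: dict[int, float] = {
    1: 0.0,
    2: 0.5,
    3: 1.0,
    4: 2.5,
    5: 5.5,
    6: 7.0,
    7: 14.0,
}

#: Target weekly consumption means (times/week) used to calibrate the
#: synthetic cohort's per-item rating distributions.  Values are typical
#: for Finnish school children around age 11.
DEFAULT_WEEKLY_MEANS: dict[str, float] = {
    "dark_bread": 4.8,
    "sweet_pastry": 1.15,
    "biscuits_and_cookies": 1.8,
    "ice_cream": 2.0,
    "sugary_juice_drink": 2.25,
    "sugary_soft_drink": 1.4,
    "sweets_and_chocolate": 1.4,
    "pizza": 0.55,
    "hamburger_and_hotdog": 0.6,
    "milk_and_sourmilk": 10.5,
    "cooked_vegetables": 1.7,
    "fresh_and_grated_vegetables": 5.65,
    "fruit_and_berries": 4.55,
    "juice": 3.5,
    "salty_snacks": 1.0,
    "water": 9.8,
}

#: Summary dietary indices screened alongside the individual items.
SUMMARY_INDICES: list[str] = ["sweet_treat_index", "plant_consumption_index"]
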