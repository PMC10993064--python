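"""Synthetic dataset generator emulating a national dietary-intake survey.

The real study population (group-level mean and centile consumption over 74
food categories for sex x education-tertile x income-quintile groups, a food
composition matrix derived from a national food-composition database, and two
sets of per-food GHGE coefficients) is not publicly available.  This module
generates a complete, self-consistent stand-in with the same statistical
structure so that every stage of the pipeline is testable:

* individual consumption is drawn from a zero-inflated log-normal per
  (group, food); group means and the 10th/90th centiles are the *empirical*
  statistics of the simulated individuals (all individuals, non-consumers
  included), so mean, p10 and p90 are mutually consistent by construction;
* the composition matrix comes from per-food templates with multiplicative
  noise and exact macro-energy closure (energy density = 17*(protein + carb)
  + 37*fat + 29*alcohol kJ/g), so E% accounting is exact;
* the LCA GHGE coefficient template ranks ruminant meat above cheese above
  pork/poultry above fish/eggs above plant staples; the land-use variant
  multiplies domestic foods by a class-specific uplift and leaves wild fish,
  wild berries and imports untouched;
* baseline diets are calibrated (design-time, frozen constants below) to the
  published average Finnish adult conditions: male ~9.4 MJ/day with dietary
  GHGE ~5.3 kg CO2e/cap/day, female ~7.4 MJ with ~3.8 kg, insufficient fibre
  and folate, excess saturated fat, too little carbohydrate energy and excess
  sodium, while protein and amino acid minima are comfortably met.

The generator is deterministic: one seed fixes every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import RecommendationSet
from .foods import (
    CompositionMatrix,
    FoodCategory,
    FoodTable,
    GHGETable,
    GroupDiet,
    compute_nutrients,
)
from .io import DataBundle, write_bundle

__all__ = ["GeneratorConfig", "generate", "generate_to", "make_toy", "adequate_group"]

SEXES = ("male", "female")
STRATA = ("all", "Educ1", "Educ2", "Educ3", "IncQ1", "IncQ3", "IncQ5")

# kJ per gram of energy-yielding nutrient (Nordic labelling convention)
KJ_PER_G = {"protein": 17.0, "carb": 17.0, "fat": 37.0, "sfa": 37.0, "alcohol": 29.0}

# ---------------------------------------------------------------------------
# food template: 74 categories in 13 main reporting groups
#
# columns: id, main_group, mean_male (g/cap/day before _CONSUMPTION_SCALE),
#   pi (probability of zero consumption), sigma (log-scale sd of the positive
#   part), milk_eq (g raw milk / g), beef_content (fraction of beef carcass),
#   then per-gram densities: protein, fat, sfa_share (SFA as fraction of fat),
#   carb, fibre, alcohol (g/g), sodium (mg/g), iron (mg/g), calcium (mg/g),
#   potassium (mg/g), zinc (mg/g), vit_c (mg/g), vit_d (ug/g), folate (ug/g),
#   b12 (ug/g), ghge_lca (kg CO2e/kg), landuse_uplift (dimensionless)
# ---------------------------------------------------------------------------

_COLS = (
    "id main_group mean_male pi sigma milk_eq beef prot fat sfash carb fibre "
    "alc na fe ca k zn vitc vitd fol b12 ghge uplift"
).split()

_TEMPLATE_ROWS = [
    # cereals
    ("rye_bread",         "cereals", 55, 0.05, 0.60, 0, 0, .085, .012, .20, .45, .087, 0, 4.2, .028, .30, 2.4, .013, 0,   0,    .40, 0,    1.10, 1.45),
    ("wheat_bread",       "cereals", 60, 0.05, 0.60, 0, 0, .080, .040, .25, .47, .040, 0, 4.2, .011, .20, 1.5, .008, 0,   0,    .25, 0,    0.95, 1.45),
    ("crispbread",        "cereals", 12, 0.30, 0.70, 0, 0, .100, .015, .20, .60, .150, 0, 3.8, .035, .40, 3.5, .030, 0,   0,    .40, 0,    0.90, 1.45),
    ("oat_porridge",      "cereals", 95, 0.15, 0.65, 0, 0, .021, .011, .18, .090, .017, 0, 1.5, .007, .08, 0.6, .004, 0,   0,    .06, 0,    0.55, 1.45),
    ("other_porridges",   "cereals", 25, 0.40, 0.70, 0, 0, .020, .005, .20, .100, .012, 0, 1.5, .006, .10, 0.5, .003, 0,   0,    .05, 0,    0.60, 1.45),
    ("pasta",             "cereals", 40, 0.30, 0.65, 0, 0, .050, .010, .20, .28, .018, 0, 0.1, .006, .07, 0.4, .005, 0,   0,    .07, 0,    0.90, 1.20),
    ("rice",              "cereals", 25, 0.35, 0.70, 0, 0, .027, .003, .30, .28, .010, 0, 0.0, .002, .03, 0.3, .004, 0,   0,    .04, 0,    3.50, 1.00),
    ("pastries_buns",     "cereals", 45, 0.20, 0.65, 0, 0, .070, .150, .45, .50, .020, 0, 3.2, .012, .40, 1.2, .007, 0,   .005, .20, 0,    1.70, 1.40),
    # potatoes
    ("potatoes_boiled",   "potatoes", 75, 0.10, 0.65, 0, 0, .017, .001, .25, .15, .013, 0, 0.05, .004, .06, 3.8, .003, .08, 0,   .10, 0,    0.35, 1.50),
    ("potatoes_fried",    "potatoes", 18, 0.40, 0.70, 0, 0, .025, .070, .30, .20, .017, 0, 3.0, .005, .10, 4.0, .004, .06, 0,   .12, 0,    0.85, 1.50),
    ("potato_dishes",     "potatoes", 22, 0.40, 0.70, 0, 0, .020, .040, .40, .12, .012, 0, 4.0, .004, .30, 3.0, .003, .04, 0,   .10, 0,    0.90, 1.50),
    # vegetables
    ("tomatoes",          "vegetables", 28, 0.15, 0.55, 0, 0, .009, 0, 0, .027, .014, 0, 0.03, .003, .10, 2.7, 0,    .14, 0,   .30, 0,    2.40, 1.30),
    ("cucumber",          "vegetables", 22, 0.20, 0.55, 0, 0, .006, 0, 0, .015, .007, 0, 0.02, .002, .20, 1.5, 0,    .08, 0,   .14, 0,    2.00, 1.30),
    ("carrots_roots",     "vegetables", 32, 0.15, 0.55, 0, 0, .008, 0, 0, .060, .028, 0, 0.40, .003, .30, 2.9, 0,    .05, 0,   .25, 0,    0.35, 1.50),
    ("cabbages",          "vegetables", 16, 0.30, 0.60, 0, 0, .013, 0, 0, .035, .026, 0, 0.10, .004, .45, 2.5, 0,    .40, 0,   .60, 0,    0.40, 1.50),
    ("onion_garlic",      "vegetables", 14, 0.20, 0.55, 0, 0, .011, 0, 0, .070, .018, 0, 0.02, .002, .25, 1.6, 0,    .07, 0,   .20, 0,    0.45, 1.50),
    ("leafy_salads",      "vegetables", 14, 0.25, 0.60, 0, 0, .013, 0, 0, .015, .014, 0, 0.05, .010, .40, 3.0, 0,    .20, 0,   .80, 0,    1.60, 1.30),
    ("other_fruiting_veg","vegetables", 12, 0.35, 0.60, 0, 0, .009, 0, 0, .040, .018, 0, 0.02, .004, .10, 2.1, 0,    .90, 0,   .45, 0,    2.20, 1.05),
    ("vegetable_dishes",  "vegetables", 42, 0.25, 0.60, 0, 0, .020, .040, .25, .070, .020, 0, 4.0, .006, .35, 2.4, .003, .10, 0, .30, 0,  1.10, 1.50),
    # fruits & berries
    ("apples_pears",      "fruits_berries", 58, 0.20, 0.60, 0, 0, .003, 0, 0, .110, .021, 0, 0.01, .001, .06, 1.2, 0, .05, 0,  .05, 0,    0.32, 1.10),
    ("citrus",            "fruits_berries", 38, 0.30, 0.65, 0, 0, .008, 0, 0, .090, .018, 0, 0.01, .001, .30, 1.6, 0, .45, 0,  .30, 0,    0.50, 1.00),
    ("bananas",           "fruits_berries", 40, 0.30, 0.65, 0, 0, .010, 0, 0, .200, .017, 0, 0.01, .003, .05, 3.6, 0, .10, 0,  .20, 0,    0.75, 1.00),
    ("berries_cultivated","fruits_berries", 22, 0.30, 0.70, 0, 0, .007, 0, 0, .080, .030, 0, 0.01, .004, .25, 1.6, 0, .45, 0,  .25, 0,    0.95, 1.45),
    ("berries_wild",      "fruits_berries", 16, 0.40, 0.75, 0, 0, .007, 0, 0, .070, .050, 0, 0.01, .004, .20, 1.0, 0, .30, 0,  .20, 0,    0.12, 1.00),
    ("other_fruits",      "fruits_berries", 18, 0.35, 0.70, 0, 0, .006, 0, 0, .130, .022, 0, 0.01, .003, .10, 2.2, 0, .25, 0,  .15, 0,    0.60, 1.00),
    ("dried_fruits",      "fruits_berries",  5, 0.55, 0.80, 0, 0, .025, 0, 0, .600, .080, 0, 0.10, .020, .60, 7.5, 0, .02, 0,  .10, 0,    1.40, 1.00),
    # legumes, seeds & nuts
    ("legumes_pulses",    "legumes_nuts", 14, 0.50, 0.75, 0, 0, .080, .010, .15, .120, .070, 0, 0.10, .020, .45, 3.0, .010, .01, 0, .55, 0, 0.80, 1.30),
    ("soy_products",      "legumes_nuts",  8, 0.45, 0.80, 0, 0, .140, .070, .15, .030, .015, 0, 0.20, .020, 1.5, 1.5, .010, 0, 0,  .30, 0, 1.30, 1.00),
    ("nuts",              "legumes_nuts",  9, 0.45, 0.75, 0, 0, .200, .550, .12, .080, .070, 0, 0.10, .030, 1.0, 6.5, .030, 0, 0,  .60, 0, 1.60, 1.00),
    ("seeds",             "legumes_nuts",  4, 0.55, 0.80, 0, 0, .220, .450, .12, .100, .150, 0, 0.05, .080, 2.5, 7.0, .060, 0, 0,  .90, 0, 1.20, 1.10),
    # meat (beef carcass fractions: beef 100%, offals 88%, meat dishes 50%, sausages & cuts 7.5%)
    ("beef",              "meat", 28, 0.35, 0.70, 0, 1.000, .210, .120, .45, 0, 0, 0, 0.70, .026, .05, 3.0, .045, 0, .002, .10, .020, 34.0, 1.35),
    ("pork",              "meat", 32, 0.35, 0.70, 0, 0,     .200, .140, .38, 0, 0, 0, 0.60, .008, .05, 3.2, .025, 0, .006, .04, .008, 5.50, 1.35),
    ("poultry",           "meat", 42, 0.30, 0.65, 0, 0,     .200, .080, .30, 0, 0, 0, 0.70, .005, .06, 2.6, .013, 0, .003, .06, .004, 4.30, 1.30),
    ("lamb_game",         "meat",  5, 0.60, 0.85, 0, 0,     .200, .100, .45, 0, 0, 0, 0.60, .025, .06, 3.0, .040, 0, .003, .05, .025, 22.0, 1.15),
    ("offals",            "meat",  3, 0.50, 0.90, 0, 0.880, .180, .050, .35, .02, 0, 0, 0.70, .080, .05, 3.0, .040, .02, .010, 2.0, .300, 6.00, 1.35),
    ("meat_dishes",       "meat", 24, 0.30, 0.65, 0, 0.500, .140, .150, .42, .04, .005, 0, 11.0, .015, .20, 2.5, .025, 0, .002, .10, .010, 11.5, 1.35),
    ("sausages",          "meat", 30, 0.30, 0.65, 0, 0.075, .120, .200, .40, .04, 0, 0, 11.5, .010, .10, 2.0, .020, .01, .005, .04, .008, 6.80, 1.35),
    ("sausage_cuts",      "meat", 14, 0.40, 0.70, 0, 0.075, .140, .180, .40, .02, 0, 0, 13.0, .010, .10, 2.2, .020, 0, .005, .04, .008, 6.80, 1.35),
    ("meat_cuts",         "meat", 18, 0.35, 0.70, 0, 0.075, .180, .080, .38, 0, 0, 0, 13.0, .009, .08, 2.8, .020, 0, .004, .04, .007, 6.20, 1.35),
    # fish & eggs
    ("fatty_fish",        "fish_eggs", 18, 0.45, 0.75, 0, 0, .190, .120, .20, 0, 0, 0, 0.50, .004, .10, 3.5, .005, 0, .080, .15, .030, 5.20, 1.05),
    ("lean_fish",         "fish_eggs", 12, 0.50, 0.80, 0, 0, .180, .010, .25, 0, 0, 0, 0.80, .003, .20, 3.8, .005, 0, .020, .12, .020, 2.20, 1.05),
    ("wild_fish",         "fish_eggs",  8, 0.55, 0.85, 0, 0, .190, .008, .25, 0, 0, 0, 0.50, .004, .30, 3.9, .005, 0, .100, .10, .020, 0.60, 1.00),
    ("fish_products",     "fish_eggs", 10, 0.50, 0.80, 0, 0, .140, .100, .25, .05, 0, 0, 10.0, .004, .30, 2.8, .005, 0, .050, .12, .015, 3.20, 1.10),
    ("shellfish",         "fish_eggs",  2, 0.75, 0.90, 0, 0, .150, .010, .30, 0, 0, 0, 4.00, .020, .40, 2.0, .015, 0, .004, .15, .080, 6.00, 1.00),
    ("eggs",              "fish_eggs", 24, 0.30, 0.65, 0, 0, .125, .100, .30, 0, 0, 0, 1.30, .018, .50, 1.3, .013, 0, .017, .45, .020, 2.60, 1.30),
    # milk (dairy; milk equivalents in g raw milk per g product)
    ("milk_skim",         "milk", 140, 0.30, 0.80, 1.0, 0, .034, .001, .60, .049, 0, 0, 0.40, 0, 1.20, 1.6, .004, 0, .010, .05, .004, 0.92, 1.40),
    ("milk_semi",         "milk", 130, 0.35, 0.85, 1.0, 0, .034, .015, .65, .048, 0, 0, 0.40, 0, 1.20, 1.6, .004, 0, .010, .05, .004, 1.02, 1.40),
    ("milk_whole",        "milk",  25, 0.55, 0.90, 1.0, 0, .033, .035, .65, .047, 0, 0, 0.40, 0, 1.15, 1.5, .004, 0, .010, .04, .004, 1.12, 1.40),
    ("sour_milk",         "milk",  55, 0.45, 0.85, 1.0, 0, .033, .010, .65, .040, 0, 0, 0.40, 0, 1.20, 1.6, .004, 0, .010, .09, .004, 0.97, 1.40),
    ("yoghurt",           "milk",  75, 0.35, 0.80, 1.3, 0, .040, .020, .60, .100, 0, 0, 0.50, 0, 1.30, 1.8, .005, 0, .008, .05, .003, 1.35, 1.40),
    ("cheese_ripened",    "milk",  42, 0.20, 0.60, 10.0, 0, .260, .300, .65, 0, 0, 0, 9.50, 0, 8.00, 1.0, .040, 0, .005, .30, .015, 9.80, 1.40),
    ("cheese_fresh",      "milk",  14, 0.40, 0.70, 4.0, 0, .100, .120, .65, .030, 0, 0, 5.00, 0, 1.00, 1.0, .005, 0, .002, .10, .005, 4.20, 1.40),
    ("cream",             "milk",  18, 0.35, 0.70, 5.0, 0, .020, .250, .65, .030, 0, 0, 0.30, 0, 0.80, 1.0, .003, 0, .003, .04, .002, 4.40, 1.40),
    ("ice_cream_desserts","milk",  16, 0.45, 0.80, 2.0, 0, .035, .090, .65, .220, 0, 0, 0.70, 0, 1.20, 1.6, .004, 0, .002, .04, .002, 2.30, 1.40),
    # fats & oils
    ("butter",            "fats_oils",  9, 0.40, 0.75, 0, 0, .005, .810, .68, 0, 0, 0, 0.60, 0, .15, 0.2, 0, 0, .010, 0, 0,    12.5, 1.40),
    ("butter_veg_spread", "fats_oils", 14, 0.35, 0.70, 0, 0, .004, .600, .40, 0, 0, 0, 1.00, 0, .05, 0.2, 0, 0, .220, 0, 0,    6.50, 1.30),
    ("margarine",         "fats_oils", 14, 0.35, 0.75, 0, 0, .002, .600, .25, 0, 0, 0, 1.00, 0, .05, 0.2, 0, 0, .220, 0, 0,    1.60, 1.10),
    ("veg_oils",          "fats_oils",  9, 0.30, 0.75, 0, 0, 0,    1.00, .12, 0, 0, 0, 0,    0, 0,   0,   0, 0, 0,    0, 0,    1.90, 1.10),
    ("dressings",         "fats_oils",  7, 0.45, 0.75, 0, 0, .010, .400, .15, .060, 0, 0, 5.00, 0, .10, 0.5, 0, 0, 0,  .05, 0,  2.20, 1.10),
    # sugar & sweets
    ("sugar_syrups",      "sugar_sweets", 12, 0.25, 0.80, 0, 0, 0, 0, 0, .980, 0, 0, 0.02, 0, .02, 0.2, 0, 0, 0, 0, 0,        0.80, 1.25),
    ("chocolate",         "sugar_sweets", 12, 0.35, 0.70, 0, 0, .060, .320, .60, .550, .020, 0, 0.40, .012, 1.90, 4.0, .010, 0, 0, .10, 0, 4.80, 1.00),
    ("sweets_candy",      "sugar_sweets", 12, 0.40, 0.75, 0, 0, .010, .005, .50, .850, 0, 0, 0.30, 0, .05, 0.2, 0, 0, 0, 0, 0,  1.80, 1.10),
    ("honey_jam",         "sugar_sweets",  9, 0.45, 0.75, 0, 0, 0, 0, 0, .700, .005, 0, 0.05, 0, .05, 0.6, 0, .02, 0, .02, 0,   1.00, 1.15),
    ("sweet_desserts",    "sugar_sweets", 12, 0.50, 0.80, 0, 0, .030, .080, .50, .250, .003, 0, 0.80, .002, .80, 1.2, .003, 0, .002, .05, .001, 2.00, 1.30),
    # drinks
    ("coffee",            "drinks", 520, 0.12, 0.50, 0, 0, .001, 0, 0, 0, 0, 0, 0.02, 0, .02, 0.5, 0, 0, 0, .01, 0,            0.14, 1.00),
    ("tea",               "drinks", 110, 0.45, 0.80, 0, 0, 0, 0, 0, 0, 0, 0, 0.01, 0, 0, 0.2, 0, 0, 0, .01, 0,                 0.07, 1.00),
    ("juices",            "drinks",  75, 0.35, 0.75, 0, 0, .003, 0, 0, .095, .001, 0, 0.02, .002, .08, 1.5, 0, .30, 0, .12, 0,  0.85, 1.05),
    ("soft_drinks_sugar", "drinks", 130, 0.40, 0.85, 0, 0, 0, 0, 0, .100, 0, 0, 0.05, 0, .02, 0.1, 0, 0, 0, 0, 0,              0.40, 1.10),
    ("soft_drinks_diet",  "drinks",  90, 0.50, 0.90, 0, 0, 0, 0, 0, .002, 0, 0, 0.10, 0, .02, 0.1, 0, 0, 0, 0, 0,              0.30, 1.10),
    ("waters_other",      "drinks", 180, 0.30, 0.80, 0, 0, 0, 0, 0, .001, 0, 0, 0.02, 0, .10, 0.1, 0, 0, 0, 0, 0,              0.08, 1.05),
    # alcohol
    ("beer",              "alcohol", 230, 0.35, 0.90, 0, 0, .003, 0, 0, .030, 0, .045, 0.03, 0, .04, 0.4, 0, 0, 0, .06, 0,     0.75, 1.35),
    ("wine",              "alcohol",  35, 0.50, 0.90, 0, 0, 0, 0, 0, .025, 0, .105, 0.02, .005, .08, 1.0, 0, 0, 0, .01, 0,     1.50, 1.00),
    ("spirits",           "alcohol",  12, 0.60, 0.95, 0, 0, 0, 0, 0, 0, 0, .320, 0.01, 0, 0, 0, 0, 0, 0, 0, 0,                 2.20, 1.10),
    ("cider_longdrink",   "alcohol",  25, 0.55, 0.90, 0, 0, 0, 0, 0, .050, 0, .045, 0.02, 0, .02, 0.3, 0, 0, 0, .01, 0,        0.90, 1.30),
]

MAIN_GROUPS = [
    "cereals", "potatoes", "vegetables", "fruits_berries", "legumes_nuts",
    "meat", "fish_eggs", "milk", "fats_oils", "sugar_sweets", "drinks", "alcohol",
]
# 13th group: sweet & savoury extras folded into sugar_sweets? -> keep 12 + misc
# (the reporting groups are data, not code: they come from the template's main_group column)

# ---------------------------------------------------------------------------
# design-time calibration constants (frozen; see docs/methods.md)
# ---------------------------------------------------------------------------

# scales template consumption so the male baseline is ~9.4 MJ/cap/day
_CONSUMPTION_SCALE = 0.83
# scales the LCA coefficient template so the male baseline GHGE is 5.3 kg CO2e/cap/day
_GHGE_SCALE = 1.2489
# shrinks/stretches land-use uplifts toward 1 so the male EEIO/LCA baseline
# ratio is ~1.22 (uplift' = 1 + gamma * (uplift - 1))
_UPLIFT_GAMMA = 0.712
# nutrient-density calibration (applied multiplicatively to the template):
# sodium to the observed excess (~3.3 g male, ~2.5 g female), iron so the
# female baseline sits at its observed-intake bound (~10 mg), vitamin D so
# fortification keeps both sexes adequate
_DENSITY_SCALE: dict[str, float] = {"na": 1.25, "fe": 1.40, "vitd": 1.15, "fol": 1.15, "ca": 1.12}

# female consumption multipliers per main group (baseline female ~7.4 MJ and
# GHGE ~3.8 kg CO2e/cap/day, with a lighter, less meat- and alcohol-heavy diet)
SEX_MULT = {
    "male": {g: 1.0 for g in MAIN_GROUPS},
    "female": {
        "cereals": 0.80, "potatoes": 0.70, "vegetables": 1.05,
        "fruits_berries": 1.15, "legumes_nuts": 1.05, "meat": 0.58,
        "fish_eggs": 0.85, "milk": 0.80, "fats_oils": 0.75,
        "sugar_sweets": 0.95, "drinks": 0.95, "alcohol": 0.45,
    },
}

# socio-economic gradients per main group (education tertiles and income
# quintiles; higher education -> more fish, legumes, fruit, vegetables and
# alcohol, fewer potatoes; income gradients milder)
STRATUM_MULT = {
    "all":   {},
    "Educ1": {"fish_eggs": 0.85, "legumes_nuts": 0.85, "fruits_berries": 0.88,
              "vegetables": 0.90, "alcohol": 0.62, "potatoes": 1.15, "sugar_sweets": 1.10,
              "meat": 1.08, "milk": 1.02},
    "Educ2": {},
    "Educ3": {"fish_eggs": 1.20, "legumes_nuts": 1.25, "fruits_berries": 1.13,
              "vegetables": 1.12, "alcohol": 1.43, "potatoes": 0.90, "sugar_sweets": 0.92,
              "meat": 0.95},
    "IncQ1": {"fruits_berries": 0.90, "fish_eggs": 0.90, "alcohol": 0.85, "potatoes": 1.10},
    "IncQ3": {},
    "IncQ5": {"fruits_berries": 1.12, "fish_eggs": 1.15, "alcohol": 1.25,
              "potatoes": 0.92, "meat": 1.05},
}

NUTRIENT_META = pd.DataFrame(
    {
        "unit": {
            "energy": "kJ/g", "protein": "g", "fat": "g", "sfa": "g", "carb": "g",
            "fibre": "g", "alcohol": "g", "sodium": "mg", "iron": "mg",
            "calcium": "mg", "potassium": "mg", "zinc": "mg", "vit_c": "mg",
            "vit_d": "ug", "folate": "ug", "b12": "ug", "lysine": "g",
            "methionine": "g",
        },
        "energy_factor": {
            "energy": 0.0, "protein": 17.0, "fat": 37.0, "sfa": 37.0,
            "carb": 17.0, "fibre": 0.0, "alcohol": 29.0, "sodium": 0.0,
            "iron": 0.0, "calcium": 0.0, "potassium": 0.0, "zinc": 0.0,
            "vit_c": 0.0, "vit_d": 0.0, "folate": 0.0, "b12": 0.0,
            # amino acids carry no separate energy factor: their energy is
            # already accounted for within protein
            "lysine": 0.0, "methionine": 0.0,
        },
    }
)
NUTRIENT_META.index.name = "nutrient_id"

# lysine / methionine as fractions of protein, by protein source quality
_AA_SHARES = {  # main_group -> (lysine share, methionine share)
    "meat": (0.078, 0.026), "fish_eggs": (0.080, 0.028), "milk": (0.075, 0.026),
    "legumes_nuts": (0.060, 0.012), "cereals": (0.028, 0.016),
}
_AA_DEFAULT = (0.050, 0.015)


def default_recommendations() -> pd.DataFrame:
    """Synthetic recommendation table.

    The fibre, SFA, carbohydrate, sodium and iron bounds follow published
    Nordic/Finnish levels (fibre 35/25 g min, SFA 10 E% max, carbohydrate
    45 E% min, sodium 2.4 g max, female iron 10 mg observed / 15 mg
    recommended); the remaining bounds are plausible placeholders standing in
    for the full recommendation list, set so that protein and amino-acid
    minima are comfortably met by baseline diets.
    """
    rows: list[tuple] = []

    def add(nut, sex, bt, form, value, source="synthetic", policy=""):
        rows.append((nut, sex, bt, form, value, source, policy))

    for sex in SEXES:
        add("fibre", sex, "min", "absolute", 35.0 if sex == "male" else 25.0, "FNR2014")
        add("sfa", sex, "max", "energy_percent", 10.0, "NNR2012")
        add("carb", sex, "min", "energy_percent", 45.0, "NNR2012")
        add("fat", sex, "min", "energy_percent", 25.0, "NNR2012")
        add("fat", sex, "max", "energy_percent", 40.0, "NNR2012")
        add("protein", sex, "min", "energy_percent", 10.0, "NNR2012")
        add("protein", sex, "max", "energy_percent", 20.0, "NNR2012")
        add("sodium", sex, "max", "absolute", 2400.0, "NNR2012")
        add("calcium", sex, "min", "absolute", 800.0, "NNR2012")
        add("potassium", sex, "min", "absolute", 2500.0)
        add("zinc", sex, "min", "absolute", 6.5 if sex == "male" else 5.5)
        add("vit_c", sex, "min", "absolute", 75.0, "NNR2012")
        add("vit_d", sex, "min", "absolute", 10.0, "NNR2012")
        add("folate", sex, "min", "absolute", 300.0, "NNR2012")
        add("b12", sex, "min", "absolute", 2.0, "NNR2012")
        add("iron", sex, "max", "absolute", 60.0)
        # WHO-style amino-acid minima with a 24 % safety margin
        add("lysine", sex, "min", "absolute", 2.8 if sex == "male" else 2.3, "WHO+24%")
        add("methionine", sex, "min", "absolute", 0.95 if sex == "male" else 0.80, "WHO+24%")
    add("iron", "male", "min", "absolute", 9.0, "NNR2012")
    # female iron: observed-intake level by default, recommended level under
    # the sensitivity policy
    add("iron", "female", "min", "absolute", 10.0, "observed intake", "observed")
    add("iron", "female", "min", "absolute", 15.0, "NNR2012", "recommended")
    return pd.DataFrame(
        rows,
        columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"],
    )


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    ``seed`` fixes every output bit-for-bit.  ``n_individuals`` is the number
    of simulated persons per socio-demographic group whose empirical mean and
    10th/90th centiles become the group diet.  ``composition_noise`` and
    ``ghge_noise`` are log-scale standard deviations of the multiplicative
    noise on the composition and LCA coefficient templates.
    """

    seed: int = 0
    n_individuals: int = 200
    sexes: tuple[str, ...] = SEXES
    strata: tuple[str, ...] = STRATA
    composition_noise: float = 0.05
    ghge_noise: float = 0.08
    template: pd.DataFrame | None = None   # override the built-in food template

    def __post_init__(self) -> None:
        if self.n_individuals < 20:
            raise ValueError("n_individuals must be >= 20")
        for s in self.strata:
            if s not in STRATUM_MULT:
                raise ValueError(f"unknown stratum {s!r}")
        for s in self.sexes:
            if s not in SEX_MULT:
                raise ValueError(f"unknown sex {s!r}")


def default_template() -> pd.DataFrame:
    t = pd.DataFrame(_TEMPLATE_ROWS, columns=_COLS).set_index("id")
    t["mean_male"] = t["mean_male"].astype(float) * _CONSUMPTION_SCALE
    t["ghge"] = t["ghge"].astype(float) * _GHGE_SCALE
    t["uplift"] = 1.0 + _UPLIFT_GAMMA * (t["uplift"].astype(float) - 1.0)
    for col, s in _DENSITY_SCALE.items():
        t[col] = t[col].astype(float) * s
    return t


def _composition_from(template: pd.DataFrame, rng: np.random.Generator,
                      noise: float) -> CompositionMatrix:
    n = len(template)
    jitter = lambda col: template[col].to_numpy(float) * np.exp(  # noqa: E731
        rng.normal(0.0, noise, n)
    )
    dens = pd.DataFrame(index=template.index)
    dens.index.name = "food_id"
    dens["protein"] = jitter("prot")
    dens["fat"] = jitter("fat")
    dens["sfa"] = dens["fat"] * template["sfash"].to_numpy(float)
    dens["carb"] = jitter("carb")
    dens["fibre"] = jitter("fibre")
    dens["alcohol"] = template["alc"].to_numpy(float)  # declared, not noisy
    for nut, col in [
        ("sodium", "na"), ("iron", "fe"), ("calcium", "ca"), ("potassium", "k"),
        ("zinc", "zn"), ("vit_c", "vitc"), ("vit_d", "vitd"), ("folate", "fol"),
        ("b12", "b12"),
    ]:
        dens[nut] = jitter(col)
    lys = np.empty(n)
    met = np.empty(n)
    for i, g in enumerate(template["main_group"]):
        ls, ms = _AA_SHARES.get(g, _AA_DEFAULT)
        lys[i], met[i] = ls, ms
    dens["lysine"] = dens["protein"] * lys
    dens["methionine"] = dens["protein"] * met
    # exact macro-energy closure
    dens["energy"] = (
        KJ_PER_G["protein"] * dens["protein"]
        + KJ_PER_G["fat"] * dens["fat"]
        + KJ_PER_G["carb"] * dens["carb"]
        + KJ_PER_G["alcohol"] * dens["alcohol"]
    )
    return CompositionMatrix(dens, NUTRIENT_META)


def _sample_group(template: pd.DataFrame, sex: str, stratum: str, n: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Empirical mean/p10/p90 of n simulated individuals for one group."""
    mult = np.array(
        [
            SEX_MULT[sex][g] * STRATUM_MULT[stratum].get(g, 1.0)
            for g in template["main_group"]
        ]
    )
    target = template["mean_male"].to_numpy(float) * mult
    pi = template["pi"].to_numpy(float)
    sigma = template["sigma"].to_numpy(float)
    # zero-inflated log-normal with mean matched to the target location:
    # E[X] = (1 - pi) * exp(m + sigma^2/2)  =>  m = log(target/(1-pi)) - sigma^2/2
    m = np.log(target / (1.0 - pi)) - sigma**2 / 2.0
    consume = rng.random((n, len(target))) >= pi[None, :]
    draws = np.exp(m[None, :] + sigma[None, :] * rng.standard_normal((n, len(target))))
    x = np.where(consume, draws, 0.0)
    return pd.DataFrame(
        {
            "mean": x.mean(axis=0),
            "p10": np.quantile(x, 0.10, axis=0),
            "p90": np.quantile(x, 0.90, axis=0),
        },
        index=template.index,
    )


def generate(config: GeneratorConfig | None = None) -> DataBundle:
    """Generate a complete in-memory dataset bundle."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    template = config.template if config.template is not None else default_template()

    foods = FoodTable(
        FoodCategory(
            id=str(i),
            name=str(i).replace("_", " "),
            main_group=str(r["main_group"]),
            milk_eq=float(r["milk_eq"]),
            beef_content=float(r["beef"]),
        )
        for i, r in template.iterrows()
    )
    comp = _composition_from(template, rng, config.composition_noise)
    lca = template["ghge"].to_numpy(float) * np.exp(
        rng.normal(0.0, config.ghge_noise, len(template))
    )
    ghge = {
        "lca": GHGETable(pd.Series(lca, index=template.index), "lca"),
        "eeio_landuse": GHGETable(
            pd.Series(lca * template["uplift"].to_numpy(float), index=template.index),
            "eeio_landuse",
        ),
    }
    energy = comp.energy_density
    diets: dict[str, GroupDiet] = {}
    for sex in config.sexes:
        for stratum in config.strata:
            stats = _sample_group(template, sex, stratum, config.n_individuals, rng)
            gid = f"{sex}/{stratum}"
            diets[gid] = GroupDiet(
                group_id=gid,
                mean=stats["mean"],
                p10=stats["p10"],
                p90=stats["p90"],
                energy_obs=float(energy.to_numpy() @ stats["mean"].to_numpy()),
            )
    recs = RecommendationSet(default_recommendations())
    return DataBundle(foods=foods, diets=diets, composition=comp, ghge=ghge,
                      recommendations=recs)


def generate_to(directory: str | Path, config: GeneratorConfig | None = None) -> DataBundle:
    """Generate a dataset and write it to ``directory`` in the CSV schemas."""
    bundle = generate(config)
    write_bundle(bundle, directory)
    return bundle


def check_adequacy_profile(bundle: DataBundle, group_id: str = "male/all") -> dict[str, bool]:
    """Which recommendations the group's baseline diet violates.

    The default generator is calibrated so the average baseline diet of both
    sexes falls short on fibre, folate and carbohydrate energy and exceeds the
    SFA and sodium limits, while protein and amino-acid bounds hold — the
    nutritional-inadequacy pattern of the emulated study population.
    """
    group = bundle.group(group_id)
    profile = compute_nutrients(group.mean, bundle.composition)
    out: dict[str, bool] = {}
    for _, row in bundle.recommendations.bounds_for(group.sex).iterrows():
        nut = row["nutrient_id"]
        if row["form"] == "absolute":
            v = profile.intake[nut]
        else:
            v = profile.e_percent[nut]
        violated = v < row["value"] if row["bound_type"] == "min" else v > row["value"]
        out[f"{nut}:{row['bound_type']}"] = bool(violated)
    return out


def adequate_group(bundle: DataBundle, diet: pd.Series, group_id: str = "synthetic/adequate",
                   spread: float = 0.5) -> GroupDiet:
    """Wrap a recommendation-satisfying diet as a synthetic group.

    Used to exercise the feasibility identity: a group whose observed mean
    already satisfies every constraint is returned unchanged by the optimiser.
    The habit box is ``[(1-spread)*x, (1+spread)*x]``.
    """
    diet = diet.reindex(bundle.foods.ids).astype(float)
    energy = float(bundle.composition.energy_density.to_numpy() @ diet.to_numpy())
    return GroupDiet(
        group_id=group_id,
        mean=diet,
        p10=(1.0 - spread) * diet,
        p90=(1.0 + spread) * diet,
        energy_obs=energy,
    )


# ---------------------------------------------------------------------------
# miniature hand-checkable bundle
# ---------------------------------------------------------------------------

def make_toy() -> DataBundle:
    """Deterministic 3-food bundle with an analytically solvable instance.

    Foods A and B have unit energy density (1 kJ/g) and GHGE coefficients in
    ratio 2:1; food C is inert (zero energy and emissions) and fixed by a
    degenerate habit box.  For the toy group (mean 100 g of A and B each,
    energy 200 kJ) a cap at 250 units of emissions together with the energy
    equality forces the unique solution (50, 150) with objective 0.5: a
    two-equation, two-unknown system.  The cap corresponds to a one-sixth
    reduction from the baseline of 300.
    """
    foods = FoodTable(
        [
            FoodCategory("food_a", "food a", "group_a"),
            FoodCategory("food_b", "food b", "group_b"),
            FoodCategory("food_c", "food c", "group_c"),
        ]
    )
    idx = foods.ids
    dens = pd.DataFrame(
        {"energy": [1.0, 1.0, 0.0], "protein": [0.01, 0.02, 0.0]}, index=idx
    )
    dens.index.name = "food_id"
    meta = pd.DataFrame(
        {"unit": {"energy": "kJ/g", "protein": "g"},
         "energy_factor": {"energy": 0.0, "protein": 17.0}}
    )
    meta.index.name = "nutrient_id"
    comp = CompositionMatrix(dens, meta)
    lca = pd.Series([2000.0, 1000.0, 0.0], index=idx)
    ghge = {
        "lca": GHGETable(lca, "lca"),
        "eeio_landuse": GHGETable(1.25 * lca, "eeio_landuse"),
    }
    diet = GroupDiet(
        group_id="toy/all",
        mean=pd.Series([100.0, 100.0, 50.0], index=idx),
        p10=pd.Series([0.0, 0.0, 50.0], index=idx),
        p90=pd.Series([1000.0, 1000.0, 50.0], index=idx),
        energy_obs=200.0,
    )
    recs = RecommendationSet(
        pd.DataFrame(
            columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"]
        )
    )
    return DataBundle(foods=foods, diets={"toy/all": diet}, composition=comp,
                      ghge=ghge, recommendations=recs)
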