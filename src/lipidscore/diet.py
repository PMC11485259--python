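"""Isocaloric macronutrient substitution models and diet-quality indices.

The substitution model regresses a variance-standardized score on all
macronutrient energy densities except the leave-out nutrient (saturated fat
by default), so each coefficient reads as the expected score change when the
leave-out nutrient is isocalorically replaced by that macronutrient.
Predictors are divided by the reporting scale (8 %E by default).

Diet-quality indices: an 11-stratum low-carbohydrate-diet score (0-30, with
animal- and vegetable-based variants), a 9-component alternate Mediterranean
score (0-9, median-based) and an Alternate Healthy Eating Index (0-110,
linear interpolation between per-component cut-offs supplied via config).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import CollinearityError, ols

logger = logging.getLogger(__name__)

DEFAULT_MACRO_COLS = ("sfa_pct", "ufa_pct", "protein_pct", "carb_pct")
DEFAULT_SUBSTITUTION_COVARIATES = ("energy_kcal", "alcohol_g", "bmi", "age")


def fit_substitution(scores: pd.Series, macros: pd.DataFrame, *,
                     leave_out: str = "sfa_pct", scale: float = 8.0,
                     macro_cols=DEFAULT_MACRO_COLS,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Leave-one-out isocaloric substitution estimates, per ``scale`` %E.

    Returns one row per retained macronutrient with ``beta`` (score change
    when ``scale`` %E of the leave-out nutrient is replaced by that
    macronutrient), standard error, 95% CI and p-value.
    """
    if leave_out not in macro_cols:
        raise ValueError(f"leave-out nutrient {leave_out!r} must be one of {macro_cols}")
    kept = [c for c in macro_cols if c != leave_out]
    y = scores.to_numpy(dtype=float)
    blocks = [np.ones(len(y))]
    names = ["intercept"]
    for c in kept:
        blocks.append(macros[c].to_numpy(dtype=float) / scale)
        names.append(c)
    if covariates is not None:
        for c in covariates.columns:
            blocks.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(blocks)
    try:
        fit = ols(y, X, tuple(names))
    except CollinearityError as exc:
        raise CollinearityError(
            f"macronutrient columns linearly dependent after leaving out {leave_out!r}: {exc}") from exc
    ci = fit.conf_int()
    rows = []
    for c in kept:
        i = names.index(c)
        rows.append((c, fit.beta[i], fit.se[i], ci[i, 0], ci[i, 1], fit.p[i]))
    out = pd.DataFrame(rows, columns=["macronutrient", "beta", "se", "ci_low", "ci_high", "p"])
    out.attrs["leave_out"] = leave_out
    out.attrs["scale_pct_energy"] = scale
    return out.set_index("macronutrient")


# ---------------------------------------------------------------------------
# Low-carbohydrate-diet score (0-30)
# ---------------------------------------------------------------------------

_LCD_COMPONENTS = {
    "total": {"fat": ("sfa_pct", "ufa_pct"), "protein": ("protein_pct",),
              "carb": ("carb_pct",)},
    "animal": {"fat": ("animal_fat_pct",), "protein": ("animal_protein_pct",),
               "carb": ("carb_pct",)},
    "vegetable": {"fat": ("vegetable_fat_pct",), "protein": ("vegetable_protein_pct",),
                  "carb": ("carb_pct",)},
}


def _strata_points(values: pd.Series, reverse: bool = False) -> pd.Series:
    """11 equal-count strata of the analysis sample; points 0..10 ascending
    (descending for ``reverse``).  Ties broken by rank order (documented rule)."""
    ranks = values.rank(method="first")
    strata = pd.qcut(ranks, 11, labels=False)
    pts = strata.astype(int)
    return (10 - pts) if reverse else pts


def lcd_score(macros: pd.DataFrame, variant: str = "total") -> pd.Series:
    """Low-carbohydrate-diet score: 0-10 points per component, total 0-30.

    High fat and protein intake score high; carbohydrate scoring is
    reversed.  Strata are equal-count bins of the analysis sample.
    """
    if variant not in _LCD_COMPONENTS:
        raise ValueError(f"unknown LCD variant: {variant!r}")
    comp = _LCD_COMPONENTS[variant]
    missing = [c for cols in comp.values() for c in cols if c not in macros.columns]
    if missing:
        raise KeyError(f"missing %E columns for LCD score: {missing}")
    fat = macros[list(comp["fat"])].sum(axis=1)
    protein = macros[list(comp["protein"])].sum(axis=1)
    carb = macros[list(comp["carb"])].sum(axis=1)
    if fat.nunique() == 1 and protein.nunique() == 1 and carb.nunique() == 1:
        # identical intakes: same (middle) score for everyone
        return pd.Series(15, index=macros.index, name=f"lcd_{variant}")
    total = _strata_points(fat) + _strata_points(protein) + _strata_points(carb, reverse=True)
    total.name = f"lcd_{variant}"
    return total


# ---------------------------------------------------------------------------
# Alternate Mediterranean diet score (0-9)
# ---------------------------------------------------------------------------

AMED_MEDIAN_COMPONENTS = ("vegetables", "fruits", "nuts", "whole_grains",
                          "legumes", "fish", "mufa_sfa_ratio")
AMED_REVERSED = ("red_processed_meat",)
AMED_ALCOHOL = "alcohol_g"


def amed_score(foods: pd.DataFrame, macros: pd.DataFrame | None = None) -> pd.Series:
    """Alternate Mediterranean diet score: 9 components, pooled medians.

    One point for intake above the sample median in beneficial components,
    below the median for red/processed meat, and for alcohol between 5 and
    15 g/day.  ``mufa_sfa_ratio`` is computed from ``macros`` when absent.
    """
    foods = foods.copy()
    if "mufa_sfa_ratio" not in foods.columns:
        if macros is None or not {"mufa_pct", "sfa_pct"} <= set(macros.columns):
            raise KeyError("missing component: mufa_sfa_ratio (supply it or pass macros)")
        foods["mufa_sfa_ratio"] = macros["mufa_pct"] / macros["sfa_pct"]
    needed = [*AMED_MEDIAN_COMPONENTS, *AMED_REVERSED, AMED_ALCOHOL]
    missing = [c for c in needed if c not in foods.columns]
    if missing:
        raise KeyError(f"missing aMed components: {missing}")
    total = pd.Series(0, index=foods.index, dtype=int)
    for c in AMED_MEDIAN_COMPONENTS:
        total += (foods[c] > foods[c].median()).astype(int)
    for c in AMED_REVERSED:
        total += (foods[c] < foods[c].median()).astype(int)
    alc = foods[AMED_ALCOHOL]
    total += ((alc >= 5.0) & (alc <= 15.0)).astype(int)
    total.name = "amed"
    return total


# ---------------------------------------------------------------------------
# Alternate Healthy Eating Index (0-110)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AheiComponent:
    column: str
    worst: float   # intake scoring 0
    best: float    # intake scoring 10 (may be below `worst` for adverse components)


# Published AHEI-2010 cut-offs shipped as a config preset (external reference
# values, pooled-sex where the original is sex-specific).
AHEI_2010_CUTOFFS = (
    AheiComponent("vegetables", 0.0, 5.0),          # servings/day
    AheiComponent("fruits", 0.0, 4.0),
    AheiComponent("whole_grains", 0.0, 82.5),       # g/day
    AheiComponent("nuts_legumes", 0.0, 1.0),        # servings/day
    AheiComponent("long_chain_n3", 0.0, 250.0),     # mg/day
    AheiComponent("pufa_pct", 2.0, 10.0),           # % energy
    AheiComponent("ssb", 1.0, 0.0),                 # servings/day (adverse)
    AheiComponent("red_processed_meat", 1.5, 0.0),  # servings/day (adverse)
    AheiComponent("trans_pct", 4.0, 0.5),           # % energy (adverse)
    AheiComponent("sodium", 3337.0, 1112.0),        # mg/day (adverse)
)
AHEI_ALCOHOL = {"column": "alcohol_drinks", "best_range": (0.5, 2.0),
                "zero_points": 2.5, "max_adverse": 3.5}


def _linear_component(values: pd.Series, worst: float, best: float) -> pd.Series:
    frac = (values - worst) / (best - worst)
    return (frac.clip(0.0, 1.0) * 10.0).astype(float)


def _alcohol_component(values: pd.Series, spec: dict) -> pd.Series:
    lo, hi = spec["best_range"]
    pts = pd.Series(0.0, index=values.index)
    pts[(values >= lo) & (values <= hi)] = 10.0
    rising = (values > 0) & (values < lo)
    pts[rising] = spec["zero_points"] + (10.0 - spec["zero_points"]) * values[rising] / lo
    falling = (values > hi) & (values < spec["max_adverse"])
    pts[falling] = 10.0 * (spec["max_adverse"] - values[falling]) / (spec["max_adverse"] - hi)
    pts[values == 0] = spec["zero_points"]
    pts[values >= spec["max_adverse"]] = 0.0
    return pts


def ahei_score(foods: pd.DataFrame, cutoffs=AHEI_2010_CUTOFFS, *,
               include_alcohol: bool = True, alcohol_spec: dict = AHEI_ALCOHOL) -> pd.Series:
    """AHEI: per-component linear interpolation between cut-offs, 0-10 each.

    With ``include_alcohol=False`` the non-monotone alcohol component is
    dropped (maximum 100), matching the "without alcohol points" variant.
    """
    if not cutoffs:
        raise ValueError("AHEI cut-offs must be supplied")
    missing = [c.column for c in cutoffs if c.column not in foods.columns]
    if include_alcohol and alcohol_spec["column"] not in foods.columns:
        missing.append(alcohol_spec["column"])
    if missing:
        raise KeyError(f"missing AHEI components: {missing}")
    total = pd.Series(0.0, index=foods.index)
    for comp in cutoffs:
        total += _linear_component(foods[comp.column], comp.worst, comp.best)
    if include_alcohol:
        total += _alcohol_component(foods[alcohol_spec["column"]], alcohol_spec)
    total.name = "ahei" if include_alcohol else "ahei_no_alcohol"
    return total


def average_ffqs(ffq_a: pd.DataFrame, ffq_b: pd.DataFrame) -> pd.DataFrame:
    """Average two repeated dietary assessments column-wise (documented
    pre-step for using the two assessments closest to blood collection)."""
    if list(ffq_a.columns) != list(ffq_b.columns):
        raise ValueError("FFQ tables must share columns")
    return (ffq_a + ffq_b) / 2.0
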