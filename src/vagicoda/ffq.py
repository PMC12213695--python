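"""Food-frequency-questionnaire processing.

Item-level daily intakes (g/day) are turned into food-group totals, the
nine-part macronutrient composition with energy/fiber/alcohol totals,
percent-of-energy shares, alcoholic-unit categories and the MEDI-LITE
Mediterranean-diet adherence score (0-18).  The module is item-agnostic:
it is driven entirely by a food-composition table (nutrients per 100 g
of each item) and an item-to-group map supplied by the caller; small
synthetic versions of both are bundled for testing and simulation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .association import spearman
from .coda import PARTS

#: The 24 admissible food-group labels.
FOOD_GROUPS = (
    "tubers",
    "vegetables",
    "legumes",
    "fruits",
    "dried fruits and seeds",
    "milk and yogurt",
    "cheese",
    "cereals and derived products",
    "bakery products",
    "stuffed pasta",
    "sweets and snacks",
    "red and processed meat",
    "white meat",
    "fish",
    "eggs",
    "olive oil",
    "other plant-derived fats",
    "animal-derived fats",
    "sugar",
    "non-alcoholic beverages",
    "alcoholic beverages",
    "vegetable products",
    "salt and spices",
    "other",
)

#: Atwater energy factors, kcal per gram.
ATWATER = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0, "alcohol": 7.0}

#: Macronutrient part -> Atwater class.
PART_CLASS = {
    "AP": "protein",
    "VP": "protein",
    "SS": "carbohydrate",
    "ST": "carbohydrate",
    "SFA": "fat",
    "MUFA": "fat",
    "LA": "fat",
    "ALA": "fat",
    "PUFA": "fat",
}

GRAMS_PER_AU = 10.0
ENERGY_PLAUSIBLE_RANGE = (500.0, 3500.0)

ABSTAINER = "abstainer"
LOW_DRINKER = "<=1 AU/day"
HIGH_DRINKER = ">1 AU/day"

_FCT_COLUMNS = list(PARTS) + ["fiber_g", "alcohol_g", "energy_kcal"]


def synthetic_fct() -> pd.DataFrame:
    """Bundled synthetic food-composition table (per 100 g of item).

    One dominant item per energy component, so that nutrient derivation
    is exactly invertible; energies are the exact Atwater sums of the
    item contents.  A stand-in for licensed national databases.
    """
    rows = {
        # item: (part, grams per 100 g)
        "beef": ("AP", 20.0),
        "soy": ("VP", 36.0),
        "table sugar": ("SS", 99.0),
        "bread": ("ST", 47.0),
        "butter": ("SFA", 50.0),
        "olive oil": ("MUFA", 73.0),
        "sunflower oil": ("LA", 62.0),
        "walnuts": ("ALA", 9.0),
        "fish oil": ("PUFA", 30.0),
    }
    fct = pd.DataFrame(0.0, index=list(rows) + ["wheat bran", "wine"], columns=_FCT_COLUMNS)
    for item, (part, grams) in rows.items():
        fct.loc[item, part] = grams
    fct.loc["wheat bran", "fiber_g"] = 40.0
    fct.loc["wine", "alcohol_g"] = 10.0
    for part in PARTS:
        fct["energy_kcal"] += fct[part] * ATWATER[PART_CLASS[part]]
    fct["energy_kcal"] += fct["alcohol_g"] * ATWATER["alcohol"]
    fct.index.name = "item"
    return fct


def synthetic_group_map() -> pd.Series:
    """Item-to-food-group map matching :func:`synthetic_fct`."""
    return pd.Series(
        {
            "beef": "red and processed meat",
            "soy": "legumes",
            "table sugar": "sugar",
            "bread": "bakery products",
            "butter": "animal-derived fats",
            "olive oil": "olive oil",
            "sunflower oil": "other plant-derived fats",
            "walnuts": "dried fruits and seeds",
            "fish oil": "fish",
            "wheat bran": "cereals and derived products",
            "wine": "alcoholic beverages",
        },
        name="group",
    )


def aggregate_food_groups(item_intakes: pd.DataFrame, group_map: pd.Series) -> pd.DataFrame:
    """Sum item intakes (g/day) into the 24 food groups.

    Total grams are conserved exactly; unmapped items are rejected with
    the offenders listed; groups without items come back as zeros.
    """
    unmapped = [c for c in item_intakes.columns if c not in group_map.index]
    if unmapped:
        raise ValueError(f"items without a food-group mapping: {unmapped}")
    bad = sorted(set(group_map.loc[list(item_intakes.columns)]) - set(FOOD_GROUPS))
    if bad:
        raise ValueError(f"unknown food-group labels: {bad}")
    out = pd.DataFrame(0.0, index=item_intakes.index, columns=list(FOOD_GROUPS))
    for item in item_intakes.columns:
        out[group_map[item]] += item_intakes[item].astype(float)
    return out


def derive_nutrients(item_intakes: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Derive daily nutrient intakes from item intakes and an FCT.

    Linear: component g/day = sum over items of intake/100 x per-100 g
    content.  Returns the nine parts plus fiber_g, alcohol_g and
    energy_kcal per subject.
    """
    missing = [c for c in item_intakes.columns if c not in fct.index]
    if missing:
        raise ValueError(f"items missing from the food-composition table: {missing}")
    fsub = fct.loc[list(item_intakes.columns), _FCT_COLUMNS].to_numpy(dtype=float)
    if (fsub < 0).any():
        raise ValueError("food-composition values must be non-negative")
    vals = item_intakes.to_numpy(dtype=float) / 100.0 @ fsub
    return pd.DataFrame(vals, index=item_intakes.index, columns=_FCT_COLUMNS)


def energy_percent(
    grams: pd.DataFrame, energy_kcal: pd.Series, factors: dict | None = None
) -> pd.DataFrame:
    """Percent of total energy per macronutrient part.

    %E_x = 100 * grams_x * factor_x / energy_kcal with Atwater factors
    (protein 4, carbohydrate 4, fat 9 kcal/g) by default.
    """
    factors = dict(ATWATER, **(factors or {}))
    energy = pd.Series(energy_kcal, index=grams.index).astype(float)
    if (energy <= 0).any():
        raise ValueError("energy must be positive for percent-of-energy")
    out = {}
    for part in grams.columns:
        cls = PART_CLASS.get(part)
        if cls is None:
            raise ValueError(f"unknown macronutrient part {part!r}")
        out[part] = 100.0 * grams[part].astype(float) * factors[cls] / energy
    return pd.DataFrame(out, index=grams.index)


def screen_energy(energy_kcal):
    """Energy-plausibility flag: True iff 500 <= kcal/day <= 3500.

    The bounds themselves count as plausible (closed interval).
    """
    lo, hi = ENERGY_PLAUSIBLE_RANGE
    energy = np.asarray(energy_kcal, dtype=float)
    if (energy < 0).any():
        raise ValueError("negative energy intake")
    flag = (energy >= lo) & (energy <= hi)
    if np.isscalar(energy_kcal) or np.ndim(energy_kcal) == 0:
        return bool(flag)
    if isinstance(energy_kcal, pd.Series):
        return pd.Series(flag, index=energy_kcal.index, name="energy_plausible")
    return flag


def alcohol_units(alcohol_g_per_day):
    """Convert g/day of ethanol to alcoholic units and a category.

    1 AU = 10 g ethanol.  Categories: abstainer (0 AU), "<=1 AU/day"
    (0 < AU <= 1) and ">1 AU/day".
    """
    scalar = np.isscalar(alcohol_g_per_day) or np.ndim(alcohol_g_per_day) == 0
    g = np.atleast_1d(np.asarray(alcohol_g_per_day, dtype=float))
    if (g < 0).any():
        raise ValueError("negative alcohol intake")
    au = g / GRAMS_PER_AU
    cat = np.where(au == 0, ABSTAINER, np.where(au <= 1, LOW_DRINKER, HIGH_DRINKER))
    if scalar:
        return float(au[0]), str(cat[0])
    if isinstance(alcohol_g_per_day, pd.Series):
        idx = alcohol_g_per_day.index
        return pd.Series(au, index=idx, name="alcohol_au"), pd.Series(
            cat, index=idx, name="alcohol_category"
        )
    return au, cat


def default_medi_lite_cutoffs() -> dict:
    """Load the bundled MEDI-LITE cutoff configuration."""
    ref = importlib.resources.files("vagicoda.data") / "medi_lite_cutoffs.yaml"
    return yaml.safe_load(ref.read_text())


def _component_score(kind: str, value: float, lo: float, hi: float, below_score: int) -> int:
    if kind == "positive":
        return 0 if value < lo else (1 if value < hi else 2)
    if kind == "negative":
        return 2 if value <= lo else (1 if value <= hi else 0)
    if kind == "alcohol":
        if value > hi:
            return 0
        if value >= lo:
            return 2
        return below_score
    raise ValueError(f"unknown component kind {kind!r}")


def medi_lite(
    foodgroup_intakes: pd.DataFrame, alcohol_au: pd.Series, cutoffs: dict | None = None
) -> pd.Series:
    """MEDI-LITE Mediterranean-diet adherence score, integer 0-18.

    Nine components each scored 0/1/2: six positive food groups
    (cereals, legumes, fruit, vegetables, nuts, olive oil), two negative
    (dairy, red/processed meat) and alcohol, peaked at moderate intake.
    Cutoffs default to the bundled configuration.
    """
    cfg = cutoffs if cutoffs is not None else default_medi_lite_cutoffs()
    components = cfg.get("components")
    if not components:
        raise ValueError("cutoff configuration must define 'components'")
    alcohol_au = pd.Series(alcohol_au, index=foodgroup_intakes.index).astype(float)
    scores = pd.Series(0, index=foodgroup_intakes.index, dtype=int)
    n_comp = 0
    for name, spec in components.items():
        kind = spec.get("kind")
        if kind not in {"positive", "negative", "alcohol"}:
            raise ValueError(f"component {name!r}: unknown kind {kind!r}")
        if "lo" not in spec or "hi" not in spec or spec["lo"] > spec["hi"]:
            raise ValueError(f"component {name!r}: cutoffs must satisfy lo <= hi")
        if kind == "alcohol":
            values = alcohol_au
        else:
            groups = spec.get("groups", [])
            missing = [g for g in groups if g not in foodgroup_intakes.columns]
            if missing:
                raise ValueError(f"component {name!r}: food groups not in table: {missing}")
            values = foodgroup_intakes[groups].sum(axis=1)
        below = int(spec.get("below_score", 1))
        scores += values.apply(
            lambda v: _component_score(kind, float(v), float(spec["lo"]), float(spec["hi"]), below)
        ).astype(int)
        n_comp += 1
    if n_comp != 9:
        raise ValueError(f"MEDI-LITE requires 9 components, got {n_comp}")
    return scores.rename("medi_lite")


def nutrient_food_sources(
    foodgroup_table: pd.DataFrame, nutrient_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p between every food group and every nutrient.

    Identifies the dietary sources of each nutritional component.
    Constant columns give undefined (NaN) correlations with a warning.
    Returns (rho, p) DataFrames, food groups in rows.
    """
    if not foodgroup_table.index.equals(nutrient_table.index):
        raise ValueError("subject indices are not aligned")
    if len(foodgroup_table) < 3:
        raise ValueError("need at least 3 subjects")
    rho = pd.DataFrame(index=foodgroup_table.columns, columns=nutrient_table.columns, dtype=float)
    pval = rho.copy()
    for g in foodgroup_table.columns:
        for nut in nutrient_table.columns:
            res = spearman(foodgroup_table[g], nutrient_table[nut])
            rho.loc[g, nut] = res.rho
            pval.loc[g, nut] = res.p
    return rho, pval


@dataclass
class NutrientProfile:
    """Per-subject dietary summary produced by :func:`process_ffq`."""

    grams: pd.DataFrame
    percent_energy: pd.DataFrame
    food_groups: pd.DataFrame
    alcohol_au: pd.Series
    alcohol_category: pd.Series
    medi_lite: pd.Series
    energy_plausible: pd.Series


def process_ffq(
    item_intakes: pd.DataFrame,
    fct: pd.DataFrame,
    group_map: pd.Series,
    cutoffs: dict | None = None,
) -> NutrientProfile:
    """One-call FFQ pipeline: nutrients, %E, groups, alcohol, MEDI-LITE."""
    grams = derive_nutrients(item_intakes, fct)
    groups = aggregate_food_groups(item_intakes, group_map)
    pct = energy_percent(grams[list(PARTS)], grams["energy_kcal"])
    au, cat = alcohol_units(grams["alcohol_g"])
    score = medi_lite(groups, au, cutoffs=cutoffs)
    plausible = screen_energy(grams["energy_kcal"])
    return NutrientProfile(
        grams=grams,
        percent_energy=pct,
        food_groups=groups,
        alcohol_au=au,
        alcohol_category=cat,
        medi_lite=score,
        energy_plausible=plausible,
    )
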