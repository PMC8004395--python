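"""FSA-NPS diet quality scoring, meal-level quality profiles and the dietary
derived variables (excess fructose, FODMAP outliers, implausible-energy
filter, intake aggregation).

The British Food Standards Agency Nutrient Profiling System scores each food
per 100 g: 0-10 points for each unfavorable component (energy in kJ, total
sugars, saturated fat, sodium) minus 0-5 points for each favorable component
(fiber, protein, fruit/vegetable fraction), giving a score from -15 (most
healthy) to +40 (least healthy).  The diet index (FSA-NPS DI) is the
energy-weighted mean item score over everything a subject consumed; higher
means a less healthy diet.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FSANPSGrids",
    "load_default_grids",
    "fsanps_item_score",
    "fsanps_class",
    "score_food_db",
    "fsanps_diet_index",
    "meal_quality_profile",
    "excess_fructose",
    "fodmap_outlier_mask",
    "filter_implausible_energy",
    "aggregate_intake",
]

#: class upper bounds (score strictly below bound); a score of exactly 40
#: falls in class E for both scales.
_CLASS_BOUNDS_FOOD = [("A", 0), ("B", 3), ("C", 10), ("D", 18), ("E", 41)]
_CLASS_BOUNDS_DRINK = [("A", 1), ("B", 2), ("C", 5), ("D", 9), ("E", 41)]

SCORE_MIN, SCORE_MAX = -15, 40


@dataclass(frozen=True)
class FSANPSGrids:
    """Point-attribution breakpoints for every FSA-NPS component.

    ``unfavorable`` and ``favorable`` map component name to a pair
    ``(breakpoints, points)`` where a component earns the points attached to
    the highest breakpoint it strictly exceeds.
    """

    unfavorable: dict
    favorable: dict

    def __post_init__(self):
        for comps, max_pts in ((self.unfavorable, 10), (self.favorable, 5)):
            for name, (bp, pts) in comps.items():
                bp = np.asarray(bp, dtype=float)
                if np.any(np.diff(bp) <= 0):
                    raise ValueError(f"{name}: breakpoints must be strictly increasing")
                if len(pts) != len(bp) or pts[-1] != max_pts or min(pts) <= 0:
                    raise ValueError(
                        f"{name}: points must end at {max_pts} and be positive"
                    )

    @staticmethod
    def from_mapping(cfg: dict) -> "FSANPSGrids":
        def norm(section):
            out = {}
            for name, entry in section.items():
                bp = list(entry["breakpoints"])
                pts = list(entry.get("points", range(1, len(bp) + 1)))
                out[name] = (bp, pts)
            return out

        return FSANPSGrids(norm(cfg["unfavorable"]), norm(cfg["favorable"]))

    @staticmethod
    def from_yaml(path) -> "FSANPSGrids":
        with open(path) as fh:
            return FSANPSGrids.from_mapping(yaml.safe_load(fh))


def load_default_grids() -> FSANPSGrids:
    """Packaged point-attribution grids (Deschasaux-style breakpoints)."""
    ref = importlib.resources.files("dietmg.data") / "fsanps_grids.yaml"
    return FSANPSGrids.from_mapping(yaml.safe_load(ref.read_text()))


def _component_points(value, breakpoints, points):
    pts = 0
    for bp, p in zip(breakpoints, points):
        if value > bp:
            pts = p
    return pts


def fsanps_item_score(nutrients_per_100g, fruit_veg_pct=None, grids=None) -> int:
    """FSA-NPS score of one item from its per-100 g composition.

    Parameters
    ----------
    nutrients_per_100g : mapping
        Must provide every grid component (``energy_kj``, ``sugars_g``,
        ``saturated_fat_g``, ``sodium_mg``, ``fiber_g``, ``protein_g``); the
        fruit/vegetable percentage may be given here or separately.
    fruit_veg_pct : float, optional
        Fruit/vegetable/legume/nut percentage, overriding the mapping entry.
    """
    grids = grids or load_default_grids()
    comp = dict(nutrients_per_100g)
    if fruit_veg_pct is not None:
        comp["fruit_veg_pct"] = fruit_veg_pct
    score = 0
    for section, sign in ((grids.unfavorable, +1), (grids.favorable, -1)):
        for name, (bp, pts) in section.items():
            if name not in comp:
                raise KeyError(f"missing FSA-NPS component {name!r}")
            v = float(comp[name])
            if v < 0:
                raise ValueError(f"negative value for {name}: {v}")
            score += sign * _component_points(v, bp, pts)
    return int(score)


def fsanps_class(score, is_drink: bool) -> str:
    """Map an item score to quality class A (best) ... E (worst).

    Drinks use stricter bounds (A < 1, B < 2, C < 5, D < 9, E <= 40) than
    other foods (A < 0, B < 3, C < 10, D < 18, E <= 40).
    """
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    bounds = _CLASS_BOUNDS_DRINK if is_drink else _CLASS_BOUNDS_FOOD
    for cls, ub in bounds:
        if score < ub:
            return cls
    raise AssertionError("unreachable")


def score_food_db(food_db: pd.DataFrame, grids=None) -> pd.DataFrame:
    """Score and classify every item of a food composition table.

    Expects per-100 g columns ``energy_kj`` (or ``energy_kcal``),
    ``sugars_g``, ``saturated_fat_g``, ``sodium_mg``, ``fiber_g``,
    ``protein_g``, ``fruit_veg_pct`` and a boolean ``is_drink``.
    Returns a frame indexed like ``food_db`` with ``score`` and ``class``.
    """
    grids = grids or load_default_grids()
    db = food_db.copy()
    if "energy_kj" not in db.columns:
        db["energy_kj"] = db["energy_kcal"] * 4.184
    out = {}
    for item, row in db.iterrows():
        s = fsanps_item_score(row, grids=grids)
        out[item] = (s, fsanps_class(s, bool(row["is_drink"])))
    return pd.DataFrame.from_dict(out, orient="index", columns=["score", "class"])


def fsanps_diet_index(diary: pd.DataFrame, scores, energies) -> float:
    """Energy-weighted mean FSA-NPS score over all consumed portions.

    ``scores`` maps item -> FSA-NPS score; ``energies`` maps item ->
    kcal per 100 g.  Portion energy (per-100 g energy x grams / 100) is the
    weight, so recurring items count once per portion.
    """
    scores = pd.Series(scores)
    energies = pd.Series(energies)
    missing = set(diary["item"]) - (set(scores.index) & set(energies.index))
    if missing:
        raise KeyError(f"items without score/energy: {sorted(missing)[:5]}")
    w = energies.loc[diary["item"]].to_numpy() * diary["grams"].to_numpy() / 100.0
    s = scores.loc[diary["item"]].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total consumed energy is zero")
    return float((w * s).sum() / total)


def meal_quality_profile(
    diary: pd.DataFrame,
    classes,
    include_snacks: bool = False,
    high_classes=("A",),
    low_classes=("E",),
) -> dict:
    """Per-class item prevalence over (main) meals and the high/low ratio.

    Counts items per FSA-NPS class over the retained meals of one subject's
    diary; ``ratio`` is count(high classes) / count(low classes) with the
    denominator floored at 1 when no low-quality item occurs.
    """
    classes = pd.Series(classes)
    d = diary if include_snacks else diary[diary["is_main"]]
    if d.empty:
        raise ValueError("diary has no main meals")
    cls = classes.loc[d["item"]].to_numpy()
    counts = pd.Series(cls).value_counts().reindex(list("ABCDE"), fill_value=0)
    n = counts.sum()
    high = int(counts.loc[list(high_classes)].sum())
    low = int(counts.loc[list(low_classes)].sum())
    return {
        "counts": counts,
        "prevalence": counts / n,
        "ratio": high / max(low, 1),
    }


def excess_fructose(fructose_g: float, monosaccharides_g: float) -> float:
    """Excess fructose of one meal: max(fructose - glucose, 0), taking
    glucose as total monosaccharides minus fructose."""
    if not 0 <= fructose_g <= monosaccharides_g:
        raise ValueError("need 0 <= fructose <= total monosaccharides")
    glucose = monosaccharides_g - fructose_g
    return max(fructose_g - glucose, 0.0)


def fodmap_outlier_mask(values) -> np.ndarray:
    """Flag values outside mean +/- 4 SD (population mean/SD over subjects);
    a zero-variance vector flags nothing."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    m = v.mean()
    return (v < m - 4 * sd) | (v > m + 4 * sd)


def filter_implausible_energy(
    diaries: pd.DataFrame,
    food_db: pd.DataFrame,
    kcal_min: float = 800.0,
    kcal_max: float = 4500.0,
):
    """Drop subjects whose mean daily energy intake is below ``kcal_min`` or
    above ``kcal_max`` kcal (bounds themselves are kept).

    Returns ``(kept_diaries, report)`` where the report lists every subject
    with its mean daily intake and exclusion status.
    """
    kcal = food_db["energy_kcal"]
    d = diaries.copy()
    d["kcal"] = kcal.loc[d["item"]].to_numpy() * d["grams"].to_numpy() / 100.0
    daily = d.groupby(["subject", "day"])["kcal"].sum()
    mean_daily = daily.groupby("subject").mean()
    excluded = (mean_daily < kcal_min) | (mean_daily > kcal_max)
    report = pd.DataFrame(
        {"mean_daily_kcal": mean_daily, "excluded": excluded}
    )
    kept = diaries[~diaries["subject"].map(excluded)].copy()
    return kept, report


def aggregate_intake(diary: pd.DataFrame, food_db: pd.DataFrame, nutrient_cols=None):
    """Nutrient totals per meal, per day and as the 4-day mean.

    Every diary row contributes ``grams/100 x per-100 g`` nutrients.  Returns
    a dict with ``per_meal`` (subject, day, meal index), ``per_day`` and
    ``mean_daily`` frames.
    """
    unknown = set(diary["item"]) - set(food_db.index)
    if unknown:
        raise KeyError(f"unknown food items: {sorted(unknown)[:5]}")
    if nutrient_cols is None:
        nutrient_cols = [
            c
            for c in food_db.columns
            if food_db[c].dtype.kind in "fi" and c not in ("fruit_veg_pct",)
        ]
    nut = food_db.loc[diary["item"], nutrient_cols].to_numpy()
    contrib = nut * (diary["grams"].to_numpy()[:, None] / 100.0)
    wide = pd.DataFrame(contrib, columns=nutrient_cols, index=diary.index)
    wide[["subject", "day", "meal"]] = diary[["subject", "day", "meal"]]
    per_meal = wide.groupby(["subject", "day", "meal"]).sum()
    per_day = per_meal.groupby(["subject", "day"]).sum()
    mean_daily = per_day.groupby("subject").mean()
    return {"per_meal": per_meal, "per_day": per_day, "mean_daily": mean_daily}
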