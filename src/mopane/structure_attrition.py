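"""Plot structure metrics, tree height distributions and emergent-tree attrition.

Structure metrics are densities (per hectare, scaled by the sampled area of
each plant's stratum), canopy volumes and species richness per plot.  The
attrition analysis follows a matched cohort of emergent trees (live trees
taller than 10 m, main stems thicker than 90 cm circumference) between two
surveys and classifies each tree's fate from its stems' outcomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .canopy_geometry import CrownDimensions, crown_volume
from .survey_model import (
    IMPACT_CATEGORIES,
    PlantRecord,
    PlotSurvey,
    StemRecord,
    sampled_area_ha,
)

__all__ = [
    "StructureMetrics",
    "EmergentFate",
    "structure_metrics",
    "height_distribution",
    "DEFAULT_HEIGHT_BINS",
    "stem_impact_table",
    "classify_emergent_fates",
    "derive_emergent_outcomes",
    "annual_attrition_rate",
    "pollard_probability",
    "DEFAULT_POLLARD_COEF",
]

EMERGENT_HEIGHT_M = 10.0
MAIN_STEM_CIRCUMFERENCE_CM = 90.0

#: Logit coefficients (intercept, slope per metre of stem diameter) for the
#: probability that a main stem is pollarded.
DEFAULT_POLLARD_COEF = (4.5596, -10.0834)

#: Tree height bins (m) for the height-distribution contingency analysis:
#: 3.1-6, 6.1-10, 10.1-14, >14.
DEFAULT_HEIGHT_BINS = (3.0, 6.0, 10.0, 14.0)

STEM_OUTCOMES = ("standing", "pollarded", "fallen", "other")
TREE_FATES = ("intact", "lost_main_stem", "lost_completely")

_SEVERITY = {c: i for i, c in enumerate(IMPACT_CATEGORIES)}


@dataclass(frozen=True)
class StructureMetrics:
    """Structure of one plot: canopy volumes, densities, richness."""

    shrub_canopy_volume: float  # m3/ha
    tree_canopy_volume: float
    total_canopy_volume: float
    shrub_density: float  # per ha
    live_tree_density: float
    live_standing_tree_density: float
    live_prostrate_tree_density: float
    density_lt10m: float
    density_gt10m: float
    pollarded_stem_density: float
    dead_tree_density: float
    mean_tree_height: float | None
    shrub_species_richness: int
    tree_species_richness: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_prostrate(stems: Sequence[StemRecord]) -> bool:
    if not stems:
        return False
    return all(
        s.impact_old in ("pushed_over", "uprooted") or s.impact_new in ("pushed_over", "uprooted")
        for s in stems
    )


def structure_metrics(survey: PlotSurvey) -> StructureMetrics:
    """Compute the plot-level structure metric set from a validated survey."""
    design = survey.design

    def density(plants: Iterable[PlantRecord]) -> float:
        return sum(1.0 / sampled_area_ha(design, p.sampled_stratum) for p in plants)

    def volume(plants: Iterable[PlantRecord]) -> float:
        return sum(
            crown_volume(p.shape_code, CrownDimensions.of(p))
            / sampled_area_ha(design, p.sampled_stratum)
            for p in plants
        )

    live_shrubs = survey.plants_by_form("shrub")
    live_trees = survey.plants_by_form("tree")
    dead_trees = survey.plants_by_form("tree", alive=False)

    prostrate = [p for p in live_trees if _is_prostrate(survey.stems_of(p.plant_id))]
    standing = [p for p in live_trees if p not in prostrate]
    lt10 = [p for p in live_trees if p.height_m <= EMERGENT_HEIGHT_M]
    gt10 = [p for p in live_trees if p.height_m > EMERGENT_HEIGHT_M]

    pollard_density = 0.0
    for p in live_trees + dead_trees:
        area = sampled_area_ha(design, p.sampled_stratum)
        for s in survey.stems_of(p.plant_id):
            if "broken" in (s.impact_old, s.impact_new):
                pollard_density += 1.0 / area

    shrub_vol = volume(live_shrubs)
    tree_vol = volume(live_trees)
    heights = [p.height_m for p in standing]

    return StructureMetrics(
        shrub_canopy_volume=shrub_vol,
        tree_canopy_volume=tree_vol,
        total_canopy_volume=shrub_vol + tree_vol,
        shrub_density=density(live_shrubs),
        live_tree_density=density(live_trees),
        live_standing_tree_density=density(standing),
        live_prostrate_tree_density=density(prostrate),
        density_lt10m=density(lt10),
        density_gt10m=density(gt10),
        pollarded_stem_density=pollard_density,
        dead_tree_density=density(dead_trees),
        mean_tree_height=(sum(heights) / len(heights)) if heights else None,
        shrub_species_richness=len({p.species_code for p in live_shrubs}),
        tree_species_richness=len({p.species_code for p in live_trees}),
    )


def height_distribution(
    trees: Iterable[PlantRecord], bins: Sequence[float] = DEFAULT_HEIGHT_BINS
) -> np.ndarray:
    """Counts of live trees per height bin.

    ``bins`` are edges (b0, b1, ..., bk); bins are (b0, b1], (b1, b2], ...,
    (bk, inf), so a tree of exactly 6.0 m falls in the 3.1-6 m bin.
    """
    edges = list(bins)
    counts = np.zeros(len(edges), dtype=int)
    for p in trees:
        if not p.alive:
            continue
        h = round(p.height_m, 1)
        if h <= edges[0]:
            raise ValueError(f"tree height {h} m at or below the first bin edge {edges[0]}")
        idx = len(edges) - 1
        for i in range(len(edges) - 1):
            if edges[i] < h <= edges[i + 1]:
                idx = i
                break
        counts[idx] += 1
    return counts


def _most_severe(category: str) -> int:
    return _SEVERITY[category]


def stem_impact_table(stems: Sequence[StemRecord], merge_uprooted: bool = True) -> pd.DataFrame:
    """Percent of the stem population in each impact category, by age.

    Each stem contributes its single recorded category per age (categories
    are already the most severe impact observed), so percentages sum to 100
    within an age.  ``merge_uprooted`` folds 'uprooted' into 'pushed_over',
    giving the conventional four-row table.
    """
    if not stems:
        raise ValueError("stem_impact_table requires at least one stem")
    cats = ["none", "branches", "broken", "pushed_over"]
    if not merge_uprooted:
        cats.append("uprooted")
    n = len(stems)
    rows = []
    for cat in cats:
        row = {"category": cat}
        for age in ("old", "new"):
            count = 0
            for s in stems:
                c = getattr(s, f"impact_{age}")
                if merge_uprooted and c == "uprooted":
                    c = "pushed_over"
                if c == cat:
                    count += 1
            row[f"percent_{age}"] = 100.0 * count / n
            row[f"count_{age}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EmergentFate:
    """Fate of one cohort emergent tree between two surveys."""

    tree_id: str
    n_main_stems: int
    n_stems: int
    fate: str  # intact | lost_main_stem | lost_completely
    stem_outcomes: tuple[tuple[str, str], ...]  # (stem_id, outcome)

    def __post_init__(self):
        if self.fate not in TREE_FATES:
            raise ValueError(f"unknown fate {self.fate!r}")


def classify_emergent_fates(
    outcomes: pd.DataFrame,
    main_stem_circumference_cm: float = MAIN_STEM_CIRCUMFERENCE_CM,
) -> tuple[list[EmergentFate], dict]:
    """Tree fates and summary percentages from per-stem outcomes.

    ``outcomes`` needs columns tree_id, stem_id, circumference_cm, outcome
    (standing | pollarded | fallen | other, measured at the resurvey).  A
    tree is *intact* when no main stem (circumference above the threshold
    at the first survey) was lost, *lost_completely* when no stem remains
    standing, otherwise *lost_main_stem*.  The summary reports tree-fate
    percentages over the cohort and stem-outcome percentages over the stem
    population.
    """
    required = {"tree_id", "stem_id", "circumference_cm", "outcome"}
    if not required.issubset(outcomes.columns):
        raise ValueError(f"outcomes table must have columns {sorted(required)}")
    bad = set(outcomes["outcome"]) - set(STEM_OUTCOMES)
    if bad:
        raise ValueError(f"unknown stem outcomes {sorted(bad)}")

    fates: list[EmergentFate] = []
    for tree_id, grp in outcomes.groupby("tree_id", sort=True):
        is_main = grp["circumference_cm"] > main_stem_circumference_cm
        lost = grp["outcome"] != "standing"
        if lost.all():
            fate = "lost_completely"
        elif (lost & is_main).any():
            fate = "lost_main_stem"
        else:
            fate = "intact"
        fates.append(
            EmergentFate(
                tree_id=str(tree_id),
                n_main_stems=int(is_main.sum()),
                n_stems=len(grp),
                fate=fate,
                stem_outcomes=tuple(
                    (str(r.stem_id), str(r.outcome)) for r in grp.itertuples()
                ),
            )
        )

    n_trees = len(fates)
    n_stems = len(outcomes)
    summary = {
        "n_trees": n_trees,
        "n_stems": n_stems,
        "tree_pct": {
            fate: 100.0 * sum(f.fate == fate for f in fates) / n_trees for fate in TREE_FATES
        },
        "stem_pct": {
            oc: 100.0 * (outcomes["outcome"] == oc).sum() / n_stems for oc in STEM_OUTCOMES
        },
    }
    summary["stem_lost_pct"] = 100.0 - summary["stem_pct"]["standing"]
    return fates, summary


def derive_emergent_outcomes(
    cohort: PlotSurvey,
    resurvey: PlotSurvey,
    emergent_height_m: float = EMERGENT_HEIGHT_M,
) -> pd.DataFrame:
    """Per-stem outcome table for emergent trees matched across two surveys.

    The cohort is the first survey's live trees above the emergent height.
    A stem still present and unbroken at resurvey is standing; new 'broken'
    impact means pollarded, 'pushed_over'/'uprooted' means fallen; a stem
    absent from the resurvey (or on a plant that disappeared) is 'other'.
    """
    rows = []
    re_stems = {(s.plant_id, s.stem_id): s for s in resurvey.stems}
    re_plants = {p.plant_id for p in resurvey.plants}
    for plant in cohort.plants_by_form("tree"):
        if plant.height_m <= emergent_height_m:
            continue
        for s in cohort.stems_of(plant.plant_id):
            later = re_stems.get((s.plant_id, s.stem_id))
            if later is None:
                outcome = "other"
            elif later.impact_new == "broken":
                outcome = "pollarded"
            elif later.impact_new in ("pushed_over", "uprooted"):
                outcome = "fallen"
            elif s.plant_id not in re_plants:
                outcome = "other"
            else:
                outcome = "standing"
            rows.append(
                {
                    "tree_id": plant.plant_id,
                    "stem_id": s.stem_id,
                    "circumference_cm": s.circumference_cm,
                    "outcome": outcome,
                }
            )
    return pd.DataFrame(rows, columns=["tree_id", "stem_id", "circumference_cm", "outcome"])


def annual_attrition_rate(
    n_cohort: int, n_lost: int, years: float, compound: bool = False
) -> float:
    """Percent of a monitored cohort lost per annum.

    The default is the simple linear rate (n_lost / n_cohort) / years * 100.
    ``compound=True`` gives the equivalent constant annual rate
    100 * (1 - (1 - p)^(1/years)).
    """
    if years <= 0:
        raise ValueError("years must be > 0")
    if not 0 <= n_lost <= n_cohort:
        raise ValueError("need 0 <= n_lost <= n_cohort")
    if n_cohort == 0:
        raise ValueError("empty cohort")
    p = n_lost / n_cohort
    if compound:
        return 100.0 * (1.0 - (1.0 - p) ** (1.0 / years))
    return 100.0 * p / years


def pollard_probability(
    stem_diameter_m: float | np.ndarray,
    coefficients: tuple[float, float] = DEFAULT_POLLARD_COEF,
) -> float | np.ndarray:
    """Probability that a main stem of the given diameter is pollarded.

    Inverse-logit of ``intercept + slope * diameter``; with the default
    coefficients the odds are even near 0.45 m diameter, above which stems
    are effectively safe from pollarding.
    """
    d = np.asarray(stem_diameter_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("stem diameter must be >= 0")
    b0, b1 = coefficients
    p = expit(b0 + b1 * d)
    return float(p) if np.isscalar(stem_diameter_m) else p
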