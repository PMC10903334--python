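"""Plot-level percent-damage estimators from ordinal canopy-loss scores.

Canopy loss is scored in ordinal percent classes and converted to the class
midpoint for analysis.  Plot-level estimates are weighted means:

* tree canopy loss is weighted by stem cross-sectional area;
* new shrub loss is weighted by measured crown volume V_M, old shrub loss
  by the reconstructed pre-damage volume V_R = V_M * 100 / (100 - %loss);
* bark (debarking) damage is weighted by stem circumference, reported
  separately for trees <= 7 m and > 7 m tall.

Weights are rescaled to a common per-hectare basis before species or
strata sampled over different belt widths are combined, so the estimates
are invariant to a uniform rescaling of belt widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .canopy_geometry import CrownDimensions, crown_volume
from .survey_model import (
    AGENTS,
    AGES,
    PlantRecord,
    PlotSurvey,
    StemRecord,
    TransectDesign,
    sampled_area_ha,
)

__all__ = [
    "DamageScale",
    "WALKER_SCALE",
    "PlotDamageSummary",
    "class_midpoint",
    "reconstructed_volume",
    "tree_damage_percent",
    "shrub_damage_percent",
    "bark_damage_percent",
    "plot_damage_summary",
]


@dataclass(frozen=True)
class DamageScale:
    """Ordered percent-loss classes and their numeric midpoints."""

    bounds: tuple[tuple[float, float], ...]
    midpoints: tuple[float, ...]

    def __post_init__(self):
        if len(self.bounds) != len(self.midpoints):
            raise ValueError("bounds and midpoints must have equal length")
        prev_hi = -1.0
        for (lo, hi), mid in zip(self.bounds, self.midpoints):
            if lo > hi or not (lo <= mid <= hi):
                raise ValueError(f"midpoint {mid} outside class [{lo}, {hi}]")
            if lo <= prev_hi and not (lo == 0 and prev_hi == -1):
                raise ValueError("classes must be ordered and non-overlapping")
            prev_hi = hi
        if self.bounds[0][0] != 0 or self.bounds[-1][1] != 100:
            raise ValueError("classes must cover 0..100")

    def label(self, index: int) -> str:
        lo, hi = self.bounds[index]
        return f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"

    @property
    def labels(self) -> list[str]:
        return [self.label(i) for i in range(len(self.bounds))]

    def index_of(self, label: str) -> int:
        lab = str(label).strip().replace("–", "-")
        for i in range(len(self.bounds)):
            if self.label(i) == lab:
                return i
        # accept a bare numeric percent and map it into its class
        try:
            return self.class_for_percent(float(lab))
        except ValueError:
            raise ValueError(f"unknown damage class label {label!r}") from None

    def midpoint(self, index: int) -> float:
        if not 0 <= index < len(self.midpoints):
            raise ValueError(f"loss class index {index} out of range")
        return self.midpoints[index]

    def class_for_percent(self, percent: float) -> int:
        """Index of the class containing a raw percent value."""
        if not 0 <= percent <= 100:
            raise ValueError("percent must lie in [0, 100]")
        for i, (lo, hi) in enumerate(self.bounds):
            if lo <= percent <= hi:
                return i
        # percent falls in a gap between printed integer classes (e.g. 5.5):
        # assign the class whose interval is nearest
        dists = [min(abs(percent - lo), abs(percent - hi)) for lo, hi in self.bounds]
        return int(min(range(len(dists)), key=dists.__getitem__))


#: The nine-class canopy-loss scale: 0, 1-5, 6-10, 11-25, 26-50, 51-75,
#: 76-90, 91-99, 100 percent, with midpoints 0, 3, 8, 18, 38, 63, 83, 95, 100.
WALKER_SCALE = DamageScale(
    bounds=((0, 0), (1, 5), (6, 10), (11, 25), (26, 50), (51, 75), (76, 90), (91, 99), (100, 100)),
    midpoints=(0, 3, 8, 18, 38, 63, 83, 95, 100),
)


def class_midpoint(loss_class: int, scale: DamageScale = WALKER_SCALE) -> float:
    """Numeric midpoint (percent) of an ordinal loss class."""
    return scale.midpoint(loss_class)


def reconstructed_volume(v_measured: float, old_damage_pct: float) -> float:
    """Pre-damage crown volume V_R from measured volume and percent loss.

    V_R = V_M * 100 / (100 - %damage); undefined at 100% loss.
    """
    if not 0 <= old_damage_pct <= 100:
        raise ValueError("old_damage_pct must lie in [0, 100]")
    if old_damage_pct == 100:
        raise ValueError("reconstruction undefined at 100% loss")
    return v_measured * 100.0 / (100.0 - old_damage_pct)


def _plant_midpoint(
    plant: PlantRecord, agent: str, age: str, scale: DamageScale
) -> float:
    cls = plant.loss_class(agent, age)
    return scale.midpoint(cls) if cls is not None else 0.0


def tree_damage_percent(
    survey: PlotSurvey,
    agent: str,
    age: str,
    scale: DamageScale = WALKER_SCALE,
    uprooted_is_total: bool = True,
) -> float | None:
    """Percent tree canopy volume lost to (agent, age) on a plot.

    Weighted mean of per-tree loss midpoints with weights equal to the
    summed stem cross-sectional area of each live tree, rescaled per
    hectare by the tree's sampling stratum.  Trees without a recorded entry
    contribute zero loss.  When ``uprooted_is_total`` a live tree whose
    stems are all uprooted or pushed over in the matching age, with no loss
    class recorded, is scored as 100% loss.  Returns None (missing, not 0)
    when the plot holds no live trees with stems.
    """
    num = den = 0.0
    any_tree = False
    for plant in survey.plants_by_form("tree"):
        stems = survey.stems_of(plant.plant_id)
        if not stems:
            continue
        any_tree = True
        weight = sum(s.cross_section_m2 for s in stems)
        weight /= sampled_area_ha(survey.design, plant.sampled_stratum)
        pct = _plant_midpoint(plant, agent, age, scale)
        if (
            uprooted_is_total
            and agent == "elephant"
            and plant.loss_class(agent, age) is None
            and all(
                getattr(s, f"impact_{age}") in ("pushed_over", "uprooted") for s in stems
            )
        ):
            pct = 100.0
        num += weight * pct
        den += weight
    if not any_tree or den == 0:
        return None
    return num / den


def shrub_damage_percent(
    survey: PlotSurvey,
    agent: str,
    age: str,
    scale: DamageScale = WALKER_SCALE,
) -> float | None:
    """Percent shrub canopy volume lost to (agent, age) on a plot.

    New damage is weighted by measured crown volume; old damage by the
    reconstructed pre-damage volume.  Weights are divided by the sampled
    area of each shrub's stratum so belts of different width combine on a
    common per-hectare basis.  Returns None when the plot has no live
    shrubs with crown volume.
    """
    num = den = 0.0
    for plant in survey.plants_by_form("shrub"):
        vol = crown_volume(plant.shape_code, CrownDimensions.of(plant))
        if vol <= 0:
            continue
        pct = _plant_midpoint(plant, agent, age, scale)
        if age == "old":
            old_total = min(
                sum(
                    _plant_midpoint(plant, a, "old", scale)
                    for a in AGENTS
                ),
                scale.midpoints[-2],  # cap below total loss; V_R undefined at 100
            )
            weight = reconstructed_volume(vol, old_total)
        else:
            weight = vol
        weight /= sampled_area_ha(survey.design, plant.sampled_stratum)
        num += weight * pct
        den += weight
    if den == 0:
        return None
    return num / den


def bark_damage_percent(
    survey: PlotSurvey,
    agent: str,
    age: str,
    height_group: str,
) -> float | None:
    """Percent of bark (stem circumference) removed by (agent, age).

    ``height_group`` is "le7m" (trees <= 7 m tall) or "gt7m".  The estimate
    is the circumference-weighted mean debarked fraction over live-tree
    stems in the group, scaled per hectare by stratum before combining.
    Returns None when the group holds no stems.
    """
    if height_group not in ("le7m", "gt7m"):
        raise ValueError("height_group must be 'le7m' or 'gt7m'")
    num = den = 0.0
    any_stem = False
    for plant in survey.plants_by_form("tree"):
        in_group = (plant.height_m <= 7.0) == (height_group == "le7m")
        if not in_group:
            continue
        area = sampled_area_ha(survey.design, plant.sampled_stratum)
        for s in survey.stems_of(plant.plant_id):
            any_stem = True
            frac = getattr(s, f"debark_{age}_fraction")
            if getattr(s, f"debark_{age}_agent") != agent:
                frac = 0.0
            w = s.circumference_cm / area
            num += w * frac
            den += w
    if not any_stem or den == 0:
        return None
    return 100.0 * num / den


@dataclass
class PlotDamageSummary:
    """All damage cells for one plot, as a tidy table.

    ``table`` columns: form (tree|shrub|bark), agent, age, group
    (total|le7m|gt7m), percent (NaN = missing).  ``percent(...)`` gives
    cell access.
    """

    plot_id: str
    table: pd.DataFrame = field(repr=False)

    def percent(self, form: str, agent: str, age: str, group: str = "total") -> float | None:
        m = self.table[
            (self.table["form"] == form)
            & (self.table["agent"] == agent)
            & (self.table["age"] == age)
            & (self.table["group"] == group)
        ]
        if m.empty:
            raise KeyError((form, agent, age, group))
        v = m["percent"].iloc[0]
        return None if pd.isna(v) else float(v)


def plot_damage_summary(
    survey: PlotSurvey, scale: DamageScale = WALKER_SCALE
) -> PlotDamageSummary:
    """Damage percentages for every (form, agent, age) cell of one plot.

    Fire damage is computed like any other agent but callers conventionally
    report it separately.  Bark damage is reported for the two tree height
    groups (<= 7 m, > 7 m); canopy damage as the plot total.
    """
    rows = []
    for agent in AGENTS:
        for age in AGES:
            rows.append(
                {
                    "form": "tree",
                    "agent": agent,
                    "age": age,
                    "group": "total",
                    "percent": tree_damage_percent(survey, agent, age, scale),
                }
            )
            rows.append(
                {
                    "form": "shrub",
                    "agent": agent,
                    "age": age,
                    "group": "total",
                    "percent": shrub_damage_percent(survey, agent, age, scale),
                }
            )
            if agent != "fire":
                for group in ("le7m", "gt7m"):
                    rows.append(
                        {
                            "form": "bark",
                            "agent": agent,
                            "age": age,
                            "group": group,
                            "percent": bark_damage_percent(survey, agent, age, group),
                        }
                    )
    return PlotDamageSummary(plot_id=survey.plot_id, table=pd.DataFrame(rows))


def combined_damage_percent(
    old_pct: float, new_pct: float, combiner: str = "additive"
) -> float:
    """Combine old and new loss into a single percent.

    "additive" sums the two (capped at 100); "sequential" compounds them as
    1 - (1-old)(1-new).  Additive is the default combiner.
    """
    if combiner == "additive":
        return min(old_pct + new_pct, 100.0)
    if combiner == "sequential":
        return 100.0 * (1.0 - (1.0 - old_pct / 100.0) * (1.0 - new_pct / 100.0))
    raise ValueError("combiner must be 'additive' or 'sequential'")
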