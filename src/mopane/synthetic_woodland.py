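"""Synthetic mopane-woodland surveys and a forward simulator of elephant impact.

The generator emulates the statistical structure of nested belt-transect
field data under three elephant-density regimes (low, intermediate, high),
so every analysis stage can be exercised without external data, and doubles
as an individual-based forward simulator of pollarding, debarking, canopy
dieback and windthrow:

* plant counts are Poisson draws from per-hectare intensities over the
  sampled area of each stratum;
* tree heights follow a regime-specific mixture over the field height bins
  (the high-density regime lacks 6.1-10 m trees but keeps >14 m relicts);
* main-stem diameter is tied to height through a saturating logistic
  allometry (with a proportional floor where the curve is uninvertible)
  plus lognormal noise;
* the probability that a stem is pollarded falls with stem diameter through
  a logit-linear curve (default: even odds near 0.45 m diameter);
* emergent stems accrue debark fractions that progress linearly between
  surveys, canopy dieback follows a 3-parameter logistic in percent
  circumference debarked, and heavily debarked stems can be toppled by
  windthrow;
* shrub utilisation probability depends on shrub height class.

All randomness flows from a single integer seed through named streams
(per plot, per process), so adding plants to one plot never perturbs the
draws of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .damage_metrics import WALKER_SCALE, DamageScale
from .structure_attrition import DEFAULT_POLLARD_COEF, pollard_probability
from .survey_model import (
    DamageEntry,
    PlantRecord,
    PlotSurvey,
    StemRecord,
    TransectDesign,
    write_survey,
)

__all__ = [
    "RegimeConfig",
    "regime_config",
    "REGIME_LABELS",
    "simulate_plot",
    "apply_elephant_impacts",
    "simulate_resurvey",
    "generate_fixture_suite",
    "simulate_pollarding_dataset",
    "simulate_dieback_dataset",
    "simulate_debark_progression_dataset",
    "simulate_height_diameter_dataset",
]

REGIME_LABELS = ("low", "intermediate", "high")

_SHRUB_SPECIES = ("colmop", "commos", "diccin", "grelep", "fluvir", "maepar")
_TREE_SPECIES = ("colmop", "comapi", "terpru")


def _stream(seed: int, *key) -> np.random.Generator:
    """Independent named random stream derived from one master seed."""
    parts = [int(seed) & 0x7FFFFFFF]
    for k in key:
        digest = hashlib.blake2s(repr(k).encode(), digest_size=4).digest()
        parts.append(int.from_bytes(digest, "big"))
    return np.random.default_rng(np.random.SeedSequence(parts))


@dataclass(frozen=True)
class RegimeConfig:
    """All parameters of one simulated elephant-density regime.

    Defaults are anchored to the fitted curves and rates of the study
    system: the pollarding logit (4.5596, -10.0834 per m diameter), the
    debark progression line (0.53565 x + 0.25674), the dieback curve
    (A=0.63541, k=0.57294, x0=0.034 on percent debarked), the
    height-diameter allometry (A=22.43158 m, k=0.47110, x0=0.17881 m) and
    the shrub-use probabilities by height class (23.4% below 1 m, 80.2% for
    1.1-3 m, under high density).
    """

    label: str = "high"
    seed: int = 0
    n_plots: int = 7
    baseline_length_m: float = 50.0
    belt_widths: Mapping[str, float] = field(
        default_factory=lambda: {"common_shrub": 2.0, "rare_shrub": 5.0, "tree": 20.0}
    )
    emergent_census_area_ha: float = 1.0

    # per-hectare intensities
    shrub_density_per_ha: float = 2100.0
    tree_density_per_ha: float = 193.0
    dead_tree_density_per_ha: float = 9.0

    # tree height mixture over bins (3-6, 6-10, 10-14, >14 m]
    tree_height_bin_probs: tuple[float, float, float, float] = (0.90, 0.01, 0.03, 0.06)
    tree_height_bin_edges: tuple[float, ...] = (3.0, 6.0, 10.0, 14.0, 18.0)
    shrub_frac_below_1m: float = 0.6

    # stems per tree: probabilities of 1, 2, 3 main stems
    stem_count_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)

    # height-diameter allometry h = A / (1 + exp(-k (d - x0))), d in metres
    allometry_A: float = 22.43158
    allometry_k: float = 0.47110
    allometry_x0: float = 0.17881
    allometry_noise_sd: float = 0.08
    diameter_floor_ratio: float = 0.045  # m diameter per m height

    # impact process
    pollard_coef: tuple[float, float] = DEFAULT_POLLARD_COEF
    impact_intensity: float = 1.0  # fraction of stems encountered by elephants
    branch_use_prob: float = 0.55
    new_impact_intensity: float = 0.5

    # debarking and dieback (emergent stems)
    emergent_debark_max: float = 0.7
    debark_slope: float = 0.53565
    debark_intercept: float = 0.25674
    debark_resid_sd: float = 0.08
    dieback_A: float = 0.63541
    dieback_k: float = 0.57294
    dieback_x0: float = 0.034
    dieback_x_scale: str = "percent"  # x = 100 * debark fraction
    dieback_noise_sd: float = 0.05

    # shrub utilisation by height class
    shrub_use_prob_lt1m: float = 0.234
    shrub_use_prob_1to3m: float = 0.802
    shrub_new_use_prob: float = 0.3

    # resurvey dynamics
    windthrow_threshold: float = 0.5  # debark fraction beyond which windthrow operates
    windthrow_prob: float = 0.5  # per resurvey interval, for stems past threshold
    interval_encounter_prob: float = 0.25  # chance a main stem is tried in the interval
    other_loss_prob: float = 0.02
    recruitment_per_ha_per_yr: float = 20.0

    def __post_init__(self):
        # YAML round-trips deliver lists; normalise sequence fields to tuples
        for name in (
            "tree_height_bin_probs",
            "tree_height_bin_edges",
            "stem_count_probs",
            "pollard_coef",
        ):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(self, "belt_widths", dict(self.belt_widths))
        for name in (
            "impact_intensity",
            "branch_use_prob",
            "new_impact_intensity",
            "shrub_use_prob_lt1m",
            "shrub_use_prob_1to3m",
            "shrub_new_use_prob",
            "windthrow_prob",
            "interval_encounter_prob",
            "other_loss_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.shrub_density_per_ha < 0 or self.tree_density_per_ha < 0:
            raise ValueError("densities must be >= 0")
        if abs(sum(self.tree_height_bin_probs) - 1.0) > 1e-9:
            raise ValueError("tree_height_bin_probs must sum to 1")
        if self.dieback_x_scale not in ("percent", "fraction"):
            raise ValueError("dieback_x_scale must be 'percent' or 'fraction'")

    @property
    def design(self) -> TransectDesign:
        return TransectDesign(
            baseline_length_m=self.baseline_length_m,
            belt_width_by_stratum=dict(self.belt_widths),
            emergent_census_area_ha=self.emergent_census_area_ha,
        )

    def dieback_mean(self, debark_fraction: float | np.ndarray) -> float | np.ndarray:
        """Expected dieback fraction at a given debark fraction."""
        x = np.asarray(debark_fraction, dtype=float)
        if self.dieback_x_scale == "percent":
            x = 100.0 * x
        return self.dieback_A / (1.0 + np.exp(-self.dieback_k * (x - self.dieback_x0)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["belt_widths"] = dict(d["belt_widths"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegimeConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


#: regime-specific overrides of the (high-density) defaults
_REGIME_PRESETS: dict[str, dict] = {
    "low": dict(
        label="low",
        n_plots=8,
        shrub_density_per_ha=1406.0,
        tree_density_per_ha=259.0,
        dead_tree_density_per_ha=32.0,
        tree_height_bin_probs=(0.45, 0.40, 0.09, 0.06),
        impact_intensity=0.12,
        new_impact_intensity=0.02,
        shrub_use_prob_lt1m=0.05,
        shrub_use_prob_1to3m=0.15,
        emergent_debark_max=0.1,
    ),
    "intermediate": dict(
        label="intermediate",
        n_plots=8,
        shrub_density_per_ha=1004.0,
        tree_density_per_ha=205.0,
        dead_tree_density_per_ha=24.0,
        tree_height_bin_probs=(0.40, 0.26, 0.20, 0.14),
        impact_intensity=0.5,
        new_impact_intensity=0.15,
        shrub_use_prob_lt1m=0.15,
        shrub_use_prob_1to3m=0.55,
        emergent_debark_max=0.35,
    ),
    "high": dict(label="high", n_plots=7),
}


def regime_config(label: str, seed: int = 0, **overrides) -> RegimeConfig:
    """Preset configuration for one elephant-density regime."""
    if label not in _REGIME_PRESETS:
        raise ValueError(f"regime must be one of {REGIME_LABELS}")
    kwargs = dict(_REGIME_PRESETS[label])
    kwargs.update(overrides)
    return RegimeConfig(seed=seed, **kwargs)


def _diameter_from_height(h: float, config: RegimeConfig, rng: np.random.Generator) -> float:
    """Main-stem diameter (m) for a tree of height ``h`` via inverse allometry.

    Where the logistic allometry is uninvertible (heights below its lower
    plateau) a proportional floor keeps diameter monotone in height.
    """
    arg = config.allometry_A / h - 1.0
    if arg > 0:
        d_inv = config.allometry_x0 - np.log(arg) / config.allometry_k
    else:
        d_inv = np.inf
    d = max(d_inv, config.diameter_floor_ratio * h)
    d = float(np.clip(d, 0.03, 2.0))
    return d * float(np.exp(rng.normal(0.0, config.allometry_noise_sd)))


def _draw_tree_height(config: RegimeConfig, rng: np.random.Generator) -> float:
    edges = config.tree_height_bin_edges
    i = rng.choice(len(config.tree_height_bin_probs), p=config.tree_height_bin_probs)
    return round(float(rng.uniform(edges[i] + 0.1, edges[i + 1])), 1)


def _draw_shrub_height(config: RegimeConfig, rng: np.random.Generator) -> float:
    if rng.random() < config.shrub_frac_below_1m:
        return round(float(rng.uniform(0.1, 1.0)), 1)
    return round(float(rng.uniform(1.0, 3.0)), 1)


def _crown(h: float, rng: np.random.Generator, shrub: bool) -> tuple[float, float, float]:
    if shrub:
        d1 = h * rng.uniform(0.5, 1.4)
        depth = h * rng.uniform(0.5, 0.95)
    else:
        d1 = h * rng.uniform(0.35, 0.9)
        depth = h * rng.uniform(0.35, 0.75)
    d2 = d1 * rng.uniform(0.6, 1.0)
    return round(d1, 2), round(d2, 2), round(min(depth, h), 2)


def simulate_plot(config: RegimeConfig, plot_id: str, seed: int | None = None) -> PlotSurvey:
    """Generate one un-impacted plot survey under a regime configuration.

    The same (config.seed, plot_id) always yields an identical survey.
    """
    seed = config.seed if seed is None else seed
    design = config.design
    rng = _stream(seed, "plot", config.label, plot_id)

    plants: list[PlantRecord] = []
    stems: list[StemRecord] = []

    area_shrub = design.baseline_length_m * design.belt_width_by_stratum["common_shrub"] / 1e4
    area_tree = design.baseline_length_m * design.belt_width_by_stratum["tree"] / 1e4

    n_shrub = rng.poisson(config.shrub_density_per_ha * area_shrub)
    for i in range(n_shrub):
        h = _draw_shrub_height(config, rng)
        d1, d2, depth = _crown(h, rng, shrub=True)
        plants.append(
            PlantRecord(
                plant_id=f"{plot_id}-s{i:04d}",
                species_code=str(rng.choice(_SHRUB_SPECIES, p=(0.5, 0.1, 0.1, 0.1, 0.1, 0.1))),
                growth_form="shrub",
                height_m=h,
                crown_d1_m=d1,
                crown_d2_m=d2,
                crown_depth_m=depth,
                shape_code=int(rng.integers(1, 8)),
                sampled_stratum="common_shrub",
            )
        )

    n_tree = rng.poisson(config.tree_density_per_ha * area_tree)
    for i in range(n_tree):
        h = _draw_tree_height(config, rng)
        d1, d2, depth = _crown(h, rng, shrub=False)
        pid = f"{plot_id}-t{i:04d}"
        plants.append(
            PlantRecord(
                plant_id=pid,
                species_code=str(rng.choice(_TREE_SPECIES, p=(0.9, 0.07, 0.03))),
                growth_form="tree",
                height_m=h,
                crown_d1_m=d1,
                crown_d2_m=d2,
                crown_depth_m=depth,
                shape_code=int(rng.integers(1, 8)),
                sampled_stratum="tree",
            )
        )
        n_stem = 1 + int(rng.choice(3, p=config.stem_count_probs))
        d_main = _diameter_from_height(h, config, rng)
        for j in range(n_stem):
            d = d_main if j == 0 else d_main * rng.uniform(0.4, 0.9)
            stems.append(
                StemRecord(
                    plant_id=pid,
                    stem_id=f"{pid}-st{j}",
                    circumference_cm=round(max(d * np.pi * 100.0, 1.0), 1),
                )
            )

    # extra emergent-tree census around the plot: tall trees only, sampled
    # over the census area beyond the tree belt
    p_tall = config.tree_height_bin_probs[2] + config.tree_height_bin_probs[3]
    extra_area = max(config.emergent_census_area_ha - area_tree, 0.0)
    n_emergent = rng.poisson(config.tree_density_per_ha * p_tall * extra_area)
    tall_probs = np.array(config.tree_height_bin_probs[2:], dtype=float)
    tall_probs /= tall_probs.sum() if tall_probs.sum() > 0 else 1.0
    edges = config.tree_height_bin_edges
    for i in range(n_emergent):
        b = 2 + int(rng.choice(2, p=tall_probs))
        h = round(float(rng.uniform(edges[b] + 0.1, edges[b + 1])), 1)
        d1, d2, depth = _crown(h, rng, shrub=False)
        pid = f"{plot_id}-e{i:04d}"
        plants.append(
            PlantRecord(
                plant_id=pid,
                species_code="colmop",
                growth_form="tree",
                height_m=h,
                crown_d1_m=d1,
                crown_d2_m=d2,
                crown_depth_m=depth,
                shape_code=int(rng.integers(1, 8)),
                sampled_stratum="emergent",
            )
        )
        n_stem = 1 + int(rng.choice(3, p=config.stem_count_probs))
        d_main = _diameter_from_height(h, config, rng)
        for j in range(n_stem):
            d = d_main if j == 0 else d_main * rng.uniform(0.4, 0.9)
            stems.append(
                StemRecord(
                    plant_id=pid,
                    stem_id=f"{pid}-st{j}",
                    circumference_cm=round(max(d * np.pi * 100.0, 1.0), 1),
                )
            )

    n_dead = rng.poisson(config.dead_tree_density_per_ha * area_tree)
    for i in range(n_dead):
        h = _draw_tree_height(config, rng)
        pid = f"{plot_id}-d{i:04d}"
        plants.append(
            PlantRecord(
                plant_id=pid,
                species_code="colmop",
                growth_form="tree",
                height_m=h,
                crown_d1_m=0.0,
                crown_d2_m=0.0,
                crown_depth_m=0.0,
                shape_code=2,
                alive=False,
                sampled_stratum="tree",
            )
        )

    survey = PlotSurvey(
        plot_id=plot_id,
        reserve="GNP" if config.label == "high" else "MWR",
        year=2014,
        regime=config.label,
        design=design,
        plants=plants,
        stems=stems,
    )
    survey.validate()
    return survey


def _loss_entry(pct: float, age: str, scale: DamageScale) -> DamageEntry:
    return DamageEntry(agent="elephant", age=age, loss_class=scale.class_for_percent(pct))


def apply_elephant_impacts(
    survey: PlotSurvey, config: RegimeConfig, seed: int | None = None
) -> PlotSurvey:
    """Impose elephant utilisation on an un-impacted survey.

    Each encountered stem is pollarded with the diameter-dependent logit
    probability, else loses branches with a fixed probability; pollarded
    stems truncate their tree to a coppiced height drawn in (0, 3] m.
    Emergent stems accrue debark fractions and logistic canopy dieback.
    Shrubs are used with height-class-dependent probability.  Damage
    classes are back-filled from the realised canopy losses.
    """
    seed = config.seed if seed is None else seed
    scale = WALKER_SCALE
    out_plants: list[PlantRecord] = []
    out_stems: list[StemRecord] = []
    stems_by_plant: dict[str, list[StemRecord]] = {}
    for s in survey.stems:
        stems_by_plant.setdefault(s.plant_id, []).append(s)

    for plant in survey.plants:
        rng = _stream(seed, "impact", survey.plot_id, plant.plant_id)
        if not plant.alive:
            out_plants.append(replace(plant))
            out_stems.extend(replace(s) for s in stems_by_plant.get(plant.plant_id, []))
            continue

        if plant.growth_form == "shrub":
            use_p = (
                config.shrub_use_prob_lt1m
                if plant.height_m < 1.0
                else config.shrub_use_prob_1to3m
            )
            entries: list[DamageEntry] = []
            if rng.random() < use_p:
                old_pct = float(rng.uniform(1.0, 75.0))
                entries.append(_loss_entry(old_pct, "old", scale))
                if rng.random() < config.shrub_new_use_prob:
                    entries.append(_loss_entry(float(rng.uniform(1.0, 25.0)), "new", scale))
            out_plants.append(replace(plant, damage_entries=tuple(entries)))
            continue

        # tree: process each stem
        my_stems = stems_by_plant.get(plant.plant_id, [])
        new_stems: list[StemRecord] = []
        stem_loss: list[tuple[float, float]] = []  # (cross-section weight, loss pct)
        any_pollard = False
        for s in my_stems:
            d = s.diameter_m
            impact_old = "none"
            loss_old = 0.0
            if rng.random() < config.impact_intensity:
                if rng.random() < pollard_probability(d, config.pollard_coef):
                    impact_old = "broken"
                    any_pollard = True
                    loss_old = float(rng.uniform(50.0, 95.0))
                elif rng.random() < config.branch_use_prob:
                    impact_old = "branches"
                    loss_old = float(rng.uniform(1.0, 25.0))
            impact_new = "none"
            loss_new = 0.0
            if impact_old != "broken" and rng.random() < config.new_impact_intensity:
                impact_new = "branches"
                loss_new = float(rng.uniform(1.0, 10.0))

            debark_old = 0.0
            dieback = None
            is_emergent = plant.height_m > 10.0 or d > 0.45
            if is_emergent and impact_old != "broken":
                debark_old = float(rng.uniform(0.0, config.emergent_debark_max))
                mean = float(config.dieback_mean(debark_old))
                dieback = float(
                    np.clip(mean + rng.normal(0.0, config.dieback_noise_sd), 0.0, 1.0)
                )
            new_stems.append(
                replace(
                    s,
                    impact_old=impact_old,
                    impact_new=impact_new,
                    coppicing=impact_old == "broken",
                    debark_old_fraction=round(debark_old, 4),
                    dieback_fraction=None if dieback is None else round(dieback, 4),
                )
            )
            stem_loss.append((s.cross_section_m2, loss_old))
            stem_loss.append((0.0, loss_new))  # placeholder keeps indices aligned

        w = sum(wt for wt, _ in stem_loss[::2]) or 1.0
        plant_old = sum(wt * pct for wt, pct in stem_loss[::2]) / w
        plant_new = max((pct for _, pct in stem_loss[1::2]), default=0.0)
        entries = []
        if plant_old > 0:
            entries.append(_loss_entry(plant_old, "old", scale))
        if plant_new > 0:
            entries.append(_loss_entry(plant_new, "new", scale))

        new_plant = replace(plant, damage_entries=tuple(entries))
        if any_pollard:
            # the stem snaps between ground level and 3 m, then coppices;
            # the hedged plant regrows into the 3.1-6 m class
            hedged_h = round(float(rng.uniform(3.1, 6.0)), 1)
            if hedged_h < plant.height_m:
                new_plant = replace(
                    new_plant,
                    height_m=hedged_h,
                    crown_depth_m=round(min(plant.crown_depth_m, hedged_h), 2),
                    crown_d1_m=round(plant.crown_d1_m * 0.7, 2),
                    crown_d2_m=round(plant.crown_d2_m * 0.7, 2),
                )
        out_plants.append(new_plant)
        out_stems.extend(new_stems)

    out = PlotSurvey(
        plot_id=survey.plot_id,
        reserve=survey.reserve,
        year=survey.year,
        regime=survey.regime,
        design=survey.design,
        plants=out_plants,
        stems=out_stems,
    )
    out.validate()
    return out


def simulate_resurvey(
    survey: PlotSurvey, config: RegimeConfig, years: int = 8, seed: int | None = None
) -> tuple[PlotSurvey, pd.DataFrame]:
    """Advance an impacted survey by ``years`` of chronic utilisation.

    Emergent stems progress their debark fraction along the configured
    linear relation, update dieback, and are lost to pollarding (diameter
    logit times the interval encounter probability), to windthrow once
    debarking exceeds the threshold, or to other causes.  Returns the later
    survey plus a truth table of per-stem outcomes (columns tree_id,
    stem_id, circumference_cm, outcome) for the emergent cohort, suitable
    for :func:`mopane.structure_attrition.classify_emergent_fates`.
    """
    seed = config.seed if seed is None else seed
    emergent_ids = {
        p.plant_id
        for p in survey.plants_by_form("tree")
        if p.height_m > 10.0
    }
    truth_rows = []
    out_stems: list[StemRecord] = []
    lost_stem_keys: set[tuple[str, str]] = set()

    for s in survey.stems:
        rng = _stream(seed, "resurvey", survey.plot_id, s.plant_id, s.stem_id)
        if s.plant_id not in emergent_ids or s.impact_old == "broken":
            out_stems.append(replace(s))
            continue
        debark_new = config.debark_slope * s.debark_old_fraction + config.debark_intercept
        debark_new += float(rng.normal(0.0, config.debark_resid_sd))
        debark_new = float(np.clip(debark_new, 0.0, 1.0))
        mean = float(config.dieback_mean(debark_new))
        dieback = float(np.clip(mean + rng.normal(0.0, config.dieback_noise_sd), 0.0, 1.0))

        d = s.diameter_m
        u = rng.random()
        if u < config.interval_encounter_prob * pollard_probability(d, config.pollard_coef):
            outcome = "pollarded"
        elif debark_new > config.windthrow_threshold and rng.random() < config.windthrow_prob:
            outcome = "fallen"
        elif rng.random() < config.other_loss_prob:
            outcome = "other"
        else:
            outcome = "standing"
        truth_rows.append(
            {
                "tree_id": s.plant_id,
                "stem_id": s.stem_id,
                "circumference_cm": s.circumference_cm,
                "outcome": outcome,
            }
        )
        if outcome == "other":
            lost_stem_keys.add((s.plant_id, s.stem_id))
            continue
        new_total = min(debark_new, 1.0)
        old_part = min(s.debark_old_fraction, new_total)
        out_stems.append(
            replace(
                s,
                impact_new={
                    "standing": s.impact_new,
                    "pollarded": "broken",
                    "fallen": "pushed_over",
                }[outcome],
                debark_old_fraction=round(old_part, 4),
                debark_new_fraction=round(new_total - old_part, 4),
                dieback_fraction=round(dieback, 4),
            )
        )

    stems_left = {}
    for s in out_stems:
        stems_left.setdefault(s.plant_id, []).append(s)
    out_plants = []
    for p in survey.plants:
        if p.plant_id in emergent_ids and not stems_left.get(p.plant_id):
            continue  # tree lost completely to 'other' causes
        out_plants.append(replace(p))

    # recruitment into the smallest shrub class
    rng = _stream(seed, "resurvey", survey.plot_id, "recruitment")
    area_shrub = (
        survey.design.baseline_length_m
        * survey.design.belt_width_by_stratum["common_shrub"]
        / 1e4
    )
    n_rec = rng.poisson(config.recruitment_per_ha_per_yr * years * area_shrub)
    for i in range(n_rec):
        h = round(float(rng.uniform(0.1, 0.5)), 1)
        d1, d2, depth = _crown(h, rng, shrub=True)
        out_plants.append(
            PlantRecord(
                plant_id=f"{survey.plot_id}-r{i:04d}",
                species_code="colmop",
                growth_form="shrub",
                height_m=h,
                crown_d1_m=d1,
                crown_d2_m=d2,
                crown_depth_m=depth,
                shape_code=int(rng.integers(1, 8)),
                sampled_stratum="common_shrub",
            )
        )

    out = PlotSurvey(
        plot_id=survey.plot_id,
        reserve=survey.reserve,
        year=survey.year + years,
        regime=survey.regime,
        design=survey.design,
        plants=out_plants,
        stems=[s for s in out_stems if (s.plant_id, s.stem_id) not in lost_stem_keys],
    )
    out.validate()
    truth = pd.DataFrame(
        truth_rows, columns=["tree_id", "stem_id", "circumference_cm", "outcome"]
    )
    return out, truth


def generate_fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    configs: Sequence[RegimeConfig] | None = None,
    resurvey_years: int = 8,
) -> dict:
    """Write the canonical survey fixture set and a manifest.

    Produces impacted surveys for each regime (one directory per plot), a
    paired first-survey/resurvey set with a per-plot emergent-fate truth
    table for the high-density regime, and ``manifest.json`` listing every
    file together with the seed and configuration digests.  Running twice
    with the same seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if configs is None:
        configs = [regime_config(label, seed=seed) for label in REGIME_LABELS]

    manifest: dict = {"seed": seed, "resurvey_years": resurvey_years, "regimes": {}}
    for config in configs:
        entry = {"config": config.to_dict(), "plots": []}
        for i in range(config.n_plots):
            plot_id = f"{config.label}_p{i + 1:02d}"
            base = simulate_plot(config, plot_id)
            impacted = apply_elephant_impacts(base, config)
            plot_dir = out_dir / plot_id
            write_survey(impacted, plot_dir)
            files = [f"{plot_id}/plants.csv", f"{plot_id}/stems.csv", f"{plot_id}/plot.json"]
            plot_entry = {"plot_id": plot_id, "files": files}
            if config.label == "high":
                later, truth = simulate_resurvey(impacted, config, years=resurvey_years)
                re_dir = out_dir / f"{plot_id}_resurvey"
                write_survey(later, re_dir)
                truth_path = out_dir / f"{plot_id}_emergent_truth.csv"
                truth.to_csv(truth_path, index=False)
                plot_entry["resurvey_files"] = [
                    f"{plot_id}_resurvey/plants.csv",
                    f"{plot_id}_resurvey/stems.csv",
                    f"{plot_id}_resurvey/plot.json",
                ]
                plot_entry["truth_file"] = truth_path.name
            entry["plots"].append(plot_entry)
        manifest["regimes"][config.label] = entry

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# Flat datasets for fit-recovery studies
# ---------------------------------------------------------------------------


def simulate_pollarding_dataset(
    n: int,
    seed: int,
    coef: tuple[float, float] = DEFAULT_POLLARD_COEF,
    diameter_range: tuple[float, float] = (0.07, 0.8),
) -> pd.DataFrame:
    """Stem diameters (m) with Bernoulli pollarding outcomes from the logit.

    Diameters are uniform over ``diameter_range``, which by default covers
    main stems above the 20 cm circumference recording threshold through
    emergent-sized stems.
    """
    rng = _stream(seed, "pollard-dataset")
    d = rng.uniform(*diameter_range, size=n)
    p = pollard_probability(d, coef)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"diameter_m": d, "pollarded": y})


def simulate_dieback_dataset(
    n: int,
    seed: int,
    config: RegimeConfig | None = None,
    noise_sd: float = 0.05,
    x_max: float = 100.0,
) -> pd.DataFrame:
    """Canopy-dieback fractions against percent circumference debarked."""
    config = config or regime_config("high")
    rng = _stream(seed, "dieback-dataset")
    x = rng.uniform(0.0, x_max, size=n)
    frac = x / 100.0 if config.dieback_x_scale == "percent" else x
    y = np.asarray(config.dieback_mean(frac)) + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"debark_pct": x, "dieback_fraction": y})


def simulate_debark_progression_dataset(
    n: int, seed: int, config: RegimeConfig | None = None
) -> pd.DataFrame:
    """Paired debark fractions (first survey, resurvey) from the linear law."""
    config = config or regime_config("high")
    rng = _stream(seed, "debark-dataset")
    x = rng.uniform(0.0, 0.6, size=n)
    y = config.debark_slope * x + config.debark_intercept
    y = np.clip(y + rng.normal(0.0, config.debark_resid_sd, size=n), 0.0, 1.0)
    return pd.DataFrame({"debark_first": x, "debark_resurvey": y})


def simulate_height_diameter_dataset(
    n: int, seed: int, config: RegimeConfig | None = None, noise_sd: float | None = None
) -> pd.DataFrame:
    """Tree heights (m) against main-stem diameter (m) from the allometry."""
    config = config or regime_config("high")
    if noise_sd is None:
        noise_sd = 1.0
    rng = _stream(seed, "allometry-dataset")
    d = rng.uniform(0.07, 1.2, size=n)
    h = config.allometry_A / (1.0 + np.exp(-config.allometry_k * (d - config.allometry_x0)))
    h = h + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"diameter_m": d, "height_m": h})
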