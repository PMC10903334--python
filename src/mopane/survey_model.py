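"""Domain types and delimited-file I/O for nested belt-transect woodland surveys.

A plot is sampled with a *nested belt transect*: a fixed-length baseline
(50 m in the default design) carries progressively wider belts so that
rarer, larger plants are counted over larger areas than common shrubs.
Tall emergent trees may additionally be censused over a fixed area around
the plot.  Each live plant carries its height, two perpendicular canopy
diameters, canopy depth and one of seven canopy shape codes; tree stems
additionally carry circumference, elephant-impact categories (old and new),
debarking fractions and, for emergent trees, a canopy-dieback fraction.

On disk a survey is a directory holding ``plants.csv``, ``stems.csv`` and a
``plot.json`` sidecar with the transect design and plot metadata.  All
parsing is locale-independent (decimal point, UTF-8, header row).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "STRATA",
    "AGENTS",
    "AGES",
    "IMPACT_CATEGORIES",
    "GROWTH_FORMS",
    "SurveyValidationError",
    "TransectDesign",
    "DamageEntry",
    "PlantRecord",
    "StemRecord",
    "PlotSurvey",
    "sampled_area_ha",
    "read_survey",
    "write_survey",
]

#: Sampling strata in order of (non-decreasing) belt width.
STRATA = ("common_shrub", "rare_shrub", "tree", "emergent")

#: Recognised damage agents.  Fire is recorded but reported separately.
AGENTS = ("elephant", "unknown", "fire")

#: Age of utilisation: new (< 8 months, exposed wood still pale) vs old.
AGES = ("old", "new")

#: Stem impact categories, ordered from least to most severe.
IMPACT_CATEGORIES = ("none", "branches", "broken", "pushed_over", "uprooted")

GROWTH_FORMS = ("shrub", "tree")

#: Species treated as shrubs at any height because they are multi-stemmed.
DEFAULT_MULTISTEM_SPECIES = frozenset({"captom", "capparis"})

_TOL = 1e-9


class SurveyValidationError(ValueError):
    """Raised when survey records violate their invariants.

    ``messages`` holds one row-addressed message per offending record.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class TransectDesign:
    """Nested belt-transect geometry.

    Belt widths must be non-decreasing from the common-shrub stratum through
    the rare-shrub stratum to the tree stratum.  ``emergent_census_area_ha``
    is the area of the extra emergent-tree census; ``None`` means the census
    was unbounded and emergent densities cannot be computed.
    """

    baseline_length_m: float = 50.0
    belt_width_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {"common_shrub": 2.0, "rare_shrub": 5.0, "tree": 20.0}
    )
    emergent_census_area_ha: float | None = 1.0

    def __post_init__(self):
        if self.baseline_length_m <= 0:
            raise ValueError("baseline_length_m must be > 0")
        widths = dict(self.belt_width_by_stratum)
        for stratum, w in widths.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            if w <= 0:
                raise ValueError(f"belt width for {stratum!r} must be > 0")
        order = [s for s in ("common_shrub", "rare_shrub", "tree") if s in widths]
        for a, b in zip(order, order[1:]):
            if widths[a] > widths[b] + _TOL:
                raise ValueError(
                    f"belt widths must be non-decreasing: {a}={widths[a]} > {b}={widths[b]}"
                )
        if self.emergent_census_area_ha is not None and self.emergent_census_area_ha <= 0:
            raise ValueError("emergent_census_area_ha must be > 0 or None")

    def to_dict(self) -> dict:
        return {
            "baseline_length_m": self.baseline_length_m,
            "belt_width_by_stratum": dict(self.belt_width_by_stratum),
            "emergent_census_area_ha": self.emergent_census_area_ha,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransectDesign":
        return cls(
            baseline_length_m=float(d.get("baseline_length_m", 50.0)),
            belt_width_by_stratum={k: float(v) for k, v in d["belt_width_by_stratum"].items()},
            emergent_census_area_ha=(
                None
                if d.get("emergent_census_area_ha") is None
                else float(d["emergent_census_area_ha"])
            ),
        )


def sampled_area_ha(design: TransectDesign, stratum: str) -> float:
    """Area in hectares over which plants of ``stratum`` were sampled.

    For belt strata this is ``baseline_length × belt_width / 10,000``; for
    the emergent census it is the configured census area.
    """
    if stratum == "emergent":
        if design.emergent_census_area_ha is None:
            raise ValueError("emergent census area is unbounded; density undefined")
        return design.emergent_census_area_ha
    try:
        width = design.belt_width_by_stratum[stratum]
    except KeyError:
        raise ValueError(f"stratum {stratum!r} unknown to this design") from None
    return design.baseline_length_m * width / 10_000.0


@dataclass(frozen=True)
class DamageEntry:
    """One scored canopy-volume loss: (agent, age) -> ordinal loss class."""

    agent: str
    age: str
    loss_class: int  # index into a DamageScale

    def __post_init__(self):
        if self.agent not in AGENTS:
            raise ValueError(f"unknown agent {self.agent!r}")
        if self.age not in AGES:
            raise ValueError(f"unknown age {self.age!r}")
        if self.loss_class < 0:
            raise ValueError("loss_class must be a non-negative class index")


@dataclass
class PlantRecord:
    """One shrub or tree as measured on a plot visit."""

    plant_id: str
    species_code: str
    growth_form: str
    height_m: float
    crown_d1_m: float
    crown_d2_m: float
    crown_depth_m: float
    shape_code: int
    alive: bool = True
    sampled_stratum: str = "common_shrub"
    damage_entries: tuple[DamageEntry, ...] = ()

    def __post_init__(self):
        errs = self._invariant_errors()
        if errs:
            raise ValueError("; ".join(errs))

    def _invariant_errors(self) -> list[str]:
        errs = []
        if self.growth_form not in GROWTH_FORMS:
            errs.append(f"growth_form must be one of {GROWTH_FORMS}")
        if self.alive and not self.height_m > 0:
            errs.append("live plant must have height > 0")
        if self.height_m < 0:
            errs.append("height must be >= 0")
        if self.crown_d1_m < 0 or self.crown_d2_m < 0 or self.crown_depth_m < 0:
            errs.append("crown dimensions must be >= 0")
        if self.crown_d2_m > self.crown_d1_m + _TOL:
            errs.append(f"crown_d2 ({self.crown_d2_m}) exceeds crown_d1 ({self.crown_d1_m})")
        if self.crown_depth_m > self.height_m + _TOL:
            errs.append(f"crown_depth ({self.crown_depth_m}) exceeds height ({self.height_m})")
        if self.shape_code not in range(1, 8):
            errs.append(f"shape_code must be in 1..7, got {self.shape_code}")
        if self.sampled_stratum not in STRATA:
            errs.append(f"unknown sampled_stratum {self.sampled_stratum!r}")
        seen = set()
        for e in self.damage_entries:
            key = (e.agent, e.age)
            if key in seen:
                errs.append(f"duplicate damage entry for {key}")
            seen.add(key)
        return errs

    def loss_class(self, agent: str, age: str) -> int | None:
        """The recorded loss class for (agent, age), or None if unscored."""
        for e in self.damage_entries:
            if e.agent == agent and e.age == age:
                return e.loss_class
        return None


@dataclass
class StemRecord:
    """One tree stem: circumference above the basal swelling plus impacts."""

    plant_id: str
    stem_id: str
    circumference_cm: float
    impact_old: str = "none"
    impact_new: str = "none"
    coppicing: bool = False
    debark_old_fraction: float = 0.0
    debark_new_fraction: float = 0.0
    debark_old_agent: str = "elephant"
    debark_new_agent: str = "elephant"
    dieback_fraction: float | None = None  # emergent trees only

    def __post_init__(self):
        errs = self._invariant_errors()
        if errs:
            raise ValueError("; ".join(errs))

    def _invariant_errors(self) -> list[str]:
        errs = []
        if not self.circumference_cm > 0:
            errs.append("circumference_cm must be > 0")
        for name in ("impact_old", "impact_new"):
            if getattr(self, name) not in IMPACT_CATEGORIES:
                errs.append(f"{name} must be one of {IMPACT_CATEGORIES}")
        for name in ("debark_old_fraction", "debark_new_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must lie in [0, 1]")
        if self.debark_old_fraction + self.debark_new_fraction > 1.0 + _TOL:
            errs.append("debark_old_fraction + debark_new_fraction must be <= 1")
        for name in ("debark_old_agent", "debark_new_agent"):
            if getattr(self, name) not in ("elephant", "unknown"):
                errs.append(f"{name} must be 'elephant' or 'unknown'")
        if self.dieback_fraction is not None and not 0.0 <= self.dieback_fraction <= 1.0:
            errs.append("dieback_fraction must lie in [0, 1]")
        return errs

    @property
    def diameter_m(self) -> float:
        """Stem diameter in metres, assuming a circular cross-section."""
        return self.circumference_cm / (100.0 * math.pi)

    @property
    def cross_section_m2(self) -> float:
        """Cross-sectional area in m², the weight for canopy-loss averaging."""
        r = self.circumference_cm / (2.0 * math.pi) / 100.0
        return math.pi * r * r


@dataclass
class PlotSurvey:
    """One dated visit to a plot: design, plant records and stem records."""

    plot_id: str
    reserve: str
    year: int
    regime: str  # low | intermediate | high elephant density
    design: TransectDesign
    plants: list[PlantRecord] = field(default_factory=list)
    stems: list[StemRecord] = field(default_factory=list)

    def validate(self) -> None:
        """Cross-record invariants; raises SurveyValidationError."""
        errs = []
        by_id: dict[str, PlantRecord] = {}
        for p in self.plants:
            if p.plant_id in by_id:
                errs.append(f"duplicate plant_id {p.plant_id!r}")
            by_id[p.plant_id] = p
        seen_stems = set()
        for s in self.stems:
            key = (s.plant_id, s.stem_id)
            if key in seen_stems:
                errs.append(f"duplicate stem {key}")
            seen_stems.add(key)
            plant = by_id.get(s.plant_id)
            if plant is None:
                errs.append(f"stem {s.stem_id!r} references missing plant {s.plant_id!r}")
            elif plant.growth_form != "tree":
                errs.append(f"stem {s.stem_id!r} attached to non-tree plant {s.plant_id!r}")
        if errs:
            raise SurveyValidationError(errs)

    def plants_by_form(self, growth_form: str, alive: bool | None = True) -> list[PlantRecord]:
        out = []
        for p in self.plants:
            if p.growth_form != growth_form:
                continue
            if alive is not None and p.alive is not alive:
                continue
            out.append(p)
        return out

    def stems_of(self, plant_id: str) -> list[StemRecord]:
        return [s for s in self.stems if s.plant_id == plant_id]

    def plant(self, plant_id: str) -> PlantRecord:
        for p in self.plants:
            if p.plant_id == plant_id:
                return p
        raise KeyError(plant_id)


# ---------------------------------------------------------------------------
# Canonical CSV schema
# ---------------------------------------------------------------------------

PLANT_COLUMNS = [
    "plant_id",
    "species_code",
    "growth_form",
    "height_m",
    "crown_d1_m",
    "crown_d2_m",
    "crown_depth_m",
    "shape_code",
    "alive",
    "sampled_stratum",
]
DAMAGE_COLUMNS = [f"damage_{agent}_{age}" for agent in AGENTS for age in AGES]

STEM_COLUMNS = [
    "plant_id",
    "stem_id",
    "circumference_cm",
    "impact_old",
    "impact_new",
    "coppicing",
    "debark_old_fraction",
    "debark_new_fraction",
    "debark_old_agent",
    "debark_new_agent",
    "dieback_fraction",
]


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


def _infer_growth_form(species: str, height: float, multistem: Iterable[str]) -> str:
    if any(str(species).lower().startswith(m) for m in multistem):
        return "shrub"
    return "shrub" if height <= 3.0 else "tree"


def read_survey(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    scale=None,
    multistem_species: Iterable[str] = DEFAULT_MULTISTEM_SPECIES,
) -> PlotSurvey:
    """Read a survey directory (plants.csv, stems.csv, plot.json).

    ``columns`` maps canonical column names to the names used in the file,
    for ingesting heterogeneous raw tables.  Rows violating record
    invariants are rejected collectively with row-addressed messages.
    ``scale`` (a :class:`mopane.damage_metrics.DamageScale`) is used to
    translate loss-class labels; the default nine-class scale is used when
    omitted.  If the growth_form column is absent it is inferred from the
    shrub definition: height <= 3 m, or a multi-stemmed species at any
    height.
    """
    from .damage_metrics import WALKER_SCALE

    scale = scale or WALKER_SCALE
    path = Path(path)
    meta_path = path / "plot.json"
    plants_path = path / "plants.csv"
    stems_path = path / "stems.csv"
    if not plants_path.exists():
        raise FileNotFoundError(plants_path)
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    design = TransectDesign.from_dict(meta["design"])

    rename = {v: k for k, v in (columns or {}).items()}
    pdf = pd.read_csv(plants_path, dtype=str, keep_default_na=False).rename(columns=rename)
    missing = [c for c in ("plant_id", "height_m", "crown_d1_m", "crown_d2_m") if c not in pdf.columns]
    if missing:
        raise SurveyValidationError([f"plants.csv: missing required column(s) {missing}"])

    errors: list[str] = []
    plants: list[PlantRecord] = []
    for i, row in enumerate(pdf.to_dict("records"), start=1):
        try:
            height = float(row["height_m"])
            species = row.get("species_code", "unknown")
            form = row.get("growth_form", "") or _infer_growth_form(
                species, height, multistem_species
            )
            entries = []
            for agent in AGENTS:
                for age in AGES:
                    label = str(row.get(f"damage_{agent}_{age}", "")).strip()
                    if label:
                        entries.append(
                            DamageEntry(agent=agent, age=age, loss_class=scale.index_of(label))
                        )
            plants.append(
                PlantRecord(
                    plant_id=str(row["plant_id"]),
                    species_code=str(species),
                    growth_form=form,
                    height_m=height,
                    crown_d1_m=float(row["crown_d1_m"]),
                    crown_d2_m=float(row["crown_d2_m"]),
                    crown_depth_m=float(row.get("crown_depth_m", 0) or 0),
                    shape_code=int(float(row.get("shape_code", 1) or 1)),
                    alive=_parse_bool(row.get("alive", True)),
                    sampled_stratum=str(row.get("sampled_stratum", "common_shrub")),
                    damage_entries=tuple(entries),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"plants.csv row {i}: {exc}")

    stems: list[StemRecord] = []
    if stems_path.exists():
        sdf = pd.read_csv(stems_path, dtype=str, keep_default_na=False).rename(columns=rename)
        for i, row in enumerate(sdf.to_dict("records"), start=1):
            try:
                dieback = str(row.get("dieback_fraction", "")).strip()
                stems.append(
                    StemRecord(
                        plant_id=str(row["plant_id"]),
                        stem_id=str(row["stem_id"]),
                        circumference_cm=float(row["circumference_cm"]),
                        impact_old=str(row.get("impact_old", "none") or "none"),
                        impact_new=str(row.get("impact_new", "none") or "none"),
                        coppicing=_parse_bool(row.get("coppicing", False)),
                        debark_old_fraction=float(row.get("debark_old_fraction", 0) or 0),
                        debark_new_fraction=float(row.get("debark_new_fraction", 0) or 0),
                        debark_old_agent=str(row.get("debark_old_agent", "elephant") or "elephant"),
                        debark_new_agent=str(row.get("debark_new_agent", "elephant") or "elephant"),
                        dieback_fraction=float(dieback) if dieback else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"stems.csv row {i}: {exc}")

    if errors:
        raise SurveyValidationError(errors)

    survey = PlotSurvey(
        plot_id=str(meta["plot_id"]),
        reserve=str(meta.get("reserve", "")),
        year=int(meta["year"]),
        regime=str(meta.get("regime", "")),
        design=design,
        plants=plants,
        stems=stems,
    )
    survey.validate()
    return survey


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # shortest exact round-trip representation
    return str(v)


def write_survey(survey: PlotSurvey, path: str | Path, scale=None) -> Path:
    """Write a survey to a directory in the canonical schema.

    Re-reading the directory with :func:`read_survey` yields an equivalent
    survey, field for field.
    """
    from .damage_metrics import WALKER_SCALE

    scale = scale or WALKER_SCALE
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    survey.validate()

    prow = []
    for p in survey.plants:
        row = {
            "plant_id": p.plant_id,
            "species_code": p.species_code,
            "growth_form": p.growth_form,
            "height_m": _fmt(p.height_m),
            "crown_d1_m": _fmt(p.crown_d1_m),
            "crown_d2_m": _fmt(p.crown_d2_m),
            "crown_depth_m": _fmt(p.crown_depth_m),
            "shape_code": p.shape_code,
            "alive": _fmt(p.alive),
            "sampled_stratum": p.sampled_stratum,
        }
        for col in DAMAGE_COLUMNS:
            row[col] = ""
        for e in p.damage_entries:
            row[f"damage_{e.agent}_{e.age}"] = scale.label(e.loss_class)
        prow.append(row)
    pd.DataFrame(prow, columns=PLANT_COLUMNS + DAMAGE_COLUMNS).to_csv(
        path / "plants.csv", index=False
    )

    srow = []
    for s in survey.stems:
        srow.append(
            {
                "plant_id": s.plant_id,
                "stem_id": s.stem_id,
                "circumference_cm": _fmt(s.circumference_cm),
                "impact_old": s.impact_old,
                "impact_new": s.impact_new,
                "coppicing": _fmt(s.coppicing),
                "debark_old_fraction": _fmt(s.debark_old_fraction),
                "debark_new_fraction": _fmt(s.debark_new_fraction),
                "debark_old_agent": s.debark_old_agent,
                "debark_new_agent": s.debark_new_agent,
                "dieback_fraction": _fmt(s.dieback_fraction),
            }
        )
    pd.DataFrame(srow, columns=STEM_COLUMNS).to_csv(path / "stems.csv", index=False)

    meta = {
        "plot_id": survey.plot_id,
        "reserve": survey.reserve,
        "year": survey.year,
        "regime": survey.regime,
        "design": survey.design.to_dict(),
    }
    (path / "plot.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path
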