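"""Crown volume and its apportionment into vertical height layers.

Each crown is modelled as a solid with elliptical horizontal cross-sections.
The two measured canopy diameters ``d1 >= d2`` fix the maximal semi-axes
``r1 = d1/2`` and ``r2 = d2/2``; the canopy depth fixes the vertical extent
from crown base to crown top; and one of seven shape archetypes fixes how
the cross-section scales with relative height ``t`` in ``[0, 1]`` (0 = crown
base, 1 = crown top) through a radius profile ``f(t)``:

=====  ====================  ==================================  ==========
code   archetype             profile f(t)                        f² integral
=====  ====================  ==================================  ==========
1      spheroid              2*sqrt(t(1-t))                      2/3
2      cylinder              1                                   1
3      cone, point down      t                                   1/3
4      cone, point up        1 - t                               1/3
5      dome (rounded top)    sqrt(1 - t²)                        2/3
6      dome (rounded base)   sqrt(1 - (1-t)²)                    2/3
7      flattened spheroid    2*sqrt(t(1-t)) with depth < d2      2/3
=====  ====================  ==================================  ==========

The volume between two absolute heights is then the exact integral

    V(z_lo, z_hi) = pi * r1 * r2 * depth * (F(t_hi) - F(t_lo)),

with ``F`` the closed-form antiderivative of ``f²`` tabulated below.  Code 7
(the oblate "lens") shares the spheroidal profile; it differs only in that
its depth is smaller than its diameters, which the formula handles without a
special case.  The mapping of code integers to archetypes is configurable
because recording protocols label the outlines, not the formulas.

Summing the slab volumes over any partition of the vertical axis recovers
the total crown volume exactly; this conservation property is what makes
per-height-layer canopy-volume profiles internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_model import PlantRecord, TransectDesign, sampled_area_ha

__all__ = [
    "SHAPE_ARCHETYPES",
    "CrownDimensions",
    "HeightLayerScheme",
    "FOUR_LAYER_SCHEME",
    "FIVE_LAYER_SCHEME",
    "crown_volume",
    "slab_volume",
    "layer_profile",
]


def _F_spheroid(t):
    # f(t)^2 = 4 t (1 - t)
    return 2.0 * t**2 - (4.0 / 3.0) * t**3


def _F_cylinder(t):
    return t


def _F_cone_down(t):
    return t**3 / 3.0


def _F_cone_up(t):
    return (1.0 - (1.0 - t) ** 3) / 3.0


def _F_dome_top(t):
    return t - t**3 / 3.0


def _F_dome_base(t):
    return t**2 - t**3 / 3.0


#: code -> (archetype name, antiderivative F of the squared radius profile)
SHAPE_ARCHETYPES: Mapping[int, tuple[str, Callable]] = {
    1: ("spheroid", _F_spheroid),
    2: ("cylinder", _F_cylinder),
    3: ("cone_point_down", _F_cone_down),
    4: ("cone_point_up", _F_cone_up),
    5: ("dome_rounded_top", _F_dome_top),
    6: ("dome_rounded_base", _F_dome_base),
    7: ("flattened_spheroid", _F_spheroid),
}


@dataclass(frozen=True)
class CrownDimensions:
    """Measured crown extents of one plant, in metres.

    ``top_height`` is the plant height; the crown base sits ``depth`` below
    it.  A recorded base below ground is clamped to 0.
    """

    d1: float
    d2: float
    depth: float
    top_height: float

    def __post_init__(self):
        if self.d2 > self.d1 + 1e-9:
            raise ValueError("d2 must not exceed d1")
        if self.depth < 0 or self.d1 < 0:
            raise ValueError("dimensions must be non-negative")

    @property
    def base_height(self) -> float:
        return max(self.top_height - self.depth, 0.0)

    @classmethod
    def of(cls, plant: PlantRecord) -> "CrownDimensions":
        return cls(
            d1=plant.crown_d1_m,
            d2=plant.crown_d2_m,
            depth=min(plant.crown_depth_m, plant.height_m),
            top_height=plant.height_m,
        )


def _profile(shape_code: int) -> Callable:
    try:
        return SHAPE_ARCHETYPES[shape_code][1]
    except KeyError:
        raise ValueError(f"unknown canopy shape code {shape_code!r}") from None


def crown_volume(shape_code: int, dims: CrownDimensions) -> float:
    """Total crown volume in m³ for a shape archetype and measured extents."""
    F = _profile(shape_code)
    r1, r2 = dims.d1 / 2.0, dims.d2 / 2.0
    span = dims.top_height - dims.base_height
    return float(np.pi * r1 * r2 * span * (F(1.0) - F(0.0)))


def slab_volume(shape_code: int, dims: CrownDimensions, z_lo: float, z_hi: float) -> float:
    """Crown volume between absolute heights ``z_lo`` and ``z_hi`` (m³).

    Zero where the interval misses the crown.  Additive over adjacent
    intervals and monotone non-decreasing in ``z_hi``.
    """
    if z_hi < z_lo:
        raise ValueError("z_hi must be >= z_lo")
    F = _profile(shape_code)
    base, top = dims.base_height, dims.top_height
    span = top - base
    if span <= 0:
        return 0.0
    lo = min(max(z_lo, base), top)
    hi = min(max(z_hi, base), top)
    t_lo = (lo - base) / span
    t_hi = (hi - base) / span
    r1, r2 = dims.d1 / 2.0, dims.d2 / 2.0
    return float(np.pi * r1 * r2 * span * (F(t_hi) - F(t_lo)))


@dataclass(frozen=True)
class HeightLayerScheme:
    """A partition of [0, inf) into height layers.

    ``boundaries`` are the interior layer edges in metres (strictly
    increasing); the last layer is open above.  Heights are recorded at
    0.1 m resolution, so contiguous printed labels like "1.1-3.0" and
    "3.1-6.0" are realised as intervals (1.0, 3.0], (3.0, 6.0] on heights
    rounded to 0.1 m: an exact 3.0 m falls in the lower layer.  For slab
    apportionment of continuous crown volume the edges act as plain cut
    points.
    """

    boundaries: tuple[float, ...]

    def __post_init__(self):
        b = self.boundaries
        if len(b) < 1 or any(x2 <= x1 for x1, x2 in zip(b, b[1:])) or b[0] <= 0:
            raise ValueError("boundaries must be strictly increasing and positive")

    @property
    def n_layers(self) -> int:
        return len(self.boundaries) + 1

    def edges(self) -> list[tuple[float, float]]:
        lows = (0.0,) + self.boundaries
        highs = self.boundaries + (np.inf,)
        return list(zip(lows, highs))

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in self.edges():
            if np.isinf(hi):
                out.append(f">{lo:g}")
            elif lo == 0.0:
                out.append(f"0-{hi:g}")
            else:
                out.append(f"{lo + 0.1:g}-{hi:g}")
        return out

    def layer_index(self, height_m: float) -> int:
        """Layer holding a plant of this total height (0.1 m convention)."""
        h = round(height_m, 1)
        for i, (lo, hi) in enumerate(self.edges()):
            if (lo == 0.0 and h <= hi) or lo < h <= hi:
                return i
        return self.n_layers - 1


#: 0-1.0, 1.1-3.0, 3.1-6.0, >6.0 m
FOUR_LAYER_SCHEME = HeightLayerScheme((1.0, 3.0, 6.0))
#: 0-1.0, 1.1-3.0, 3.1-6.0, 6.1-10.0, >10.0 m
FIVE_LAYER_SCHEME = HeightLayerScheme((1.0, 3.0, 6.0, 10.0))


def layer_profile(
    plants: Iterable[PlantRecord],
    scheme: HeightLayerScheme,
    design: TransectDesign,
    live_only: bool = True,
) -> pd.Series:
    """Per-layer canopy-volume density (m³ ha⁻¹) for a set of plants.

    Each plant's crown volume is split into the scheme's layers with
    :func:`slab_volume` and scaled by the sampled area of the plant's
    stratum, then summed per layer.
    """
    totals = np.zeros(scheme.n_layers)
    for plant in plants:
        if live_only and not plant.alive:
            continue
        dims = CrownDimensions.of(plant)
        area = sampled_area_ha(design, plant.sampled_stratum)
        for i, (lo, hi) in enumerate(scheme.edges()):
            hi_eff = dims.top_height if np.isinf(hi) else hi
            if hi_eff <= lo:
                continue
            totals[i] += slab_volume(plant.shape_code, dims, lo, hi_eff) / area
    return pd.Series(totals, index=scheme.labels, name="volume_m3_per_ha")
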