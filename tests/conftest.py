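import numpy as np
import pytest

from mopane.survey_model import (
    DamageEntry,
    PlantRecord,
    PlotSurvey,
    StemRecord,
    TransectDesign,
)

#: loss classes: 0->0%, 1->3%, 2->8%, 3->18%, 4->38%, 5->63%, 6->83%, 7->95%, 8->100%


@pytest.fixture
def design():
    return TransectDesign(
        baseline_length_m=50.0,
        belt_width_by_stratum={"common_shrub": 2.0, "rare_shrub": 5.0, "tree": 20.0},
        emergent_census_area_ha=1.0,
    )


@pytest.fixture
def hand_survey(design):
    """Small plot with hand-computable volumes, densities and damage.

    Areas: common_shrub 0.01 ha, tree 0.1 ha, emergent 1 ha.
    """
    plants = [
        # cylinder shrub, V = pi*1*1*1 = pi; old elephant loss class 4 (38%)
        PlantRecord("s1", "colmop", "shrub", 2.0, 2.0, 2.0, 1.0, shape_code=2,
                    sampled_stratum="common_shrub",
                    damage_entries=(DamageEntry("elephant", "old", 4),)),
        # cylinder shrub, V = pi*0.5*0.5*1 = pi/4; undamaged
        PlantRecord("s2", "colmop", "shrub", 1.0, 1.0, 1.0, 1.0, shape_code=2,
                    sampled_stratum="common_shrub"),
        # cylinder tree, V = pi*1*1*2 = 2*pi; old elephant class 1 (3%)
        PlantRecord("t1", "colmop", "tree", 4.0, 2.0, 2.0, 2.0, shape_code=2,
                    sampled_stratum="tree",
                    damage_entries=(DamageEntry("elephant", "old", 1),)),
        # spheroid tree, V = (2/3)*pi*2*2*4 = 32*pi/3
        PlantRecord("t2", "colmop", "tree", 8.0, 4.0, 4.0, 4.0, shape_code=1,
                    sampled_stratum="tree"),
        # emergent cylinder tree, V = pi*1.5*1.5*6 = 13.5*pi
        PlantRecord("t3", "colmop", "tree", 12.0, 3.0, 3.0, 6.0, shape_code=2,
                    sampled_stratum="emergent"),
        # dead tree, no crown
        PlantRecord("t4", "colmop", "tree", 5.0, 0.0, 0.0, 0.0, shape_code=2,
                    alive=False, sampled_stratum="tree"),
    ]
    stems = [
        StemRecord("t1", "t1-a", circumference_cm=100.0),
        StemRecord("t2", "t2-a", circumference_cm=200.0, debark_old_fraction=0.5),
        StemRecord("t3", "t3-a", circumference_cm=300.0, debark_old_fraction=0.2),
    ]
    s = PlotSurvey(
        plot_id="hand", reserve="MWR", year=2014, regime="low",
        design=design, plants=plants, stems=stems,
    )
    s.validate()
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(20240226)
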