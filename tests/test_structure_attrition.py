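import math

import numpy as np
import pandas as pd
import pytest

from mopane.structure_attrition import (
    DEFAULT_HEIGHT_BINS,
    annual_attrition_rate,
    classify_emergent_fates,
    derive_emergent_outcomes,
    height_distribution,
    pollard_probability,
    stem_impact_table,
    structure_metrics,
)
from mopane.survey_model import PlantRecord, PlotSurvey, StemRecord


def recover_composition(n_total, printed_pcts, decimals=1):
    """Brute-force the unique integer composition of ``n_total`` whose
    percentages round to the printed values (``decimals`` may vary per value)."""
    if isinstance(decimals, int):
        decimals = [decimals] * len(printed_pcts)
    candidates = []
    for pct, dec in zip(printed_pcts, decimals):
        lo, hi = pct - 0.5 * 10**-dec, pct + 0.5 * 10**-dec
        cs = [c for c in range(n_total + 1) if lo <= 100.0 * c / n_total < hi]
        assert cs, f"no count of {n_total} rounds to {pct}"
        candidates.append(cs)
    solutions = [
        combo
        for combo in __import__("itertools").product(*candidates)
        if sum(combo) == n_total
    ]
    assert len(solutions) == 1, f"composition not unique: {solutions}"
    return solutions[0]


class TestStructureMetrics:
    def test_hand_survey_metrics(self, hand_survey):
        m = structure_metrics(hand_survey)
        assert m.shrub_canopy_volume == pytest.approx((math.pi + math.pi / 4) / 0.01)
        assert m.tree_canopy_volume == pytest.approx(
            2 * math.pi / 0.1 + (32 * math.pi / 3) / 0.1 + 13.5 * math.pi / 1.0
        )
        assert m.total_canopy_volume == pytest.approx(
            m.shrub_canopy_volume + m.tree_canopy_volume
        )
        assert m.shrub_density == pytest.approx(200.0)
        assert m.live_tree_density == pytest.approx(21.0)
        assert m.live_standing_tree_density == pytest.approx(21.0)
        assert m.live_prostrate_tree_density == 0.0
        assert m.density_lt10m == pytest.approx(20.0)
        assert m.density_gt10m == pytest.approx(1.0)
        assert m.dead_tree_density == pytest.approx(10.0)
        assert m.pollarded_stem_density == 0.0
        assert m.mean_tree_height == pytest.approx((4.0 + 8.0 + 12.0) / 3)
        assert m.shrub_species_richness == 1
        assert m.tree_species_richness == 1

    def test_density_partition_invariant(self, hand_survey):
        m = structure_metrics(hand_survey)
        assert m.density_lt10m + m.density_gt10m == pytest.approx(m.live_tree_density)

    def test_no_trees(self, design):
        plants = [PlantRecord("s", "colmop", "shrub", 1.0, 1.0, 1.0, 0.5, shape_code=2,
                              sampled_stratum="common_shrub")]
        m = structure_metrics(PlotSurvey("p", "MWR", 2001, "low", design, plants, []))
        assert m.live_tree_density == 0.0
        assert m.tree_canopy_volume == 0.0
        assert m.mean_tree_height is None

    def test_halving_by_doubling_widths(self, hand_survey, design):
        import dataclasses

        wide = dataclasses.replace(
            hand_survey,
            design=dataclasses.replace(
                design,
                belt_width_by_stratum={
                    k: 2 * v for k, v in design.belt_width_by_stratum.items()
                },
                emergent_census_area_ha=2.0,
            ),
        )
        m0 = structure_metrics(hand_survey)
        m1 = structure_metrics(wide)
        assert m1.live_tree_density == pytest.approx(m0.live_tree_density / 2)
        assert m1.shrub_density == pytest.approx(m0.shrub_density / 2)


def _tree(i, h):
    return PlantRecord(f"t{i}", "colmop", "tree", float(h), 1.0, 1.0, 0.5,
                       shape_code=2, sampled_stratum="tree")


class TestHeightDistribution:
    def test_one_tree_per_bin(self):
        trees = [_tree(i, h) for i, h in enumerate((4, 7, 12, 20))]
        assert height_distribution(trees).tolist() == [1, 1, 1, 1]

    def test_boundary_six_falls_in_first_bin(self):
        assert height_distribution([_tree(0, 6.0)]).tolist() == [1, 0, 0, 0]
        assert height_distribution([_tree(0, 6.1)]).tolist() == [0, 1, 0, 0]

    def test_counts_partition_population(self, rng):
        trees = [_tree(i, round(rng.uniform(3.1, 25.0), 1)) for i in range(200)]
        assert height_distribution(trees).sum() == 200

    def test_height_below_first_edge_rejected(self):
        with pytest.raises(ValueError, match="first bin"):
            height_distribution([_tree(0, 2.0)])


class TestStemImpactTable:
    def test_one_stem_per_category(self):
        stems = [
            StemRecord("t", f"s{i}", 100.0, impact_old=c)
            for i, c in enumerate(("none", "branches", "broken", "pushed_over"))
        ]
        tab = stem_impact_table(stems)
        assert tab["percent_old"].tolist() == [25.0, 25.0, 25.0, 25.0]
        assert tab["percent_new"].tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_printed_percentages_recovered_from_composition(self):
        """The old-damage composition of a 312-stem population reproducing
        10.9 / 16.3 / 65.7 / 7.1 percent is unique and sums to 100."""
        counts = recover_composition(312, (10.9, 16.3, 65.7, 7.1))
        assert counts == (34, 51, 205, 22)
        cats = ("none", "branches", "broken", "pushed_over")
        stems = [
            StemRecord("t", f"s{i}-{j}", 100.0, impact_old=c)
            for i, (c, n) in enumerate(zip(cats, counts))
            for j in range(n)
        ]
        tab = stem_impact_table(stems)
        assert [round(p, 1) for p in tab["percent_old"]] == [10.9, 16.3, 65.7, 7.1]
        assert tab["percent_old"].sum() == pytest.approx(100.0, abs=0.1)

    def test_new_damage_composition(self):
        counts = recover_composition(312, (34.9, 64.7, 0.32, 0.0), decimals=[1, 1, 2, 1])
        assert counts == (109, 202, 1, 0)

    def test_uprooted_merges_into_pushed_over(self):
        stems = [StemRecord("t", "a", 100.0, impact_old="uprooted")]
        tab = stem_impact_table(stems)
        assert tab.set_index("category")["percent_old"]["pushed_over"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one stem"):
            stem_impact_table([])


def _outcomes(rows):
    return pd.DataFrame(rows, columns=["tree_id", "stem_id", "circumference_cm", "outcome"])


class TestEmergentFates:
    def test_all_standing_is_all_intact(self):
        rows = [(f"t{i}", "a", 120.0, "standing") for i in range(5)]
        fates, summ = classify_emergent_fates(_outcomes(rows))
        assert all(f.fate == "intact" for f in fates)
        assert summ["tree_pct"]["intact"] == 100.0
        assert summ["stem_pct"]["standing"] == 100.0

    def test_printed_stem_population_percentages(self):
        """127 stems at 91 standing / 23 pollarded / 11 fallen / 2 other
        reproduce the printed 71.7 / 18.1 / 8.7 / 1.6 percent."""
        counts = recover_composition(127, (71.7, 18.1, 8.7, 1.6))
        assert counts == (91, 23, 11, 2)
        rows = []
        i = 0
        for outcome, n in zip(("standing", "pollarded", "fallen", "other"), counts):
            for _ in range(n):
                rows.append((f"t{i}", "a", 120.0, outcome))
                i += 1
        fates, summ = classify_emergent_fates(_outcomes(rows))
        got = {k: round(v, 1) for k, v in summ["stem_pct"].items()}
        assert got == {"standing": 71.7, "pollarded": 18.1, "fallen": 8.7, "other": 1.6}
        assert summ["stem_lost_pct"] == pytest.approx(28.3, abs=0.05)

    def test_two_stem_tree_losing_smaller_main_stem(self):
        rows = [("t0", "big", 150.0, "standing"), ("t0", "small", 100.0, "pollarded")]
        fates, _ = classify_emergent_fates(_outcomes(rows))
        assert fates[0].fate == "lost_main_stem"
        assert fates[0].n_main_stems == 2

    def test_losing_all_stems_is_complete_loss(self):
        rows = [("t0", "a", 150.0, "fallen"), ("t0", "b", 100.0, "pollarded")]
        fates, _ = classify_emergent_fates(_outcomes(rows))
        assert fates[0].fate == "lost_completely"

    def test_losing_only_minor_stem_stays_intact(self):
        rows = [("t0", "a", 150.0, "standing"), ("t0", "b", 60.0, "pollarded")]
        fates, _ = classify_emergent_fates(_outcomes(rows))
        assert fates[0].fate == "intact"

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown stem outcome"):
            classify_emergent_fates(_outcomes([("t0", "a", 100.0, "vanished")]))


class TestDeriveOutcomes:
    def test_matched_surveys(self, design):
        plants = [
            PlantRecord("e1", "colmop", "tree", 12.0, 3.0, 3.0, 5.0, shape_code=2,
                        sampled_stratum="emergent"),
            PlantRecord("e2", "colmop", "tree", 14.0, 3.0, 3.0, 5.0, shape_code=2,
                        sampled_stratum="emergent"),
            PlantRecord("t1", "colmop", "tree", 5.0, 2.0, 2.0, 2.0, shape_code=2,
                        sampled_stratum="tree"),
        ]
        stems14 = [
            StemRecord("e1", "a", 200.0),
            StemRecord("e2", "a", 180.0),
            StemRecord("e2", "b", 120.0),
            StemRecord("t1", "a", 60.0),
        ]
        cohort = PlotSurvey("p", "GNP", 2014, "high", design, plants, stems14)
        stems22 = [
            StemRecord("e1", "a", 200.0, impact_new="pushed_over"),
            StemRecord("e2", "a", 180.0),
            StemRecord("e2", "b", 120.0, impact_new="broken"),
            StemRecord("t1", "a", 60.0),
        ]
        later = PlotSurvey("p", "GNP", 2022, "high", design, plants, stems22)
        out = derive_emergent_outcomes(cohort, later)
        assert len(out) == 3  # t1 is not emergent
        by = out.set_index(["tree_id", "stem_id"])["outcome"]
        assert by[("e1", "a")] == "fallen"
        assert by[("e2", "a")] == "standing"
        assert by[("e2", "b")] == "pollarded"
        fates, _ = classify_emergent_fates(out)
        assert {f.tree_id: f.fate for f in fates} == {
            "e1": "lost_completely",
            "e2": "lost_main_stem",
        }


class TestAttritionRate:
    def test_printed_cohort_rate(self):
        # 89 emergent trees, 10 complete losses over 8 years -> 1.4 % / a
        assert annual_attrition_rate(89, 10, 8) == pytest.approx(1.4, abs=0.005)

    def test_no_loss_zero(self):
        assert annual_attrition_rate(100, 0, 8) == 0.0

    def test_total_loss_in_one_year(self):
        assert annual_attrition_rate(100, 100, 1) == 100.0

    def test_scale_invariance(self):
        assert annual_attrition_rate(89, 10, 8) == pytest.approx(
            annual_attrition_rate(890, 100, 8)
        )

    def test_compound_option(self):
        rate = annual_attrition_rate(89, 10, 8, compound=True)
        assert rate == pytest.approx(100 * (1 - (1 - 10 / 89) ** (1 / 8)))
        # compounding on a shrinking base needs a higher constant rate
        assert rate > annual_attrition_rate(89, 10, 8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            annual_attrition_rate(10, 11, 8)
        with pytest.raises(ValueError):
            annual_attrition_rate(10, 1, 0)


class TestPollardProbability:
    def test_even_odds_near_45cm_diameter(self):
        assert pollard_probability(0.45) == pytest.approx(0.5055, abs=5e-4)

    def test_zero_diameter(self):
        assert pollard_probability(0.0) == pytest.approx(0.9897, abs=5e-4)

    def test_large_stems_are_safe(self):
        assert pollard_probability(1.0) == pytest.approx(0.00397, abs=5e-5)
        assert pollard_probability(5.0) < 1e-15

    def test_monotone_decreasing(self):
        d = np.linspace(0, 2, 50)
        p = pollard_probability(d)
        assert np.all(np.diff(p) < 0)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            pollard_probability(-0.1)
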