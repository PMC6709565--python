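"""Derived alarm-burden metrics, reaction summaries, exceedance flags."""

import numpy as np
import pytest

from infuselog import (
    CareArea,
    Drug,
    ExceedanceCategory,
    ReactionModel,
    alarms_per_infusion,
    build_alarm_burden,
    build_cshl_table,
    build_episodes,
    first_time_reactions_by_area,
    flag_exceedance,
    mean_area_ratio,
    occlusion_start_ratio,
    round_half_up,
    sample_reaction_time,
    summarize_reactions,
    tally_cshl_counts,
    tally_event_counts,
)
from infuselog.metrics import NotApplicableError, UndefinedRatioError
from _oracles import two_pass_summary


class TestRatios:
    @pytest.mark.parametrize(
        "alarms,starts,expected",
        [(7784, 904, 8.61), (113277, 30527, 3.71), (0, 500, 0.0)],
    )
    def test_alarms_per_infusion(self, alarms, starts, expected):
        assert alarms_per_infusion(alarms, starts) == expected

    def test_zero_starts_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            alarms_per_infusion(10, 0)

    def test_unweighted_mean_of_area_ratios(self):
        assert mean_area_ratio([3.71, 4.36, 1.33, 8.61]) == 4.50
        assert mean_area_ratio([2.5, 2.5, 2.5, 2.5]) == 2.5

    def test_mean_requires_all_four_areas(self):
        with pytest.raises(ValueError):
            mean_area_ratio([1.0, 2.0, 3.0])

    def test_mean_equals_brute_force_summation(self, rng):
        ratios = [round(float(r), 2) for r in rng.uniform(0.5, 9, size=4)]
        assert mean_area_ratio(ratios) == round_half_up(sum(ratios) / 4)

    @pytest.mark.parametrize(
        "occ,starts,expected",
        [(2446, 904, 2.71), (62944, 30527, 2.06), (0, 100, 0.0)],
    )
    def test_occlusion_start_ratio(self, occ, starts, expected):
        assert occlusion_start_ratio(occ, starts) == expected

    def test_round_half_up_ties_go_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.495, 2) == 2.50


class TestAlarmBurdenFromFixture:
    def test_percent_column(self, fixture_tables):
        table = build_alarm_burden(fixture_tables)
        assert table.percent_by_type["occlusion_downstream"] == 38.32
        assert table.percent_by_type["near_end_of_infusion"] == 12.61
        assert table.percent_by_type["callback"] == 36.30

    def test_percent_column_sums_to_100(self, fixture_tables):
        table = build_alarm_burden(fixture_tables)
        assert sum(table.percent_by_type.values()) == pytest.approx(100, abs=0.05)

    def test_single_type_toy_counts(self):
        counts = {
            a: {"total_infusion_starts": 10, "callback": 10}
            for a in ("NICU", "GICU", "CICU", "PICU", "WHOLE_HOSPITAL")
        }
        table = build_alarm_burden(counts)
        assert table.percent_by_type == {"callback": 100.00}

    def test_negative_counts_rejected(self):
        counts = {"WHOLE_HOSPITAL": {"total_infusion_starts": 10, "callback": -1}}
        with pytest.raises(ValueError, match="negative"):
            build_alarm_burden(counts)

    def test_frame_keeps_na_cells_absent(self, fixture_tables):
        frame = build_alarm_burden(fixture_tables).to_frame()
        assert np.isnan(frame.loc["air_accumulation", "NICU"])
        assert frame.loc["flow_error", "GICU"] == 0


class TestCSHLTableFromFixture:
    def test_percent_of_cshl_starts(self, fixture_tables):
        table = build_cshl_table(fixture_tables)
        assert table.pct_of_cshl_starts["callback"] == 90.48
        assert table.pct_of_cshl_starts["occlusion_downstream"] == 14.16

    def test_percent_of_unit_totals(self, fixture_tables):
        table = build_cshl_table(fixture_tables)
        assert table.pct_of_unit_total["infusion_starts"] == 11.87
        assert table.pct_of_unit_total["callback"] == 14.64

    def test_rare_but_hazardous_empty_container_alarms(self, fixture_tables):
        table = build_cshl_table(fixture_tables)
        assert table.eoi_eos_pct_of_cshl_starts() == 1.7

    def test_zero_denominator_cells_absent(self):
        counts = {
            "DOBUTAMINE": {"infusion_starts": 5, "callback": 3},
        }
        table = build_cshl_table(counts, nicu_counts={"total_infusion_starts": 50})
        assert table.pct_of_unit_total["infusion_starts"] == 10.0
        assert table.pct_of_unit_total["callback"] is None  # no unit denominator


class TestSummarizeReactions:
    def test_tiny_examples(self):
        frame = summarize_reactions({CareArea.NICU: [10, 20, 30], CareArea.PICU: [7]})
        nicu = frame.loc["NICU"]
        assert (nicu["mean"], nicu["median"], nicu["max"], nicu["min"]) == (
            20.0, 20.0, 30.0, 10.0,
        )
        picu = frame.loc["PICU"]
        assert picu["mean"] == picu["median"] == picu["max"] == picu["min"] == 7.0
        assert picu["sd"] == 0.0

    def test_empty_areas_omitted(self):
        frame = summarize_reactions({CareArea.NICU: [], CareArea.GICU: [1.0]})
        assert list(frame.index) == ["GICU"]

    def test_matches_two_pass_oracle_on_simulated_reactions(self):
        model = ReactionModel(mu=2.9, sigma=0.8, p_outlier=0.02, outlier_scale=10)
        rng = np.random.default_rng(11)
        draws = [sample_reaction_time(model, rng) for _ in range(5000)]
        frame = summarize_reactions({CareArea.NICU: draws})
        expected = two_pass_summary(draws)
        for stat, value in expected.items():
            assert frame.loc["NICU", stat] == value, stat


class TestExceedance:
    def test_exceeds_half_life(self):
        flag = flag_exceedance(Drug.NORADRENALINE, 444.25)
        assert flag.category is ExceedanceCategory.EXCEEDS_HALF_LIFE
        assert flag.ratio_to_half_life == pytest.approx(444.25 / 180, abs=0.005)

    def test_within_half_life(self):
        flag = flag_exceedance(Drug.DOPAMINE, 4.00)
        assert flag.category is ExceedanceCategory.WITHIN_HALF_LIFE

    def test_extreme_beyond_six_half_lives(self):
        flag = flag_exceedance(Drug.DOBUTAMINE, 780)
        assert flag.category is ExceedanceCategory.EXTREME
        assert flag.ratio_to_half_life == pytest.approx(6.5)

    def test_boundary_is_not_extreme(self):
        assert (
            flag_exceedance(Drug.DOBUTAMINE, 720).category
            is ExceedanceCategory.EXCEEDS_HALF_LIFE
        )

    def test_other_drug_not_applicable(self):
        with pytest.raises(NotApplicableError):
            flag_exceedance(Drug.OTHER, 10.0)


class TestPipelineVsGroundTruth:
    def test_counts_equal_simulator_counters_exactly(self, small_sim):
        _, events, truth = small_sim
        result = build_episodes(events)
        counts = tally_event_counts(result)
        assert counts["NICU"]["total_infusion_starts"] == truth.n_starts["NICU"]
        for alarm_type, n in truth.alarms_by_type["NICU"].items():
            assert counts["NICU"][alarm_type.lower()] == n
        assert counts["NICU"]["total_alarms"] == truth.total_alarms

        cshl = tally_cshl_counts(result)
        for drug, n in truth.cshl_starts_by_drug.items():
            assert cshl[drug]["infusion_starts"] == n
        for drug, per_type in truth.cshl_alarms_by_drug_type.items():
            for alarm_type, n in per_type.items():
                assert cshl[drug][alarm_type.lower()] == n

    def test_first_time_reactions_come_from_true_reactions(self):
        from collections import Counter

        from infuselog import nicu_default_config, simulate_event_log

        # no repeat re-raises: every generated reaction is a true one and the
        # first-time filter may only drop accidental same-type pairs
        config = nicu_default_config(n_infusions=30, seed=5, p_repeat=0.0)
        events, truth = simulate_event_log(config)
        result = build_episodes(events)
        got = Counter(
            v
            for vs in first_time_reactions_by_area(result, drugs=list(Drug)).values()
            for v in vs
        )
        truth_counter = Counter(
            v for vs in truth.reaction_times.values() for v in vs
        )
        assert not got - truth_counter  # multiset inclusion


def test_boxplot_export(tmp_path):
    from infuselog import plot_reaction_boxplot

    path = plot_reaction_boxplot(
        {CareArea.NICU: [5, 10, 400], CareArea.PICU: [7, 8, 9]},
        tmp_path / "box.png",
    )
    assert path.exists() and path.stat().st_size > 0
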