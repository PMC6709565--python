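"""Episode reconstruction, reaction times, repeat flagging, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infuselog import (
    AlarmReaction,
    AlarmType,
    CareArea,
    Drug,
    EventKind,
    OrderingError,
    PumpEvent,
    PumpModel,
    build_episodes,
    decompose_recovery,
    mark_first_time,
    reaction_time,
)
from _oracles import brute_force_episodes, brute_force_first_time, random_structureless_log


def _ev(pump, t, kind, alarm=None, profile="NICU", drug="Dobutamine 250mg/50ml",
        in_library=True):
    return PumpEvent(pump, PumpModel.SP, t, kind, alarm, profile, drug, in_library)


class TestReactionTime:
    def test_subtraction_on_quarter_grid(self):
        assert reaction_time(36000.00, 36017.50) == 17.50

    def test_zero_interval(self):
        assert reaction_time(100.0, 100.0) == 0.0

    def test_restart_before_alarm_is_ordering_error(self):
        with pytest.raises(OrderingError):
            reaction_time(100.00, 99.00)


class TestDecomposeRecovery:
    def test_components_and_identities(self):
        d = decompose_recovery(0, 30, 47.5, 50)
        assert d.time_to_alarm == 30
        assert d.reaction_time == 17.5
        assert d.resolution_time == 2.5
        assert d.total_recovery == 50
        assert d.total_noninfusion == 47.5

    def test_degenerate_all_equal(self):
        d = decompose_recovery(5, 5, 5, 5)
        assert (d.time_to_alarm, d.reaction_time, d.resolution_time) == (0, 0, 0)

    def test_ordering_violation_names_the_pair(self):
        with pytest.raises(OrderingError, match="restart_time.*alarm_time"):
            decompose_recovery(0, 30, 20, 50)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=4, max_size=4))
    def test_identities_hold_for_any_ordered_quadruple(self, ts):
        onset, alarm, restart, resolved = sorted(ts)
        d = decompose_recovery(onset, alarm, restart, resolved)
        assert d.total_recovery == pytest.approx(
            d.time_to_alarm + d.reaction_time + d.resolution_time
        )
        assert d.total_noninfusion == pytest.approx(d.total_recovery - d.resolution_time)
        assert min(d.time_to_alarm, d.reaction_time, d.resolution_time) >= 0


class TestMarkFirstTime:
    def test_same_type_window_example(self):
        alarms = [
            AlarmReaction(AlarmType.OCCLUSION_DOWNSTREAM, t) for t in (0, 20, 400)
        ]
        flags = [a.first_time for a in mark_first_time(alarms, repeat_window=120)]
        assert flags == [True, False, True]

    def test_single_alarm_is_first_time(self):
        (a,) = mark_first_time([AlarmReaction(AlarmType.CALLBACK, 10.0)])
        assert a.first_time

    def test_rule_is_type_scoped(self):
        alarms = [
            AlarmReaction(AlarmType.CALLBACK, 0.0),
            AlarmReaction(AlarmType.OCCLUSION_DOWNSTREAM, 10.0),
        ]
        assert [a.first_time for a in mark_first_time(alarms)] == [True, True]

    def test_restart_rule_distinguishes_resolved_repeats(self):
        # unresolved re-announcement -> repeat; resolved then re-alarmed -> first
        a1 = AlarmReaction(AlarmType.CALLBACK, 0.0, restart_time=None)
        a2 = AlarmReaction(AlarmType.CALLBACK, 50.0)
        flags = mark_first_time([a1, a2], rule="restart")
        assert [a.first_time for a in flags] == [True, False]
        b1 = AlarmReaction(AlarmType.CALLBACK, 0.0, restart_time=20.0)
        b2 = AlarmReaction(AlarmType.CALLBACK, 50.0)
        flags = mark_first_time([b1, b2], rule="restart")
        assert [a.first_time for a in flags] == [True, True]

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from([AlarmType.CALLBACK, AlarmType.OCCLUSION_DOWNSTREAM]),
                st.integers(min_value=0, max_value=2000),
            ),
            max_size=12,
        ),
        st.floats(min_value=1, max_value=500),
    )
    def test_window_rule_matches_all_pairs_scan(self, raw, window):
        raw = sorted(raw, key=lambda p: p[1])
        alarms = [AlarmReaction(t, float(time)) for t, time in raw]
        got = [a.first_time for a in mark_first_time(alarms, repeat_window=window)]
        expected = brute_force_first_time(
            [(t, float(time)) for t, time in raw], window
        )
        assert got == expected


class TestBuildEpisodes:
    def test_direct_construction(self):
        events = [
            _ev("P1", 0, EventKind.INFUSION_START),
            _ev("P1", 100, EventKind.ALARM, AlarmType.OCCLUSION_DOWNSTREAM),
            _ev("P1", 117.5, EventKind.RESTART),
            _ev("P1", 3600, EventKind.INFUSION_STOP),
        ]
        result = build_episodes(events)
        assert len(result.episodes) == 1 and not result.rejects
        ep = result.episodes[0]
        assert ep.care_area is CareArea.NICU
        assert ep.drug is Drug.DOBUTAMINE
        assert (ep.start_time, ep.end_time) == (0, 3600)
        (alarm,) = ep.alarms
        assert alarm.reaction_time == 17.5
        assert alarm.first_time

    def test_orphan_alarm_is_rejected_not_dropped(self):
        result = build_episodes([_ev("P1", 5, EventKind.ALARM, AlarmType.CALLBACK)])
        assert result.episodes == []
        assert len(result.rejects) == 1
        assert result.rejects[0].reason == "alarm_without_open_episode"

    def test_episode_count_equals_start_count(self, small_sim):
        _, events, _ = small_sim
        n_starts = sum(e.event_kind is EventKind.INFUSION_START for e in events)
        result = build_episodes(events)
        assert len(result.episodes) == n_starts == 50

    def test_alarm_conservation(self, rng):
        """AlarmReactions + alarm rejects account for every ALARM event."""
        events = random_structureless_log(rng, n_pumps=10, events_per_pump=60)
        result = build_episodes(events)
        n_alarm_events = sum(e.event_kind is EventKind.ALARM for e in events)
        n_attached = sum(len(ep.alarms) for ep in result.episodes)
        assert n_attached + len(result.alarm_rejects) == n_alarm_events

    def test_restart_resolves_all_pending_alarms(self):
        events = [
            _ev("P1", 0, EventKind.INFUSION_START),
            _ev("P1", 10, EventKind.ALARM, AlarmType.CALLBACK),
            _ev("P1", 20, EventKind.ALARM, AlarmType.OCCLUSION_DOWNSTREAM),
            _ev("P1", 30, EventKind.RESTART),
            _ev("P1", 100, EventKind.INFUSION_STOP),
        ]
        (ep,) = build_episodes(events).episodes
        assert [a.restart_time for a in ep.alarms] == [30, 30]

    def test_unclosed_episode_stays_open_with_unresolved_alarm(self):
        events = [
            _ev("P1", 0, EventKind.INFUSION_START),
            _ev("P1", 10, EventKind.ALARM, AlarmType.CALLBACK),
        ]
        (ep,) = build_episodes(events).episodes
        assert ep.end_time is None
        assert ep.alarms[0].restart_time is None
        assert ep.alarms[0].reaction_time is None

    def test_matches_brute_force_on_noisy_random_logs(self, rng):
        events = random_structureless_log(rng, n_pumps=20, events_per_pump=50)
        result = build_episodes(events)
        oracle_eps, oracle_rejects = brute_force_episodes(events)

        got = [
            {
                "pump_id": ep.pump_id,
                "start": ep.start_time,
                "end": ep.end_time,
                "alarms": [
                    (a.alarm_type, a.alarm_time, a.restart_time) for a in ep.alarms
                ],
            }
            for ep in result.episodes
        ]
        assert got == oracle_eps
        assert sorted((r.pump_id, r.timestamp, r.event_kind) for r in result.rejects) \
            == sorted(oracle_rejects)
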