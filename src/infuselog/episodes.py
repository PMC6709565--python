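"""Infusion-lifecycle reconstruction and reaction-time extraction.

An infusion episode is the lifecycle of one infusion on one pump channel:
INFUSION_START opens it, ALARM events interrupt it, each RESTART resolves the
alarms currently pending on that pump, and INFUSION_STOP closes it.  The
clinically central quantity is the *reaction time*

    reaction time = restart timestamp - alarm timestamp     (seconds)

and, for an occlusion with known physical onset, the recovery decomposition

    total recovery time  = time to alarm + reaction time + resolution time
    total noninfusion    = time to alarm + reaction time

Only *first-time* alarms — the initial occurrence of an alarm type within an
episode, excluding immediate repeats — feed reaction-time statistics; repeats
are flagged by :func:`mark_first_time` under either a repeat-window rule
(default, 120 s) or a stricter no-intervening-restart rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .normalize import CareArea, CareAreaMap, Drug, DrugMap
from .schema import AlarmType, EventKind, PumpEvent, quantize

#: Default repeat window in seconds.  Spans the half-lives of the studied
#: drugs (60-180 s); configurable because the underlying manual-review rule
#: was not formalised.
DEFAULT_REPEAT_WINDOW = 120.0


class OrderingError(ValueError):
    """Timestamps violate the required ordering."""


@dataclass(slots=True)
class AlarmReaction:
    """One alarm paired with the restart that resolved it (if any)."""

    alarm_type: AlarmType
    alarm_time: float
    restart_time: float | None = None
    first_time: bool = True

    @property
    def reaction_time(self) -> float | None:
        """Seconds from alarm to restart; None while unresolved."""
        if self.restart_time is None:
            return None
        return reaction_time(self.alarm_time, self.restart_time)


@dataclass(slots=True)
class InfusionEpisode:
    """Reconstructed lifecycle of one infusion."""

    pump_id: str
    care_area: CareArea
    drug: Drug
    start_time: float
    end_time: float | None = None        # None: never closed in the log
    alarms: list[AlarmReaction] = field(default_factory=list)
    in_library: bool = False


@dataclass(slots=True)
class RejectedEvent:
    """A structurally orphan event (no open episode to attach to)."""

    pump_id: str
    timestamp: float
    event_kind: EventKind
    reason: str


@dataclass(frozen=True, slots=True)
class RecoveryDecomposition:
    """Additive decomposition of one interruption-recovery cycle."""

    time_to_alarm: float
    reaction_time: float
    resolution_time: float

    @property
    def total_recovery(self) -> float:
        return self.time_to_alarm + self.reaction_time + self.resolution_time

    @property
    def total_noninfusion(self) -> float:
        return self.time_to_alarm + self.reaction_time


def reaction_time(alarm_time: float, restart_time: float) -> float:
    """Restart minus alarm timestamp, seconds, on the 0.25 s grid."""
    if restart_time < alarm_time:
        raise OrderingError(
            f"restart at {restart_time} precedes alarm at {alarm_time}"
        )
    return quantize(restart_time - alarm_time)


def decompose_recovery(
    onset_time: float,
    alarm_time: float,
    restart_time: float,
    resolved_time: float,
) -> RecoveryDecomposition:
    """Split occlusion onset -> alarm -> restart -> resolved into components."""
    pairs = [
        ("onset_time", onset_time, "alarm_time", alarm_time),
        ("alarm_time", alarm_time, "restart_time", restart_time),
        ("restart_time", restart_time, "resolved_time", resolved_time),
    ]
    for a_name, a, b_name, b in pairs:
        if b < a:
            raise OrderingError(f"{b_name} ({b}) precedes {a_name} ({a})")
    return RecoveryDecomposition(
        time_to_alarm=alarm_time - onset_time,
        reaction_time=restart_time - alarm_time,
        resolution_time=resolved_time - restart_time,
    )


def mark_first_time(
    alarms: Sequence[AlarmReaction],
    repeat_window: float = DEFAULT_REPEAT_WINDOW,
    rule: str = "window",
) -> list[AlarmReaction]:
    """Flag each alarm as first-time or repeat, in place; returns the list.

    ``rule="window"`` (default): an alarm is a repeat iff an earlier alarm of
    the same type on the episode lies within ``repeat_window`` seconds before
    it.  ``rule="restart"``: an alarm is a repeat iff the most recent earlier
    same-type alarm was not followed by a restart before this alarm
    (i.e. the alarm re-announces a still-unresolved condition).
    """
    alarms = list(alarms)
    if any(
        alarms[i].alarm_time > alarms[i + 1].alarm_time for i in range(len(alarms) - 1)
    ):
        raise OrderingError("alarms must be sorted by alarm_time")
    if rule not in {"window", "restart"}:
        raise ValueError(f"unknown repeat rule {rule!r}")
    for i, cur in enumerate(alarms):
        prior = [a for a in alarms[:i] if a.alarm_type is cur.alarm_type]
        if rule == "window":
            cur.first_time = not any(
                cur.alarm_time - p.alarm_time <= repeat_window for p in prior
            )
        else:
            if not prior:
                cur.first_time = True
            else:
                last = prior[-1]
                intervened = (
                    last.restart_time is not None
                    and last.restart_time <= cur.alarm_time
                )
                cur.first_time = intervened
    return alarms


@dataclass
class EpisodeBuildResult:
    episodes: list[InfusionEpisode]
    rejects: list[RejectedEvent]

    @property
    def alarm_rejects(self) -> list[RejectedEvent]:
        return [r for r in self.rejects if r.event_kind is EventKind.ALARM]


def build_episodes(
    events: Iterable[PumpEvent],
    care_map: CareAreaMap | None = None,
    drug_map: DrugMap | None = None,
    repeat_window: float = DEFAULT_REPEAT_WINDOW,
    repeat_rule: str = "window",
) -> EpisodeBuildResult:
    """Reconstruct infusion episodes from a (per-pump sorted) event stream.

    Orphan ALARM/RESTART/STOP events with no open episode on their pump are
    collected into the rejects report, never silently dropped; an
    INFUSION_START arriving while an episode is already open closes the stale
    episode open-ended and is itself counted as an anomaly.  Every ALARM event
    ends up either as an :class:`AlarmReaction` on some episode or as a
    reject.
    """
    care_map = care_map or CareAreaMap.default()
    drug_map = drug_map or DrugMap.default()
    events = sorted(events, key=lambda e: (e.pump_id, e.timestamp))

    episodes: list[InfusionEpisode] = []
    rejects: list[RejectedEvent] = []
    open_ep: dict[str, InfusionEpisode] = {}
    pending: dict[str, list[AlarmReaction]] = {}

    def _close(pump_id: str, end_time: float | None) -> None:
        ep = open_ep.pop(pump_id)
        ep.end_time = end_time
        mark_first_time(ep.alarms, repeat_window=repeat_window, rule=repeat_rule)
        pending.pop(pump_id, None)
        episodes.append(ep)

    for ev in events:
        pid = ev.pump_id
        if ev.event_kind is EventKind.INFUSION_START:
            if pid in open_ep:
                rejects.append(
                    RejectedEvent(pid, ev.timestamp, ev.event_kind,
                                  "start_while_episode_open")
                )
                _close(pid, None)
            drug = (
                drug_map.normalize(ev.drug_text)
                if ev.in_library and ev.drug_text
                else Drug.OTHER
            )
            open_ep[pid] = InfusionEpisode(
                pump_id=pid,
                care_area=care_map.normalize(ev.profile_text),
                drug=drug,
                start_time=ev.timestamp,
                in_library=ev.in_library,
            )
            pending[pid] = []
        elif ev.event_kind is EventKind.ALARM:
            if pid not in open_ep:
                rejects.append(
                    RejectedEvent(pid, ev.timestamp, ev.event_kind,
                                  "alarm_without_open_episode")
                )
                continue
            assert ev.alarm_type is not None
            reaction = AlarmReaction(ev.alarm_type, ev.timestamp)
            open_ep[pid].alarms.append(reaction)
            pending[pid].append(reaction)
        elif ev.event_kind is EventKind.RESTART:
            if pid not in open_ep:
                rejects.append(
                    RejectedEvent(pid, ev.timestamp, ev.event_kind,
                                  "restart_without_open_episode")
                )
                continue
            resolved = [a for a in pending[pid] if a.alarm_time <= ev.timestamp]
            if not resolved:
                rejects.append(
                    RejectedEvent(pid, ev.timestamp, ev.event_kind,
                                  "restart_without_pending_alarm")
                )
                continue
            for alarm in resolved:
                alarm.restart_time = ev.timestamp
            pending[pid] = [a for a in pending[pid] if a.restart_time is None]
        elif ev.event_kind is EventKind.INFUSION_STOP:
            if pid not in open_ep:
                rejects.append(
                    RejectedEvent(pid, ev.timestamp, ev.event_kind,
                                  "stop_without_open_episode")
                )
                continue
            _close(pid, ev.timestamp)

    # episodes still open at end of log stay open-ended
    for pid in sorted(open_ep):
        _close(pid, None)

    episodes.sort(key=lambda e: (e.pump_id, e.start_time))
    return EpisodeBuildResult(episodes=episodes, rejects=rejects)


def write_rejects(rejects: Iterable[RejectedEvent], path: str | Path) -> Path:
    """Write the rejects report as CSV."""
    from .schema import format_timestamp

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["pump_id", "timestamp", "event_kind", "reason"])
        for r in rejects:
            writer.writerow(
                [r.pump_id, format_timestamp(r.timestamp), r.event_kind.value, r.reason]
            )
    return path
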