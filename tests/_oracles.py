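"""Independent reference implementations used only by the test suite.

These are deliberately naive (O(n^2) scans, two-pass statistics) and share no
code with the package's episode builder or summary statistics, so agreement
is evidence rather than tautology.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

from infuselog.schema import EventKind, PumpEvent


def brute_force_episodes(events: list[PumpEvent]):
    """O(n^2) reference episode matcher.

    Returns (episodes, rejects) where each episode is a dict
    {pump_id, start, end, alarms: [(type, alarm_time, restart_time)]} and
    rejects is a list of (pump_id, timestamp, event_kind) tuples.  Semantics:
    a START opens an episode (closing any stale open one open-ended, and
    flagging the START as an anomaly), alarms attach to the episode open at
    their time, a restart resolves every unresolved alarm at or before it in
    the same episode, a STOP closes.  Assumes strictly distinct timestamps
    per pump.
    """
    episodes = []
    rejects = []
    by_pump: dict[str, list[PumpEvent]] = {}
    for ev in sorted(events, key=lambda e: (e.pump_id, e.timestamp)):
        by_pump.setdefault(ev.pump_id, []).append(ev)

    for pump_id, evs in sorted(by_pump.items()):
        starts = [e for e in evs if e.event_kind is EventKind.INFUSION_START]
        # episode bounds: [start, close) where close is the first STOP or
        # START strictly after start; a STOP closes inclusively.
        bounds = []
        for s in starts:
            close_t = None
            closed_by_stop = False
            for e in evs:
                if e.timestamp > s.timestamp and e.event_kind in (
                    EventKind.INFUSION_STOP,
                    EventKind.INFUSION_START,
                ):
                    close_t = e.timestamp
                    closed_by_stop = e.event_kind is EventKind.INFUSION_STOP
                    break
            bounds.append((s.timestamp, close_t, closed_by_stop))

        def episode_index_at(t: float):
            for i, (s, c, closed_by_stop) in enumerate(bounds):
                if t < s:
                    continue
                if c is None:
                    return i
                if t < c or (t == c and closed_by_stop):
                    # events exactly at the STOP time belong to the episode
                    # only if they sort before the STOP; distinct timestamps
                    # assumed, so t == c only for the STOP itself.
                    return i if t < c else None
            return None

        ep_alarms: dict[int, list] = {i: [] for i in range(len(bounds))}
        for e in evs:
            if e.event_kind is EventKind.ALARM:
                i = episode_index_at(e.timestamp)
                if i is None:
                    rejects.append((pump_id, e.timestamp, e.event_kind))
                else:
                    ep_alarms[i].append([e.alarm_type, e.timestamp, None])
            elif e.event_kind is EventKind.INFUSION_START:
                # anomaly: a START inside another episode's open bound
                for s, c, closed_by_stop in bounds:
                    if s < e.timestamp and (c == e.timestamp and not closed_by_stop):
                        rejects.append((pump_id, e.timestamp, e.event_kind))
                        break
            elif e.event_kind in (EventKind.RESTART, EventKind.INFUSION_STOP):
                pass

        restarts = [e for e in evs if e.event_kind is EventKind.RESTART]
        for r in restarts:
            i = episode_index_at(r.timestamp)
            if i is None:
                rejects.append((pump_id, r.timestamp, r.event_kind))
                continue
            resolved_any = False
            for alarm in ep_alarms[i]:
                if alarm[2] is None and alarm[1] <= r.timestamp:
                    alarm[2] = r.timestamp
                    resolved_any = True
            if not resolved_any:
                rejects.append((pump_id, r.timestamp, r.event_kind))

        for e in evs:
            if e.event_kind is EventKind.INFUSION_STOP:
                matched = any(
                    c == e.timestamp and closed for (s, c, closed) in bounds
                )
                if not matched:
                    rejects.append((pump_id, e.timestamp, e.event_kind))

        for i, (s, c, closed_by_stop) in enumerate(bounds):
            episodes.append(
                {
                    "pump_id": pump_id,
                    "start": s,
                    "end": c if closed_by_stop else None,
                    "alarms": [tuple(a) for a in sorted(ep_alarms[i], key=lambda a: a[1])],
                }
            )
    return episodes, rejects


def brute_force_first_time(alarms, repeat_window: float) -> list[bool]:
    """All-pairs scan version of the repeat-window first-time rule.

    ``alarms`` is a sequence of (alarm_type, alarm_time) sorted by time.
    """
    flags = []
    for i, (t_i, time_i) in enumerate(alarms):
        repeat = False
        for j, (t_j, time_j) in enumerate(alarms):
            if j < i and t_j == t_i and 0 <= time_i - time_j <= repeat_window:
                repeat = True
        flags.append(not repeat)
    return flags


def _round2(x: float, nd: int = 2) -> float:
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def two_pass_summary(values) -> dict[str, float]:
    """Two-pass mean/population-SD/max/min/median, rounded half-up to 2 dp."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / n
    if n % 2:
        median = xs[n // 2]
    else:
        median = (xs[n // 2 - 1] + xs[n // 2]) / 2
    return {
        "mean": _round2(mean),
        "sd": _round2(math.sqrt(var)),
        "max": _round2(xs[-1]),
        "min": _round2(xs[0]),
        "median": _round2(median),
    }


def random_structureless_log(
    rng, n_pumps: int, events_per_pump: int
) -> list[PumpEvent]:
    """A noisy random log: kinds drawn with no state machine, so orphan
    alarms/restarts/stops and starts-while-open all occur.  Timestamps are
    strictly increasing quarter-seconds per pump."""
    from infuselog.schema import AlarmType, PumpModel

    kinds = [
        EventKind.INFUSION_START,
        EventKind.ALARM,
        EventKind.RESTART,
        EventKind.INFUSION_STOP,
    ]
    probs = [0.2, 0.4, 0.25, 0.15]
    alarm_types = list(AlarmType)
    events = []
    for p in range(n_pumps):
        t = 0.0
        for _ in range(events_per_pump):
            t += 0.25 * int(rng.integers(1, 200))
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            at = (
                alarm_types[int(rng.integers(len(alarm_types)))]
                if kind is EventKind.ALARM
                else None
            )
            events.append(
                PumpEvent(
                    pump_id=f"R{p:03d}",
                    pump_model=PumpModel.SP,
                    timestamp=t,
                    event_kind=kind,
                    alarm_type=at,
                    profile_text="NICU",
                    drug_text="Dobutamine 250mg/50ml" if kind is EventKind.INFUSION_START else None,
                    in_library=kind is EventKind.INFUSION_START,
                )
            )
    return events
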