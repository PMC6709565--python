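"""Derived alarm-burden and reaction-time metrics.

Everything downstream of episode reconstruction is a ratio, percentage or
summary statistic over raw counts: alarms per infusion by care area (and the
unweighted mean over the four critical-care areas), whole-population alarm
frequency percentages, the critical short half-life (CSHL) breakdown with its
two percentage denominators, reaction-time summaries, and half-life
exceedance flags.

All printed-table style rounding is half-up to 2 decimals, computed with
exact decimal arithmetic from the integer counts.  Three published derived
values are known not to follow from the published raw counts; they are kept
in :data:`KNOWN_PRINT_DISCREPANCIES` so the mismatch is asserted, never
silently "fixed".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .episodes import EpisodeBuildResult
from .normalize import CSHL_DRUGS, CareArea, Drug, HalfLifeTable
from .schema import AlarmType, CountTableFixture

#: Care areas making up the critical-care aggregate, in published column order.
CRITICAL_AREAS = ("NICU", "GICU", "CICU", "PICU")

#: Alarm-type metric keys in published row order.
ALARM_METRICS = tuple(t.value.lower() for t in AlarmType)

#: Published derived cells that do not follow from the published raw counts:
#: name -> (printed value, value recomputed from the printed counts).
KNOWN_PRINT_DISCREPANCIES: Mapping[str, tuple[float, float]] = {
    "critical_care_total_alarms": (467437, 467237),
    "whole_hospital_alarms_per_infusion": (1.39, 1.38),
    "general_occlusion_start_ratio": (0.52, 0.53),
}


class UndefinedRatioError(ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class NotApplicableError(ValueError):
    """The operation applies only to the four CSHL drugs."""


def round_half_up(value: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero-on-tie upward, as in the printed tables."""
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: float, den: float, ndigits: int = 2) -> float:
    return round_half_up(Decimal(str(num)) / Decimal(str(den)), ndigits)


def alarms_per_infusion(total_alarms: int, total_starts: int) -> float:
    """Mean alarms per infusion for one care area, half-up to 2 dp."""
    if total_starts <= 0:
        raise UndefinedRatioError("alarms per infusion undefined with zero starts")
    return _ratio(total_alarms, total_starts)


def mean_area_ratio(per_area_ratios: Sequence[float]) -> float:
    """Unweighted mean of the four per-area alarms-per-infusion ratios.

    This — not the pooled quotient of summed counts — is how the published
    critical-care "alarms per infusion" figure is defined; both are exposed
    by :class:`AlarmBurdenTable`.
    """
    if len(per_area_ratios) != len(CRITICAL_AREAS):
        raise ValueError(
            f"expected {len(CRITICAL_AREAS)} per-area ratios, got {len(per_area_ratios)}"
        )
    total = sum(Decimal(str(r)) for r in per_area_ratios)
    return round_half_up(total / len(per_area_ratios))


def occlusion_start_ratio(downstream_occlusions: int, starts: int) -> float:
    """Downstream occlusions per infusion start, half-up to 2 dp."""
    if starts <= 0:
        raise UndefinedRatioError("occlusion/start ratio undefined with zero starts")
    return _ratio(downstream_occlusions, starts)


# --------------------------------------------------------------------------
# Count extraction


def _area_counts_from_fixture(fixture: CountTableFixture) -> dict[str, dict[str, int]]:
    return {name: dict(row) for name, row in fixture.area_counts.items()}


def tally_event_counts(result: EpisodeBuildResult) -> dict[str, dict[str, int]]:
    """Tally starts and per-type alarm counts per care area from episodes.

    Adds the two aggregate pseudo-areas: ``ALL_CRITICAL_CARE`` (sum over the
    four critical-care areas) and ``WHOLE_HOSPITAL`` (every episode,
    UNMAPPED profiles included).
    """
    counts: dict[str, dict[str, int]] = {}
    for ep in result.episodes:
        row = counts.setdefault(
            ep.care_area.value,
            {"total_infusion_starts": 0, **{m: 0 for m in ALARM_METRICS}},
        )
        row["total_infusion_starts"] += 1
        for alarm in ep.alarms:
            row[alarm.alarm_type.value.lower()] += 1
    for agg, members in (
        ("ALL_CRITICAL_CARE", CRITICAL_AREAS),
        ("WHOLE_HOSPITAL", tuple(a for a in counts)),
    ):
        agg_row = {"total_infusion_starts": 0, **{m: 0 for m in ALARM_METRICS}}
        for area in members:
            for k, v in counts.get(area, {}).items():
                agg_row[k] = agg_row.get(k, 0) + v
        counts[agg] = agg_row
    for row in counts.values():
        row["total_alarms"] = sum(row.get(m, 0) for m in ALARM_METRICS)
    return counts


def tally_cshl_counts(result: EpisodeBuildResult) -> dict[str, dict[str, int]]:
    """NICU-scoped per-drug starts and alarm counts for the four CSHL drugs."""
    counts: dict[str, dict[str, int]] = {
        d.value: {"infusion_starts": 0, **{m: 0 for m in ALARM_METRICS}}
        for d in CSHL_DRUGS
    }
    for ep in result.episodes:
        if ep.care_area is not CareArea.NICU or ep.drug not in CSHL_DRUGS:
            continue
        row = counts[ep.drug.value]
        row["infusion_starts"] += 1
        for alarm in ep.alarms:
            row[alarm.alarm_type.value.lower()] += 1
    total = {"infusion_starts": 0, **{m: 0 for m in ALARM_METRICS}}
    for row in counts.values():
        for k, v in row.items():
            total[k] += v
    counts["FOUR_DRUG_TOTAL"] = total
    return counts


# --------------------------------------------------------------------------
# Alarm-burden table


@dataclass
class AlarmBurdenTable:
    """Per-care-area alarm burden with derived ratios and percentages."""

    counts: Mapping[str, Mapping[str, int]]            # area -> metric -> count
    alarms_per_infusion_by_area: Mapping[str, float]   # 2 dp, per area
    mean_critical_ratio: float | None                  # unweighted mean of 4 areas
    pooled_critical_ratio: float | None                # Σalarms / Σstarts
    percent_by_type: Mapping[str, float]               # whole-population %, 2 dp
    computed_critical_total_alarms: int                # sum over the four areas

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (alarm types × areas); absent cells are NaN."""
        areas = [a for a in ("ALL_CRITICAL_CARE", *CRITICAL_AREAS, "WHOLE_HOSPITAL")
                 if a in self.counts]
        rows = ["total_infusion_starts", *ALARM_METRICS]
        data = {
            a: [self.counts[a].get(m, np.nan) for m in rows] for a in areas
        }
        frame = pd.DataFrame(data, index=rows)
        frame["whole_population_pct"] = [np.nan] + [
            self.percent_by_type.get(m, np.nan) for m in ALARM_METRICS
        ]
        return frame

    def to_dict(self) -> dict:
        return {
            "counts": {a: dict(r) for a, r in self.counts.items()},
            "alarms_per_infusion_by_area": dict(self.alarms_per_infusion_by_area),
            "mean_critical_ratio": self.mean_critical_ratio,
            "pooled_critical_ratio": self.pooled_critical_ratio,
            "percent_by_type": dict(self.percent_by_type),
            "computed_critical_total_alarms": self.computed_critical_total_alarms,
        }


def build_alarm_burden(
    source: CountTableFixture | EpisodeBuildResult | Mapping[str, Mapping[str, int]],
) -> AlarmBurdenTable:
    """Compute every derived alarm-burden quantity from raw counts.

    ``source`` may be the published-count fixture, an episode-reconstruction
    result, or a plain area -> metric -> count mapping.  Absent (N/A) cells
    stay absent through every aggregation; negative counts are rejected.
    """
    if isinstance(source, CountTableFixture):
        counts = _area_counts_from_fixture(source)
    elif isinstance(source, EpisodeBuildResult):
        counts = tally_event_counts(source)
    else:
        counts = {a: dict(r) for a, r in source.items()}

    for area, row in counts.items():
        for metric, v in row.items():
            if v < 0:
                raise ValueError(f"negative count {metric}={v} in area {area}")

    # areas absent from the log (or with zero starts) simply carry no ratio;
    # the unweighted critical-care mean exists only when all four areas do
    api: dict[str, float] = {}
    area_ratios: list[float] = []
    pooled_alarms = 0
    pooled_starts = 0
    for area in CRITICAL_AREAS:
        row = counts.get(area)
        if not row or not row.get("total_infusion_starts"):
            continue
        total_alarms = sum(row[m] for m in ALARM_METRICS if m in row)
        api[area] = alarms_per_infusion(total_alarms, row["total_infusion_starts"])
        area_ratios.append(api[area])
        pooled_alarms += total_alarms
        pooled_starts += row["total_infusion_starts"]

    if "WHOLE_HOSPITAL" not in counts:
        raise ValueError("whole-population (WHOLE_HOSPITAL) counts are required")
    hosp_row = counts["WHOLE_HOSPITAL"]
    hosp_total = sum(hosp_row[m] for m in ALARM_METRICS if m in hosp_row)
    if hosp_row.get("total_infusion_starts"):
        api["WHOLE_HOSPITAL"] = alarms_per_infusion(
            hosp_total, hosp_row["total_infusion_starts"]
        )

    percent_by_type = {
        m: _ratio(100 * hosp_row.get(m, 0), hosp_total)
        for m in ALARM_METRICS
        if m in hosp_row and hosp_total
    }

    return AlarmBurdenTable(
        counts=counts,
        alarms_per_infusion_by_area=api,
        mean_critical_ratio=(
            mean_area_ratio(area_ratios)
            if len(area_ratios) == len(CRITICAL_AREAS)
            else None
        ),
        pooled_critical_ratio=(
            _ratio(pooled_alarms, pooled_starts) if pooled_starts else None
        ),
        percent_by_type=percent_by_type,
        computed_critical_total_alarms=pooled_alarms,
    )


# --------------------------------------------------------------------------
# CSHL table


@dataclass
class CSHLAlarmTable:
    """NICU critical short half-life breakdown with its two percent columns.

    ``pct_of_unit_total`` divides each four-drug row total by the NICU-wide
    count for the same metric; ``pct_of_cshl_starts`` divides each alarm row
    total by the four-drug infusion-start total.  Cells with a zero or absent
    denominator are absent (None), not zero.
    """

    counts: Mapping[str, Mapping[str, int]]     # drug -> metric -> count
    pct_of_unit_total: Mapping[str, float | None]
    pct_of_cshl_starts: Mapping[str, float | None]
    cshl_starts: int

    def eoi_eos_pct_of_cshl_starts(self) -> float:
        """End-of-infusion + end-of-syringe events per CSHL start, %, 1 dp."""
        total = self.counts["FOUR_DRUG_TOTAL"]
        n = total.get("end_of_infusion", 0) + total.get("end_of_syringe", 0)
        return round_half_up(Decimal(100 * n) / Decimal(self.cshl_starts), 1)

    def to_frame(self) -> pd.DataFrame:
        metrics = ["infusion_starts"] + [
            m for m in ALARM_METRICS if m in self.counts["FOUR_DRUG_TOTAL"]
        ]
        drugs = [d for d in self.counts if d != "FOUR_DRUG_TOTAL"]
        frame = pd.DataFrame(
            {d: [self.counts[d].get(m, np.nan) for m in metrics] for d in drugs},
            index=metrics,
        )
        frame["four_drug_total"] = [
            self.counts["FOUR_DRUG_TOTAL"].get(m, np.nan) for m in metrics
        ]
        frame["pct_of_unit_total"] = [
            v if (v := self.pct_of_unit_total.get(m)) is not None else np.nan
            for m in metrics
        ]
        frame["pct_of_cshl_starts"] = [
            v if (v := self.pct_of_cshl_starts.get(m)) is not None else np.nan
            for m in metrics
        ]
        return frame

    def to_dict(self) -> dict:
        return {
            "counts": {d: dict(r) for d, r in self.counts.items()},
            "pct_of_unit_total": dict(self.pct_of_unit_total),
            "pct_of_cshl_starts": dict(self.pct_of_cshl_starts),
            "cshl_starts": self.cshl_starts,
        }


def build_cshl_table(
    source: CountTableFixture | EpisodeBuildResult | Mapping[str, Mapping[str, int]],
    nicu_counts: Mapping[str, int] | None = None,
) -> CSHLAlarmTable:
    """Compute the CSHL breakdown's derived cells from raw counts.

    ``nicu_counts`` supplies the per-metric NICU-wide denominators; it is
    taken from the source itself when the source is the fixture or an episode
    result.
    """
    if isinstance(source, CountTableFixture):
        counts = {d: dict(r) for d, r in source.cshl_counts.items()}
        nicu_counts = dict(source.area_counts["NICU"])
    elif isinstance(source, EpisodeBuildResult):
        counts = tally_cshl_counts(source)
        nicu_counts = tally_event_counts(source).get("NICU", {})
    else:
        counts = {d: dict(r) for d, r in source.items()}
        nicu_counts = dict(nicu_counts or {})

    if "FOUR_DRUG_TOTAL" not in counts:
        total: dict[str, int] = {}
        for drug, row in counts.items():
            for k, v in row.items():
                total[k] = total.get(k, 0) + v
        counts["FOUR_DRUG_TOTAL"] = total
    total = counts["FOUR_DRUG_TOTAL"]
    cshl_starts = total.get("infusion_starts", 0)

    metrics = ["infusion_starts"] + [m for m in ALARM_METRICS if m in total]
    pct_unit: dict[str, float | None] = {}
    pct_starts: dict[str, float | None] = {}
    for m in metrics:
        unit_key = "total_infusion_starts" if m == "infusion_starts" else m
        denom = (nicu_counts or {}).get(unit_key, 0)
        pct_unit[m] = _ratio(100 * total[m], denom) if denom else None
        if m == "infusion_starts":
            pct_starts[m] = None
        else:
            pct_starts[m] = _ratio(100 * total[m], cshl_starts) if cshl_starts else None

    return CSHLAlarmTable(
        counts=counts,
        pct_of_unit_total=pct_unit,
        pct_of_cshl_starts=pct_starts,
        cshl_starts=cshl_starts,
    )


# --------------------------------------------------------------------------
# Reaction-time summaries and exceedance


def summarize_reactions(
    reactions_by_area: Mapping[object, Sequence[float]],
    ddof: int = 0,
) -> pd.DataFrame:
    """Mean, SD, max, min, median of reaction times per care area, 2 dp.

    Areas with no resolved first-time reactions are omitted.  SD is the
    population SD by default (``ddof=0``); pass ``ddof=1`` for the sample SD.
    """
    rows = {}
    for area, values in reactions_by_area.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            continue
        sd = float(np.std(arr, ddof=ddof)) if arr.size > ddof else 0.0
        rows[getattr(area, "value", str(area))] = {
            "n": int(arr.size),
            "mean": round_half_up(float(np.mean(arr))),
            "sd": round_half_up(sd),
            "max": round_half_up(float(np.max(arr))),
            "min": round_half_up(float(np.min(arr))),
            "median": round_half_up(float(np.median(arr))),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if not frame.empty:
        frame = frame.astype({"n": int})
    return frame


def first_time_reactions_by_area(
    result: EpisodeBuildResult,
    drugs: Iterable[Drug] = CSHL_DRUGS,
) -> dict[CareArea, list[float]]:
    """Resolved first-time reaction times for the given drugs, per care area."""
    drugs = set(drugs)
    out: dict[CareArea, list[float]] = {}
    for ep in result.episodes:
        if ep.drug not in drugs:
            continue
        for alarm in ep.alarms:
            if alarm.first_time and alarm.restart_time is not None:
                out.setdefault(ep.care_area, []).append(alarm.reaction_time)
    return out


class ExceedanceCategory(str, Enum):
    WITHIN_HALF_LIFE = "WITHIN_HALF_LIFE"
    EXCEEDS_HALF_LIFE = "EXCEEDS_HALF_LIFE"
    EXTREME = "EXTREME"


#: An interruption is EXTREME when it outlasts this many half-lives.
EXTREME_HALF_LIFE_MULTIPLE = 6.0


@dataclass(frozen=True)
class ExceedanceFlag:
    drug: Drug
    reaction_time: float
    category: ExceedanceCategory
    ratio_to_half_life: float


def flag_exceedance(
    drug: Drug,
    reaction_time: float,
    half_lives: HalfLifeTable | None = None,
) -> ExceedanceFlag:
    """Classify a reaction time against the drug's plasma half-life.

    WITHIN_HALF_LIFE when the restart came within the drug's maximum
    half-life; EXTREME when it exceeded six half-lives; EXCEEDS_HALF_LIFE in
    between.  The ratio is computed against the maximum half-life.
    """
    if drug not in CSHL_DRUGS:
        raise NotApplicableError(f"half-life exceedance applies only to CSHL drugs, not {drug}")
    half_lives = half_lives or HalfLifeTable.default()
    _, hl_max = half_lives.range_for(drug)
    ratio = reaction_time / hl_max
    if reaction_time <= hl_max:
        category = ExceedanceCategory.WITHIN_HALF_LIFE
    elif ratio > EXTREME_HALF_LIFE_MULTIPLE:
        category = ExceedanceCategory.EXTREME
    else:
        category = ExceedanceCategory.EXCEEDS_HALF_LIFE
    return ExceedanceFlag(drug, reaction_time, category, ratio)


def plot_reaction_boxplot(
    reactions_by_area: Mapping[object, Sequence[float]],
    path: str | Path,
) -> Path:
    """Export a per-care-area reaction-time boxplot (median line, quartile
    box, outlier markers)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = [getattr(a, "value", str(a)) for a in reactions_by_area]
    data = [list(v) for v in reactions_by_area.values()]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * max(1, len(data)), 4))
    if data:
        ax.boxplot(data, tick_labels=labels, sym="rx")
    ax.set_ylabel("reaction time (s)")
    ax.set_title("First-time CSHL interruption reaction times")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
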