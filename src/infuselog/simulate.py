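"""Seedable discrete-event simulator of infusion-pump event logs.

The study-scale raw logs behind the published count tables were never
deposited, so this module generates synthetic logs with the statistical
structure the analysis assumes, parameterised directly from the embedded
count tables: per-care-area alarm-type mixes and alarms-per-infusion rates,
the NICU critical short half-life (CSHL) drug mix and CSHL fraction of
starts, heavy-tailed (contaminated-lognormal) clinician reaction times, and
free-text profile/drug name variants for the normalisation step to chew on.

Every simulation carries ground-truth counters (every count and every true
reaction time), so pipeline output can be checked against what was actually
generated rather than against another estimate.  The same seed always yields
a byte-identical event stream.

A small occlusion line-pressure sub-model is included: with in-line pressure
ramping at a constant rate above baseline, a fixed occlusion-alarm threshold
annunciates after (threshold - baseline)/ramp seconds, while a dynamic
(auto-offset) threshold set a fixed margin above recorded line pressure
annunciates after offset/ramp seconds — never later than the fixed setting
whenever baseline + offset <= threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .normalize import CSHL_DRUGS, CareArea, Drug
from .schema import (
    AlarmType,
    EventKind,
    PumpEvent,
    PumpModel,
    load_fixture_tables,
    quantize,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class NoAlarmError(ValueError):
    """The occlusion scenario can never reach its alarm threshold."""


# --------------------------------------------------------------------------
# Occlusion line-pressure sub-model


@dataclass(frozen=True)
class OcclusionModel:
    """Linear line-pressure ramp against fixed vs dynamic alarm thresholds.

    Units: mmHg and mmHg/s.  ``dynamic_offset`` defaults to the 30 mmHg
    auto-offset margin recommended for early occlusion detection.
    """

    baseline_line_pressure: float
    ramp_rate: float
    fixed_threshold: float
    dynamic_offset: float = 30.0


def time_to_alarm(model: OcclusionModel, mode: str) -> float:
    """Seconds from occlusion onset to alarm, quantized to 0.25 s.

    ``mode="fixed"``: pressure must climb from baseline to the fixed
    threshold.  ``mode="dynamic"``: the threshold rides a fixed offset above
    the recorded baseline, so only the offset must be climbed.
    """
    if model.ramp_rate <= 0:
        raise NoAlarmError("line pressure is not rising; the alarm never fires")
    if mode == "fixed":
        margin = model.fixed_threshold - model.baseline_line_pressure
        if margin <= 0:
            raise NoAlarmError("fixed threshold at or below baseline pressure")
    elif mode == "dynamic":
        margin = model.dynamic_offset
        if margin <= 0:
            raise NoAlarmError("non-positive dynamic offset")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return quantize(margin / model.ramp_rate)


# --------------------------------------------------------------------------
# Reaction-time model


@dataclass(frozen=True)
class ReactionModel:
    """Contaminated lognormal clinician reaction-time model.

    Draws are lognormal(mu, sigma) in log-seconds; with probability
    ``p_outlier`` a draw is multiplied by ``outlier_scale`` to reproduce the
    extreme delayed-response outliers seen in practice (maxima tens of times
    the median).  Draws are clamped to >= 0.25 s and quantized to 0.25 s.
    """

    mu: float = 2.86          # log-seconds; exp(mu) ~ 17.5 s median
    sigma: float = 0.9
    p_outlier: float = 0.02
    outlier_scale: float = 10.0

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("reaction sigma must be > 0")
        if not 0 <= self.p_outlier <= 1:
            raise ConfigError("p_outlier must be in [0, 1]")
        if self.outlier_scale < 1:
            raise ConfigError("outlier_scale must be >= 1")

    def mean(self) -> float:
        """Closed-form mean of the contaminated draw (before quantization)."""
        base = float(np.exp(self.mu + self.sigma**2 / 2))
        return base * ((1 - self.p_outlier) + self.p_outlier * self.outlier_scale)

    def median(self) -> float:
        """Median of the uncontaminated component, exp(mu)."""
        return float(np.exp(self.mu))


def sample_reaction_time(model: ReactionModel, rng: np.random.Generator) -> float:
    model.validate()
    draw = float(rng.lognormal(model.mu, model.sigma))
    if rng.random() < model.p_outlier:
        draw *= model.outlier_scale
    return max(0.25, quantize(draw))


# --------------------------------------------------------------------------
# Simulation configuration


def _as_prob_vector(mix: Mapping, enum_cls) -> dict:
    out = {enum_cls(k): float(v) for k, v in mix.items()}
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"probability vector sums to {total!r}, not 1")
    if any(v < 0 for v in out.values()):
        raise ConfigError("negative probability")
    return out


@dataclass
class AreaConfig:
    """Generative parameters for one care area.

    ``mean_alarms_per_infusion`` / ``cshl_mean_alarms`` are the *target* raw
    alarm rates, as a log tally would count them; the generator draws primary
    alarms at rate target/(1 + p_repeat) and re-raises each with probability
    ``p_repeat`` (an immediate same-type repeat shortly after the restart), so
    the expected logged rate equals the target while repeat filtering has
    true positives to find.
    """

    care_area: CareArea
    n_infusions: int
    alarm_mix: dict[AlarmType, float]            # non-CSHL infusions
    mean_alarms_per_infusion: float
    cshl_fraction: float = 0.0
    cshl_drug_mix: dict[Drug, float] = field(default_factory=dict)
    cshl_alarm_mix: dict[AlarmType, float] = field(default_factory=dict)
    cshl_mean_alarms: float = 0.0
    reaction: ReactionModel = field(default_factory=ReactionModel)
    profile_texts: tuple[str, ...] = ()
    drug_texts: dict[Drug, tuple[str, ...]] = field(default_factory=dict)
    other_drug_texts: tuple[str, ...] = (
        "Morphine 1mg/ml", "Midazolam 50mg/50ml", "Amoxicillin 1g",
        "Ganciclovir", "TPN", "Fentanyl 50mcg/ml",
    )
    duration_median_s: float = 7200.0
    duration_sigma: float = 0.75
    p_repeat: float = 0.05
    in_library_fraction: float = 0.6739   # non-CSHL infusions; CSHL always in-library
    sp_fraction: float = 0.8              # syringe pumps per pump fleet
    infusions_per_pump: float = 10.0

    def validate(self) -> None:
        if self.n_infusions < 0:
            raise ConfigError("n_infusions must be >= 0")
        for rate in (self.mean_alarms_per_infusion, self.cshl_mean_alarms):
            if rate < 0:
                raise ConfigError("alarm rates must be >= 0")
        if not 0 <= self.cshl_fraction <= 1:
            raise ConfigError("cshl_fraction must be in [0, 1]")
        if not 0 <= self.p_repeat < 1:
            raise ConfigError("p_repeat must be in [0, 1)")
        self.alarm_mix = _as_prob_vector(self.alarm_mix, AlarmType)
        if self.cshl_fraction > 0:
            self.cshl_drug_mix = _as_prob_vector(self.cshl_drug_mix, Drug)
            self.cshl_alarm_mix = _as_prob_vector(self.cshl_alarm_mix, AlarmType)
            if not self.profile_texts:
                raise ConfigError("profile_texts must not be empty")
        self.reaction.validate()

    # -- analytic expectations used by parameter-recovery checks -----------

    def expected_alarms_per_infusion(self) -> float:
        return (
            self.cshl_fraction * self.cshl_mean_alarms
            + (1 - self.cshl_fraction) * self.mean_alarms_per_infusion
        )

    def expected_alarm_mix(self) -> dict[AlarmType, float]:
        total = self.expected_alarms_per_infusion()
        out: dict[AlarmType, float] = {}
        for t in AlarmType:
            rate = self.cshl_fraction * self.cshl_mean_alarms * self.cshl_alarm_mix.get(t, 0.0) + (
                1 - self.cshl_fraction
            ) * self.mean_alarms_per_infusion * self.alarm_mix.get(t, 0.0)
            if rate:
                out[t] = rate / total
        return out

    def expected_alarms_per_cshl_start(self, alarm_type: AlarmType) -> float:
        """Expected logged alarms of one type per CSHL infusion start."""
        return self.cshl_mean_alarms * self.cshl_alarm_mix.get(alarm_type, 0.0)


@dataclass
class SimulationConfig:
    areas: list[AreaConfig]
    seed: int = 0

    def validate(self) -> None:
        for area in self.areas:
            area.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            areas = []
            for a in raw["areas"]:
                a = dict(a)
                a["care_area"] = CareArea(a["care_area"])
                a["alarm_mix"] = {AlarmType(k): v for k, v in a.get("alarm_mix", {}).items()}
                a["cshl_alarm_mix"] = {
                    AlarmType(k): v for k, v in a.get("cshl_alarm_mix", {}).items()
                }
                a["cshl_drug_mix"] = {
                    Drug(k): v for k, v in a.get("cshl_drug_mix", {}).items()
                }
                a["drug_texts"] = {
                    Drug(k): tuple(v) for k, v in a.get("drug_texts", {}).items()
                }
                a["profile_texts"] = tuple(a.get("profile_texts", ()))
                if "other_drug_texts" in a:
                    a["other_drug_texts"] = tuple(a["other_drug_texts"])
                if "reaction" in a:
                    a["reaction"] = ReactionModel(**a["reaction"])
                areas.append(AreaConfig(**a))
            config = cls(areas=areas, seed=int(raw.get("seed", 0)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> Path:
        def _plain(obj):
            if isinstance(obj, dict):
                return {getattr(k, "value", k): _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return getattr(obj, "value", obj)

        raw = {
            "seed": self.seed,
            "areas": [_plain(asdict(a)) for a in self.areas],
        }
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
        return path


_NICU_PROFILE_TEXTS = (
    "NICU", "Neonatal", "NEONATOLOGIE", "SCBU", "SCN",
    "NICU rule of 6", "Neonates <2 kg",
)

_CSHL_DRUG_TEXTS: dict[Drug, tuple[str, ...]] = {
    Drug.ADRENALINE: ("Adrenaline 1mg/50ml", "Epinephrine", "ADRENALINE"),
    Drug.NORADRENALINE: (
        "Noradrenaline 4mg/50ml", "norepinephrine", "NORADRENALINE 0.1mg/ml",
    ),
    Drug.DOBUTAMINE: ("Dobutamine 250mg/50ml", "DOBUTamine"),
    Drug.DOPAMINE: ("Dopamine 200mg/50ml", "DOPamine"),
}


def nicu_default_config(
    n_infusions: int = 10_000,
    seed: int = 0,
    *,
    cshl_fraction: float | None = None,
    p_repeat: float = 0.05,
    reaction: ReactionModel | None = None,
) -> SimulationConfig:
    """NICU-like configuration parameterised from the embedded count tables.

    The non-CSHL alarm mix and rate are the NICU column with the four-drug
    CSHL counts removed; the CSHL mix, rate, drug mix and fraction of starts
    come from the CSHL breakdown itself.  These defaults *are* the published
    study conditions; override only to model a different unit.
    """
    fx = load_fixture_tables()
    nicu = fx.area_counts["NICU"]
    total5 = fx.cshl_counts["FOUR_DRUG_TOTAL"]

    cshl_starts = total5["infusion_starts"]
    cshl_alarm_counts = {
        AlarmType(k.upper()): v for k, v in total5.items() if k != "infusion_starts"
    }
    cshl_alarms = sum(cshl_alarm_counts.values())

    non_counts: dict[AlarmType, int] = {}
    for k, v in nicu.items():
        if k in ("total_infusion_starts", "total_alarms"):
            continue
        t = AlarmType(k.upper())
        non_counts[t] = v - cshl_alarm_counts.get(t, 0)
    non_alarms = sum(non_counts.values())
    non_starts = nicu["total_infusion_starts"] - cshl_starts

    area = AreaConfig(
        care_area=CareArea.NICU,
        n_infusions=n_infusions,
        alarm_mix={t: c / non_alarms for t, c in non_counts.items()},
        mean_alarms_per_infusion=non_alarms / non_starts,
        cshl_fraction=(
            cshl_starts / nicu["total_infusion_starts"]
            if cshl_fraction is None
            else cshl_fraction
        ),
        cshl_drug_mix={
            Drug(d): fx.cshl_counts[d]["infusion_starts"] / cshl_starts
            for d in ("ADRENALINE", "NORADRENALINE", "DOBUTAMINE", "DOPAMINE")
        },
        cshl_alarm_mix={t: c / cshl_alarms for t, c in cshl_alarm_counts.items()},
        cshl_mean_alarms=cshl_alarms / cshl_starts,
        reaction=reaction or ReactionModel(),
        profile_texts=_NICU_PROFILE_TEXTS,
        drug_texts=dict(_CSHL_DRUG_TEXTS),
        p_repeat=p_repeat,
    )
    return SimulationConfig(areas=[area], seed=seed)


# --------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Counters recorded while generating, for oracle comparisons.

    ``alarms_by_type`` counts every logged alarm including repeat re-raises;
    ``repeat_alarms`` counts the re-raises alone.  ``reaction_times`` holds
    the true (non-repeat) reaction times per area; ``cshl_reaction_times``
    restricts to CSHL episodes.
    """

    n_starts: dict[str, int] = field(default_factory=dict)
    alarms_by_type: dict[str, dict[str, int]] = field(default_factory=dict)
    repeat_alarms: dict[str, int] = field(default_factory=dict)
    cshl_starts_by_drug: dict[str, int] = field(default_factory=dict)
    cshl_alarms_by_drug_type: dict[str, dict[str, int]] = field(default_factory=dict)
    reaction_times: dict[str, list[float]] = field(default_factory=dict)
    cshl_reaction_times: dict[str, list[float]] = field(default_factory=dict)

    @property
    def total_alarms(self) -> int:
        return sum(sum(d.values()) for d in self.alarms_by_type.values())

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "n_starts": self.n_starts,
            "alarms_by_type": self.alarms_by_type,
            "repeat_alarms": self.repeat_alarms,
            "cshl_starts_by_drug": self.cshl_starts_by_drug,
            "cshl_alarms_by_drug_type": self.cshl_alarms_by_drug_type,
            "total_alarms": self.total_alarms,
            "n_reaction_times": {k: len(v) for k, v in self.reaction_times.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        return path


# --------------------------------------------------------------------------
# Event generation


def simulate_event_log(
    config: SimulationConfig,
) -> tuple[list[PumpEvent], GroundTruth]:
    """Generate a pump event log plus its ground-truth counters.

    Per infusion: an INFUSION_START with free-text profile and drug names, a
    Poisson number of alarms each followed by a RESTART after a sampled
    reaction time (with optional same-type repeat re-raises), and an
    INFUSION_STOP.  Pumps carry independent deterministic substreams derived
    from the global seed, so the stream is reproducible and unaffected by
    per-pump reordering.
    """
    config.validate()
    events: list[PumpEvent] = []
    truth = GroundTruth()

    for area_idx, area in enumerate(config.areas):
        a_name = area.care_area.value
        truth.n_starts.setdefault(a_name, 0)
        truth.alarms_by_type.setdefault(a_name, {})
        truth.repeat_alarms.setdefault(a_name, 0)
        truth.reaction_times.setdefault(a_name, [])
        truth.cshl_reaction_times.setdefault(a_name, [])
        if area.n_infusions == 0:
            continue

        non_mix_types = list(area.alarm_mix)
        non_mix_p = np.array([area.alarm_mix[t] for t in non_mix_types])
        cshl_mix_types = list(area.cshl_alarm_mix)
        cshl_mix_p = (
            np.array([area.cshl_alarm_mix[t] for t in cshl_mix_types])
            if cshl_mix_types
            else None
        )
        drug_list = list(area.cshl_drug_mix)
        drug_p = (
            np.array([area.cshl_drug_mix[d] for d in drug_list]) if drug_list else None
        )

        n_pumps = max(1, int(round(area.n_infusions / area.infusions_per_pump)))
        base = area.n_infusions // n_pumps
        remainder = area.n_infusions % n_pumps

        for pump_idx in range(n_pumps):
            n_here = base + (1 if pump_idx < remainder else 0)
            if n_here == 0:
                continue
            rng = np.random.default_rng([config.seed, area_idx, pump_idx])
            pump_id = f"{a_name}-{pump_idx:05d}"
            model = PumpModel.SP if rng.random() < area.sp_fraction else PumpModel.LVP
            t = quantize(rng.uniform(0, 3600))

            for _ in range(n_here):
                profile = str(rng.choice(area.profile_texts))
                is_cshl = bool(
                    drug_p is not None and rng.random() < area.cshl_fraction
                )
                if is_cshl:
                    drug = drug_list[int(rng.choice(len(drug_list), p=drug_p))]
                    drug_text = str(rng.choice(area.drug_texts[drug]))
                    in_library = True
                    mean_alarms = area.cshl_mean_alarms
                    mix_types, mix_p = cshl_mix_types, cshl_mix_p
                else:
                    drug = Drug.OTHER
                    in_library = bool(rng.random() < area.in_library_fraction)
                    drug_text = (
                        str(rng.choice(area.other_drug_texts)) if in_library else None
                    )
                    mean_alarms = area.mean_alarms_per_infusion
                    mix_types, mix_p = non_mix_types, non_mix_p

                start = t
                events.append(
                    PumpEvent(pump_id, model, start, EventKind.INFUSION_START,
                              None, profile, drug_text, in_library)
                )
                truth.n_starts[a_name] += 1
                if is_cshl:
                    truth.cshl_starts_by_drug[drug.value] = (
                        truth.cshl_starts_by_drug.get(drug.value, 0) + 1
                    )

                duration = quantize(
                    rng.lognormal(np.log(area.duration_median_s), area.duration_sigma)
                )
                k = int(rng.poisson(mean_alarms / (1 + area.p_repeat)))
                offsets = np.sort(rng.uniform(0, duration, size=k))
                drawn = (
                    [mix_types[i] for i in rng.choice(len(mix_types), size=k, p=mix_p)]
                    if k
                    else []
                )

                def _record_alarm(alarm_type: AlarmType, ta: float, repeat: bool) -> float:
                    """Emit ALARM + RESTART, book counters; returns restart time."""
                    reaction = sample_reaction_time(area.reaction, rng)
                    tr = quantize(ta + reaction)
                    events.append(
                        PumpEvent(pump_id, model, ta, EventKind.ALARM,
                                  alarm_type, profile, drug_text, in_library)
                    )
                    events.append(
                        PumpEvent(pump_id, model, tr, EventKind.RESTART,
                                  None, profile, drug_text, in_library)
                    )
                    by_type = truth.alarms_by_type[a_name]
                    by_type[alarm_type.value] = by_type.get(alarm_type.value, 0) + 1
                    if repeat:
                        truth.repeat_alarms[a_name] += 1
                    else:
                        truth.reaction_times[a_name].append(tr - ta)
                        if is_cshl:
                            truth.cshl_reaction_times[a_name].append(tr - ta)
                    if is_cshl:
                        per_drug = truth.cshl_alarms_by_drug_type.setdefault(
                            drug.value, {}
                        )
                        per_drug[alarm_type.value] = (
                            per_drug.get(alarm_type.value, 0) + 1
                        )
                    return tr

                cur = start
                for off, alarm_type in zip(offsets, drawn):
                    ta = quantize(max(start + off, cur + 1.0))
                    cur = _record_alarm(alarm_type, ta, repeat=False)
                    if rng.random() < area.p_repeat:
                        te = quantize(cur + rng.uniform(1.0, 30.0))
                        cur = _record_alarm(alarm_type, te, repeat=True)

                stop = quantize(max(start + duration, cur + rng.uniform(10.0, 60.0)))
                events.append(
                    PumpEvent(pump_id, model, stop, EventKind.INFUSION_STOP,
                              None, profile, drug_text, in_library)
                )
                t = quantize(stop + rng.uniform(300.0, 3600.0))

    events.sort(key=lambda e: (e.pump_id, e.timestamp))
    return events, truth


def sample_occlusion_scenarios(
    n: int, rng: np.random.Generator
) -> list[OcclusionModel]:
    """Random alarmable occlusion scenarios for property checks."""
    out = []
    for _ in range(n):
        baseline = float(rng.uniform(5.0, 80.0))
        out.append(
            OcclusionModel(
                baseline_line_pressure=baseline,
                ramp_rate=float(rng.uniform(0.05, 5.0)),
                fixed_threshold=baseline + float(rng.uniform(1.0, 500.0)),
                dynamic_offset=float(rng.uniform(5.0, 60.0)),
            )
        )
    return out
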