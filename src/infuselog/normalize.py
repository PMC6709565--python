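"""Free-text normalisation: profile names -> care areas, drug names -> drugs.

Pump drug libraries let institutions free-text their profile (care-area)
names and drug entries, so the same neonatal unit may appear as "NICU",
"Neonatal", "NEONATOLOGIE" or "SCBU" and noradrenaline as "norepinephrine"
or "Noradrenaline 4mg/50ml".  Analysis requires grouping these into the four
critical-care areas (NICU, PICU, GICU, CICU) and the four critical
short half-life (CSHL) drugs (adrenaline, noradrenaline, dobutamine,
dopamine).  Matching is case-folded substring matching against configurable
stem lists (YAML), longest stem first; anything unmatched falls to
UNMAPPED / OTHER, so normalisation is total and never raises on arbitrary
text.  Glyceryl trinitrate (GTN/NTG) is deliberately not a CSHL stem and
normalises to OTHER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger("infuselog")


class CareArea(str, Enum):
    NICU = "NICU"
    PICU = "PICU"
    GICU = "GICU"
    CICU = "CICU"
    UNMAPPED = "UNMAPPED"


class Drug(str, Enum):
    ADRENALINE = "ADRENALINE"
    NORADRENALINE = "NORADRENALINE"
    DOBUTAMINE = "DOBUTAMINE"
    DOPAMINE = "DOPAMINE"
    OTHER = "OTHER"


#: The four critical short half-life drugs.
CSHL_DRUGS: tuple[Drug, ...] = (
    Drug.ADRENALINE,
    Drug.NORADRENALINE,
    Drug.DOBUTAMINE,
    Drug.DOPAMINE,
)


def _fold(text: str) -> str:
    return " ".join(str(text).casefold().split())


def _load_default_yaml() -> dict:
    text = (
        resources.files("infuselog.data")
        .joinpath("default_maps.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


class _StemMap:
    """Longest-stem-first substring matcher over case-folded stems."""

    def __init__(self, stems: Mapping[str, list[str]]):
        # (stem, label) pairs sorted by stem length descending, then stem
        self._pairs: list[tuple[str, str]] = sorted(
            ((_fold(s), label) for label, ss in stems.items() for s in ss),
            key=lambda p: (-len(p[0]), p[0]),
        )

    def match(self, text: str) -> tuple[str | None, bool]:
        """Return (label, ambiguous): the label of the longest matching stem.

        ``ambiguous`` is True when two stems of equal (maximal) length match
        but name different labels.
        """
        folded = _fold(text)
        if not folded:
            return None, False
        best_len: int | None = None
        labels: set[str] = set()
        for stem, label in self._pairs:
            if best_len is not None and len(stem) < best_len:
                break
            if stem and stem in folded:
                best_len = len(stem)
                labels.add(label)
        if not labels:
            return None, False
        if len(labels) > 1:
            return None, True
        return labels.pop(), False


@dataclass(frozen=True)
class CareAreaMap:
    """Free-text profile name -> care-area group, total via UNMAPPED."""

    _matcher: _StemMap

    @classmethod
    def from_dict(cls, stems: Mapping[str, list[str]]) -> "CareAreaMap":
        unknown = set(stems) - {a.value for a in CareArea}
        if unknown:
            raise ValueError(f"unknown care area(s) in map: {sorted(unknown)}")
        return cls(_StemMap(stems))

    @classmethod
    def default(cls) -> "CareAreaMap":
        return cls.from_dict(_load_default_yaml()["care_area_map"])

    def normalize(self, profile_text: str) -> CareArea:
        label, ambiguous = self._matcher.match(profile_text)
        if ambiguous:
            logger.warning("ambiguous profile text %r -> UNMAPPED", profile_text)
            return CareArea.UNMAPPED
        return CareArea(label) if label else CareArea.UNMAPPED


@dataclass(frozen=True)
class DrugMap:
    """Free-text drug name -> canonical CSHL drug, total via OTHER.

    Ambiguous text matching stems of two different drugs at equal length maps
    to OTHER with a warning (no tie rule exists for manual free-text review).
    """

    _matcher: _StemMap

    @classmethod
    def from_dict(cls, stems: Mapping[str, list[str]]) -> "DrugMap":
        unknown = set(stems) - {d.value for d in Drug}
        if unknown:
            raise ValueError(f"unknown drug(s) in map: {sorted(unknown)}")
        return cls(_StemMap(stems))

    @classmethod
    def default(cls) -> "DrugMap":
        return cls.from_dict(_load_default_yaml()["drug_map"])

    def normalize(self, drug_text: str | None) -> Drug:
        if drug_text is None:
            return Drug.OTHER
        label, ambiguous = self._matcher.match(drug_text)
        if ambiguous:
            logger.warning("ambiguous drug text %r -> OTHER", drug_text)
            return Drug.OTHER
        return Drug(label) if label else Drug.OTHER


@dataclass(frozen=True)
class HalfLifeTable:
    """Plasma half-life range per CSHL drug, seconds: drug -> (min, max)."""

    ranges: Mapping[Drug, tuple[float, float]]

    def __post_init__(self) -> None:
        for drug, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid half-life range for {drug}: ({lo}, {hi})")

    @classmethod
    def default(cls) -> "HalfLifeTable":
        raw = _load_default_yaml()["half_lives"]
        return cls({Drug(k): (float(v[0]), float(v[1])) for k, v in raw.items()})

    def range_for(self, drug: Drug) -> tuple[float, float]:
        return self.ranges[drug]


def load_maps(path: str | Path | None = None) -> tuple[CareAreaMap, DrugMap, HalfLifeTable]:
    """Load (care-area map, drug map, half-life table) from YAML.

    With no path, the packaged defaults are used.  A site-local YAML may
    override any of the three sections; missing sections fall back to the
    defaults.
    """
    base = _load_default_yaml()
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        base.update({k: v for k, v in override.items() if k in base})
    return (
        CareAreaMap.from_dict(base["care_area_map"]),
        DrugMap.from_dict(base["drug_map"]),
        HalfLifeTable({Drug(k): (float(v[0]), float(v[1])) for k, v in base["half_lives"].items()}),
    )


def normalize_profile(profile_text: str, care_map: CareAreaMap | None = None) -> CareArea:
    """Map a free-text profile name to its care-area group (UNMAPPED default)."""
    return (care_map or CareAreaMap.default()).normalize(profile_text)


def normalize_drug(drug_text: str | None, drug_map: DrugMap | None = None) -> Drug:
    """Map a free-text drug name to a canonical CSHL drug (OTHER default)."""
    return (drug_map or DrugMap.default()).normalize(drug_text)
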