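"""Indicator-hierarchy configuration for the E-S-A vulnerability index.

The index system has three layers: three objectives (exposure, sensitivity,
adaptability), eight elements (B1..B8) grouped under them, and the individual
indicators (C1..C23 in the reference system) carrying within-element weights
from an expert (Delphi) survey. The hierarchy ships as a YAML document; the
default configuration bundled with the package is the 23-indicator system for
highly developed islands.

Element-to-objective membership is structural: B1-B2 are exposure, B3-B4
sensitivity, B5-B8 adaptability, and the objective-level aggregation is an
equal-weight mean (fixed, not configurable, to keep assessments comparable
across study areas).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

ELEMENT_OBJECTIVE: dict[str, str] = {
    "B1": "exposure",
    "B2": "exposure",
    "B3": "sensitivity",
    "B4": "sensitivity",
    "B5": "adaptability",
    "B6": "adaptability",
    "B7": "adaptability",
    "B8": "adaptability",
}

OBJECTIVE_ELEMENTS: dict[str, tuple[str, ...]] = {
    "exposure": ("B1", "B2"),
    "sensitivity": ("B3", "B4"),
    "adaptability": ("B5", "B6", "B7", "B8"),
}

#: Vulnerability class intervals: class k is (breaks[k-1], breaks[k]], with
#: class 1 open below and class 5 open above.
DEFAULT_CLASS_BREAKS: tuple[float, ...] = (0.6, 0.7, 0.9, 1.0)

CLASS_LABELS: dict[int, str] = {
    1: "non-vulnerable",
    2: "near vulnerable",
    3: "slightly vulnerable",
    4: "moderate vulnerable",
    5: "severe vulnerable",
}

WEIGHT_SUM_TOL = 0.02  # printed weights are rounded; per-element sums may be 0.99-1.01


class ConfigError(ValueError):
    """Invalid indicator hierarchy or run configuration."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator of the hierarchy.

    ``polarity`` states how the raw value relates to vulnerability: for a
    negative indicator larger raw values mean a more vulnerable system and the
    standardized score is C/S; for a positive indicator it is S/C. ``weight``
    is the within-element Delphi weight. ``spatial_mode`` distinguishes
    spatially heterogeneous layers from island-wide constants. The standard
    value S is either fixed in the config or the regional mean of the raw
    layer over the study area.
    """

    id: str
    name: str
    element_id: str
    objective: str
    polarity: str
    weight: float
    spatial_mode: str = "heterogeneous"
    standard_rule: str = "regional_mean"
    standard_value: float | None = None

    def __post_init__(self) -> None:
        if self.element_id not in ELEMENT_OBJECTIVE:
            raise ConfigError(f"{self.id}: unknown element {self.element_id!r}")
        if self.objective != ELEMENT_OBJECTIVE[self.element_id]:
            raise ConfigError(
                f"{self.id}: element {self.element_id} belongs to "
                f"{ELEMENT_OBJECTIVE[self.element_id]!r}, not {self.objective!r}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ConfigError(f"{self.id}: polarity must be positive|negative")
        if not 0 < self.weight <= 1:
            raise ConfigError(f"{self.id}: weight must lie in (0, 1]")
        if self.spatial_mode not in ("uniform", "heterogeneous"):
            raise ConfigError(f"{self.id}: spatial_mode must be uniform|heterogeneous")
        if self.standard_rule not in ("fixed", "regional_mean"):
            raise ConfigError(f"{self.id}: standard_rule must be fixed|regional_mean")
        if self.standard_rule == "fixed" and (
            self.standard_value is None or not self.standard_value > 0
        ):
            raise ConfigError(f"{self.id}: fixed standard_rule needs a positive standard_value")


@dataclass
class IndexConfig:
    """The full hierarchy plus the five vulnerability class intervals."""

    indicators: list[IndicatorSpec]
    class_breaks: tuple[float, ...] = DEFAULT_CLASS_BREAKS

    def __post_init__(self) -> None:
        ids = [s.id for s in self.indicators]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate indicator ids")
        if list(self.class_breaks) != sorted(self.class_breaks) or len(
            set(self.class_breaks)
        ) != len(self.class_breaks):
            raise ConfigError("class breaks must be strictly increasing")
        for eid, specs in self.by_element().items():
            total = sum(s.weight for s in specs)
            if abs(total - 1.0) > WEIGHT_SUM_TOL:
                raise ConfigError(
                    f"element {eid}: weights sum to {total:.3f}, outside 1 +/- {WEIGHT_SUM_TOL}"
                )

    def by_element(self) -> dict[str, list[IndicatorSpec]]:
        out: dict[str, list[IndicatorSpec]] = {}
        for s in self.indicators:
            out.setdefault(s.element_id, []).append(s)
        return out

    def get(self, indicator_id: str) -> IndicatorSpec:
        for s in self.indicators:
            if s.id == indicator_id:
                return s
        raise KeyError(indicator_id)


def _spec_from_mapping(m: dict) -> IndicatorSpec:
    try:
        return IndicatorSpec(
            id=str(m["id"]),
            name=str(m.get("name", m["id"])),
            element_id=str(m["element"]),
            objective=str(m.get("objective", ELEMENT_OBJECTIVE.get(str(m["element"]), ""))),
            polarity=str(m["polarity"]),
            weight=float(m["weight"]),
            spatial_mode=str(m.get("spatial_mode", "heterogeneous")),
            standard_rule=str(m.get("standard_rule", "regional_mean")),
            standard_value=(None if m.get("standard_value") is None else float(m["standard_value"])),
        )
    except KeyError as exc:
        raise ConfigError(f"indicator block missing field {exc}") from exc


def load_index_config(source: str | Path | dict) -> IndexConfig:
    """Load an :class:`IndexConfig` from a YAML file path or a parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict) or "indicators" not in doc:
        raise ConfigError("configuration must be a mapping with an 'indicators' list")
    indicators = [_spec_from_mapping(m) for m in doc["indicators"]]
    breaks = tuple(float(b) for b in doc.get("class_breaks", DEFAULT_CLASS_BREAKS))
    return IndexConfig(indicators, breaks)


def default_index_config() -> IndexConfig:
    """The bundled 23-indicator system for highly developed islands."""
    ref = importlib.resources.files("islevi").joinpath("data/island_indicators.yaml")
    return load_index_config(yaml.safe_load(ref.read_text()))


def warn_weight_renormalization(element_id: str, total: float) -> None:
    if abs(total - 1.0) > 1e-9:
        warnings.warn(
            f"element {element_id}: weights sum to {total:.3f}; renormalizing to 1",
            stacklevel=3,
        )
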