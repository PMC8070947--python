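"""Three-level discretization feeding the conditional-probability stage.

The conditional-probability analysis works on categorical states, so each
continuous layer (the standardized indicator scores and the final IEVI) is cut
into a small number of ordered levels. The default rule splits at 0.6 and 0.7
(level 1 below 0.6, level 2 in [0.6, 0.7), level 3 at or above 0.7); soil
environmental quality uses its own narrow band with breaks at 0.24 and 0.25.
Intervals are left-closed/right-open, so a value exactly on a break belongs to
the upper level.

This 3-level result scale is distinct from the five reporting classes of the
vulnerability index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import CategoricalRaster, Raster


@dataclass(frozen=True)
class LevelingRule:
    """Ordered thresholds cutting one variable into ``len(breaks) + 1`` states."""

    variable_id: str
    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "breaks", tuple(float(b) for b in self.breaks))
        if len(self.breaks) < 1:
            raise ValueError("a leveling rule needs at least one break")
        if list(self.breaks) != sorted(set(self.breaks)):
            raise ValueError(f"{self.variable_id}: breaks must be strictly increasing")

    @property
    def n_states(self) -> int:
        return len(self.breaks) + 1


#: Default rule for standardized indicator layers and the assessment result.
DEFAULT_BREAKS: tuple[float, float] = (0.6, 0.7)
#: Soil environmental quality sits in a much narrower numeric band.
SOIL_BREAKS: tuple[float, float] = (0.24, 0.25)


def default_rule(variable_id: str) -> LevelingRule:
    return LevelingRule(variable_id, DEFAULT_BREAKS)


def soil_rule(variable_id: str = "soil") -> LevelingRule:
    return LevelingRule(variable_id, SOIL_BREAKS)


def discretize(values: Raster, rule: LevelingRule) -> CategoricalRaster:
    """Cut a continuous layer into ordered states; invalid cells stay invalid."""
    levels = np.searchsorted(np.asarray(rule.breaks), values.values, side="right") + 1
    levels = np.where(values.valid, levels, 1).astype(np.int32)
    return CategoricalRaster(values.grid, levels, rule.n_states, values.valid.copy())
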