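"""Synthetic islands with the statistical structure the analysis assumes.

No public rasters accompany the reference assessment, so end-to-end behaviour
is exercised on generated scenarios: an island land mask (union of ellipses)
inside a surrounding sea ring, spatially autocorrelated continuous indicator
fields, island-wide-constant adaptability indicators, and a *latent
vulnerability field* to which designated indicators are tied by a monotone
link of configurable strength. The latent field is the generator's ground
truth for recovery tests; it is never handed to the analysis.

Construction of a heterogeneous field: white noise is smoothed with a
moving-average kernel of the stated correlation length, z-scored over the
study area, blended with the (z-scored) latent field as

    z = sign * link * latent + sqrt(1 - link^2) * noise,

then rescaled to the requested mean and noise scale. ``sign`` is +1 for
negative-polarity indicators (high latent vulnerability -> high raw value)
and -1 for positive ones. Link strength 0 gives empirical independence from
the latent field; 1 gives a deterministic monotone link. Fields are shifted
up to a small positive floor if needed so standardization ratios are always
defined.

Everything is bit-reproducible given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .config import IndexConfig, IndicatorSpec
from .discretize import LevelingRule, SOIL_BREAKS, default_rule
from .grid import Grid, Raster, RegionMask, buffer_mask


@dataclass(frozen=True)
class Ellipse:
    """Island outline: center (map meters), semi-axes (meters), rotation (radians)."""

    cx: float
    cy: float
    a: float
    b: float
    rotation: float = 0.0


@dataclass(frozen=True)
class FieldSpec:
    """One heterogeneous indicator field of a scenario.

    ``corr_length`` is the moving-average window in cells (1 = no smoothing);
    ``link`` in [0, 1] ties the field monotonically to the latent
    vulnerability field.
    """

    mean: float
    noise_scale: float
    corr_length: int = 4
    link: float = 0.0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if not self.noise_scale > 0:
            raise ValueError("noise_scale must be positive")
        if not 0 <= self.link <= 1:
            raise ValueError("link strength must lie in [0, 1]")
        if self.corr_length < 1:
            raise ValueError("corr_length must be >= 1 cell")


@dataclass(frozen=True)
class IslandScenario:
    seed: int
    grid: Grid
    ellipses: tuple[Ellipse, ...]
    fields: dict[str, FieldSpec]
    uniform_values: dict[str, float] = field(default_factory=dict)
    buffer_distance: float = 1000.0
    latent_corr_length: int = 6
    positive_floor: float = 0.01

    def with_seed(self, seed: int) -> "IslandScenario":
        return replace(self, seed=seed)


def _rasterize_ellipses(grid: Grid, ellipses: tuple[Ellipse, ...]) -> np.ndarray:
    x, y = grid.cell_centers()
    member = np.zeros(grid.shape, dtype=bool)
    for e in ellipses:
        dx, dy = x - e.cx, y - e.cy
        u = dx * np.cos(e.rotation) + dy * np.sin(e.rotation)
        v = -dx * np.sin(e.rotation) + dy * np.cos(e.rotation)
        member |= (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
    return member


def generate_island(scenario: IslandScenario) -> tuple[RegionMask, RegionMask]:
    """Land mask (rasterized ellipse union) and study area (land + buffer ring)."""
    grid = scenario.grid
    for e in scenario.ellipses:
        half_w = grid.n_cols * grid.cell_size / 2
        half_h = grid.n_rows * grid.cell_size / 2
        center = (grid.origin[0] + half_w, grid.origin[1] - half_h)
        if (
            abs(e.cx - center[0]) + max(e.a, e.b) > half_w
            or abs(e.cy - center[1]) + max(e.a, e.b) > half_h
        ):
            raise ValueError(f"ellipse {e} extends outside the grid")
    land = RegionMask(grid, _rasterize_ellipses(grid, scenario.ellipses))
    if land.n_member == 0:
        raise ValueError("ellipses rasterized to an empty land mask")
    study = buffer_mask(land, scenario.buffer_distance)
    return land, study


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], corr_length: int) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr_length > 1:
        noise = ndimage.uniform_filter(noise, size=corr_length, mode="reflect")
    return noise


def _zscore(a: np.ndarray, sel: np.ndarray) -> np.ndarray:
    mu, sd = a[sel].mean(), a[sel].std()
    if sd == 0:
        raise ValueError("degenerate (constant) field; increase grid size")
    return (a - mu) / sd


def generate_fields(
    scenario: IslandScenario,
) -> tuple[dict[str, Raster], Raster]:
    """Raw indicator fields plus the latent vulnerability field.

    Heterogeneous fields are returned per the scenario's field specs; uniform
    indicators are materialized as constant rasters. All layers are valid
    exactly on the study-area mask.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = scenario.grid
    _, study = generate_island(scenario)
    sel = study.member
    latent = _zscore(_smooth_noise(rng, grid.shape, scenario.latent_corr_length), sel)

    out: dict[str, Raster] = {}
    for name in sorted(scenario.fields):  # fixed draw order => determinism
        spec = scenario.fields[name]
        eps = _zscore(_smooth_noise(rng, grid.shape, spec.corr_length), sel)
        sign = 1.0 if spec.polarity == "negative" else -1.0
        z = sign * spec.link * latent + np.sqrt(1.0 - spec.link**2) * eps
        values = spec.mean + spec.noise_scale * z
        lo = values[sel].min()
        if lo < scenario.positive_floor:
            values = values + (scenario.positive_floor - lo)
        values = np.where(sel, values, np.nan)
        out[name] = Raster(grid, values, sel.copy())
    for name, value in scenario.uniform_values.items():
        vals = np.where(sel, float(value), np.nan)
        out[name] = Raster(grid, vals, sel.copy())
    latent_r = Raster(grid, np.where(sel, latent, np.nan), sel.copy())
    return out, latent_r


@dataclass
class SyntheticIsland:
    """A fully generated scenario: masks, raw fields, and the hidden truth."""

    scenario: IslandScenario
    land: RegionMask
    study_area: RegionMask
    fields: dict[str, Raster]
    latent: Raster


def simulate(scenario: IslandScenario) -> SyntheticIsland:
    land, study = generate_island(scenario)
    fields, latent = generate_fields(scenario)
    return SyntheticIsland(scenario, land, study, fields, latent)


# ---------------------------------------------------------------------------
# Presets

#: Indicator ids of the five heterogeneous layers analysed downstream.
HETEROGENEOUS_IDS = ("steep_slope", "land_development", "npp", "groundwater", "soil")
#: The two indicators planted as key drivers in the "two_islands" preset.
PLANTED_KEYS = ("steep_slope", "npp")

_UNIFORM_ADAPTABILITY = {
    "self_regulation": 0.18,
    "social_support": 0.97,
    "environmental_protection": 0.98,
    "management": 0.40,
}

_BASE_GRID = Grid(64, 64, 100.0, origin=(0.0, 6400.0), crs_label="synthetic-utm")
_TWO_ELLIPSES = (
    Ellipse(2200.0, 4300.0, 1100.0, 800.0, 0.4),
    Ellipse(4300.0, 2200.0, 1300.0, 900.0, -0.3),
)


def _preset_fields(key_link: float, other_link: float) -> dict[str, FieldSpec]:
    # Noise scales keep every field comfortably positive (mean - 5 sd > floor),
    # so the positivity safety net never shifts a preset distribution.
    return {
        "steep_slope": FieldSpec(0.5, 0.10, 4, key_link),
        "land_development": FieldSpec(0.5, 0.10, 4, other_link),
        "npp": FieldSpec(0.5, 0.10, 4, key_link),
        "groundwater": FieldSpec(0.5, 0.10, 4, other_link),
        "soil": FieldSpec(0.18, 0.03, 4, other_link),
    }


def scenario_presets(seed: int = 0) -> dict[str, IslandScenario]:
    """Named study scenarios.

    ``two_islands``
        Two elliptical islands on a 64 x 64 grid of 100 m cells with a 1 km
        sea buffer; five heterogeneous indicators plus four island-wide
        adaptability constants. Steep-slope proportion and NPP are strongly
        linked (0.95) to the latent vulnerability field, the rest weakly
        (0.1), planting those two as the recoverable key indicators.
    ``independent``
        Same layout with every link strength 0.
    ``deterministic``
        Same layout with every link strength 1 (all fields are monotone
        transforms of the latent field).
    """
    common = dict(
        grid=_BASE_GRID,
        ellipses=_TWO_ELLIPSES,
        uniform_values=dict(_UNIFORM_ADAPTABILITY),
        buffer_distance=1000.0,
        latent_corr_length=6,
    )
    return {
        "two_islands": IslandScenario(seed=seed, fields=_preset_fields(0.95, 0.1), **common),
        "independent": IslandScenario(seed=seed, fields=_preset_fields(0.0, 0.0), **common),
        "deterministic": IslandScenario(seed=seed, fields=_preset_fields(1.0, 1.0), **common),
    }


def synthetic_index_config() -> IndexConfig:
    """Reduced indicator hierarchy matching the preset field set.

    One heterogeneous indicator per exposure/sensitivity element (two for
    environmental conditions) with a fixed standard value of 0.75, plus one
    uniform indicator per adaptability element standardized against 1.0 so
    the element scores equal the configured constants.
    """
    s = 0.75
    mk = lambda id_, elem, w, mode, std: IndicatorSpec(  # noqa: E731
        id=id_,
        name=id_.replace("_", " "),
        element_id=elem,
        objective={"B1": "exposure", "B2": "exposure", "B3": "sensitivity", "B4": "sensitivity"}.get(
            elem, "adaptability"
        ),
        polarity="negative",
        weight=w,
        spatial_mode=mode,
        standard_rule="fixed",
        standard_value=std,
    )
    return IndexConfig(
        [
            mk("steep_slope", "B1", 1.0, "heterogeneous", s),
            mk("land_development", "B2", 1.0, "heterogeneous", s),
            mk("npp", "B3", 1.0, "heterogeneous", s),
            mk("groundwater", "B4", 0.5, "heterogeneous", s),
            mk("soil", "B4", 0.5, "heterogeneous", s),
            mk("self_regulation", "B5", 1.0, "uniform", 1.0),
            mk("social_support", "B6", 1.0, "uniform", 1.0),
            mk("environmental_protection", "B7", 1.0, "uniform", 1.0),
            mk("management", "B8", 1.0, "uniform", 1.0),
        ]
    )


def synthetic_leveling_rules() -> dict[str, LevelingRule]:
    """Three-level rules for the preset stack: defaults plus the soil band."""
    rules = {name: default_rule(name) for name in HETEROGENEOUS_IDS}
    rules["soil"] = LevelingRule("soil", SOIL_BREAKS)
    rules["result"] = default_rule("result")
    return rules
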