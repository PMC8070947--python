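"""End-to-end orchestration of the four analysis stages on one raster stack.

Stage order mirrors the assessment workflow: (1) E-S-A index computation on
the raw stack, (2) three-level discretization of the standardized indicator
layers and the result, (3) pairwise probability graph, conditional/optimal
state subsets and their spatial matches, (4) entropy-difference key-indicator
ranking and tiered promotion regions.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import bayes, entropy, index, promotion
from .config import IndexConfig
from .discretize import LevelingRule, discretize as _discretize
from .grid import CategoricalRaster, Raster, RegionMask
from .synthetic import (
    HETEROGENEOUS_IDS,
    PLANTED_KEYS,
    IslandScenario,
    simulate,
    synthetic_index_config,
    synthetic_leveling_rules,
)


@dataclass
class AnalysisResult:
    """Everything the four stages compute for one study area."""

    assessment: index.AssessmentResult
    states: dict[str, CategoricalRaster]  # discretized indicators
    result_states: CategoricalRaster
    graph: bayes.ProbabilityGraph
    css: dict[int, bayes.StateSubset]
    optimal: bayes.StateSubset
    css_masks: dict[int, RegionMask]
    entropy_report: entropy.EntropyReport
    promotion: promotion.PromotionResult


def analyze(
    raw: dict[str, Raster | float],
    cfg: IndexConfig,
    domain: RegionMask,
    leveling_rules: dict[str, LevelingRule],
    bn_variables: list[str],
    key_threshold: float = entropy.DEFAULT_KEY_THRESHOLD,
    zones: CategoricalRaster | None = None,
) -> AnalysisResult:
    """Run the full analysis.

    ``bn_variables`` names the standardized indicator layers entering the
    probability graph; each needs a leveling rule (as does ``result``, the
    discretized vulnerability index).
    """
    assessment = index.assess(raw, cfg, domain)
    states = {v: _discretize(assessment.rc[v], leveling_rules[v]) for v in bn_variables}
    result_states = _discretize(assessment.ievi, leveling_rules["result"])
    stack = dict(states)
    stack["result"] = result_states
    graph = bayes.build_probability_graph(stack, "result", domain)

    css: dict[int, bayes.StateSubset] = {}
    css_masks: dict[int, RegionMask] = {}
    for level in range(1, result_states.n_states + 1):
        if graph.marginals["result"][level - 1] == 0:
            continue
        css[level] = bayes.conditional_state_subset(graph, level)
        css_masks[level] = bayes.match_subset(states, css[level], domain)
    optimal = bayes.optimal_state_subset(graph, 1)

    report = entropy.rank_key_indicators(result_states, states, domain, key_threshold)
    # Promotion works on the strongest pair of indicators; fall back to the
    # two best-ranked when fewer than two clear the threshold.
    keys = report.key_indicators
    if len(keys) < 2:
        keys = list(report.table["indicator"].head(2))
    rules = promotion.derive_promotion_rules(graph, keys)
    promo = promotion.promotion_regions(states, result_states, rules, domain, zones=zones)
    return AnalysisResult(
        assessment,
        states,
        result_states,
        graph,
        css,
        optimal,
        css_masks,
        report,
        promo,
    )


def analyze_scenario(
    scenario: IslandScenario, key_threshold: float = entropy.DEFAULT_KEY_THRESHOLD
) -> tuple[AnalysisResult, "SyntheticContext"]:
    """Generate a synthetic island and run the full analysis on it."""
    island = simulate(scenario)
    raw: dict[str, Raster | float] = dict(island.fields)
    result = analyze(
        raw,
        synthetic_index_config(),
        island.study_area,
        synthetic_leveling_rules(),
        list(HETEROGENEOUS_IDS),
        key_threshold=key_threshold,
    )
    return result, SyntheticContext(island, PLANTED_KEYS)


@dataclass
class SyntheticContext:
    island: "object"
    planted_keys: tuple[str, ...]
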