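"""Spatial-pattern promotion regions from key-indicator state subsets.

A cell is worth prioritizing for management when its *key indicators* already
sit in the states most favourable to a good vulnerability outcome while its
assessed vulnerability has not reached that outcome:

* first-level promotion: the cell satisfies the first-level state subset of
  the key indicators (the optimal subset restricted to them) but the result
  is not level 1. If the strict subset matches nothing, a relaxed fallback
  subset (each required state widened to include the next level, e.g. {1} ->
  {1 | 2}) is applied instead, and the rule provenance is recorded.
* second-level promotion: the cell satisfies the second-level subset (the
  CSS of result level 2 restricted to the keys) but the result is level 3.
  Second-level cells exclude any first-level cells, so the two reported areas
  are disjoint tiers.

Areas are accounted exactly in hectares (cell count x cell_size^2 / 10^4),
optionally split by a zone layer (e.g. per island).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import (
    ProbabilityGraph,
    StateSubset,
    conditional_state_subset,
    match_subset,
    optimal_state_subset,
)
from .grid import CategoricalRaster, RegionMask, require_aligned


@dataclass
class PromotionRuleSet:
    """Tiered state subsets over the key indicators plus result conditions."""

    first_level: StateSubset
    second_level: StateSubset
    fallback_first_level: StateSubset | None = None
    first_requires_result_not: int = 1
    second_requires_result: int = 3


@dataclass
class PromotionResult:
    first_mask: RegionMask
    second_mask: RegionMask
    areas: pd.DataFrame  # columns: tier, zone, hectares, rule_provenance
    rule_provenance: str  # 'strict' or 'fallback'


def derive_promotion_rules(
    g: ProbabilityGraph,
    key_indicators: list[str],
    second_css_level: int = 2,
    relax_by: int = 1,
) -> PromotionRuleSet:
    """Build the tiered rules from the probability graph and the key set.

    The first-level subset is the optimal state subset (target result 1)
    restricted to the key indicators; the fallback widens each of its states
    by ``relax_by`` adjacent levels. The second-level subset is the CSS of
    result level ``second_css_level`` restricted to the keys.
    """
    optimal = optimal_state_subset(g, 1).restricted_to(key_indicators, "first level")
    fallback = optimal.relaxed(relax_by, g.n_states)
    second = conditional_state_subset(g, second_css_level).restricted_to(
        key_indicators, "second level"
    )
    return PromotionRuleSet(optimal, second, fallback)


def region_area(mask: RegionMask, zones: CategoricalRaster | None = None):
    """Area of a mask in hectares; with ``zones``, a per-zone breakdown.

    Exact accounting: member-cell count times cell_size^2 / 10^4. The zone
    split sums to the total by construction.
    """
    cell_ha = mask.grid.cell_size**2 / 1e4
    if zones is None:
        return mask.n_member * cell_ha
    require_aligned(mask.grid, zones.grid)
    sel = mask.member & zones.valid
    counts = np.bincount(zones.levels[sel], minlength=zones.n_states + 1)[1:]
    labels = zones.labels or {}
    return pd.DataFrame(
        {
            "zone": [labels.get(z, str(z)) for z in range(1, zones.n_states + 1)],
            "hectares": counts * cell_ha,
        }
    )


def promotion_regions(
    stack: dict[str, CategoricalRaster],
    result: CategoricalRaster,
    rules: PromotionRuleSet,
    domain: RegionMask,
    zones: CategoricalRaster | None = None,
) -> PromotionResult:
    """Identify the two promotion tiers and account their areas."""
    missing = [v for v in rules.first_level.assignments if v not in stack]
    missing += [v for v in rules.second_level.assignments if v not in stack]
    if missing:
        raise KeyError(f"missing key indicator layers {sorted(set(missing))}")
    require_aligned(domain.grid, result.grid)

    not_level = rules.first_requires_result_not
    needs_promotion = result.valid & (result.levels != not_level)
    first = match_subset(stack, rules.first_level, domain)
    first_member = first.member & needs_promotion
    provenance = "strict"
    if not first_member.any() and rules.fallback_first_level is not None:
        fallback = match_subset(stack, rules.fallback_first_level, domain)
        first_member = fallback.member & needs_promotion
        provenance = "fallback"
    first_mask = RegionMask(domain.grid, first_member)

    second = match_subset(stack, rules.second_level, domain)
    second_member = (
        second.member
        & result.valid
        & (result.levels == rules.second_requires_result)
        & ~first_member
    )
    second_mask = RegionMask(domain.grid, second_member)

    rows = []
    for tier, mask, prov in (
        ("first", first_mask, provenance),
        ("second", second_mask, "strict"),
    ):
        if zones is None:
            rows.append(
                {"tier": tier, "zone": "all", "hectares": region_area(mask), "rule_provenance": prov}
            )
        else:
            split = region_area(mask, zones)
            for _, r in split.iterrows():
                rows.append(
                    {
                        "tier": tier,
                        "zone": r["zone"],
                        "hectares": r["hectares"],
                        "rule_provenance": prov,
                    }
                )
    return PromotionResult(first_mask, second_mask, pd.DataFrame(rows), provenance)
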