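"""Conditional and optimal state subsets from the probability graph.

After discretizing every standardized indicator and the result into three
ordered levels, all pairwise conditional probability tables are estimated
from cell co-occurrence. The conditional state subset (CSS) of result level
r collects, per indicator, the state most probable given that result; the
optimal subset collects the states that maximize the probability of the
best result (level 1).
"""

from islevi import match_subset, region_area, scenario_presets
from islevi.pipeline import analyze_scenario

res, _ = analyze_scenario(scenario_presets(seed=1)["two_islands"])

for level, subset in res.css.items():
    states = {v: min(s) for v, s in subset.assignments.items()}
    ha = region_area(res.css_masks[level])
    print(f"CSS {level}: {states}   matched area {ha:.0f} ha")

opt = {v: min(s) for v, s in res.optimal.assignments.items()}
print(f"optimal subset: {opt}")
if res.optimal.ties:
    print(f"  ties broken toward lowest state: {res.optimal.ties}")

# A CSS describes which indicator states are characteristic of each
# vulnerability level; its matched area shows where that state combination
# actually occurs. The optimal subset is the combination most favourable to
# a level-1 (non-vulnerable) outcome.
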