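"""Rank indicators by entropy difference and identify the key drivers.

The entropy difference V(I) = |S(E,I) - S(E)| (the conditional entropy of an
indicator given the assessment result, in bits) measures how tightly each
indicator is associated with the result: smaller V = stronger association.
The scenario plants steep-slope proportion and NPP as the true drivers.
"""

from islevi import scenario_presets
from islevi.pipeline import analyze_scenario

res, ctx = analyze_scenario(scenario_presets(seed=1)["two_islands"])

print(f"result entropy S(E) = {res.entropy_report.result_entropy:.3f} bits")
print(res.entropy_report.table.to_string(index=False))
print(f"planted key indicators: {ctx.planted_keys}")
top2 = tuple(res.entropy_report.table['indicator'].head(2))
print(f"top-2 recovered:        {top2}")

# The two planted drivers occupy the smallest entropy differences. Under
# these study conditions the association floor sits near 1 bit (three-level
# partitions of result and indicator need not share boundaries), so key
# selection is by rank; the key_flag column applies the 1-bit cutoff.
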