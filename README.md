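# islevi

**Island ecological vulnerability assessment on raster stacks.**

`islevi` is a Python library for assessing the ecological vulnerability of
islands and their surrounding waters and for analysing which indicators
drive it. It is aimed at spatial ecologists and coastal-management analysts
working with gridded indicator layers (slope, land development, NPP,
groundwater/soil quality, ...) over an island plus a 1 km sea buffer.

The package implements:

* the **E-S-A index**: per-cell standardization `RC = C/S` (or `S/C` for
  positive indicators), weighted element aggregation `RB = Σ RC_i W_i`,
  equal-weight objectives `RE, RS, RA`, and the island ecological
  vulnerability index as their geometric mean,

      IEVI = (RE · RS · RA)^(1/3),

  classified into five levels (non-vulnerable ≤ 0.6 < near ≤ 0.7 < slight
  ≤ 0.9 < moderate ≤ 1.0 < severe);
* **conditional-probability analysis** on three-level discretized layers:
  the complete pairwise conditional probability tables P(Aᵢ|Bⱼ) estimated
  from cell co-occurrence, the *conditional state subsets* (per result
  level, the most probable state of each indicator) and the *optimal state
  subset* (the indicator states maximizing P(result = 1 | X = s));
* **entropy-difference key indicators**: V(I) = |S(E,I) − S(E)| = S(I|E) in
  bits; smaller V means a stronger association with the assessment result;
* **spatial promotion regions**: disjoint first/second-level management
  tiers from the key-indicator subsets, with exact hectare accounting;
* a **synthetic island generator** (ellipse islands, autocorrelated fields,
  planted monotone dependence on a latent vulnerability field) so the whole
  pipeline is testable end-to-end without external data.

Layers are single-band GeoTIFFs; a thin CLI (`islevi simulate | assess |
bn | entropy | promote`) chains the stages through files.

## Worked example

```python
from islevi import scenario_presets
from islevi.pipeline import analyze_scenario

result, ctx = analyze_scenario(scenario_presets(seed=1)["two_islands"])
print(result.assessment.fractions)
print(result.entropy_report.table)
```

prints (seed 1):

```
 state               label  cells  fraction
     1      non-vulnerable    913  0.392182
     2     near vulnerable   1270  0.545533
     3 slightly vulnerable    145  0.062285
     4 moderate vulnerable      0  0.000000
     5   severe vulnerable      0  0.000000

       indicator  joint_entropy  entropy_difference  key_flag
             npp       2.317404            1.061411     False
     steep_slope       2.346775            1.090781     False
            soil       2.575041            1.319048     False
land_development       2.714435            1.458441     False
     groundwater       2.766907            1.510914     False
```

The island-wide adaptability score is (0.18+0.97+0.98+0.40)/4 = **0.6325**,
the IEVI spans 0.446–0.814, and just over half of the study area falls in
the near-vulnerable class. The entropy table ranks indicators by strength of
association with the assessed result: the two smallest entropy differences
belong to NPP and steep-slope proportion — exactly the two indicators the
scenario ties to its latent vulnerability field, so the planted drivers are
recovered. The same run derives state subsets and maps 35 ha of first-level
and 145 ha of second-level promotion regions (see `examples/` for one short
script per capability).

Equivalent shell workflow:

```bash
islevi simulate --preset two_islands --seed 1 --out run/sim
islevi assess  --config run/sim/config.yaml --out run/assess
islevi bn      --config run/sim/config.yaml --assess-dir run/assess --out run/bn
islevi entropy --config run/sim/config.yaml --assess-dir run/assess --out run/entropy
islevi promote --config run/sim/config.yaml --assess-dir run/assess --out run/promote
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the synthetic study
conditions, and the numerical design choices (interval closures,
tie-breaking, nodata handling, the sign convention of the entropy
difference).
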