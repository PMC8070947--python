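# Methods

This note documents the models and procedures implemented in `islevi`, the
parameters that matter, the synthetic study conditions, and the numerical
choices made where the underlying methodology leaves the design open.

## The vulnerability index

Island ecological vulnerability is decomposed, following IPCC usage, into
**exposure** (external interference), **sensitivity** (susceptibility to
interference), and **adaptability** (capacity to absorb it). The index is
computed per raster cell over a study area defined as the island land plus a
1 km sea buffer (Euclidean distance between cell centers; the buffer
distance is a parameter, default 1000 m).

1. **Standardization.** Each raw indicator layer C is scored against a
   standard value S: `RC = C/S` for negative-polarity indicators (larger raw
   value = more vulnerable) and `RC = S/C` for positive ones. S is either a
   fixed constant from the configuration or the regional mean of the raw
   layer over the study area (land plus buffer — the full assessment scope;
   a different domain may be passed explicitly). `C = S` scores exactly 1
   for both polarities. Nonpositive raw values under a positive polarity are
   rejected rather than clamped.
2. **Element aggregation.** Within each of eight elements (B1 natural
   pressure, B2 human interference, B3 ecological status, B4 environmental
   conditions, B5 self-regulation, B6 social support, B7 environmental
   protection, B8 management level), `RB = sum(RC_i * W_i)` with
   expert-survey weights. Published weight tables are rounded, so per-element
   sums may be 0.99–1.01; weights are renormalized to sum exactly 1, with a
   warning, and sums further than 0.02 from 1 are rejected.
3. **Objective aggregation.** Equal weights, fixed by design for
   cross-study comparability: `RE = (RB1+RB2)/2`, `RS = (RB3+RB4)/2`,
   `RA = (RB5+RB6+RB7+RB8)/4`. Adaptability indicators are island-wide
   constants, so RA is spatially uniform; the bundled constants
   (0.18, 0.97, 0.98, 0.40) give RA = 0.6325.
4. **IEVI.** The geometric mean `IEVI = (RE * RS * RA)^(1/3)`, so
   `min(RE,RS,RA) <= IEVI <= max(RE,RS,RA)` cell-wise and any zero objective
   annihilates the cell.
5. **Classification.** Five classes with left-open/right-closed intervals:
   non-vulnerable (-inf, 0.6], near (0.6, 0.7], slight (0.7, 0.9], moderate
   (0.9, 1.0], severe (1.0, inf). The printed interval notation ("0.6~0.7")
   is ambiguous at the breakpoints; the right-closed convention matches the
   "IEVI <= 0.6" / "0.6 < IEVI <= 0.7" phrasing of the class definitions and
   is applied consistently.

Any cell invalid (nodata) in any input layer of a multi-layer operation is
invalid in the output — a conservative intersection that never fabricates
values. Cross-layer operations require exact grid alignment (shape, cell
size, origin, CRS tag); an explicit nearest-neighbour resample is available
for pre-processing, but nothing resamples implicitly, because silent
resampling corrupts categorical layers.

## Discretization for the dependence analysis

The conditional-probability and entropy stages operate on ordered states.
Standardized indicator layers and the IEVI result are cut into three levels,
default breaks {0.6, 0.7}; soil environmental quality, which occupies a much
narrower numeric band, uses {0.24, 0.25}. Intervals are
left-closed/right-open, so a value exactly on a break belongs to the upper
level. These rules apply to the standardized (RC) scale; users may bind a
rule to any layer. The 3-level result scale is distinct from the 5-class
reporting scale. No data-driven thresholding (quantiles, Jenks) is offered:
the leveling rules are part of the study design, not fitted.

## The probability graph and state subsets

Each discretized layer is a categorical variable observed per cell. Over the
cells valid in *every* layer of the stack, the package builds the complete
set of pairwise contingency tables and column-normalizes them into
conditional probability tables P(A=i | B=j); columns with zero support are
flagged undefined, never divided. Using one shared cell set makes the Bayes
identity `P(A|B)P(B) = P(B|A)P(A)` and the marginal consistency
`P(A=i) = sum_j P(A=i|B=j) P(B=j)` hold to numerical precision across all
pairs. No structure learning or inference beyond these pairwise tables is
performed — the downstream analysis uses nothing more.

* **Conditional state subset (CSS) of result level r:** per indicator X, the
  state s maximizing `P(X=s | result=r)`.
* **Optimal state subset:** per indicator X, the state s maximizing
  `P(result=1 | X=s)` (states of X with zero support are excluded).

The two directions are deliberately different: a CSS characterizes an
observed result level; the optimal subset identifies the indicator states
most favourable to the best outcome. Probability ties are broken toward the
lowest state index, deterministically, and every tie is recorded on the
returned subset. Probabilities are maximum-likelihood cell frequencies with
no smoothing.

## Entropy-difference key indicators

Association between the result E and an indicator I is scored as

    V(I) = |S(E,I) - S(E)| = S(I | E)   (base-2, 0 log 0 = 0),

the conditional entropy of the indicator given the result. `V = 0` when the
result determines the indicator; `V = S(I) <= log2(m_i)` under empirical
independence. Smaller V = stronger association; indicators with V below a
threshold (default 1 bit, configurable) are flagged key. The formulation as
a printed difference `S(E) - S(E,I)` is nonpositive (joint entropy dominates
a marginal); the absolute-value reading is the only nonnegative one
consistent with reported values above 1 bit for 3-state indicators, and is
what this package computes. Note the claimed 0–1 range of V is likewise
inconsistent with values up to log2 3 ≈ 1.585; no range clipping is applied.
A mutual-information alternative `S(E)+S(I)-S(E,I)` is available behind
`method="mutual_information"` for sensitivity checks; bias-corrected
estimators and significance tests are out of scope.

A consequence worth knowing: V is bounded above by S(I), so an indicator
with degenerate state occupancy gets a small V regardless of association.
Balanced leveling rules matter more to this statistic than to the index.

## Promotion regions

Given the key indicators, two disjoint management tiers are mapped:

* **first level** — cells matching the optimal subset restricted to the keys
  whose result is not level 1; if that strict subset matches nothing, each
  required state is widened to include the next level ({1} -> {1|2}) and the
  fallback provenance is recorded;
* **second level** — cells matching the level-2 CSS restricted to the keys
  whose result is level 3, minus any first-level cells (the tiers are
  reported as distinct priorities, so the disjoint convention is fixed here
  and documented rather than left ambiguous).

Area accounting is exact: member cells × cell_size² / 10⁴ ha, optionally
split by a categorical zone layer (e.g. per island); the split sums to the
total by construction. When fewer than two indicators clear the key
threshold, the pipeline uses the two best-ranked indicators, since the
promotion rules are defined over a key pair.

## Synthetic study conditions

The generator emulates the structure the analysis assumes, not any real
coastline: ellipse-union islands on a 64 × 64 grid of 100 m cells (a 1 km
buffer then occupies 10 cells and fits the grid with margin), five
spatially autocorrelated indicator fields, four island-wide adaptability
constants, and a latent vulnerability field that serves as ground truth for
recovery tests and is never passed to the analysis.

Heterogeneous fields are moving-average-smoothed white noise (window =
correlation length, default 4 cells; latent field 6 cells), z-scored over
the study area, blended with the latent field as
`z = sign*link*latent + sqrt(1-link²)*noise`, and rescaled to the field's
mean and noise scale. Link 1 gives a deterministic monotone transform of
the latent field (rank correlation ±1); link 0 gives empirical
independence. Kernel smoothing was chosen over exact Gaussian-process
sampling because only qualitative spatial structure is needed at desk
scale. Fields are shifted up to a 0.01 floor if they would otherwise touch
zero, purely as a safety net; preset means and noise scales (0.5 ± 0.10;
soil 0.18 ± 0.03, standard value 0.75) are chosen so the floor never binds
and the standardized scores span all three levels of the default breaks.

Presets: `two_islands` (steep-slope proportion and NPP linked at 0.95, the
other three fields at 0.1 — planting those two as recoverable key drivers),
`independent` (all links 0), `deterministic` (all links 1). Under the
`two_islands` conditions the planted keys occupy the top-2 entropy ranks in
every tested seed, while their absolute V sits near 1.06–1.13 bits: with
three-level cuts at {0.6, 0.7}, the result and indicator partitions need
not share boundaries, which leaves a conditional-entropy floor of ≈ 0.74
bits even at link 1. Key identification on these synthetic conditions is
therefore a rank statement; the 1-bit flag behaves as designed but only
triggers near determinism. What passing tests show is that the machinery
recovers planted monotone dependence; they do not show that real island
indicators are this well behaved (real layers have non-Gaussian marginals,
anisotropy, and cross-indicator dependence the generator does not emulate).

## Numerical choices and limitations

* Grid alignment uses exact integer equality and 1e-9 relative tolerance on
  floating fields; CRS labels compare verbatim.
* GeoTIFF I/O writes float64 bands with NaN nodata (bit-exact round-trips)
  and int32 bands with nodata 0 for categorical/mask layers, carrying
  ModelPixelScale/ModelTiepoint tags; reprojection and vector geometry are
  out of scope.
* CPT columns must sum to 1 within 1e-9; argmax ties are detected at 1e-12
  absolute tolerance.
* Problem sizes: the bundled scenarios run on 64 × 64 grids (≈ 2300
  study-area cells) and the recovery statistic uses 20 seeds — sizes chosen
  so the full pipeline and its validation run interactively on a laptop.
* The analysis requires pre-aligned inputs; mixing source resolutions is the
  user's responsibility via the explicit resample step.
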