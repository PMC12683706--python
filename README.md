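# escapes

Energetic resource landscapes ("E-scapes") coupled to animal-movement models.

Coastal restoration decisions increasingly hinge on whether rebuilt habitat
actually supports the food webs that wildlife depend on. This package
implements the full analysis chain for one such assessment: it maps where the
energy used by a forage fish (Gulf menhaden, *Brevoortia patronus*) is
produced across a marsh–water landscape, and then asks whether a central-place
predator (brown pelican, *Pelecanus occidentalis*) responds to that map when
it forages. It is written for movement and trophic ecologists who want the
chain — stable-isotope mixing, landscape indices, step-selection, hidden
Markov movement models — as tested, scriptable Python.

## The model chain

**1. Basal resource use (Bayesian mixing model).** Consumer tissue tracers
(δ¹³C, δ³⁴S) are modeled as a concentration-weighted mixture of three basal
sources (phytoplankton, benthic microalgae, marsh grass), corrected by
trophic enrichment factors (1.00 ± 0.63 ‰ C, 0.50 ± 0.20 ‰ S):

    μ_t(p) = Σᵢ pᵢ C_it (δ_it + TEF_t) / Σᵢ pᵢ C_it

with a Dirichlet(1,1,1) prior on the source simplex *p*, sampled by adaptive
random-walk Metropolis (split-R̂ convergence diagnostics).

**2. The E-scape.** Each source maps to a producing habitat layer: marsh
cover, marsh–water edge (boundary length × 10 m width), and water weighted by
relative chlorophyll-a. The index of energetic importance of source *i* is

    IEIᵢ = fsourceᵢ / fhabitatᵢ

calibrated at random 500 m buffers, and the habitat resource index of each
1 km landscape foraging unit *x* is

    HRI_x = Σᵢ median(IEIᵢ) · fhabitatᵢ,ₓ

so HRI = 1 is landscape-average resource production for the consumer.

**3. Movement response.** GPS fixes are segmented into complete same-day
colony-to-colony trips, rediscretized to 15 min, and turned into step series.
An integrated step-selection function compares each observed step with K = 50
control steps drawn from fitted gamma/von Mises kernels and estimates the
selection coefficient β on log(HRI) by exact conditional likelihood (the
constant-time Cox construction). A 3-state hidden Markov model (stationary /
foraging / traveling) with gamma step lengths and von Mises turns lets the
state-transition probabilities depend on log(HRI) through a multinomial-logit
link, fitted by 50-restart quasi-Newton maximization and decoded with the
Viterbi algorithm.

## Worked example

The synthetic pipeline runs the whole chain with known ground truth:

```bash
escapes run-all --outdir demo --seed 0
```

or in Python:

```python
import numpy as np
from escapes import (LandscapeConfig, make_landscape, EScapeBuilder,
                     edge_area, simulate_isotopes, IsotopeMixingModel, TEF)
from escapes.simulate import default_sources

hab, chl = make_landscape(LandscapeConfig(width=200, height=200, seed=3))
builder = EScapeBuilder(fsource=(0.68, 0.23, 0.09), n_points=200, random_state=1)
escape = builder.fit_transform((hab, chl))
print(builder.iei_table_.summary)
```

```
          source    median       q25       q75  n_points
0  phytoplankton  1.698587  1.253161  2.514098       200
1        benthic  4.435462  3.952970  5.083426       200
2          marsh  0.289869  0.244214  0.365228       200
```

Water and edge habitat carry IEI well above 1 (the consumer draws on them
disproportionately to their area) while marsh sits below 1; the resulting HRI
map averages ≈ 1 by construction (here `np.nanmean(escape.hri.values)` →
0.994). Fitting the mixing model on synthetic consumers drawn from a known
simplex recovers it:

```python
X = simulate_isotopes((0.68, 0.23, 0.09), n=200, noise_sd=0.5, seed=5).to_numpy()
model = IsotopeMixingModel(default_sources(), TEF(), random_state=7).fit(X)
print(model.summary_[["source", "mean", "sd"]])
```

```
          source     mean        sd
0  phytoplankton  0.657672  0.013486
1        benthic  0.271402  0.027634
2          marsh  0.070926  0.014582
```

Downstream, `StepSelectionFunction` reports β on log(HRI) with its SE (a β of
1.05 means an exp(1.05) ≈ 2.9-fold increase in step-choice likelihood per
unit log(HRI)), and `CovariateHMM` reports per-state step-length/turn
parameters and covariate slopes for each of the six state transitions with
95% CIs.

## Layout

| Module | Contents |
| --- | --- |
| `escapes.raster` | planar raster container, ASCII-grid text I/O |
| `escapes.habitat` | cover aggregation, edge area, relative chlorophyll, buffer fractions |
| `escapes.escape_map` | IEI calibration, HRI mapping, covariate extraction, `EScapeBuilder` |
| `escapes.mixing` | concentration-dependent mixing model, `IsotopeMixingModel` |
| `escapes.trajectory` | trip segmentation, rediscretization, steps and turns |
| `escapes.ssf` | movement kernels, control steps, `StepSelectionFunction`, RSS |
| `escapes.hmm` | covariate-transition HMM, `CovariateHMM`, Viterbi, transition curves, foraging overlap |
| `escapes.simulate` | synthetic landscapes, isotopes and tracks with ground truth |
| `escapes.scenarios` | parameter-recovery benchmark studies |
| `escapes.pipeline`, `escapes.cli` | staged runner, run manifest, `escapes` CLI |

See `docs/methods.md` for modeling assumptions, defaults and limitations.
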