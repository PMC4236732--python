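# chlamydoe

Design-of-experiments and two-round response-surface regression for the
bioenergetics of *Chlamydomonas reinhardtii*.

## The problem

How do light, carbon and inorganic nitrogen sources jointly shape algal
respiration and photosynthesis?  Screening them one at a time misses
interactions and quadratic saturation; a planned design over all five
culture factors — light irradiance (0–200 µmol photons m⁻² s⁻¹), acetate
(0–1 g L⁻¹), CO₂ (ordinal: 0.035 % air vs 1.5 % enrichment), nitrate
(0–20 mM) and ammonium (0–15 mM) — lets a single 42-run experiment
estimate every linear, quadratic and pairwise-interaction effect on six
bioenergetic responses: dark cellular respiration (CR), the apparent
maximal activities of the cytochromial and alternative respiratory
pathways (MA_CYT, MA_ALT), and the PSII quantum yield, non-photochemical
quenching and gross O₂ evolution under saturating light (ΦPSII₈₀₀,
NPQ₈₀₀, P₈₀₀).

`chlamydoe` is a reusable implementation of that workflow for
biostatisticians and algal physiologists: design construction, full
ANOVA-diagnosed least squares, two-round effect selection, response
simulation, and validation.

## The model

Each response is a centered second-order polynomial fitted by ordinary
least squares:

    ŷ = b₀ + Σᵢ bᵢ xᵢ + Σᵢ bᵢᵢ (xᵢ − c̄ᵢ)² + Σᵢⱼ bᵢⱼ (xᵢ − c̄ᵢ)(xⱼ − c̄ⱼ)

with c̄ the fit-sample mean of each factor.  The ordinal CO₂ factor
enters as an indicator of its high level ("extension term").  Effects
are selected in two rounds:

1. **Forward stepwise by AICc** with effect heredity (a selected
   quadratic or interaction brings its parent linear terms).
2. **Backward pruning by descending p-value**, stopped when a removal
   makes the replicate-group lack-of-fit test significant (p ≤ 0.05)
   or drops R² below 0.60.

Fits carry the complete diagnostic battery: SS decomposition, whole
model / per-effect / lack-of-fit ANOVA, standardized β-weights, AICc,
and RMSE both in response units and as a percentage of the response's
average scale (mean − minimum).  Fitted surfaces are simulated as
single-factor profiles with closed-form quadratic optima and
interaction slices; predictive ability is quantified by 5-fold
cross-validation (MAE_CV / RMSE_CV) and against held-out measured
combinations (MAE_EV / RMSE_EV).

The six second-round response equations ship as a structured registry
(`chlamydoe.load_published_models()`), together with the eight measured
validation combinations.

## Worked example

```python
import chlamydoe as c
from chlamydoe.simulate import NoiseModel, generate_responses

factors = c.table1_factors()                       # the 5 culture factors
design = c.build_design(factors, seed=0)           # 42 runs, 7 center points
models = c.load_published_models()                 # the 6 response equations
resp = generate_responses(design, models, NoiseModel(seed=1))

out = c.run_two_round(design, resp)                # both selection rounds
print(out["CR"].round2.summary())
```

```
Response: CR    n = 40   effects = 3
R2 = 0.6600   R2adj = 0.6316   RMSE_F = 2.9 (25% of average scale)   MAE_F = 2.194
AICc = 206.24   whole-model F(3,36) = 23.290, p = <0.0001   lack-of-fit: p = 0.4249
------------------------------------------------------------------------
effect                          coef      beta           p
ammonium                     -0.5063    -0.583    <0.0001*
acetate                        6.904     0.516    <0.0001*
light                        0.02361     0.394     0.0003*
------------------------------------------------------------------------
CR = 8.29 + 6.9*acetate - 0.506*ammonium + 0.0236*light
```

Respiration is fitted on the 40 runs where it could be measured; the
three retained factors say that acetate and light stimulate dark
respiration while ammonium suppresses it, with the β-weights ranking
their contributions.  Profile optima come in closed form:

```python
v = models["MA_ALT"].vertex("acetate")
print(f"MA_ALT acetate optimum: {v.location:.3f} g/L ({v.curvature})")
# MA_ALT acetate optimum: 0.623 g/L (concave)
```

A command-line interface wraps the same stages:

```sh
chlamydoe design --runs 42 --center 7 --seed 0 --out design.csv
chlamydoe simulate --design design.csv --seed 1 --out responses.csv
chlamydoe fit --design design.csv --responses responses.csv --out report/
chlamydoe profile --model MA_ALT --factor acetate --at ammonium=7.32 --out curve.csv
chlamydoe validate --mode ev
chlamydoe run --seed 0 --out bundle/        # the full pipeline
```

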