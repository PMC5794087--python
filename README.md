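# mvbocc

Multispecies co-occurrence occupancy modelling and diel activity overlap for
camera-trap data.

Camera traps on trails record when grizzly bears, black bears and human
recreationists (motorised and non-motorised) use the same network of sites.
Two questions follow: do the species *occur* at the same sites once habitat
is accounted for, and — where they do — does one species change how heavily
the other *uses* a site or *when* it is active?  `mvbocc` is a small library
plus pipeline for answering both from timestamped camera events:

* collapse events into site × species × occasion detection histories,
* fit a multivariate Bernoulli occupancy model in which both joint
  occurrence and per-occasion intensity of use respond to covariates and to
  the latent presence of other species,
* rank candidate interaction structures by WAIC,
* estimate diel activity overlap with circular kernel densities, and
* generate fully synthetic datasets with the same structure, so every stage
  is testable without field data.

It is aimed at quantitative ecologists working with multi-season-naive
(single season) camera grids.

## The model

For S species the joint latent presence vector **Z** at a site follows a
log-linear multivariate Bernoulli distribution,

    P(Z = z) ∝ exp( Σᵢ zᵢ fᵢ + Σ_{i<j} zᵢ zⱼ f_ij ),

with first-order natural parameters fᵢ = xα′αᵢ (log odds of occurring alone
relative to the all-absent state, a function of site covariates) and pairwise
natural parameters f_ij = xγ′γ_ij (log odds-ratios of co-occurrence: 0 means
independence, negative means avoidance).  For two species this is the
familiar (ψ₁₁, ψ₁₀, ψ₀₁, ψ₀₀) parameterisation with
f₁ = log(ψ₁₀/ψ₀₀), f₂ = log(ψ₀₁/ψ₀₀), f₁₂ = log(ψ₁₁ψ₀₀/ψ₀₁ψ₁₀).

Conditional on z, species i is detected in a 4-day occasion with probability
pᵢ — for trail cameras an *intensity of use* rather than a nuisance
parameter — modelled on the logit scale with site covariates plus additive
modifiers switched on by the latent presence of other species (e.g. a black
bear intensity shift where grizzly bears are present).  The site likelihood
marginalises all 2^S latent states; missing occasions contribute nothing.

Inference is Bayesian: independent standard logistic priors on every
coefficient, MCMC with multiple independent chains, split-R̂ convergence
checks, and WAIC (with the variance-form penalty) for ranking a candidate
set of interaction structures, with Akaike-style WAIC weights.

Diel activity is handled on the 24-hour circle: von Mises kernel densities
with a plug-in concentration rule, the coefficient of overlapping
Δ̂₁ = ∫ min(f̂_a, f̂_b) between two densities, and smoothed-bootstrap
confidence intervals, including present/absent site-partition comparisons.

## Worked example

```python
import mvbocc as m

# a two-species world with spatial avoidance (f12 = -0.5)
spec = m.ModelSpec(
    species=("a", "b"),
    occurrence={"a": ("const",), "b": ("const",)},
    detection={"a": ("const",), "b": ("const",)},
    pairs={("a", "b"): ("const",)},
    name="pairwise",
)
truth = m.SyntheticTruth(spec=spec, params={
    "psi[a]:const": 0.0, "psi[b]:const": 0.0,
    "psi[a~b]:const": -0.5, "p[a]:const": -0.5, "p[b]:const": -0.5,
})
sim = m.simulate_dataset(truth, n_sites=300, n_occasions=18, seed=3)
model = m.MultispeciesOccupancyModel(sim.history, sim.deployments, spec)
res = model.fit(chains=2, iterations=1000, warmup=500, seed=11)
print(res.summary().round(3))
```

prints (logit scale)

```
                 mean     sd   2.5%  97.5%   rhat
parameter
psi[a]:const    0.178  0.156 -0.128  0.491  1.008
psi[b]:const    0.312  0.148  0.019  0.606  1.005
psi[a~b]:const -0.928  0.232 -1.395 -0.469  1.001
p[a]:const     -0.513  0.043 -0.598 -0.429  1.016
p[b]:const     -0.485  0.042 -0.563 -0.401  1.004
```

The pairwise term `psi[a~b]:const` is the estimated log odds-ratio of
co-occurrence (truth −0.5; the posterior mean here, −0.93, is within its own
credible interval of the truth — single-replicate noise at 300 sites), and
`p[·]:const` are per-occasion intensity-of-use intercepts (truth −0.5 ≈
0.38 on the probability scale).  Derived quantities come from the state
probabilities:

```python
psi = m.state_probs([0.0, 0.0], {(0, 1): -0.5})
m.marginal_prob(psi, 0)           # P(species a occurs)      -> 0.445
m.conditional_prob(psi, 0, 1, 1)  # P(a | b present)          -> 0.378
```

The same objects drive the shell pipeline:

```bash
mvbocc simulate  --output-dir run --seed 7
mvbocc histories --output-dir run --events run/events.csv --deployments run/deployments.csv
mvbocc fit       --output-dir run --events run/events.csv --deployments run/deployments.csv
mvbocc rank ... ; mvbocc overlap ... ; mvbocc report ...
```

Every CSV artifact carries a `# config_hash=` stamp and `report` refuses to
collate artifacts from mismatched configurations.

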