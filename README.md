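# gsbup

Hospital-efficiency analysis with a generalized slacks-based DEA model that
handles undesirable inputs and outputs with preference weights, plus a
Malmquist productivity index built on it and a censored (Tobit) regression
second stage. Written for health-services researchers benchmarking
hospitals or hospital groups, but applicable to any panel of
decision-making units (DMUs) whose factors split into desirable inputs
(DI), undesirable inputs (UI), desirable outputs (DO) and undesirable
outputs (UO).

## The model

Each DMU consumes desirable inputs x^D and undesirable inputs x^I and
produces desirable outputs y^G and undesirable outputs y^B. A DMU's
efficiency is the optimum of the non-oriented fractional program

    min δ₀ = (Σᵢ ωᵢ αᵢ + Σₕ νₕ θₕ) / (Σₗ σₗ γₗ + Σᵣ μᵣ βᵣ)

    s.t.  Σⱼ λⱼ x^D_ij = αᵢ x^D_i0,   Σⱼ λⱼ x^I_lj = γₗ x^I_l0,
          Σⱼ λⱼ y^G_rj = βᵣ y^G_r0,   Σⱼ λⱼ y^B_hj = θₕ y^B_h0,
          Σⱼ λⱼ ∈ Γ,  λ ≥ 0,  0 ≤ α, θ ≤ 1,  β, γ ≥ 1,

where α/θ contract the factors that should shrink (DI, UO), β/γ expand the
factors that should grow (DO, UI), the preference weights satisfy
Σω + Σν = 1 and Σσ + Σμ = 1, and Γ constrains the intensity sum
(Σλ = 1, < 1 or > 1). δ₀ ∈ [0, 1], and δ₀ = 1 exactly when the DMU is
efficient — equivalently when all slacks, e.g. the input excess
s^D− = (1 − α)·x^D₀, vanish. The program is solved as a linear program via
the Charnes–Cooper transformation (HiGHS backend).

On top of the scorer the package provides:

* **Projection** of an inefficient DMU to the frontier point
  (α*·x^D, β*·y^G, γ*·x^I, θ*·y^B), which provably re-scores to δ = 1;
* **Returns-to-scale classification** from the range of Σλ* over
  alternative optima of the free-intensity solve;
* **Malmquist index** M₀ = √((δ_t(t)/δ_t(t+1)) · (δ_{t+1}(t)/δ_{t+1}(t+1)))
  with the decomposition M₀ = TEC₀ · FS₀ into own-efficiency change and
  frontier shift. In this orientation M₀ < 1 means productivity improved;
* **Tobit second stage**: maximum-likelihood censored-normal regression of
  scores on exogenous covariates, with standard errors from the observed
  information;
* **Seeded synthetic generators** with planted frontiers, frontier drift
  and known regression coefficients, so every stage is testable offline.

## Worked example

The package bundles the input–output table of the seven Hong Kong hospital
clusters in 2013 (two desirable inputs: full-time staff and beds; one
undesirable input: in-patient discharge rate; three desirable outputs:
patient-days, emergency and outpatient attendances; one undesirable
output: crude mortality rate).

```python
from gsbup import GsbupEfficiency, datasets

panel = datasets.load_cluster_panel()
est = GsbupEfficiency(gamma="crs").fit(panel)   # equal preference weights
print(est.scores_.round(4))
print(est.rts_())
```

prints

```
HKEC    0.8757
HKWC    1.0000
KCC     0.7465
KEC     1.0000
KWC     1.0000
NTEC    1.0000
NTWC    1.0000
Name: delta, dtype: float64
HKEC    IRS
HKWC    CRS
KCC     DRS
KEC     CRS
KWC     CRS
NTEC    DRS
NTWC    CRS
Name: rts, dtype: object
```

Clusters scoring 1 are on the best-practice frontier; HKEC at 0.8757 can,
per its slack vector, shed 9.7 beds, raise its discharge rate by 1.9
points and expand its three service outputs by 242/48/229 thousand units
to reach the frontier. The bundled reference table also carries the
scores and slacks published alongside this panel;
`datasets.compare_with_published()` reports where the two agree (the HKEC
slack row to all printed digits, both frontier clusters, five of seven
scale labels) and where they provably cannot (see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
gsbup worked-example --out out/
gsbup efficiency --panel panel.csv --spec spec.yml --gamma crs --out scores.csv
gsbup malmquist  --panel panel.csv --spec spec.yml --out malmquist.csv
gsbup tobit      --scores scores.csv --covariates covars.csv --out tobit.csv
gsbup simulate frontier --seed 1 --out sim/
```

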