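# Methods

## Model and assumptions

The efficiency measure is a non-oriented, slacks-based DEA model over four
factor roles. The production possibility set is spanned by intensity-weighted
combinations of the observed DMUs: desirable inputs can only be contracted
(ratio α ∈ [0, 1] per factor), undesirable outputs contracted (θ ∈ [0, 1]),
desirable outputs expanded (β ≥ 1) and undesirable inputs expanded (γ ≥ 1).
The score is the minimised ratio of the weighted contraction ratios to the
weighted expansion ratios. This presumes:

* free disposability in the role-consistent directions and convexity of the
  technology (under the Σλ = 1 regime);
* strictly positive factor values for the evaluated DMU — the ratios divide
  by its observed levels. Zeros are handled before solving (below);
* preference weights expressing managerial priorities; they scale the
  objective only, so frontier membership (δ = 1) is weight-independent.

The intensity-sum regimes follow the source model's naming: Σλ = 1 is
labelled CRS, Σλ < 1 IRS and Σλ > 1 DRS. Readers should note the naming
clash with the wider DEA literature, where the convexity constraint Σλ = 1
is normally called VRS and the unconstrained cone CRS; this package keeps
the labels exactly as the model defines them. The strict inequalities are
not LP-representable and are closed with an offset ε_Γ = 1e-9; the strict
positivity of the Charnes–Cooper scale variable t is implemented as
t ≥ 1e-6, which is inert because the transformation is scale-invariant.

## Solving

The fractional program is linearised by the Charnes–Cooper substitution and
solved with HiGHS through `scipy.optimize.linprog`. Ratio variables,
intensities and slacks are recovered by dividing by t. A solution is
declared efficient when every ratio variable is within `tol = 1e-6` of one —
a unit-free criterion equivalent to all slacks vanishing, chosen above the
solver's feasibility tolerance (~1e-7) and far below data resolution.
Consistency of the back-transformation is asserted in the tests: the
fractional objective recomputed from (α, β, γ, θ) equals the LP objective to
1e-8.

λ need not be unique at the optimum (the slacks are, given the ratios). Any
optimal λ is reported. Returns-to-scale labels therefore do not rely on the
solver's arbitrary choice: the free-intensity program is solved first, its
optimal δ* is fixed, and — because fixing the optimal value turns the
fractional objective into the linear cut num − δ*·den = 0 — minimising and
maximising Σλ over the optimal face are two plain LPs. A Σλ*-range touching
1 (tolerance 1e-6) is labelled CRS, a range entirely below 1 IRS, above 1
DRS.

Projections are computed in both equivalent forms (ratio-scaled target and
λ-weighted panel combination) and must agree to a relative 1e-5, else a
numerical error is raised.

## Mixed-period evaluations and the Malmquist index

Cross-period scores reuse the same LP with the frontier matrices from one
period and the target vectors from another. The box bounds α, θ ≤ 1 and
β, γ ≥ 1 can then be infeasible (e.g. a unit that out-produces the whole
foreign frontier). Such solves are retried once with relaxed boxes
(contractions ≤ 10, expansions ≥ 0.1) and flagged `mixed_period_relaxed`;
if still infeasible the result is flagged and the index components reported
missing. The index is composed from the four δ evaluations; M = TEC × FS
holds identically, and swapping the two panels maps M to 1/M. Because the
scores are contraction ratios, M < 1 denotes productivity improvement and
FS < 1 frontier progress — inverted relative to the output-distance
convention; interpretation strings follow this model's own convention.
Multi-period averages are geometric means (indices compose
multiplicatively), with arithmetic means reported alongside.

## Second stage

Efficiency scores are censored at 1 (and formally at 0), so the covariate
analysis uses a two-sided censored-normal likelihood with default bounds
[0, 1] — in practice only the upper bound binds for DEA scores. The
likelihood is maximised by BFGS over (β, log σ) from the least-squares
start, with analytic gradients and a Newton-CG polish if the scaled
gradient exceeds 1e-6·max(1, |ℓ|); standard errors come from the inverse
observed information in the (β, σ) parametrisation. Panel structure is
ignored: the likelihood is pooled, with no random effects. No standard
R² exists for this model; the report gives McFadden's pseudo-R² against an
intercept-only fit and the squared correlation of the linear predictor with
the observed response, labelled as such. An exactly linear response
(zero residual variance) short-circuits to the least-squares solution with
a warning, since the likelihood is then unbounded in σ.

## Synthetic data

The frontier generator plants efficient DMUs on a random hyperplane
w·(x^D, −x^I, −y^G, y^B) = 0 with strictly positive w, which supports the
convex technology, so planted-efficient units provably score 1; inefficient
units are copies of efficient ones degraded by role-consistent multipliers
(inputs inflated, desirable outputs deflated, …), so a feasible projection
to the generating point exists and the planted score gap is strict. Panels
are generated at unit scale and rescaled column-wise — legitimate because
the measure is units-invariant — by default to the mean factor levels of
the seven-cluster system in 2013 when the panel has the 2/1/3/1 layout.
Drift series scale desirable outputs by g per period, with options to
freeze individual DMUs (isolating frontier shift) or decay their own
outputs (isolating technical-efficiency change). The regression generator
draws standard-normal covariates and clips the latent response to [0, 1].
The generators reproduce first moments and the planted frontier/censoring
structure only; they make no attempt to mimic real inter-hospital
correlation, measurement error or serial dependence, so green tests show
correctness of the method, not validity of any real-world conclusion.

Problem sizes in the test suite (50 seeded panels up to n = 20 with factor
dimensions up to 2/1/3/1; regression designs up to n = 2000 with ~20%
censoring; brute-force cross-checks on panels with n ≤ 4 and total
dimension ≤ 4) were chosen so that the independent oracles — grid sweeps
with SLSQP polish of the fractional program, quadrature of the censored
likelihood — remain exhaustive at those scales.

## Zero handling and validation

Negative values always error. A DMU with all-zero inputs or all-zero
outputs errors. Zero factor values would make the ratio constraints
degenerate; the default policy substitutes 1e-3 × the factor's cross-DMU
mean (every substitution logged and returned in the validation report;
idempotent), and a `reject` policy refuses them outright. Descriptive
statistics use the sample SD (n−1), Fisher skewness and excess kurtosis —
the common statistical-software defaults; a constant column reports SD 0
and NaN higher moments with a warning.

## The bundled worked example and its published reference

The seven-cluster 2013 panel ships with the scores, slacks and scale labels
published alongside it. Reproduction succeeds exactly where the published
table is internally consistent with the cluster-level panel:

* both published frontier clusters (KEC, NTWC) score 1 with zero slacks;
* the published HKEC slack row is reproduced to all printed digits
  (0.00, 9.74, 1.89, 241.84, 48.00, 228.95, 0.00), implying δ = 0.8757;
* five of seven scale labels agree (HKEC IRS, KCC DRS, KEC CRS, NTEC DRS,
  NTWC CRS).

The remaining published scores cannot be produced by this model from the
cluster-level panel under any preference weights or intensity regime.
The sharpest case: one cluster holds the strict minimum undesirable output
(mortality 16.2 against 21.6 for the next best) and the minimum
undesirable input, so it is undominated and must score 1, yet is published
at 0.754. Moreover the λ-systems implied by four of the published slack
rows have no non-negative solution over the cluster panel, and one
published score equals the arithmetic mean of that cluster's four
hospital-level scores. The published figures therefore appear to derive
from hospital-level data that was not released with the table. The
comparison utility (`datasets.compare_with_published`) reports agreement
and disagreement row by row rather than reconciling them; the package
asserts only the weight-independent facts and its own internally
consistent solutions. The published "updated score" column (re-scoring
slack-adjusted data) is retained in the reference file but not asserted:
under the projection property every re-scored projection is exactly 1,
which the published column contradicts for three clusters.

## Known limitations

* No super-efficiency ranking, weight-restriction extensions, or bootstrap
  confidence intervals for scores.
* No circular/fixed-base Malmquist variants; no further decomposition of
  the frontier-shift term.
* The undesirable-input expansion γ ≥ 1 can project a percentage factor
  (e.g. a discharge rate) above 100%; the model imposes no cap, and none
  is added.
* Second stage: no bootstrap correction for the generated-regressor
  problem (scores are estimates), no instrumental variables.
* Composite published scale labels of the form "CRS(IRS)" have no stated
  definition; only primary labels are produced.
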