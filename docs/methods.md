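# Methods

## Model

A tumor (or metastatic lesion) grows as a continuous-time multi-type
branching process started from one cell. Every cell divides at rate *b*
and dies at rate *d* (*d* < *b*, supercritical); at each division one
daughter acquires a new passenger mutation with probability *u*
(infinite-allele model: no recurrent mutation, and passengers do not
alter *b* or *d*). The death–birth ratio δ = *d*/*b* is the extinction
probability of one cell's lineage; all frequency-domain quantities
depend on (δ, u) only, while *b* sets the clock. Mutations whose
lineages survive forever ("successful") are labelled *k* = 1, 2, … by
appearance order.

Two asymptotic facts drive the closed forms. First, the population
sizes at which successful mutations appear form, to leading order in
*u*, a Poisson process of rate *u* per unit of population size (each
unit of net growth costs 1/(1−δ) divisions, each producing a surviving
new lineage with probability u(1−δ)). Second, every surviving lineage
grows like e^{(b−d)t} times an i.i.d. exponential random factor, so the
eventual fraction of a clone that started as 1 cell among *i* surviving
competitors is Beta(1, *i*)-distributed. Mixing over the binomial number
of surviving competitors and the Poisson appearance size gives the
fixation probability ρ_k = [u/(u − ln δ)]^k, the frequency CDF
F_k(α) = 1 − [1 − ln(1 − α(1−δ))/u]^(−k), the conditional law given the
origin size z (CDF 1 − (1 − α + δα)^z), its mean
(1 − δ^{z+1})/((1−δ)(z+1)), and the ML/MAP origin-size estimators. The
expected subclonal spectrum u(1−α)/((1−δ)α) and clonal count δu/(1−δ)
follow from a first-step recursion over population size.

These are first-order results in *u*: they neglect, e.g., that nested
mutations share lineage fluctuations. The tree-probability formulas
additionally approximate "mutation *j* arises in the lineage of *i*" by
the mean eventual fraction of *i* and factorize one conditional
(P(B|A∩C) ≈ P(B|C)). Their accuracy is therefore checked empirically
against the simulator (see Validation).

## Key parameters

| parameter | meaning | default | why |
|---|---|---|---|
| b | division rate (1/day) | 0.25 | typical colorectal value; pure time scale |
| d | death rate (1/day) | — | set via δ |
| δ = d/b | death–birth ratio | study values 0.72–0.999 | fast metastases ≈ 0.72, early tumors ≈ 0.99+ |
| u | passengers per division | 0.015 | exome: 5·10⁻¹⁰ per bp × 3·10⁷ bp |
| v | prior rate for MAP origin estimate | 10⁻⁹ | per-site mutation probability |
| window | allele-fraction fit range | [0.12, 0.25] | ≥0.25 may be clonal; <0.12 under-powered at ~100× |

## Simulator

The Gillespie event loop keeps one clone label per live cell. Cells in
a clone are exchangeable, so drawing a uniformly random cell per event
is distribution-identical to size-weighted clone sampling at O(1) cost;
each event is a division with probability b/(b+d) (the daughter starting
a new clone with probability u) and a death otherwise. Waiting times are
exponential with total rate N(b+d). The kernel is numba-jitted and uses
only `np.random.random()` draws so that the pure-Python fallback
reproduces the identical MT19937 stream; one root seed deterministically
derives per-run kernel and classification seeds.

A run ends at extinction, at the stop size M, or at an explicit event
cap (outcome "truncated", never silent). Defaults: M = 5·10⁴ for
δ ≤ 0.96 and 5·10³ above, since the event count grows as
M(1+δ)/(1−δ).

**Classification at a finite stop.** Whether an extant mutation is
"successful" is resolved by drawing one eventual-survival
Bernoulli(1−δ) per live cell (the branching property makes the future
independent of the past given the present): a mutation with m carrier
cells is successful iff some carrier survives — marginally 1 − δ^m —
and fixes iff no non-carrier survives (marginally δ^{m_nc}). Using
per-cell draws rather than independent per-mutation draws keeps nested
mutations consistent (a successful descendant implies a successful
ancestor). Given the survival draws, the *eventual* cell fraction has
an exact conditional law, Beta(s_carrier, s_noncarrier), from the same
exponential-limit argument as the theory; `MutationReport.frequency` is
drawn from it. The plain carrier fraction at the stop is kept as
`observed_frequency`; at δ = 0.99 and M = 5·10³ it still carries
transient spread of order √((1+δ)/((1−δ)M)) ≈ 0.28, which the Beta draw
removes by sampling the estimand the theory actually describes.

Ensembles condition on survival (expected attempts n/(1−δ), hard-capped
at 10×) and optionally on ≥3 successful mutations for tree statistics;
topologies are classified from each mutation's nearest successful
ancestor.

## Spectrum fit

Per sample: keep ploidy ∈ [1.8, 2.2] and purity ≥ 0.70 (inclusive
bounds; missing metadata excludes with an audit reason); divide observed
allele fractions by purity (values > 0.5 flagged, retained, excluded by
the window); build the cumulative curve at each in-window fraction α_i
as #{j : α_j > α_i, α_j ≤ 0.25} (strict ">", ties therefore share
counts); fit count = a(1/α − 1/0.25) through the origin by least
squares. R² is computed about the mean of the counts (a through-origin
fit has no canonical R²; this choice is documented for
reproducibility). δ = 1 − u/(2a) for an assumed u; a < u/2 is reported
as evidence against the neutral fit rather than clamped.

**Confidence interval.** The OLS t-interval on the slope is *not* used:
cumulative counts at neighbouring fractions are strongly positively
correlated, and in repeated synthetic cohorts the t-interval covered the
true amplitude only ~24% of the time. Under the model the in-window
mutation count N is Poisson with mean a(1/lo − 1/hi), which pivots into
an exact Garwood interval for a; the reported 95% CI is that interval,
widened if necessary to bracket the LS point estimate. Measured
coverage of δ* by the mapped CI (200 synthetic replicates, depth 100,
purity 0.85, u = 0.015) is 92–98% for δ* ∈ {0.97, 0.99, 0.997}.

**Amplitude convention.** a = u/(2(1−δ)) (the diploid, allele-fraction
convention): the factor 2 converts cell fractions to allele fractions
for heterozygous diploid mutations without LOH. The published median
MSS amplitude 2.86 then maps to δ = 0.997.

## Synthetic data generator

`generate_synthetic_table` draws a Poisson number (mean
u(1−α_min)/((1−δ)α_min)) of cell fractions from the 1/α² density on
[α_min, 1] by inverse transform, halves them to allele fractions,
dilutes by purity, and observes each through Binomial(reads, af) with
Poisson read depth. Defaults chosen once: α_min = 0.05 (2.5% allele
fraction at purity 1 — near the practical detection floor), depth 100×
(typical exome), purity 0.85 (a realistic cohort average), ploidy 2.0
by construction.

It emulates: the model's exact spectrum shape and Poisson count law,
purity dilution, and binomial sequencing noise. It does not emulate:
copy-number change/LOH, sub-Poisson or locus-dependent depth, mapping or
calling artifacts, MSI hypermutation, or subclonal drivers. Passing the
end-to-end recovery tests therefore shows the *statistical pipeline* is
calibrated under the model, not that real tumors obey the model — the
published cohort re-analysis is deliberately out of scope.

With u = 0.015 the expected number of in-window mutations is
4.33·u/(2(1−δ)) ≈ 1.1 at δ = 0.97 and 3.2 at δ = 0.99, so a fraction of
replicates has < 2 points and admits no fit at all; coverage statements
are therefore over replicates that yield a valid fit (a CI is a property
of a fit that exists), and the valid-fit yield is reported alongside.

## Numerical choices

* Quadrature: `scipy.integrate.quad`, absolute tolerance 1e-10
  (1e-12 for the fixation integral), with convergence checked against
  the returned error estimate; failures raise rather than warn.
* The mean-subclonal-fraction integrals ∫α g_k dα are evaluated after
  the substitution s = −ln(1 − α(1−δ)), giving a smooth bounded
  integrand on [0, −ln δ] and taming the integrable singularity at
  α → 1 when δ = 0. The densities g_k are closed-form derivatives of
  the CDF (no numerical differentiation).
* δ = 0 is handled as an exact limit everywhere (fixation 0, clonal
  count 0); δ ≥ 1 is rejected at construction (every denominator
  carries 1−δ).
* Probabilities are clipped to [0, 1] only for overshoot below 1e-12;
  larger violations raise.
* Tree probabilities are not renormalized (the published closed forms
  sum to 100.2%, 100.0%, 99.9% at δ = 0.72, 0.96, 0.99); a normalized
  view exists but is never used in validation.
* Simulation sizes used by the test-suite ensembles: 2,000 surviving
  runs at M = 5·10⁴ (δ = 0.72) and M = 5·10³ (δ = 0.99), chosen as the
  smallest sizes at which Monte Carlo error (KS ≈ 0.03 at 2,000 runs)
  dominates finite-size effects.

## Known limitations

* All closed forms are O(u) asymptotics; at fast growth the tree
  formulas deviate from exact simulation by up to ~2 percentage points
  for the middle topologies (the same gap visible in the published
  formula-vs-simulation comparison), which exceeds 3 Monte Carlo SE at
  2,000 runs.
* No LOH/copy-number change, no drivers, no plateau phase, no spatial
  structure, no stem-cell hierarchy: the model targets neutral
  exponential expansion only.
* The successful/fixed classification at a finite stop is itself an
  operationalization (exact in its marginals, approximate in ignoring
  the unobserved future genealogy); the stop sizes above make its
  residual effects smaller than Monte Carlo error in every check
  performed.
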