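# Methods

## The model chain

The analysis treats county healthcare-seeking as a two-layer problem:
an **aggregate flow layer**, where village→township patient flows form
a weighted bipartite graph whose communities are the functional
hospital service areas (HSAs), and a **micro choice layer**, where each
village's cross-region care decision follows a random-utility model.
The edge-village construct connects the two: a village whose detected
community differs from the one anchored by its own administrative
township, and whose outflow mostly crosses the administrative border,
is functionally decoupled from its assigned service system.

## Flow network

OD records are aggregated to counts `D_ij` (village i → township j,
the township hosting the destination facility). Origins with fewer
than `min_records = 10` records are excluded before normalization to
limit small-count noise; the exclusion list is always reported. Weights
are the outflow proportions `W_ij = D_ij / Σ_j D_ij`, so every retained
row sums to one (checked to 1e-12). Proportions are the default edge
weights; raw counts are available (`weight_mode="count"`) for
sensitivity analysis, since either reading of "flow intensity" is
defensible. The directed village→township weight is attached to a
single undirected edge — origins never point at origins, so no merge
conflicts arise — because Newman–Girvan modularity is defined on
undirected graphs. A user-supplied merge map (old id → new id) applied
before aggregation stands in for the merging of small communities into
neighbouring administrative villages; no merging rule is inferred from
the data.

## Modularity and Louvain

Weighted Newman–Girvan modularity uses the convention `A_ii = 2 w_ii`
for self-loops, which makes the aggregation identity exact: collapsing
communities into super-nodes whose self-loop carries the
intra-community weight leaves Q unchanged (tested to 1e-10). The
Louvain implementation is from scratch: the local stage sweeps nodes in
sorted order shuffled by the seed, moving each node to the
neighbouring community with the largest modularity gain (ties break to
the lowest community index, so runs are reproducible); the aggregation
stage collapses communities and repeats until no level improves Q by
more than `min_gain = 1e-9`, a floating-point-safe version of "until
modularity no longer improves". All levels are recorded, so any
intermediate delineation (e.g. the partition before the last
aggregation) is addressable; the algorithm is not forced to stop after
two iterations. An exhaustive set-partition search (guarded at 12
nodes) provides the global optimum on small graphs; Louvain matches it
within 0.05 on ≥ 90% of random 4–10-node graphs and never exceeds it.

## HSA delineation and edge villages

Every community containing at least one village becomes an HSA; its
provider list splits facilities of member townships by the
in-county flag (an HSA can have no within-county provider). Two
post-processing rules place units the flow data cannot: units with
zero population join the HSA of an adjacent village (ties → lowest HSA
id, logged), and sparse villages follow the majority of their observed
flows, falling back to a user-supplied auxiliary assignment map — the
stand-in for expert knowledge of predominant care-seeking patterns —
when they have no flows at all. The operation is idempotent and fails
loudly on unassignable units.

A village is an edge village iff (a) its HSA differs from its
administrative reference — the HSA containing its township's
destination node, or, for townships without such a node (e.g. no
facility), the modal HSA of the township's own villages — and (b) its
cross-township outflow share exceeds `share_threshold = 0.5`. The
threshold operationalizes "distinct cross-region behaviour", which has
no canonical value; it is exposed as a parameter and raising it can
only remove villages (tested). Villages without observed flows are
never flagged: an edge-village verdict requires evidence. The HSA with
the largest population is labelled the super-HSA, a purely descriptive
tag.

## Indicator system

Twelve village-level indicators, grouped by whether cross-region care
reflects deliberate choice (active: travel time, facility capacity,
cross-county flag) or supply shortfall context (passive: population,
village class 1–3, share aged 60+, minority share, road distance, bus
frequency, elevation, slope, cohesion).

* **Cohesion** evaluates the printed patch formula exactly from
  (perimeter, area) pairs and the total building coverage area A; it
  is reported raw, with a warning (not clamping) outside the nominal
  [−1, 1] range, because the formula itself does not enforce the range.
  A ≤ 1 is rejected (the `(1−1/√A)^{-1}` term blows up).
* **Capacity** is the first principal factor of the standardized
  facility indicators (wage expenditure; physician, nurse and health-
  technician counts) — one factor, no rotation, sign-fixed so the
  physician loading is positive, scores standardized. Perceived
  quality and technology level are treated as absorbed by this scale
  rather than separately measured.
* **Travel time** is synthetic (Euclidean distance × seeded terrain
  multiplier ÷ 40 km/h + a 60 s access penalty) or table-driven, where
  repeated timestamped measurements are averaged after dropping values
  more than 3 MAD from the median. Village locations are
  population-weighted centroids.
* **Bus coverage** counts a village as covered when a stop lies within
  a 5-minute walk at 4.5 km/h (≈ 375 m); both are configurable.
* Elevation and slope are pass-through attributes; no DEM processing.

## Elastic net

Both penalized families are implemented directly. The linear family
minimizes `(1/2n)Σ(y−β₀−x'β)² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` by cyclic
coordinate descent with soft-thresholding; the logistic family wraps
the same solver in penalized IRLS (proximal Newton). Convergence is
declared when the largest coefficient change falls below 1e-7.
Predictors are standardized to unit variance before fitting;
coefficients are reported on the standardized scale together with each
predictor's mean and SD. `λ_max = max_j |x_j'(y−ȳ)|/(nα)` (the KKT
bound at which every slope is exactly zero; α floored at 1e-3 so the
ridge end stays finite) anchors a 50-point geometric grid down to
`1e-4 λ_max` per α, α ∈ {0, 0.1, …, 1}. Tenfold cross-validation is
seeded and stratified for binary responses; the selected pair
minimizes mean out-of-fold deviance with ties broken toward the larger
λ (parsimony). The reported out-of-sample deviance ratio is
`1 − CV deviance / null CV deviance`; commercial implementations
define this quantity differently, so it need not match them
numerically. The selection response defaults to the logistic family
with the edge-village flag, matching how such screenings are run in
practice, while the linear family implements the printed squared-error
loss verbatim; both are tested.

## Choice model

With a binary menu {non-cross-region, cross-region}, the conditional
logit reduces to a binary logit on covariate differences: utility
carries generic coefficients on the alternative-specific covariates
(travel time, capacity — the local facility's values vs the best
cross-region candidate's) and the ASC plus case-specific covariates
(cohesion, village class, population, ethnic share) on the non-base
alternative only. The default base is the non-cross-region
alternative; the `base_alternative` switch re-parameterizes (negating
ASC and case-specific coefficients, leaving the likelihood unchanged),
which resolves ambiguity about which alternative a report treats as
"mode #1" without silently choosing. Estimation is Newton–Raphson on
the analytic gradient (gradient norm < 1e-9 at the optimum), with the
covariance from the inverse observed information. Normal mixing over
chosen coefficients uses maximum simulated likelihood with scrambled
Halton draws (bases 2, 3, …; first 50 points dropped; seeded); with
the mixing SDs fixed at zero it reproduces the exact MLE to 1e-4.
Diagnostics: joint Wald test over the slopes (`β'V⁻¹β`), nested LR
test `2(ll_full − ll_reduced)`, and VIFs `1/(1−R²_k)` with perfect
collinearity flagged as infinite. The paper-style significance screen
(high p, non-significant LR, low VIF) is reported, never auto-refit.
Odds-ratio transforms `exp(β̂)` are the recommended effect-size
reading; semi-elasticity arithmetic on logit coefficients is easy to
get wrong and is deliberately not automated.

## Synthetic county generator

The generator emulates a mountainous autonomous county: 7 townships
(seeded, well-separated seeds on a 60-km plane), 8–12 villages per
township placed by Poisson scatter within township Voronoi cells, 0–2
facilities per township (a facility-less township is possible, so the
administrative reference for its villages is the modal HSA), one
larger out-of-county hospital just beyond the border, and 4,314
respondents assigned to villages proportional to population.
Destination choice follows the random-utility model with i.i.d. Gumbel
errors (the canonical logit error): travel time and capacity enter
every alternative; the ASC and the four village covariates enter
cross-township alternatives; the anchor facility (largest in-county
capacity) adds `super_hsa_pull` utility, planting the super-HSA.

Default parameters are the study conditions: the six utility
coefficients and ASC are the published point estimates for (travel
time −0.0033925 s⁻¹, capacity 0.0054233, cohesion 33.47307, village
class −1.420579, population 0.0002493, minority share 4.166709;
ASC −27.25859); covariate distributions are calibrated to the
published indicator moments (population lognormal with mean ≈ 1,897
and SD ≈ 2,233; minority share a bimodal Beta with mean 0.606 and SD
0.413; facility capacity scale N(1387, 251); travel times on the
~1,400 s scale). The 60-km county scale was chosen so the emergent
structure matches the reported study: final modularity ≈ 0.45–0.6,
roughly 16–20 edge villages among ~70, and a mean cross-county share
near 0.30.

Ground-truth labels come from the exact choice probabilities: a
village's functional township is the one receiving its largest
expected flow share, and its true edge status applies the same
reference rule as the delineation (own township when it hosts a
facility and keeps at least one loyal village; modal functional
township otherwise). Building patches per village split a
30 m²-per-capita footprint into rectangles whose number falls — and
whose cohesion therefore rises — with the `clustering` parameter;
`clustering = 1` yields a single square patch.

What the generator does **not** emulate: road-network routing and
congestion (travel time is Euclidean × terrain noise), within-village
heterogeneity of respondents (utilities are village-level, as in the
village-scale analysis), temporal structure, actual-vs-intended care
distinctions (flagged, not modelled), and spatial autocorrelation of
covariates beyond township geometry. Passing tests therefore show the
*methods* are correct and well-calibrated under the stated choice
process, not that any particular real county satisfies that process.

## Test and experiment sizes

Planted-recovery experiments use 20 counties with a steep distance
decay (−0.02 s⁻¹), low Gumbel noise (scale 0.05), one facility per
township and 20,000 respondents, making every village's choice margin
decisive so that exact precision/recall is a fair demand.
Calibration experiments use 500 null replicates at n = 800 per
replicate for Wald/LR type-I error, 100 replicates at n = 2,000 for
parameter recovery and interval coverage, and 50 replicates at n = 500
for elastic-net signal recovery; these sizes give Monte-Carlo standard
errors small enough for the stated bands while keeping the default
suite quick on one core.

## Known limitations

* Modularity maximization has a resolution limit; very small genuine
  HSAs can be absorbed. No Leiden refinement or resolution parameter
  is provided.
* The edge-village verdict for a village with no observed flows is
  "not edge" by construction; a survey with systematic non-response in
  exactly the misaligned villages would bias counts downward.
* Elastic-net CV standardizes predictors on the full sample before
  fold fitting; with n in the hundreds this leakage is negligible but
  it is a documented simplification.
* The mixed-logit covariance uses a numerical Hessian of the simulated
  likelihood; with few draws the mixing-SD standard errors are rough.
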