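# Methods

This package implements a complete analysis chain for habitat selection
around ungulate dispersal — movement-type classification from net squared
displacement (NSD), behavioural segmentation of the dispersal period,
fine-scale step selection functions (SSF), and broad-scale route tests
against correlated-random-walk (CRW) nulls — together with a synthetic
world (landscape + trajectory generator) that gives every stage known
ground truth. This note documents the models, the generator, the
numerical choices, and what the tests do and do not establish.

## Trajectory model and screening

Trajectories are time-stamped projected planar positions (metres) on a
nominal 2-h fix schedule. Coordinates live in a single projected frame;
no geodesic arithmetic is used, which is adequate for a study extent of
order 100 km. Steps are straight segments between consecutive retained
fixes; a step is *regular* when its duration is within ±10 min of the
2-h interval, and only regular steps enter step-length and SSF analyses.
Turning angles are signed, counter-clockwise positive, in (−180°, 180°].

Gross position outliers are screened by their out-and-back signature: a
fix is removed when both adjacent legs exceed a rate-implied threshold
(default 5,000 m per 2-h interval, scaled by the actual gap) while the
surrounding fixes are an ordinary distance apart. The gap-scaled leg
threshold is capped at 10 km: real sustained travel does not mimic a
spike however long the gap, and without the cap spikes across long fix
gaps (common at ~66% fix success) become undetectable. Screening
iterates to a fixed point and is idempotent; removed fixes are reported
with reason codes, never silently dropped. The numeric threshold is a
package choice (configurable) — the screening idea it implements is
stated qualitatively in the field protocol, not as a number.

Trajectories are optionally trimmed (default: first 48 h) to drop
capture-affected behaviour.

## NSD movement typing

NSD(t) is the squared straight-line displacement (km²) from the first
retained fix. Four candidate models are fitted to each animal-year by
nonlinear least squares and ranked by AICc:

| model     | form                                   | parameters |
|-----------|----------------------------------------|------------|
| resident  | NSD = c                                | c |
| dispersal | NSD = δ / (1 + exp((θ − t)/φ))         | asymptote δ (km²), midpoint θ (d), scale φ (d) |
| migration | NSD = δ[s(t; θ_d, φ_d) − s(t; θ_r, φ_r)] | shared δ, departure/return midpoints and scales |
| nomadism  | NSD = b·t                              | slope b |

with s a logistic and θ_r > θ_d enforced by parameterizing the return
midpoint as θ_d + gap (gap ≥ 1 d). Sigmoid fits use multi-start
initialization (θ over data quantiles, φ ∈ {2, 8, 20} d) to avoid local
minima; a failed candidate is reported absent, not fatal. AICc (not AIC)
is used because series are a few hundred effective points after
thinning; long series are thinned to ≤800 points for fitting speed only.

Classification codifies the visual NSD-graph inspection used in the
field:

* resident winner → resident; nomadism winner → other (atypical);
* a shape-model winner whose 99th-percentile NSD stays below
  (5 km)² is home-range-scale noise → resident. The robust peak
  (99th percentile rather than maximum) keeps a single residual
  position outlier from masquerading as a displacement;
* dispersal winner with its 97.5% crossing inside the data span and no
  return → disperser; a rise followed by NSD falling below 25% of peak →
  exploratory;
* migration winner: if the series actually returns below 25% of peak,
  the residence time (days with NSD above half peak) separates migrants
  (≥ 60 d on the distant range) from exploratory movements (weeks);
  a migration winner that never returns is treated as dispersal-shaped,
  because its second sigmoid is then fitting plateau noise;
* poor fits (pseudo-R² < 0.5 for shape models) and truncated series →
  other, with machine-readable rationale codes throughout.

Series not covering 1 April–31 October are refused (classified "other"
with an `insufficient_span` code), mirroring the cohort-inclusion rule.

Dispersal events are resolved to the nearest day by inverting the
fitted logistic: start where it first exceeds 2.5% of δ
(θ − φ·ln 39), end at 97.5% (θ + φ·ln 39). The thresholds are symmetric,
scale-free and configurable; note that 2.5% of δ in NSD units is ~16% of
the displacement in distance units, so the extracted window begins once
directed movement is clearly under way. Because the crossing days come
from the fitted main sigmoid, a short displacement followed by ≥30
stationary days before the main rise is excluded by construction. For
exploratory movements the outbound sigmoid of the double-logistic fit
defines the window. Before/after windows span exactly 26 days
(the average dispersal duration) on either side; matched residents are
paired greedily, hardest-to-cover dispersers first, each to a distinct
resident whose data span all four windows, with unmatched dispersers
reported.

## Movement rates and behavioural segmentation

Movement rate (m/h) is compared across the four periods (before, during,
after, rest-of-year reference) with a linear mixed model with a random
intercept per animal, fitted by REML (statsmodels MixedLM); Wald 95% CIs
and the CI-overlap rule at α = 0.05 judge period contrasts. Reports emit
both model-based and raw per-period means/SEs, since either convention
may be wanted downstream.

During-dispersal rates are binned (default 0.5 m/min; empty bins dropped
because log 0 is undefined) and the natural-log frequencies fitted with
a two-segment continuous "broken-stick" line. The breakpoint ψ is
estimated by Muggeo's iterative linearization (working covariate
V = −1(x > ψ), update ψ ← ψ + γ/β₂), seeded by a coarse grid search over
interior bins so the iteration starts near the global optimum;
SE(ψ) = SE(γ)/|β₂| at convergence. A single-line null is fitted
alongside; a breakpoint is only reported when the two-segment fit
improves RSS relative to total variation by more than a tolerance
(10⁻⁶), which also keeps exactly collinear inputs from reporting a
spurious break. Admissible breakpoints keep at least two bins strictly
on each side.

Steps split at ψ × interval (rounded to the nearest metre; 7.118 m/min
× 120 min → 854 m): shorter steps represent foraging/resting, longer
steps directed travel. Boundary steps go to the long class (the
source convention leaves equality open). Per-class turning-angle
histograms (10° bins) are emitted; in simulation the long class has
lower circular spread, the directional-travel signature.

## Fine-scale SSF

Availability kernels are leave-one-individual-out empirical histograms
of regular step lengths (50-m bins) and turning angles (10° bins),
excluding the focal animal to avoid circularity; length and angle are
drawn independently. Each observed step is matched with 10 random steps
sharing its start point and prior heading: a bin is drawn by mass, the
value uniformly within the bin (upper edges half-open), the endpoint by
planar polar displacement; out-of-extent endpoints are redrawn (≤100
attempts). Covariates are attached at endpoints only.

Covariates are the standard elk set: terrain ruggedness (TRI: mean
absolute elevation difference to the 8-neighbourhood, edge cells using
available neighbours) plus its square, monthly NDVI (the layer matching
the step's calendar month), distance to roads, and percent canopy plus
its square. All are z-scaled per fitted dataset (per group × period);
squared terms are squares of the scaled linear term, re-scaled, so the
collinearity screen (all pairwise |r| < 0.3, all VIF < 2) treats each
column on the same footing. For generator-truth comparisons the design
can instead be scaled by landscape-wide moments — the scale on which the
generator's coefficients are defined — since per-dataset scaling would
rescale coefficients by the sample/landscape SD ratio and blur recovery
checks.

The conditional logistic likelihood Σ_s [x_obs·β − log Σ_j exp(x_j·β)]
is maximized by damped Newton iterations (step halving on likelihood
decrease) with observed-information SEs. Convergence requires both a
relative log-likelihood change below 10⁻¹⁰ and a parameter step below
10⁻⁸. Complete separation is flagged (|β| exceeding 15 on z-scaled
covariates, or an exploding SE) and reported with infinite-SE sentinels;
merely ill-conditioned fits keep their honest large SEs so that pooling
down-weights rather than discards them.

Population-level coefficients come from two-stage estimation: per
coefficient, individual estimates are combined by inverse-variance
weighting with a between-individual variance τ² estimated by REML
(1-D bounded optimization of the restricted likelihood). This
per-coefficient random-effects combination is the package's
implementation of the two-step mixed conditional-logistic estimator; its
equivalence at these problem sizes is validated on simulation (a
brute-force τ² profile oracle in the tests). A coefficient is marked
strong when |β| > 2·SE. The eight-model suite (dispersers/residents ×
before/during/after, plus the during-dispersal long/short split) shares
one covariate structure; a model with fewer than two usable individual
fits is reported not-estimable and the suite continues.

Validation is k-fold (k = 5) cross-validation: held-out step scores are
cut into 10 quantile bins (ties broken by score rank) and Spearman's r_S
computed between bin rank and the count of observed steps per bin. The
null permutes which step within each held-out stratum is "observed"
(200 permutations). A model is *useful* when mean r_S > 0.65 and exceeds
the null's 95th percentile. k, the permutation count and the bin count
are package choices (the validation literature the protocol cites states
none of them); the 0.65 bar is the field's usefulness convention.

## Broad-scale CRW route test

For each disperser, 10 CRW null paths are built from that individual's
own long-step length and turn histograms (no cross-individual leakage),
with the observed start point and initial heading, one null step per
observed long step — so null routes have comparable length by
construction. Individuals with fewer than 5 long steps are excluded with
a report. Observed long-step endpoints (label 1) versus null-path
vertices (label 0) are compared per individual with a binomial GLM on
the scaled covariates; NDVI months for null vertices track the
temporally corresponding observed step. Coefficients are averaged across
individuals and each covariate tested against zero with an exact
two-sided one-sample Wilcoxon signed-rank test (exact for n ≤ 25; zero
differences dropped — Pratt's treatment of zeros is the noted
alternative). Sign counts per covariate are reported alongside.

## The synthetic world

The generator exists so that every estimator above can be checked
against known truth; it is an idealization chosen to make the estimators
identifiable, not a mechanistic elk model.

**Landscape.** A 120 km × 120 km (minimum) stack of aligned layers:
elevation as a sum of smooth random fields with a mountains-to-plains
west-east gradient plus cell-scale relief (±18 m), so ruggedness varies
at the scale animals experience within single steps, as real 30-m
terrain does; ruggedness derived from elevation by the TRI rule; percent
canopy with both landscape- and stand-scale structure; a sparse network
of 14 roughly straight roads rasterized and converted to a Euclidean
distance surface; and 12 monthly NDVI layers combining valley-scale
(18-km) and patch-scale structure with cell-level heterogeneity, scaled
by a seasonal green-up curve peaking in July (July mean > January mean
over any extent). Terrain layers default to 30-m cells and NDVI to
250-m; the tests and the acceptance analyses run at 150-m/500-m cells to
keep runtimes reasonable — a resolution, not a model, choice. Layers
persist as ESRI ASCII grids (plain text).

**Movement.** At each 2-h tick the agent proposes K = 50 candidate steps
and picks one with probability ∝ exp(β·x + attraction), a discrete-choice
SSF matching the estimand (K is deliberately larger than the 10
availability steps used in estimation; with candidates and availability
drawn from the same kernels the conditional-logit estimand equals the
generating β up to finite-K bias, which the recovery tests bound).
Covariates in the utility are z-scaled by landscape-wide moments, so
`true_betas` are on the scale the estimators report; the default vector
(0.155, −0.135, 0.288, 0.113, −0.113, −0.053) mirrors the qualitative
during-dispersal pattern: intermediate-ruggedness preference, forage
attraction, weak road and canopy effects.

Behaviour is a phase schedule per mode. Encamped phases use short steps
(gamma bout pace, mean 180 m) with uniform headings and a mild pull to
the current range centre. Transit phases follow a waypoint moving from
origin to target across the scheduled window (completing slightly early
so the lagging agent settles on time) and are a two-state Markov mixture
of travel bouts and encamped ticks: bouts persist ~4 ticks (8 h), their
stationary frequency is set from the required net speed (with a floor of
0.30, because real routes meander — actual distance travelled exceeds
the straight line), and bout pace is drawn per tick from a declining
gamma distribution (mean 1,150 m per 2 h, smoothly saturated at
~3.4 km) with tight candidate spread around it — so selection decides
*where* to step, not how far, and the realized movement-rate
distribution is two-part declining (the short/long structure the
segmented regression detects) with long steps typically following long
steps (directional runs). Modes: residents stay anchored all year;
migrants move 25–35 km to a summer range in late May and return after
95–115 days; dispersers relocate once, drawing displacement from
29.16–98.01 km and duration from 12–47 days, between mid-May and early
August; exploratory animals make the same outbound movement (12–30
days), pause briefly, and return to within 5 km of the origin. Dispersal
targets are placed uniformly over feasible directions; with route
steering enabled (`route_steer_ndvi`), candidate directions are weighted
by mean scaled July NDVI along the straight-line route, giving
route-level forage selection for power analyses. In a minimal 120-km
extent, long dispersal targets only fit from off-centre starts, so
infeasible draws redraw the start point.

Fixes are thinned by collar-specific success (0.817 females/0.662
males) and corrupted with probability 0.01 per fix by a single displaced
position (10–40 km offset, back on the true path at the next fix),
matching the out-and-back signature the screen removes. Identical
configs (same seed) reproduce trajectory sets bit-identically.

**What the generator does not emulate.** Predation risk, grouping,
memory, real geography, habitat-dependent fix failure, autocorrelated
GPS error, stopover re-ranging during migration, and any feedback of
landscape on behaviour beyond the exponential selection kernel. Passing
recovery and calibration tests therefore shows the estimators are
correct and calibrated *under the stated generating model* — not that
real elk satisfy that model.

## Problem sizes and frozen analysis conditions

The simulation-based analyses (tests and the acceptance script) run at
these sizes, chosen to give stable verdicts at interactive runtimes:

* SSF parameter recovery: 10 animals × 300 strata, 20 replicates;
  verdicts: median |bias| per scaled covariate < 0.1 and ≥85% 2-SE
  coverage.
* Movement-type recovery: a 50-animal cohort (10 resident, 14 disperser,
  12 exploratory, 14 migrant) with realistic thinning and outliers;
  verdict ≥90% accuracy.
* Validation calibration: 10 animals × 150 strata per replicate, 20
  replicates; no-selection fires ≤10%, strong selection
  (2.0, −1.2, 2.5, 0.8, −1.2, −0.6) fires ≥90%.
* Broad-scale: 10 dispersers per replicate, 20 replicates; the null
  rejection rate across the four covariates stays within [0, 0.15] at
  α = 0.05, and the strong NDVI-steered condition — fine-scale NDVI
  coefficient 4, route steering 14 over 48 candidate directions, 60–98-km
  dispersals over 12–25 days (an effect size chosen so route-level
  selection is genuinely strong relative to the n = 10 Wilcoxon's
  granularity) — is detected in ≥80% of replicates.

## Known limitations

* The NSD-threshold event window (2.5%/97.5% of δ) excludes the first
  ~16% of the displacement in distance units; straight-line distances
  measured inside the extracted window are accordingly ~15% below the
  full relocation distance. Duration is unaffected.
* The per-coefficient REML pooling ignores cross-coefficient covariance
  of the individual fits; with the shared covariate structure and
  screened collinearity this is minor, and the simulation checks bound
  it, but it is not the full multivariate two-step estimator.
* Ties in validation score-binning are broken by score rank; a fully
  tied degenerate model concentrates all observed steps in the top bin,
  whose tied-count Spearman value is below 1 — the maximum attainable
  under average-rank ties.
* The Wilcoxon route test with n = 10 individuals has coarse attainable
  p-values (rejection effectively requires 8–9 concordant signs), which
  bounds its power regardless of effect size.
* Exact reproduction across platforms relies on NumPy Generator stream
  stability for a fixed seed.
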