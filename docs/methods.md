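# Methods

This note documents the models and procedures implemented in `navskill`,
the defaults chosen where the underlying study design leaves them open,
and what the synthetic-data generator does and does not emulate.

## Trajectory preprocessing

Raw logs are grouped into trials by (participant, phase, task, block)
with explicit start/end indicator rows, then resampled to a uniform time
base by weighted linear interpolation: a sample at query time t is the
convex combination of the two bracketing measurements with weights
proportional to temporal proximity. Yaw is interpolated on the circle
along the shortest arc (350° → 10° passes through 0°), because linear
interpolation in raw degrees is wrong across the 0/360 seam. The
resampling rate is a single configuration constant, `dt = 0.1 s` by
default, used consistently by the simulator and the scorer; the original
logging rate of such experiments is hardware-dependent and unspecified,
so `dt` is deliberately configurable. Coordinates are planar (x, y);
all error measures are planar distances and bearings.

Linear interpolation can only shorten a polyline (triangle inequality),
so resampled path lengths are lower bounds on raw path lengths; the
navigation ratio is therefore computed on logs resampled (or logged)
at the analysis `dt`.

## Error measures

Four components, each on [0, 1]:

* **Final rotation error** — minimal circular difference between final
  yaw and goal bearing, / 180. Computing |α_p − α_g| as the *minimal*
  circular difference is required for the stated [0, 1] range; a raw
  subtraction can exceed 180°.
* **Cumulative rotation error** — per resampled step the rotation is
  classified toward / away / static (static below
  `static_rot_threshold = 0.5°/step`, so sensor jitter is not scored as
  movement), scored 0 / 1 / 0.5 and averaged. A printed formulation that
  multiplies the (sign+1)/2 term by the rotation magnitude in degrees
  would leave [0, 1] and would score toward-goal rotation *worse* than
  away-goal rotation; the sign-corrected, magnitude-free mapping
  satisfies every stated property of the measure. A magnitude-weighted
  variant (per-step weight Δα / ΣΔα) is available via
  `ScoringConfig(weighted_rotation=True)`.
* **Final distance error** — |d_e − δ_c| / (d_s − δ_c), clamped at 1,
  with catchment offset δ_c = 4 m (the interaction circle is centred
  about 4 m ahead of the observer, so stopping δ_c short of the goal is
  the optimal response). If the start is already inside the catchment
  (d_s ≤ δ_c) the ratio is undefined and the trial is scored 0/1 by goal
  attainment.
* **Cumulative distance error** — per step, (d′ − d_opt) / (2Δd) with
  d_opt = max(0, d − Δd), clamped to [0, 1]; a static step (below
  `static_dist_threshold = 5 mm/step`) scores 0.5, mirroring the neutral
  case of the rotation measure. Moving straight toward the goal gives 0,
  straight away 1, and an unbiased random walk far from the goal has
  expectation (1 − cos θ)/2 averaged over uniform θ, i.e. 0.5.

Rotation-only tasks (ROT, RWM, RFM; translations disabled) combine the
two rotation components / 2 — this includes the map-based rotation task,
since its translations are equally disabled. All other tasks combine all
four components / 4. Per participant × task the five repetitions are
averaged first and the means standardized across participants with the
sample (n−1) SD; a zero-variance task column is an error naming the
column, not a silent NaN.

Both cumulative errors exist as vectorised batch functions and as
one-pass streaming accumulators; they agree to 10⁻¹² and are tested for
invariance under global rigid transforms of the world frame.

Navigation is scored only on the testing block (learning blocks have
randomized goal orders and are not comparable): per goal leg,
`r_d` = walked path length / shortest-path route length (Dijkstra on the
road-network graph), averaged over the six legs. Arrow presses are
counted per learning block as an index of learning.

## Regularised exploratory factor analysis

With n in the tens and p = 8 tasks, the sample correlation matrix is
ill-conditioned and unrestricted ML EFA is erratic. The REFA model
constrains the unique variances to be proportional to the anti-image
estimate,

    Ψ = λ Ψ̃,   Ψ̃_j = 1 / (R⁻¹)_jj,

and estimates the single scalar λ by maximum likelihood (bounded scalar
minimisation of the profiled discrepancy over λ ∈ (0, 1/max Ψ̃]). With
`lam=0` the model falls back to standard ML EFA with p free uniquenesses,
which is the configuration used for cross-checks against R's
`stats::factanal`: both optimise the same profiled likelihood
F(Ψ) = Σ_{j>m}(θ_j − log θ_j − 1) over the eigenvalues θ of
Ψ^{−1/2} R Ψ^{−1/2}, and agree to ~10⁻⁶ in canonical loadings on a
common fixture. Uniquenesses are floored at 0.005 and a boundary hit is
flagged as a Heywood case — a real phenomenon of small-sample ML EFA,
not an implementation failure (the independent implementation finds the
identical boundary optimum).

The number of factors is estimated by a permutation test equivalent to
parallel analysis: each column of Z is permuted independently B times
(default 500) and the k-th factor is retained while the k-th observed
eigenvalue exceeds the permuted (1 − α) quantile, stopping at the first
failure. Permuting whole rows would leave R unchanged; requesting it is
an error by design. On null data the test retains ≥ 1 factor in ≈ α of
runs; on a planted 3-factor structure with communalities ≈ 0.5 and
n = 500 it returns 3.

The unrotated solution is rotated by oblique geomin (criterion
Σ_i (Π_j (l_ij² + ε))^{1/m}, ε = 0.01) using the gradient-projection
algorithm with 100 random orthonormal starts. Geomin is multimodal;
converged solutions are clustered up to column permutation and sign at a
Tucker-congruence threshold of 0.95 into distinct solution *sets*,
reported with criterion value and basin size. ε, the number of starts
and the clustering threshold are configurable because no standard fixes
them; the defaults reliably expose the multimodality on cross-loaded
structures. Communalities are computed from the model-implied common
variance (diag ΛΦΛ′) and are rotation-invariant, so all sets of one fit
report identical communalities (tested to 10⁻⁶); the reported
communality table therefore belongs to the unrotated fit, not to any
particular set.

Factor scores for regression use the Bartlett estimator on a chosen
set's pattern matrix — an explicit choice, since regression "on a
factor" requires a scoring rule and none is canonical.

## Inference

Composites average the z-scores of each side of the four design
dimensions (egocentric {ROT, MOV, RFM, MFM, CHA}, allocentric
{RWM, MWM, CWM}, distance {MOV, MWM, MFM}, direction {ROT, RWM, RFM},
perceived {ROT, MOV, RWM, MWM, CHA, CWM}, remembered {RFM, MFM}, static
{six non-chase tasks}, dynamic {CHA, CWM}); the chase tasks combine
distance and direction judgements and belong to neither single-judgement
composite.

"Robust regression" is OLS with an HC3 sandwich covariance and a Wald χ²
(1 df) — the χ² reference reproduces the reporting convention of the
emulated analyses (e.g. χ² = 5.47 → p = .019 under χ²₁). The χ²
reference is asymptotic: calibration is within 1.5 pp of nominal at
n = 100 but inflates to ≈ 7% at n = 20, which is documented rather than
hidden behind a small-sample correction the original convention does not
use. A Huber M-estimation variant (`method="huber"`) is provided because
"robust regression" is software-dependent. White's test regresses the
squared OLS residuals on {x, x²}; the statistic n·r² is χ² with 2 df.
Šidák-corrected levels use families of 8 (confirmatory composites) and
3 (factors of one rotation set). The repeated-measures F uses the
eigenvalue form of the Greenhouse–Geisser ε̂ (clamped to
[1/(k−1), 1]); paired contrasts are F = t² with Cohen's d for dependent
samples. Cohen's d for the one-sample t is t/√n. The critical-|r|
helper defaults to the subscript-as-df convention (df = 20 at n = 20)
with the textbook n − 2 selectable.

## Synthetic world

The generator emulates the *statistical* structure of the study design,
not behaviour: a 40 m × 40 m field with 20 spheres (radius 0.25 m,
pairwise ≥ 2 m, placed by rejection sampling), eight tasks × five blocks
with spheres re-randomised per task, and a navigation phase on a road
network (default: 7 × 7 street grid, 35 m spacing, straight edges, six
spread-out goals) over three learning blocks with random goal orders
plus one testing block with a fixed order.

Agents are proportional heading controllers (turn rate 120°/s, speed
2 m/s, dt = 0.1 s) with Gaussian noise. Five abilities in (0, 1) are
derived from standard-normal latent factors through a loading matrix
(rows with norm ≤ 1; residual variance fills to 1; normal-CDF squash):

| ability | tasks it perturbs | noise scale at skill = 0 |
|---|---|---|
| motor (HID) | all; dominates continuous pursuit | 60°/step (chase), 2°/step (static) |
| memory fidelity | RFM, MFM | 40° bearing / 6 m position |
| map skill | RWM, MWM, CWM | 30° / 5 m / 3 m continuous read |
| navigation | wrong-turn probability, arrow presses | p_wrong = 0.15·(1 − skill) |
| aim precision | final aim/stop of all static tasks | 12° / 1.5 m |

The asymmetry between the chase and static motor-noise scales encodes
the study's own rationale: continuous interception stresses HID control,
whereas discrete aim-and-stop actions at comfortable turn rates do not.
Aim precision is an independent factor so that the static composites are
*null* predictors of navigation by construction. The default loading
matrix shares one factor between motor skill and navigation ability with
correlation 0.6 (the planted link the acceptance experiments must
recover); `NULL_LOADINGS` removes it for type-I-error checks.

Navigation walks the network junction by junction: the agent takes a
shortest-path edge except with probability p_wrong it takes an edge
through which the route becomes *strictly* longer (on a grid, many
non-canonical edges still lie on an equal-length path and must not count
as errors), then re-plans. Learning blocks add an exploration surcharge
0.3·0.6^(block−1) to p_wrong. Arrow presses per learning block are
Poisson with mean 24.15·(1.5 − nav_skill)·0.52^(block−1), spread over
the block's six legs — a monotone decline chosen to match the observed
magnitude of press counts, with no claim to a cognitive model. Chase
constants the design leaves open (sphere speed 1 m/s, interception at
the 4 m catchment radius) are configurable and should be treated as
unvalidated defaults. Distractor spheres in the chase tasks move
independently of everything the analysis measures, so their motion is
only simulated when full logs are requested
(`SimConfig(log_distractor_motion=True)`); the pursued target always
moves by the same random-waypoint process as the general sphere-motion
simulator.

What passing parameter-recovery tests shows: the pipeline detects a
planted dynamic-skill → navigation link of the stated size at the
Šidák-corrected level in ≥ 90% of 200-agent worlds while leaving the
planted-null composites at their false-positive level, and the factor
machinery recovers a planted 3-factor structure. What it does not show:
that human data have this structure, that the noise magnitudes are
realistic, or that the controllers resemble human locomotion — the
generator's trial-to-trial variability is purely the controllers'
Gaussian noise plus layout randomness, with none of the fatigue,
learning or strategy shifts of real participants.

## Numerical choices

* ML-EFA optimisation: L-BFGS-B on the uniquenesses with the analytic
  gradient diag(Σ̂ − R)/Ψ², bounds [0.005, 1], the standard
  (1 − m/2p)·Ψ̃ start; scalar λ by bounded Brent.
* Geomin GPA: Armijo backtracking line search; the criterion trace is
  non-increasing, a stalled line search at a minimiser counts as
  converged.
* Column matching for clustering/canonicalisation: greedy maximal
  congruence with sign fixing (largest-|loading| element positive),
  columns ordered by sum of squared loadings.
* Three-factor test fixtures anchor the two-indicator factor with one
  cross-loading: a bare doublet factor drifts into boundary (Heywood)
  ML optima even at large n — verified identically in the independent
  implementation.
* The permutation test vectorises over B but keeps column-wise
  permutation explicit; derived seeds come from named CRC32 substreams
  of one root seed, so adding draws to one stage never shifts another.

## Problem sizes in the shipped checks

The test suite and acceptance script run desk-scale versions of every
experiment: 10⁴ random trajectories for the [0, 1] guarantees, n = 20
fixtures for the ML-EFA cross-check, n = 200/500 worlds for the
permutation-test calibration, and 100 replicate worlds × 200 agents × 40
trials for the planted-link recovery — sizes chosen so the whole chain
re-runs in minutes on one CPU while keeping every Monte-Carlo assertion
comfortably inside its binomial noise band.

## Known limitations

* The one-parameter λ rule follows the proportionality assumption
  directly; the literature's variants (e.g. grid search against a
  generalized-cross-validation criterion) can be substituted behind the
  same interface.
* The HC3-Wald χ² convention over-rejects mildly at n ≈ 20 (see above).
* The simulator's navigation phase abstracts locomotion to junction
  decisions; within-edge trajectories are straight lines, so
  path-deviation measures other than the distance ratio would be
  degenerate on synthetic navigation logs.
* MAT/database ingestion is out of scope; the CSV schema in
  `navskill.trajio` is the interchange format.
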