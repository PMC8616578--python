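# Methods

This note documents the models and procedures implemented in
`ofc_encoding`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## The task and the synthetic generator

The generator (`ofc_encoding.task`) emulates a rodent cued-gamble task.
On each trial the animal pokes a center port; auditory click trains from
the left and right speakers run throughout a cue period of 2.5–3 s, with
the Poisson click rate conveying the water volume offered at that side
(default map 6/12/24/48 µl → 10/20/30/40 Hz, configurable).  After a
uniform 0–350 ms pre-flash interval, 20 ms light flashes are presented on
a 250 ms grid, the flash count conveying reward probability (default
2 + 8·p flashes).  One side is always safe (p = 1), the other risky
(p drawn from {0, 0.25, 0.5, 0.75}); offered volumes are independent
across sides.  After the go cue the animal exits the center port
(50–250 ms latency) and reaches a side port 150–450 ms later; on wins the
reward is delivered at side-port entry.  Inter-trial intervals are
U(2, 4) s.

Choices are drawn from a logistic on the expected-value difference,
P(left) = σ(β·(EV_L − EV_R)) with β = 0.05/µl.  This is deliberately a
*sampling policy*, not a behavioral model: the value is chosen so both
win (~70%) and loss (~20%) outcomes are well populated at every session
length, which the downstream conditional analyses require.  Opt-outs
occur independently with probability 0.05.

Per-trial history covariates are computed strictly from earlier trials:
previous outcome, previous reward rate (mean rewarded volume over all
preceding trials), and session progress (trial index normalized to
[0, 1]).

What the generator does **not** emulate: slow drift or non-Poisson spike
statistics (bursting, refractoriness), correlated noise across neurons,
electrode artifacts, and any genuine decision process.  Tests passing on
this generator therefore establish the *estimators'* correctness and
calibration under the model class, not robustness to real-data
violations of it.

## Ground-truth neurons

`make_archetypes` plants five response archetypes expressed directly in
the model basis, so parameter recovery is well defined:

1. *trial-start burst* — transient response via equal previous-outcome
   kernels (a trial-start-locked event present on every trial after the
   first);
2. *persistent cue* — sustained cue-period activity driven by per-click
   and per-flash kernels.  Stimulus kernels must be small per event
   (clicks arrive at tens of Hz, and the log-rate elevation is the click
   rate times the kernel integral); defaults give a ~0.6 log-unit
   sustained elevation;
3. *pre-choice + reward history* — the only archetype whose previous-win
   and previous-loss kernels differ, with mass both at short lags (trial
   start) and at 1.3–2 s lags so the differential re-emerges in the
   pre-choice epoch.  This is the planted positive for every
   reward-history recovery test;
4. *choice-locked* — lateralized center-port-exit response;
5. *reward-locked* — asymmetric win/loss response at outcome.

Background rates default to 5 Hz; weights are jittered lognormally
(σ = 0.1) across units within an archetype.  Simulation draws counts
from Poisson(exp(Xθ + θ₀)) in 50 ms bins over per-trial [−2, 6] s
windows; a rate above 500 Hz raises an error rather than being clipped,
since it always indicates mis-scaled kernels.

## Basis and GLM

Kernels live on a causal 4 s lag grid of 50 ms bins and are weighted
sums of M = 9 basis functions: seven raised cosines on a log-time axis,
φ_j(τ) = ½cos(a·log τ − b_j) + ½ clipped to |a·log τ − b_j| ≤ π, with
peak lags log-linearly spaced from 25 ms to 2 s and `a` chosen so
adjacent cosines cross at amplitude ½; plus two decaying exponentials
(τ = 25 and 50 ms) peaking in the first two lag bins for impulse-like
onsets.  All columns are scaled to peak 1.

The encoding model is a Poisson GLM with exponential link over 15
one-hot task variables (clicks, flashes, left/right choice, safe/risky
choice, win/loss, previous win/loss/opt-out, previous reward rate,
session progress), fit by minimizing the penalized negative
log-likelihood Σ_t λ_t − y_t·log λ_t + (ξ/2)‖θ‖² (the offset θ₀ is not
penalized, so the ridge limit leaves the mean rate intact).  The
objective is convex; we run L-BFGS followed by damped Newton refinement
to a size-invariant gradient tolerance (‖g‖∞ < 10⁻⁶·n).  Kernel
covariances are the inverse Hessian at the optimum.

Model selection follows a balanced five-partition scheme: trials are
stratified on the joint (outcome × previous outcome × choice) cell and
dealt round-robin, one partition held out; for each ξ on a log-spaced
grid over [10⁻⁵, 10] (7 points, 3 refinement rounds bracketing the
argmin), four models are fit by 4-fold cross-validation on the remaining
partitions, the fold with lowest validation NLL is kept, and the ξ with
lowest held-out test NLL wins.  Held-out R² is computed on 250 ms
boxcar-smoothed rates (shrinking windows at the edges, matching the
common MATLAB `smooth` convention) and may be negative; units with
R² ≤ 0 are excluded downstream.

Identifiability: the left/right-choice and safe/risky-choice streams
share the center-exit anchor and are exactly collinear, so only their
per-condition sums are identifiable.  The ridge resolves the degeneracy
numerically; the recovery oracle (`kernel_recovery`) therefore scores
the four observable (side, safety) effective kernels and skips kernels
whose planted peak is below 0.3 log-units (< ~35% rate modulation),
where kernel estimates sit at the noise floor and correlation measures
only noise.

## Clustering and validation

Two feature spaces: (i) z-scored trial-averaged PSTHs on the
trial-start-aligned [−2, 4] s grid (121 bins, 250 ms smoothing), and
(ii) 19 conditional features — epoch-averaged z-scored rates for
win/loss and rewarded volume {0, 6, 12, 24, 48 µl} over [0, 3] s after
reward, previous win/loss over [−1, 2] s after trial start, left/right
choice over [0, 1.5] s after center exit, and left/right expected value
in log-2 bins {[0,6), [6,12), [12,24), [24,48]} over [−1, 0] s before
side-port entry.  Conditional rates are z-scored with each neuron's
pooled (marginal) statistics so conditions remain comparable; empty
condition cells are imputed with the neuron's marginal epoch mean and
logged.  Both spaces are reduced by PCA to >95% cumulative variance.
K-means uses 50 seeded k-means++ replicates, best inertia.

The gap statistic draws its reference uniformly over the PCA-aligned
bounding box (the criterion's standard construction), uses
Gap(K) = E*[log W_K] − log W_K with SE·√(1 + 1/B), and selects the
*largest* K with Gap(K) ≥ Gap(K−1) + 2·SE(K−1) (1 when no significant
jump exists).  Silhouette and ARI go through scikit-learn; the
subsampled-ARI procedure reclusters 90% subsamples and scores agreement
with the full clustering on the shared units.  Mahalanobis cluster
separation is the root form √((x−μ)ᵀS⁻¹(x−μ)) — the average-z-score
reading, under which the own-cluster mean of a d-dimensional Gaussian
cluster is E[χ_d] ≈ √d — averaged over each source cluster.

### PAIRS

After whitening, each point's mean angle to its k nearest-by-angle
neighbors is compared against matched standard-Gaussian references;
PAIRS = (median_ref − median_data)/median_ref, with a two-sided p-value
from a normal fit to per-reference PAIRS values and a KS test on the
angle distributions.  Two angle conventions are implemented: *signed*
(arccos of the cosine, [0, π]; default) and *folded* (arccos |cos|,
[0, π/2]).  The default was fixed by validating the neighbor-count
criterion (smallest k whose pooled reference median angle exceeds π/4)
against the published selections: with signed angles the criterion
reproduces k = 8 for 659 points in 11 dimensions; folded angles do not.

At 659 points in 18 dimensions, however, the median angle to even the
single nearest neighbor of a Gaussian cloud is ≈0.85 rad > π/4 under
either convention, so the criterion selects k = 1 there; the published
k = 3 for that space is not a possible output of the criterion as
stated (the antecedent method that introduced PAIRS also used k = 3,
suggesting the value was adopted rather than derived).  The package
reports what the criterion computes.

### Covariance-regime experiment

`regime_experiment` generates 5-cluster ground-truth datasets (100
points per cluster, dimension matching the supplied covariances):
cluster means from N(0, scale·Σ_total), points from N(μ, Σ_within),
PCA to >95%, then records the silhouette-argmax K and the gap-selected
K per replicate across scales {0.1, 0.5, 1, 2, 3, 5}.  Reproducing the
data-like regime requires the deposited total/within covariances; the
package's tests exercise the data-free large-scale limit with synthetic
squared-exponential covariances and both metrics recover K = 5.

## Encoding metrics

**CPD.**  For a covariate group (reward = {win, loss}; reward history =
{prevWin, prevLoss, prevOptOut}; choice = {left, right}; clicks;
flashes), the reduced design replaces member streams by their mean, so
the event response survives with the condition-averaged kernel and no
refit is needed.  CPD_t = (SSE_red − SSE_full)/SSE_red × 100 with SSE
across trials per 50 ms bin (250 ms smoothing for display), computed on
the full dataset.  For the three trial-level groups each condition is
weighted 1/n_condition so imbalanced trial counts do not bias the
contrast.  The shuffle null (500 draws) permutes condition labels across
trials while keeping each trial's event timing — implemented by swapping
per-trial kernel responses, so no refit or re-convolution is needed; for
clicks/flashes the null swaps the left/right kernel assignment on a
random half of trials.  Reported values are null-mean-subtracted, bins
inside the one-sided 95% band are zeroed before cluster averaging, and
units with any raw CPD above 0.5% are flagged as outliers for cluster
averages (threshold configurable; the synthetic planted effects are far
stronger than cortical data, so recovery tests disable it).

**Mutual information.**  For the trial-level groups only, MI_t between
spike counts and the condition is estimated by a doubly stochastic
sampling: 500 parameter vectors from N(θ̂, H⁻¹) pass through the
exponential link and Poisson spiking, truncated at 10 spikes/bin
(200 Hz); p(y_t | x_k) averages the sampled count distributions over
trials in condition k, H(X) comes from empirical condition frequencies,
and MI_t = Σ_k p(x_k) Σ_y p(y|x_k) log[p(y|x_k)/p(y)] (natural log
internally, reported in bits).  Significance is assessed against 500
trial-label shuffles.

*Known bias:* because the estimator reads encoding off the fitted
model's predicted rates, any estimation noise in the fitted condition
kernels is a systematic condition difference that is aligned with the
true labels by construction, and the label-shuffle null cannot
reproduce it.  On simulated null units ~25–35% of bins test significant
instead of 5%.  A calibrated null would need the GLM refit inside every
shuffle; the package implements the procedure as defined and documents
the bias rather than silently altering the method.  CPD and d′, which
compare against observed counts, calibrate correctly (measured 6.7% and
6.8% on null units).

**d′.**  Per bin, |μ_prevWin − μ_prevLoss| / √(½(σ²_prevWin +
σ²_prevLoss)) on 250 ms-smoothed single-trial rates.  The unsigned form
inflates the null, so the mean of a 1000-draw label-permutation null is
subtracted; the permutation preserves the per-condition trial counts
(matched composition), which makes the per-bin test exact — equal-size
subsampling instead makes the null systematically wide (1–3% rejection
on null units versus the nominal 5%).

## Epoch regressions

Single-trial rates averaged over the post-choice epoch ([0, 1] s after
reward onset) or a configurable pre-choice window are regressed with
OLS (statsmodels): (i) outcomes 1–5 trials back (win = +1, loss = −1,
previous opt-out = 0) plus choice and intercept, with per-coefficient
t-tests and an F-test against the intercept-only model; (ii) current
win/loss + previous win/loss + choice; (iii) rewarded volume (µl) +
current loss indicator + previous win/loss + choice; (iv) reward
prediction error (V_rewarded − p·V_chosen) + choice.  A unit is
*adaptive* when the current- and previous-reward coefficients are both
significant (p < 0.05) with opposite signs, *modulated non-adaptive*
with the same sign, *not significant* otherwise.  The classification is
invariant to rate rescaling.  Opt-out trials (and trials whose previous
trial was an opt-out, for models ii–iv) are excluded.  Cluster
enrichment uses exact Clopper–Pearson binomial 95% CIs; enrichment is
read off by CI-versus-point-estimate comparison.

## Numerical and scale choices

* RNG: every public entry point takes a seed; internal streams are
  spawned from named `SeedSequence` children, so runs are reproducible
  and substreams independent.
* Default analysis constants: 50 ms bins, 4 s kernels, M = 9, ξ grid
  [10⁻⁵, 10] (7 × 3 rounds), 5 partitions, 500 CPD shuffles, 500 MI
  samples/shuffles, 1000 d′ shuffles, 5000 gap references, 10000 PAIRS
  references, 0.95 PCA threshold, 1 Hz inclusion, R² > 0 inclusion,
  0.5% CPD outlier cutoff.
* The test suite runs everything at reduced problem sizes chosen as the
  package's own testing scale — 150-trial sessions for most fixtures,
  400 trials for parameter recovery, tens of shuffles/references where
  the assertion concerns structure rather than tail quantiles — so the
  whole suite completes on a laptop; the defaults above are what an
  analysis run uses.
* Degenerate inputs fail loudly: zero-variance test data, empty
  condition cells (imputed and logged in the conditional feature space,
  errors elsewhere), singular cluster covariances (ridge then
  pseudo-inverse with a warning), rate overflow in simulation.

## Limitations

* The generator's archetypes are expressed in the model's own basis, so
  parameter recovery is an internal-consistency check, not evidence
  about model mismatch.
* MI significance is anti-conservative (see above); MI *values* remain
  comparable across conditions and clusters.
* The deposited-data adapter expects a converted trial/event/spike
  layout and is best-effort: the archive's native schema is not
  specified in the package's sources, and adapter failure never blocks
  synthetic operation.
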