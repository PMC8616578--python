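# ofc-encoding

Analysis pipeline for spike trains recorded (or simulated) during a
rodent cued-gamble task, aimed at the question of whether orbitofrontal
neurons form functional subpopulations and how those subpopulations
encode rewards, choices and reward history.

The package provides, end to end:

* a **synthetic task-and-spike generator** — sessions with the task's
  event structure (clicks conveying offered volume, flashes conveying
  reward probability, safe/risky sides, win/loss/opt-out outcomes) and
  neurons simulated from a ground-truth Poisson GLM with five planted
  response archetypes;
* a **Poisson encoding GLM**: spike counts y_t in 50 ms bins follow
  y_t ~ Poisson(λ_t), log λ_t = Σ_s (X^(s) ∗ k_s)(t) + θ₀, with each
  kernel k_s(τ) = Σ_j θ_s^(j) φ_j(τ) built from M = 9 log-raised-cosine
  basis functions over 4 s of lag, an L2 penalty (ξ/2)‖θ‖², balanced
  5-partition cross-validation and a refined grid search for ξ, and
  held-out R²;
* **response clustering** on two feature spaces (z-scored trial-averaged
  PSTHs; 19 conditional epoch-averaged features), with k-means and
  cross-method consistency P(C_cond | C_PSTH);
* **cluster validation**: gap statistic, silhouette, subsampled ARI,
  Mahalanobis cluster separation, the PAIRS nearest-neighbor-angle test
  against Gaussian references, and a covariance-regime experiment
  comparing how silhouette and gap select cluster number as clusters
  become tightly packed;
* **encoding metrics** per neuron and cluster: coefficient of partial
  determination CPD_t = (SSE_reduced − SSE_full)/SSE_reduced × 100 with
  shuffle nulls, sampling-based mutual information between spike counts
  and task conditions, and shuffle-corrected d′ for previous-win versus
  previous-loss;
* **trial-history regressions** of epoch-averaged rates (outcomes 1–5
  trials back; current vs. previous reward; rewarded volume; reward
  prediction error) with an adaptive-value-coding classification and
  cluster-enrichment statistics.

See `docs/methods.md` for the models, default constants, design
decisions and known limitations.

## Worked example

```python
import numpy as np
import ofc_encoding as oe

cfg = oe.TaskConfig(n_trials=300, seed=1)
session = oe.generate_session(cfg, seed=1)
basis = oe.build_basis()
design = oe.build_design_matrix(session, basis=basis)

# simulate the planted reward-history archetype and refit it
neuron = oe.make_archetypes(cfg, seed=3, basis=basis)[2]
spikes = oe.simulate_spikes(session, neuron, seed=11, basis=basis)
fit = oe.fit_glm(spikes.binned_counts, design, xi=0.5)
recovery = oe.kernel_recovery(neuron, fit, basis)
print({k: round(v, 2) for k, v in recovery.items()})
print("median kernel correlation:", round(float(np.median(list(recovery.values()))), 2))
```

Output:

```
{'prevWin': 0.99, 'prevLoss': -0.25, 'prevOptOut': -0.45, 'win': 0.95, 'loss': 0.22, 'left+safe': 0.98, 'left+risky': 0.91, 'right+safe': 0.9, 'right+risky': 0.95}
median kernel correlation: 0.91
```

The previous-win kernel — this archetype's defining feature, with mass
at trial start and again at 1.3–2 s lags so its effect re-emerges just
before the choice — is recovered at r = 0.99 from 300 trials, as are the
win and effective choice-epoch kernels (the left/right and safe/risky
streams are collinear, so only their per-condition sums are
identifiable).  The small previous-loss/opt-out and loss kernels are
noise-dominated at this session length: correlation on a near-zero
kernel is uninformative, which is why the recovery oracle's median is
taken over kernels with substantial planted amplitude (see the methods
note).

Running the full pipeline from the shell:

```sh
ofc-encoding all --seed 1 --out runs/
```

writes a run directory with the session tables, fitted-model summary,
cluster labels and consistency matrix, validation curves, tidy CPD/MI/d′
series, regression tables with the adaptive/non-adaptive classification,
and a figure bundle.

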