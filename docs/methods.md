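# Methods

## Problem setting

Inpatient insulin titration is cast as a Markov decision process
(S, A, P, G, γ).  A hospital day is divided into seven timeslots
(pre/post-breakfast, pre/post-lunch, pre/post-dinner, pre-bedtime); an
observation `o_t` per slot carries the capillary glucose (mmol/L, possibly
missing), static demographic/lab covariates and the previous action.  An
action is an insulin class (short/rapid-acting, long-acting, premixed) with
an integer dose of 1–40 U, or an explicit no-dose token — "no injection" is
a distinct token rather than dose 0 because the dose vocabulary starts at
1 U.  The per-measurement reward is the clipped Magni blood-glucose risk
index mapped to [−1, 1] (see below); the discount is γ = 0.9.  Trajectories
need at least two treatment days.

## Reward

For glucose `b` in mg/dl:

    r(b) = −1                                                   b < 70
    r(b) = 1 − clip(10·(c₀·((ln b)^c₁ − c₂))², 0, 15.5) / 7.75  otherwise

with c₀ = 1.509, c₁ = 1.084, c₂ = 5.381.  Two conventions are worth
stating explicitly:

* **Parenthesization.** c₀ multiplies the whole bracket `((ln b)^c₁ − c₂)`,
  the symmetrization of the original blood-glucose risk-index literature;
  it puts the zero-risk glucose near 112.5 mg/dl.  The alternative literal
  grouping `(c₀·(ln b)^c₁ − c₂)²` is available via
  `RewardParams(literal_grouping=True)` for sensitivity analysis; it moves
  the peak and is not the default.
* **Missingness.** The reward at a slot with no glucose measurement is
  undefined: it is carried as a masked value and excluded from sums, never
  imputed.

The within-target-range (WTR) band is 3.9–10.0 mmol/L inclusive at both
ends, matching the time-in-range convention; the daily WTR ratio is the
fraction of a day's *measured* values in the band.

## Synthetic cohort

Real inpatient EHR data of the kind this pipeline targets are not publicly
shareable, so all learning and evaluation run against a seeded simulator
whose ground truth is known.  Per timeslot (slot = t mod 7):

    g[t] = basal_glucose + meal_effect(slot) − sensitivity · E[t] + ε,   g ≥ 1.5

`E[t]` accumulates effective insulin with minimal class kinetics: a
short/rapid dose acts fully on the next slot; a bedtime long-acting dose
acts uniformly on each of the next seven slots; a premixed dose splits
half-prandial (next slot) / half-basal (next seven slots).  Defaults (chosen
once, as plausible for a poorly controlled admission cohort): basal glucose
N(10.5, 1.5²) mmol/L, per-meal rises N(2.5, 0.5²), insulin sensitivity
log-normal with median 0.30 mmol/L per unit and log-sd 0.25, modulated by
one covariate (exp(0.25·z)) so static features are informative; measurement
noise sd 0.3 mmol/L (set to 0 in the noiseless studies); regimen mix 40%
premixed (injections at pre-breakfast and pre-dinner), 30% basal-only
(bedtime), 30% basal-bolus (bedtime basal + three pre-meal boluses).

**Oracle doses.**  Each patient carries the integer doses minimizing squared
deviation of steady-state glucose from 6.5 mmol/L, found by brute force over
1–40 U: premixed patients take an equal dose at both injections; basal-bolus
patients get the basal fitted first against the no-meal slots and then each
bolus against its own post-meal slot (boluses act on a single slot, so they
decouple given the basal).  Ties break toward the smaller dose.

**Behavior policy.**  The logged (clinician) policy emulates bedside
practice with therapeutic inertia: the day-1 dose is oracle + N(−6, 3²)
(conservative start), and each later day every injection moves by the
five-branch guideline step (−2/0/+2/+4/+6 U) applied to the previous day's
glucose at the slot it covers, plus N(0, 1) jitter, clamped to [1, 40].
This matters for two reasons.  It makes the log *deliberately sub-optimal*
(under-dosed early, drifting slightly past the oracle late, since the
guideline table targets 80–109 mg/dl while the oracle targets
6.5 mmol/L ≈ 117 mg/dl), so improvement of reinforcement learning over pure
imitation is a measurable effect.  And it creates genuine within-patient
dose variation, without which individual dose-response — in particular the
hypoglycemia downside of over-dosing — is unidentifiable from the log; a
constant-mean jittered behavior policy was tried first and left the learned
model believing ever-larger doses were always better.

All randomness derives from the single cohort seed through per-patient
`SeedSequence` substreams; the same seed reproduces the cohort bit-for-bit.
The degraded-data operations (`degrade_trajectory`, keeping at most k
measurements per day, and `add_observation_noise`) reproduce the
low-data-quality simulation conditions; both are deterministic under their
seed and never touch actions or covariates.

**What the simulator does not capture:** diet variation and carbohydrate
content, exercise, steroid effects, within-day insulin kinetics finer than
the slot grid, glucometer error structure, and nonlinear or time-varying
insulin sensitivity.  Passing the simulator studies therefore shows the
pipeline's machinery is sound and the RL-over-imitation effect is real *in
a world satisfying these assumptions*; it is not clinical evidence.

## Patient model

`f_R` embeds each slot's features (glucose z-scored as (g − 8)/4 with an
explicit measurement mask, slot one-hot, day index, previous action class +
normalized dose, covariates) plus learned slot/day positional embeddings,
and runs a causal transformer; the hidden vector at position t is the state
s_t = f_R(O_{1:t}).  `f_T` is an MLP over (s_t, action embedding) with a
residual connection and layer norm, returning the next state and a
tanh-bounded reward estimate; the action embedding sums a learned dose-token
embedding, a class embedding, and a *numeric* dose channel (a linear map of
dose/40) so that dynamics generalize ordinally to doses rare in the log.
`f_P` is an MLP producing the glucose point prediction and a WTR logit.

Training teacher-forces logged actions: from every position the dynamics are
unrolled K = 7 steps (one day), and at depth k the rolled state is penalized
by (i) glucose MSE and WTR cross-entropy of `f_P` against step-(t+k) truth,
(ii) reward-head MSE against the step-(t+k) Magni reward (measured slots
only), and (iii) at one depth per batch (cycled), the consistency loss
‖ŝ_{t,k} − s_enc(t+k)‖² pairing the rolled state with the (stop-gradient)
encoded state at the same absolute timestep — one pair per target step keeps
the cost linear and the stop-gradient prevents representation collapse.
Total loss μ·L_T + L_P with μ = 0.1, Adam (lr 1e−3, weight decay 1e−4),
batches of 32, gradient-norm clip 5.  Full-scale architecture: hidden 256,
3 encoder layers, 8 heads, dropout 0.4, padding 128, 100 epochs.  The
scaled-down profile used throughout the tests: hidden 32, 2 layers, 2 heads,
dropout 0.1, 20–25 epochs — on 200 noiseless patients this reaches held-out
one-day-ahead glucose MAE ≈ 1.0–1.2 mmol/L against a cohort sd ≈ 2 mmol/L.

## Policy model

The policy and value heads are MLPs over the (frozen) patient-model states;
the policy outputs 41 logits masked by the patient's regimen schedule
(inferred from logged injections: dose tokens at scheduled slots, the
no-dose token elsewhere).  The joint loss is

    L = L_RL1 + ε₁·L_RL2 + ε₂·L_SL,   ε₁ = ε₂ = 1

* `L_SL`: cross-entropy of the logged dose under π.  Because the dose
  vocabulary is ordered, the imitation target is ordinally smoothed — a
  discretized Gaussian (sd 1.5 U) around the logged dose — which shares
  evidence between neighboring doses; with hard one-hot targets the
  41-way head needed far more data to separate conditional dose modes.
* `L_RL1`: −Σ A_t log π(a_t|s_t) on logged trajectories with advantage
  A_t = R_t − V(s_t); V is regressed on the discounted returns (coefficient
  0.5), the advantage is treated as a constant in the policy term, and
  advantages are standardized within each batch so the RL terms cannot
  swamp the imitation anchor.  Raw-return weighting is available via
  `use_advantage=False`.
* `L_RL2`: the same advantage-weighted form on trajectories *generated* by
  sampling a ∼ π and stepping the learned dynamics, starting from each
  day's last slot and rolling one day (depth 7) with a γ^K V bootstrap.
  Roll-out rewards are the analytic Magni reward of the glucose predicted
  by `f_P` at each rolled state rather than the learned reward head: the
  glucose head extrapolates the (locally linear) dose-response far better
  than a bounded reward regression, and passing it through the true reward
  preserves the hypoglycemia cliff exactly for doses rarely logged.

Training runs a short imitation-only warm-up (default 5 epochs; the value
head is fitted during warm-up) before the RL terms engage, so that early
roll-outs sample doses inside the clinically seen range where the patient
model is trustworthy.  The two-stage schedule is enforced: `train_policy`
refuses an untrained patient model unless explicitly overridden.  Whether
the two RL terms share one value function is an open design point; one
shared V(s) is used.

At the bedside (simulator evaluation), the dose decision is the rounded
probability-weighted mean dose under π — the natural point estimate for an
ordinal vocabulary; modal and sampling decodes are also provided.

## Planner

Decision-time planning is beam search over `f_T`: at each of K steps the
candidate doses are the policy's top-M tokens (M = 5; full 41-token
expansion available, and used by the exhaustive-equivalence tests), partial
plans are scored by accumulated discounted model reward plus a terminal
value bootstrap, the top B = 10 survive, and the best complete plan by
v = Σ γ^i r̂ + γ^K V(s_K) is returned.  Slots with no scheduled injection
are forced to no-dose.  Equal-value plans break ties toward the
lexicographically smaller dose sequence — a deliberate safety bias toward
less insulin.

## Off-policy evaluation

Per-step ratios ρ_t = π₁(a_t|s_t)/π₀(a_t|s_t); trajectory weight
w = Π ρ_t; `V_IS = Σ (wᵢ/N)·Gᵢ` and the self-normalized
`V_WIS = Σ (wᵢ/Σwⱼ)·Gᵢ` with `Gᵢ = Σ γ^{t−1} r_{i,t}` (t starting at 1, so
the first reward is undiscounted — the printed estimator convention; the
policy-side return recursion indexes from the current step, which is the
same convention shifted).  ESS = (Σw)²/Σw².  The behavior policy π₀ is estimated by
the same policy architecture trained with the imitation loss only, with
probabilities floored at 1e−3 (renormalized) to guarantee support; both
policies are evaluated under the regimen-schedule mask, so no-injection
slots contribute ratio 1.  The full-trajectory product is used in the WIS
weight.

## Numerical and design notes

* The neural stack is a small reverse-mode autodiff over numpy arrays
  (`rltitr.nn`): tensors record backward closures, a topological sweep
  accumulates gradients; layers are linear, embedding, layer norm, causal
  multi-head self-attention, dropout; the optimizer is Adam with L2 weight
  decay and global gradient-norm clipping.  Gradients are verified against
  central finite differences in the test suite.
* Degenerate inputs fail loudly: empty observation sequences, non-monotone
  timeslots, doses outside 1–40, inverted clip bounds, empty reward lists,
  zero behavior-policy probabilities (support violation naming the step),
  all-zero WIS weights, NaN training losses.
* Sequences longer than the padding length keep their most recent steps;
  padded positions cannot influence earlier states (causal masking).
* Checkpoints are single-file zip archives of parameter arrays plus a JSON
  config; loading reproduces predictions bit-for-bit.
* Problem sizes in the tests — 200 patients × 3 days for the learning
  studies, hidden width 32, 25/40 epochs, 40 evaluation patients, five
  seeds — were chosen as the smallest configuration at which the
  qualitative claims are stable under reseeding.

## Known limitations

* The simulator's linear, stationary dose-response is far simpler than
  human glucose dynamics; results quantify machinery, not clinical effect.
* One action per timeslot: a basal+bolus day is represented as
  class-specific actions at their conventional slots, so simultaneous
  same-slot injections of different classes are not expressible.
* The learned model's dose-response is only trustworthy near the logged
  dose distribution; planning and model-based roll-outs inherit that
  limitation (mitigated, not removed, by the warm-up, the numeric dose
  channel and glucose-grounded roll-out rewards).
* Off-policy estimates degrade as π₁ departs from π₀ (watch the reported
  ESS); no doubly robust estimator is provided.
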