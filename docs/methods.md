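# Methods

## The task

The flexible visual-motion discrimination (FVMD) task dissociates
perceptual decisions from motor plans.  On each trial two colored saccade
targets (red and green) appear at a left and a right location, randomly
swapped across trials; 400 ms later a random-dot motion stimulus moves at
315° or 135° with a coherence between 0 and 1.  Motion at 315° rewards a
saccade to the red target, 135° to the green target, so the correct
response side is the XOR of motion direction and color configuration: no
fixed stimulus–response mapping exists.  On zero-coherence trials the
rewarded side is a coin flip.

Model trials are rate-coded input channels, not rendered dot fields:

* **Motion (9 channels).**  Preferred directions evenly spaced over 360°,
  von Mises tuning.  Channel n carries
  `r_n = (2/3)(a c exp(κ cos(θ−θ_n)) + b N(0, 2) + sqrt(2/α) N(0, σ_in)) + d`
  with `a = 4/e^κ` after motion onset (0 before), `b` a 0/1 step at
  motion onset, `c` the coherence, and `d` a 2-amplitude untuned visual
  drive present from target onset.  At the preferred direction the tuned
  drive is `(8/3)c` independent of κ.  For `c = 0` the tuned term is
  replaced by the untuned constant `0.4·max(c)`.
* **Color targets (8 channels).**  Two channels per (hemisphere ×
  color); the subgroup whose color occupies the module's response field
  is active at 4/3, the other is silent.  Each hemisphere's target module
  sees the contralateral target location.

**Input adaptation.**  Sensory drives carry a transient-plus-sustained
profile: the exponential decay filter `f(x) = base^t · x` (base 1/3, one
decay unit per 100 ms) acts on the transient fraction of each drive above
a sustained floor (`sustained_frac`, default 0.5), starting at target
onset for the color channels and at motion onset for the untuned motion
drive.  Inputs therefore remain present until the end of the trial, as
required by the task (the color×location binding must be readable at
decision time); `sustained_frac = 0` selects the pure-decay profile for
sensitivity checks.  A 100-ms zero-input fixation period precedes target
onset (a longer fixation carries no information).

## The network

200 rectified-linear rate units, Δt = 20 ms, membrane time constant
τ = 100 ms (α = 0.2).  Two "hemispheres", each containing a motion module
and a target module; every nominal module has 40 excitatory and 10
inhibitory units.  Dale's law is enforced structurally: the trainable
matrix W parameterizes effective weights `|W| ⊙ mask ⊙ sign(presynaptic)`.

Connectivity is Bernoulli-sampled once per network: within a nominal
module p = 0.5; between the two modules of a hemisphere p = 0.25;
between corresponding modules of opposite hemispheres p = 0.10 with
excitatory sources only; no self-connections.  The expected recurrent
count is 4·(50·49)·0.5 + 2·(2·50·50)·0.25 + 4·(40·50)·0.10 = 8200.
Inputs project excitatorily (p = 0.32) to their module class; only
excitatory target-module units reach the two softmax response units,
densely contralaterally (p = 0.32) and sparsely ipsilaterally (p = 0.08).
Input and output weights are drawn N(0.2, 0.05²) and frozen; per input
channel and output unit, extreme low values are re-drawn from the
acceptable band so min ≥ ¾·max over the nonzero fan (a literal
redraw-whole-channel-until-valid rule has vanishing acceptance
probability at this fan-out).

**Short-term plasticity.**  Standard presynaptic
facilitation/depression: per presynaptic unit j, variables (u_j, x_j)
with `s_j = u_j x_j r_j` entering the recurrent drive; even-indexed units
facilitate (τ_f = 1.5 s, τ_d = 0.2 s, U = 0.15), odd-indexed units
depress (τ_f = 0.2 s, τ_d = 1.5 s, U = 0.45).

**Dynamics.**  `h ← (1−α)h + α·relu(W_eff s + W_in x + b + sqrt(2/α)
N(0, σ_rec))` with σ_rec = 0.3 by default (configurable).  σ_rec is a
free parameter; it was chosen by two constraints.  Below ~0.2 the task
is solvable almost feedforward and a quarter of trained networks never
align their feedback with the learned association (their CT−IT
modulation is zero or negative); at 0.5 every probed network aligns but
convergence takes ~1500 iterations.  At 0.3 all probed networks develop
positive feedback alignment and converge in 200–850 iterations.

**Initialization of W.**  Gamma-distributed magnitudes (shape 0.1) on
masked entries.  The gamma *scale* sets how much of a trained network's
weight statistics is inherited from initialization: at scale 1.0 every
cross-module group mean carries a ≈+0.06 excitatory offset that
initialization alone explains, swamping the learned sign structure of the
feedback projection.  At the default scale 0.02 the trained values
dominate and the selectivity-aligned structure (matched-excitatory /
nonmatched-inhibitory tendency) is visible in the group means.  h0 is
initialized small positive and trained; bias starts at 0.

## Training

BPTT with hand-derived adjoint gradients through both the rate and the
STP recursions (clipped STP updates use pass-through gradients inside the
feasible region; the |W| parameterization uses sign(W) as its
subgradient).  Gradients are validated against central finite differences
at 1e-7 absolute tolerance in the test suite.  Adam (β₁ = 0.9,
β₂ = 0.999), learning rate 0.01, global L2 gradient clip 0.1.  Only W,
bias and h0 are updated; masks, Dale signs, input and output weights are
frozen.

The loss is (a) cross-entropy of the softmax outputs against the correct
response, scored from 100 ms after motion onset to trial end; (b) an
activity cost `c_act·mean(h²)` (c_act = 1e-3); (c) a weight cost
`c_wt·mean(W_eff²)` (c_wt = 1e-4).  Batches of 256 trials balance
direction × configuration × coherence over the training coherences
{0.60, 0.90}.  Every 25 iterations a held-out 512-trial batch is scored
by window-mean argmax; training stops at ≥99% accuracy or 2000
iterations.  Under the defaults networks converge in roughly 200–850
iterations (about two to four minutes per network on one CPU core).
Testing uses the untrained coherences {0.75, 0.55, 0.35, 0}.

## Analyses

* **Behavior.**  Choice = argmax of the window-mean output probability
  (a per-step majority variant is available).  RT = first step of the
  first run of ≥3 consecutive post-onset steps with |p_L − p_R| > 0.8;
  600 ms fallback when the threshold is never held.
* **Direction selectivity.**  Sliding-window ROC (100 ms windows; 5 ms
  steps for 10-ms-binned spike data, one-step for RNN rates), oriented by
  each unit's preferred direction fixed in a 50–250 ms reference window;
  choice labels replace direction labels on zero-coherence trials.  The
  per-network DS–coherence correlation is the unit-mean Spearman
  correlation between ROC and coherence pooled over all windows of the
  trial; pre-onset windows anchor the chance end of the correlation
  (epoch-restricted variants run much higher, ~0.5–0.8, because they
  discard the uninformative part of the time course).
* **CT/IT.**  A trial is CT for a unit when the relevant target (correct;
  chosen on ambiguous trials) is contralateral to the unit's hemisphere;
  for RNN units "contralateral" follows the dense output projection.
* **Partial correlations.**  First-order partial correlations of
  windowed activity with the signed stimulus code (±{4,2,1,0} by
  coherence; positive toward the preferred direction) given the choice
  code (−2 preferred / +2 nonpreferred), and vice versa.
* **Modulation index.**  MI = (δ_contra − δ_ipsi)/(δ_contra + δ_ipsi),
  δ = mean rate difference preferred − nonpreferred in 50–250 ms,
  split by saccade side; undefined (flagged) when the denominator is 0.
* **Connectivity.**  Signed selectivity strengths (315−135 differential
  for motion units, red−green post-target differential for target units)
  label cross-module pairs matched/nonmatched; the match-weight statistic
  is the Pearson correlation between weight rank and the negated absolute
  rank difference of the two units' selectivities (sign fixed so that
  positive = stronger-matched pairs carry larger weights; a brute-force
  rank oracle pins the convention).
* **Perturbations.**  Feedback ablation (zero the within-hemisphere
  target→motion block), 100× weight shuffling over the existing feedback
  edges (per hemisphere; totals preserved exactly), specific/nonspecific
  group ablation, and no-feedback retraining with optional 1.176
  density compensation.  When landscapes of perturbed networks are
  compared with the intact network, the perturbed activity is projected
  through the intact network's choice axis and unit selection — refitting
  the axis per variant would place depths on incomparable scales — and
  the depth/separation comparison is made on the per-coherence
  landscapes at the nonzero coherences, paired over networks.
* **Landscape.**  Saccade-selective target-module units → PCA on
  condition-averaged activity (direction × coherence × choice), top 5
  components; linear SVM (C = 1) on last-100-ms means with 10-fold CV;
  the best fold's unit normal is the choice axis and its hyperplane the
  zero point.  The potential V(x, t) integrates the negative
  trial-expected drift outward from the boundary on a uniform grid (40
  bins over the central 99% of visited positions, a bin edge exactly at
  0); a midpoint rule makes constant drift g give V = −gx exactly.
  Unvisited bins stay blank and stop the outward integration.  For
  trained networks drift samples are pooled in 100-ms time bins, because
  by ~300 ms most trajectories have settled at the attractors and
  per-step occupancy near the boundary is too sparse.  Basin depth =
  −min V per side at 300 ms post-onset; separation = distance between
  the two minima; model aggregation keeps positions inside the
  contiguous visited span of ≥4 models.

## Synthetic electrophysiology

The generator emulates the schema of a parietal recording session in
this task (two directions; a four-step coherence ladder
0/0.13/0.25/0.50 typical of monkey psychophysics; target locations
re-randomized independently on every trial; correct and error outcomes;
RTs) with
injectable ground truth: logistic psychometric choices (slope 8, 2%
lapse) so error trials arise naturally at low coherence; drift-to-bound
RTs (bound/(v₀ + v₁·c) + Gaussian noise, clipped to 150–600 ms); ramping
direction selectivity whose stimulus-locked amplitude scales with
coherence and whose decision-locked component follows the choice (mixing
weight λ); a CT-only modulation g_mod (+g_mod on preferred, −g_mod/2 on
nonpreferred trials); an RT-coupled selectivity latency; Poisson counts
in 10 ms bins from −500 to +600 ms.  What it does not emulate: cross-
neuron noise correlations, non-Poisson spiking statistics, drift in
excitability across a session, and eye-movement artifacts — so passing
recovery tests validates the analysis code, not claims about biological
LIP.

The session-level CT-vs-IT test is a permutation test on the
saccade-side labels (statistic: unit-mean of δ_contra − δ_ipsi).  The
naive across-neuron t-test is ~4× anticonservative here because all
neurons share the same trials; permuting side labels is exactly
calibrated in this design, since the target configuration — and hence
the saccade side given the chosen color — is an independent fair coin.

## Problem sizes

Desk-scale defaults throughout: cohorts of 5 networks (a full-scale
study would train ~50), 640-trial test batteries (40 per direction ×
configuration × coherence cell), 50 mask draws for connection-count
statistics, 200 synthetic sessions for recovery/calibration, 1000
bootstrap resamples.  All are parameters.

## Known limitations

* The nonmatched-feedback group mean lands near zero rather than
  clearly inhibitory at desk scale: training reliably makes matched
  feedback more excitatory than nonmatched, but a net-inhibitory
  nonmatched average emerges only partially in 5-network cohorts (see
  the connectivity tests for the exact assertions).
* Several hyperparameters (κ, σ_in, σ_rec, learning rate, loss weights,
  init scale) have no canonical values and follow the conventions
  documented above; quantitative magnitudes of derived statistics (e.g.
  the match-weight correlation) depend on them and should be read as
  scale-level, not digit-level, quantities.
* The energy landscape is one-dimensional by construction; dynamics
  orthogonal to the choice axis are projected away.
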