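# Methods

## Causal networks and queries

All computation is over three binary variables (X1, Y, X2), with Y the middle
variable of one of three topologies: chain (X1→Y→X2), common cause
(X1←Y→X2), or common effect (X1→Y←X2). Joints are exact products over the 8
states, indexed by the bit triple x1·4 + y·2 + x2 (a fixed convention so
visit counts and CSV exports are stable). The default parameterization is
the one taught in the experiments the package emulates: base rates .5 for
all root variables; child-given-parent probabilities .75 (parent present) and
.25 (absent); for the common effect, a noisy-OR gate with strengths .5 per
cause and zero leak, so the effect never occurs without a cause and its base
rate is exactly 0.4375. Under these values the chain and common-cause joints
are identical, which the test suite asserts.

The experimental design crosses 27 inferences × 3 structures × 3 response
deadlines (243 trials per participant). An inference queries one variable
(always "present") while each of the other two is present, absent, or
unknown — 3 × 3 × 3 = 27, including three pure base-rate queries. Unknown
conditioning variables are marginalized over in both exact inference and the
sampler's counting rule. Conditioning events of probability zero raise an
error in exact inference; only the sampler-based estimators have a 50%
default.

## Sampler

Judgments come from a Metropolis–Hastings chain over the 8 states: start at a
prototype ((1,1,1) or (0,0,0), fair coin), propose uniformly one of the 3
single-variable mutations, accept with min(1, P(proposal)/P(current)),
re-recording the current state on rejection. Two conventions matter and are
fixed by analysis rather than taste:

- **The start state is recorded sample #1**, so chain length n means n − 1
  transitions. This convention — and only this one — reproduces the
  chain-length-2 response-type probabilities analytically (50% default with
  probability 25/27, 100% with 1/18, 0% with 1/54 for the focal conflict
  inference).
- **No burn-in, no thinning.** The prototype bias of short chains is the
  model's explanatory substance, not a numerical artifact to be removed.

`run_chains` vectorizes over chains (the per-step state update is a numpy
operation over all chains at once); `run_chain` is the scalar reference
implementation, and the tests check both against the closed form above. For
response-type analyses, `exact_response_type_probabilities` propagates the
exact distribution over (state, visited-set) pairs through the kernel — an
O(32 · chain length) enumeration that gives the exact probability of
computed/0/50/100 responses at any chain length.

## Judgment rules

The MS estimate is the relative frequency N_match/(N_match + N_other), with
every contributing state's count initialized at 1e-10 so an entirely
unvisited pair of outcome sets yields 0.5 rather than 0/0. The BMS estimate
is (N_match + β)/(N_match + N_other + 2β), the posterior mean after a
symmetric Beta(β, β) prior; β = 0 reduces exactly to the MS. Responses are
the point judgments (posterior means) scaled to 0–100 and are kept
continuous; participant rounding is not modeled. A linear scaled mapping
s·p is provided as an optional operation but excluded from the default model
menu; it is deliberately not clipped, since values outside the scale are a
property of that mapping the caller should see.

Default-response detection always uses the visitation criterion (were both
outcome sets reached?), never floating-point equality against 0/50/100.

## Fitting

With no closed-form likelihood, fitting uses probability density
approximation: per grid cell, simulate responses per query, estimate each
query's response density with a Gaussian KDE, and score the observed
responses by summed log density; the fit is the argmax cell. Choices the
method leaves open, fixed here and exposed as parameters:

- **Grid**: chain lengths 2, 4, …, 70 (35 values). β grid: 0, 0.1–0.9, 1,
  then for each sub-uniform value the β > 1 whose Beta(β, β) has the same
  total variation distance (TVD) from the uniform (computed by root-solving
  the unique density crossing in (0, ½); accuracy ≪ 1e-6), and 100 as the
  stand-in counterpart of 0 (a Beta(∞, ∞) prior would put all responses at
  exactly 50). This yields 1.11, 1.26, 1.45, 1.73, 2.14, 2.83, 4.14, 7.35,
  21.54 — 21 values, 735 cells.
- **KDE**: Gaussian kernel, Silverman bandwidth 0.9·min(SD, IQR/1.349)·n^(−1/5),
  fallback fixed bandwidth of 2.0 percentage points when the simulated set is
  (near-)degenerate, density floor 1e-10. No boundary reflection at 0/100
  (the simplest dialect; reflection would shift likelihoods near the edges
  and is left as future work).
- **Simulations per cell**: 10,000 by default, 2,000 in recovery studies.
  Within a cell, all 27 query distributions are computed from one shared set
  of chains, and chains are shared across β values at the same chain length —
  β enters only the judgment rule, so each cell/query marginal distribution
  is identical to independent simulation at a fraction of the cost.
- **Ties** in the argmax break toward the smaller chain length, then the
  smaller β (prefer the simpler process).
- **BIC** uses k = 2 (BMS) or k = 1 (MS, the β = 0 row of the same grid) and
  n = the responses in the fitted unit (27 in the standard design), not
  trials pooled across conditions. Per-participant posterior model
  probabilities are arithmetic means of the unit-level BIC weights.

`BMSGridSearch` is a scikit-learn-style estimator (`fit` on one unit's
responses; fitted attributes `chain_length_`, `beta_`, `log_likelihood_`,
`bic_`); `SimulationBank` holds the reusable simulated grid when fitting many
units.

## Parameter recovery

The recovery study generates ≥ 30 synthetic BMS participants with true
parameters drawn uniformly from the full grid, 27 responses each (one unit),
and refits them on a coarse grid — every other chain length (2, 6, …, 70)
crossed with eleven β values spanning both halves of the β grid — at 2,000
simulations per cell. Pearson correlations between true and estimated values
are the recovery index, with .75 as the pass bound for both parameters; runs
across several seeds land at r ≈ 0.8–0.95 per parameter.

Identifiability degrades at long chain lengths, because predictions change
less and less as chains grow. The package's test operationalizes this as
estimation error rather than correlation: the mean absolute chain-length
error for true values ≤ 40 is smaller than for true values > 40. (A
correlation restricted to the short-chain subrange is *lower* than the
full-grid correlation purely through restriction of range, so correlation is
the wrong instrument for a subrange comparison.)

## Synthetic data

The generator emulates the full 243-trial design: one fresh chain per trial,
one BMS judgment per chain, deadlines as pure labels (the deadline conditions
are not given any behavioral effect by default, since the fitted prior was
not deadline-dependent; a hook allows deadline-specific chain lengths for
power analyses), and an optional contamination rate substituting uniform
random responses (off by default). Tables use a plain CSV schema
(participant, structure, deadline, per-variable state or "unknown", queried
variable and value, response) with a line-numbered validator.

What the generator does **not** emulate: response times, joystick/mouse
response granularity, participant rounding, guessing mixtures, or
inference-dependent chain lengths. Passing tests therefore demonstrate that
the pipeline is correct and that parameters are recoverable under the model's
own assumptions — not that empirical data satisfy those assumptions.

## Analyses

Variability is indexed by the Gini Mean Difference (mean |v_i − v_j| over
unordered pairs, computed via the sorted-sample identity). Accuracy is
−|response − normative| and conservatism −|response − 50|, both signed so
higher is better/more conservative. For variability and distribution
analyses the 27 inferences collapse into seven symmetry groups (chain and
common-cause structures only; the common effect contributes too few
symmetric observations): conflict / ambiguous / consistent / base-rate
inferences, split by whether the queried variable is middle or terminal
(two known) or graph-adjacent to the known one (one known), with canonical
normative values 75, 50, 75, 62.5, 75, 90, 50 percent and per-participant
counts 24, 12, 48, 24, 24, 12, 18. Responses to queries whose exact
normative probability is below 50% are flipped to 100 − response;
exactly-50% queries are never flipped (a flip would be ambiguous and is a
no-op on the normative value). "Adjacent" means joined by an edge ignoring
direction, which gives the same grouping for the chain and common-cause
topologies. Predicted group variability averages the per-query predicted
distributions (after flips) as an equal-weight mixture, draws 10,000
responses, and takes their GMD.

## Problem sizes and determinism

Monte-Carlo responses and chain simulations default to 10,000 per condition;
recovery uses 30 participants and 2,000 simulations per cell, which makes a
full generate-and-refit study a ~20-second computation while leaving the
correlation bound a comfortable margin. All stochastic operations take a
single numpy Generator (or seed); CLI runs log their seed and configuration
hash in a manifest sufficient to replay them bit-identically.

## Known limitations

- The PDA likelihood inherits KDE bias at the scale boundaries (no
  reflection); likelihoods of responses at exactly 0/100 lean on the floor.
- Chain-length estimates above ~40 are noisy by construction (flat
  likelihood ridge); summaries of fitted chain lengths should be read with
  that in mind.
- Mixture/guessing response processes and adaptive chain lengths are out of
  scope; the generator's contamination hook exists only for robustness
  checks of the fitting pipeline.
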