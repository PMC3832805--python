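# Methods

## Model

The model is a two-layer sigmoid belief network over binary variables.
Roots are five latent causes (H1–H5), interpreted as contexts the
animal postulates to explain correlated events, plus the exogenous
press action A. Leaves are the observables: sounds S1–S3, levers
L1–L2, foods F1–F3. A node fires with probability
σ(bias + Σ active-parent weights); weights are in log-odds units, so a
weight of +4 turns a 2% background into ~90% when its parent is
active. The adjacency is fixed (Hi→{Si,Fi} for i≤3; H4→{L1,F1,F2};
H5→{L2,F1,F2}; A→{F1,F2}); only weights and biases are learned.

Latent causes are independent Bernoulli per trial bin, with no
temporal persistence: bins are separated experimental events, and the
marginal likelihood of a bin sums all 2⁵ latent configurations
exactly. This keeps the likelihood deterministic, makes brute-force
enumeration a usable test oracle, and avoids any latent-imputation
noise. Identical bins are aggregated by a multiplicity count before
evaluation; the paradigm produces only ~15 distinct bin patterns, so
likelihood cost is independent of training length. When the action
node is unobserved in a training bin it is marginalized like a latent;
at test it is always clamped (see below).

## Synthetic paradigm

Time is discretized into bins (think ~10 s of a session). Defaults:

| parameter | default | meaning |
|---|---|---|
| n_pavlovian_per_cs | 200 | bins per CS in Pavlovian training |
| pavlovian_pairing_prob | 0.45 | P(food in a CS bin) — food arrives intermittently while the sound plays |
| n_instrumental_per_lever | 1600 | bins per lever session |
| press_prob | 0.9 | P(press in a lever bin) |
| reinforce_prob | 0.05 | P(food per press): the RR20 random-ratio schedule |
| n_blank | 400 | empty inter-trial bins per phase |
| cross_food_leak | 0.0 | P(other instrumental food in a lever bin) |

The counts emulate extended training (several sessions per phase) and
were chosen so the posterior concentrates enough for the qualitative
weight pattern to be stable across seeds; they cost nothing at run
time thanks to pattern compression. Pairing below 1 reflects the real
paradigm, where pellets arrive on a time schedule during a long CS, so
most CS bins contain no food. press_prob below 1 matters
structurally: the press/no-press contrast inside lever sessions is
what identifies the action→food weights separately from the lever
contexts — with A present in every lever bin the two are confounded
and the action weight is undetermined in sign. Blank bins anchor the
background rates. Test bins (lever plus at most one sound, foods and
action unobserved) are never added to the training set: the test runs
in extinction precisely so that no further learning occurs.

## Priors

All parameters get independent Gaussian priors. Link weights are
zero-centered with scale 5.0; biases of observables are centered at
−4.0 with scale 0.5; latent biases are centered at −2.0 with scale
0.4. The three families encode one idea — *a mostly-empty, rare-event
world* — and each choice is load-bearing:

* **Zero-centered weights, generous scale.** Before training the
  agent holds no belief about how causes affect events. The scale
  must accommodate strongly saturated links: the inhibitory
  context→food weights have to reach several log-odds *below* an
  already-low background before the "different" test condition stays
  at baseline. A scale of 2 caps them too early and leaves partial
  transfer in that condition; a much larger scale leaves long flat
  plateaus on which saturated weights drift, inflating the posterior
  spread of sums like b_F2 + w(H2→F2) + w(H4→F2) + w(A→F2) that the
  test-phase predictions pass through σ(·).
* **Deep observable backgrounds.** Foods, sounds and levers are rare
  absent their causes. Deep backgrounds serve two purposes: cue→cause
  inference at test is crisp (the likelihood ratio σ(b+w)/σ(b) is
  large), and the reward logit in lever sessions sits far above
  background, which is what makes *both* the context→food and
  action→food weights positive, as in the trained network the model
  is meant to produce. If biases are instead learned under a wide
  zero-centered prior they collapse to wherever the blank bins push
  them, and the inhibitory links — no longer needed to explain the
  absence of the other food — are never learned.
* **Latent causes rare a priori.** The likelihood is exactly
  invariant under relabeling any latent cause as its own absence
  (negate its outgoing weights, shift child biases); a zero-centered
  latent-bias prior leaves the two labelings equally probable and
  chains land in mirrored modes. Centering below zero selects the
  convention "a context is occasionally present and excites its
  observables". The fairly tight scale (0.4) also suppresses a
  near-degenerate relabeling in which a Pavlovian cause captures only
  the sound+food co-occurrence bins (an "event" rather than a
  context), which would corrupt the test-phase predictions.

## Inference

Single-parameter random-walk Metropolis over the 28 parameters, in a
canonical sorted order, with per-parameter Gaussian proposals adapted
during burn-in toward a 20–45% acceptance rate and frozen afterwards.
Two independent chains run by default for 15,000 iterations each
(5,000 burn-in, thinning 5; ~40 s on one core), pooled after burn-in.
Convergence is monitored by rank-normalized split-R̂ and ESS (via
arviz) with a 1.1 flag threshold.

Chains start at the posterior mode, located by L-BFGS from a
positive-basin point (prior mean with link weights at +2). This is
deliberate: because of the relabeling symmetries above, the posterior
has well-separated modes that single-parameter moves cannot cross;
started at the prior mean, chains fall into arbitrary labelings and
split-R̂ exceeds 1.5 with effective sample sizes in the single
digits. Mode-started chains at the final settings give R̂ ≤ ~1.1
across parameters and seeds.

The one-latent/one-food toy model provides an independent correctness
check: MCMC posterior means and standard deviations are compared with
dense 3-D grid integration (tolerances 0.05 absolute on means, 10%
relative on sds).

## Test-phase evaluation

Evidence fixes the visible cues; the latent posterior over all 32
configurations is computed exactly per posterior draw; food
probabilities are posterior-draw averages of
Σ_config P(config|evidence)·σ(food activation). The action is
clamped, never inferred: pressing is the option being evaluated, so
A=1 is an intervention and contributes no evidence about latents.
Efficacy is the predicted probability of the action's own food under
do(A=1); utility sums the *other* foods' probabilities weighted by
their current values (zero under satiety — devaluation); the response
score is R = α·E + β·U with α = β = 1 by default. The linear rule is
the minimal combination preserving the decomposition; effects are
reported as differences from baseline, not as absolute press rates.
Because efficacy never reads food values, the specific-PIT effect is
bit-for-bit invariant under devaluation, and the general-PIT effect
vanishes exactly at zero utility — these are structural properties of
the decomposition, not tuning outcomes.

Utility counts only non-target foods: general PIT requires an
*additional* predicted reward. A consequence is that the model does
not reproduce the overall drop of baseline responding in sated
animals; motivational modulation of baseline vigor is out of scope.

## What the generator does and does not emulate

It reproduces the contingency structure of the paradigm — cue/food
pairing, lever/press/reward statistics under a random-ratio schedule,
phase separation, context exclusivity, and the optional context
overlap (cross_food_leak) — with known ground truth and exact
reproducibility per seed. It does not emulate within-session learning
curves, response latencies or vigor, interval schedules, magazine
approach, stimulus generalization between sounds, or any temporal
correlation between bins. Passing tests therefore show that the
*model* behaves as claimed under the paradigm's statistics; they do
not validate it against real behavioral data.

## Numerical choices

Log-sigmoids are computed via log1p-style identities (no overflow up
to |logit| ~ 700); the enumeration uses a hand-rolled logsumexp with a
per-pattern max shift. The latent-posterior normalizer cannot
underflow to zero because every sigmoid factor is strictly positive;
an internal error is raised if it ever does. Equality tolerances in
tests are 1e-10 against enumeration oracles. Sweep runs derive
per-condition seeds from a root seed through named SeedSequence
substreams, so every experiment is reproducible end to end from one
integer.

## Known limitations

* The three prior families are informative and jointly tuned to the
  regime in which the network expresses all three transfer effects;
  the qualitative pattern is robust across seeds at the defaults, but
  far outside them (e.g. near-deterministic Pavlovian pairing, or
  wide flat bias priors) individual effects degrade for the
  structural reasons described above.
* The action→food weights are only sign-identified through the
  press/no-press contrast; under press_prob = 1 their posterior sign
  is undetermined. Relatedly, the context→own-food weights
  (H4→F1, H5→F2) have true generative value zero and their posterior
  sign is not a stable model output.
* Habitual responding, motivational effects on baseline rates,
  aversive (LiCl) devaluation and neural localization are not
  modeled.
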