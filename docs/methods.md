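# Methods

This note documents the model as implemented: its assumptions, the
constants that matter and why they have the values they do, what the
synthetic data generator does and does not emulate, and the numerical
choices a maintainer would want to know about.

## Plant, target and controller

All computation is in SI units (radians); degrees appear only at I/O
boundaries, and the trial data dialect stores stiffness in Nm/deg
(conversion ×180/π; 0.30 Nm/deg ↔ 17.2 Nm/rad, checked by the parser).

The wrist is a rigid inertia I driven by muscle torque and the spring
force, integrated with the explicit first-order scheme the model is defined
with — the discrete system *is* the model, so no adaptive integrator is
used. The error state x = (θ−t, θ̇−ṫ) follows the same double-integrator
form, which makes the direct error-state simulation exactly equal to
wrist-minus-target on shared noise draws (property-tested).

**Effective inertia I = 1.0 kg·m².** This is deliberately not the physical
inertia of a hand (~0.0025 kg·m²). The framework is behavioural: the
feedback gains map angular error to torque, and the time scale of the
closed loop is set by L/I. Three constraints pin the regime: (i) the
controller's stiffness L_p must lie *between* the soft (0.3) and hard
(17.2 Nm/rad) springs, or the coupling manipulation cannot matter; (ii) the
closed-loop bandwidth must sit just above the target band (0.12–0.64
rad/s), or tracking is trivially good or hopeless; (iii) the partner's
feedback policy must be identifiable from 40 s of interaction, which fails
when L/I approaches a deadbeat loop. I = 1 with Q = diag(1, 0.1), R = 0.03
and q = 1 gives L = (5.72, 3.85) Nm/rad and a ~1.3 rad/s loop, satisfying
all three. Both I and R are configurable.

**Force cancellation.** The command is u = −L·x̂ − F, the certainty-
equivalent optimal policy when the additive disturbance F is felt and
therefore known. Without the cancellation a pure error-feedback controller
must hold a standing error F/L_p against the spring, which mechanically
drags the better partner by several degrees at hard coupling — contrary to
both the observed behaviour (the better partner is not hindered) and the
model logic (goal-integration predictions flat in stiffness). With
cancellation the interaction is purely informational, and the interaction
effort grows with stiffness through the |F| term in |u|.

**Sensory model.** Visual observations of the target's position and
velocity enter every step with i.i.d. noise (σv, 3σv per second);
σv ∈ [0.5°, 8°] is the per-subject skill parameter, calibrated so solo RMS
errors span ≈1.2–5.7°, the empirical 1–6° range. The 10-spot/400 ms display
cloud is modelled explicitly in the protocol module for completeness, but
the tracking filters consume the per-step observation stream of the
observation equation. Proprioception (σ = 0.005 rad) is effectively exact.
Sensory-delay compensation (forward propagation through the noise-free
state equation) is implemented but defaults to zero delay, since no latency
is specified anywhere.

**Force transduction in connected trials is noiseless.** The framework
treats the partner's wrist as known through the interaction force and books
*all* haptic-channel uncertainty about the partner's goal into
σ̃²v + σ²s(K). Adding sensing noise on F would double-count that budget and
would make goal integration stiffness-graded, which contradicts its
defining prediction. The haptic-*tracking* condition, by contrast, models a
human's limited torque sensing (σ_F = 0.05 Nm) precisely because its
purpose is to emulate the human control experiment that σ²s is calibrated
from.

## Interaction strategies

*Follow the leader.* The observation switches wholesale (z = θ−t or
z = θ−θ̃): while the partner's wrist is strictly nearer the target,
the agent locks onto it (position and velocity, claimed noise 0.005 rad /
0.01 rad/s) and receives no visual update; ties go to the target. The
branch is evaluated on true distances — it is the strategy's definition,
not an inference. The result is a pursuit of the momentarily-closer wrist:
the better partner is dragged badly; within this implementation the worse
partner still gains (they mostly follow a better proxy), so the *pair mean*
improvement is negative rather than each partner's individually.

*Goal inference.* Each agent runs a linear 4-state Kalman filter over
[partner's internal error estimate (2), target state (2)]. Because the
population is homogeneous and forces are cancelled, the partner's wrist
acceleration each step equals −L·(their posterior error estimate) exactly,
so the filter's generative model — partner filter gain G from the known
σ̃v, shared L, target prior — is exactly matched, and the inferred goal
approaches the information ceiling: the partner's own estimation error.
The goal prior is an Ornstein–Uhlenbeck process (velocity leak 1.0 /s,
position leak 0.2 /s) matched to the multi-sine's stationary moments; it
keeps the inference bounded when the force carries little information
instead of letting an unanchored random walk drift without limit.

*Fusion.* The inferred goal enters the error-state filter as an extra
position/velocity channel at the claimed variance σ̃²v + σ²s(K) (velocity
channel scaled by the same factor as vision). Goal integration sets
σ²s ≡ 0 — so it over-trusts the haptic channel at soft coupling, which is
exactly the model's documented failure mode — and neuromechanical goal
sharing uses the calibrated table; at the hard level σ²s = 0 by
construction, so the two strategies coincide there (bit-identical,
regression-tested). Fusion begins after a 5 s burn-in.

*Identification.* The joint state–parameter estimation of the partner's
gains is implemented as a 10-state extended Kalman filter (the gain-state
products are the nonlinearity; Jacobians are rebuilt each step) with the
own-target substitution active, a conservative (3×) force-noise assumption
that suppresses a mean-reversion bias on the velocity gain, and a pure
integrator target model (the goal states are vision-anchored here, so the
OU leak would only bias them). On the planted-gain recovery harness the
20-seed median error is ≈8.5 % (joint) at hard coupling, degrading
monotonically to ≈11.5 % at soft. Inside closed-loop dyad simulations,
however, excitation is poor (a good partner's error is small) and
errors-in-variables shrinkage makes in-loop identification unreliable; the
strategies therefore default to the *like-me* prior — partner gains equal
to own — which is exact in the homogeneous synthetic population.
Identification and inference remain available as standalone operations on
recorded force/proprioception histories.

## Metrics and effort bookkeeping

Tracking error is the RMS cursor–target distance over the trial.
Improvement Δc = 1 − e_c/e and relative error Δp = 1 − e_p/e pair each solo
trial with the nearest preceding connected trial within the same stiffness
block (the reverse pairing and the reciprocal effort convention α/α_c − 1
are available behind flags; the shipped conventions follow the sign logic
of the published narrative: elevated connected-trial effort is positive).
The simulated effort proxy of a trial is mean |u| (Nm). Recorded efforts in
the trial-pair tables add a tonic baseline of 1.0 Nm-equivalent, standing
in for the tonus/co-contraction floor of torque-calibrated EMG; this places
the interaction-effort ratio E in the 0–0.5 range of the published effort
axis. Qualitative effort checks (the ≥2× follow-the-leader inflation, the
better partner's elevated effort) are run on the raw mean-|u| ratios,
which do not depend on the baseline. Better/worse roles are assigned per
dyad (the subject with the larger mean relative error is the worse
partner), as in the dyad-level analyses.

## Statistics

The improvement and effort models are linear mixed models with a dyad-level
random intercept, fitted by maximum likelihood whenever a likelihood-ratio
test consumes them (REML available for coefficient reporting). Full random
slopes for all coefficients are not estimable on 14 dyads; an intercept +
Δp-slope option exists and the structure used is recorded on each fit. The
3-df stiffness LRT is calibrated: under a null generative model its
rejection rate is ≈5 % over 500 synthetic datasets (acceptance-tested
within the 99 % binomial band). The repeated-measures ANOVAs (role ×
stiffness) test Mauchly sphericity and apply Greenhouse–Geisser correction
to the stiffness effects when it rejects; post-hocs are Tukey–Kramer within
role, and the six one-sample effort t-tests use α = 0.05/6.

## Synthetic populations and the reference curves

The generator simulates complete sessions — 45 trials of 40 s in three
15-trial stiffness blocks, medium first, hard/soft order a seeded
permutation, connected trials by a fair coin, per-trial phase offsets —
for dyads whose two σv values are drawn uniformly from the skill band, and
writes 19-column trial-pair tables (errors deg, efforts Nm-equivalent,
stiffness Nm/deg, dyad id, block order). Co-contraction columns carry a
constant placeholder and reciprocal-activation columns the raw |u| mean;
the headline analysis uses neither. What the generator does *not* emulate:
learning or fatigue across the session, EMG time series, signal-dependent
motor noise, trial-to-trial adaptation of the strategies, or social
factors. Passing tests therefore show that the *pipeline* recovers planted
structure and that the *model* produces the documented qualitative surface
— not that real dyads are distributed like the synthetic ones.

The sensitivity analysis scores each strategy's fitted improvement/effort
curves (pooled least-squares fits of the same fixed-effect forms, on a
common Δp grid across the three stiffness levels) against **stylized
reference curves** — synthetic constants encoding the published pattern
(worse-partner improvement graded ≈0.1→0.4 with stiffness, better partner
flat, better-partner effort positive and graded at medium/hard) on the
published axis scales. They stand in for the empirical mixed-model fits
when the experiment's data file is unavailable and are labelled synthetic
wherever they appear. Scores are mean absolute and root-mean-square
deviations; both must give the same strategy ordering. The default grid is
3 × 3 cells (q ∈ {0.25, 1, 4}, σ²μ ∈ {0.005, 0.02, 0.08} (rad/s²)²) with
four paired seeds and 8 dyads × 5 trials/block per cell — chosen so the
full grid runs in about a minute; a 5 × 5 × 5-seed grid is behind a flag.
Cells whose solo trajectories exceed an RMS-jerk ceiling of 3 rad/s³
(≈4× the default-configuration jerk) are marked unscored rather than
failing the sweep.

## Numerical choices and degenerate inputs

Kalman updates in the compiled kernels use closed-form 2×2 and
scalar-innovation forms; covariances get a 1e-12 position-jitter per
predict to stay positive definite over 8000 steps. The coupling inversion
θ̃ = θ + (F + D(θ̇ − θ̃̇_prev))/K handles the damping term with a
backward-difference recursion (exact to O(dt) on noiseless records) rather
than dropping it. Zero coupling stiffness raises identifiability errors in
every force-channel operation (haptic tracking, identification, inference);
a dyad at K = 0 reduces bit-exactly to two solo runs on the same per-agent
noise streams, and swapping agent labels swaps the outputs exactly (noise
is seeded per subject, not per slot). Non-finite observations skip the
filter update and are flagged. Mixed-model fits retry with derivative-free
optimizers when the default optimizer's Hessian is singular at a variance
boundary.

## Known limitations

* The empirical trial-pair and haptic-tracking data files are not
  redistributed; the empirical-statistics path is implemented and tested
  only mechanically (parsers, graceful degradation) plus via generative
  recovery.
* The simulated haptic-tracking calibration produces a steeper σ²s profile
  than human data likely would (the simulated hard-coupling floor is
  superhuman), which compresses the neuromechanical strategy's soft/medium
  improvement relative to the published curves. Supplying the real
  calibration file (`analysis/01_calibrate_haptic.py --s2 ...`) replaces it.
* Under follow-the-leader the worse partner retains a small positive
  improvement here, where the published simulations report detriment for
  both partners; the pair-mean detriment and the ≥2× effort inflation are
  reproduced.
* Effort magnitudes at hard coupling depend on the tonic-baseline constant;
  only trends and ratios should be interpreted.
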