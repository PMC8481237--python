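# Methods

## Model

A trial hides a signed motion coherence *c* (fraction of coherently
moving dots, sign = direction; `+0.128` ≡ 12.8% rightward). Momentary
observations are i.i.d. Gaussian per 10-ms step, z_t ~ N(c, w_z). The
agent's internal model is deliberately *incomplete*: it does not know
the discrete set of coherences used in the experiment nor the true
observation noise. It carries

* a Gaussian prior over c, N(0, σ₀), approximating the across-trial
  distribution of coherences it has experienced, and
* a learned likelihood width σ_z in place of the true w_z.

Conjugacy makes the posterior after t steps Gaussian:
σ_t² = 1/(t σ_z⁻² + σ₀⁻²) and μ_t = σ_z⁻² σ_t² Σz_j. The direction
choice is the sign of μ_t (ties broken by a seeded fair coin);
confidence is Φ(|μ_t|/σ_t), the posterior mass on the chosen side.
With a sure-bet option worth r_sure = ratio·r_direction, utility
maximization opts out exactly when confidence ≤ ratio (ties to the
sure bet).

Because μ_t/σ_t² = σ_z⁻² Σz_j, the belief dynamics are a re-scaling of
a drift-diffusion process on V_t = Σz_j, and any bound Θ′(t) on |μ_t|
is equivalent to the bound Θ(t) = (t + σ_z²/σ₀²) Θ′(t) on |V_t| —
an identity the suite checks to bit-level stop/choice agreement.

## Stopping rule and the predictive distribution

With observation cost k per step, the agent stops when the expected
one-step confidence gain, E[Φ(|μ_{t+1}|/σ_{t+1})] − Φ(|μ_t|/σ_t),
drops to k/r_direction. The expectation is over the agent's forecast of
the next observation. Two forecasts are implemented:

* `predictive="posterior"` (default): the full posterior predictive
  N(μ_t, √(σ_t² + σ_z²)) — the Bayes-exact forecast under the agent's
  own generative model. Under this forecast the bounded simulations
  reproduce the published cost effects at the stated cost of 10⁻⁴
  (accuracy 81.6→79.5%, P(high) 64.7→83.7%, P(high|error) 31→70%,
  d′ 1.80→1.65, meta-d′ 1.80→1.23), which is why it is the default.
* `predictive="likelihood"`: N(μ_t, σ_z), the learned likelihood
  recentred on the current mean, ignoring the residual uncertainty in
  the inferred coherence. Under this forecast the same cost produces a
  much weaker effect (accuracy 81.2%, P(high|error) 55%).

The gain integral is evaluated with paired 48/96-node Gauss–Legendre
panels split at the |μ| kink (disagreement beyond 1e-8 falls back to
adaptive quadrature, absolute tolerance 1e-10); the iso-gain bound is
bisected to 1e-6 in μ, bracketing each step with the previous step's
bound since the bound collapses over time. Cost accrues per
observation taken, including the first.

**The one-step rule is near-optimal but not the DP optimum.** Exhaustive
finite-horizon dynamic programming on a discretized belief grid (and,
as an independent check, exact breadth-first tree enumeration) shows
the optimal continue-region extends beyond the one-step bound at
mid-trial steps: close to the bound, continuing retains option value
that a single-step gain comparison ignores. On the toy instance used
in the tests (σ_z = 2, σ₀ = 1, cost 10⁻³, H = 10) the myopic agent's
expected utility falls short of the DP value by ~6×10⁻⁴ — under one
observation cost — and dominates every fixed-sample-size strategy; the
bound locations differ by up to 0.24 in μ at mid-trial. The package
implements the one-step rule because it is the model whose simulations
match the published behaviour; the DP comparison lives in the test
suite as an oracle.

## Synthetic task

`TaskConfig` defaults define the study conditions: seven coherence
magnitudes {0, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2}% with uniform level
and sign sampling (so each signed level has expected frequency 1/14),
durations 100–900 ms in 10-ms steps, and a sure-bet offered on an
independent fair-coin half of trials. Durations follow a truncated
exponential with a 120-ms scale (mean ≈ 210 ms). That scale is not a
free knob: the estimation pipeline ties the prior width to the task
mixture through σ₀² = Var(c) + σ_z²·E[1/t], and the reference
parameter sets (w_z, σ_z, σ₀) = (0.90, 1.60, 0.46) and
(1.69, 3.59, 0.87) imply E[1/t] ≈ 0.054–0.063 — a harmonic-mean
duration near 160–180 ms that a uniform duration mix (E[1/t] = 0.028)
cannot produce. The 120-ms scale solves the consistency constraint
midway between the two reference sets; uniform durations remain
selectable.

Fixed-duration semantics: when |μ_t| crosses the bound the belief
freezes (later observations are ignored) but the trial runs to its
scheduled end; choice, confidence, and wagering all use the frozen
belief. At zero coherence correctness is a fair coin, mirroring the
random reward rule, and such trials are excluded from accuracy-based
fits. Reaction-time semantics: the trial ends at the bound;
`simultaneous` reports confidence at the bound, `sequential` keeps
updating the belief through the non-decision time (default 250 ms) and
reports the refined confidence signed by the committed choice — it can
fall below 0.5, representing a change of mind that revises the report
but not the choice.

What the generator does **not** emulate: motion-energy structure of
real dot stimuli, lapses, sequential dependencies, attention or
engagement drift, and delay-period events. Passing tests therefore
establish internal consistency of the model and pipeline, not fidelity
to any animal's data.

## Parameter estimation

1. `fit_wz`: rightward choices on no-sure-bet, nonzero-coherence trials
   are Bernoulli(Φ(√t·c/w_z)); bounded 1-D MLE on w_z ∈ [0.05, 10].
2. `estimate_prior`: one draw N(c, noise/√t) per trial, Gaussian MLE of
   the pooled draws. The prior mean is reported but the model clamps
   μ₀ = 0 (symmetric task).
3. `fit_sigma_z`: the stated belief Φ(σ_z⁻² Σz / √(tσ_z⁻² + σ₀⁻²)) is
   fitted to the recorded choices with the per-trial observation sums
   re-simulated from (c, t, w_z) — the experimenter never observes the
   subject's actual samples. Bounded 1-D MLE on σ_z ∈ [0.05, 20].
4. `iterate_prior_noise`: steps 2–3 alternate, the prior re-drawn with
   the current σ_z, until |Δσ₀| < tol (default 10⁻³, max 20 passes).
   Common random numbers are reused across passes so the fixed point is
   deterministic given the generator. The iteration contracts by
   roughly ×3–4 per pass.
5. `fit_utility_ratio`: P(sure | c, t) has the closed form
   P(|Σz| < s*(t)) with s*(t) = Φ⁻¹(ratio)·σ_z²·√(tσ_z⁻² + σ₀⁻²);
   bounded MLE on ratio ∈ (0.5, 1).
6. `particle_filter_loglik` / `grid_search_cost_model`: for a positive
   cost the choice probability has no closed form; it is estimated by
   forward-simulating particles (default 20,000) through the bounded
   policy per (c, t) condition, and the (cost, w_z) pair is fitted by
   grid search (reference resolutions 10⁻⁵ for cost, 0.01 for w_z) with
   the step 2–4 inner loop re-run at every w_z.
7. `vuong_test`: non-nested model comparison,
   Z = [L₁ − L₂ − ½(K₁−K₂)ln N] / (√N·w), with w the root mean square
   of the pointwise log-likelihood ratios (uncentered by default; the
   centered textbook variant is a flag), plus the unpenalized variant.

**Identifiability.** With free observations the direction choices are
the sign of the observation sum, so they identify w_z only; the
estimator for (σ_z, σ₀) converges to a pseudo-true fixed point set by
w_z and the task mixture, not to the generating agent's internal
values. Recovery runs at 5×10⁴ trials return w_z within ~2% and the
sure-bet threshold within ~0.02, while σ_z comes back ~8% (M1 values)
to ~27% (M2 values) above the generating numbers — the measured fixed
point, not an estimation bug. Estimates of σ_z/σ₀ from this pipeline
should be read as self-consistent calibration values for the data at
hand.

## Metacognition

Equal-variance SDT throughout. d′ = z(HR) − z(FAR) with the log-linear
half-count correction for empty cells (applied identically to type-1
and type-2 rates and counted in the result). Binary-rating meta-d′ is
the MLE of the rating counts conditional on each (stimulus, response)
cell, with the type-1 criterion carried over in scaled form
(meta-c₁ = c₁·meta-d′/d′) and free type-2 criteria on both sides;
optimization is Nelder–Mead on (meta-d′, log offsets). The cost
analysis uses σ₀ = 0.46 (the M1 fit); the alternative σ₀ = 0.75
changes the zero-cost numbers negligibly and weakens the cost effect
(it widens early bounds), and is one parameter change away.

## Experiments and their problem sizes

The scripted analyses default to the study-scale sizes (10⁶ trials for
the cost/metacognition analysis, 2×10⁴ trials per coherence for the
reaction-time analysis, 10⁷ trials for the classifier analysis); the
test suite and acceptance checks run the same code at reduced sizes
chosen so every Monte-Carlo assertion keeps a ≥3–4 standard-error
margin: 2×10⁵–10⁶ trials for the cost analysis, 2,500 trials per
signed coherence for the reaction-time analysis, and 1.5×10⁵–10⁶
trials for the classifiers. The classifier threshold is placed
analytically at the median of |Σz| over the subject's samples so
P(high) = 0.5; classifiers are unregularized logistic fits evaluated
on a held-out 20% split, falling back to ordinary regularization when
the data are separable (flagged in the outcome).

## Known limitations

* The one-step stopping rule is provably not the exact DP optimum (see
  above); the acceptance suite keeps a strict DP-equality check that
  documents the deviation.
* σ_z and σ₀ are pseudo-identified at zero cost (see Identifiability);
  the corresponding strict recovery checks document the fixed-point
  bias rather than being relaxed.
* Multi-level confidence ratings, response-specific meta-d′,
  reward-rate optimization across trials, and time-varying cost
  schedules beyond validation are out of scope.
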