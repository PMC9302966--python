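# Methods

This note documents the analysis model, the synthetic-data generator,
the numerical choices, and the limits of what the validation shows.

## Analysis pipeline

The unit of observation is one utterance (trial) of a monosyllabic /ɛ/
word, represented by its F1 trajectory sampled uniformly (default
`step_ms = 5`; sample *k* is time *k*·step after vowel onset) in mels
(`m = 2595·log10(1 + f/700)`; the constants are exposed in
`f1adapt.units`).

**Roles.** Within each (participant, study) session, adjacency by trial
index defines the roles: perturbed trials (up/down); *post-perturbation*
trials — unperturbed trials directly after a perturbed one, the carriers
of one-shot adaptation; and baseline trials. The compensation baseline
is by default *all* unperturbed trials (including post-perturbation
trials; `PipelineConfig.exclude_post_from_comp_baseline` removes them,
and `comp_baseline_role="baseline_adapt"` restricts both analyses to
unperturbed-after-unperturbed trials). The adaptation baseline is always
the unperturbed-after-unperturbed set. Post trials are paired to their
preceding perturbed trial regardless of whether the word matches
(`same_word_pairs_only` restricts to same-word pairs for sensitivity
analysis).

**Filtering.** Vowels shorter than 100 ms are dropped (inclusive
boundary: ≥ 100 ms is kept). After responses are computed, participants
whose sign-corrected average lies more than 4 SD from the group mean on
either measure are excluded in a single, non-iterative pass.

**Baselines and normalization.** For each (participant, word), the
baseline is the pointwise mean across baseline trials, where each time
point averages the trials that reach it, truncated at the last point
with at least `baseline_min_n = 3` contributors. Pairs with fewer than
3 baseline trials are dropped from analysis. Normalization subtracts the
baseline on the common time support.

**Windows.** Half-open `[t0, t1)`: compensation 150–250 ms, adaptation
0–100 ms (alternative 50–150 ms via config). A window mean is computed
when at least `min_coverage = 50%` of the window has samples — partial
vowels contribute with the samples they have. Participant-level
responses average the normalized trajectories first (pointwise, with the
same truncation rule) and then take the window mean; with unequal trial
lengths this differs from averaging per-trial window means, and the
average-then-window order is the one used.

**Sign correction.** For analyses that pool directions, responses from
up-shifted (or post-up) trials are multiplied by −1, so positive always
means "opposing the shift". Double application is an error, tracked by a
flag column.

## Statistical models

**Direction models.** `response ~ direction + (1|participant) +
(1|study)`, treatment-coded with down as reference so β estimates
up − down. Estimation is REML. Because every model in this package is a
Gaussian model with crossed random *intercepts*, the covariance
V = σ²ₑI + Σₖ σ²ₖZₖZₖᵀ admits exact Woodbury algebra; the restricted
likelihood is evaluated in O(n·q²) (q = number of random levels) and
maximized by Nelder–Mead over log-variances with two starts. This
in-package fitter exists because generic mixed-model optimizers proved
fragile on variance-boundary fits in this design; it is validated in the
test suite against statsmodels `MixedLM` and against R `lme4`/`lmerTest`
on shared fixtures (agreement to ≤0.1% on β/SE and ≤2% on df). A factor
with a single observed level (e.g. study in a one-study dataset) is
dropped with a note; with no usable factors the model reduces to OLS.

**Satterthwaite df.** For coefficient *j* with sampling variance
φ(θ) = [(XᵀV(θ)⁻¹X)⁻¹]ⱼⱼ, df = 2φ²/(gᵀAg), where g = ∇φ (central
differences over θ = variances) and A is the inverse observed REML
information (numerical Hessian). p-values use the t distribution at that
df. Effect sizes: d = β/σ_residual; per-term partial η² = t²/(t² + df)
(the η² definition is a package choice and is labeled as partial in
output).

**t-tests.** Paired t on participants' up vs down averages and
one-sample t per direction. Cohen's d is mean/SD (one-sample) or
mean(diff)/SD(diff) (paired). Zero-variance inputs are reported as
undefined rather than raising.

**Cluster-based permutation.** Over per-participant average normalized
trajectories on 0–250 ms: one-sample t per time point (or paired t on
per-participant condition differences), two-tailed threshold at
`alpha_point = 0.05` with df = n−1 per time point, clusters = maximal
same-sign suprathreshold runs, mass = Σt. The null is the distribution
of the maximum |mass| under per-participant whole-trajectory sign flips
(vs zero) or condition swaps (between; equivalent to sign-flipping the
differences — the between-condition test is paired, matching the
within-participant design). Cluster p = (1+b)/(1+n_perm) for random
permutations (never zero); when 2ⁿ ≤ n_perm the full set of assignments
is enumerated and p = b/2ⁿ, which is exact and includes the identity.
Participants contribute at the time points they cover; the tested range
is truncated (with a warning) where fewer than 3 remain. Default
n_perm = 10,000, reduced in the test suite.

**Relationship models.** After sign correction, each adaptation response
is paired with the compensation response of its preceding perturbed
trial (trial level) or each participant contributes two points — their
average up- and down-direction responses (participant level). Shift
magnitudes are normalized by the mean magnitude in the data (so the
normalized mean is exactly 1, and fits are invariant to magnitude
units); with a single unique magnitude, the magnitude terms are aliased
and dropped. Fixed effects: compensation, normalized magnitude,
direction, plus the compensation × magnitude interaction at the trial
level only — with two points per participant the interaction is nearly
collinear with the compensation main effect (VIF ≫ 10) and is omitted
at the participant level. The only random intercept is participant
(study is collinear with participant and magnitude). Stepwise model
simplification is deliberately not performed; the stated models are fit
in full.

**Correlation aggregation.** Pearson r per participant (≥ 10 complete
pairs) between trial-level compensation and the subsequent adaptation;
Fisher z = atanh(r) (|r| = 1 clamped to 1−10⁻¹² and flagged); one-sample
t on z; mean z transformed back to r for reporting. The correlation of
participants' r with their overall mean adaptation is reported as a
check that trial-level coupling is not confined to strong adapters.

## Synthetic-data generator

Each trial is simulated as

    f1(t) = b_w(t) + ε_trial + smooth_noise(t) + c(t) + a(t)

- `b_w(t) = target_w − dip·exp(−t/τ)`: word- and participant-specific
  baseline with an exponential consonant-to-vowel transition
  (target ≈ 680 mels ≈ 580 Hz for /ɛ/; dip 150 mels; τ = 40 ms).
- `ε_trial ~ N(0, 30 mels)`: between-trial offset — the dominant noise
  source, sized so simulated trial-level effect sizes (d ≈ 0.2–0.3)
  match what this paradigm typically yields.
- `smooth_noise`: white Gaussian (8 mels) smoothed by a 25 ms moving
  average, rescaled to preserve the marginal SD.
- `c(t)`: compensation, −sign(shift)·g_c·magnitude·ramp(t), with a
  piecewise-linear ramp from 0 at 120 ms to 1 at 200 ms — the simplest
  monotone onset consistent with compensation latencies; only on
  perturbed trials.
- `a(t)`: one-shot adaptation, −sign(prev shift)·g_a·prev magnitude,
  constant across the vowel (it is feedforward — present before feedback
  latency), only on the single trial directly following a perturbed
  trial; no multi-trial carryover is modeled.

Per-participant gains (g_c, g_a) are bivariate normal with means
0.04/0.012, SDs 0.02/0.008 and correlation 0.4 by default. Schedules
draw `round(p·n)` perturbed trials with up/down balanced within one,
re-drawn until minimum counts of post-up, post-down and
baseline-after-baseline trials are met; words cycle in shuffled blocks.
Durations are lognormal (median 320 ms, log-SD 0.5, truncated to
[100, 600] ms) with an explicit 1% short-vowel (< 100 ms) mixture to
exercise the duration filter. `study_set_configs()` reproduces the
six-study design structure (14/13/40/40/11/15 participants;
160–800 trials; 25–50% perturbed; shifts 123.6±10, 125, 125, 125,
107.9±29.9, 94.3±6.8 mels; the respective word lists). All randomness
descends from one seed through named `SeedSequence` substreams, so
experiments are bit-reproducible.

**What the generator does not emulate.** Real speakers are far more
heterogeneous than the default gain SDs (real participant-level response
spreads are an order of magnitude wider than the injected gain
variability), trial-level coupling between compensation and adaptation
is absent (gains are fixed within participant, so within-participant
trial-level correlations are ≈ 0 by construction), there is no
generalization structure across words, no F2, no session drift, and no
autocorrelated motor noise. Passing parameter-recovery tests therefore
shows the *pipeline* is unbiased and calibrated under its assumed signal
model — not that real data satisfy those assumptions.

## Validation design and problem sizes

The acceptance suite checks, at sizes chosen to keep the whole suite in
the minutes range on one CPU: brute-force equivalence of windowing,
baselines, normalization and the outlier screen on 100+ random fixtures;
exact agreement of the cluster p with full enumeration of all 2⁴
sign-flip assignments at n = 4 × 6 time points; type-I control over 200
null experiments of 20 participants × 120 trials (family-wise cluster
false positives ≤ 7.5%, direction-model α ≤ 10%, n_perm = 500);
recovery of the injected effects at 40 participants × 240 trials with
g_c = 0.05, g_a = 0.015 and 125-mel shifts, pooled over three seeds —
expected sign-corrected compensation 6.25 × mean ramp over the window
(= 6.25·0.828125 ≈ 5.18 mels; the ramp mean follows from the 5 ms grid
over [150, 250)) and adaptation 1.875 mels, each within 2 SE, with
|β_comp| ≥ 2|β_adapt|; and the relationship machinery at a scenario
*designed a priori by attenuation-corrected power analysis* — with
ρ = 0.4, gain SDs 0.05/0.02, noise 20 mels, 400 trials, the observed
participant-level correlation is attenuated to ≈ 0.25, so 150
participants give ≈ 95% power — passing in ≥ 80% of 20 runs, plus a
500-participant null (ρ = 0) whose mean per-participant r must stay
within ±0.02.

`scripts/acceptance.py` runs the full six-study design at its published
scale (133 participants, ~39,000 trials, n_perm = 5000; ~10 s on one
CPU) and reports the computed headline statistics. Under the default
generator the direction effects reproduce the magnitudes this paradigm
prints (compensation β ≈ −7…−9 mels, adaptation β ≈ −2…−3 mels,
cluster onsets ≈ 100–150 ms), while the relationship coefficients
hover near zero at this scale — an expected consequence of the modest
default gain heterogeneity, which is why the relationship machinery is
validated at its dedicated powered scenario instead.

## Numerical and degenerate-input conventions

- Variance components snapped to 0 below 10⁻⁸ of the response variance;
  Cholesky factorizations jittered only on failure.
- A zero-residual (noise-free) direction fit raises rather than
  reporting infinite t.
- Satterthwaite df clipped to [1, n−p]; on a singular information
  matrix the residual df is used and noted.
- Window means with insufficient coverage propagate as NaN and are
  dropped pairwise by downstream tests.
- CSV round-trips use `float_precision="round_trip"` so written
  experiments re-read bit-identically.

## Known limitations

- Only random-intercept structures are supported (the designs analyzed
  need nothing more; a by-participant random slope for compensation is
  intentionally absent, consistent with its removal for non-convergence
  in this literature).
- The cluster test assumes exchangeability under sign flips
  (symmetric null) across participants.
- Sessions are identified by participant ID; a speaker contributing two
  studies should appear under distinct participant-session IDs (as the
  simulator ensures).
- The generator's effect and noise scales are stand-ins calibrated to
  printed summary statistics, not fits to raw data.
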