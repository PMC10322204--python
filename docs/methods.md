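# Methods

## The problem and the model

Mild cognitive impairment (MCI) is a predementia stage that clinical practice
identifies with instruments such as the mini-mental state examination (MMSE,
a 0–30 score). The package derives a voice-based screening index from a
dual-task protocol: each subject is recorded while performing serial-7
mental subtraction aloud (the *calculation* state, roughly five answer
utterances) and while reading the printed answer sequence (the *reading*
baseline, two repetitions). The working hypothesis is that a cognitively
demanding task perturbs vocal prosody, and that the perturbation grows as
cognition declines — so the per-subject *feature difference* (calculation
mean minus reading mean of each acoustic feature) carries diagnostic signal
that the raw features do not.

The pipeline consumes a long-format utterance table — one row per (subject,
state, utterance) with p numeric acoustic feature columns, as exported by
standard acoustic-functional extractors — plus a per-subject label table
with MMSE scores. Groups follow the usual clinical cutoffs: MMSE ≥ 28
healthy, 24–27 MCI, ≤ 23 cognitive disease (CD); CD subjects are merged
into the MCI group (they remain flagged internally so cohort summaries can
still report them).

### Stage 1 — per-feature state-effect screen

Each feature f is modelled at the utterance level (no per-subject
averaging, to use every repeated measurement) with a Gaussian
random-intercept model

    f_ik = (β₀ + b_i) + β₁ s_ik + ε_ik,   b_i ~ N(0, σ_b²),  ε ~ N(0, σ_e²),

where s indicates the calculation state. Features with a two-sided Wald
p-value for β₁ below 1% are kept; no multiple-testing correction is applied
(the screen is a filter, not an inference). The model is fitted by exact
profiled maximum likelihood: for fixed γ = σ_b²/σ_e² the marginal
covariance is block compound-symmetric, so GLS estimates and the residual
variance reduce to per-subject sums, and a one-dimensional likelihood in
log γ is minimized numerically (with the γ = 0 boundary checked
explicitly). This is orders of magnitude faster than a generic mixed-model
fit — the screen runs per feature and again inside every cross-validation
fold — and the test suite cross-checks it against statsmodels' MixedLM (ML)
and against the paired t-test, to which the model reduces in a balanced
one-utterance-per-state design.

### Stage 2 — MMSE-correlation filter

Features whose subject-level difference has absolute Pearson correlation
with the MMSE score strictly greater than 0.15 are kept. Differences here
are computed from state means (stage 1 is the only stage that uses
utterance-level rows). Correlations are computed across all subjects;
zero-variance features, whose correlation is undefined, are excluded and
logged.

### Stage 3 — AUC ranking

Surviving features are ranked by single-feature ROC AUC for the
healthy-vs-MCI contrast, computed rank-based (Mann–Whitney; ties count ½)
and orientation-free as max(a, 1−a), since a feature that *decreases* with
impairment discriminates just as well; the raw orientation is available by
configuration. The top n features are kept, where n defaults to the number
of training subjects so that the downstream covariance matrix keeps full
rank. Ties are broken by ascending column index for reproducibility.

### Aggregation and the index

The selected differences are standardized and aggregated by PCA;
components are retained up to a cumulative explained-variance contribution
of 80% (inclusive rule: the smallest m whose cumulative ratio reaches the
target, with 1e-12 float-sum slack). Correlation-matrix PCA is the default
because acoustic functionals have incommensurate units; covariance-matrix
PCA is available via `pca_scale=False`.

On the m component scores an L1-penalized logistic regression is fitted
with MCI coded 1 and an unpenalized intercept. The penalty weight is chosen
by 5-fold stratified cross-validation at minimum mean binomial deviance
over a data-driven log-spaced path (from the smallest penalty that zeroes
every coefficient down four decades — the R-glmnet convention; 100 values
by default). Because the fold split is random, the chosen penalty and hence
the fit vary from run to run; the fit is therefore repeated 20 times and
the coefficients averaged — fold assignment is the *only* stochastic
element that differs between repeats. With averaged intercept α₀ and
coefficients αᵢ the MCI discrimination index is

    MCIDI = 1 / (1 + exp(−α₀ − Σᵢ αᵢ·PCᵢ)) ∈ (0, 1),

interpretable as a modelled MCI probability. The decision threshold τ is
the smallest candidate (midpoints between consecutive sorted unique
training MCIDI values, plus {0, 1}) minimizing the balanced error rate;
a subject is called MCI when MCIDI ≥ τ.

**BER definition.** The balanced error rate is sometimes described as a
"harmonic mean" of the false-positive and false-negative rates, but the
literal harmonic mean is degenerate: predicting a single class for everyone
zeroes one rate and hence the harmonic mean, so minimizing it always admits
a trivial solution inconsistent with any interior threshold. The package
therefore uses the standard arithmetic BER, (FPR + FNR)/2, by default, and
exposes the harmonic variant (`ber_mode="harmonic"`) for completeness.

### Evaluation

Confusion matrices with MCI positive; sensitivity, specificity, PPV, NPV,
F-measure (harmonic mean of PPV and sensitivity) and accuracy, each
reported as undefined (not 0) on a zero denominator, plus 2-decimal
half-up roundings matching printed-table conventions; ROC/AUC (rank-based,
equal to the trapezoidal area); Welch's unequal-variance t-test for group
separation of the index; Pearson correlation between index and MMSE.
k-fold cross-validation refits the *entire* pipeline — screen, PCA, lasso,
threshold — on each training fold, the only leakage-free reading; pooled
held-out predictions (each fold decided at its own threshold) are reported
along with per-fold metrics and their means. k up to n (leave-one-out) is
supported; folds are stratified whenever k does not exceed the minority
class count, plain shuffled folds otherwise.

## Synthetic cohorts

No recordings ship with the package, so `mcidi.simulate` generates
utterance tables with the structure the analysis assumes:

    f_ikp = μ_p + b_ip + s_ik · (β₁_p + γ_p (30 − MMSE_i)) + ε_ikp.

Feature roles: *null* (β₁ = γ = 0), *state_only* (β₁ = ±state_effect_size,
γ = 0) and *state_mmse* (additionally γ = mmse_link_slope > 0). The
MMSE-linked term enters the *state effect*, not the baseline level,
matching the dual-task hypothesis; consequently the subject difference of a
state_mmse feature is β₁ + γ(30 − MMSE) + averaging noise, and correlates
negatively with MMSE. Random intercepts b cancel exactly in the
difference, which is the design's point.

Defaults are the reference study conditions: 198 subjects with a
deterministic 150 healthy / 48 MCI split; MMSE drawn per group
(healthy ≈ N(29.6, 0.6), MCI ≈ N(26.0, 0.9), rounded and clamped to the
clinical ranges in strict-cutoff mode); calculation-utterance counts
round(N(5.39, 1.21)) clipped to ≥ 3; exactly 2 readings; σ_b = σ_e = 1.
The feature-role mix (60% state-only, 8% MMSE-linked, 32% null) mirrors the
reported selection funnel proportions at a desk-scale feature count of
p = 300 (the real extraction produces ~15,000 functionals; the pipeline is
O(p) in the screen, so scale is a cost knob, not a structural one).

`mmse_link_slope = 0.14` was calibrated once, in closed form, so that a
planted feature's difference AUC lands mid-band of the reported 0.63–0.70
single-feature range: with averaging noise variance σ_e²(E[1/n_calc] + 1/2)
≈ 0.686 and group MMSE-deficit means ≈ 0.47 (healthy) and ≈ 4.05 (MCI),
AUC ≈ Φ(3.58γ / √(1.372 + 0.97γ²)) ≈ 0.665 at γ = 0.14.

A verification cohort — new subjects from the same measurement process — is
drawn by fixing `feature_seed` (which pins feature roles, baselines and
effect signs) while varying `seed` (which drives all subject-level draws);
without a shared `feature_seed`, a second draw is a different feature
universe and any fitted model evaluates at chance on it.

What the generator does *not* emulate: openSMILE feature semantics (columns
are anonymous), cross-feature correlation beyond the shared MMSE factor
(an optional within-role block correlation of the random intercepts
exists, but intercepts cancel in differences), recording-environment shift
between cohorts, label noise from imperfect MMSE sensitivity, and
non-Gaussian feature distributions. Passing tests therefore demonstrate
the pipeline's statistical correctness and its ability to recover planted
dual-task signal — not clinical performance on real voices.

## Numerical choices and edge cases

- Mixed model: γ optimized on log scale over e^[−12, 12] (bounded Brent,
  xatol 1e-8), zero boundary compared explicitly; degenerate fits
  (constant response) return p = 1 rather than failing.
- PCA retention uses a 1e-12 tolerance on the cumulative ratio so an exact
  80% boundary (equal eigenvalues) is treated inclusively.
- Threshold search returns the smallest minimizing candidate; the decision
  rule is inclusive (≥ τ → MCI) and fixed so confusion counts are
  deterministic.
- Correlation threshold is a strict inequality (> 0.15).
- Lasso repeats that fail outright fall back to the strongest penalty on
  the path with a warning; class coding is always MCI = 1.
- All randomness (generator, lasso fold splits, CV folds) flows from
  integer seeds; the generator derives one sub-stream per subject from a
  root seed sequence, so cohorts are reproducible row for row and model
  files are byte-identical across reruns.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full derivation at the
198-subject / 300-feature reference conditions (screen calibration uses
100 subjects × 500 null features; the balanced-design equivalence check
uses 400 paired subjects). Unit tests exercise the same code paths on
smaller cohorts with fewer lasso repeats purely to keep the feedback loop
tight; those reduced settings are never used for the headline numbers.

## Known limitations

- The Wald test references the normal distribution; in very small cohorts
  a t-type reference would be less anti-conservative.
- Repeat-averaged L1 coefficients are averaged on the penalized scale
  (no refit on the averaged support); the averaged model is therefore not
  itself the solution of any single penalized problem.
- The verification-cohort simulation draws from the same feature
  distribution as training; real cross-population shift (different venues,
  recording chains) is not modelled, so synthetic verification accuracy
  will exceed what heterogeneous real cohorts yield.
- `n_select` defaults to the training-subject count to protect PCA rank,
  which implicitly ties model capacity to cohort size.
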