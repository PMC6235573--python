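# Methods

`peakshift` analyzes trial-level data from the peak-interval (PI)
procedure: a cue signals that reward becomes available after a fixed
interval (FI); on unrewarded "probe" trials the cue stays on 3–4× longer
than the trained interval, and the time course of responding reveals the
animal's temporal expectation. The package implements the full analysis
chain — peak-function fitting, single-trial change-point detection,
percent-change shift statistics, and grid-based Bayes factors for "no
shift" — together with a generative model of PI behavior that reproduces
the statistical structure of cross-cue transfer designs, so every stage is
testable without any external data.

## Data model

Trials live in two linked CSV tables: `trials.csv` (one row per trial:
subject, group, context, phase ∈ {train, change, test}, session, trial
index, cue, trial type ∈ {fi, probe}, programmed FI duration, probe length,
rewarded-response time) and `responses.csv` (one row per nosepoke, seconds
from cue onset). The composite key is (subject, phase, session,
trial index). Times are stored with 6 decimals; acquisition hardware in
this field resolves ~1 ms, so 3+ decimals suffice. Trials with zero
responses are legal (they count in peak-function denominators and are
invalid for single-trial fitting). Validation returns violations as data
(`validate_dataset`), never exceptions, so diagnostic reporting is cheap.

A test-phase cue must have been introduced in an earlier phase; the check
accepts introduction at either training or the change phase, because the
reward-structure-control designs legitimately add a novel cue during
retraining.

## Generative model

Single trials follow the break-run-break account: a low Poisson baseline
rate `r_low`, an abrupt high-rate run at `r_high`, then baseline again.
For an effective peak time `pt`:

- run midpoint `m ~ Normal(pt, γ·pt)` — the multiplicative noise makes the
  midpoint CV equal γ at every interval (the scalar property, by
  construction);
- run half-width `h ~ Normal(ω·pt, η·ω·pt)` truncated to `h > 0`;
- responses: inhomogeneous Poisson, `r_high` inside
  `[max(0, m−h), m+h]` (clipped to the trial), `r_low` outside.

FI trials end at the first response at or after the FI criterion; that
response is the rewarded one. Sampling is exact: if no response at or past
the criterion exists by `max(run end, criterion)`, the first later
baseline arrival is drawn from the memoryless exponential. With
`r_low = 0` the process is resampled (bounded retries), then a single
response is injected at the criterion.

Cross-cue transfer is proportional. If a retrained cue's duration shifted
by a fraction Δ = (new − old)/old, a cue withheld during retraining has
test-phase effective peak time `D0 · (1 + τ_eff · Δ)`, where

- `τ_eff = tau` (default 0.5) in the context where the change was learned,
- `τ_eff = tau × context_attenuation` (default 0.4) in a context where no
  change was experienced,
- `τ_eff = 0` in covariance-violated (uncorrelated) designs, encoded as a
  design flag — transfer is blocked, not merely attenuated.

Explicitly retrained cues express their programmed duration. A per-subject
× cue multiplicative bias (CV 0.05, drawn once, fixed across phases) adds
between-subject variability that cancels exactly in within-subject percent
changes. Proportional (rather than additive) transfer is a modeling choice
consistent with reporting shifts as percent changes; the data the designs
emulate cannot distinguish the two.

Defaults: `r_low = 0.05`, `r_high = 1.5` responses/s, `γ = 0.15`,
`ω = 0.35`, `η = 0.10`. Rates are repository choices (no rate magnitudes
are fixed by the designs); γ sits in the canonical Weber-fraction range
for rodent interval timing. `tau = 0.5` and `context_attenuation = 0.4`
are calibrations that approximate the observed transfer pattern (≈ half
the changed cue's proportional shift, further attenuated to ≈ 0.4× off
context); they are calibration targets, not ground truth.

Design presets cover the five experiment families: single-cue change
(8→4, 16→32, and an exposure-only control), within-range change (8→12),
reward-structure controls with a novel cue, three-cue correlated/
uncorrelated (covariance-violation) designs, and the two-context design
whose test phase is two sessions, one per context, with both cues
probe-only. Probe trials are 30% of each cue's trials in training (20% for
the reintroduced cue at test), with lengths uniform on 3–4× the longest
duration in effect (pinned to 96–128 s in the 32-s designs). Session
counts per phase are free parameters; reproduction runs use two training
and two test sessions sized to give ≈ 40 probe trials per analysis cell.
What the generator does *not* model: learning dynamics within phases,
extinction-driven rate decline across test sessions, inter-trial-interval
responding, and any asymmetry of the response burst. Passing tests
therefore show the analysis chain is correct and well-calibrated for
steady-state break-run-break behavior — not that real rats satisfy these
assumptions.

## Peak functions and the generalized-Gaussian fit

Responses from qualifying probe trials are counted into half-open 1-s bins
`[b, b+1)` from cue onset and averaged over trials (empty trials included
in the denominator). The number of bins is `floor(min probe length /
width)`, so every contributing trial covers every bin. For training
averages, the final k training sessions are used with k matched to the
number of test sessions (inferred from the data unless set). The 8→4
design's conservative trial filter — first response must occur before
32 s — is the configurable `early_response_cutoff`, default off, applied
at both binning and single-trial stages.

The fitted model is `y(t) = B + S·exp(−½(|t − PT|/SP)^K)`: baseline B,
scale S, mode PT (taken as the peak time), spread SP, and a kurtosis
exponent K (K = 2 is the ordinary Gaussian). CV = SP/PT. Fitting is
bounded least squares (trust-region reflective) on bin centers
(b + 0.5) against raw rates — normalization and 6-bin smoothing exist only
in the display utility and never feed the fit or any statistic.
Initialization: PT₀ = argmax bin center, B₀ = min rate, S₀ = max − min,
SP₀ = half-width at half-height, with a fixed multi-start over
K₀ ∈ {1, 2, 4}; bounds B ∈ [0, max], S ∈ (0, 2·max], PT ∈ [0, T_end],
SP ∈ (0, T_end], K ∈ [0.5, 10]. The schedule is fixed, so fits are
deterministic. Noiseless recovery is exact to < 0.1% over a 3×3×3
(PT, SP, K) grid; under generator noise with ~40 trials per cell the
fitted PT tracks the programmed run midpoint within 5%.

Bin left-edge vs center abscissae is genuinely open; centers are used and
the CV is invariant to the choice under time rescaling (tested).

## Single-trial start/stop detection

Each probe trial is fit with three flat rate lines (low–high–low). With
change points s ≤ e restricted to response times (the empirical rate
function only changes there; boundary responses belong to the run), the
fit maximizes

    I(s, e) = d₁(r − r₁) + d₂(r₂ − r) + d₃(r − r₃)

over all pairs, where segment i ∈ {[0,s), [s,e], (e,T]} has duration d_i
and rate r_i, and r = n/T. Ties break toward the smallest s, then
smallest e. The search is exhaustive and vectorized; a naive double-loop
brute force is kept as an independent oracle and agrees exactly on 1,000
random simulated trials. Validity filters (annotating, never deleting):
≥ 3 responses, start < session peak time < stop, and the optional early-
response cutoff. Single-response degenerate fits (s = e) are always caught
by the response-count filter. Start/stop summaries average valid trials
only; cells with no valid trials are reported missing, not zero.

## Shift statistics

Per-subject shifts are `100·(test − train)/train` for peak time, CV,
start, or stop, computed on non-normalized values. The within-group test
is a one-sample t of the percent changes against zero (df = n − 1);
between-group planned comparisons use the pooled-variance two-sample t
(df = n_a + n_b − 2). Zero-variance cases are flagged degenerate rather
than silently producing NaNs. Omnibus mixed-model ANOVA is deliberately
out of scope — the tidy `shifts.csv` table feeds any standard ANOVA tool.
Note that t statistics on percent changes need not equal t statistics
computed on the raw values; both routes are available from the tables.

## Grid Bayes factors for "no shift"

Per-subject percent changes are modeled as Normal(θ, σ) with σ the pooled
within-group SD across the tested and reference groups (df-weighted; the
concatenated-SD variant is exposed but inflates σ by the between-group
mean difference, so within-group pooling is the default). The group
marginal likelihood L(θ|D) is the product over subjects, computed in log
space on a uniform θ-grid and normalized to integrate to 1. The null prior
is the same construction after subtracting the sample mean (mean-zero by
design). Alternative priors:

- **incremental**: uniform on ±h convolved with the null prior, with h the
  largest *absolute* per-subject shift in the reference group (absolute,
  so leftward reference shifts still widen both sides);
- **reference**: the reference group's own marginal likelihood.

BF = Σ L·π_null·step / Σ L·π_alt·step; BF > 1 favors no shift, with
heuristic bands > 3 substantial, > 10 strong, > 100 decisive. Numerical
choices: grid step 0.05 percentage points; range = all construction
inputs ± 8·σ·max(1, √n), further widened by the incremental halfwidth,
with widen-and-retry on a 1e−9 truncated-mass check (the product of
normals is normal, so truncation is checked in closed form); the uniform
kernel uses trapezoid end-weights so the discrete convolution matches the
continuous uniform⊛normal density to O(step²). The module is fully
deterministic. Against the conjugate normal–normal closed form the grid
BF agrees within 0.5% over a 50-point sweep, is exactly 1 for identical
prior arrays, and moves < 0.1% under 10× grid refinement. The exact grid
and integration conventions of any particular historical analysis are
unreported in this literature, so absolute BFs should be compared across
pipelines only approximately.

## Reproduction runs and problem sizes

`peakshift.reproduce` (driven by `scripts/acceptance.py`) regenerates
every headline number from scratch: the K = 2 identity; the noiseless
recovery grid; the 16-to-32 full pipeline at τ = 0.59 (10 subjects,
~40 probes per cell, 20 seeds) recovering +59%/+100% programmed shifts;
the uncorrelated three-cue design (2 × 5 subjects, 100 replicates) showing
blocked transfer and incremental-prior BF > 1; the single-trial oracle on
1,000 trials; the conjugate BF sweep; and midpoint-CV constancy across
8/16/32 s (5,000 draws per level, Feltz–Miller equality-of-CVs test).

## Known limitations

- The simulator's transfer rule is phenomenological; it encodes *that*
  transfer is proportional and context-gated, not a learning mechanism.
- The three-flat-line objective is the standard index from the single-trial
  literature, pinned here by a brute-force oracle; alternative objectives
  would give systematically different (if highly correlated) start/stop
  values.
- Reported BFs from noisy small-n groups are heavy-tailed across
  replicates; calibration claims are about exceedance fractions, not BF
  magnitudes.
- No importer exists for vendor acquisition formats or for published
  figure source files; the two-CSV schema is the only ingest path.
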