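# Methods

## Stimulus and design generation

A picture is an ordered list of drawable segment identifiers. The
fragmentation generator fixes one seeded permutation of the segments
(the deletion order) and, at level *L* ∈ 1..7, removes the first
round(n · (1 − 0.7^(L−1))) of them, rounding half away from zero. Nested
retained sets and deterministic regeneration from (picture, seed) follow
by construction. Scrambling tiles the image into a 16 × 16 grid (256
tiles), zero-padding symmetrically when dimensions do not divide, and
applies a seeded tile permutation; the tile multiset is preserved
exactly.

ERP blocks place 10 distinct picture sequences plus 5 repeats into 15
slots. Repeats follow their initial presentation after 1 or 2
intervening sequences, drawn uniformly; placement uses a constructive
scheduler with rejection restarts, so every generated block satisfies
the constraints exactly. The level schedule within a sequence is fixed
at 6 → 5 → 4 → 3 (most to least fragmented of the levels in use);
termination on "yes" is the observer's business, not the design's, so
the same design serves real and simulated responses.

fMRI sessions are generated from explicit `n_blocks` and
`runs_per_block` rather than a fixed session length: each block is 4
rest TRs, then 9-TR stimulus runs separated by 4 rest TRs, with run
conditions cycling through primed/unprimed/scrambled in an order
randomized once per session seed and then held fixed. Three blocks of
three runs give 117 TRs; session length is therefore a derived
quantity, never a target.

## Synthetic observer

Identification is governed by a latent threshold: on each presentation
the observer draws t_eff = threshold + u/slope with standard-logistic
u, answers "yes" iff level ≤ t_eff, and lapses (misses) with a small
probability. This makes P(yes | level) = (1 − lapse) · σ(slope ·
(threshold − level)), monotone in completeness, while the slope → ∞
limit identifies exactly at the integer threshold level (the boundary
resolves to "yes"). Repetition priming adds `priming_shift` (default
1 level) to the threshold. `fit_observer_threshold` maximizes exactly
this likelihood over per-presentation yes/no responses; the AML
truncation (levels after the first "yes" are unobserved) leaves the
Bernoulli likelihood valid, and 200 simulated sequences recover the
threshold to well under 0.25 levels in the tests.

## Synthetic EEG

Epochs are sums of Gaussian bumps plus white noise on 8 posterior
channels at 512 Hz, −100..500 ms. Component latencies and analysis
windows: P1 peak 115 ms (window 100–120 ms, PO5/PO6), N1 peak 180 ms
(170–200 ms, PO7/PO8), Ncl peak 320 ms (300–340 ms, PO7/PO8); bump SD
is 8.5 ms (~20 ms FWHM) — windows and peaks are fixed by the analysis
design, the waveform shape is a modeling choice. Each bump is scaled so
its mean over the component's own window equals the configured
amplitude in μV; window-mean extraction is then an exact inverse of the
injection at zero noise, which is what the recovery tests assert.
Default group × condition amplitudes encode the qualitative pattern of
interest — closure negativity (Ncl) reduced in patients, N1 repetition
enhancement similar across groups, P1 repetition suppression in
controls only — and are placeholders in physical units, not calibrated
to any recorded data. The generator deliberately omits 1/f background,
ocular artifacts, channel covariance and latency jitter, so passing
tests certify the analysis chain's algebra and statistics, not its
robustness to real-EEG nuisance structure.

## Synthetic BOLD network

The four closure nodes (DS, LOC, PFC, HIPP) follow a latent VAR(p) at
one step per TR (the neuronal time-grid of the connectivity model is a
design choice; TR resolution keeps generator and analyzer on the same
clock). Coefficients are stored in the minus-sign convention
x[n] = −Σ A[i] x[n−i] + C s[n] + u[n]; `a_effective = −A` is the
conventional regression form. Stationarity is enforced via the
companion-matrix spectral radius (< 1, else an error naming the value).
Condition boxcars drive DS with unit weight; group networks use
self-decay 0.5 and coupling 0.4 at lag 1 — controls DS→PFC and PFC→LOC,
patients DS↔LOC and HIPP→DS. Each ROI voxel is the node series,
convolved with the canonical HRF (or passed through unchanged with the
`identity` option, which isolates the VAR machinery from hemodynamic
blurring), times a positive gain ~N(1, 0.1), plus white observation
noise (SD 0.5 against unit-variance innovations). ROIs are disjoint
8-voxel blocks in a small synthetic grid; the nominal Talairach
coordinates of the four regions ride along as metadata only. Ground
truth (A, Σᵤ, gains, edges) is always emitted so recovery tests never
reverse-engineer it.

## ERP analysis

Rejection drops a trial iff any channel strictly exceeds the ±120 μV
limit within −100..500 ms; a trial peaking at exactly 120.0 μV is
retained, since the stated criterion carries no boundary semantics.
Baselining subtracts each trial's −100..0 ms channel mean (making that
interval exactly zero-mean per trial), averaging is arithmetic per
condition, and window amplitudes are means over window samples and
electrodes, split by hemisphere (odd electrode numbers left). The
repeated-measures multivariate analysis is realized as a univariate
mixed-model ANOVA — between-subject factor group, within-subject factor
condition, hemisphere collapsed by default — implemented from classical
sums of squares and cross-checked in the tests against an independent
mixed-ANOVA implementation to 1e-8; the output labels the formulation.
Degenerate zero-variance inputs return F = 0, p = 1 rather than NaN.
Cohen's d for the group effect uses subject means and the pooled SD.
Subjects with missing cells are dropped listwise per component and
logged.

## fMRI GLM

The canonical HRF is the double-gamma difference with response peak 6 s,
undershoot peak 16 s, unit dispersions, peak:undershoot ratio 1/6 and
32 s support, sampled at TR resolution and unit-peak normalized; its
value at lag 0 is exactly 0 and its continuous form peaks at 5.0 s.
Design matrices hold one causally convolved boxcar column per non-rest
condition, an intercept, and Legendre drift terms (linear + quadratic
by default). Estimation is per-voxel OLS; the ReML-with-AR-model
estimation of standard packages is approximated by a single-pass AR(1)
prewhitening using the pooled lag-1 residual autocorrelation, and the
fit records which was used. Second-level ROI inference is one-sample t
within group (df = n − 1) and pooled two-sample t between groups
(df = n₁ + n₂ − 2), signed control-minus-patient. Spatial preprocessing
(realignment, normalization, smoothing) is out of scope; masks live in
the synthetic grid's own coordinates.

## Geweke measures and maps

All directed and instantaneous terms are log-ratios of residual
variances from nested least-squares fits of the (per-segment demeaned
and variance-normalized) series. Within the decomposition the residual
variances use the maximum-likelihood normalization (divide by the
number of regression rows): restricted and full models then share a
denominator, so nestedness makes F_x→y and F_y→x nonnegative by
construction, Cauchy–Schwarz makes F_x.y nonnegative, and the
additivity identity F_x,y = F_x→y + F_y→x + F_x.y holds to machine
precision because every term comes from the same fits. (A
df-corrected normalization would leak small negative values of order
p/n into the directed terms.) The standalone VAR fitter, by contrast,
reports the conventional df-corrected innovation covariance. Internal
pair order is canonicalized so that swapping the two series swaps the
directed components bit-exactly. Variance normalization also makes all
measures invariant to positive rescaling of either series.

Maps: the reference series is the mean raw time course of the mask
voxels; voxels inside the mask are flagged and excluded from the pair
fits (a voxel nearly identical to its own ROI mean makes the joint
residual covariance singular — by design there is no regularization
fallback, the code fails loudly on genuinely degenerate input).
Condition-specific maps restrict the usable rows to that condition's
runs plus p lead-in TRs, and lagged pairs never span a segment
boundary. The default VAR order is p = 1 (overridable; a BIC/AIC
selector is provided and logs its choice).

Thresholding builds the null by circularly time-shifting the reference
series (shift uniform in p+1 .. T−p−1), which preserves its
autocorrelation while destroying cross-dependence, and recomputes the
dGCM per surrogate. The B × V surrogate values are pooled into a single
empirical null — voxels are exchangeable under this null, and pooling
gives p-value resolution 1/(B·V+1), without which B = 200 could not
resolve anything below the Benjamini–Hochberg bar at hundreds of
voxels. Per-voxel two-sided p-values are then BH-corrected at q = 0.05
by default. The voxel-side lag moments are precomputed once, so the B
surrogate recomputations cost only reference-side and cross moments;
a 500-voxel, 600-TR map with B = 200 thresholds in well under a second.

Group inference: subject-level connection values default to dGCI
(raw directed F values are emitted alongside); per connection and group
the summary is median and IQR with a two-sided Wilcoxon signed-rank
test of median ≠ 0 (exact for n ≤ 25 without zeros or ties, otherwise
normal approximation with Pratt zero handling), and the between-group
comparison is the Wilcoxon rank-sum test.

Hemodynamic caveat: on real BOLD, regional HRF latency differences can
masquerade as directed influence. The difference term F_x→y − F_y→x
mitigates (symmetric lags cancel) but does not remove this confound;
no deconvolution is attempted, and the simulator's `identity` HRF
option exists precisely to test the inference machinery free of it.

## Pipeline

A run is one YAML config plus a master seed; per-stage seeds are
spawned through `SeedSequence` keyed by a CRC of the stage name, so
reruns are byte-identical. The demo configuration uses 10 subjects per
group, 4 ERP blocks of 40 trials per condition, and a 12-block fMRI
session (468 TRs), sized to finish in about a second while leaving the
group connectivity tests with enough primed-condition TRs to recover
both groups' routes. Defaulted analysis parameters (p, B, q, HRF
parameters, rejection limit) are logged at INFO level, and the
effective config is written back into the run directory. Exit codes: 0
success, 2 config error, 3 data-contract error, 4 numerical failure.

## Verification scales

The acceptance script and test suite run the stochastic checks at:
100 replicates × 400 TRs for single-edge recovery; 20 seeds × 500
voxels × 600 TRs × B = 200 for FDR calibration; 1000 replicates at
n = 20/group for rank-sum type-I calibration; and 20 replicates of 20
subjects/group × 240 TRs for the two-group property. In the two-group
check, the "differing" set is the union of the groups' direct edges;
the genuinely null set excludes HIPP→LOC because the patients'
HIPP→DS→LOC chain induces a real indirect group difference in pairwise
influence there — an expected property of pairwise Granger measures,
not an error.

## Known limitations

- Pairwise (conditional-on-nothing) Geweke measures pick up indirect
  and common-driver influence; the package does not implement
  conditional/partial or spectral variants.
- The mixed ANOVA is univariate; sphericity is not corrected (with the
  default three conditions and the simulator's exchangeable noise the
  assumption holds by construction).
- The AR(1) prewhitening is a one-pass approximation, not full ReML.
- Synthetic EEG/BOLD omit most physiological nuisance structure; see
  the generator sections for exactly what is and is not emulated.
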