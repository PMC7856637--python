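# Methods

This note records the model underlying `tcmcorr`, the numerical choices made,
and the rationale for defaults. Symbols: TR = repetition time, IC =
independent component, TCM = task-correlated motion, FF = Fano factor.

## Paradigm and synthetic generator

The target acquisition is an overt-speech event design: runs of 10 trials of
6.8 s each, inter-trial intervals jittered among 13.6, 15.3 and 17 s, TR
1.7 s, 186 volumes per run of which the first 9 are discarded (177 retained).
The first onset falls 7 TRs (11.9 s) into the retained series, leaving a
baseline window for percent-signal-change scaling; the mean trial-to-trial
period of 22.1 s defines the task fundamental frequency (1/22.1 Hz ≈
0.045 Hz). The full paradigm has 6 runs (60 trials); the pipeline default
simulates one run per dataset for desk-scale turnaround, with the multi-run
schedule available through `ScheduleConfig.n_runs`.

`tcmcorr.simulate` generates ground-truth-labeled runs on a small voxel grid
(default 20×20×10 at 3 mm): a constant baseline plus

- a **BOLD signal**: onset trains convolved with the canonical HRF, scaled to
  ~2% signal change, inside a compact gray-matter "language" region;
- a **TCM artifact**: spiky biphasic deflections confined to the first 3 TRs
  after each onset, amplitude 2–5% varying across trials, inside a
  fronto-temporal + extracerebral-rim mask that partially overlaps the signal
  region;
- cubic **polynomial drift**, Gaussian **thermal noise** (SD 5 in raw units),
  and a rigid-motion trace (smooth random walk plus stimulus-locked bumps)
  whose displacement drives censoring.

The generator stores the truth (masks, per-trial artifact amplitudes, seeds)
so components and voxels can be scored against it. Every stochastic element
derives from one integer seed; per-run and per-dataset child seeds come from
`numpy.random.SeedSequence` reduced below 2³¹.

## Analysis path

Each run is smoothed with a 6 mm FWHM Gaussian kernel, mask-normalized so
that smoothing never mixes signal across an exclusion boundary; scaled to
percent signal change against the 7-TR pre-task baseline; and frames whose
frame-to-frame rigid displacement exceeds 0.3 mm are censored. The
voxel-level impulse response is estimated by FIR deconvolution: 8 lagged
onset-indicator regressors (0–11.9 s) shared across runs, per-run Legendre
drift polynomials up to order 3, and the 6 motion parameters plus their first
differences as nuisance regressors. The reported R² is the partial R² of the
FIR block after the nuisance block (exactly 0 when the nuisance model already
explains the series). Activation maps threshold voxelwise at R² ≥ 0.16 and
retain only 26-connected clusters of ≥ 30 voxels.

## Canonical HRF

The canonical response is a double-gamma

h(t) = A · [ (t^α₁ β₁^α₁ e^{−β₁ t}) / Γ(α₁) − c · (t^α₂ β₂^α₂ e^{−β₂ t}) / Γ(α₂) ],

defaults A = 1, α₁ = 2.5, β₁ = 0.4, α₂ = 12, β₂ = 0.7, c = 1/6.6 (peak near
5 s, undershoot near 15 s). `fit_canonical` fits all six parameters to an
empirical impulse response by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method "trf"), returns goodness of fit r²,
and flags non-convergence. The fit is exact on its own samples (r² = 1) and
recovers the amplitude within ~3% under 5% additive noise.

## ICA decomposition and component features

Each run is decomposed by spatial ICA (`sklearn` FastICA on the
voxel-centered data). The model order is chosen automatically by a
Marchenko–Pastur-style noise-floor cut on the data eigenvalues (typically 3
components for the default generator: artifact, BOLD, drift/mixture);
components are sign-canonicalized to positive time-course skewness and
variance-normalized.

Per component, `extract_features` computes:

- **IC impulse response**: FIR deconvolution of the component time course
  against the stimulus, and its canonical-HRF fit r²;
- **task-band spectral concentration**: periodogram power at the task
  fundamental relative to the broadband median;
- **spikiness**: excess kurtosis and maximum absolute z of the time course;
- **voxel-HRF match fraction**: among active voxels where the component loads
  (|z| above threshold), the fraction whose voxelwise FIR response correlates
  with the canonical shape at r ≥ 0.7;
- **spatial overlap** of the thresholded map with the artifact-prone
  (fronto-temporal + rim) mask.

A conservative hand-emulating **rule** labels a component noise only when the
evidence is redundant: poor canonical match (match fraction below 5% of
loading voxels), plus task-locked spectral power or spikiness, plus
artifact-mask overlap. The **classifier** is an L2 logistic regression on the
standardized features, trained on ground-truth labels from ≥ 10 independent
synthetic datasets and scored by leave-one-dataset-out (LODO)
sensitivity/specificity; training refuses fewer than 10 datasets unless
explicitly overridden.

## Component removal

Non-aggressive removal subtracts, from each voxel series, the noise
components' *unique* fitted contribution — the projection of the series onto
the noise time courses **residualized against the retained set**
(Frisch–Waugh–Lovell form). The fitted betas equal those of the joint
regression on all component time courses, but the subtracted shapes are
orthogonal to the retained components, so variance shared with retained
components is preserved and per-voxel variance can never increase. (Literal
joint-regression subtraction violates that invariant whenever component time
courses are temporally correlated: compensating betas on the retained
components re-inject artifact into voxels that never contained it.)
Aggressive removal subtracts the full projection onto the noise time courses
alone. Voxel means are preserved in both modes.

Because an onset-locked artifact is inevitably correlated with the
hemodynamic response (here ρ ≈ −0.3), removal without further care strips
task-locked BOLD variance from pure-signal voxels. The pipeline therefore
passes an explicit **signal-protection** matrix — the canonical task
regressor (onset train ⊛ canonical HRF) plus the Legendre drift basis — and
residualizes the noise time courses against it *instead of* the retained
component time courses. The protected model must replace, not augment, the
retained set: whitened components are mutually decorrelated, so a retained
BOLD component plus an exact task regressor can jointly span the artifact
direction and leave nothing to remove. Protection is on by default
(`ica.signal_protection`) and skipped automatically when no stimulus schedule
accompanies externally supplied data.

## Evaluation metrics

Temporal stability is measured inside a 5 mm sphere centered on the peak-R²
surviving activation voxel: the coefficient of variation (SD/mean) of the
ROI-averaged series per run, and the trial-by-trial Fano factor
(variance/mean) over the first 3 TRs (5.1 s) after each onset — the frames in
which speech-locked motion concentrates. Per-run FF values are normalized by
the run mean by default (hence exactly 1 on average for a single run; use
`normalization="none"` for absolute comparisons). Spatial specificity is the
count of surviving activation voxels in gray- and white-matter masks; methods
are compared by paired t-tests with degenerate cases (identical or
zero-variance differences) flagged explicitly.

## Validation experiments

`tcmcorr.experiments` packages the end-to-end claims:

- `classifier_recovery`: LODO sensitivity/specificity of the classifier and
  the rule against ground truth on independent datasets (defaults reach 1.0 /
  1.0; the rule trades sensitivity ~0.5 for specificity 1.0 by design).
- `selectivity`: on fresh runs, canonical-fit r² improves strongly in
  artifact-prone signal voxels (Δr² ≈ +1.0 of a possible [−1, 1] fit range)
  and changes < 0.05 in artifact-immune signal voxels; the in-window Fano
  factor in artifact-prone ROIs drops from ~3 (uncorrected) to near zero
  after either removal path.
- `hrf_recovery`: amplitude recovery of the canonical fit under noise.

`scripts/acceptance.py` runs all three plus the numeric oracle and identity
checks, from a single seed, into a JSON report.

## Known limitations

- The generator is a desk-scale caricature: no spatial autocorrelation in the
  thermal noise, no physiological noise, box-shaped tissue masks, rigid
  motion applied only through the censoring path rather than by resampling
  the volumes.
- Signal protection deliberately leaves behind any artifact energy collinear
  with the canonical task model; in artifact-only voxels a canonical-shaped
  residue therefore survives non-aggressive removal. This is the intended
  trade-off for not touching task-locked BOLD.
- After removal, the in-window Fano factor of both corrected paths is near
  zero and dominated by the window-mean denominator (which aggressive removal
  shrinks); the ordering between non-aggressive and aggressive removal is
  therefore not stable seed-to-seed, while uncorrected ≫ corrected is.
- Automatic ICA model order is tuned to the generator's noise structure;
  real data typically need more components and benefit from manual review of
  borderline labels.
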