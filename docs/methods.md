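# Methods

## Problem and pipeline

`neurotrust` models an objective readout of mentor–trainee trust during
robot-assisted surgery: the EEG of a mentor surgeon observing a trainee is
summarized as a 96-dimensional brain-state vector, and a binary label —
*trustworthy* vs *concerning*, derived from the mentor's NASA-TLX
performance score — is predicted from that vector. The pipeline stages are

1. **Cleaning.** Supra-threshold excursion runs (3/5/7-point spikes above a
   configurable amplitude threshold, default 40 in the recording's native
   units) and longer saturations are masked; a 60 Hz notch and a
   0.5–128 Hz band-pass remove environmental artifacts; blink-contaminated
   stretches are masked by a frontal threshold detector. Artifact handling
   only marks samples — values are never edited — and all downstream
   computations exclude masked points.
2. **Spectral estimation.** Short-time PSDs with a 1 s Kaiser window
   (β = 8.6) and 50% overlap. Windows with more than 25% masked samples are
   dropped; lighter contamination is repaired by linear interpolation
   before the FFT. A single-pass 3-SD rule removes statistical outliers
   from derived series.
3. **Cognitive features.** Mental load per cortical system (summed
   time-averaged total power), situation awareness (frontal θ + γ power),
   blink rate (masked fraction of time points), frontal α asymmetry
   AI = (L−R)/(L+R) over the F3/F7 vs F4/F8 dynamic ranges, and completion
   time N/f_s. Mental workload and engagement are pass-through slots for
   externally computed probabilities; they are never computed here because
   they require proprietary classifiers and baseline databases.
4. **Functional features.** Per band (θ 4–8, α 8–12, β 12–35, γ 35–60 Hz),
   instantaneous phases from the band-passed analytic signal give the
   phase-locking value Γ for every channel pair; block means over a
   six-system parcellation yield 6 strengths + 15 communications per band,
   84 features total, each in [0, 1].
5. **Classification.** Kernel-target alignment ranks features; a linear SVM
   (C = 1, fold-internal z-scoring) is scored under LOOCV and stratified
   10-fold CV; fuzzy C-means clustering with the scatter criterion
   J = tr(S_W⁻¹S_B) validates separability; Welch t-tests and Pearson
   correlations characterize the selected features.

## Numerical and design choices

* **Filters** are zero-phase (forward–backward Butterworth order 4, IIR
  notch Q = 30) so downstream phase estimates are unbiased by group delay.
  Filter order and Q are fixed for reproducibility.
* **Phase-difference sign convention.** Γ is computed on the signed wrapped
  phase difference, i.e. the standard resultant length |Σ e^{iΔφ}|/P. An
  absolute-valued difference would leave the cosine sum unchanged but bias
  the sine sum positive (E[sin|Δφ|] = 1/π under the null), inflating the
  no-coupling floor to ≈0.32 and breaking invariance under a common phase
  shift. The absolute wrapped difference (range [0, π]) is still exposed by
  `phase_difference` for diagnostics. Range normalization of Δφ is a no-op
  for Γ and is not applied.
* **Phase extraction** uses band-pass + Hilbert analytic signal rather than
  empirical-mode decomposition: mode-to-band assignment in EMD is not
  deterministic, whereas the band-passed analytic phase is the standard
  construction the phase-locking value assumes.
* **Strength averaging** excludes self-pairs; including the unit diagonal
  would floor two-channel systems (PF, O) at 0.5.
* **Masking policy for Γ**: a time point is excluded for a pair if either
  channel is masked there; P is the per-pair retained count.
* **Excursion runs** longer than the largest listed spike length are masked
  as a conservative superset (saturations); runs of unlisted shorter
  lengths (4, 6) are left, matching the stated spike taxonomy.
* **Blink detector**: frontal channels band-passed to 0.5–4 Hz; a point is
  a blink when |amplitude| > 6·MAD for ≥ 50 ms. This is a deliberately
  simple, training-free substitute for classifier-based ocular artifact
  detection; it is calibrated only to catch stereotyped high-amplitude
  deflections, and its false-negative rate on subtle blinks is unknown.
* **Outlier removal** is single-pass by convention (mean/SD of the input
  series computed once); iterating the rule would remove more points and
  is intentionally not done.
* **KTA optimization**: centred kernel alignment of the weighted linear
  kernel, maximized by projected gradient ascent with backtracking
  (non-negative weights, unit L2 norm, tolerance 1e-6, ≤ 500 iterations,
  seeded initialization at the per-feature alignment scores). Because the
  centred alignment is exactly flat in how weight splits across duplicated
  columns, the selection step adds greedy correlation suppression
  (|r| > 0.95 to an already selected feature skips the candidate), so only
  one of a correlated pair is selected.
* **Cross-validation**: LOOCV treats one recording's feature vector as one
  sample; 10-fold CV is stratified by label (24 concerning samples in the
  simple task would otherwise produce single-class folds). Feature scaling
  is fit on training folds only. The F-score is F1 with *trustworthy*
  positive. The dimension sweep selects features once on the full data by
  default (`selection_mode="global"`); a `per-fold` mode re-selects inside
  every training fold for bias-free curves, at higher cost.
* **Fuzzy C-means**: fuzzifier m = 2, tolerance 1e-6, ≤ 300 iterations,
  seeded Dirichlet initialization; a singular within-cluster scatter is
  ridge-regularized (logged).
* **t-tests** are Welch (unequal variances and group sizes) with Bonferroni
  correction across the tested set, starred at corrected 1e-4 / 1e-3 / 0.05.
* **PCA** projects z-scored features (mixed units across cognitive and
  functional dimensions).
* **Trust labels**: NASA-TLX scores on the 0–20 tick scale; PL = 20 − PS
  and the strictly-greater PL > 11 rule (PL = 11 is concerning). The
  mental-demand score is carried as the task-complexity covariate.

## What the synthetic generators emulate — and what they do not

The study's recordings are not publicly deposited, so the package ships two
generators that reproduce the *statistical structure the analysis assumes*:

* The **feature-level** generator draws independent Gaussians per feature
  and group, calibrated so that every published key feature has exactly the
  printed group means and standard errors (SD = SE·√N at the published
  group sizes: 63/24 for the simple task, 43/40 for the complex one), with
  draws clipped to each feature's legal range. Non-key features have equal
  means in both groups. Background levels for unlisted features (e.g. ML
  ≈ 50 power units, CT 1800 ± 720 s per the reported 30 ± 12 min
  recordings, MW/E 0.5 ± 0.15) are fixed, documented choices. An optional
  correlation-matrix hook imposes published pairwise correlations when
  needed. One printed SE of 0.00 is floored at 0.005, the rounding bound
  of the two-decimal display.
* The **signal-level** generator mixes, per channel and band, a shared band
  oscillator with an independent phase random walk (convex weight g) plus
  white noise, so estimated Γ is ≈1 at g = 1, at the 1/√P floor at g = 0,
  and strictly increasing in between. Artifact injection adds raised-cosine
  frontal blink templates and supra-threshold spike runs at known times.

Neither generator attempts physiological realism (no 1/f spectra, volume
conduction, or electrode noise models). Because features are drawn
independently, synthetic classification accuracies are **upper-bound
analogues** of the real ones: the real feature space has strong
inter-feature correlations (engagement correlates −0.3…−0.6 with every key
feature) that the printed tables do not quantify. Two concrete consequences,
measured by the test suite:

* With independent features at the printed effect sizes (d ≈ 3–4 per strong
  feature), the accuracy-vs-dimension curve saturates at 100% by d ≈ 3, so
  the smallest-dimension-at-maximum rule settles at 2–3 features for both
  tasks. The complex task's reported nine-feature optimum therefore cannot
  emerge from this generator — the corresponding acceptance test documents
  and asserts the published value and fails honestly against the synthetic
  analogue, while the accuracy floors in the same experiment pass.
* Blink rate and asymmetry index are calibrated to small effects (d ≈ 0.8);
  their Bonferroni-corrected significance holds in roughly 55–70% of seeds,
  not near-always, and the unit tests assert corrected significance only
  for the seven strong functional features.

## Problem sizes and runtime

The simulation experiments average over 10 dataset seeds derived from one
base seed; dimension sweeps cover d = 2..15 under LOOCV; coupled-EEG
contract tests use 30–60 s two-channel recordings at 256 Hz. These sizes
make the full suite and the acceptance script each run in a few minutes on
one CPU while keeping every statistical check comfortably powered.

## Known limitations

* The blink detector is threshold-based and not a substitute for
  classifier- or regression-based ocular correction on real clinical EEG.
* Γ is undirected and volume-conduction-naïve (no lagged/imaginary
  coherence variants); this matches the construction it reproduces.
* Mental workload and engagement can only be supplied externally.
* Synthetic accuracies should be read as calibration checks of the
  pipeline, not as forecasts of performance on newly recorded data.
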