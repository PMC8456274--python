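# Methods

This note documents the statistical models, algorithms and design choices
behind `ldims`, module by module, together with the defaults and what the
bundled synthetic experiments do and do not demonstrate.

## Acquisition model (`ldims.simulate`)

A single laser shot of a subject's serum spot is modelled as

    I_shot(m) = Σ_i h_i · C · P_i · G(m; mz_i, σ) + chem(m) + b + ε(m)

* `h_i = 2^(log2 abundance)` — the subject's true apex intensity of feature
  *i*; control-class abundances are drawn once per panel
  (log2 ~ N(6.0, 0.7), so typical apexes sit near 60 intensity units and
  clear the downstream raw-intensity screen floor of 25), and biomarkers add
  a signed `effect_log2fc` in cases.
* `C` — a **shared** per-shot ionization-yield factor (lognormal, unit mean,
  CV `shot_cv_common`, default 4.0). Laser-to-sample coupling varies wildly
  shot to shot and multiplies every ion species in that shot; this shared
  component is why TIC-style normalization exists in MS practice.
* `P_i` — an independent per-peak lognormal factor (CV `shot_cv`, default
  0.35, scaled per feature by `ionization_cv`).
* `G` — unit-height Gaussian line shape (σ default 0.35 Da); line shape is a
  modelling choice, chosen because it is analytically checkable.
* `chem(m)` — Poisson-placed transient nuisance peaks whose heights scale
  with the shot-averaged detector-noise level (uniform 0.5–3.5 × that
  level). They are acquisition artifacts, not compounds: they average away
  with shots, and they are exactly the true negatives the S/N ≤ 3 screen
  exists to remove.
* `b`, `ε` — constant baseline (2.0) and additive detector noise
  (single-shot SD 6.0).

An `n_shots` acquisition is the mean of `n_shots` independent shots. Because
peak shapes are linear in per-shot heights, the simulator samples the
*shot-averaged* height factors and an exactly-distributed `N(0, σ/√n)`
detector term instead of materialising every shot; the distribution is
identical and the cost is O(grid + peaks × shots).

Consequences of the defaults, all verified by the test suite:

* apex CV across replicates = 13.4% at 1000 shots and 4.2% at 10,000 shots,
  decaying exactly as 1/√n (slope −0.5 on log-log axes);
* ~94% of the 1000-shot replicate variance is the shared yield component —
  removable in principle from a single spectrum — and ~6% is per-peak and
  irreducible;
* cohort defaults (effect_log2fc 0.25, between-subject CV 0.15 in the
  pipeline configuration) put single-replicate diagnosis in the regime where
  replicate noise visibly perturbs the classifier, which is the regime the
  stabilizer exists for. The operation-level default effect of 1.0 gives the
  clean strong-signal cohorts used for recovery experiments.

Feature centers are drawn uniformly with a minimum spacing (8 Da; 12 Da in
the binned pipeline) and a 2 Da edge margin so every line shape lies fully
inside the scanned range. Optional cation-adduct satellites (+21.98/+37.96
Da) are off by default. The generator does not model desorption physics,
isotope envelopes, mass-calibration drift, or MS/MS.

## SMP extraction (`ldims.preprocessing`)

* **Peak detection**: a grid point is a peak iff it has a full centered
  window (default 5 points), is the *strict* maximum of that window, and
  exceeds the global median intensity. Equivalent to an exhaustive O(n·w)
  scan (tested against one).
* **S/N**: `(apex − baseline) / noise_sigma`; baseline = median and
  noise_sigma = 1.4826 × MAD of the background region, i.e. points farther
  than 1.5 Da from every *strong* peak (apex > median + 3 robust SDs —
  weak local maxima are background texture and belong in the noise
  estimate). Zero noise yields a capped sentinel (1e6). When a spectrum is
  a denoised/stabilized version of a native acquisition, the caller may
  pass the native spectrum as `noise_reference`: denoising deflates the
  apparent noise floor without adding information, so significance is still
  judged against the acquisition's own noise. The pipeline does this for
  stabilized spectra; without it, smoothing ripples become spurious
  "features".
* **Filter**: peaks with S/N strictly greater than 3 are retained (S/N ≤ 3
  excluded; the boundary value 3.0 is excluded).
* **Alignment**: all surviving peaks are pooled and sorted by m/z; a new
  cluster starts when the gap to the previous peak exceeds the tolerance
  (default 0.1 Da; 1.5 bin widths in the binned pipeline). This is greedy
  single-linkage with a gap rule; since planted features are spaced far
  beyond the tolerance it coincides with width-capped clustering in
  practice. Consensus m/z is the intensity-weighted mean; a feature is kept
  only if present in ≥ `min_fraction` of spectra (0.5 by default, 0.85 in
  the pipeline); absent cells are imputed as 0 — absence is informative and
  the sparse learner needs a complete matrix. Clustering the globally
  sorted pool makes the result invariant to spectrum order.
* No TIC normalization by default (the biomarker screen's intensity
  restriction is stated in raw units); no baseline-wander correction or
  isotope handling.

## Deep stabilizer (`ldims.stabilizer`)

Topology (all sizes configurable):

* **Input representation** — intensities are divided by a robust scale
  (99th percentile of the training references) and presented as two
  channels: the raw spectrum and a *yield-normalized shape* (signal above
  the per-spectrum median, divided by the per-spectrum yield = mean of the
  top 1/16 excursions). The normalized channel makes the shared per-shot
  yield factor visible to translation-invariant convolutions.
* **Generator** — two parallel branches of dense blocks (default 2 blocks ×
  2 conv layers, growth 12, base width 8, kernel 9; the bundled experiments
  use kernel 5 / growth 8 for speed). The coarse branch predicts a residual
  on top of a *yield-corrected base reconstruction*
  `baseline + ycal · shape`, where `ycal` is the mean yield of the training
  references — the classical normalization the network then refines. The
  refinement branch emits a refinement signal and a sigmoid attention mask
  in [0, 1]; the fused output is `coarse + mask ⊙ refinement`, clipped to
  ≥ 0. Output heads are zero-initialized, so the untrained generator *is*
  the base reconstruction and training only moves away from it when that
  lowers the loss.
* **Discriminator** — three strided convolutions, global average pooling,
  linear logit; scores reference vs stabilized spectra (optionally
  conditioned on the input, off by default).
* **Losses** — generator: `1.0 × MAE(output, reference) + 0.01 ×
  non-saturating adversarial term`; discriminator: standard binary
  cross-entropy on (reference, stabilized-detached). Adam (lr 2–3e-3),
  batch 16. Inference is deterministic; the seed controls initialization
  and batch order only. Non-finite losses raise a training-diverged error
  naming the epoch.
* **Training pairs** — low member: one technical replicate (binned,
  default 512 bins over m/z 100–1000); high member: the mean of all of that
  sample's replicates, the high-shot-equivalent reference.
* The network operates on whole binned spectra, not on extracted feature
  vectors; SMP extraction is re-run on the stabilized spectra.

Everything runs on a ~350-line reverse-mode autodiff core
(`ldims.autodiff`): float32 tensors, hand-written vector-Jacobian products,
convolutions lowered to BLAS matmuls via shifted-slice stacking (the input
gradient is itself a correlation with the flipped kernel, so backward stays
in BLAS). Gradients are verified against central finite differences in the
test suite. Backward passes break their own closure cycles and an inference
mode skips graph construction, keeping memory flat over long runs.

What the synthetic experiments show: with ~200–320 training pairs and 12–20
epochs on one CPU, held-out reconstruction error falls well below the
identity baseline and the median per-feature replicate CV drops roughly
threefold (≈ 12% → 3–4%). What they do not show: performance on real
instrument data, where line shapes, baselines and noise couplings are
richer than this generator; transfer across instruments; or behaviour at
full 80,000-point resolution (supported via configuration, not routinely
exercised).

## Diagnosis (`ldims.diagnosis`)

* **Elastic net** — standardized logistic regression with combined L1+L2
  penalty (saga). With `cv_folds` set, the mixing parameter (0.1–1.0 by
  0.1) and penalty strength (5-point path) are selected by inner
  cross-validated AUC; with `cv_folds=None` a fixed (C, l1_ratio) is used —
  the ensemble fits use (0.5, 0.3) for stability, the sparse screening fits
  (0.3, 0.9).
* **OPLS-DA** — hand-written NIPALS: the requested number of
  class-orthogonal components is removed (orthogonal scores have exactly
  zero training correlation with the class), then one predictive PLS
  component is extracted; probabilities come from a univariate logistic
  link on the predictive score.
* **Metrics** — trapezoidal AUC; AUPRC by precision-recall step
  integration; operating point = ROC point nearest (0, 1) ("upper-left"),
  with Youden's J behind a flag; 95% CI by stratified percentile bootstrap
  (2000 resamples by default).
* **Cross-validation** — stratified k-fold (default 5) with out-of-fold
  pooling; any hyperparameter selection happens inside training folds.
* **Permutation test** — the full cross-validated-AUC pipeline is re-run on
  each of `n_perm` label permutations; `p = (1 + #{null ≥ observed}) /
  (n_perm + 1)`. Calibration (type-I error at nominal 0.05 within
  [0.02, 0.09]) is verified over 200 null cohorts in the acceptance suite.
* **Replicate ensemble** — each of `n_models` models draws one technical
  replicate per individual ("blinded inter-replication combinations"),
  fits the classifier, and records out-of-fold probabilities for every
  individual plus the nonzero-coefficient set. The fold partition is fixed
  across models so that model-to-model variation reflects the replicate
  draw — the quantity stabilization acts on — not partition randomness.
* **Biomarker screen** — a feature passes iff Welch-t p < 0.001 (pooled
  variance behind a flag; unadjusted for multiplicity, Bonferroni behind a
  flag), mean raw intensity > 25 in the enriched class, and hit frequency
  strictly > 60 per 100 ensemble fits. Zero-variance features get p = 1
  (equal means) or 0 and are flagged.

## MK surface (`ldims.mk`)

For n = 1..100: each model's threshold is the nth linear-interpolation
percentile of *its own* control probabilities (exclusive-rank conventions
can be layered on by the caller; the linear convention is the documented
default); patient labels are `prob > threshold` (strict, so the percentile
≈ specificity up to ties); specificity is the mean control-negative
fraction over models. The surface CV at n is, by default, the mean over
patients of the CV of that patient's predicted-label vector across models
("CV of probability as label instability"); the CV of per-model
sensitivities is available as an alternative mode, and the raw
(specificity, sensitivity, CV) rows are always exported so other
conventions can be applied downstream.

**VUS** integrates `cv(n) · mean_sensitivity(n)` against specificity by the
trapezoid rule along the percentile sweep — the volume of the CV sheet over
its (specificity, sensitivity) footprint. It is exactly 0 for a
zero-variance ensemble, equals the constant c for a constant-CV,
unit-sensitivity surface with specificity spanning [0, 1], and is invariant
to patient and model orderings. `select_threshold` returns the largest
percentile with CV strictly below the ceiling (default 10%), or None when
no percentile qualifies. Absolute VUS values depend on cohort size, model
count and noise level; only comparisons within a configuration (e.g.
native vs stabilized) are meaningful.

## Pipeline (`ldims.pipeline`)

`run_pipeline(config, mode)` executes simulation → binning → (optionally
stabilizer training + application) → SMP extraction → replicate-ensemble
diagnosis → screen → MK surface, writing feature matrices, surface tables,
screen reports, a checkpoint and a manifest (config hash, seed scheme) when
an output directory is set. Both modes share the binned domain and the same
simulated replicates, so the only difference between `no_stabilization`
("N") and `deep_stabilized` ("D") is the stabilizer. Stage seeds are
`(global_seed + fixed offset) mod 2^31`, with offsets recorded in the
manifest; reruns with the same config are byte-identical.

Default experiment scale — 14+14 subjects, 10 replicates × 1000 shots,
4096-point grid binned to 512, 30 ensemble models, 12 stabilizer epochs —
keeps a full two-mode comparison around 20 s on one CPU. These sizes are
the package's desk-scale defaults; every one of them is a config field.

The `ldims` command-line tool is a thin layer over these functions:
`simulate`, `extract`, `train-stabilizer`, `stabilize`, `fit`/`evaluate`,
`screen`, `mk-surface`, `run-all`, plus `--version` and `--cite`.

## Known limitations

* The acquisition model is a statistical surrogate validated by its
  documented CV-versus-shot-count behaviour, not a physical model of
  desorption/ionization.
* The stabilizer's benefit hinges on the existence of a shared noise
  component; on data whose replicate noise is purely feature-independent,
  no single-spectrum method can beat the identity map by much, and the
  honest expectation is parity.
* VUS magnitudes are configuration-specific and not comparable across
  cohort sizes or model counts.
* OPLS-DA is implemented with one predictive component and binary classes
  only, which is all the diagnosis task needs.
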