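# Methods

`drgquant` implements the quantitative core of a sensory-neuron joint-pain
study workflow: stimulus-locked calcium response calling in dorsal root
ganglion (DRG) recordings, marker co-expression quantification from
RNAscope-style per-cell calls and from single-cell count matrices, and the
behavioral/molecular endpoint derivations that precede inferential
statistics. A synthetic-data layer generates every input with full ground
truth, so each stage is testable without any external download.

## Calcium-response model

A recording is a framed fluorescence movie (or a per-ROI trace table)
acquired at 0.7 Hz: 30 force-free global baseline frames, then one epoch
per stimulus of 10 pre-stimulus, 10 application and 10 post-stimulus
frames. Defaults match a two-photon protocol with a 981.36 × 981.36 µm
field at 1.92 µm/pixel; all layout parameters are configurable through
`ImagingProtocol`.

For each neuron, F₀ is the mean raw fluorescence over the baseline period
and ΔF/F₀(t) = (F(t) − F₀)/F₀. A neuron is a **responder** to a stimulus
when its peak ΔF/F₀ within the 10-frame application window is strictly
greater than k = 4 times the standard deviation of baseline ΔF/F₀. Design
choices where the convention is genuinely open:

* **Baseline period** for both F₀ and the SD defaults to the 30-frame
  global force-free block (`baseline_mode="global"`); the 10-frame
  pre-stimulus block is available as `baseline_mode="prestim"`.
* **SD convention** is the sample SD (ddof = 1); ddof is exposed. Because
  ΔF/F₀ is an affine function of raw fluorescence, thresholding raw
  fluorescence at k·SD(raw) or ΔF/F₀ at k·SD(ΔF/F₀) gives the identical
  decision, so no separate "raw SD" mode is needed.
* **Strict inequality** at the threshold: a peak of exactly 4 SD is a
  non-responder.
* A numerical guard (`PEAK_ATOL = 1e-12`) keeps floating-point dust (~1
  ulp of ΔF/F₀ arising from averaging a perfectly constant baseline) from
  tripping the strict comparison when the baseline SD is exactly zero. It
  is irrelevant at any non-degenerate noise level.

With ΔF/F₀ noise that is i.i.d. N(0, σ²) and the true σ supplied as the
baseline SD, the rule's false-positive probability per 10-frame window is
1 − Φ(4)¹⁰ ≈ 3.17 × 10⁻⁴. `noise_false_positive_rate` checks this by
Monte-Carlo through the same vectorized decision used by `call_response`.
When the SD is instead *estimated* from 30 baseline frames, estimation
error inflates the empirical rate several-fold (to roughly 0.3–0.7% per
window at these frame counts); this is a property of the rule itself and
is visible in noisy end-to-end runs.

**Peak AUC.** The response size is the trapezoidal integral of ΔF/F₀ (in
ΔF/F₀·seconds, frame spacing 1/0.7 s) over the maximal contiguous run of
positive ΔF/F₀ frames containing the application-window peak. The run may
extend into the post-stimulus frames but is clipped at the epoch boundary
so it never bleeds into a neighbouring stimulus. Responder peak search
never looks outside the application window.

**Session summaries.** The total number of neurons imaged can be supplied
directly or extrapolated from a counted sub-region of average density
(`round(count × imaged_area / subregion_area)`, halves away from zero).
Percent responders is 100 × responses / total neurons. Responder soma
areas are summarized as relative-frequency histograms with default 100 µm²
bins from 0 to 2000 µm²; out-of-range areas fold into the end bins by
default so frequencies always sum to 1.

## Synthetic imaging sessions

`synth.generate_imaging_dataset` emulates the acquisition: per neuron,
fluorescence = F_base · (1 + ΔF/F₀ signal) + Gaussian noise with SD
`noise_sd · F_base` (so `noise_sd` is also the ΔF/F₀ noise SD).
Responder flags are per-stimulus Bernoulli draws; baselines and soma areas
are lognormal (area defaults span roughly 80–1,600 µm², i.e. diameters of
~10–45 µm, covering small nociceptors through large proprioceptors).

* **Transient kernel.** The default `kernel="sustained"` is a saturating
  rise (τ_rise = 0.2 s) toward a plateau held while the force is applied,
  followed by an exponential decay (τ_decay = 1.5 s, GCaMP6s-like) after
  release. This reflects the sustained 10-frame force application: at a
  0.7 Hz frame rate an impulse-shaped transient would concentrate almost
  all of its mass in a single frame, which is neither physiological for a
  held force nor useful for characterizing detection. A
  difference-of-exponentials `kernel="impulse"` is provided for brief
  events.
* **Amplitude convention.** Kernel samples are normalized so the maximum
  *sampled* ΔF/F₀ equals the configured amplitude; ground-truth amplitude
  is therefore exactly the noiseless peak ΔF/F₀.
* **Inter-stimulus recovery.** The transient is truncated at its epoch's
  end, mirroring a protocol that rests the animal between stimuli until
  fluorescence returns to baseline; no response bleeds across epochs.
* **Onset** is uniform over the first 3 application frames
  (`onset_jitter_frames`).
* **Determinism.** One seed per call; per-neuron RNG substreams are
  spawned from a `SeedSequence`, so a given neuron's trace does not
  depend on how many neurons follow it.
* **Stack rendering.** `render_stack` draws each neuron as a 2-D Gaussian
  blob (SD = soma radius/2) whose ROI is the soma disc, scaled so the
  ROI-mean equals the trace value; mean-ROI extraction of a noiseless,
  non-overlapping stack therefore reproduces the generating traces to
  numerical precision. Overlaps are allowed unless `forbid_overlap` is
  set. No optics, photobleaching or motion is simulated.

Default study conditions (responder probability 0.1 per stimulus, ΔF/F₀
noise SD 0.02, lognormal amplitudes with median 1.0 ΔF/F₀ floored at 0.2)
were chosen once as plausible values for awake-anesthetized DRG GCaMP6s
recordings; real recordings do not report these parameters, so they are
exposed in `SimConfig` rather than treated as calibrated constants.

## Marker co-expression

**Combination lattice.** With k probes, every counted neuron belongs to
exactly one of the 2^k positivity combinations (the all-negative class is
counted and reported as `none`). `classify_combinations` reports raw
counts and percent-of-whole; counts always partition the cell set.

**Nested aggregation.** Sectioned tissue is quantified per section,
sections are averaged within each animal (2–4 sections per animal is the
generator default), and the mean ± SEM (sample SD/√n) is taken across
animals. SEM is reported missing — never zero — when only one unit
exists. A `level="section"` mode treats sections as units directly.

**Diameter distributions.** Per-subset relative-frequency histograms plus
pairwise two-sample Kolmogorov–Smirnov comparisons (D = sup|ECDF₁ −
ECDF₂|, two-tailed asymptotic p-value via `scipy.stats.ks_2samp`). The
test suite verifies D against a brute-force double-loop ECDF oracle on
small samples.

**Count-matrix QC.** Cells are retained when n_features > 200 (genes with
count > 0, strict) and percent_mito < 15 (strict); covariates are always
recomputed from the matrix, never trusted from metadata. Mitochondrial
genes are identified by a configurable name prefix (default `mt-`) or an
explicit `var["is_mito"]` flag. The filter is idempotent and preserves
gene set and cell order. Normalization is ln(1 + 10,000 × count /
cell_total) — the standard library-size log-normalization, with both
constants configurable. A cell "expresses" a gene when its normalized
value is strictly greater than 0.1; co-expression fractions may be
conditioned on a marker gene (e.g. the fraction of Scn10a⁺ cells also
expressing Piezo2 and Ntrk1), and a raw-count thresholding flag exists for
sensitivity analysis. Clustering, UMAP and cluster annotation are
deliberately out of scope; co-expression operates on the filtered matrix
directly.

**Synthetic marker tables and matrices.** Both generators draw each
cell's combination from a configurable probability lattice. The default
RNAscope lattice is anchored to typical mouse lumbar-DRG quantification
(triple-positive 16%, Piezo2-only 27%, Scn10a∧Piezo2 38% of all
neurons); the default scRNA lattice is anchored so the Scn10a-conditioned
Piezo2∧Ntrk1 fraction is 38% (0.19/0.50). The count generator builds QC
structure constructively — passing cells get 350–900 detected genes and
2–10% mitochondrial counts; failing cells get 50–200 genes or 20–50%
mitochondrial counts — so the retained set is known exactly, not just in
expectation. Positive marker genes receive 1 + Poisson(2) counts; with
library sizes in the hundreds-to-thousands range, any count ≥ 1 exceeds
the 0.1 normalized threshold, so configured lattice probabilities are
also the ground-truth threshold co-expression fractions. What the
generators do **not** emulate: empty droplets and ambient RNA, doublets,
gene–gene count correlations beyond the marker lattice, overdispersion
structure of real UMI data, and segmentation error in RNAscope calls —
passing tests demonstrate correctness of the quantification rules, not
robustness to those artifacts.

## Behavioral and molecular endpoints

* **Swelling difference score**: post-injection minus baseline (mm),
  negatives allowed.
* **Time-course AUC**: trapezoidal integral of the raw measurements over
  the time axis, baseline point included, no baseline anchoring;
  `subtract_baseline=True` exposes the anchored alternative. The choice
  of days vs weeks on the time axis rescales the AUC linearly and is left
  to the caller's table.
* **Withdrawal thresholds** are log₁₀-transformed (base configurable).
* **Comparative CT**: ΔCT = CT_target − CT_reference per sample, ΔΔCT
  against the control-group mean ΔCT, fold change 2^(−ΔΔCT); the control
  group's fold changes have geometric mean 1 by construction.
* **Group summaries** report mean ± SEM (sample SD/√n; missing for
  n = 1). Inferential statistics (RM-ANOVA, post-tests, Mann–Whitney,
  t-tests) are delegated to standard statistical software; this package
  produces the tidy tables they consume.

The up-down (Dixon) 50% withdrawal-threshold estimator is an upstream
instrument procedure and is out of scope; tables arrive with thresholds
already estimated.

## Verification strategy and problem sizes

The test suite pins every operation to an independent oracle (hand
enumeration, closed forms, brute-force ECDF/trapezoid/binning loops, a
scanpy cross-check for normalization) and checks distributional
properties at sizes chosen for tight Monte-Carlo bounds at interactive
runtimes: 10⁶ noise windows for the specificity of the 4σ rule (3
binomial SEs ≈ 5 × 10⁻⁵), 300-neuron noiseless sessions for exact
recovery, 2,000-neuron sessions for ≥99% sensitivity at 6σ amplitudes,
7,500-cell marker tables and 2,000-cell count matrices for 3-SE parameter
recovery. `scripts/acceptance.py` re-runs all of these from scratch from
a single seed.

## Known limitations

* Responder calling assumes stimulus-locked epochs; spontaneous activity
  during the baseline inflates the SD and deflates sensitivity (by
  design, as in the thresholding rule itself).
* No motion correction, ROI segmentation, spike inference, or
  cross-session neuron matching.
* The KS p-value is asymptotic; for very small subsets the statistic is
  still exact but the p-value is approximate.
* Extrapolated neuron totals assume the counted sub-region has average
  density; the arithmetic, not the sampling design, is validated here.
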