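# Methods

`mechtox` implements an in vitro strategy for assessing drug hepatotoxicity
from untargeted LC–MS metabolomics of a hepatocyte-like cell model (HepG2):
data conditioning, a global toxicity classifier plus one-vs-all classifiers
for five hepatotoxicity mechanisms, VIP biomarker ranking, pathway-level
fingerprints, a Mantel-test meta-analysis of those fingerprints, and
per-concentration mechanism-participation ("radar") scoring of test
compounds. A synthetic-study generator with planted ground truth makes every
stage testable end to end without any external data.

## Study designs

Two designs are modelled. The *training* design incubates mechanism-labelled
hepatotoxicants (oxidative stress OS, mitochondrial disruption MI, apoptosis
APT, steatosis ST, cholestasis CHOL) at their IC10 and IC50 — the
concentrations reducing the MTT viability readout by 10% and 50%, obtained
by logit-curve interpolation — alongside non-toxic compounds at matched
concentrations, untreated controls and cell-free blanks, in quadruplicate
wells. The *test* design examines compounds blind at a fixed ladder of 1,
10, 100 and 1000 µM (capped by solubility). Both designs spread samples over
batches in randomized injection order, with a pooled QC sample injected
every 8 injections; every batch begins and ends with a QC.

`reference_compound_panel()` ships a curated 29-compound panel (25
hepatotoxicants, 4 non-toxic) with literature primary/secondary mechanisms
and IC10/IC50 values for realistic design construction; the demo pipeline
uses a balanced synthetic panel (5 single-mechanism compounds per mechanism
plus 9 non-toxic) so that every mechanism model has equally many positive
probes and the negative probes (~104) roughly balance the toxic probes, as
in a well-designed training campaign.

## Synthetic data model

Intensities are generated on the natural-log scale and exponentiated:

    log x = baseline_f + batch_{b,f} + drift_{b,f}(order) + treatment + ε

* **Baselines**: per-feature log-normal, `baseline_log_mean = 11.5`,
  `baseline_log_sd = 1.0` (arbitrary peak-area units). The feature panel
  (baselines, m/z, RT, annotation) has its own `assay_seed` so that training
  and test studies acquired "on the same assay" share it.
* **Within-batch drift**: per feature, a unit-variance Gaussian-process draw
  over injection order (squared-exponential kernel, length-scale
  `drift_smoothness = 20` injections) scaled by `drift_amplitude = 0.15`.
  Smooth by construction, hence recoverable by regression on injection
  order — the assumption behind QC-based support-vector drift correction.
* **Between-batch shifts**: per (batch, feature) normal log-offsets with
  `batch_scale_sd = 0.2`.
* **Noise**: i.i.d. log-normal with `rsd_noise = 0.15` (≈15% CV, routine for
  cellular LC–MS work).
* **Blanks** sit at `blank_fraction = 0.05` of baseline, so the 3×-blank
  background filter has known truth.
* **Dose–response**: each toxic compound carries two saturating
  log-logistic curves. The *cytotoxic* response is anchored at (IC10, 0.1)
  and (IC50, 0.5) — by definition of the MTT-derived ICs — and drives the
  shared general-toxicity signature and the protein decline. The
  *mechanism-specific* response is anchored at (IC10, 0.5) and (IC50, 0.9):
  mechanism-linked metabolic alterations (e.g. glutathione depletion under
  oxidative stress) precede overt cytotoxicity, which is exactly why the
  low toxic concentration is informative about mechanism while the IC50
  adds overlapping general-toxicity signal. Secondary mechanisms activate
  at `secondary_strength = 0.5` of the primary response.
* **Signatures**: each mechanism perturbs 12 disjoint marker features
  (directions mixed up/down, emulating e.g. GSH-like depletion and
  acetyl-polyamine-like accumulation), plus 15 shared general-toxicity
  markers. Effect sizes are expressed in units of `effect_reference_sd =
  0.15` log units (one within-condition SD at default noise); the default
  `effect_size = 3.0` therefore realizes ≈1.5 SD marker shifts at the IC10
  of the mechanism response and ≈2.7 SD at the IC50. The magnitudes are a
  package choice — no quantitative effect sizes exist to copy — selected so
  planted signatures are strong and clearly recoverable.
* **Protein content**: `protein_baseline × (1 − protein_decline ×
  cytotoxic activation)` with 3% CV; `protein_decline = 0.5` by default
  (moderate cell loss), so the 1/3-of-baseline exclusion rule only triggers
  when a study plants a stronger decline. Blanks report the baseline
  protein reading, which makes the stated blank-referenced exclusion rule
  exercisable literally.

One master seed drives every sub-stream; identical inputs reproduce a study
bit for bit.

What the generator deliberately does **not** emulate: chromatographic peak
shapes, m/z drift, missing-peak structure correlated with abundance,
correlated metabolite co-regulation, or compound-specific off-target
signatures. Passing tests therefore demonstrate that the pipeline recovers
truth under its own statistical assumptions, not that real studies will
reach the same figures.

## Data conditioning

Stage order is fixed: within-batch QC-SVR correction → between-batch ratio
correction → QC RSD filter → blank filter → low-protein exclusion →
autoscaling.

* **QC-SVRC**: per feature and batch, an RBF-kernel SVR of QC intensity on
  injection order; every sample is divided by the predicted drift at its
  injection order and re-scaled to the batch QC median. Hyperparameters are
  scale-free (the cited approach leaves them open): ε = median absolute
  deviation of the QC intensities, C = their range. Features with < 3
  usable QCs or a flat QC trace pass through unchanged and are flagged; a
  flat trace yields an exactly-identity correction.
* **Between-batch**: per feature, each batch is divided by (reference
  profile in that batch / reference in the first batch). The reference is
  the per-batch mean QC profile by default, or a named re-injected sample.
  Zero/undefined reference ratios flag the feature instead of dividing.
* **RSD filter**: RSD = 100·sd/mean over QC injections (pairwise-complete);
  features strictly above 30% are removed, as are features with > 50%
  missing QC values. "At least three-fold above blank" is inclusive
  (ratio ≥ 3 kept); both boundary conventions follow the stated rules
  literally.
* **Low-protein exclusion** removes treated samples below 1/3 of the mean
  baseline protein; the baseline selector defaults to blank samples (the
  stated criterion taken literally) with a `control` override, since blank
  wells are cell-free and their "protein" is a background reading.
* **Autoscaling** (mean-centre, unit sample SD) stores its parameters so
  test data are always scaled with training parameters; zero-variance
  columns are removed and reported.
* **IC interpolation**: viabilities are clipped to (0.001, 0.999),
  logit-transformed and interpolated piecewise-linearly against log10
  concentration; IC10/IC50 are the first crossings of viability 0.9/0.5.
  A least-squares logit line is fitted alongside and its slope/midpoint
  reported. Interpolation (rather than the LS line) is used for the ICs so
  curves that pass exactly through an anchor return it exactly;
  extrapolation beyond the tested range is flagged and warned.

## Discriminant models

The discriminant is a two-class PLS regression (y coded 1/0, centred)
fitted by NIPALS with X- and y-deflation on autoscaled data. Component
signs are canonicalized (largest-magnitude weight positive) so fits are
bit-reproducible. At full rank the fit equals ordinary least squares, which
the tests exploit as an oracle.

* **Assembly**: TOX contrasts all toxic-compound samples (both
  concentrations) against non-toxic-compound samples plus controls; each
  mechanism model is one-vs-all (positives: compounds with that primary
  mechanism; negatives: everything else usable). Compounds with secondary
  mechanisms count as positives only for their primary mechanism by
  default; a `dual_label` option adds them to both positive sets. No
  explicit "general-toxicity subtraction" exists; the one-vs-all contrast
  performs it implicitly, because general-toxicity signal is present in
  both classes.
* **Model complexity**: repeated (10×) stratified random 3-fold CV with
  re-autoscaling inside each training fold (leakage-free); the LV count
  minimizes the mean classification error (ŷ ≥ 0.5), ties toward fewer
  LVs; RMSECV is reported alongside.
* **ROC and threshold**: AUROC is the Mann–Whitney concordance probability
  (ties ½) of the out-of-fold scores, reported as mean ± sd over repeats;
  the decision threshold sits where the sensitivity and specificity curves
  intersect (linear interpolation between grid points, ties toward the
  lower threshold).
* **VIP**: VIP_j = sqrt(p·Σ_a SS_a w²_{aj} / Σ_a SS_a) with SS_a the
  y-variance explained by LV a; mean(VIP²) = 1 is asserted for every fit.
  Biomarkers are features with VIP > 1.5, signed by the mean autoscaled
  difference between classes.
* **Permutation testing**: the cross-validated AUROC is recomputed for B
  label permutations; p = (#{AUC_perm ≥ AUC_obs}+1)/(B+1), never zero.
  B = 200 in the full protocol; the permutation CV uses a single repeat by
  default to keep the null affordable.
* Models are trained on the annotated-metabolite subset of the filtered
  table, mirroring a campaign that identifies metabolites before
  modelling; the CHOL model is trained and reported but flagged
  non-validated — a HepG2-like system has very limited bile-acid synthesis
  and transport — and is excluded from the radar axes by default.

## Pathway fingerprints and meta-analysis

Per mechanism, annotated metabolites are Welch-t-tested against controls
(α = 0.05, unadjusted by default; Benjamini–Hochberg optional). Pathway
over-representation uses the hypergeometric upper tail of significant
members among the measured annotated background. The impact factor is the
sum of member importances (relative betweenness centrality within the
pathway graph, normalized to sum 1; uniform for graphs with < 3 edges; zero
when no graph exists). Pathways with more than 3 hits form the fingerprint;
the reportable subset additionally has p < 0.05 and impact > 0.01. The
hits filter is applied first — it is the analysis-inclusion rule.

Fingerprints are compared pairwise by a Mantel test: pathways become points
in the (−log10 p, impact) plane, Euclidean pathway–pathway distances form a
dissimilarity matrix per mechanism, lower triangles are unfolded and
Pearson-correlated (the Z_M score), and significance comes from jointly
permuting pathway labels of one matrix (B = 999 by default; one-sided for
positive association — both choices are package defaults, since no
permutation count or sidedness is prescribed for this stage). Pathways
absent from a fingerprint are imputed at the null point (p = 1, impact = 0)
with a warning; descriptors are used raw by default, with an optional
z-scaling because the two descriptors have unequal ranges.

## Test-compound scoring

Test tables are drift/batch-corrected, then scaled with the *training*
autoscaler (no test-set feature filtering — prediction needs the training
feature space). Low-protein wells are excluded first (reason "LP").
Replicate wells are averaged per compound × concentration before
thresholding; the mean ŷ of each model, clipped to [0, 1], is that axis's
toxicity index (clipping of a 0/1-coded discriminant is the minimal
realization of the 0–1 "participation" scale; min–max rescaling is offered
as an option). Binary calls use each model's CV-derived threshold. The
concordance summary reports, per concentration, the fraction of toxic
compounds whose literature (or planted) mechanism is among the positive
calls, and the fraction called TOX-positive.

## Problem sizes and numerical choices

The demo/acceptance study uses 500 features (200 annotated), 25 toxic + 9
non-toxic training compounds × 2 concentrations × 4 wells over 4 batches
(364 injections including QCs and blanks), a 25-compound test ladder, 20
background pathways plus one planted pathway per mechanism, B = 999 Mantel
permutations and 3 replicate studies for the Mantel false-positive summary.
These sizes were chosen to be study-realistic while keeping a full pipeline
run in the tens of seconds. Calibration checks run 200 null replicates at
B = 200.

Degenerate inputs are rejected rather than coerced: constant y, single-class
ROC, zero-variance distance triangles, empty backgrounds, all-viable/all-dead
dose-response curves. Missing intensities are excluded pairwise in means and
RSDs; model training requires complete data and offers feature-median
imputation (`missing="impute_median"`), since peak filling happens upstream
of this package.

## Known limitations

* The generator's nuisance model is simpler than real LC–MS data (see
  above); absolute performance figures on synthetic studies exceed what the
  same models achieve on real data.
* The error-rate LV-selection criterion degrades under strong class
  imbalance (a trivial always-majority classifier bounds the error); the
  balanced designs avoid this, but user-supplied designs should keep
  negative probes comparable in number to positives.
* Pathway impact requires topology; without graphs, impacts are zero and
  the p-value carries the fingerprint alone.
* The CHOL axis is constructed but should not be interpreted in HepG2-like
  systems.
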